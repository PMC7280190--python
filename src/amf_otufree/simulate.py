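"""Synthetic amplicon data with recorded ground truth.

The simulator emulates the study design this pipeline targets: pooled
454-style sequencing of ~700 bp LSU rDNA amplicons from soil AMF
communities, with five replicates of each of four groups (bulk soil Bs vs
root-associated soil Rs, crossed with two sampling times 1S/2S).  Reference
taxa are generated by mutating a common ancestor sequence; reads are drawn
multinomially from a per-sample composition, carry a 5' MID tag, and are
decorated with substitution errors and per-base Phred qualities.  A fraction
of reads are chimeric joins of two parent taxa, and a fraction are junk
reads each violating exactly one QC rule (short / low-quality / ambiguous
base) so QC sensitivity is attributable per rule.

Quality model: each base gets its own error probability p_b, lognormally
dispersed around the mean ``error_rate`` (E[p_b] = error_rate), and the
Phred value is Q_b = -10 log10(p_b).  Substitutions are then drawn per base
at p_b, so the quality string is consistent with the realized error process
while the mean Phred stays well above the error-rate-implied point value
(heterogeneous per-base quality is how real instruments behave).

Everything is reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import AmpliconRead

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_GENERA = ["Glomus", "Rhizophagus", "Septoglomus", "Archeospora", "Funneliformis"]


@dataclass
class SimulationTruth:
    """Ground truth for a simulated reference panel.

    ``taxa`` maps taxon name → amplicon sequence for every simulated taxon,
    including taxa deliberately *withheld* from the written reference FASTA
    (these emulate lineages absent from public databases and should surface
    as de novo groups).
    """

    seed: int
    length: int
    taxa: dict[str, str]
    withheld: frozenset[str]
    accessions: dict[str, str]

    @property
    def in_db(self) -> list[str]:
        return [t for t in self.taxa if t not in self.withheld]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    mask = rng.random(seq.shape[0]) < rate
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n)) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def simulate_reference(
    n_taxa: int,
    length: int = 700,
    divergence: float = 0.05,
    seed: int = 1,
    n_withheld: int = 0,
) -> SimulationTruth:
    """Simulate a panel of reference taxa diverged from a common ancestor.

    Each taxon mutates the ancestor independently at ``divergence``
    substitutions/site, so the expected pairwise identity between two taxa is
    (1-d)^2 + d^2/3.  ``n_withheld`` extra taxa are generated and recorded in
    the truth but meant to be left out of the written reference FASTA.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if not 0 < divergence < 0.5:
        raise ValueError("divergence must be in (0, 0.5)")
    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, 4, size=length).astype(np.uint8)
    taxa: dict[str, str] = {}
    accessions: dict[str, str] = {}
    withheld = []
    total = n_taxa + n_withheld
    for i in range(total):
        genus = _GENERA[i % len(_GENERA)]
        name = f"{genus} sp. SIM{i + 1:03d}"
        taxa[name] = _decode(_mutate(ancestor, divergence, rng))
        accessions[name] = f"SIM{i + 1:06d}"
        if i >= n_taxa:
            withheld.append(name)
    return SimulationTruth(
        seed=seed,
        length=length,
        taxa=taxa,
        withheld=frozenset(withheld),
        accessions=accessions,
    )


def write_reference_fasta(truth: SimulationTruth, path: str | Path) -> None:
    """Write the in-database taxa (withheld taxa excluded) as FASTA."""
    with open(path, "w") as fh:
        for name in truth.in_db:
            fh.write(f">{truth.accessions[name]} {name}\n{truth.taxa[name]}\n")


def make_mid_map(sample_ids: list[str], length: int = 8, seed: int = 1) -> dict[str, str]:
    """Distinct fixed-length MID tags per sample (equal length ⇒ prefix-free)."""
    rng = np.random.default_rng(seed)
    tags: set[str] = set()
    out = {}
    for sample in sample_ids:
        while True:
            tag = _decode(rng.integers(0, 4, size=length).astype(np.uint8))
            if tag not in tags:
                tags.add(tag)
                out[sample] = tag
                break
    return out


def vineyard_design(n_replicates: int = 5) -> pd.DataFrame:
    """The study's sample layout: soil (Bs/Rs) × time (1S/2S) × replicates."""
    rows = []
    for soil in ("Bs", "Rs"):
        for time in ("1S", "2S"):
            for rep in range(1, n_replicates + 1):
                rows.append((f"{soil}{time}-{rep}", soil, time, rep))
    return pd.DataFrame(
        rows, columns=["sample", "soil", "time", "replicate"]
    ).set_index("sample")


def study_compositions(
    truth: SimulationTruth,
    metadata: pd.DataFrame,
    seed: int = 1,
    decay: float = 0.35,
    fold_shift: tuple[str, str, str, float] | None = None,
    group_jitter: float = 0.30,
    withheld_share: float = 0.05,
) -> dict[str, dict[str, float]]:
    """Per-sample taxon probabilities with a rank-abundance profile.

    In-database taxa follow a geometric rank-abundance curve p_i ∝
    exp(-decay·i); each withheld taxon receives a fixed ``withheld_share`` of
    the in-database mass so database-absent lineages stay abundant enough to
    be observable.  Each soil×time group perturbs the baseline by a
    lognormal jitter (shared within the group) so groups differ
    compositionally; ``fold_shift = (taxon, column, level, fold)`` multiplies
    one taxon's probability by ``fold`` in samples whose metadata ``column``
    equals ``level``.
    """
    taxa = list(truth.taxa)
    in_db_rank = 0
    base = np.empty(len(taxa))
    in_db_total = sum(
        np.exp(-decay * i) for i in range(len(taxa) - len(truth.withheld))
    )
    for i, name in enumerate(taxa):
        if name in truth.withheld:
            base[i] = withheld_share * in_db_total
        else:
            base[i] = np.exp(-decay * in_db_rank)
            in_db_rank += 1
    rng = np.random.default_rng(seed)
    group_cols = [c for c in ("soil", "time") if c in metadata.columns]
    factors: dict[tuple, np.ndarray] = {}
    out: dict[str, dict[str, float]] = {}
    for sample, meta in metadata.iterrows():
        key = tuple(meta[c] for c in group_cols)
        if key not in factors:
            factors[key] = np.exp(rng.normal(0.0, group_jitter, size=len(taxa)))
        p = base * factors[key]
        if fold_shift is not None:
            taxon, column, level, fold = fold_shift
            if meta[column] == level:
                p[taxa.index(taxon)] *= fold
        p = p / p.sum()
        out[sample] = dict(zip(taxa, p))
    return out


def _quality_and_errors(
    codes: np.ndarray, error_rate: float, sigma: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-base qualities and substitution-mutated codes for one read."""
    L = codes.shape[0]
    if error_rate <= 0:
        return np.full(L, 40, dtype=np.int32), codes.copy()
    p = error_rate * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=L)
    p = np.clip(p, 1e-4, 0.75)
    quals = np.clip(np.rint(-10.0 * np.log10(p)), 2, 40).astype(np.int32)
    out = codes.copy()
    mask = rng.random(L) < p
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n)) % 4
    return quals, out


def _apply_indels(
    codes: np.ndarray, quals: np.ndarray, indel_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    L = codes.shape[0]
    del_mask = rng.random(L) < indel_rate / 2.0
    ins_mask = rng.random(L) < indel_rate / 2.0
    if not del_mask.any() and not ins_mask.any():
        return codes, quals
    seq_parts: list[np.ndarray] = []
    qual_parts: list[np.ndarray] = []
    for i in range(L):
        if ins_mask[i]:
            seq_parts.append(rng.integers(0, 4, size=1).astype(np.uint8))
            qual_parts.append(np.array([quals[i]], dtype=np.int32))
        if not del_mask[i]:
            seq_parts.append(codes[i : i + 1])
            qual_parts.append(quals[i : i + 1])
    if not seq_parts:
        return codes[:1], quals[:1]
    return np.concatenate(seq_parts), np.concatenate(qual_parts)


def simulate_reads(
    truth: SimulationTruth,
    compositions: dict[str, dict[str, float]],
    reads_per_sample: int | dict[str, int],
    mid_map: dict[str, str],
    error_rate: float = 0.005,
    indel_rate: float = 0.0,
    chimera_fraction: float = 0.05,
    junk_fraction: float = 0.10,
    quality_sigma: float = 2.0,
    seed: int = 1,
) -> tuple[list[AmpliconRead], pd.DataFrame]:
    """Simulate a multiplexed read pool plus a per-read ground-truth table.

    Returns the pooled reads (MID tags prepended, sample_id unassigned as in
    raw data) and a DataFrame with columns read_id / sample / category /
    taxon / parents / breakpoint, where category ∈ {normal, chimera,
    junk_short, junk_lowq, junk_ambiguous}.  Junk types are emitted in equal
    shares and each violates exactly one QC rule.
    """
    if not 0 <= chimera_fraction <= 1 or not 0 <= junk_fraction <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    if chimera_fraction + junk_fraction >= 1:
        raise ValueError("special-read fractions must sum to < 1")
    missing = set(compositions) - set(mid_map)
    if missing:
        raise ValueError(f"samples without MID tags: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    taxa_codes = {
        name: np.frombuffer(seq.encode(), dtype=np.uint8).copy() for name, seq in truth.taxa.items()
    }
    decode_map = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        decode_map[b] = i
    for name in taxa_codes:
        taxa_codes[name] = decode_map[taxa_codes[name]]

    reads: list[AmpliconRead] = []
    truth_rows = []
    junk_kinds = ("junk_short", "junk_lowq", "junk_ambiguous")
    junk_counter = 0
    for sample in sorted(compositions):
        comp = compositions[sample]
        names = list(comp)
        probs = np.array([comp[t] for t in names], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-8:
            raise ValueError(f"composition of {sample} does not sum to 1")
        n = reads_per_sample[sample] if isinstance(reads_per_sample, dict) else reads_per_sample
        mid = mid_map[sample]
        mid_codes = decode_map[np.frombuffer(mid.encode(), dtype=np.uint8)]
        u = rng.random(n)
        taxon_draws = rng.choice(len(names), size=n, p=probs)
        for i in range(n):
            read_id = f"{sample}_r{i:06d}"
            category = "normal"
            taxon: str | None = names[taxon_draws[i]]
            parents = ""
            breakpoint_ = -1
            if u[i] < junk_fraction:
                category = junk_kinds[junk_counter % 3]
                junk_counter += 1
            elif u[i] < junk_fraction + chimera_fraction:
                category = "chimera"
            if category == "chimera":
                a, b = rng.choice(len(names), size=2, replace=False)
                ca, cb = taxa_codes[names[a]], taxa_codes[names[b]]
                L = min(ca.shape[0], cb.shape[0])
                breakpoint_ = int(rng.integers(int(0.2 * L), int(0.8 * L) + 1))
                src = np.concatenate([ca[:breakpoint_], cb[breakpoint_:]])
                quals, codes = _quality_and_errors(src, error_rate, quality_sigma, rng)
                taxon = None
                parents = f"{names[a]}|{names[b]}"
            elif category == "junk_short":
                src = taxa_codes[taxon]
                L = int(rng.integers(50, 200))
                start = int(rng.integers(0, src.shape[0] - L + 1))
                codes = src[start : start + L].copy()
                quals = np.full(L, 35, dtype=np.int32)
            elif category == "junk_lowq":
                src = taxa_codes[taxon]
                quals = np.full(src.shape[0], 15, dtype=np.int32)
                codes = _mutate(src, 0.03, rng)
            elif category == "junk_ambiguous":
                src = taxa_codes[taxon]
                quals, codes = _quality_and_errors(src, error_rate, quality_sigma, rng)
            else:
                src = taxa_codes[taxon]
                quals, codes = _quality_and_errors(src, error_rate, quality_sigma, rng)
                if indel_rate > 0:
                    codes, quals = _apply_indels(codes, quals, indel_rate, rng)
            seq = _decode(codes)
            if category == "junk_ambiguous":
                n_amb = int(rng.integers(1, 4))
                pos = rng.choice(len(seq), size=min(n_amb, len(seq)), replace=False)
                chars = list(seq)
                for pidx in pos:
                    chars[pidx] = "N"
                    quals[pidx] = 2
                seq = "".join(chars)
            full_seq = mid + seq
            full_quals = np.concatenate([np.full(len(mid), 37, dtype=np.int32), quals])
            reads.append(AmpliconRead(read_id=read_id, sequence=full_seq, qualities=full_quals))
            truth_rows.append(
                (read_id, sample, category, taxon if taxon is not None else "", parents, breakpoint_)
            )
    truth_table = pd.DataFrame(
        truth_rows,
        columns=["read_id", "sample", "category", "taxon", "parents", "breakpoint"],
    )
    return reads, truth_table
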