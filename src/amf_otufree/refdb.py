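"""Curated reference database of primer-delimited LSU rDNA fragments.

The classification step of the pipeline compares every read against a
reference database of *univocal* (deduplicated) amplicon fragments: reference
LSU sequences are loaded from FASTA, entries whose taxon name says
"uncultured" are excluded, each remaining sequence is reduced in silico to
the fragment delimited by the amplification primer pair (IUPAC-aware exact
matching, primer sites excluded), and exact duplicate fragments are merged
into a single representative record.

Primer sequences are not shipped with the package: they are an input, to be
supplied via configuration alongside the reference FASTA.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: default header rule: accession, whitespace, then the taxon name
DEFAULT_HEADER_PATTERN = r"^(?P<accession>\S+)\s+(?P<taxon>.+\S)\s*$"


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse amplification primers, each 5'→3' on its own strand."""

    forward: str
    reverse: str

    def __post_init__(self):
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not p:
                raise ValueError(f"{name} primer is empty")
            bad = set(p.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"{name} primer has non-IUPAC codes: {sorted(bad)}")
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


@dataclass
class ReferenceRecord:
    """One univocal, primer-delimited reference fragment.

    ``merged_accessions`` lists every input accession whose fragment was
    identical to this one (the representative is the lexicographically
    smallest); ``source_span`` is the 0-based half-open interval of the
    fragment on its source sequence.
    """

    accession: str
    taxon_name: str
    sequence: str
    source_span: tuple[int, int] = (0, 0)
    merged_accessions: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty reference sequence")
        if "uncultured" in self.taxon_name.lower():
            raise ValueError("reference taxon names must not be 'uncultured'")
        if not self.merged_accessions:
            self.merged_accessions = (self.accession,)


def load_reference_fasta(
    path: str | Path,
    header_pattern: str = DEFAULT_HEADER_PATTERN,
    report: dict | None = None,
) -> list[tuple[str, str, str]]:
    """Load (accession, taxon_name, sequence) triples from a reference FASTA.

    Sequences are uppercased.  Records whose taxon name contains the token
    "uncultured" (case-insensitive) are excluded; headers that do not match
    ``header_pattern`` are skipped with a warning, never silently dropped.
    If ``report`` is a dict it is filled with counts
    (loaded / excluded_uncultured / skipped_unparseable).
    """
    pattern = re.compile(header_pattern)
    out: list[tuple[str, str, str]] = []
    n_uncultured = 0
    n_skipped = 0
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    for rec in records:
        m = pattern.match(rec.description)
        if not m:
            logger.warning("header %r matches no parsing rule; record skipped", rec.description)
            n_skipped += 1
            continue
        accession, taxon = m.group("accession"), m.group("taxon")
        if "uncultured" in taxon.lower():
            n_uncultured += 1
            continue
        out.append((accession, taxon, str(rec.seq).upper()))
    if not records:
        logger.warning("reference FASTA %s contains no records", path)
    if n_uncultured:
        logger.info("excluded %d 'uncultured' reference records", n_uncultured)
    if report is not None:
        report.update(
            loaded=len(out), excluded_uncultured=n_uncultured, skipped_unparseable=n_skipped
        )
    return out


def _iupac_regex(primer: str) -> re.Pattern:
    return re.compile("".join(f"[{IUPAC[c]}]" for c in primer.upper()))


def extract_amplicon(
    sequence: str,
    primers: PrimerPair,
    include_primers: bool = False,
) -> tuple[str, tuple[int, int]] | None:
    """In-silico PCR: the fragment delimited by the primer pair, or None.

    The forward primer is located on the plus strand (first hit) and the
    reverse-complement of the reverse primer downstream of it (nearest hit);
    matching is IUPAC-aware and exact (0 mismatches beyond degeneracy).  By
    default primer sites are excluded from the returned fragment, since the
    primer-annealing region is invariant by construction and should not
    reward classification identity.  Returns ``(fragment, (start, end))``
    with a 0-based half-open span on ``sequence``, or None when either site
    is absent.
    """
    seq = sequence.upper()
    fwd_re = _iupac_regex(primers.forward)
    rev_site_re = _iupac_regex(reverse_complement(primers.reverse))
    fwd_hits = list(fwd_re.finditer(seq))
    if not fwd_hits:
        return None
    if len(fwd_hits) > 1:
        logger.debug("forward primer matches %d times; using the first", len(fwd_hits))
    fwd = fwd_hits[0]
    rev = rev_site_re.search(seq, fwd.end())
    if rev is None:
        return None
    if include_primers:
        span = (fwd.start(), rev.end())
    else:
        span = (fwd.end(), rev.start())
    fragment = seq[span[0] : span[1]]
    if not fragment:
        return None
    return fragment, span


def deduplicate(records: list[ReferenceRecord]) -> list[ReferenceRecord]:
    """Exact-string deduplication into univocal records.

    One representative per identical fragment; the representative accession is
    the lexicographically smallest and every merged accession is retained in
    provenance.  Output order follows the representative accession.
    """
    by_seq: dict[str, list[ReferenceRecord]] = {}
    for rec in records:
        by_seq.setdefault(rec.sequence, []).append(rec)
    out = []
    for seq, group in by_seq.items():
        group = sorted(group, key=lambda r: r.accession)
        rep = group[0]
        out.append(
            ReferenceRecord(
                accession=rep.accession,
                taxon_name=rep.taxon_name,
                sequence=seq,
                source_span=rep.source_span,
                merged_accessions=tuple(r.accession for r in group),
            )
        )
    out.sort(key=lambda r: r.accession)
    return out


def build_reference_db(
    fasta_path: str | Path,
    primers: PrimerPair,
    header_pattern: str = DEFAULT_HEADER_PATTERN,
    include_primers: bool = False,
    report: dict | None = None,
) -> list[ReferenceRecord]:
    """Full curation: load → exclude uncultured → primer-delimit → dedup."""
    load_report: dict = {}
    raw = load_reference_fasta(fasta_path, header_pattern, report=load_report)
    records = []
    n_no_product = 0
    for accession, taxon, seq in raw:
        product = extract_amplicon(seq, primers, include_primers=include_primers)
        if product is None:
            n_no_product += 1
            continue
        fragment, span = product
        records.append(ReferenceRecord(accession, taxon, fragment, span))
    db = deduplicate(records)
    if report is not None:
        report.update(load_report, no_product=n_no_product, univocal=len(db))
    return db


def write_reference_db(db: list[ReferenceRecord], out_dir: str | Path) -> None:
    """Write the curated database as FASTA plus a TSV provenance table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "refdb.fasta", "w") as fa:
        for rec in db:
            fa.write(f">{rec.accession} {rec.taxon_name}\n{rec.sequence}\n")
    with open(out_dir / "refdb_provenance.tsv", "w") as tsv:
        tsv.write("accession\tmerged_accessions\ttaxon_name\tfragment_length\n")
        for rec in db:
            tsv.write(
                f"{rec.accession}\t{','.join(rec.merged_accessions)}\t"
                f"{rec.taxon_name}\t{len(rec.sequence)}\n"
            )


def read_reference_db(path: str | Path) -> list[ReferenceRecord]:
    """Read a curated database FASTA written by :func:`write_reference_db`."""
    out = []
    for acc, taxon, seq in load_reference_fasta(path):
        out.append(ReferenceRecord(acc, taxon, seq))
    return out
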