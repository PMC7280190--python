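"""Per-read taxonomic assignment without OTU clustering.

Every QC-passing read is aligned against the curated reference database and
labelled with the best-hit taxon when the hit reaches coverage ≥ 80% of the
read and identity ≥ 97% (both thresholds inclusive) — the species-level
criteria this pipeline classifies at.  Reads meeting the criteria against no
reference are checked for being chimeric joins of two reference taxa, and
the remainder are grouped among themselves with the same two thresholds:
connected components (single linkage) of the pairwise similarity relation,
each component becoming a "de novo" taxon.

Best-hit tie-breaking is a fixed chain (score, then identity, then coverage,
then accession) so runs are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .alignment import AlignmentHit, KmerIndex, align_pair
from .preprocess import AmpliconRead
from .refdb import ReferenceRecord

logger = logging.getLogger(__name__)

MIN_COVERAGE = 80.0
MIN_IDENTITY = 97.0


@dataclass(frozen=True)
class TaxonLabel:
    """Either a reference-derived ("known") taxon or a "de novo_k" group."""

    kind: str  # "known" | "de_novo"
    name: str

    def __post_init__(self):
        if self.kind not in ("known", "de_novo"):
            raise ValueError(f"bad label kind {self.kind!r}")


@dataclass
class Assignment:
    read_id: str
    sample_id: str
    label: TaxonLabel | None  # None = unclassified (chimera or noise)
    best_hit: AlignmentHit | None
    chimera_flag: bool = False


@dataclass
class DeNovoGroup:
    label: TaxonLabel
    member_ids: list[str]
    member_seqs: list[str]

    @property
    def representative(self) -> str:
        """Longest member sequence; ties broken by first occurrence."""
        best = self.member_seqs[0]
        for seq in self.member_seqs[1:]:
            if len(seq) > len(best):
                best = seq
        return best


def _hit_key(hit: AlignmentHit):
    # best hit: highest score, then identity, then coverage, then accession
    return (-hit.score, -hit.identity, -hit.coverage, hit.subject_accession)


def best_hit(
    seq: str,
    refdb: list[ReferenceRecord],
    index: KmerIndex | None = None,
    read_id: str = "",
    stop_at: tuple[float, float] | None = None,
) -> AlignmentHit | None:
    """Best-scoring local alignment of ``seq`` over the reference database.

    With ``index`` given, only the top k-mer-sharing references are aligned,
    inside a seeded diagonal band (the heuristic fast path), and ``stop_at =
    (min_cov, min_ident)`` allows returning as soon as the strongest-seeded
    candidate already satisfies both thresholds; without an index every
    reference is aligned with the exact full DP.
    """
    hits: list[AlignmentHit] = []
    if index is not None:
        for idx, _count, band in index.candidates(seq):
            rec = refdb[idx]
            hit = align_pair(seq, rec.sequence, read_id, rec.accession, band=band)
            if stop_at is not None and hit.meets(*stop_at):
                return hit
            hits.append(hit)
    else:
        for rec in refdb:
            hits.append(align_pair(seq, rec.sequence, read_id, rec.accession))
    if not hits:
        return None
    return min(hits, key=_hit_key)


def _record_of(refdb: list[ReferenceRecord], accession: str) -> ReferenceRecord:
    for rec in refdb:
        if rec.accession == accession:
            return rec
    raise KeyError(accession)


def _taxon_of(refdb: list[ReferenceRecord], accession: str) -> str:
    return _record_of(refdb, accession).taxon_name


def classify_known(
    read: AmpliconRead | str,
    refdb: list[ReferenceRecord],
    min_cov: float = MIN_COVERAGE,
    min_ident: float = MIN_IDENTITY,
    index: KmerIndex | None = None,
) -> Assignment:
    """Classify one read against the reference database.

    The label is known(taxon of the best hit) iff the best hit has coverage
    ≥ ``min_cov`` and identity ≥ ``min_ident`` (inclusive); otherwise the
    read is unclassified.  Raises ValueError on an empty database.
    """
    if not refdb:
        raise ValueError("reference database is empty")
    if isinstance(read, AmpliconRead):
        seq, read_id, sample_id = read.sequence, read.read_id, read.sample_id
    else:
        seq, read_id, sample_id = read, "", ""
    stop = (min_cov, min_ident) if index is not None else None
    hit = best_hit(seq, refdb, index=index, read_id=read_id, stop_at=stop)
    if hit is not None and hit.meets(min_cov, min_ident):
        taxon = _taxon_of(refdb, hit.subject_accession)
        return Assignment(read_id, sample_id, TaxonLabel("known", taxon), hit)
    return Assignment(read_id, sample_id, None, hit)


def flag_chimera(
    read: AmpliconRead | str,
    refdb: list[ReferenceRecord],
    min_cov: float = MIN_COVERAGE,
    min_ident: float = MIN_IDENTITY,
    grid_step: int = 50,
    central_frac: float = 0.6,
    index: KmerIndex | None = None,
    same_lineage_identity: float | None = 94.0,
) -> bool:
    """Bi-segment chimera test for a read that failed classification.

    The read is split at every breakpoint on a fixed grid (multiples of
    ``grid_step`` inside the central ``central_frac`` of the read); it is
    flagged chimeric iff some breakpoint yields two segments that each meet
    the (coverage, identity) criteria against two *different* reference
    taxa.  Intended for reads already unclassified by :func:`classify_known`
    (the full read meets the criteria against nothing).

    ``same_lineage_identity`` guards against calling a chimera between two
    reference entries that are themselves near-identical: when the two
    matched subjects align at or above this identity (at ≥60% coverage of
    the shorter), they are treated as one lineage and the breakpoint does
    not count.  Chimeras between such parents are unresolvable anyway;
    distinct species sit well below this bar.  Set None to disable.
    """
    seq = read.sequence if isinstance(read, AmpliconRead) else read
    L = len(seq)
    lo = (1.0 - central_frac) / 2.0
    first = int(-(-lo * L // grid_step)) * grid_step  # ceil to grid
    for b in range(max(first, grid_step), int((1.0 - lo) * L) + 1, grid_step):
        left, right = seq[:b], seq[b:]
        if len(left) < 20 or len(right) < 20:
            continue
        stop = (min_cov, min_ident) if index is not None else None
        hit_l = best_hit(left, refdb, index=index, stop_at=stop)
        if hit_l is None or not hit_l.meets(min_cov, min_ident):
            continue
        hit_r = best_hit(right, refdb, index=index, stop_at=stop)
        if hit_r is None or not hit_r.meets(min_cov, min_ident):
            continue
        rec_l = _record_of(refdb, hit_l.subject_accession)
        rec_r = _record_of(refdb, hit_r.subject_accession)
        if rec_l.taxon_name == rec_r.taxon_name:
            continue
        if same_lineage_identity is not None:
            a, b = rec_l.sequence, rec_r.sequence
            q, s = (a, b) if len(a) <= len(b) else (b, a)
            parents = align_pair(q, s)
            if parents.coverage >= 60.0 and parents.identity >= same_lineage_identity:
                continue
        return True
    return False


def _chimera_screen(
    seq: str,
    index: KmerIndex,
    stride: int = 4,
    min_frac: float = 0.4,
    end_frac: float = 0.2,
) -> bool:
    """Cheap k-mer screen: do the two read *ends* vote for different subjects?

    The outer ``end_frac`` segments lie outside the central breakpoint window,
    so each end belongs purely to one parent of a chimeric join.
    """
    end = max(int(end_frac * len(seq)), index.k + stride)
    if 2 * end > len(seq):
        return False
    votes = []
    for part in (seq[:end], seq[-end:]):
        cand = index.candidates(part, stride=stride, top_n=1)
        n_sampled = max(1, (len(part) - index.k) // stride + 1)
        if not cand or cand[0][1] < min_frac * n_sampled:
            return False
        votes.append(cand[0][0])
    return votes[0] != votes[1]


def sequence_relation(
    a: str,
    b: str,
    min_cov: float = MIN_COVERAGE,
    min_ident: float = MIN_IDENTITY,
    band: tuple[int, int] | None = None,
) -> bool:
    """The symmetric read-vs-read similarity relation for de novo grouping.

    Coverage is evaluated with the *shorter* sequence as the query, which
    makes the relation symmetric; at equal lengths the two orientations give
    the same coverage and the first is used.
    """
    if len(a) <= len(b):
        q, s = a, b
    else:
        q, s = b, a
        if band is not None:
            band = (-band[1], -band[0])  # diagonals flip with the orientation
    hit = align_pair(q, s, band=band)
    return hit.meets(min_cov, min_ident)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_de_novo(
    reads: list[tuple[str, str]],
    min_cov: float = MIN_COVERAGE,
    min_ident: float = MIN_IDENTITY,
    method: str = "auto",
    exact_limit: int = 300,
) -> list[DeNovoGroup]:
    """Group unassigned reads into de novo taxa by single linkage.

    ``reads`` is a list of (read_id, sequence).  Two reads are related when
    they meet both thresholds under :func:`sequence_relation`; groups are the
    connected components of that relation.  Labels "de novo_k" are assigned
    by descending group size, ties by first-read order.

    ``method``: "exact" evaluates every pair (the reference semantics);
    "indexed" links each read to existing groups through a k-mer index over
    group representatives (a fast approximation for large inputs); "auto"
    picks exact for n ≤ ``exact_limit``.
    """
    n = len(reads)
    if n == 0:
        return []
    if method == "auto":
        method = "exact" if n <= exact_limit else "indexed"
    uf = _UnionFind(n)
    if method == "exact":
        for i in range(n):
            for j in range(i + 1, n):
                if uf.find(i) == uf.find(j):
                    continue
                if sequence_relation(reads[i][1], reads[j][1], min_cov, min_ident):
                    uf.union(i, j)
    elif method == "indexed":
        index = KmerIndex([], k=11)
        rep_of: list[int] = []  # indexed-sequence position -> read index
        for i, (_rid, seq) in enumerate(reads):
            linked_roots: set[int] = set()
            for pos, _count, band in index.candidates(seq, top_n=8, min_share=4):
                j = rep_of[pos]
                root = uf.find(j)
                if root in linked_roots:
                    continue
                if sequence_relation(seq, reads[j][1], min_cov, min_ident, band=band):
                    uf.union(i, j)
                    linked_roots.add(uf.find(i))
            # index this read as a representative only if it starts a new
            # component (keeps posting lists short; members of an existing
            # component are all mutually ≥97% similar to their representative)
            if uf.find(i) == i:
                index.add(seq, len(rep_of))
                rep_of.append(i)
    else:
        raise ValueError(f"unknown method {method!r}")
    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(uf.find(i), []).append(i)
    ordered = sorted(components.values(), key=lambda m: (-len(m), m[0]))
    groups = []
    for k, members in enumerate(ordered, start=1):
        groups.append(
            DeNovoGroup(
                label=TaxonLabel("de_novo", f"de novo_{k}"),
                member_ids=[reads[i][0] for i in members],
                member_seqs=[reads[i][1] for i in members],
            )
        )
    return groups


def export_representatives(groups: list[DeNovoGroup], path: str | Path) -> None:
    """One representative (longest member, tie → first) per group, as FASTA."""
    with open(path, "w") as fh:
        for g in groups:
            fh.write(f">{g.label.name}\n{g.representative}\n")


def import_external_names(
    groups: list[DeNovoGroup], hit_table: dict[str, str]
) -> dict[str, str]:
    """Attach externally obtained names (e.g. from a BLAST of the exported
    representatives) to de novo groups without altering membership.

    ``hit_table`` maps group label → external name; labels not present keep
    their de novo name.  Unknown labels raise KeyError.
    """
    known_labels = {g.label.name for g in groups}
    unknown = set(hit_table) - known_labels
    if unknown:
        raise KeyError(f"hit table references unknown groups: {sorted(unknown)}")
    return {g.label.name: hit_table.get(g.label.name, g.label.name) for g in groups}


def _purge_chimeric_panel_entries(
    panel: list[ReferenceRecord],
    n_ref: int,
    min_cov: float,
    min_ident: float,
) -> bool:
    """Drop panel lineages that look chimeric against the rest of the panel.

    A chimera admitted before any pure read of one of its parents cannot be
    recognized at admission time; once the missing parent lineage joins the
    panel, the stale entry becomes detectable and must be removed — a panel
    containing two entries that share a parent would make every pure read of
    that parent look bi-segmental.  Iterates to a fixpoint; returns whether
    anything was removed.
    """
    any_removed = False
    removed = True
    while removed:
        removed = False
        for k in range(len(panel) - 1, n_ref - 1, -1):
            entry = panel[k]
            others = panel[:k] + panel[k + 1 :]
            idx = KmerIndex([r.sequence for r in others])
            if _chimera_screen(entry.sequence, idx) and flag_chimera(
                entry.sequence, others, min_cov, min_ident, index=idx
            ):
                del panel[k]
                removed = True
                any_removed = True
    return any_removed


def assign_reads(
    per_sample: dict[str, list[AmpliconRead]],
    refdb: list[ReferenceRecord],
    min_cov: float = MIN_COVERAGE,
    min_ident: float = MIN_IDENTITY,
    chimera_check: bool = True,
    use_index: bool = True,
    denovo_method: str = "auto",
    min_group_size: int = 1,
    panel_ident_relax: float = 3.0,
) -> tuple[list[Assignment], list[DeNovoGroup]]:
    """Full assignment stage over demultiplexed, QC-passing reads.

    Every read ends exactly one of: known, de novo, chimera-flagged, or
    unclassified noise (member of a de novo group smaller than
    ``min_group_size``).  De novo groups are global across samples.

    Chimera flagging runs against the reference database *plus* a panel of
    mutually dissimilar unclassified reads built on the fly: a chimera whose
    parents are absent from the database can only be recognized against the
    de novo lineages themselves, and unflagged chimeras of near-boundary
    breakpoints are exactly the reads that can spuriously bridge two de novo
    taxa under single linkage.  The panel admits a read only after it
    survives the chimera test; the test runs with its segment-identity bar
    relaxed by ``panel_ident_relax`` points so that error-laden chimeras —
    whose parent segments sit just below the classification threshold, and
    which would otherwise slip into the panel as spurious "lineages" — are
    still recognized.
    """
    if not refdb:
        raise ValueError("reference database is empty")
    index = KmerIndex([rec.sequence for rec in refdb]) if use_index else None
    panel: list[ReferenceRecord] = list(refdb)
    panel_index = KmerIndex([rec.sequence for rec in refdb])
    panel_counter = 0
    chim_ident = min_ident - panel_ident_relax
    assignments: dict[str, Assignment] = {}
    leftovers: list[tuple[str, str]] = []
    for sample in sorted(per_sample):
        for read in per_sample[sample]:
            asn = classify_known(read, refdb, min_cov, min_ident, index=index)
            asn.sample_id = sample
            if asn.label is None:
                is_chimera = False
                if chimera_check and _chimera_screen(read.sequence, panel_index):
                    is_chimera = flag_chimera(
                        read, panel, min_cov, chim_ident, index=panel_index
                    )
                if is_chimera:
                    asn.chimera_flag = True
                else:
                    leftovers.append((read.read_id, read.sequence))
                    # admit to the panel if unlike every panel lineage so far
                    novel = True
                    for pos, _c, band in panel_index.candidates(
                        read.sequence, top_n=4, min_share=4
                    ):
                        if sequence_relation(
                            read.sequence, panel[pos].sequence, min_cov, min_ident,
                            band=band,
                        ):
                            novel = False
                            break
                    if novel:
                        k = panel_counter
                        panel_counter += 1
                        panel.append(
                            ReferenceRecord(
                                f"PANEL{k:05d}", f"panel lineage {k}", read.sequence
                            )
                        )
                        if _purge_chimeric_panel_entries(
                            panel, len(refdb), min_cov, chim_ident
                        ):
                            panel_index = KmerIndex([r.sequence for r in panel])
                        else:
                            panel_index.add(read.sequence)
            assignments[read.read_id] = asn
    groups = cluster_de_novo(leftovers, min_cov, min_ident, method=denovo_method)
    kept_groups = []
    for g in groups:
        if len(g.member_ids) >= min_group_size:
            kept_groups.append(g)
            for rid in g.member_ids:
                assignments[rid].label = g.label
    logger.info(
        "assigned %d reads: %d de novo groups (%d kept)",
        len(assignments),
        len(groups),
        len(kept_groups),
    )
    return list(assignments.values()), kept_groups
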