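"""Samples × taxa count tables: building, rarefaction, filtering, Venn.

Counts are held as a pandas DataFrame (rows = samples, columns = taxa,
known and de novo labels side by side) with per-sample metadata (soil Bs/Rs,
sampling time 1S/2S, replicate index).  Sequencing effort is equalized by
rarefaction — random subsampling without replacement of every sample to a
common depth (7,000 by default, the study's normalization depth) — and taxa
are retained only when at least one replicate holds at least 10 of their
sequences, so that a taxon's presence cannot be explained by sequencing
error alone.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

RAREFACTION_DEPTH = 7000
MIN_REPLICATE_COUNT = 10


@dataclass
class AbundanceTable:
    counts: pd.DataFrame  # samples x taxa, non-negative integers
    metadata: pd.DataFrame  # index = samples; columns include soil/time/replicate

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if set(self.counts.index) != set(self.metadata.index):
            raise ValueError("sample set differs between counts and metadata")
        self.metadata = self.metadata.loc[self.counts.index]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def group_labels(self, columns: list[str] | str) -> pd.Series:
        if isinstance(columns, str):
            columns = [columns]
        return self.metadata[columns].astype(str).agg("".join, axis=1)


def build_table(assignments, metadata: pd.DataFrame) -> AbundanceTable:
    """Count labelled reads per (sample, taxon); chimera/unclassified excluded.

    ``assignments`` is the output of the assignment stage; taxon columns are
    ordered known labels first (alphabetically), then de novo labels by
    index.  Samples with zero classified reads keep an all-zero row.
    """
    rows = []
    for a in assignments:
        if a.label is not None:
            rows.append((a.sample_id, a.label.name, a.label.kind))
    df = pd.DataFrame(rows, columns=["sample", "taxon", "kind"])
    counts = (
        df.groupby(["sample", "taxon"]).size().unstack(fill_value=0)
        if len(df)
        else pd.DataFrame()
    )
    counts = counts.reindex(index=metadata.index, fill_value=0).fillna(0).astype(int)
    zero = counts.sum(axis=1) == 0
    if zero.any():
        logger.warning("samples with zero classified reads: %s", list(counts.index[zero]))
    known = sorted(c for c in counts.columns if not c.startswith("de novo_"))
    denovo = sorted(
        (c for c in counts.columns if c.startswith("de novo_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    return AbundanceTable(counts[known + denovo], metadata.copy())


def rarefy(
    table: AbundanceTable,
    depth: int = RAREFACTION_DEPTH,
    seed: int = 1,
    under_depth: str = "keep",
) -> AbundanceTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` follow ``under_depth``: "keep"
    (left untouched, with a warning — the default) or "error".  Reproducible
    under a fixed seed.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    if under_depth not in ("keep", "error"):
        raise ValueError(f"unknown under-depth policy {under_depth!r}")
    rng = np.random.default_rng(seed)
    out = table.counts.copy()
    for sample in out.index:
        row = out.loc[sample].to_numpy()
        total = int(row.sum())
        if total < depth:
            if under_depth == "error":
                raise ValueError(f"sample {sample} has {total} < depth {depth}")
            logger.warning("sample %s has %d < depth %d; kept as-is", sample, total, depth)
            continue
        if total > depth:
            out.loc[sample] = rng.multivariate_hypergeometric(row, depth)
    return AbundanceTable(out, table.metadata.copy())


def rarefaction_curve(sample_counts, depths) -> pd.Series:
    """Analytic expected richness E[S(d)] at each subsampling depth.

    E[S(d)] = Σ_t (1 − C(N−n_t, d) / C(N, d)) for a sample with taxon counts
    n_t summing to N.  Monotone non-decreasing in d; raises on d > N.
    """
    counts = np.asarray(sample_counts, dtype=np.int64)
    counts = counts[counts > 0]
    N = int(counts.sum())
    depths = np.atleast_1d(np.asarray(depths, dtype=np.int64))
    if (depths > N).any():
        raise ValueError("depth exceeds the sample total")
    if (depths < 0).any():
        raise ValueError("negative depth")

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    values = []
    for d in depths:
        keep = counts > N - d  # these taxa are certain to appear
        certain = int(keep.sum())
        rest = counts[~keep]
        if rest.size:
            miss = np.exp(log_choose(N - rest, d) - log_choose(N, d))
            values.append(certain + float(np.sum(1.0 - miss)))
        else:
            values.append(float(certain))
    return pd.Series(values, index=depths, name="expected_richness")


def filter_low_abundance(
    table: AbundanceTable, min_count: int = MIN_REPLICATE_COUNT
) -> AbundanceTable:
    """Keep a taxon iff some replicate holds at least ``min_count`` sequences.

    The criterion is inclusive and the filter only drops taxa columns, never
    samples; dropped taxa are logged.
    """
    keep = table.counts.max(axis=0) >= min_count
    dropped = list(table.counts.columns[~keep])
    if dropped:
        logger.info("low-abundance filter dropped %d taxa", len(dropped))
    return AbundanceTable(table.counts.loc[:, keep], table.metadata.copy())


def median_abundance(table: AbundanceTable, group_columns: list[str] | str) -> pd.DataFrame:
    """Per-taxon median count over replicates within each group level.

    Even replicate counts use the arithmetic-midpoint convention.  Returns a
    DataFrame indexed by group level with taxa as columns.
    """
    labels = table.group_labels(group_columns)
    return table.counts.groupby(labels).median()


def venn_partition(sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Counts of every exclusive region of a 2-4 set Venn partition.

    Region keys are the sorted tuples of set names whose intersection
    (minus all other sets) the region represents; region counts sum to the
    size of the union.
    """
    if not 2 <= len(sets) <= 4:
        raise ValueError("venn_partition supports 2 to 4 sets")
    names = sorted(sets)
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for included in itertools.combinations(names, r):
            region = set.intersection(*(sets[n] for n in included))
            for other in names:
                if other not in included:
                    region -= sets[other]
            out[included] = len(region)
    return out


def taxon_presence(table: AbundanceTable, group_columns: list[str] | str) -> dict[str, set]:
    """Per group level, the set of taxa with a nonzero count in any replicate."""
    labels = table.group_labels(group_columns)
    present = table.counts.groupby(labels).sum() > 0
    return {level: set(present.columns[present.loc[level]]) for level in present.index}


def write_counts_tsv(table: AbundanceTable, path) -> None:
    """Counts TSV with taxa as rows and samples as columns."""
    table.counts.T.to_csv(path, sep="\t", index_label="taxon")


def read_counts_tsv(path, metadata: pd.DataFrame) -> AbundanceTable:
    counts = pd.read_csv(path, sep="\t", index_col="taxon").T
    counts.index.name = None
    return AbundanceTable(counts.astype(int), metadata)
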