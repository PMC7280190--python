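"""Community statistics over the samples × taxa table.

Alpha diversity (observed richness, Shannon entropy in nats, Gini-Simpson),
beta diversity (Bray-Curtis dissimilarity, principal-coordinates analysis,
one-factor PERMANOVA with a permutation p-value), per-taxon two-group
Wilcoxon rank-sum comparisons with Benjamini-Hochberg adjustment (the
"heat tree" stage), and a LEfSe-style two-stage differential-abundance
analysis (Kruskal-Wallis screen, then a bootstrap linear-discriminant
effect size on the log10 scale).

Conventions, fixed here and flagged where alternatives exist:
"Simpson index" means Gini-Simpson 1 − Σ p_i² (inverse Simpson behind a
flag); Shannon uses natural log (base-2 flag); "adjusted p-value" means
Benjamini-Hochberg; PERMANOVA permutes raw labels, matching one-factor
designs.  All permutation machinery is reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .abundance import AbundanceTable

# -- alpha diversity ---------------------------------------------------------


def _props(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero count vector")
    return c / total


def observed_richness(counts) -> int:
    """Number of taxa with a nonzero count."""
    c = np.asarray(counts, dtype=float)
    if c.sum() == 0:
        raise ValueError("all-zero count vector")
    return int((c > 0).sum())


def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy H = −Σ p_i ln p_i (nats; pass ``base=2`` for bits)."""
    p = _props(counts)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base) if base else h


def simpson(counts, variant: str = "gini") -> float:
    """Simpson diversity: Gini-Simpson 1 − Σ p_i² (or ``variant="inverse"``)."""
    p = _props(counts)
    s = float((p**2).sum())
    if variant == "gini":
        return 1.0 - s
    if variant == "inverse":
        return 1.0 / s
    raise ValueError(f"unknown Simpson variant {variant!r}")


def alpha_diversity_table(table: AbundanceTable) -> pd.DataFrame:
    rows = {
        s: (
            observed_richness(table.counts.loc[s]),
            shannon(table.counts.loc[s]),
            simpson(table.counts.loc[s]),
        )
        for s in table.samples
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["observed_richness", "shannon", "simpson"]
    )


def alpha_group_test(values, groups, method: str = "kruskal") -> tuple[float, float]:
    """Group test of a per-sample diversity value (default Kruskal-Wallis).

    Requires ≥2 groups with ≥2 samples each.  When every value is identical
    the statistic is 0 and p is 1 (the maximal attainable).  ``method`` may
    be "kruskal" or "anova".
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    split = [values[groups == g] for g in levels]
    if any(len(s) < 2 for s in split):
        raise ValueError("every group needs at least two samples")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    if method == "kruskal":
        stat, p = sps.kruskal(*split)
    elif method == "anova":
        stat, p = sps.f_oneway(*split)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(stat), float(p)


# -- beta diversity ----------------------------------------------------------


@dataclass
class DistanceMatrix:
    data: np.ndarray
    ids: list[str]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        n = self.data.shape[0]
        if self.data.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if len(self.ids) != n:
            raise ValueError("id list length mismatch")
        if not np.allclose(self.data, self.data.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0):
            raise ValueError("distance matrix diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity Σ|x−y| / Σ(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative abundances")
    denom = float((x + y).sum())
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(table: AbundanceTable) -> DistanceMatrix:
    X = table.counts.to_numpy(dtype=float)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = bray_curtis(X[i], X[j])
    return DistanceMatrix(D, table.samples)


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # over positive eigenvalues only


def pcoa(dist: DistanceMatrix) -> PCoAResult:
    """Classical scaling: Gower-center −½D², eigendecompose, scale by √λ.

    Negative eigenvalues (possible for non-Euclidean dissimilarities like
    Bray-Curtis) are reported but excluded from the coordinates and from the
    %-variance denominator.
    """
    D = dist.data
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, abs(evals).max() * 1e-10) if n else 0.0
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    axes = [f"PC{i + 1}" for i in range(int(pos.sum()))]
    prop = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=dist.ids, columns=axes),
        eigenvalues=evals,
        proportion_explained=prop,
    )


@dataclass
class PermanovaResult:
    f_statistic: float
    r_squared: float
    p_value: float
    n_permutations: int


def permanova(
    dist: DistanceMatrix, labels, n_perm: int = 999, seed: int = 1
) -> PermanovaResult:
    """One-factor PERMANOVA (Anderson) with a label-permutation p-value.

    SS_total = Σ_{i<j} d²_ij / n; SS_within sums the analogous within-group
    terms; F = (SS_between/(g−1)) / (SS_within/(n−g)).  The p-value is
    (1 + #{permuted F ≥ observed F}) / (1 + n_perm) under raw label
    permutation, reproducible under ``seed``.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n != dist.data.shape[0]:
        raise ValueError("label length does not match the distance matrix")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    levels, codes = np.unique(labels, return_inverse=True)
    g = len(levels)
    if g < 2:
        raise ValueError("need at least two groups")
    D2 = dist.data**2
    iu = np.triu_indices(n, 1)
    ss_total = float(D2[iu].sum()) / n
    sizes = np.bincount(codes)

    def ss_within_batch(code_matrix: np.ndarray) -> np.ndarray:
        ssw = np.zeros(code_matrix.shape[0])
        for k in range(g):
            M = (code_matrix == k).astype(float)
            ssw += ((M @ D2) * M).sum(axis=1) / (2.0 * sizes[k])
        return ssw

    ssw_obs = float(ss_within_batch(codes[None, :])[0])
    ssa_obs = ss_total - ssw_obs
    f_obs = (ssa_obs / (g - 1)) / (ssw_obs / (n - g))
    r2 = ssa_obs / ss_total

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n), dtype=codes.dtype)
    for i in range(n_perm):
        perms[i] = codes[rng.permutation(n)]
    ssw_perm = ss_within_batch(perms)
    ssa_perm = ss_total - ssw_perm
    f_perm = (ssa_perm / (g - 1)) / (ssw_perm / (n - g))
    count = int((f_perm >= f_obs - 1e-12).sum())
    p = (1.0 + count) / (1.0 + n_perm)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm)


# -- differential abundance --------------------------------------------------


@dataclass
class DiffResult:
    """Per-taxon differential-abundance result.

    ``effect`` is a log2 median ratio for the Wilcoxon stage or a log10 LDA
    score for the LEfSe-style stage; ``enriched`` names the favoured group.
    """

    taxon: str
    statistic: float
    p_raw: float
    p_adj: float
    effect: float
    enriched: str = ""


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return sps.false_discovery_control(p, method="bh")


def _rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum: exact for n ≤ 8 per group, else normal
    approximation with tie correction."""
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return float(len(x) * len(y) / 2.0), 1.0
    method = "exact" if max(len(x), len(y)) <= 8 else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def per_taxon_wilcoxon(
    table: AbundanceTable,
    factor: str | list[str],
    levels: tuple[str, str] | None = None,
    alpha: float = 0.05,
) -> list[DiffResult]:
    """Per-taxon two-group Wilcoxon rank-sum comparison ("heat tree" stage).

    ``factor`` selects the metadata grouping; it must resolve to exactly two
    levels (or pass ``levels`` explicitly).  effect = log2((median_A + 1) /
    (median_B + 1)) for levels (A, B); significance is adjusted p < ``alpha``
    (Benjamini-Hochberg) — the adjusted p is reported, the caller applies
    the cutoff.
    """
    labels = table.group_labels(factor)
    if levels is None:
        found = sorted(labels.unique())
        if len(found) != 2:
            raise ValueError(f"factor has {len(found)} levels; pass `levels`")
        levels = (found[0], found[1])
    a_idx = labels[labels == levels[0]].index
    b_idx = labels[labels == levels[1]].index
    if len(a_idx) < 2 or len(b_idx) < 2:
        raise ValueError("each group needs at least two replicates")
    stats_, p_raw, effects, enriched = [], [], [], []
    for taxon in table.taxa:
        x = table.counts.loc[a_idx, taxon].to_numpy(dtype=float)
        y = table.counts.loc[b_idx, taxon].to_numpy(dtype=float)
        s, p = _rank_sum_test(x, y)
        med_a, med_b = float(np.median(x)), float(np.median(y))
        stats_.append(s)
        p_raw.append(p)
        effects.append(float(np.log2((med_a + 1.0) / (med_b + 1.0))))
        enriched.append(levels[0] if med_a >= med_b else levels[1])
    p_adj = bh_adjust(p_raw)
    return [
        DiffResult(t, stats_[i], p_raw[i], float(p_adj[i]), effects[i], enriched[i])
        for i, t in enumerate(table.taxa)
    ]


def lda_effect_size(
    table: AbundanceTable,
    class_factor: str | list[str],
    kw_alpha: float = 0.05,
    lda_cutoff: float = 1.0,
    n_boot: int = 30,
    scale: float = 1e6,
    seed: int = 1,
) -> list[DiffResult]:
    """LEfSe-style differential abundance: KW screen then bootstrap LDA score.

    Samples are scaled to a fixed total (``scale``, default 1e6).  Stage 1
    runs a per-taxon Kruskal-Wallis test across the classes and keeps taxa
    with BH-adjusted p < ``kw_alpha``.  Stage 2 fits, on each of ``n_boot``
    stratified bootstrap resamples, a linear discriminant over the retained
    taxa; a taxon's effect size is log10 of the largest absolute among-class
    difference of its discriminant-projected class means (floored at 1 so
    scores are non-negative), averaged over bootstraps.  Taxa with score ≥
    ``lda_cutoff`` are reported, with ``effect`` signed positive when the
    enriched class is the alphabetically first one (two-class designs).
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    labels = table.group_labels(class_factor)
    levels = sorted(labels.unique())
    if len(levels) < 2:
        raise ValueError("need at least two classes")
    sizes = labels.value_counts()
    if (sizes < 2).any():
        raise ValueError("every class needs at least two replicates")

    X = table.counts.to_numpy(dtype=float)
    row_tot = X.sum(axis=1, keepdims=True)
    row_tot[row_tot == 0] = 1.0
    X = X / row_tot * scale
    y = labels.to_numpy()
    taxa = table.taxa

    p_raw = np.ones(len(taxa))
    stat = np.zeros(len(taxa))
    for j in range(len(taxa)):
        split = [X[y == lv, j] for lv in levels]
        if np.ptp(X[:, j]) == 0:
            stat[j], p_raw[j] = 0.0, 1.0
        else:
            stat[j], p_raw[j] = sps.kruskal(*split)
    p_adj = bh_adjust(p_raw)
    retained = np.where(p_adj < kw_alpha)[0]
    if retained.size == 0:
        return []

    rng = np.random.default_rng(seed)
    Xr = X[:, retained]
    class_rows = {lv: np.where(y == lv)[0] for lv in levels}
    eff_sum = np.zeros(retained.size)
    n_ok = 0
    for _ in range(n_boot):
        idx = np.concatenate(
            [rng.choice(rows, size=rows.size, replace=True) for rows in class_rows.values()]
        )
        Xb, yb = Xr[idx], y[idx]
        if any((Xb[yb == lv].std(axis=0) == 0).all() for lv in levels):
            continue
        try:
            lda = LinearDiscriminantAnalysis(solver="svd")
            lda.fit(Xb, yb)
            w = lda.scalings_[:, 0]
        except Exception:
            continue
        norm = np.linalg.norm(w)
        if norm == 0 or not np.isfinite(norm):
            continue
        w = w / norm
        means = np.stack([Xb[yb == lv].mean(axis=0) for lv in levels])
        proj = means * w[None, :]  # per-feature contribution of class means
        diff = np.abs(proj[:, None, :] - proj[None, :, :]).max(axis=(0, 1))
        eff_sum += diff
        n_ok += 1
    if n_ok == 0:
        return []
    scores = np.log10(np.maximum(eff_sum / n_ok, 1.0))

    results = []
    for k, j in enumerate(retained):
        class_means = {lv: X[y == lv, j].mean() for lv in levels}
        top = max(class_means, key=class_means.get)
        score = float(scores[k])
        if score < lda_cutoff:
            continue
        effect = score if (len(levels) != 2 or top == levels[0]) else -score
        results.append(
            DiffResult(taxa[j], float(stat[j]), float(p_raw[j]), float(p_adj[j]), effect, top)
        )
    results.sort(key=lambda r: -abs(r.effect))
    return results
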