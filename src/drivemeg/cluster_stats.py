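"""Factorial statistics in source space.

Per-vertex two-factor (2 x 3) repeated-measures ANOVA, adjacency-based
spatial clustering of suprathreshold F maps with a within-subject
permutation null (max-cluster-mass distribution), and post-hoc machinery:
exact/approximate Wilcoxon signed-rank tests, Benjamini-Hochberg FDR,
percentile-bootstrap means with (optionally Bonferroni-corrected) CIs, and
Spearman rank correlation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse
import scipy.sparse.csgraph
import scipy.stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "FactorialDataset", "Cluster", "ClusterResult",
    "rm_anova_f", "spatial_clusters", "permutation_cluster_test",
    "wilcoxon_signed_rank", "fdr_bh", "bootstrap_mean_ci", "spearman_corr",
]

EFFECTS = ("main_workload", "main_valence", "interaction")

#: factor level index per condition cell, CONDITIONS order (workload-major)
_WORKLOAD_IDX = np.array([0, 0, 0, 1, 1, 1])
_VALENCE_IDX = np.array([0, 1, 2, 0, 1, 2])


@dataclass
class FactorialDataset:
    """Subjects x 6 conditions x vertices data in a 2 x 3 design."""

    power: np.ndarray
    condition_names: tuple = ("LW/LV", "LW/NV", "LW/HV",
                              "HW/LV", "HW/NV", "HW/HV")

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.ndim == 2:
            self.power = self.power[:, :, np.newaxis]
        if self.power.ndim != 3 or self.power.shape[1] != 6:
            raise ValueError("power must be (subjects, 6 conditions, vertices)")
        if np.isnan(self.power).any():
            raise ValueError("factorial design must have no missing cells")

    @property
    def n_subjects(self) -> int:
        return self.power.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.power.shape[2]


def rm_anova_f(dataset: FactorialDataset | np.ndarray) -> dict[str, np.ndarray]:
    """Two-factor within-subject ANOVA F maps, one value per vertex.

    Classical sums-of-squares decomposition with each effect tested against
    its own subject-by-effect interaction error term; degrees of freedom are
    (1, n-1) for workload, (2, 2(n-1)) for valence and the interaction.
    Vertices with zero error variance get F = +inf (flagged via a log entry).
    """
    if not isinstance(dataset, FactorialDataset):
        dataset = FactorialDataset(dataset)
    X = dataset.power
    n = dataset.n_subjects
    if n < 3:
        raise ValueError("need at least 3 subjects for the rmANOVA")
    a, b = 2, 3
    # reshape to (subjects, a, b, vertices)
    Y = X.reshape(n, a, b, -1)

    m = Y.mean(axis=(0, 1, 2))                    # grand mean per vertex
    m_s = Y.mean(axis=(1, 2))                     # (n, v)
    m_a = Y.mean(axis=(0, 2))                     # (a, v)
    m_b = Y.mean(axis=(0, 1))                     # (b, v)
    m_ab = Y.mean(axis=0)                         # (a, b, v)
    m_sa = Y.mean(axis=2)                         # (n, a, v)
    m_sb = Y.mean(axis=1)                         # (n, b, v)

    ss_a = n * b * ((m_a - m) ** 2).sum(axis=0)
    ss_b = n * a * ((m_b - m) ** 2).sum(axis=0)
    ss_ab = n * ((m_ab - m_a[:, None, :] - m_b[None, :, :]
                  + m) ** 2).sum(axis=(0, 1))
    ss_as = b * ((m_sa - m_a[None] - m_s[:, None] + m) ** 2).sum(axis=(0, 1))
    ss_bs = a * ((m_sb - m_b[None] - m_s[:, None] + m) ** 2).sum(axis=(0, 1))
    resid = (Y - m_ab[None] - m_sa[:, :, None] - m_sb[:, None]
             + m_a[None, :, None] + m_b[None, None] + m_s[:, None, None] - m)
    ss_abs = (resid ** 2).sum(axis=(0, 1, 2))

    def f_ratio(ss_eff, df_eff, ss_err, df_err):
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss_eff / df_eff) / (ss_err / df_err)
        zero_err = ss_err <= 0
        if zero_err.any():
            logger.warning("zero error variance at %d vertices; F set to inf",
                           int(zero_err.sum()))
            F = np.where(zero_err, np.inf, F)
            F = np.where(zero_err & (ss_eff <= 0), 0.0, F)
        return F

    return {
        "main_workload": f_ratio(ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        "main_valence": f_ratio(ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        "interaction": f_ratio(ss_ab, (a - 1) * (b - 1), ss_abs,
                               (a - 1) * (b - 1) * (n - 1)),
    }


def effect_dfs(effect: str, n_subjects: int) -> tuple[int, int]:
    """Numerator/denominator degrees of freedom of one rmANOVA effect."""
    n = n_subjects
    return {
        "main_workload": (1, n - 1),
        "main_valence": (2, 2 * (n - 1)),
        "interaction": (2, 2 * (n - 1)),
    }[effect]


@dataclass
class Cluster:
    vertices: np.ndarray
    mass: float
    p_value: float = np.nan


@dataclass
class ClusterResult:
    effect: str
    clusters: list[Cluster]
    threshold: float
    n_permutations: int
    seed: int | None = None
    null_max_mass: np.ndarray = field(default=None, repr=False)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < alpha]

    def to_dict(self) -> dict:
        return {
            "effect": self.effect,
            "threshold": self.threshold,
            "n_perm": self.n_permutations,
            "seed": self.seed,
            "clusters": [
                {"vertices": c.vertices.tolist(), "mass": c.mass,
                 "p": c.p_value} for c in self.clusters
            ],
        }


def spatial_clusters(stat_map: np.ndarray, adjacency, threshold: float
                     ) -> list[Cluster]:
    """Connected components of the suprathreshold vertex set.

    Cluster mass is the sum of the statistic over the component's vertices.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    stat_map = np.asarray(stat_map, dtype=float)
    supra = np.flatnonzero(stat_map > threshold)
    if supra.size == 0:
        return []
    adjacency = scipy.sparse.csr_matrix(adjacency)
    sub = adjacency[np.ix_(supra, supra)]
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        sub, directed=False)
    clusters = []
    for comp in range(n_comp):
        verts = supra[labels == comp]
        clusters.append(Cluster(vertices=verts,
                                mass=float(stat_map[verts].sum())))
    clusters.sort(key=lambda c: -c.mass)
    return clusters


def permutation_cluster_test(
    dataset: FactorialDataset | np.ndarray,
    adjacency,
    effect: str,
    n_permutations: int = 5000,
    cluster_alpha: float = 0.05,
    seed: int | None = None,
    scheme: str = "full",
) -> ClusterResult:
    """Within-subject permutation test of cluster mass for one effect.

    The cluster-forming threshold is the parametric F quantile at
    ``1 - cluster_alpha`` for the effect's degrees of freedom (the per-vertex
    "p < .05" threshold).  The null distribution collects, per permutation,
    the maximum cluster mass after independently re-labelling the six
    condition cells within every subject (``scheme="full"``: all 6!
    re-orderings; ``scheme="factor"`` restricts shuffles to the tested
    factor's levels).  Cluster p-values use the positively biased estimator
    ``(1 + #{null >= observed}) / (1 + n_permutations)``; the omnibus F is
    one-sided (large values only).
    """
    if effect not in EFFECTS:
        raise ValueError(f"effect must be one of {EFFECTS}")
    if not isinstance(dataset, FactorialDataset):
        dataset = FactorialDataset(dataset)
    if n_permutations < 100:
        logger.warning("n_permutations=%d is very low; p-values will be "
                       "coarse", n_permutations)
    rng = np.random.default_rng(seed)
    n = dataset.n_subjects
    df1, df2 = effect_dfs(effect, n)
    threshold = float(scipy.stats.f.ppf(1.0 - cluster_alpha, df1, df2))

    observed_F = rm_anova_f(dataset)[effect]
    clusters = spatial_clusters(observed_F, adjacency, threshold)

    null_max = np.zeros(n_permutations)
    X = dataset.power
    for p in range(n_permutations):
        perm = np.empty_like(X)
        for s in range(n):
            order = _permute_cells(rng, scheme, effect)
            perm[s] = X[s, order]
        F = rm_anova_f(FactorialDataset(perm))[effect]
        perm_clusters = spatial_clusters(F, adjacency, threshold)
        if perm_clusters:
            null_max[p] = perm_clusters[0].mass

    for c in clusters:
        c.p_value = (1.0 + np.sum(null_max >= c.mass)) / (1.0 + n_permutations)

    return ClusterResult(effect=effect, clusters=clusters,
                         threshold=threshold, n_permutations=n_permutations,
                         seed=seed, null_max_mass=null_max)


def _permute_cells(rng, scheme: str, effect: str) -> np.ndarray:
    if scheme == "full":
        return rng.permutation(6)
    if scheme != "factor":
        raise ValueError("scheme must be 'full' or 'factor'")
    order = np.arange(6)
    if effect == "main_workload":
        # swap workload levels per valence column, keeping valence intact
        for v in range(3):
            if rng.integers(2):
                order[[v, v + 3]] = order[[v + 3, v]]
    else:
        # permute valence levels, same permutation within each workload row
        pv = rng.permutation(3)
        order = np.concatenate([pv, pv + 3])
    return order


def wilcoxon_signed_rank(x, y=None, alternative: str = "two-sided"
                         ) -> tuple[float, float]:
    """Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; ties are mid-ranked.  For n <= 12
    remaining pairs the null is enumerated exactly over all 2^n sign
    patterns; larger samples use the normal approximation with tie and
    continuity corrections.  Returns ``(W+, p)`` where W+ is the sum of
    ranks of positive differences.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n < 5:
        raise ValueError("need at least 5 non-zero differences")
    if alternative not in {"two-sided", "greater", "less"}:
        raise ValueError(f"unknown alternative {alternative!r}")

    ranks = scipy.stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())

    if n <= 12:
        sums = np.zeros(1)
        for r in ranks:  # distribution of W+ over all sign assignments
            sums = np.concatenate([sums, sums + r])
        total = sums.size
        if alternative == "greater":
            p = np.sum(sums >= w_pos - 1e-12) / total
        elif alternative == "less":
            p = np.sum(sums <= w_pos + 1e-12) / total
        else:
            p_hi = np.sum(sums >= w_pos - 1e-12) / total
            p_lo = np.sum(sums <= w_pos + 1e-12) / total
            p = min(1.0, 2.0 * min(p_hi, p_lo))
        return w_pos, float(p)

    mu = n * (n + 1) / 4.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - \
        (tie_counts ** 3 - tie_counts).sum() / 48.0
    sd = np.sqrt(var)
    if alternative == "greater":
        z = (w_pos - mu - 0.5) / sd
        p = scipy.stats.norm.sf(z)
    elif alternative == "less":
        z = (w_pos - mu + 0.5) / sd
        p = scipy.stats.norm.cdf(z)
    else:
        z = (abs(w_pos - mu) - 0.5) / sd
        p = 2.0 * scipy.stats.norm.sf(z)
    return w_pos, float(min(p, 1.0))


def fdr_bh(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR: (rejection mask, adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def bootstrap_mean_ci(values, n_iter: int = 5000, alpha: float = 0.05,
                      bonferroni_m: int = 1, seed: int | None = None
                      ) -> tuple[float, float, float]:
    """Percentile bootstrap of the mean over subject resamples.

    CI percentiles sit at ``(alpha / bonferroni_m) / 2`` in each tail, so
    ``bonferroni_m > 1`` widens the interval for multiple displayed
    contrasts.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        raise ValueError("need at least 3 values to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_iter, n))
    means = values[idx].mean(axis=1)
    tail = (alpha / bonferroni_m) / 2.0 * 100.0
    lo, hi = np.percentile(means, [tail, 100.0 - tail])
    return float(values.mean()), float(lo), float(hi)


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation (Pearson on mid-ranks, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need two equal-length samples with n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined rank correlation")
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)


def pairwise_condition_contrasts(values_by_condition: dict[str, np.ndarray],
                                 alpha: float = 0.05,
                                 n_boot: int = 5000,
                                 seed: int | None = None):
    """All pairwise signed-rank contrasts of per-subject condition values,
    BH-FDR corrected, with bootstrap mean/CI per condition.

    Returns ``(contrast rows, condition summary rows)`` as lists of dicts.
    """
    conds = list(values_by_condition)
    pairs = list(itertools.combinations(conds, 2))
    rows = []
    for a, b in pairs:
        stat, p = wilcoxon_signed_rank(values_by_condition[a],
                                       values_by_condition[b])
        diff = np.mean(values_by_condition[a] - values_by_condition[b])
        rows.append({"a": a, "b": b, "statistic": stat, "p": p,
                     "mean_diff": float(diff)})
    if rows:
        reject, p_adj = fdr_bh([r["p"] for r in rows], alpha=alpha)
        for r, rej, pa in zip(rows, reject, p_adj):
            r["p_fdr"] = float(pa)
            r["significant"] = bool(rej)
    summaries = []
    rng = np.random.default_rng(seed)
    for c in conds:
        mean, lo, hi = bootstrap_mean_ci(
            values_by_condition[c], n_iter=n_boot, alpha=alpha,
            bonferroni_m=max(len(pairs), 1),
            seed=int(rng.integers(2 ** 31)))
        summaries.append({"condition": c, "mean": mean, "ci_low": lo,
                          "ci_high": hi})
    return rows, summaries
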