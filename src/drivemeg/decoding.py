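"""Multiclass CSP + LDA decoding of experimental condition from
band-limited sensor epochs, with cross-validated evaluation, Haufe
activation-pattern extraction, source localization of patterns,
F1-weighted grand averages, and percentile-ROI condition contrasts.

The multiclass common-spatial-patterns variant whitens the class
covariances by the grand-average covariance and approximately jointly
diagonalizes them with orthogonal Jacobi rotations
(Cardoso-Souloumiac); components are ranked by the between-class
dispersion of their log-variances and the top ``n_components`` retained.
Features are log-variances of the filtered epochs; classification uses a
least-squares-solver LDA with Ledoit-Wolf-shrunk covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np
from sklearn.covariance import LedoitWolf
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix, f1_score
from sklearn.model_selection import RepeatedStratifiedKFold

from .cluster_stats import bootstrap_mean_ci, fdr_bh, wilcoxon_signed_rank
from .source import InverseOperator, apply_inverse

__all__ = [
    "CSPModel", "DecodingResult", "PatternMap",
    "ledoit_wolf_cov", "fit_multiclass_csp", "csp_features",
    "lda_fit", "lda_predict", "crossval_decode", "haufe_patterns",
    "localize_patterns", "weighted_grand_average", "percentile_roi_contrast",
]


@dataclass
class CSPModel:
    """Fitted multiclass CSP: extraction filters and bookkeeping."""

    filters: np.ndarray            # (n_components, n_channels)
    scores: np.ndarray             # ranking criterion per kept component
    class_covs: np.ndarray         # (n_classes, n_ch, n_ch), Ledoit-Wolf
    classes: np.ndarray
    n_components: int = 4


@dataclass
class DecodingResult:
    fold_f1: np.ndarray            # (n_folds,)
    mean_f1: float
    ci_low: float
    ci_high: float
    confusion: np.ndarray          # (n_classes, n_classes) pooled counts
    classes: np.ndarray
    patterns: np.ndarray           # (n_channels, n_components) fold-averaged
    fold_scheme: str
    seed: int | None


@dataclass
class PatternMap:
    """Source-space pattern magnitudes, one map per CSP component."""

    values: np.ndarray             # (n_components, n_vertices)
    normalization: str = "raw"     # "raw" | "rescaled01"
    f1_weights: np.ndarray | None = None


def ledoit_wolf_cov(data: np.ndarray) -> np.ndarray:
    """Ledoit-Wolf shrinkage covariance of (channels, samples) data or of
    stacked epochs (n_epochs, channels, samples)."""
    X = np.asarray(data, dtype=float)
    if X.ndim == 3:
        X = np.concatenate(list(X), axis=1)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    return LedoitWolf().fit(X.T).covariance_


@numba.njit(cache=False)
def _ajd_kernel(A: np.ndarray, n_iter: int, tol: float) -> np.ndarray:
    k, n, _ = A.shape
    V = np.eye(n)
    for _ in range(n_iter):
        max_s = 0.0
        for i in range(n - 1):
            for j in range(i + 1, n):
                g11 = 0.0
                g12 = 0.0
                g22 = 0.0
                for m in range(k):
                    h1 = A[m, i, i] - A[m, j, j]
                    h2 = A[m, i, j] + A[m, j, i]
                    g11 += h1 * h1
                    g12 += h1 * h2
                    g22 += h2 * h2
                # principal eigenvector of [[g11, g12], [g12, g22]]
                phi = 0.5 * np.arctan2(2.0 * g12, g11 - g22)
                x = np.cos(phi)
                y = np.sin(phi)
                if x < 0.0:
                    x, y = -x, -y
                c = np.sqrt((x + 1.0) / 2.0)
                s = y / np.sqrt(2.0 * (x + 1.0))
                if abs(s) < tol:
                    continue
                if abs(s) > max_s:
                    max_s = abs(s)
                for m in range(k):
                    for col in range(n):
                        ai = A[m, i, col]
                        aj = A[m, j, col]
                        A[m, i, col] = c * ai + s * aj
                        A[m, j, col] = -s * ai + c * aj
                    for row in range(n):
                        ai = A[m, row, i]
                        aj = A[m, row, j]
                        A[m, row, i] = c * ai + s * aj
                        A[m, row, j] = -s * ai + c * aj
                for row in range(n):
                    vi = V[row, i]
                    vj = V[row, j]
                    V[row, i] = c * vi + s * vj
                    V[row, j] = -s * vi + c * vj
        if max_s < tol:
            break
    return V


def _ortho_ajd(mats: np.ndarray, n_iter: int = 30, tol: float = 1e-7
               ) -> np.ndarray:
    """Orthogonal approximate joint diagonalization (Jacobi rotations).

    Given symmetric matrices ``mats`` (k, n, n), finds the rotation V
    maximizing the summed squared diagonals of V^T A_k V, sweeping Givens
    rotations with the closed-form Cardoso-Souloumiac angle (the principal
    eigenvector of the 2x2 pair-interaction matrix).  Sweeps stop once the
    largest rotation sine in a sweep falls below ``tol``.
    """
    A = np.ascontiguousarray(np.array(mats, dtype=np.float64, copy=True))
    return _ajd_kernel(A, n_iter, tol)


def fit_multiclass_csp(epochs: np.ndarray, labels, n_components: int = 4
                       ) -> CSPModel:
    """Fit multiclass CSP filters on (n_epochs, n_channels, n_samples) data.

    Class covariances (Ledoit-Wolf) are whitened by the grand-average
    covariance, approximately jointly diagonalized, and the resulting
    components ranked by the variance across classes of their projected
    log-variances (components whose power is most class-dependent first).
    """
    X = np.asarray(epochs, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    n_ch = X.shape[1]
    if n_components > n_ch:
        raise ValueError("cannot extract more components than channels")
    for cl in classes:
        if (labels == cl).sum() < 2 * n_components:
            raise ValueError(
                f"class {cl!r} needs at least {2 * n_components} epochs")

    covs = np.stack([ledoit_wolf_cov(X[labels == cl]) for cl in classes])
    grand = covs.mean(axis=0)
    evals, evecs = np.linalg.eigh(grand)
    if evals[-1] <= 0 or evals[0] <= 1e-12 * evals[-1]:
        raise np.linalg.LinAlgError(
            "grand-average covariance is rank deficient; reduce channels")
    whitener = (evecs / np.sqrt(evals)).T
    white_covs = np.einsum("ab,kbc,dc->kad", whitener, covs, whitener)
    V = _ortho_ajd(white_covs)
    all_filters = (V.T @ whitener)          # (n_ch, n_ch) rows = filters

    proj_var = np.einsum("fc,kcd,fd->kf", all_filters, covs, all_filters)
    scores = np.log(proj_var).var(axis=0)   # dispersion across classes
    order = np.argsort(scores)[::-1][:n_components]
    return CSPModel(filters=all_filters[order], scores=scores[order],
                    class_covs=covs, classes=classes,
                    n_components=n_components)


def csp_features(epochs: np.ndarray, model: CSPModel) -> np.ndarray:
    """Log-variance of each component's projected time course per epoch."""
    X = np.asarray(epochs, dtype=float)
    proj = np.einsum("fc,ecs->efs", model.filters, X)
    var = proj.var(axis=2)
    if (var <= 0).any():
        raise ValueError("zero-variance projection; check for constant epochs")
    return np.log(var)


def lda_fit(features: np.ndarray, labels) -> LinearDiscriminantAnalysis:
    """LDA with least-squares solver and Ledoit-Wolf shrinkage."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 classes to fit the LDA")
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    lda.fit(np.asarray(features, dtype=float), labels)
    return lda


def lda_predict(model: LinearDiscriminantAnalysis, features: np.ndarray):
    return model.predict(np.asarray(features, dtype=float))


def haufe_patterns(csp_model: CSPModel, data_covariance: np.ndarray
                   ) -> np.ndarray:
    """Forward-model activation patterns A = Sigma W (W^T Sigma W)^-1.

    ``W`` stacks the extraction filters as columns; ``Sigma`` is the
    covariance of the (band-passed) training data.  Columns of the returned
    (channels x components) matrix are the interpretable sensor patterns of
    the decoder's components.
    """
    W = csp_model.filters.T                  # (n_ch, n_comp)
    Sigma = np.asarray(data_covariance, dtype=float)
    inner = W.T @ Sigma @ W
    try:
        inv = np.linalg.inv(inner)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "W^T Sigma W is singular; filters are collinear under Sigma"
        ) from err
    return Sigma @ W @ inv


def crossval_decode(epochs: np.ndarray, labels, k: int = 10,
                    repeats: int = 3, n_components: int = 4,
                    seed: int | None = None, n_boot: int = 5000
                    ) -> DecodingResult:
    """Repeated stratified k-fold CSP+LDA decoding.

    CSP filters, the Haufe patterns and the LDA are fitted on the training
    split of every fold only; reported are the per-fold macro F1 scores,
    their mean with a percentile-bootstrap CI over fold scores, the pooled
    confusion matrix, and the fold-averaged (sign-aligned) sensor patterns.
    """
    X = np.asarray(epochs, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} epochs < k={k}; use a "
            "smaller k")
    cv = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats,
                                 random_state=seed)
    fold_f1 = []
    confusion = np.zeros((classes.size, classes.size), dtype=int)
    pattern_sum = None
    for train, test in cv.split(X, labels):
        csp = fit_multiclass_csp(X[train], labels[train],
                                 n_components=n_components)
        lda = lda_fit(csp_features(X[train], csp), labels[train])
        pred = lda_predict(lda, csp_features(X[test], csp))
        fold_f1.append(f1_score(labels[test], pred, average="macro",
                                zero_division=0))
        confusion += confusion_matrix(labels[test], pred, labels=classes)
        pat = haufe_patterns(csp, ledoit_wolf_cov(X[train]))
        if pattern_sum is None:
            pattern_sum = pat.copy()
            first_pat = pat
        else:  # align component signs with the first fold before averaging
            sign = np.sign(np.einsum("cf,cf->f", pat, first_pat))
            sign[sign == 0] = 1.0
            pattern_sum += pat * sign
    fold_f1 = np.asarray(fold_f1)
    mean, lo, hi = bootstrap_mean_ci(fold_f1, n_iter=n_boot, seed=seed)
    return DecodingResult(
        fold_f1=fold_f1, mean_f1=mean, ci_low=lo, ci_high=hi,
        confusion=confusion, classes=classes,
        patterns=pattern_sum / fold_f1.size,
        fold_scheme=f"stratified {k}-fold x {repeats} repeats",
        seed=seed,
    )


def localize_patterns(patterns: np.ndarray, inverse_op: InverseOperator
                      ) -> PatternMap:
    """Project sensor patterns (channels x components) to source space;
    per-vertex magnitudes are stored."""
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    if patterns.shape[0] != inverse_op.matrix.shape[1]:
        raise ValueError("pattern channel count mismatches inverse operator")
    src = apply_inverse(inverse_op, patterns)     # (n_vertices, n_comp)
    return PatternMap(values=np.abs(src).T, normalization="raw")


def weighted_grand_average(maps_by_subject: list[PatternMap],
                           f1_by_subject) -> PatternMap:
    """F1-weighted mean of per-subject pattern maps, min-max rescaled to
    [0, 1] (weights normalized to sum to one)."""
    f1 = np.asarray(f1_by_subject, dtype=float)
    if len(maps_by_subject) != f1.size:
        raise ValueError("one F1 weight per subject map required")
    stack = np.stack([m.values for m in maps_by_subject])
    w = f1 / f1.sum()
    avg = np.einsum("s,scv->cv", w, stack)
    rng_ = avg.max() - avg.min()
    if rng_ == 0:
        raise ValueError("grand-average map is constant; cannot rescale")
    return PatternMap(values=(avg - avg.min()) / rng_,
                      normalization="rescaled01", f1_weights=w)


def percentile_roi_contrast(
    pattern_map: PatternMap,
    power_by_condition: dict[str, np.ndarray],
    q: float = 90.0,
    alpha: float = 0.05,
    n_boot: int = 5000,
    seed: int | None = None,
) -> dict:
    """Condition contrasts of mean source power over the high-pattern ROI.

    The ROI is the set of vertices whose absolute pattern value (maximum
    over components) exceeds the ``q``-th percentile; per subject and
    condition the power map is averaged over the ROI, pairwise conditions
    are compared with Wilcoxon signed-rank tests (BH-FDR corrected), and
    bootstrap means/CIs are attached.  ``power_by_condition`` maps condition
    name to a (n_subjects, n_vertices) array.
    """
    mag = np.abs(pattern_map.values).max(axis=0)
    if np.ptp(mag) == 0:
        raise ValueError("uniform pattern map: percentile ROI is undefined")
    thresh = np.percentile(mag, q)
    roi = np.flatnonzero(mag > thresh) if q > 0 else np.arange(mag.size)
    if roi.size == 0:
        raise ValueError(f"empty ROI at the {q}th percentile")

    roi_means = {c: np.asarray(p)[:, roi].mean(axis=1)
                 for c, p in power_by_condition.items()}
    conds = list(roi_means)
    contrasts = []
    for i in range(len(conds)):
        for j in range(i + 1, len(conds)):
            a, b = conds[i], conds[j]
            stat, p = wilcoxon_signed_rank(roi_means[a], roi_means[b])
            contrasts.append({
                "a": a, "b": b, "statistic": stat, "p": p,
                "mean_diff": float(np.mean(roi_means[a] - roi_means[b])),
            })
    if contrasts:
        reject, p_adj = fdr_bh([c["p"] for c in contrasts], alpha=alpha)
        for c, rej, pa in zip(contrasts, reject, p_adj):
            c["p_fdr"] = float(pa)
            c["significant"] = bool(rej)
    rng = np.random.default_rng(seed)
    summaries = {}
    for c in conds:
        mean, lo, hi = bootstrap_mean_ci(
            roi_means[c], n_iter=n_boot, alpha=alpha,
            bonferroni_m=max(len(contrasts), 1),
            seed=int(rng.integers(2 ** 31)))
        summaries[c] = {"mean": mean, "ci_low": lo, "ci_high": hi}
    return {"roi": roi, "roi_means": roi_means, "contrasts": contrasts,
            "condition_summaries": summaries, "percentile": q}
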