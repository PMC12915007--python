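"""Source-space estimation: pre-whitening, DICS beamformer power with
baseline-relative change, and a depth-weighted minimum-norm inverse
operator used for activation-pattern localization and source band power.

All operators act on a known gain matrix (see :mod:`drivemeg.simulate`);
sources are fixed-orientation scalars, with an optional loose-orientation
weighting for 3-orientation lead fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.covariance import LedoitWolf

from .spectral import CrossSpectrum, multitaper_psd, band_power

__all__ = [
    "Whitener", "SpatialFilterSet", "SourcePowerMap", "InverseOperator",
    "compute_whitener", "dics_filters", "dics_power", "relative_change",
    "minimum_norm_operator", "apply_inverse", "source_band_power",
]


@dataclass
class Whitener:
    """Spatial pre-whitening matrix from a (shrunk) noise covariance."""

    matrix: np.ndarray          # (rank, n_sensors)
    eigenvalues: np.ndarray
    rank: int
    shrinkage: float


@dataclass
class SpatialFilterSet:
    """DICS spatial filters: one row of sensor weights per source vertex."""

    weights: np.ndarray         # (n_vertices, n_sensors), real
    reg_fraction: float
    band: str | None = None


@dataclass
class SourcePowerMap:
    """Per-vertex scalar power or baseline-relative change."""

    values: np.ndarray
    band: str | None = None
    condition: str | None = None
    subject: int | None = None
    relative: bool = False


@dataclass
class InverseOperator:
    """Minimum-norm inverse: sources x sensors."""

    matrix: np.ndarray
    snr: float
    depth_exponent: float
    orientation: str = "fixed"


def compute_whitener(noise_data_or_cov: np.ndarray,
                     rank_tolerance: float = 1e-10,
                     assume_cov: bool = False) -> Whitener:
    """Whitener W = Lambda^{-1/2} U^T from the shrunk noise covariance.

    When raw noise samples (channels x samples) are given, the covariance is
    estimated with Ledoit-Wolf shrinkage; a pre-computed covariance may be
    passed with ``assume_cov=True``.  Eigencomponents with eigenvalue at or
    below ``rank_tolerance`` times the largest are discarded (rank
    restriction).
    """
    X = np.asarray(noise_data_or_cov, dtype=float)
    if assume_cov or X.shape[0] == X.shape[1] and np.allclose(X, X.T):
        cov = X
        shrinkage = 0.0
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance matrix must be symmetric")
    else:
        lw = LedoitWolf().fit(X.T)  # samples x channels
        cov = lw.covariance_
        shrinkage = float(lw.shrinkage_)
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval[-1] <= 0:
        raise ValueError("noise covariance must be positive semidefinite")
    keep = eigval > rank_tolerance * eigval[-1]
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    W = (eigvec / np.sqrt(eigval)).T
    return Whitener(matrix=W, eigenvalues=eigval, rank=int(keep.sum()),
                    shrinkage=shrinkage)


def dics_filters(csd_band: np.ndarray | CrossSpectrum, gain: np.ndarray,
                 whitener: Whitener | None = None,
                 reg_fraction: float = 0.05,
                 band: str | None = None) -> SpatialFilterSet:
    """Unit-gain DICS beamformer filters for every source vertex.

    With S_r = Re(CSD) + reg * mean(diag(Re(CSD))) * I, the filter for
    vertex v with (whitened) lead-field column l_v is
    ``w_v = (l_v^T S_r^-1 l_v)^-1 l_v^T S_r^-1``, so ``w_v l_v = 1``.
    If a whitener is supplied, both CSD and gain are taken to sensor space
    *before* whitening and are whitened here.
    """
    if isinstance(csd_band, CrossSpectrum):
        if csd_band.matrices.shape[0] != 1:
            raise ValueError("pass a single band-averaged CSD matrix")
        csd_band = csd_band.matrices[0]
    csd_band = np.asarray(csd_band)
    L = np.asarray(gain, dtype=float)
    if whitener is not None:
        W = whitener.matrix
        csd_band = W @ csd_band @ W.T
        L = W @ L
    S = np.real(csd_band)
    loading = reg_fraction * np.mean(np.diag(S))
    S_r = S + loading * np.eye(S.shape[0])
    try:
        S_inv = np.linalg.inv(S_r)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"regularized CSD is singular (reg_fraction={reg_fraction}); "
            "increase reg_fraction") from err
    SL = S_inv @ L                       # (n_sens, n_src)
    denom = np.einsum("ij,ij->j", L, SL)
    if (np.abs(denom) < 1e-300).any():
        raise np.linalg.LinAlgError(
            "degenerate lead-field column; increase reg_fraction")
    weights = (SL / denom).T             # (n_src, n_sens)
    return SpatialFilterSet(weights=weights, reg_fraction=reg_fraction,
                            band=band)


def dics_power(filters: SpatialFilterSet,
               csd_band: np.ndarray | CrossSpectrum,
               whitener: Whitener | None = None, **tags) -> SourcePowerMap:
    """Source power P_v = Re(w_v CSD w_v^H) for every vertex."""
    if isinstance(csd_band, CrossSpectrum):
        if csd_band.matrices.shape[0] != 1:
            raise ValueError("pass a single band-averaged CSD matrix")
        csd_band = csd_band.matrices[0]
    csd_band = np.asarray(csd_band)
    if whitener is not None:
        W = whitener.matrix
        csd_band = W @ csd_band @ W.T
    Wf = filters.weights
    vals = np.real(np.einsum("vi,ij,vj->v", Wf, csd_band, Wf.conj()))
    return SourcePowerMap(values=vals, band=filters.band, **tags)


def relative_change(power_condition: SourcePowerMap,
                    power_baseline: SourcePowerMap) -> SourcePowerMap:
    """(P_cond - P_base) / P_base, elementwise over vertices."""
    pc, pb = power_condition.values, power_baseline.values
    if pc.shape != pb.shape:
        raise ValueError("condition and baseline maps differ in vertex count")
    zero = np.flatnonzero(pb == 0)
    if zero.size:
        raise ZeroDivisionError(
            f"zero baseline power at vertices {zero.tolist()[:10]}")
    return SourcePowerMap(
        values=(pc - pb) / pb, band=power_condition.band,
        condition=power_condition.condition,
        subject=power_condition.subject, relative=True,
    )


def minimum_norm_operator(gain: np.ndarray, noise_cov: np.ndarray,
                          snr: float, depth_exponent: float = 0.8,
                          loose: float | None = None) -> InverseOperator:
    """Depth-weighted minimum-norm inverse operator.

    ``M = R L^T (L R L^T + lambda^2 C)^{-1}`` with a diagonal source prior
    ``R_vv ∝ ||l_v||^(-2 * depth_exponent)`` (depth weighting counteracts
    the bias toward superficial sources) and ``lambda^2 = 1 / snr^2``.
    ``C`` is the sensor noise covariance, scaled to unit mean diagonal so
    that ``snr`` has its usual amplitude-ratio meaning.

    For 3-orientation lead fields (``gain`` of shape sensors x (3 *
    n_vertices)) a loose-orientation weighting can be applied: tangential
    orientations' prior is multiplied by ``loose``.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    L = np.asarray(gain, dtype=float)
    C = np.asarray(noise_cov, dtype=float)
    C = C / np.mean(np.diag(C))
    col_norms = np.linalg.norm(L, axis=0)
    if (col_norms == 0).any():
        raise ValueError("lead field has zero columns")
    R = col_norms ** (-2.0 * depth_exponent)
    R = R / R.mean()
    if loose is not None:
        if L.shape[1] % 3:
            raise ValueError("loose orientation requires 3 columns per vertex")
        loose_w = np.tile([loose, loose, 1.0], L.shape[1] // 3)
        R = R * loose_w
    lam2 = 1.0 / snr ** 2
    G = (L * R) @ L.T + lam2 * C
    try:
        M = (R[:, None] * L.T) @ np.linalg.inv(G)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("singular minimum-norm system") from err
    return InverseOperator(matrix=M, snr=snr, depth_exponent=depth_exponent,
                           orientation="loose" if loose is not None else "fixed")


def apply_inverse(inverse_op: InverseOperator, sensor_data: np.ndarray
                  ) -> np.ndarray:
    """Project sensor data (channels x ... ) to source space."""
    data = np.asarray(sensor_data)
    if data.shape[0] != inverse_op.matrix.shape[1]:
        raise ValueError("sensor dimension mismatch with inverse operator")
    return np.tensordot(inverse_op.matrix, data, axes=(1, 0))


def source_band_power(epochs, inverse_op: InverseOperator,
                      band_center: float, bandwidth: float = 2.0,
                      **tags) -> SourcePowerMap:
    """Multitaper band power per vertex of the inverse solution.

    Epochs (n_epochs, n_channels, n_samples) are projected through the
    inverse operator; DPSS multitaper power in the 2 Hz window around
    ``band_center`` is averaged over epochs.
    """
    data = np.asarray(getattr(epochs, "data", epochs), dtype=float)
    sfreq = getattr(epochs, "sfreq", tags.pop("sfreq", None))
    if sfreq is None:
        raise ValueError("sampling rate required (EpochSet or sfreq=...)")
    if data.size == 0 or not data.any():
        n_src = inverse_op.matrix.shape[0]
        return SourcePowerMap(values=np.zeros(n_src), **tags)
    src = np.einsum("vc,ecs->evs", inverse_op.matrix, data)
    psd = multitaper_psd(src, sfreq=sfreq, bandwidth=bandwidth,
                         fmin=max(band_center - bandwidth, 0.5),
                         fmax=band_center + bandwidth)
    vals = band_power(psd, center=band_center, bandwidth=bandwidth)
    return SourcePowerMap(values=vals, **tags)
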