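"""Synthetic dual-task cohort generator.

Generates a full synthetic study with the statistical structure the analysis
pipeline assumes: a 2 (visuo-spatial workload: LW/HW) x 3 (speech valence:
LV/NV/HV) within-subject design, multichannel sensor recordings obtained by
mixing source signals (1/f background plus condition-modulated narrowband
alpha/beta/gamma oscillations) through a smooth lead field on a sphere,
per-block baselines, an empty-room (sensor-noise-only) segment, gaze/pupil
streams with fixation and blink events, and driving telemetry.  Ground truth
(planted effects, per-source aperiodic exponents) is stored alongside so that
recovery can be tested.

The forward model is deliberately abstract: sources live on a subdivided
icosahedral sphere and project to sensors through a spatially smooth Gaussian
kernel.  Beamformer and minimum-norm math only require a known gain matrix,
so no anatomical head model is involved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
import pandas as pd
import scipy.signal
import scipy.sparse

__all__ = [
    "CONDITIONS",
    "WORKLOAD_LEVELS",
    "VALENCE_LEVELS",
    "SourceGrid",
    "LeadField",
    "SourceModel",
    "EffectSpec",
    "GazeParams",
    "GazeBlock",
    "TelemetryParams",
    "TelemetryBlock",
    "StudyConfig",
    "SyntheticStudy",
    "subdivide_icosahedron",
    "build_source_model",
    "patch_around",
    "generate_experiment",
    "generate_gaze_block",
    "generate_telemetry_block",
    "generate_factorial_cohort",
    "save_study",
    "load_study",
]

WORKLOAD_LEVELS = ("LW", "HW")
VALENCE_LEVELS = ("LV", "NV", "HV")
#: fixed condition order used everywhere: workload-major, valence-minor
CONDITIONS = tuple(f"{w}/{v}" for w in WORKLOAD_LEVELS for v in VALENCE_LEVELS)

#: narrowband oscillator pass-bands (Hz); peaks land at 10, 20 and 36 Hz,
#: inside the analysis cut-off ranges alpha 8-12, beta 15-25, gamma 30-42
OSC_BANDS = {"alpha": (8.5, 11.5), "beta": (18.5, 21.5), "gamma": (34.5, 37.5)}


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def subdivide_icosahedron(level: int) -> tuple[np.ndarray, np.ndarray]:
    """Recursively subdivide an icosahedron projected onto the unit sphere.

    Each subdivision splits every triangular face into four by inserting
    edge midpoints (deduplicated across faces) and re-projecting onto the
    sphere, so level ``k`` has ``10 * 4**k + 2`` vertices (level 5 gives the
    10,242-vertex grid commonly used as a per-hemisphere source space).

    Parameters
    ----------
    level : int
        Number of subdivisions, ``0 <= level <= 7``.

    Returns
    -------
    vertices : ndarray, shape (10 * 4**level + 2, 3)
        Unit-norm vertex coordinates.
    faces : ndarray, shape (20 * 4**level, 3)
        Vertex index triples.
    """
    if not isinstance(level, (int, np.integer)) or isinstance(level, bool):
        raise TypeError(f"level must be an integer, got {level!r}")
    if level < 0:
        raise ValueError(f"level must be non-negative, got {level}")
    if level > 7:
        raise ValueError(f"level {level} exceeds the supported maximum of 7")

    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )

    for _ in range(level):
        verts_list = list(verts)
        midpoint_cache: dict[tuple[int, int], int] = {}

        def midpoint(i: int, j: int) -> int:
            key = (i, j) if i < j else (j, i)
            idx = midpoint_cache.get(key)
            if idx is None:
                m = verts_list[i] + verts_list[j]
                m = m / np.linalg.norm(m)
                idx = len(verts_list)
                verts_list.append(m)
                midpoint_cache[key] = idx
            return idx

        new_faces = np.empty((len(faces) * 4, 3), dtype=np.int64)
        for n, (a, b, c) in enumerate(faces):
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces[4 * n:4 * n + 4] = [
                [a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca],
            ]
        verts = np.asarray(verts_list)
        faces = new_faces

    return verts, faces


@dataclass
class SourceGrid:
    """Source positions on the unit sphere with a neighbourhood graph."""

    positions: np.ndarray          # (n_vertices, 3), unit norm
    adjacency: scipy.sparse.csr_matrix  # symmetric, irreflexive, boolean

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.adjacency = scipy.sparse.csr_matrix(self.adjacency, dtype=bool)
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("grid positions must lie on the unit sphere")
        if (self.adjacency != self.adjacency.T).nnz:
            raise ValueError("adjacency must be symmetric")
        if self.adjacency.diagonal().any():
            raise ValueError("adjacency must be irreflexive")
        if (np.asarray(self.adjacency.sum(axis=1)).ravel() < 1).any():
            raise ValueError("every vertex needs at least one neighbour")

    @property
    def n_vertices(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def from_icosahedron(cls, level: int) -> "SourceGrid":
        """Grid whose adjacency is the subdivided icosahedral mesh's edges."""
        verts, faces = subdivide_icosahedron(level)
        n = len(verts)
        i = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2]])
        j = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0]])
        adj = scipy.sparse.coo_matrix(
            (np.ones(len(i), dtype=bool), (i, j)), shape=(n, n)
        ).tocsr()
        adj = (adj + adj.T).astype(bool)
        adj.setdiag(False)
        adj.eliminate_zeros()
        return cls(positions=verts, adjacency=adj)

    @classmethod
    def from_random_points(cls, n_vertices: int, k: int, seed: int) -> "SourceGrid":
        """k-nearest-neighbour grid over points drawn uniformly on the sphere."""
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((n_vertices, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        nn = np.argsort(d, axis=1)[:, :k]
        rows = np.repeat(np.arange(n_vertices), k)
        adj = scipy.sparse.coo_matrix(
            (np.ones(rows.size, dtype=bool), (rows, nn.ravel())),
            shape=(n_vertices, n_vertices),
        ).tocsr()
        adj = (adj + adj.T).astype(bool)
        adj.setdiag(False)
        adj.eliminate_zeros()
        return cls(positions=pts, adjacency=adj)


def patch_around(grid: SourceGrid, seed_vertex: int, n_hops: int = 1) -> np.ndarray:
    """Vertex indices within ``n_hops`` graph steps of ``seed_vertex``."""
    reach = np.zeros(grid.n_vertices, dtype=bool)
    reach[seed_vertex] = True
    frontier = reach.copy()
    for _ in range(n_hops):
        frontier = np.asarray((grid.adjacency @ frontier) > 0).ravel() & ~reach
        reach |= frontier
    return np.flatnonzero(reach)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

@dataclass
class LeadField:
    """Linear source-to-sensor mapping (gain matrix)."""

    gain: np.ndarray  # (n_sensors, n_sources)

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


@dataclass
class SourceModel:
    """Source grid + lead field + sensor noise covariance."""

    grid: SourceGrid
    lead_field: LeadField
    noise_cov: np.ndarray  # (n_sensors, n_sensors)
    sensor_positions: np.ndarray
    smoothness: float
    seed: int


def build_source_model(
    n_sensors: int = 64,
    grid: int | SourceGrid = 2,
    smoothness: float = 0.5,
    seed: int = 0,
    noise_rank: int = 4,
) -> SourceModel:
    """Construct the abstract spherical forward model.

    Sensors are placed quasi-uniformly on a sphere of radius 1.1; the gain
    column of source ``v`` is a Gaussian kernel of the chordal distance
    between sensor directions and the source position, width ``smoothness``,
    plus a small random perturbation that guarantees full column rank.
    Neighbouring sources therefore project through correlated columns, and
    the correlation vanishes as ``smoothness -> 0``.  The sensor noise
    covariance is diagonal-plus-low-rank (independent channel noise plus a
    few shared "environmental" components), the structure the empty-room
    segment is drawn from.
    """
    if n_sensors < 16:
        raise ValueError("n_sensors must be at least 16")
    if isinstance(grid, SourceGrid):
        src_grid = grid
    else:
        src_grid = SourceGrid.from_icosahedron(int(grid))
    if src_grid.n_vertices < 50 and not isinstance(grid, SourceGrid):
        raise ValueError("source grid must have at least 50 vertices")

    rng = np.random.default_rng(seed)
    # Fibonacci lattice: deterministic quasi-uniform sensor layout
    i = np.arange(n_sensors)
    golden = (1 + 5 ** 0.5) / 2
    theta = 2 * np.pi * i / golden
    z = 1 - (2 * i + 1) / n_sensors
    r = np.sqrt(np.maximum(0.0, 1 - z ** 2))
    sens_dir = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    sensor_positions = 1.1 * sens_dir

    d = np.linalg.norm(sens_dir[:, None, :] - src_grid.positions[None, :, :], axis=-1)
    sigma = max(smoothness, 1e-6)
    gain = np.exp(-(d ** 2) / (2 * sigma ** 2))
    gain += 1e-3 * rng.standard_normal(gain.shape)
    gain /= np.linalg.norm(gain, axis=0, keepdims=True)

    if n_sensors > src_grid.n_vertices:
        if np.linalg.matrix_rank(gain) < src_grid.n_vertices:  # pragma: no cover
            gain += 1e-3 * rng.standard_normal(gain.shape)
            gain /= np.linalg.norm(gain, axis=0, keepdims=True)

    diag = 0.5 + rng.uniform(0.0, 1.0, n_sensors)
    factors = rng.standard_normal((n_sensors, noise_rank)) * 0.3
    noise_cov = np.diag(diag) + factors @ factors.T

    return SourceModel(
        grid=src_grid,
        lead_field=LeadField(gain=gain),
        noise_cov=noise_cov,
        sensor_positions=sensor_positions,
        smoothness=smoothness,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# planted effects
# ---------------------------------------------------------------------------

@dataclass
class EffectSpec:
    """A planted condition effect on band-limited source power.

    ``gains`` multiplies the oscillator *power* (variance) of ``band`` at the
    ``vertices`` patch, one entry per condition in :data:`CONDITIONS` order.
    """

    factor: str                 # "valence" | "workload" | "interaction"
    band: str                   # "alpha" | "beta" | "gamma"
    vertices: np.ndarray
    gains: np.ndarray           # (6,) positive, CONDITIONS order

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.int64)
        self.gains = np.asarray(self.gains, dtype=float)
        if self.factor not in {"valence", "workload", "interaction"}:
            raise ValueError(f"unknown factor {self.factor!r}")
        if self.band not in OSC_BANDS:
            raise ValueError(f"unknown band {self.band!r}")
        if self.gains.shape != (6,):
            raise ValueError("gains must have one entry per condition (6)")
        if (self.gains <= 0).any():
            raise ValueError("gains must be positive")
        if self.factor == "interaction":
            lw = self.gains[:3]
            hw = self.gains[3:]
            # cross-over: valence ordering must reverse between workload levels
            if (lw[0] - lw[2]) * (hw[0] - hw[2]) >= 0:
                raise ValueError(
                    "interaction effect must reverse the LV-vs-HV ordering "
                    "across workload levels (cross-over)"
                )

    @classmethod
    def workload_effect(cls, band: str, vertices, hw_gain: float) -> "EffectSpec":
        """HW conditions get ``hw_gain`` x power, LW conditions stay at 1."""
        gains = np.array([1.0, 1.0, 1.0, hw_gain, hw_gain, hw_gain])
        return cls("workload", band, vertices, gains)

    @classmethod
    def valence_effect(cls, band: str, vertices, emotional_gain: float) -> "EffectSpec":
        """Emotional (LV, HV) conditions get ``emotional_gain`` x power vs NV."""
        g = emotional_gain
        gains = np.array([g, 1.0, g, g, 1.0, g])
        return cls("valence", band, vertices, gains)

    @classmethod
    def crossover(cls, band: str, vertices, strength: float) -> "EffectSpec":
        """LV > HV under LW, reversed under HW (cross-over interaction)."""
        s = strength
        gains = np.array([s, 1.0, 1.0 / s, 1.0 / s, 1.0, s])
        return cls("interaction", band, vertices, gains)


# ---------------------------------------------------------------------------
# gaze / telemetry blocks
# ---------------------------------------------------------------------------

@dataclass
class GazeParams:
    duration_s: float = 300.0
    sfreq: float = 250.0
    pupil_mean_mm: float = 3.5
    dilation_offset_mm: float = 0.0
    pupil_noise_mm: float = 0.02
    drift_amplitude_mm: float = 0.15
    discontinuity_rate_hz: float = 0.5   # abrupt pupil steps per second
    discontinuity_step_mm: float = 0.15
    blink_rate_hz: float = 0.2
    blink_duration_s: float = 0.15
    fixation_duration_s: float = 0.30
    saccade_duration_s: float = 0.04
    dispersion_scale: float = 100.0      # screen units (px) of fixation scatter
    screen_center: tuple[float, float] = (960.0, 540.0)

    def validate(self) -> None:
        if self.duration_s <= 0 or self.sfreq <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if self.pupil_mean_mm <= 0:
            raise ValueError("pupil mean must be positive (mm)")
        if min(self.blink_rate_hz, self.discontinuity_rate_hz,
               self.pupil_noise_mm, self.dispersion_scale) < 0:
            raise ValueError("rates, noise and scales must be non-negative")


@dataclass
class GazeBlock:
    time: np.ndarray            # (n,) seconds
    x: np.ndarray               # gaze position, screen units
    y: np.ndarray
    pupil_mm: np.ndarray        # NaN inside blink gaps
    fixations: pd.DataFrame     # onset_s, offset_s, x, y, duration_s
    blinks: pd.DataFrame        # onset_s, offset_s
    sfreq: float
    duration_s: float


def generate_gaze_block(params: GazeParams, seed: int) -> GazeBlock:
    """Simulate one block of gaze/pupil data with planted properties.

    The pupil trace is a slow sinusoid-mixture drift plus white measurement
    noise plus step discontinuities at Poisson event times (the events the
    Index of Pupillary Activity counts), with NaN gaps during blinks.
    Fixations alternate with short saccade gaps; fixation positions scatter
    around the screen centre with standard deviation ``dispersion_scale``.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n = int(round(params.duration_s * params.sfreq))
    t = np.arange(n) / params.sfreq

    # slow drift: random-phase low-frequency sinusoids (< 0.1 Hz)
    drift = np.zeros(n)
    for f in (0.013, 0.031, 0.047, 0.083):
        drift += np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    drift *= params.drift_amplitude_mm / 4.0

    pupil = (
        params.pupil_mean_mm
        + params.dilation_offset_mm
        + drift
        + params.pupil_noise_mm * rng.standard_normal(n)
    )

    # Poisson step discontinuities
    n_steps = rng.poisson(params.discontinuity_rate_hz * params.duration_s)
    step_times = np.sort(rng.uniform(0, params.duration_s, n_steps))
    for st in step_times:
        idx = int(st * params.sfreq)
        pupil[idx:] += rng.choice([-1.0, 1.0]) * params.discontinuity_step_mm

    # blinks: Poisson count, uniform onsets, NaN gaps
    n_blinks = rng.poisson(params.blink_rate_hz * params.duration_s)
    onsets = np.sort(rng.uniform(0, params.duration_s - params.blink_duration_s,
                                 n_blinks))
    # merge overlapping blinks
    blink_rows = []
    for on in onsets:
        off = on + params.blink_duration_s
        if blink_rows and on <= blink_rows[-1][1]:
            blink_rows[-1][1] = max(blink_rows[-1][1], off)
        else:
            blink_rows.append([on, off])
    for on, off in blink_rows:
        pupil[int(on * params.sfreq):int(np.ceil(off * params.sfreq))] = np.nan
    blinks = pd.DataFrame(blink_rows or np.empty((0, 2)),
                          columns=["onset_s", "offset_s"])

    # fixation sequence with jittered durations
    fix_rows = []
    cx, cy = params.screen_center
    cursor = 0.0
    while True:
        dur = max(0.05, rng.normal(params.fixation_duration_s,
                                   0.3 * params.fixation_duration_s))
        if cursor + dur > params.duration_s:
            break
        fx = cx + params.dispersion_scale * rng.standard_normal()
        fy = cy + params.dispersion_scale * rng.standard_normal()
        fix_rows.append((cursor, cursor + dur, fx, fy, dur))
        cursor += dur + max(0.01, rng.normal(params.saccade_duration_s,
                                             0.01))
    fixations = pd.DataFrame(
        fix_rows, columns=["onset_s", "offset_s", "x", "y", "duration_s"]
    )

    # gaze traces: piecewise-constant at fixation positions + tremor
    x = np.full(n, cx)
    y = np.full(n, cy)
    for _, row in fixations.iterrows():
        sl = slice(int(row.onset_s * params.sfreq),
                   int(row.offset_s * params.sfreq))
        x[sl] = row.x
        y[sl] = row.y
    x += 0.5 * rng.standard_normal(n)
    y += 0.5 * rng.standard_normal(n)

    return GazeBlock(
        time=t, x=x, y=y, pupil_mm=pupil,
        fixations=fixations, blinks=blinks,
        sfreq=params.sfreq, duration_s=params.duration_s,
    )


@dataclass
class TelemetryParams:
    duration_s: float = 300.0
    sfreq: float = 20.0
    accel_volatility: float = 0.3        # m/s^2 innovation SD
    steer_volatility: float = 0.05       # rad/s innovation SD
    brake_base: float = 0.1              # mean brake actuation in [0, 1]
    lane_noise_m: float = 0.25           # OU stationary SD of lane position
    n_lane_changes: int = 4
    violation_rate_hz: float = 0.005     # radar flashes + collisions per second

    def validate(self) -> None:
        if self.duration_s <= 0 or self.sfreq <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if not 0 <= self.brake_base <= 1:
            raise ValueError("brake_base must lie in [0, 1]")
        if min(self.accel_volatility, self.steer_volatility,
               self.lane_noise_m, self.violation_rate_hz) < 0:
            raise ValueError("volatilities and rates must be non-negative")


@dataclass
class TelemetryBlock:
    time: np.ndarray
    accel: np.ndarray           # m/s^2
    steer: np.ndarray           # rad/s
    brake: np.ndarray           # [0, 1]
    lane_pos: np.ndarray        # metres from lane centre
    lane_change_times: np.ndarray
    violations: pd.DataFrame    # time_s, kind in {radar, collision}
    sfreq: float
    duration_s: float


def generate_telemetry_block(params: TelemetryParams, seed: int) -> TelemetryBlock:
    """Simulate driving telemetry; higher volatility raises RMSSD downstream."""
    params.validate()
    rng = np.random.default_rng(seed)
    n = int(round(params.duration_s * params.sfreq))
    t = np.arange(n) / params.sfreq

    def ar1(sd: float, rho: float = 0.95) -> np.ndarray:
        innov = rng.standard_normal(n) * sd
        out = np.empty(n)
        out[0] = innov[0]
        for k in range(1, n):
            out[k] = rho * out[k - 1] + innov[k]
        return out

    accel = ar1(params.accel_volatility, rho=0.5)
    steer = ar1(params.steer_volatility, rho=0.5)
    brake = np.clip(params.brake_base + 0.05 * ar1(1.0, rho=0.9), 0.0, 1.0)
    # OU lane position with stationary SD lane_noise_m
    rho = 0.995
    lane = ar1(params.lane_noise_m * np.sqrt(1 - rho ** 2), rho=rho)

    margin = min(5.0, 0.1 * params.duration_s)
    lane_changes = np.sort(
        rng.uniform(margin, params.duration_s - margin,
                    params.n_lane_changes)
    )
    for lc in lane_changes:  # transient swerve around each change
        sl = (t >= lc - 1.0) & (t <= lc + 1.0)
        lane[sl] += rng.choice([-1.0, 1.0]) * 1.5 * np.hanning(sl.sum())

    n_viol = rng.poisson(params.violation_rate_hz * params.duration_s)
    viol = pd.DataFrame(
        {
            "time_s": np.sort(rng.uniform(0, params.duration_s, n_viol)),
            "kind": rng.choice(["radar", "collision"], n_viol),
        }
    )

    return TelemetryBlock(
        time=t, accel=accel, steer=steer, brake=brake, lane_pos=lane,
        lane_change_times=lane_changes, violations=viol,
        sfreq=params.sfreq, duration_s=params.duration_s,
    )


# ---------------------------------------------------------------------------
# study configuration and generation
# ---------------------------------------------------------------------------

def _default_effects() -> list[EffectSpec]:
    # filled in at generation time once the grid is known (patch indices)
    return []


@dataclass
class StudyConfig:
    """Configuration fully determining one synthetic cohort (given a seed).

    Defaults are sized for desk scale: 12 subjects, 64 sensors, a 162-vertex
    (level-2 icosahedron) grid, 100 Hz sampling and 300 s blocks.
    """

    n_subjects: int = 12
    n_sensors: int = 64
    grid_level: int = 2
    sfreq: float = 100.0
    block_duration_s: float = 300.0
    baseline_duration_s: float = 60.0
    empty_room_duration_s: float = 180.0
    aperiodic_exponent_range: tuple[float, float] = (0.8, 1.6)
    aperiodic_offset_range: tuple[float, float] = (-0.5, 0.5)
    osc_amplitude: float = 0.6           # oscillator SD relative to unit 1/f SD
    sensor_noise_scale: float = 0.05     # sensor noise SD scale vs signal
    lead_field_smoothness: float = 0.5
    effects: list[EffectSpec] = field(default_factory=_default_effects)
    # gaze/telemetry per-condition parameter overrides, keyed by condition
    gaze_overrides: dict[str, dict] = field(default_factory=dict)
    telemetry_overrides: dict[str, dict] = field(default_factory=dict)
    gaze_defaults: GazeParams = field(default_factory=GazeParams)
    telemetry_defaults: TelemetryParams = field(default_factory=TelemetryParams)

    @classmethod
    def with_planted_effects(cls, **kwargs) -> "StudyConfig":
        """Config whose effects emulate the study's headline findings.

        Planted on the level-``grid_level`` icosahedral grid: a parietal-like
        beta-power increase for emotional speech, a gamma increase plus beta
        decrease under high workload, and a cross-over gamma interaction.
        Gaze defaults plant higher pupil dilation, higher pupil-step rate and
        reduced gaze dispersion ("visual tunnelling") under high workload;
        telemetry defaults plant higher volatility and lane noise under HW.
        """
        cfg = cls(**kwargs)
        grid = SourceGrid.from_icosahedron(cfg.grid_level)
        n = grid.n_vertices
        cfg.effects = [
            EffectSpec.valence_effect("beta", patch_around(grid, n // 5, 1), 1.5),
            EffectSpec.workload_effect("gamma", patch_around(grid, n // 2, 1), 1.5),
            EffectSpec.workload_effect("beta", patch_around(grid, (4 * n) // 5, 1),
                                       1.0 / 1.5),
            EffectSpec.crossover("gamma", patch_around(grid, n // 10, 1), 1.6),
        ]
        for cond in CONDITIONS:
            if cond.startswith("HW"):
                cfg.gaze_overrides[cond] = {
                    "dilation_offset_mm": 0.3,
                    "discontinuity_rate_hz": 1.0,
                    "dispersion_scale": 70.0,
                }
                cfg.telemetry_overrides[cond] = {
                    "accel_volatility": 0.45,
                    "steer_volatility": 0.075,
                    "lane_noise_m": 0.375,
                }
        return cfg

    def validate(self, grid: SourceGrid) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        lo, hi = self.aperiodic_exponent_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid aperiodic exponent range")
        for eff in self.effects:
            if eff.vertices.max(initial=-1) >= grid.n_vertices:
                raise ValueError(
                    f"effect patch exceeds grid size {grid.n_vertices}"
                )
        bad = set(self.gaze_overrides) | set(self.telemetry_overrides)
        bad -= set(CONDITIONS)
        if bad:
            raise ValueError(f"overrides for unknown conditions: {sorted(bad)}")


@dataclass
class SyntheticStudy:
    """One simulated cohort: recordings, events, and ground truth."""

    config: StudyConfig
    model: SourceModel
    #: meg[subject][condition] -> (n_sensors, n_samples); conditions plus
    #: per-condition baseline blocks keyed "baseline:<condition>"
    meg: list[dict[str, np.ndarray]]
    empty_room: np.ndarray
    gaze: list[dict[str, GazeBlock]]
    telemetry: list[dict[str, TelemetryBlock]]
    true_exponents: np.ndarray   # (n_subjects, n_sources)
    true_offsets: np.ndarray
    seed: int

    @property
    def n_subjects(self) -> int:
        return len(self.meg)

    @property
    def sfreq(self) -> float:
        return self.config.sfreq


def _one_over_f_noise(rng, n_sources, n_samples, sfreq, exponents, offsets):
    """Frequency-domain shaped noise: PSD proportional to 10**offset / f**chi."""
    white = rng.standard_normal((n_sources, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    shape = np.ones((n_sources, freqs.size))
    nz = freqs > 0
    shape[:, nz] = np.sqrt(
        10.0 ** offsets[:, None] / freqs[None, nz] ** exponents[:, None]
    )
    shape[:, ~nz] = 0.0
    sig = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    # normalize to unit average variance across sources, keeping relative scale
    sig /= np.sqrt(np.mean(sig ** 2)) + 1e-30
    return sig


def _narrowband_noise(rng, n_sources, n_samples, sfreq, band):
    lo, hi = band
    sos = scipy.signal.butter(2, [lo, hi], btype="bandpass", fs=sfreq,
                              output="sos")
    x = rng.standard_normal((n_sources, n_samples))
    x = scipy.signal.sosfiltfilt(sos, x, axis=1)
    x /= x.std(axis=1, keepdims=True) + 1e-30
    return x


def _condition_gain_map(config: StudyConfig, n_sources: int) -> dict:
    """Per band: (6, n_sources) multiplicative power gains from all effects."""
    gains = {b: np.ones((6, n_sources)) for b in OSC_BANDS}
    for eff in config.effects:
        gains[eff.band][:, eff.vertices] *= eff.gains[:, None]
    return gains


def _simulate_meg_block(rng, model, config, exponents, offsets, duration_s,
                        band_power_gain=None):
    """Sensor block = lead field x (1/f + scaled oscillators) + sensor noise."""
    n_samples = int(round(duration_s * config.sfreq))
    n_src = model.grid.n_vertices
    src = _one_over_f_noise(rng, n_src, n_samples, config.sfreq,
                            exponents, offsets)
    for band, rng_band in OSC_BANDS.items():
        osc = _narrowband_noise(rng, n_src, n_samples, config.sfreq, rng_band)
        amp = config.osc_amplitude * np.ones(n_src)
        if band_power_gain is not None:
            amp = amp * np.sqrt(band_power_gain[band])
        src += amp[:, None] * osc
    sensors = model.lead_field.gain @ src
    noise = _sample_sensor_noise(rng, model.noise_cov, n_samples)
    scale = config.sensor_noise_scale * sensors.std()
    sensors = sensors + scale * noise
    return sensors


def _sample_sensor_noise(rng, noise_cov, n_samples):
    chol = np.linalg.cholesky(
        noise_cov + 1e-12 * np.eye(noise_cov.shape[0])
    )
    white = rng.standard_normal((noise_cov.shape[0], n_samples))
    noise = chol @ white
    return noise / noise.std()


def generate_experiment(config: StudyConfig, seed: int) -> SyntheticStudy:
    """Generate a full synthetic cohort; bit-identical per (config, seed)."""
    model = build_source_model(
        n_sensors=config.n_sensors,
        grid=config.grid_level,
        smoothness=config.lead_field_smoothness,
        seed=seed,
    )
    config.validate(model.grid)
    n_src = model.grid.n_vertices
    gain_map = _condition_gain_map(config, n_src)

    master = np.random.SeedSequence(seed)
    subj_seqs = master.spawn(config.n_subjects + 1)
    er_rng = np.random.default_rng(subj_seqs[-1])
    n_er = int(round(config.empty_room_duration_s * config.sfreq))
    empty_room = _sample_sensor_noise(er_rng, model.noise_cov, n_er)

    exp_lo, exp_hi = config.aperiodic_exponent_range
    off_lo, off_hi = config.aperiodic_offset_range

    meg, gaze, telemetry = [], [], []
    true_exp = np.empty((config.n_subjects, n_src))
    true_off = np.empty((config.n_subjects, n_src))
    for s in range(config.n_subjects):
        srng = np.random.default_rng(subj_seqs[s])
        exponents = srng.uniform(exp_lo, exp_hi, n_src)
        offsets = srng.uniform(off_lo, off_hi, n_src)
        true_exp[s] = exponents
        true_off[s] = offsets

        subj_meg: dict[str, np.ndarray] = {}
        subj_gaze: dict[str, GazeBlock] = {}
        subj_tel: dict[str, TelemetryBlock] = {}
        for ci, cond in enumerate(CONDITIONS):
            cond_gain = {b: gain_map[b][ci] for b in OSC_BANDS}
            subj_meg[cond] = _simulate_meg_block(
                srng, model, config, exponents, offsets,
                config.block_duration_s, cond_gain,
            )
            subj_meg[f"baseline:{cond}"] = _simulate_meg_block(
                srng, model, config, exponents, offsets,
                config.baseline_duration_s, None,
            )
            gp = _with_overrides(config.gaze_defaults,
                                 config.gaze_overrides.get(cond, {}),
                                 duration_s=config.block_duration_s)
            subj_gaze[cond] = generate_gaze_block(
                gp, seed=int(srng.integers(2 ** 31)))
            gp_base = _with_overrides(config.gaze_defaults, {},
                                      duration_s=config.baseline_duration_s)
            subj_gaze[f"baseline:{cond}"] = generate_gaze_block(
                gp_base, seed=int(srng.integers(2 ** 31)))
            tp = _with_overrides(config.telemetry_defaults,
                                 config.telemetry_overrides.get(cond, {}),
                                 duration_s=config.block_duration_s)
            subj_tel[cond] = generate_telemetry_block(
                tp, seed=int(srng.integers(2 ** 31)))
        meg.append(subj_meg)
        gaze.append(subj_gaze)
        telemetry.append(subj_tel)

    return SyntheticStudy(
        config=config, model=model, meg=meg, empty_room=empty_room,
        gaze=gaze, telemetry=telemetry,
        true_exponents=true_exp, true_offsets=true_off, seed=seed,
    )


def _with_overrides(defaults, overrides: dict, **extra):
    params = {**asdict(defaults), **overrides, **extra}
    return type(defaults)(**params)


# ---------------------------------------------------------------------------
# cohort-level factorial power datasets (for the statistics suite)
# ---------------------------------------------------------------------------

def generate_factorial_cohort(
    n_subjects: int = 12,
    n_vertices: int = 162,
    effect_vertices: np.ndarray | None = None,
    effect_gains: np.ndarray | None = None,
    within_sd: float = 0.10,
    between_sd: float = 0.05,
    effect_size: float = 0.20,
    seed: int = 0,
) -> np.ndarray:
    """Subjects x 6 conditions x vertices relative-change dataset.

    Emulates the per-vertex band-power relative changes entering the factorial
    statistics: subject-specific offsets (``between_sd``), cell-level noise
    (``within_sd``) and, optionally, an additive planted effect.  If
    ``effect_gains`` is None while ``effect_vertices`` is given, a high-
    workload main effect of size ``effect_size`` is planted.
    """
    rng = np.random.default_rng(seed)
    data = within_sd * rng.standard_normal((n_subjects, 6, n_vertices))
    data += between_sd * rng.standard_normal((n_subjects, 1, n_vertices))
    if effect_vertices is not None:
        effect_vertices = np.asarray(effect_vertices, dtype=np.int64)
        if effect_gains is None:
            effect_gains = np.array([0, 0, 0, 1, 1, 1]) * effect_size
        effect_gains = np.asarray(effect_gains, dtype=float)
        data[:, :, effect_vertices] += effect_gains[None, :, None]
    return data


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------

def save_study(study: SyntheticStudy, path) -> None:
    """Write a study to HDF5 (arrays) with JSON-encoded config attributes."""
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = study.seed
        cfg = asdict(study.config)
        cfg["effects"] = [
            {**asdict(e), "vertices": e.vertices.tolist(),
             "gains": e.gains.tolist()}
            for e in study.config.effects
        ]
        f.attrs["config_json"] = json.dumps(cfg, default=_json_default)
        f.create_dataset("empty_room", data=study.empty_room)
        gt = f.create_group("ground_truth")
        gt.create_dataset("true_exponents", data=study.true_exponents)
        gt.create_dataset("true_offsets", data=study.true_offsets)
        mdl = f.create_group("model")
        mdl.create_dataset("gain", data=study.model.lead_field.gain)
        mdl.create_dataset("noise_cov", data=study.model.noise_cov)
        mdl.create_dataset("positions", data=study.model.grid.positions)
        adj = study.model.grid.adjacency.tocoo()
        mdl.create_dataset("adjacency_ij",
                           data=np.vstack([adj.row, adj.col]))
        mdl.create_dataset("sensor_positions",
                           data=study.model.sensor_positions)
        for s in range(study.n_subjects):
            g = f.create_group(f"subjects/{s:02d}")
            for key, block in study.meg[s].items():
                g.create_dataset(f"meg/{key.replace('/', '|')}", data=block)
            for key, gb in study.gaze[s].items():
                gg = g.create_group(f"gaze/{key.replace('/', '|')}")
                for name in ("time", "x", "y", "pupil_mm"):
                    gg.create_dataset(name, data=getattr(gb, name))
                gg.attrs["sfreq"] = gb.sfreq
                gg.attrs["duration_s"] = gb.duration_s
                gg.create_dataset("fixations", data=gb.fixations.to_numpy())
                gg.create_dataset("blinks", data=gb.blinks.to_numpy())
            for key, tb in study.telemetry[s].items():
                tg = g.create_group(f"telemetry/{key.replace('/', '|')}")
                for name in ("time", "accel", "steer", "brake", "lane_pos",
                             "lane_change_times"):
                    tg.create_dataset(name, data=getattr(tb, name))
                tg.attrs["sfreq"] = tb.sfreq
                tg.attrs["duration_s"] = tb.duration_s
                tg.create_dataset(
                    "violation_times", data=tb.violations["time_s"].to_numpy())
                tg.create_dataset(
                    "violation_kinds",
                    data=np.array(tb.violations["kind"], dtype="S"))


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_study(path) -> SyntheticStudy:
    """Inverse of :func:`save_study`."""
    with h5py.File(path, "r") as f:
        cfg_raw = json.loads(f.attrs["config_json"])
        effects = [
            EffectSpec(e["factor"], e["band"], np.asarray(e["vertices"]),
                       np.asarray(e["gains"]))
            for e in cfg_raw.pop("effects")
        ]
        gaze_defaults = GazeParams(**{
            **cfg_raw.pop("gaze_defaults"),
        })
        gaze_defaults.screen_center = tuple(gaze_defaults.screen_center)
        tel_defaults = TelemetryParams(**cfg_raw.pop("telemetry_defaults"))
        cfg_raw["aperiodic_exponent_range"] = tuple(
            cfg_raw["aperiodic_exponent_range"])
        cfg_raw["aperiodic_offset_range"] = tuple(
            cfg_raw["aperiodic_offset_range"])
        config = StudyConfig(effects=effects, gaze_defaults=gaze_defaults,
                             telemetry_defaults=tel_defaults, **cfg_raw)

        pos = f["model/positions"][()]
        ij = f["model/adjacency_ij"][()]
        n = pos.shape[0]
        adjacency = scipy.sparse.coo_matrix(
            (np.ones(ij.shape[1], dtype=bool), (ij[0], ij[1])),
            shape=(n, n)).tocsr()
        grid = SourceGrid(positions=pos, adjacency=adjacency)
        model = SourceModel(
            grid=grid,
            lead_field=LeadField(gain=f["model/gain"][()]),
            noise_cov=f["model/noise_cov"][()],
            sensor_positions=f["model/sensor_positions"][()],
            smoothness=config.lead_field_smoothness,
            seed=int(f.attrs["seed"]),
        )

        meg, gaze, telemetry = [], [], []
        for sname in sorted(f["subjects"]):
            g = f[f"subjects/{sname}"]
            meg.append({k.replace("|", "/"): g[f"meg/{k}"][()]
                        for k in g["meg"]})
            sg = {}
            for k in g["gaze"]:
                gg = g[f"gaze/{k}"]
                fx = pd.DataFrame(
                    gg["fixations"][()],
                    columns=["onset_s", "offset_s", "x", "y", "duration_s"])
                bl = pd.DataFrame(gg["blinks"][()],
                                  columns=["onset_s", "offset_s"])
                sg[k.replace("|", "/")] = GazeBlock(
                    time=gg["time"][()], x=gg["x"][()], y=gg["y"][()],
                    pupil_mm=gg["pupil_mm"][()], fixations=fx, blinks=bl,
                    sfreq=float(gg.attrs["sfreq"]),
                    duration_s=float(gg.attrs["duration_s"]))
            gaze.append(sg)
            st = {}
            for k in g["telemetry"]:
                tg = g[f"telemetry/{k}"]
                viol = pd.DataFrame({
                    "time_s": tg["violation_times"][()],
                    "kind": [v.decode() for v in tg["violation_kinds"][()]],
                })
                st[k.replace("|", "/")] = TelemetryBlock(
                    time=tg["time"][()], accel=tg["accel"][()],
                    steer=tg["steer"][()], brake=tg["brake"][()],
                    lane_pos=tg["lane_pos"][()],
                    lane_change_times=tg["lane_change_times"][()],
                    violations=viol, sfreq=float(tg.attrs["sfreq"]),
                    duration_s=float(tg.attrs["duration_s"]))
            telemetry.append(st)

        return SyntheticStudy(
            config=config, model=model, meg=meg,
            empty_room=f["empty_room"][()], gaze=gaze, telemetry=telemetry,
            true_exponents=f["ground_truth/true_exponents"][()],
            true_offsets=f["ground_truth/true_offsets"][()],
            seed=int(f.attrs["seed"]),
        )
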