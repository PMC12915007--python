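"""Synthetic-cohort generator: geometry, determinism, planted effects."""

import numpy as np
import pytest

from drivemeg import simulate
from drivemeg.simulate import (
    CONDITIONS, EffectSpec, GazeParams, SourceGrid, StudyConfig,
    TelemetryParams, build_source_model, generate_experiment,
    generate_gaze_block, generate_telemetry_block, patch_around,
    subdivide_icosahedron,
)


class TestIcosahedron:
    @pytest.mark.parametrize("level,expected", [(0, 12), (1, 42), (2, 162),
                                                (3, 642)])
    def test_vertex_count_formula(self, level, expected):
        verts, faces = subdivide_icosahedron(level)
        assert len(verts) == expected == 10 * 4 ** level + 2
        assert len(faces) == 20 * 4 ** level

    def test_vertex_count_matches_edge_counting_oracle(self):
        # each subdivision adds one vertex per unique edge: V' = V + E
        verts, faces = subdivide_icosahedron(1)
        edges = set()
        for a, b, c in faces:
            for e in ((a, b), (b, c), (c, a)):
                edges.add(tuple(sorted(e)))
        v2, _ = subdivide_icosahedron(2)
        assert len(v2) == len(verts) + len(edges)

    def test_vertices_on_unit_sphere(self):
        verts, _ = subdivide_icosahedron(2)
        assert np.allclose(np.linalg.norm(verts, axis=1), 1.0, atol=1e-12)

    def test_invalid_levels(self):
        with pytest.raises(ValueError):
            subdivide_icosahedron(-1)
        with pytest.raises(ValueError):
            subdivide_icosahedron(8)
        with pytest.raises(TypeError):
            subdivide_icosahedron(1.5)


class TestSourceGrid:
    def test_adjacency_symmetric_irreflexive_connected(self):
        grid = SourceGrid.from_icosahedron(2)
        adj = grid.adjacency
        assert grid.n_vertices == 162
        assert (adj != adj.T).nnz == 0
        assert not adj.diagonal().any()
        assert (np.asarray(adj.sum(axis=1)).ravel() >= 1).all()

    def test_patch_growing(self):
        grid = SourceGrid.from_icosahedron(2)
        p0 = patch_around(grid, 10, 0)
        p1 = patch_around(grid, 10, 1)
        assert list(p0) == [10]
        assert set(p0) < set(p1)
        # 1-hop patch = vertex plus its direct neighbours
        assert set(p1) == set(grid.adjacency[10].indices) | {10}


class TestSourceModel:
    def test_deterministic_per_seed(self):
        m1 = build_source_model(n_sensors=24, grid=2, seed=5)
        m2 = build_source_model(n_sensors=24, grid=2, seed=5)
        m3 = build_source_model(n_sensors=24, grid=2, seed=6)
        assert np.array_equal(m1.lead_field.gain, m2.lead_field.gain)
        assert not np.array_equal(m1.lead_field.gain, m3.lead_field.gain)

    def test_smooth_columns_correlated_neighbours(self, model32):
        gain = model32.lead_field.gain
        grid = model32.grid
        rng = np.random.default_rng(0)
        cors = []
        for v in rng.integers(0, grid.n_vertices, 50):
            for nb in grid.adjacency[v].indices[:2]:
                cors.append(np.corrcoef(gain[:, v], gain[:, nb])[0, 1])
        assert np.mean(cors) > 0.5

    def test_smoothness_zero_decorrelates(self):
        sharp = build_source_model(n_sensors=32, grid=2, smoothness=1e-6,
                                   seed=1)
        rng = np.random.default_rng(2)
        pairs = rng.integers(0, 162, size=(100, 2))
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
        cors = [np.corrcoef(sharp.lead_field.gain[:, a],
                            sharp.lead_field.gain[:, b])[0, 1]
                for a, b in pairs]
        assert abs(np.mean(cors)) < 0.1

    def test_full_column_rank_when_overdetermined(self):
        grid = SourceGrid.from_random_points(50, k=5, seed=3)
        m = build_source_model(n_sensors=64, grid=grid, seed=3)
        assert np.linalg.matrix_rank(m.lead_field.gain) == 50

    def test_noise_cov_positive_definite(self, model32):
        assert np.linalg.eigvalsh(model32.noise_cov).min() > 0


class TestEffectSpec:
    def test_gains_must_be_positive(self):
        with pytest.raises(ValueError):
            EffectSpec("workload", "beta", [0], np.array([1, 1, 1, 0, 1, 1.0]))

    def test_crossover_must_reverse(self):
        with pytest.raises(ValueError):
            EffectSpec("interaction", "gamma", [0],
                       np.array([2.0, 1, 1.5, 2.0, 1, 1.5]))
        # a genuine cross-over validates
        EffectSpec.crossover("gamma", [0, 1], 1.5)

    def test_patch_outside_grid_rejected(self):
        cfg = StudyConfig(n_subjects=1, grid_level=2)
        cfg.effects = [EffectSpec.workload_effect("beta", [999], 1.5)]
        with pytest.raises(ValueError, match="exceeds grid"):
            generate_experiment(cfg, seed=0)


@pytest.fixture(scope="module")
def tiny_config():
    return StudyConfig(n_subjects=2, n_sensors=24, grid_level=2,
                       sfreq=100.0, block_duration_s=12.0,
                       baseline_duration_s=6.0, empty_room_duration_s=20.0,
                       gaze_defaults=GazeParams(duration_s=12.0),
                       telemetry_defaults=TelemetryParams(duration_s=12.0))


class TestGenerateExperiment:
    def test_bit_identical_regeneration(self, tiny_config):
        s1 = generate_experiment(tiny_config, seed=11)
        s2 = generate_experiment(tiny_config, seed=11)
        for c in CONDITIONS:
            assert np.array_equal(s1.meg[0][c], s2.meg[0][c])
            assert np.array_equal(s1.gaze[1][c].pupil_mm,
                                  s2.gaze[1][c].pupil_mm, equal_nan=True)
            assert np.array_equal(s1.telemetry[0][c].lane_pos,
                                  s2.telemetry[0][c].lane_pos)
        assert np.array_equal(s1.empty_room, s2.empty_room)

    def test_block_inventory(self, tiny_config):
        study = generate_experiment(tiny_config, seed=11)
        assert study.n_subjects == 2
        for s in range(2):
            assert set(study.meg[s]) == set(CONDITIONS) | {
                f"baseline:{c}" for c in CONDITIONS}

    def test_empty_room_matches_noise_covariance(self):
        cfg = StudyConfig(n_subjects=1, n_sensors=24,
                          block_duration_s=5.0, baseline_duration_s=5.0,
                          empty_room_duration_s=300.0,
                          gaze_defaults=GazeParams(duration_s=5.0),
                          telemetry_defaults=TelemetryParams(duration_s=5.0))
        study = generate_experiment(cfg, seed=3)
        sample = np.cov(study.empty_room)
        truth = study.model.noise_cov
        # empty room is scaled noise: compare correlation structure
        def corr(C):
            d = np.sqrt(np.diag(C))
            return C / np.outer(d, d)
        assert np.abs(corr(sample) - corr(truth)).max() < 0.1

    def test_planted_beta_effect_orders_conditions(self):
        import scipy.signal
        patch = [10, 11, 12]
        cfg = StudyConfig(n_subjects=1, n_sensors=48, block_duration_s=60.0,
                          baseline_duration_s=5.0, empty_room_duration_s=5.0,
                          gaze_defaults=GazeParams(duration_s=5.0),
                          telemetry_defaults=TelemetryParams(duration_s=5.0))
        cfg.effects = [EffectSpec.valence_effect("beta", patch, 1.5)]
        study = generate_experiment(cfg, seed=9)
        pinv = np.linalg.pinv(study.model.lead_field.gain)
        sos = scipy.signal.butter(2, [18.5, 21.5], btype="bandpass",
                                  fs=100.0, output="sos")
        power = {}
        for cond in ("LW/LV", "LW/NV", "LW/HV"):
            src = pinv @ study.meg[0][cond]
            filt = scipy.signal.sosfiltfilt(sos, src[patch], axis=1)
            power[cond] = filt.var(axis=1).mean()
        assert power["LW/LV"] > power["LW/NV"]
        assert power["LW/HV"] > power["LW/NV"]


class TestGazeBlock:
    def test_blink_count_poisson_mean(self):
        params = GazeParams(duration_s=30.0, blink_rate_hz=0.2)
        counts = [len(generate_gaze_block(params, seed=s).blinks)
                  for s in range(200)]
        # E[count] = r*T = 6; merged overlaps bias slightly downward
        assert abs(np.mean(counts) - 6.0) < 0.7

    def test_dilation_offset_shifts_median(self):
        base = GazeParams(duration_s=60.0)
        up = GazeParams(duration_s=60.0, dilation_offset_mm=0.3)
        d = [np.nanmedian(generate_gaze_block(up, seed=s).pupil_mm)
             - np.nanmedian(generate_gaze_block(base, seed=s).pupil_mm)
             for s in range(20)]
        assert abs(np.mean(d) - 0.3) < 0.02

    def test_nan_only_inside_blinks(self):
        block = generate_gaze_block(GazeParams(duration_s=30.0,
                                               blink_rate_hz=0.3), seed=4)
        nan_idx = np.flatnonzero(np.isnan(block.pupil_mm))
        inside = np.zeros(block.pupil_mm.size, dtype=bool)
        for _, row in block.blinks.iterrows():
            a = int(row.onset_s * block.sfreq)
            b = int(np.ceil(row.offset_s * block.sfreq))
            inside[a:b] = True
        assert inside[nan_idx].all()
        assert not np.isnan(block.pupil_mm[~inside]).any()

    def test_events_within_bounds_and_durations_positive(self):
        block = generate_gaze_block(GazeParams(duration_s=20.0), seed=5)
        fx = block.fixations
        assert (fx["duration_s"] > 0).all()
        assert (fx["onset_s"] >= 0).all()
        assert (fx["offset_s"] <= 20.0).all()


class TestTelemetryBlock:
    def test_zero_volatility_constant_acceleration(self):
        params = TelemetryParams(duration_s=20.0, accel_volatility=0.0)
        block = generate_telemetry_block(params, seed=0)
        assert np.allclose(np.diff(block.accel), 0.0)

    def test_zero_violation_rate(self):
        params = TelemetryParams(duration_s=60.0, violation_rate_hz=0.0)
        block = generate_telemetry_block(params, seed=1)
        assert len(block.violations) == 0

    def test_lane_noise_scales_deviation(self):
        lo = TelemetryParams(duration_s=60.0, lane_noise_m=0.2,
                             n_lane_changes=0)
        hi = TelemetryParams(duration_s=60.0, lane_noise_m=0.4,
                             n_lane_changes=0)
        dev_lo = np.mean([np.abs(generate_telemetry_block(lo, s).lane_pos).mean()
                          for s in range(30)])
        dev_hi = np.mean([np.abs(generate_telemetry_block(hi, s).lane_pos).mean()
                          for s in range(30)])
        assert dev_hi > dev_lo

    def test_brake_within_bounds(self):
        block = generate_telemetry_block(TelemetryParams(duration_s=30.0),
                                         seed=2)
        assert block.brake.min() >= 0.0 and block.brake.max() <= 1.0


class TestPersistence:
    def test_save_load_roundtrip(self, tiny_config, tmp_path):
        study = generate_experiment(tiny_config, seed=21)
        path = tmp_path / "study.h5"
        simulate.save_study(study, path)
        loaded = simulate.load_study(path)
        assert loaded.n_subjects == study.n_subjects
        assert loaded.config.sfreq == study.config.sfreq
        for c in CONDITIONS:
            assert np.array_equal(loaded.meg[0][c], study.meg[0][c])
        assert np.array_equal(loaded.model.lead_field.gain,
                              study.model.lead_field.gain)
        assert np.array_equal(loaded.true_exponents, study.true_exponents)
        assert (loaded.gaze[0]["LW/LV"].fixations.to_numpy()
                == study.gaze[0]["LW/LV"].fixations.to_numpy()).all()
        assert list(loaded.telemetry[1]["HW/HV"].violations["kind"]) \
            == list(study.telemetry[1]["HW/HV"].violations["kind"])


class TestFactorialCohort:
    def test_null_has_no_systematic_condition_differences(self):
        data = simulate.generate_factorial_cohort(effect_vertices=None,
                                                  seed=0)
        cond_means = data.mean(axis=(0, 2))
        assert np.abs(cond_means - cond_means.mean()).max() < 0.05

    def test_planted_effect_shifts_target_cells(self):
        data = simulate.generate_factorial_cohort(
            effect_vertices=np.arange(10), seed=0)
        hw = data[:, 3:, :10].mean()
        lw = data[:, :3, :10].mean()
        assert hw - lw > 0.1
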