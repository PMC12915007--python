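"""End-to-end orchestration of the three analyses on a synthetic study.

``run_main_effects``: 5-s epoching -> (optional) amplitude rejection ->
trial-count equalization -> Morlet CSD -> DICS source power per condition
and baseline -> relative change -> per-vertex source spectra -> aperiodic
fit/subtraction -> individual band peaks -> narrowband power maps ->
factorial permutation clustering -> cluster post-hocs.

``run_interaction_decoding``: gamma FIR band-pass -> 2-s epochs ->
multiclass CSP + LDA cross-validation -> Haufe patterns -> minimum-norm
localization -> F1-weighted grand average -> 90th-percentile ROI gamma
contrasts.

``run_behavioural``: gaze and driving measures per block, baseline
correction, condition contrasts with signed-rank + FDR and bootstrap CIs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import cluster_stats, decoding, gaze, driving, preprocess, source, spectral
from .simulate import CONDITIONS, SyntheticStudy

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "run_main_effects", "run_interaction_decoding",
           "run_behavioural"]

#: the four conditions entering the interaction decoding (no neutral speech)
DECODING_CONDITIONS = ("LW/LV", "LW/HV", "HW/LV", "HW/HV")


@dataclass
class AnalysisConfig:
    """Everything that determines an analysis run on a given study."""

    epoch_length_main_s: float = 5.0
    epoch_length_decode_s: float = 2.0
    csd_fmin: float = 1.0
    csd_fmax: float = 42.0
    csd_step: float = 1.0
    n_cycles: float = 3.0
    multitaper_bandwidth: float = 2.0
    amplitude_threshold: float | None = None   # raw units; None = skip
    gamma_band: tuple[float, float] = (30.0, 42.0)
    n_permutations: int = 5000
    cluster_alpha: float = 0.05
    test_alpha: float = 0.05
    cv_k: int = 10
    cv_repeats: int = 3
    n_csp_components: int = 4
    snr_patterns: float = 3.0
    snr_power: float = 1.0
    depth_exponent: float = 0.8
    reg_fraction: float = 0.05
    roi_percentile: float = 90.0
    n_boot: int = 5000
    seed: int = 0
    effects_tested: tuple = ("main_workload", "main_valence", "interaction")
    bands_tested: tuple = ("alpha", "beta", "gamma")

    def to_dict(self) -> dict:
        return asdict(self)


def _log_stage(name: str, t0: float, **info) -> None:
    logger.info("stage=%s wall_s=%.2f %s", name, time.perf_counter() - t0,
                " ".join(f"{k}={v}" for k, v in info.items()))


def _stage(name: str, block_id: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as err:
        raise RuntimeError(f"stage {name!r} failed on block {block_id!r}: "
                           f"{err}") from err


def _prepare_epochs(study: SyntheticStudy, subject: int, conditions,
                    length_s: float, threshold) -> dict[str, preprocess.EpochSet]:
    """Segment, reject and (for experimental conditions) equalize."""
    out = {}
    for cond in conditions:
        block = study.meg[subject][cond]
        es = _stage("segment", cond, preprocess.segment_epochs,
                    block, study.sfreq, length_s, label=cond)
        if threshold is not None:
            es, _ = _stage("reject", cond, preprocess.reject_amplitude,
                           es, threshold)
        out[cond] = es
    return out


def _source_spectra(csd_by_block: dict, common_csd: np.ndarray,
                    frequencies: np.ndarray, gain, whitener, reg_fraction):
    """Frequency-resolved DICS power: broadband filters from the common CSD
    evaluated against every block's per-frequency CSD."""
    filters = source.dics_filters(common_csd, gain, whitener,
                                  reg_fraction=reg_fraction)
    spectra = {}
    for block, csd in csd_by_block.items():
        P = np.empty((gain.shape[1], frequencies.size))
        for fi in range(frequencies.size):
            P[:, fi] = source.dics_power(filters, csd.matrices[fi],
                                         whitener).values
        spectra[block] = spectral.SpectrumSet(frequencies=frequencies,
                                              power=P)
    return spectra, filters


def _periodic_residual(spectrum: spectral.SpectrumSet
                       ) -> spectral.SpectrumSet:
    """Aperiodic-subtracted (periodic) residual of every series."""
    models = [spectral.fit_aperiodic(spectrum, series=i, refine=False)
              for i in range(spectrum.power.shape[0])]
    return spectral.subtract_aperiodic(spectrum, models)


def individual_band_peaks(study: SyntheticStudy, config: AnalysisConfig,
                          subject: int) -> spectral.BandScheme:
    """Per-subject band peaks from baseline-block sensor spectra.

    Baseline blocks are epoched (5 s), multitaper power spectra computed per
    sensor, each sensor's spectrum parameterized, and per-band peaks
    averaged across sensors (band-midpoint fallback when no peak is found).
    """
    baselines = [study.meg[subject][f"baseline:{c}"] for c in CONDITIONS]
    es = [preprocess.segment_epochs(b, study.sfreq,
                                    config.epoch_length_main_s)
          for b in baselines]
    data = np.concatenate([e.data for e in es if e.n_epochs], axis=0)
    psd = spectral.multitaper_psd(data, sfreq=study.sfreq,
                                  bandwidth=config.multitaper_bandwidth,
                                  fmin=config.csd_fmin, fmax=config.csd_fmax)
    models = [spectral.fit_aperiodic(psd, series=i)
              for i in range(psd.power.shape[0])]
    return spectral.detect_band_peaks(models)


def run_main_effects(study: SyntheticStudy, config: AnalysisConfig) -> dict:
    """DICS band-power factorial analysis with permutation clustering."""
    t0 = time.perf_counter()
    rng = np.random.default_rng(config.seed)
    whitener = source.compute_whitener(study.empty_room)
    gain = study.model.lead_field.gain
    freqs = np.arange(config.csd_fmin, config.csd_fmax + 1e-9,
                      config.csd_step)

    rel_change = {b: [] for b in config.bands_tested}
    schemes = []
    for s in range(study.n_subjects):
        scheme = individual_band_peaks(study, config, s)
        schemes.append(scheme)
        blocks = list(CONDITIONS) + [f"baseline:{c}" for c in CONDITIONS]
        epochs = _prepare_epochs(study, s, blocks,
                                 config.epoch_length_main_s,
                                 config.amplitude_threshold)
        eq = preprocess.equalize_counts({c: epochs[c] for c in CONDITIONS})
        epochs.update(eq)
        csd_by_block = {
            b: _stage("morlet_csd", b, spectral.morlet_csd,
                      epochs[b], study.sfreq, freqs,
                      n_cycles=config.n_cycles)
            for b in blocks
        }
        common = np.mean(
            [csd_by_block[c].matrices.mean(axis=0) for c in CONDITIONS],
            axis=0)
        spectra, _ = _source_spectra(csd_by_block, common, freqs, gain,
                                     whitener, config.reg_fraction)
        residuals = {b: _stage("fit_aperiodic", b, _periodic_residual, spec)
                     for b, spec in spectra.items()}
        for band in config.bands_tested:
            center = scheme.peaks[band]
            cond_power = {}
            for cond in CONDITIONS:
                p_cond = spectral.band_power(
                    residuals[cond], center, scheme.bandwidth)
                p_base = spectral.band_power(
                    residuals[f"baseline:{cond}"], center, scheme.bandwidth)
                if (p_base <= 0).any():
                    # periodic residual can dip below zero at off-peak
                    # vertices: fall back to raw band power for the ratio
                    p_cond = spectral.band_power(
                        spectra[cond], center, scheme.bandwidth)
                    p_base = spectral.band_power(
                        spectra[f"baseline:{cond}"], center,
                        scheme.bandwidth)
                rel = source.relative_change(
                    source.SourcePowerMap(p_cond, band=band, condition=cond,
                                          subject=s),
                    source.SourcePowerMap(p_base, band=band, subject=s))
                cond_power[cond] = rel.values
            rel_change[band].append(
                np.stack([cond_power[c] for c in CONDITIONS]))
    _log_stage("source_band_power", t0, n_subjects=study.n_subjects)

    adjacency = study.model.grid.adjacency
    results: dict[str, dict] = {"bands": {}, "config": config.to_dict(),
                                "band_peaks": [s.peaks for s in schemes]}
    cluster_powers = {}   # (band, effect, idx) -> per-subject cluster means
    for band in config.bands_tested:
        dataset = cluster_stats.FactorialDataset(
            np.stack(rel_change[band]))
        band_out = {"clusters": {}, "posthoc": {}}
        for effect in config.effects_tested:
            res = cluster_stats.permutation_cluster_test(
                dataset, adjacency, effect,
                n_permutations=config.n_permutations,
                cluster_alpha=config.cluster_alpha,
                seed=int(rng.integers(2 ** 31)))
            band_out["clusters"][effect] = res
            for ci, cl in enumerate(res.significant(config.test_alpha)):
                means = dataset.power[:, :, cl.vertices].mean(axis=2)
                by_cond = {c: means[:, k] for k, c in enumerate(CONDITIONS)}
                contrasts, summaries = cluster_stats.pairwise_condition_contrasts(
                    _collapse_for_effect(by_cond, effect),
                    alpha=config.test_alpha, n_boot=config.n_boot,
                    seed=int(rng.integers(2 ** 31)))
                band_out["posthoc"][(effect, ci)] = {
                    "contrasts": contrasts, "summaries": summaries}
                cluster_powers[(band, effect, ci)] = means.mean(axis=1)
        results["bands"][band] = band_out

    # rank correlations between the powers of significant clusters
    corr_rows = []
    keys = list(cluster_powers)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            rho, p = cluster_stats.spearman_corr(cluster_powers[keys[i]],
                                                 cluster_powers[keys[j]])
            corr_rows.append({"a": keys[i], "b": keys[j], "rho": rho, "p": p})
    results["cluster_correlations"] = corr_rows
    _log_stage("main_effects", t0)
    return results


def _collapse_for_effect(by_cond: dict[str, np.ndarray], effect: str
                         ) -> dict[str, np.ndarray]:
    """Collapse condition means to the tested factor's levels for post-hocs."""
    if effect == "main_workload":
        return {
            "LW": np.mean([by_cond[c] for c in CONDITIONS if c.startswith("LW")],
                          axis=0),
            "HW": np.mean([by_cond[c] for c in CONDITIONS if c.startswith("HW")],
                          axis=0),
        }
    if effect == "main_valence":
        return {
            v: np.mean([by_cond[c] for c in CONDITIONS if c.endswith(v)],
                       axis=0)
            for v in ("LV", "NV", "HV")
        }
    return dict(by_cond)


def run_interaction_decoding(study: SyntheticStudy, config: AnalysisConfig,
                             gamma_center: float | None = None) -> dict:
    """Four-class gamma-band CSP+LDA decoding with pattern localization."""
    t0 = time.perf_counter()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gamma_band
    if gamma_center is None:
        gamma_center = (lo + hi) / 2.0

    subject_results: list[decoding.DecodingResult] = []
    pattern_maps: list[decoding.PatternMap] = []
    inv_patterns = source.minimum_norm_operator(
        study.model.lead_field.gain, study.model.noise_cov,
        snr=config.snr_patterns, depth_exponent=config.depth_exponent)
    inv_power = source.minimum_norm_operator(
        study.model.lead_field.gain, study.model.noise_cov,
        snr=config.snr_power, depth_exponent=config.depth_exponent)

    power_by_condition = {c: [] for c in DECODING_CONDITIONS}
    for s in range(study.n_subjects):
        sets = {}
        for cond in DECODING_CONDITIONS:
            filtered = _stage("bandpass_fir", cond, preprocess.bandpass_fir,
                              study.meg[s][cond], study.sfreq, lo, hi)
            sets[cond] = preprocess.segment_epochs(
                filtered, study.sfreq, config.epoch_length_decode_s,
                label=cond)
            if config.amplitude_threshold is not None:
                sets[cond], _ = preprocess.reject_amplitude(
                    sets[cond], config.amplitude_threshold)
        sets = preprocess.equalize_counts(sets)
        X = np.concatenate([sets[c].data for c in DECODING_CONDITIONS])
        y = np.concatenate([np.full(sets[c].n_epochs, c)
                            for c in DECODING_CONDITIONS])
        res = decoding.crossval_decode(
            X, y, k=config.cv_k, repeats=config.cv_repeats,
            n_components=config.n_csp_components,
            seed=int(rng.integers(2 ** 31)), n_boot=config.n_boot)
        subject_results.append(res)
        pattern_maps.append(decoding.localize_patterns(res.patterns,
                                                       inv_patterns))
        for cond in DECODING_CONDITIONS:
            pmap = source.source_band_power(
                sets[cond], inv_power, band_center=gamma_center,
                bandwidth=config.multitaper_bandwidth)
            power_by_condition[cond].append(pmap.values)

    f1s = np.array([r.mean_f1 for r in subject_results])
    grand = decoding.weighted_grand_average(pattern_maps, f1s)
    roi = decoding.percentile_roi_contrast(
        grand, {c: np.stack(v) for c, v in power_by_condition.items()},
        q=config.roi_percentile, alpha=config.test_alpha,
        n_boot=config.n_boot, seed=int(rng.integers(2 ** 31)))

    confusion = np.sum([r.confusion for r in subject_results], axis=0)
    _log_stage("interaction_decoding", t0, mean_f1=float(f1s.mean()))
    return {
        "subject_results": subject_results,
        "mean_f1": float(f1s.mean()),
        "f1_by_subject": f1s,
        "pooled_confusion": confusion,
        "classes": subject_results[0].classes,
        "grand_average_pattern": grand,
        "roi_contrasts": roi,
        "gamma_center_hz": gamma_center,
        "config": config.to_dict(),
    }


def run_behavioural(study: SyntheticStudy, config: AnalysisConfig) -> dict:
    """Gaze and driving tables with baseline correction and contrasts."""
    t0 = time.perf_counter()
    rng = np.random.default_rng(config.seed)
    rows = []
    score_rows = []
    for s in range(study.n_subjects):
        measures = {c: driving.driving_measures(study.telemetry[s][c])
                    for c in CONDITIONS}
        scores = driving.composite_score(measures)
        for cond in CONDITIONS:
            gm = gaze.gaze_metrics(study.gaze[s][cond])
            gb = gaze.gaze_metrics(study.gaze[s][f"baseline:{cond}"])
            rows.append({
                "subject": s, "condition": cond,
                "workload": cond.split("/")[0],
                "valence": cond.split("/")[1],
                "dispersion": gaze.baseline_correct(gm.dispersion,
                                                    gb.dispersion),
                "blink_rate": gaze.baseline_correct(gm.blink_rate,
                                                    gb.blink_rate),
                "pupil_median_mm": gaze.baseline_correct(
                    gm.pupil_median_mm, gb.pupil_median_mm),
                "ipa": gaze.baseline_correct(gm.ipa, gb.ipa),
            })
            score_rows.append({"subject": s, "condition": cond,
                               "driving_score": scores[cond],
                               **{f"raw_{k}": v for k, v in
                                  asdict(measures[cond]).items()}})
    gaze_table = pd.DataFrame(rows)
    driving_table = pd.DataFrame(score_rows)

    contrasts = {}
    for metric in ("dispersion", "blink_rate", "pupil_median_mm", "ipa",
                   "driving_score"):
        table = driving_table if metric == "driving_score" else gaze_table
        by_workload = {
            w: table[table["condition"].str.startswith(w)]
            .groupby("subject")[metric].mean().to_numpy()
            for w in ("LW", "HW")
        }
        rows_, summ = cluster_stats.pairwise_condition_contrasts(
            by_workload, alpha=config.test_alpha, n_boot=config.n_boot,
            seed=int(rng.integers(2 ** 31)))
        by_valence = {
            v: table[table["condition"].str.endswith(v)]
            .groupby("subject")[metric].mean().to_numpy()
            for v in ("LV", "NV", "HV")
        }
        vrows, vsumm = cluster_stats.pairwise_condition_contrasts(
            by_valence, alpha=config.test_alpha, n_boot=config.n_boot,
            seed=int(rng.integers(2 ** 31)))
        contrasts[metric] = {"workload": rows_, "workload_summary": summ,
                             "valence": vrows, "valence_summary": vsumm}
    _log_stage("behavioural", t0)
    return {"gaze_table": gaze_table, "driving_table": driving_table,
            "contrasts": contrasts, "config": config.to_dict()}
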