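"""End-to-end orchestration: simulate, clean, measure, fit, threshold, score.

A single root seed drives everything: ``numpy.random.SeedSequence(seed)``
spawns one child per subject plus one for group-level randomness, so each
stage is independently reproducible and two runs with the same
configuration produce bit-identical results.

Two EEG modes are available.  ``eeg="synthesize"`` runs the full
measurement chain (synthetic multi-channel EEG, average reference,
retention segmentation, amplitude rejection, spectral band power);
``eeg="truth-power"`` feeds the generator's per-trial band power straight
into the design matrix, which isolates the GLM/inference path and is what
the large repeated-run recovery harnesses use.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import eeg_clean, fusion_glm, load_roi, paradigm_sim, spectral
from .fusion_glm import StatMap, ThresholdSpec
from .paradigm_sim import ParadigmConfig, SimulationTruth

__all__ = ["RunConfig", "ResultBundle", "run_pipeline", "validate_config"]

log = logging.getLogger("wmfusion")


@dataclass
class RunConfig:
    """Everything a reproducible multi-subject run needs."""

    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    truth: SimulationTruth | None = None
    thresholds: ThresholdSpec = field(default_factory=ThresholdSpec)
    n_subjects: int = 16
    seed: int = 0
    eeg: str = "synthesize"  # synthesize | truth-power
    amplitude_reject_uv: float = 150.0
    analysis_window_s: float = 2.5

    def resolved_truth(self) -> SimulationTruth:
        return self.truth if self.truth is not None else paradigm_sim.default_truth(self.paradigm)


def validate_config(config: RunConfig) -> list[str]:
    """All invariant violations across the nested configuration."""
    v = list(config.paradigm.validate())
    v += config.thresholds.validate()
    if config.n_subjects < 2:
        v.append("n_subjects: must be >= 2")
    if config.eeg not in ("synthesize", "truth-power"):
        v.append("eeg: must be 'synthesize' or 'truth-power'")
    truth = config.resolved_truth()
    v += truth.validate()
    grid = tuple(config.paradigm.grid_shape)
    for b in truth.band_names:
        if truth.coupling_map[b].shape != grid:
            v.append(f"truth.coupling_map[{b}]: shape does not match paradigm.grid_shape")
    return v


@dataclass
class SubjectResult:
    schedule: paradigm_sim.TrialSchedule
    power_table: spectral.BandPowerTable
    fit: fusion_glm.GLMFit
    n_rejected: int


@dataclass
class ResultBundle:
    """All artifacts of one seeded multi-subject run."""

    config: RunConfig
    subjects: list[SubjectResult]
    group_mod_maps: dict[str, StatMap]
    group_mod_masks: dict[str, np.ndarray]
    group_load_map: StatMap
    rois: load_roi.ROISet
    estimates: pd.DataFrame
    effects: pd.DataFrame
    recovery: dict
    provenance: dict

    @property
    def sign_table_text(self) -> str:
        truth = self.config.resolved_truth()
        return load_roi.render_sign_table(self.effects, truth.band_names)

    def save(self, out_dir) -> None:
        from pathlib import Path

        from . import io as wio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        voxel_mm = tuple(self.config.paradigm.voxel_mm)
        wio.save_map(self.group_load_map.t, voxel_mm, out / "group_load_t.nii")
        for b, m in self.group_mod_maps.items():
            wio.save_map(m.t, voxel_mm, out / f"group_mod_{b}_t.nii")
        wio.save_map(self.rois.labels.astype(float), voxel_mm, out / "load_rois.nii")
        self.estimates.to_csv(out / "roi_estimates.tsv", sep="\t", index=False)
        self.effects.to_csv(out / "load_effects.tsv", sep="\t", index=False)
        (out / "sign_table.txt").write_text(self.sign_table_text + "\n")
        wio.save_json(self.recovery, out / "recovery.json")
        wio.save_json(self.provenance, out / "provenance.json")


def _measure_band_power(
    rec: eeg_clean.EEGRecording,
    schedule: paradigm_sim.TrialSchedule,
    truth: SimulationTruth,
    config: RunConfig,
) -> tuple[spectral.BandPowerTable, int]:
    """EEG measurement chain: reference, segment, reject, band power.

    Rejected trials keep a row in the table (the per-load mean of retained
    trials) so the modulator columns stay aligned with the schedule while
    contributing nothing after mean-centring.
    """
    rec = eeg_clean.rereference_average(rec)
    segs = eeg_clean.extract_retention_segments(rec, schedule, window_s=config.analysis_window_s)
    segs = eeg_clean.reject_artifact_segments(segs, threshold_uv=config.amplitude_reject_uv)
    table = spectral.band_power_table(
        segs.segments, segs.fs, segs.trial_index, segs.loads,
        bands=truth.bands, channel_labels=rec.labels,
    )
    bad = ~segs.retained
    for load in np.unique(table.loads):
        sel = table.loads == load
        keep = sel & segs.retained
        if keep.any() and (sel & bad).any():
            table.rms[sel & bad] = table.rms[keep].mean(axis=0)
    return table, int(bad.sum())


def _subject(
    config: RunConfig,
    truth: SimulationTruth,
    rng: np.random.Generator,
) -> SubjectResult:
    par = config.paradigm
    schedule = paradigm_sim.make_trial_schedule(par, rng)
    trial_power = paradigm_sim.draw_band_power(schedule, truth, rng)
    if config.eeg == "synthesize":
        rec = paradigm_sim.synthesize_eeg(
            schedule, trial_power, truth, par, rng,
            analysis_window_s=config.analysis_window_s,
        )
        table, n_rej = _measure_band_power(rec, schedule, truth, config)
    else:
        table, n_rej = trial_power.as_band_power_table(), 0
    bold = paradigm_sim.synthesize_bold(schedule, trial_power, truth, par, rng)
    dm = fusion_glm.build_design_matrix(
        schedule, table, tr_s=par.tr_s, n_scans=par.n_scans,
    )
    fit = fusion_glm.fit_glm_ar1(bold, dm)
    return SubjectResult(schedule=schedule, power_table=table, fit=fit, n_rejected=n_rej)


def _signed_cluster_mask(
    stat_map: StatMap, voxel_p: float, k: int, connectivity: int = 18
) -> np.ndarray:
    """Two-direction voxel threshold + cluster-size filter; boolean mask."""
    t_crit = float(stats.t.isf(voxel_p, stat_map.df))
    out = np.zeros(stat_map.t.shape, dtype=bool)
    for sgn in (1.0, -1.0):
        supra = sgn * stat_map.t > t_crit
        labels, n = fusion_glm.cluster_labels_array(supra, connectivity=connectivity)
        for lab in range(1, n + 1):
            vox = labels == lab
            if vox.sum() >= k:
                out |= vox
    return out


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute simulate → clean → spectra → GLM → thresholds → load ROI."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid run config: " + "; ".join(violations))
    truth = config.resolved_truth()
    thr = config.thresholds
    children = np.random.SeedSequence(config.seed).spawn(config.n_subjects + 1)
    t_start = time.time()
    subjects: list[SubjectResult] = []
    for s in range(config.n_subjects):
        t0 = time.time()
        try:
            subjects.append(_subject(config, truth, np.random.default_rng(children[s])))
        except Exception as err:
            raise RuntimeError(f"stage subject[{s}] failed: {err}") from err
        log.info("subject %d done in %.1f s", s, time.time() - t0)

    try:
        # load-independent EEG-BOLD coupling: per band, the subject-level
        # modulator betas averaged over the two load conditions
        group_mod_maps: dict[str, StatMap] = {}
        group_mod_masks: dict[str, np.ndarray] = {}
        for b in truth.band_names:
            per_subject = [
                0.5 * (sr.fit.beta_map(f"ss2_mod_{b}") + sr.fit.beta_map(f"ss5_mod_{b}"))
                for sr in subjects
            ]
            gmap = fusion_glm.group_onesample(per_subject, voxel_mm=config.paradigm.voxel_mm)
            group_mod_maps[b] = gmap
            group_mod_masks[b] = _signed_cluster_mask(gmap, thr.voxel_p, thr.k_voxels)
        # task load contrast (retention ss5 - ss2) for the ROI mask
        load_betas = [
            sr.fit.beta_map("ss5_retention") - sr.fit.beta_map("ss2_retention")
            for sr in subjects
        ]
        group_load_map = fusion_glm.group_onesample(load_betas, voxel_mm=config.paradigm.voxel_mm)
    except Exception as err:
        raise RuntimeError(f"stage group failed: {err}") from err

    try:
        rois = load_roi.load_contrast_mask(group_load_map, q=thr.fdr_q, k=thr.k_voxels)
        if rois.n_rois:
            estimates = load_roi.extract_roi_estimates(
                rois, [sr.fit for sr in subjects], bands=truth.band_names
            )
            effects = load_roi.paired_band_tests(estimates)
        else:
            log.warning("load contrast yields no ROI at q=%g, k=%d", thr.fdr_q, thr.k_voxels)
            estimates = pd.DataFrame(columns=["roi", "subject", "band", "load", "estimate"])
            effects = pd.DataFrame(columns=["roi", "band", "t", "p", "sign", "tier"])
    except Exception as err:
        raise RuntimeError(f"stage load_roi failed: {err}") from err

    recovery = load_roi.recovery_report(
        truth, group_mod_masks, {b: m.t for b, m in group_mod_maps.items()}, effects, rois
    )
    provenance = {
        "seed": config.seed,
        "n_subjects": config.n_subjects,
        "eeg_mode": config.eeg,
        "grid_shape": list(config.paradigm.grid_shape),
        "elapsed_s": time.time() - t_start,
        "rho_hats": [sr.fit.rho_hat for sr in subjects],
        "n_rejected": [sr.n_rejected for sr in subjects],
    }
    return ResultBundle(
        config=config,
        subjects=subjects,
        group_mod_maps=group_mod_maps,
        group_mod_masks=group_mod_masks,
        group_load_map=group_load_map,
        rois=rois,
        estimates=estimates,
        effects=effects,
        recovery=recovery,
        provenance=provenance,
    )
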