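"""Synthetic simultaneous EEG-fMRI generator for a Sternberg paradigm.

Emulates the study conditions end to end with known ground truth: a
randomized event schedule (2.5 s encoding, 3.5 s retention, 2 s probe,
jittered 1.8-2.5 s ISI with 2.0 s mean, 40 trials per set size, six 24.5 s
baseline blocks), per-trial band-limited EEG power that fluctuates
lognormally and carries load effects, multi-channel EEG with band-specific
scalp topographies over 1/f background, and BOLD volumes in which selected
voxels respond to task phases and couple (with signed weights) to the
per-trial band-power modulators through the hemodynamic response, on top
of AR(1) noise.

The trial ISI is drawn from a Beta(2, 5) distribution scaled onto
[1800, 2500] ms, whose mean is exactly 2000 ms — a uniform draw on the
printed range could not have that mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .eeg_clean import EEGRecording
from . import spectral
from .spectral import DEFAULT_BANDS, BandDefinition

__all__ = [
    "ParadigmConfig",
    "Event",
    "TrialSchedule",
    "SimulationTruth",
    "TrialBandPower",
    "BoldSeries",
    "EEG_CHANNELS_62",
    "make_trial_schedule",
    "draw_isi",
    "draw_band_power",
    "synthesize_eeg",
    "synthesize_bold",
    "inject_gradient_artifact",
    "default_truth",
]

PHASES = ("encoding", "retention", "retrieval")
LOADS = ("ss2", "ss5")

#: 62 signal channels: the 10-20 montage plus the extended positions of a
#: 64-channel MR-compatible cap (EOG/ECG leads excluded).
EEG_CHANNELS_62: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "Pz", "P4", "P6", "P8",
    "PO9", "PO1", "POz", "PO2", "PO10", "O1", "Oz", "O2", "OI1", "OI2", "Iz", "Afz",
)


@dataclass
class ParadigmConfig:
    """Timing, sampling and geometry of one synthetic session."""

    stim_s: float = 2.5
    retention_s: float = 3.5
    probe_s: float = 2.0
    isi_range_ms: tuple[float, float] = (1800.0, 2500.0)
    isi_mean_ms: float = 2000.0
    trials_per_load: int = 40
    loads: tuple[str, ...] = LOADS
    n_baseline_blocks: int = 6
    baseline_block_s: float = 24.5
    tr_s: float = 1.815
    n_scans: int = 554
    eeg_fs_hz: float = 256.0
    n_channels: int = 62
    grid_shape: tuple[int, int, int] = (20, 20, 10)
    voxel_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def validate(self) -> list[str]:
        """Return human-readable invariant violations (empty when valid)."""
        v = []
        for name in ("stim_s", "retention_s", "probe_s", "baseline_block_s", "tr_s", "eeg_fs_hz"):
            if getattr(self, name) <= 0:
                v.append(f"{name}: must be positive")
        lo, hi = self.isi_range_ms
        if not lo < hi:
            v.append("isi_range_ms: low must be below high")
        if not (lo <= self.isi_mean_ms <= hi):
            v.append("isi_mean_ms: must lie inside isi_range_ms")
        if self.trials_per_load < 1:
            v.append("trials_per_load: must be >= 1")
        if self.n_scans < 1:
            v.append("n_scans: must be >= 1")
        if self.n_channels < 1:
            v.append("n_channels: must be >= 1")
        if len(self.grid_shape) != 3 or any(g < 1 for g in self.grid_shape):
            v.append("grid_shape: must be three positive integers")
        return v

    @property
    def scan_duration_s(self) -> float:
        return self.tr_s * self.n_scans

    def channel_labels(self) -> list[str]:
        if self.n_channels <= len(EEG_CHANNELS_62):
            return list(EEG_CHANNELS_62[: self.n_channels])
        extra = [f"EXT{i}" for i in range(self.n_channels - len(EEG_CHANNELS_62))]
        return list(EEG_CHANNELS_62) + extra


@dataclass(frozen=True)
class Event:
    phase: str
    load: str
    onset_s: float
    duration_s: float
    trial_index: int


@dataclass
class TrialSchedule:
    """Time-ordered, non-overlapping task events of one session."""

    events: list[Event]

    def retention_events(self) -> list[Event]:
        return [e for e in self.events if e.phase == "retention"]

    def events_of(self, phase: str, load: str | None = None) -> list[Event]:
        return [
            e
            for e in self.events
            if e.phase == phase and (load is None or e.load == load)
        ]

    @property
    def n_trials(self) -> int:
        return len(self.retention_events())

    @property
    def end_s(self) -> float:
        last = self.events[-1]
        return last.onset_s + last.duration_s

    def trial_loads(self) -> np.ndarray:
        return np.asarray([e.load for e in self.retention_events()])

    def isis_s(self) -> np.ndarray:
        """Realized gaps following each trial's retrieval event."""
        gaps = []
        for i, ev in enumerate(self.events[:-1]):
            if ev.phase == "retrieval":
                gaps.append(self.events[i + 1].onset_s - (ev.onset_s + ev.duration_s))
        return np.asarray(gaps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.onset_s, e.duration_s, e.phase, e.load, e.trial_index) for e in self.events],
            columns=["onset", "duration", "phase", "load", "trial_index"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TrialSchedule":
        df = pd.read_csv(path, sep="\t")
        events = [
            Event(r.phase, r.load, float(r.onset), float(r.duration), int(r.trial_index))
            for r in df.itertuples()
        ]
        return cls(events=events)


def draw_isi(rng: np.random.Generator, config: ParadigmConfig, size: int | None = None):
    """ISI draw(s) in ms: Beta(2, b) scaled to the configured range.

    b is solved so the scaled mean equals ``isi_mean_ms``; for the default
    range and mean this is Beta(2, 5) with mean exactly 2000 ms.
    """
    lo, hi = config.isi_range_ms
    f = (config.isi_mean_ms - lo) / (hi - lo)
    if not 0.0 < f < 1.0:
        raise ValueError("isi_mean_ms must lie strictly inside isi_range_ms")
    a = 2.0
    b = a * (1.0 - f) / f
    return lo + (hi - lo) * rng.beta(a, b, size=size)


def make_trial_schedule(config: ParadigmConfig, rng: np.random.Generator) -> TrialSchedule:
    """Randomized interleaved schedule with evenly interspersed baselines.

    Loads are shuffled into one interleaved order; each trial contributes an
    encoding, retention and retrieval event followed by a jittered ISI gap.
    Baseline blocks occupy evenly spaced slots among the trials.
    """
    violations = config.validate()
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    n_trials = config.trials_per_load * len(config.loads)
    labels = np.repeat(config.loads, config.trials_per_load)
    rng.shuffle(labels)
    # baseline blocks after trial positions i*n/(nb+1), evenly spaced
    nb = config.n_baseline_blocks
    baseline_after = {
        int(round((j + 1) * n_trials / (nb + 1))) - 1 for j in range(nb)
    }
    events: list[Event] = []
    t = 0.0
    for i, load in enumerate(labels):
        events.append(Event("encoding", load, t, config.stim_s, i))
        t += config.stim_s
        events.append(Event("retention", load, t, config.retention_s, i))
        t += config.retention_s
        events.append(Event("retrieval", load, t, config.probe_s, i))
        t += config.probe_s
        if i in baseline_after:
            t += float(draw_isi(rng, config)) / 1000.0
            events.append(Event("baseline", "none", t, config.baseline_block_s, -1))
            t += config.baseline_block_s
        elif i < n_trials - 1:
            t += float(draw_isi(rng, config)) / 1000.0
    schedule = TrialSchedule(events=events)
    if schedule.end_s > config.scan_duration_s:
        raise ValueError(
            f"schedule ({schedule.end_s:.1f} s) exceeds the scan run "
            f"({config.scan_duration_s:.1f} s)"
        )
    return schedule


@dataclass
class TrialBandPower:
    """Ground-truth retention-window band power per trial (µV²/Hz)."""

    values: np.ndarray  # (n_trials, n_bands)
    loads: np.ndarray
    bands: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.loads = np.asarray(self.loads)
        if np.any(self.values <= 0):
            raise ValueError("band power values must be positive")

    def as_band_power_table(self) -> spectral.BandPowerTable:
        return spectral.BandPowerTable(
            trial_index=np.arange(len(self.loads)),
            loads=self.loads,
            bands=self.bands,
            rms=self.values,
        )


@dataclass
class SimulationTruth:
    """Everything the generator knows and the analysis must recover.

    ``coupling_map`` holds the load-independent signed EEG-BOLD coupling per
    band (BOLD units per unit of mean-centred modulator).
    ``coupling_load_delta`` is a signed per-band increment added to the ss5
    modulator coupling inside the load-responsive region; its default signs
    follow the band-power load effects δ (theta +, alpha1 -, gamma +), which
    is what the ROI sign analysis is expected to read out.
    """

    bands: tuple[BandDefinition, ...]
    mean_power: dict[str, float]
    load_effect: dict[str, float]
    trial_cv: dict[str, float]
    topography: dict[str, np.ndarray]
    channel_labels: list[str]
    coupling_map: dict[str, np.ndarray]
    coupling_load_delta: dict[str, np.ndarray]
    task_beta_map: dict[tuple[str, str], np.ndarray]
    ar1_rho: float = 0.3
    noise_sd: float = 1.0
    eeg_noise_uv: float = 2.0
    baseline_bold: float = 100.0
    seed: int | None = None

    def validate(self) -> list[str]:
        v = []
        for b in self.bands:
            if not (0.5 <= b.lo_hz < b.hi_hz <= 50.0):
                v.append(f"band {b.name}: must lie within 0.5-50 Hz")
        for name, cv in self.trial_cv.items():
            if cv < 0:
                v.append(f"trial_cv[{name}]: must be >= 0")
        if not abs(self.ar1_rho) < 1:
            v.append("ar1_rho: must satisfy |rho| < 1")
        for name, mp in self.mean_power.items():
            if mp < 0:
                v.append(f"mean_power[{name}]: must be >= 0")
        return v

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    def coupling_for(self, band: str, load: str) -> np.ndarray:
        c = self.coupling_map[band]
        if load == "ss5":
            c = c + self.coupling_load_delta[band]
        return c


def _blob(grid: tuple[int, int, int], slc: tuple[slice, slice, slice], value: float) -> np.ndarray:
    m = np.zeros(grid)
    m[slc] = value
    return m


def _topography(labels: list[str], peak_prefixes: Iterable[str], peak: float = 1.0, base: float = 0.3) -> np.ndarray:
    w = np.full(len(labels), base)
    for i, lab in enumerate(labels):
        if any(lab.startswith(p) for p in peak_prefixes):
            w[i] = peak
    # normalize so the RMS-over-channels of per-channel band power (which
    # scales with w**2) equals the target scalar: mean(w**4) == 1
    w /= np.mean(w**4) ** 0.25
    return w


# Per-band modulator coupling magnitude: calibrated once so a single synthetic
# subject at noise_sd=1 yields |t| ~ 3 at coupling voxels (the default SNR
# condition).  UNIT_MOD_T is the |t| produced by a coupling of 1 BOLD unit per
# unit modulator when the modulator values have unit standard deviation
# (whitened-column norm of the retention modulator at the default timing:
# 554 scans, TR 1.815 s, 3.5 s retention, 40 trials per load).
UNIT_MOD_T = 21.5


def default_truth(
    config: ParadigmConfig | None = None,
    seed: int | None = None,
) -> SimulationTruth:
    """Study-condition defaults: band powers, load effects, maps.

    Load-effect signs follow the observed pattern (theta +, alpha1 -,
    beta/gamma +, alpha2 none at the contrast-estimate level); coupling
    signs are negative for the low bands and positive for beta2/gamma.
    """
    config = config or ParadigmConfig()
    grid = tuple(config.grid_shape)
    labels = config.channel_labels()
    bands = DEFAULT_BANDS
    mean_power = {"theta": 2.0, "alpha1": 3.0, "alpha2": 2.5, "beta1": 1.0, "beta2": 0.5, "gamma": 0.2}
    delta = {"theta": 0.30, "alpha1": -0.20, "alpha2": 0.0, "beta1": 0.10, "beta2": 0.10, "gamma": 0.15}
    cv = {b.name: 0.3 for b in bands}
    topography = {
        "theta": _topography(labels, ("Afz", "Fp", "F")),
        "alpha1": _topography(labels, ("O", "PO", "Iz")),
        "alpha2": _topography(labels, ("O", "PO", "Iz")),
        "beta1": _topography(labels, ("P", "PO", "O")),
        "beta2": _topography(labels, ("F", "Afz", "P")),
        "gamma": _topography(labels, ("F", "Afz", "FC")),
    }
    # signed coupling per band: low bands negative, beta2/gamma positive,
    # each in its own 4x3x3 voxel region (scaled to the grid when smaller)
    sign = {"theta": -1.0, "alpha1": -1.0, "alpha2": -1.0, "beta1": 1.0, "beta2": 1.0, "gamma": 1.0}
    nx, ny, nz = grid

    # slices are laid out on a 20 x 20 x 10 reference grid and scaled to the
    # configured geometry axis by axis
    def rel(ax_len, a, b, ref):
        return slice(max(0, int(a * ax_len / ref)), max(1, int(np.ceil(b * ax_len / ref))))

    def box(x0, x1, y0, y1, z0, z1):
        return (rel(nx, x0, x1, 20), rel(ny, y0, y1, 20), rel(nz, z0, z1, 10))

    blob_slices = {
        "theta": box(2, 6, 2, 5, 2, 5),
        "alpha1": box(8, 12, 2, 5, 2, 5),
        "alpha2": box(14, 18, 2, 5, 2, 5),
        "beta1": box(2, 6, 7, 10, 5, 8),
        "beta2": box(8, 12, 7, 10, 5, 8),
        "gamma": box(14, 18, 7, 10, 5, 8),
    }
    # coupling magnitude per band giving single-subject |t| ~ 3 at truth
    # voxels: modulator sd is mean_power*cv, so c = 3*noise_sd/(sd*UNIT_MOD_T)
    coupling_map = {}
    for b in bands:
        sd_mod = mean_power[b.name] * cv[b.name]
        mag = 3.0 / (sd_mod * UNIT_MOD_T)
        coupling_map[b.name] = _blob(grid, blob_slices[b.name], sign[b.name] * mag)
    # load-responsive region: 5x3x2 (30 voxels on the default grid)
    load_slc = box(7, 12, 14, 17, 4, 6)
    coupling_load_delta = {}
    for b in bands:
        sd_mod = mean_power[b.name] * cv[b.name]
        mag = 3.0 / (sd_mod * UNIT_MOD_T)
        coupling_load_delta[b.name] = _blob(
            grid, load_slc, np.sign(delta[b.name]) * 0.5 * mag
        )
    # task responses: common visual/motor blobs plus the load effect in the
    # load-responsive region (retention ss5 > ss2)
    enc_slc = box(3, 8, 14, 18, 6, 9)
    ret_common = box(13, 17, 14, 18, 6, 9)
    task_beta_map = {}
    for load in LOADS:
        task_beta_map[("encoding", load)] = _blob(grid, enc_slc, 2.0)
        ret = _blob(grid, ret_common, 2.0)
        ret[load_slc] = 1.5 if load == "ss2" else 3.0
        task_beta_map[("retention", load)] = ret
        task_beta_map[("retrieval", load)] = _blob(grid, enc_slc, 1.0)
    return SimulationTruth(
        bands=bands,
        mean_power=mean_power,
        load_effect=delta,
        trial_cv=cv,
        topography=topography,
        channel_labels=labels,
        coupling_map=coupling_map,
        coupling_load_delta=coupling_load_delta,
        task_beta_map=task_beta_map,
        seed=seed,
    )


def draw_band_power(
    schedule: TrialSchedule,
    truth: SimulationTruth,
    rng: np.random.Generator,
) -> TrialBandPower:
    """Per-trial band power: mean x load factor x lognormal fluctuation.

    value = mean_power_b * (1 + δ_b·[load == ss5]) * L, with L lognormal,
    E[L] = 1 and CV = trial_cv_b.
    """
    loads = schedule.trial_loads()
    n = len(loads)
    names = truth.band_names
    values = np.empty((n, len(names)))
    for j, b in enumerate(names):
        mean = truth.mean_power[b] * (1.0 + truth.load_effect[b] * (loads == "ss5"))
        if np.any(mean <= 0):
            raise ValueError(f"band {b}: load effect drives mean power non-positive")
        cv = truth.trial_cv[b]
        if cv > 0:
            s2 = np.log1p(cv**2)
            noise = rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=n)
        else:
            noise = np.ones(n)
        values[:, j] = mean * noise
    return TrialBandPower(values=values, loads=loads, bands=names)


def _one_over_f_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                      fs: float, rms_uv: float, exponent: float = 1.0) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f."""
    if rms_uv == 0:
        return np.zeros((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (
        rng.standard_normal((n_channels, len(freqs)))
        + 1j * rng.standard_normal((n_channels, len(freqs)))
    )
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    current = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    current[current == 0] = 1.0
    return x * (rms_uv / current)


def synthesize_eeg(
    schedule: TrialSchedule,
    trial_power: TrialBandPower,
    truth: SimulationTruth,
    config: ParadigmConfig,
    rng: np.random.Generator,
    analysis_window_s: float = 2.5,
) -> EEGRecording:
    """Multi-channel EEG whose analysis-window band power is controlled.

    Each band contributes a random-phase sinusoid at the band centre during
    every retention period, weighted across the scalp by the band topography
    (normalized so the RMS-over-channels of band power equals the trial
    target).  Amplitudes are calibrated per trial through the package's own
    spectral chain: the 6x6 cross-band leakage matrix of the unit-amplitude
    oscillations (adjacent bands bleed into each other, e.g. through the
    shared 10 Hz point of alpha1/alpha2) is solved so the analysis window's
    measured band power matches ``trial_power``.  1/f background noise is
    added on top.
    """
    fs = config.eeg_fs_hz
    hi_edge = max(b.hi_hz for b in truth.bands)
    if fs < 2 * hi_edge:
        raise ValueError("eeg_fs_hz must be at least twice the highest band edge")
    n_samples = int(np.ceil(config.scan_duration_s * fs))
    labels = truth.channel_labels
    data = np.zeros((len(labels), n_samples))
    band_list = list(truth.bands)
    n_bands = len(band_list)
    ret_events = schedule.retention_events()
    n_win = int(analysis_window_s * fs)
    for i, ev in enumerate(ret_events):
        s0 = int(np.floor(ev.onset_s * fs))
        s1 = min(int(np.floor((ev.onset_s + ev.duration_s) * fs)), n_samples)
        t = np.arange(s0, s1) / fs
        w0 = int(np.floor((ev.onset_s + ev.duration_s - analysis_window_s) * fs))
        oscs = np.empty((n_bands, s1 - s0))
        leak = np.empty((n_bands, n_bands))  # leak[measured, source]
        for j, band in enumerate(band_list):
            f_c = 0.5 * (band.lo_hz + band.hi_hz)
            phase = rng.uniform(0, 2 * np.pi)
            oscs[j] = np.sin(2 * np.pi * f_c * t + phase)
            win = oscs[j, w0 - s0 : w0 - s0 + n_win]
            spec = spectral.power_spectrum(win[None, :], fs)
            for jj, other in enumerate(band_list):
                leak[jj, j] = spectral.band_power(spec, other)[0]
        target = trial_power.values[i]
        # squared amplitudes solving measured = leak @ a2; the matrix is
        # strongly diagonally dominant, so the solution stays positive for
        # any positive target
        a2 = np.maximum(np.linalg.solve(leak, target), 0.0)
        # refine against the superposed multi-channel window: neighbouring
        # oscillators interfere (phase-dependent cross terms the leakage
        # matrix cannot represent), so measure the actual mix through the
        # analysis chain and rescale a few times
        topo = np.stack([truth.topography[b.name] for b in band_list])
        win_osc = oscs[:, w0 - s0 : w0 - s0 + n_win]
        for _ in range(4):
            mix = (topo * np.sqrt(a2)[:, None]).T @ win_osc
            spec = spectral.power_spectrum(mix, fs)
            measured = np.array(
                [spectral.rms_over_channels(spectral.band_power(spec, b)) for b in band_list]
            )
            ok = measured > 0
            a2[ok] *= target[ok] / measured[ok]
        data[:, s0:s1] += (topo * np.sqrt(a2)[:, None]).T @ oscs
    data += _one_over_f_noise(rng, len(labels), n_samples, fs, truth.eeg_noise_uv)
    return EEGRecording(data=data, fs=fs, labels=list(labels), reference="original")


@dataclass
class BoldSeries:
    """4-D BOLD data: (nx, ny, nz, n_scans) with TR and voxel size."""

    data: np.ndarray
    tr_s: float
    voxel_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4-D (x, y, z, t)")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_scans(self) -> int:
        return self.data.shape[3]

    def as_matrix(self) -> np.ndarray:
        """(n_scans, n_voxels) view used by the GLM."""
        return self.data.reshape(-1, self.n_scans).T


def _ar1_noise(rng: np.random.Generator, n_scans: int, n_voxels: int,
               rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros((n_scans, n_voxels))
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    e = rng.standard_normal((n_scans, n_voxels)) * innov_sd
    e[0] = rng.standard_normal(n_voxels) * sd
    from scipy.signal import lfilter

    return lfilter([1.0], [1.0, -rho], e, axis=0)


def synthesize_bold(
    schedule: TrialSchedule,
    trial_power: TrialBandPower,
    truth: SimulationTruth,
    config: ParadigmConfig,
    rng: np.random.Generator,
) -> BoldSeries:
    """BOLD volumes from task betas, band-power couplings and AR(1) noise.

    The modulator regressors are built by the same design-matrix code the
    analysis uses (mean-centred per band per load, convolved with the HRF),
    so with zero noise a GLM fit recovers the coupling maps exactly.
    """
    from . import fusion_glm

    grid = tuple(config.grid_shape)
    for b in truth.band_names:
        if truth.coupling_map[b].shape != grid:
            raise ValueError(f"coupling map for {b} does not match grid_shape")
    dm = fusion_glm.build_design_matrix(
        schedule,
        trial_power.as_band_power_table(),
        tr_s=config.tr_s,
        n_scans=config.n_scans,
        drop_constant_modulators=False,
    )
    n_vox = int(np.prod(grid))
    Y = np.full((config.n_scans, n_vox), truth.baseline_bold)
    for load in config.loads:
        for phase in PHASES:
            col = dm.column(f"{load}_{phase}")
            Y += np.outer(col, truth.task_beta_map[(phase, load)].ravel())
        for b in truth.band_names:
            name = f"{load}_mod_{b}"
            if name in dm.names:
                col = dm.column(name)
                Y += np.outer(col, truth.coupling_for(b, load).ravel())
    Y += _ar1_noise(rng, config.n_scans, n_vox, truth.ar1_rho, truth.noise_sd)
    data = Y.T.reshape(grid + (config.n_scans,))
    return BoldSeries(data=data, tr_s=config.tr_s, voxel_mm=tuple(config.voxel_mm))


def inject_gradient_artifact(
    rec: EEGRecording,
    event_times,
    template: np.ndarray,
    jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> EEGRecording:
    """Add a repeated artifact template at each event time.

    ``template`` is (n_channels, n_template_samples); onsets are mapped to
    samples by floor(t*fs) with optional Gaussian sample jitter.  A zero
    template returns the recording unchanged.
    """
    template = np.atleast_2d(np.asarray(template, dtype=float))
    out = rec.copy()
    if not np.any(template):
        return out
    if template.shape[0] != rec.n_channels:
        raise ValueError("template must have one row per channel")
    nt = template.shape[1]
    for t in np.asarray(event_times, dtype=float):
        s = int(np.floor(t * rec.fs))
        if jitter_sd > 0:
            if rng is None:
                raise ValueError("jitter_sd > 0 requires an rng")
            s += int(round(rng.normal(0.0, jitter_sd)))
        if s < 0 or s + nt > rec.n_samples:
            raise ValueError(f"artifact event at {t:.3f} s extends beyond the recording")
        out.data[:, s : s + nt] += template
    return out
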