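"""Power spectra, band power, and EEG load statistics.

The retention-window spectral chain: each 2.5 s segment is tapered with
cosine ramps over its first and last ``taper_fraction`` of samples
(a Tukey window), zero-padded to the next power of two, and Fourier
transformed.  At 256 Hz a 2.5 s segment (640 samples) pads to 1024 points,
giving a 0.25 Hz frequency grid.  Band power is the mean one-sided power
density over the grid points inside a band (edges inclusive), and the
scalp-global index is the root mean square of per-channel band power
("square-weighted mean over the scalp").

The working-memory load effect of a power quantity is its fractional
change with set size, (ss5 - ss2) / ss2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "PowerSpectrum",
    "BandPowerTable",
    "StatTable",
    "power_spectrum",
    "band_power",
    "rms_over_channels",
    "load_effect",
    "load_independent_index",
    "electrode_stats",
    "band_power_table",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [lo_hz, hi_hz], both edges inclusive."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not self.lo_hz < self.hi_hz:
            raise ValueError(f"band {self.name}: lo_hz must be < hi_hz")


#: Canonical six-band partition of the 5-40 Hz range used throughout.
#: Note theta's lower neighbourhood (7-8 Hz) and the 10 Hz point shared by
#: alpha1/alpha2 follow the printed band list literally.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 5.0, 7.0),
    BandDefinition("alpha1", 8.0, 10.0),
    BandDefinition("alpha2", 10.0, 13.0),
    BandDefinition("beta1", 13.0, 20.0),
    BandDefinition("beta2", 20.0, 30.0),
    BandDefinition("gamma", 30.0, 40.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


@dataclass
class PowerSpectrum:
    """One-sided power density on a uniform frequency grid.

    ``density`` has shape (n_channels, n_freqs) in µV²/Hz.
    """

    freqs: np.ndarray
    density: np.ndarray

    @property
    def df_hz(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class BandPowerTable:
    """Per-trial band power: per-channel values plus the RMS collapse.

    ``rms`` has shape (n_trials, n_bands); ``channel`` (optional) has shape
    (n_trials, n_channels, n_bands).  ``loads`` labels each trial's set size.
    """

    trial_index: np.ndarray
    loads: np.ndarray
    bands: tuple[str, ...]
    rms: np.ndarray
    channel: np.ndarray | None = None
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.trial_index = np.asarray(self.trial_index)
        self.loads = np.asarray(self.loads)
        self.rms = np.asarray(self.rms, dtype=float)
        if self.rms.shape != (len(self.trial_index), len(self.bands)):
            raise ValueError("rms shape must be (n_trials, n_bands)")

    @property
    def n_trials(self) -> int:
        return len(self.trial_index)

    def values_for(self, band: str, load: str | None = None) -> np.ndarray:
        """RMS band-power values for one band, optionally one load."""
        j = self.bands.index(band)
        v = self.rms[:, j]
        if load is None:
            return v
        return v[self.loads == load]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (t, ld) in enumerate(zip(self.trial_index, self.loads)):
            for j, b in enumerate(self.bands):
                rows.append((int(t), str(ld), b, "RMS", self.rms[i, j]))
                if self.channel is not None:
                    for k, ch in enumerate(self.channel_labels):
                        rows.append((int(t), str(ld), b, ch, self.channel[i, k, j]))
        return pd.DataFrame(rows, columns=["trial", "load", "band", "channel", "power"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BandPowerTable":
        """Rebuild a table from its TSV form (RMS rows; channels optional)."""
        df = pd.read_csv(path, sep="\t")
        rms = df[df["channel"] == "RMS"]
        bands = tuple(dict.fromkeys(rms["band"]))
        piv = rms.pivot(index="trial", columns="band", values="power")[list(bands)]
        loads = rms.drop_duplicates("trial").set_index("trial")["load"]
        trials = piv.index.to_numpy()
        return cls(
            trial_index=trials,
            loads=loads.loc[trials].to_numpy(),
            bands=bands,
            rms=piv.to_numpy(),
        )


@dataclass
class StatTable:
    """Per-electrode (or per-frequency-point) one-sample t results."""

    labels: list[str]
    t: np.ndarray
    p_uncorrected: np.ndarray
    significant_05: np.ndarray
    significant_01: np.ndarray
    significant_fdr05: np.ndarray
    df: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "electrode": self.labels,
                "t": self.t,
                "p": self.p_uncorrected,
                "sig_p05": self.significant_05,
                "sig_p01": self.significant_01,
                "sig_fdr05": self.significant_fdr05,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _tukey_taper(n: int, taper_fraction: float) -> np.ndarray:
    """Cosine ramps over the first and last ``taper_fraction`` of n samples."""
    if not 0.0 <= taper_fraction <= 0.5:
        raise ValueError("taper_fraction must be in [0, 0.5]")
    w = np.ones(n)
    m = int(round(taper_fraction * n))
    if m > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(m) / m))
        w[:m] = ramp
        w[-m:] = ramp[::-1]
    return w


def power_spectrum(
    segment: np.ndarray,
    fs: float,
    taper_fraction: float = 0.1,
    pad_pow2: bool = True,
) -> PowerSpectrum:
    """One-sided power density of a (channel x sample) segment.

    The segment is tapered, optionally zero-padded to the next power of two,
    and transformed; density is normalized by fs and the taper energy so that
    with ``taper_fraction=0, pad_pow2=False`` the integral of the density
    equals the mean squared amplitude (Parseval).
    """
    seg = np.atleast_2d(np.asarray(segment, dtype=float))
    n = seg.shape[1]
    if n < 2:
        raise ValueError("segment must have at least 2 samples")
    w = _tukey_taper(n, taper_fraction)
    tapered = seg * w
    nfft = int(2 ** np.ceil(np.log2(n))) if pad_pow2 else n
    spec = np.fft.rfft(tapered, n=nfft, axis=1)
    # one-sided density; DC and (even-nfft) Nyquist bins are not doubled
    scale = 1.0 / (fs * np.sum(w**2))
    density = (np.abs(spec) ** 2) * scale
    density[:, 1:] *= 2.0
    if nfft % 2 == 0:
        density[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return PowerSpectrum(freqs=freqs, density=density)


def band_power(spec: PowerSpectrum, band: BandDefinition) -> np.ndarray:
    """Mean density over grid points with lo_hz <= f <= hi_hz (per channel)."""
    sel = (spec.freqs >= band.lo_hz) & (spec.freqs <= band.hi_hz)
    if not np.any(sel):
        raise ValueError(f"no frequency grid point falls inside band {band.name}")
    return spec.density[:, sel].mean(axis=1)


def rms_over_channels(values: np.ndarray) -> float:
    """Root mean square across channels: sqrt(mean(values**2))."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("rms_over_channels requires at least one value")
    return float(np.sqrt(np.mean(v**2)))


def load_effect(p_ss5: float, p_ss2: float) -> float:
    """Fractional load effect (ss5 - ss2) / ss2."""
    if p_ss2 <= 0:
        raise ValueError("reference (ss2) power must be positive")
    return (p_ss5 - p_ss2) / p_ss2


def band_power_table(
    segments: np.ndarray,
    fs: float,
    trial_index: np.ndarray,
    loads: np.ndarray,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    channel_labels: list[str] | None = None,
    taper_fraction: float = 0.1,
) -> BandPowerTable:
    """Band power of every segment, per channel and RMS-collapsed.

    ``segments``: (n_trials, n_channels, n_samples).
    """
    segments = np.asarray(segments, dtype=float)
    n_tr, n_ch, _ = segments.shape
    chan = np.empty((n_tr, n_ch, len(bands)))
    for i in range(n_tr):
        spec = power_spectrum(segments[i], fs, taper_fraction=taper_fraction)
        for j, b in enumerate(bands):
            chan[i, :, j] = band_power(spec, b)
    rms = np.sqrt(np.mean(chan**2, axis=1))
    return BandPowerTable(
        trial_index=np.asarray(trial_index),
        loads=np.asarray(loads),
        bands=tuple(b.name for b in bands),
        rms=rms,
        channel=chan,
        channel_labels=list(channel_labels or [f"ch{i}" for i in range(n_ch)]),
    )


def load_independent_index(
    power: np.ndarray,
    baseline: np.ndarray | None = None,
    log_transform: bool = True,
) -> np.ndarray:
    """Retention-power index for the load-independent analysis.

    Raw band power is strictly positive, so testing it against zero is
    vacuous; by default the index is log power (tested against 0 it asks
    whether power exceeds 1 µV²/Hz on the log scale only when a baseline
    is given implicitly by the units).  With ``baseline`` the index is the
    log ratio (or relative change when ``log_transform`` is false) of
    retention power to baseline power, which is the quantity a one-sample
    test against zero meaningfully assesses.
    """
    power = np.asarray(power, dtype=float)
    if np.any(power <= 0):
        raise ValueError("band power must be positive")
    if baseline is None:
        return np.log(power) if log_transform else power
    baseline = np.asarray(baseline, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline power must be positive")
    if log_transform:
        return np.log(power / baseline)
    return (power - baseline) / baseline


def electrode_stats(
    per_subject_values: np.ndarray,
    alternative: str = "two-sided",
    fdr_q: float = 0.05,
    labels: list[str] | None = None,
) -> StatTable:
    """One-sample t-tests against zero per electrode across subjects.

    Uncorrected significance is flagged at p<0.05 and p<0.01, and a
    Benjamini-Hochberg step-up at ``fdr_q`` is run across electrodes.
    Zero-variance electrodes get sentinel values: signed infinite t with
    p=0 when the mean differs from zero, t=0 with p=1 otherwise.
    """
    x = np.atleast_2d(np.asarray(per_subject_values, dtype=float))
    n, m = x.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError("alternative must be two-sided, greater or less")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    t = np.empty(m)
    p = np.empty(m)
    ok = sd > 0
    with np.errstate(invalid="ignore"):
        t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    dist = stats.t(df=n - 1)
    if alternative == "two-sided":
        p[ok] = 2 * dist.sf(np.abs(t[ok]))
    elif alternative == "greater":
        p[ok] = dist.sf(t[ok])
    else:
        p[ok] = dist.cdf(t[ok])
    # degenerate electrodes
    deg = ~ok
    t[deg] = np.where(mean[deg] != 0, np.sign(mean[deg]) * np.inf, 0.0)
    p[deg] = np.where(mean[deg] != 0, 0.0, 1.0)
    if np.any(deg & (mean != 0)):
        warnings.warn("zero-variance electrode(s) with nonzero mean; t set to ±inf")
    rej, _, _, _ = multipletests(p, alpha=fdr_q, method="fdr_bh")
    return StatTable(
        labels=list(labels or [f"e{i}" for i in range(m)]),
        t=t,
        p_uncorrected=p,
        significant_05=p < 0.05,
        significant_01=p < 0.01,
        significant_fdr05=rej,
        df=n - 1,
    )
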