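"""EEG conditioning chain for simultaneous EEG-fMRI recordings.

Order of operations mirrors standard practice for in-scanner EEG:

1. average-artifact (template) subtraction of scanner gradient / cardiac
   artifacts locked to known event times,
2. zero-phase bandpass (0.5-50 Hz, 4th-order Butterworth, ~24 dB/octave
   design slope) and anti-aliased downsampling to 256 Hz,
3. transform to the average reference,
4. segmentation of the last part of each retention period,
5. automatic rejection of segments exceeding an absolute amplitude bound
   (default ±150 µV) in any channel.

Independent-component-based removal of ocular/muscle/cardiac activity is
deliberately not part of this chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "EEGRecording",
    "SegmentSet",
    "subtract_template_artifact",
    "standardize_recording",
    "rereference_average",
    "extract_retention_segments",
    "reject_artifact_segments",
]


@dataclass
class EEGRecording:
    """Multi-channel EEG: (n_channels, n_samples) in µV at ``fs`` Hz."""

    data: np.ndarray
    fs: float
    labels: list[str]
    reference: str = "original"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "EEGRecording":
        return replace(self, data=self.data.copy(), labels=list(self.labels))


@dataclass
class SegmentSet:
    """Equal-length trial segments: (n_trials, n_channels, n_samples)."""

    segments: np.ndarray
    fs: float
    window_s: float
    trial_index: np.ndarray
    loads: np.ndarray
    retained: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.segments = np.asarray(self.segments, dtype=float)
        if self.segments.ndim != 3:
            raise ValueError("segments must be (n_trials, n_channels, n_samples)")
        if self.retained is None:
            self.retained = np.ones(self.segments.shape[0], dtype=bool)
        self.retained = np.asarray(self.retained, dtype=bool)
        self.trial_index = np.asarray(self.trial_index)
        self.loads = np.asarray(self.loads)

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]


def _epoch_bounds(event_times, window, fs, n_samples):
    pre_s, post_s = window
    starts = np.floor((np.asarray(event_times, dtype=float) - pre_s) * fs).astype(int)
    length = int(round((pre_s + post_s) * fs))
    if length < 1:
        raise ValueError("epoch window is empty")
    complete = (starts >= 0) & (starts + length <= n_samples)
    return starts[complete], length


def subtract_template_artifact(
    rec: EEGRecording,
    event_times,
    window: tuple[float, float],
) -> EEGRecording:
    """Average-artifact subtraction around known event times.

    The per-channel mean waveform over all complete epochs
    [t - window[0], t + window[1]) is the template; it is subtracted from
    every epoch occurrence.  Samples outside epochs are unchanged.  The
    template is estimated from all epochs (global mean, not sliding).
    """
    starts, length = _epoch_bounds(event_times, window, rec.fs, rec.n_samples)
    if len(starts) < 2:
        raise ValueError("need at least 2 complete epochs to form a template")
    spacing = np.diff(np.sort(starts))
    if len(spacing) and length > spacing.min():
        raise ValueError("epoch window larger than the inter-event spacing")
    out = rec.copy()
    template = np.zeros((rec.n_channels, length))
    for s in starts:
        template += rec.data[:, s : s + length]
    template /= len(starts)
    for s in starts:
        out.data[:, s : s + length] -= template
    return out


def _bandpass_sos(band: tuple[float, float], fs: float, order: int = 4):
    lo, hi = band
    nyq = fs / 2.0
    if hi >= nyq:
        raise ValueError("band upper edge must be below Nyquist")
    return signal.butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")


def standardize_recording(
    rec: EEGRecording,
    band: tuple[float, float] = (0.5, 50.0),
    fs_out: float = 256.0,
    order: int = 4,
) -> EEGRecording:
    """Zero-phase bandpass then anti-aliased resampling to ``fs_out``.

    The filter is a 4th-order Butterworth (24 dB/octave design slope)
    applied forward and backward, so the effective attenuation is twice
    the design slope and the phase response is zero.
    """
    if fs_out > rec.fs:
        raise ValueError("fs_out must not exceed the input sampling rate")
    if rec.fs < 2 * band[1]:
        raise ValueError("input sampling rate below twice the band upper edge")
    sos = _bandpass_sos(band, rec.fs, order=order)
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    if fs_out != rec.fs:
        from fractions import Fraction

        frac = Fraction(fs_out / rec.fs).limit_denominator(1000)
        filtered = signal.resample_poly(filtered, frac.numerator, frac.denominator, axis=1)
    return EEGRecording(data=filtered, fs=fs_out, labels=list(rec.labels), reference=rec.reference)


def rereference_average(rec: EEGRecording) -> EEGRecording:
    """Subtract the per-sample channel mean (average reference)."""
    if rec.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return EEGRecording(data=data, fs=rec.fs, labels=list(rec.labels), reference="average")


def extract_retention_segments(
    rec: EEGRecording,
    schedule,
    window_s: float = 2.5,
) -> SegmentSet:
    """Cut the last ``window_s`` seconds of every retention period.

    Windows are half-open [start, end) with start sample floor(start*fs);
    a 3.5 s retention period with the default window starts 1.0 s in.
    """
    n = int(window_s * rec.fs)
    segs, idx, loads = [], [], []
    for ev in schedule.retention_events():
        start_s = ev.onset_s + (ev.duration_s - window_s)
        s0 = int(np.floor(start_s * rec.fs))
        if s0 < 0 or s0 + n > rec.n_samples:
            raise ValueError(
                f"retention window of trial {ev.trial_index} extends beyond the recording"
            )
        segs.append(rec.data[:, s0 : s0 + n])
        idx.append(ev.trial_index)
        loads.append(ev.load)
    return SegmentSet(
        segments=np.stack(segs),
        fs=rec.fs,
        window_s=window_s,
        trial_index=np.asarray(idx),
        loads=np.asarray(loads),
    )


def reject_artifact_segments(segs: SegmentSet, threshold_uv: float = 150.0) -> SegmentSet:
    """Flag segments whose absolute amplitude exceeds the bound in any channel.

    Sample values are never modified; only the ``retained`` flags change.
    The bound is strict (a sample exactly at ±threshold is retained).
    """
    peak = np.max(np.abs(segs.segments), axis=(1, 2))
    # "exceeding" the bound: strictly greater rejects
    retained = ~(peak > threshold_uv)
    return SegmentSet(
        segments=segs.segments,
        fs=segs.fs,
        window_s=segs.window_s,
        trial_index=segs.trial_index,
        loads=segs.loads,
        retained=retained,
    )
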