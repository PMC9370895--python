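"""EMG pre-processing chain.

Fixed stage order: band-pass filter -> spectral-artifact detection / notch
correction -> cycle segmentation and quality control -> full-wave
rectification -> low-pass envelope -> per-cycle time normalization to a
fixed number of phase points -> amplitude normalization across conditions.

All filters run forward-backward (zero phase), so burst timing is preserved
relative to the gait events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import (
    DegenerateCycleError,
    InsufficientCyclesError,
    InsufficientDataError,
    ParameterError,
)
from .io_eurobench import EmgRecording, GaitEvents, PipelineConfig


@dataclass
class EnvelopeTensor:
    """Normalized-cycle EMG envelopes: cycles x phase x muscles.

    ``envelopes_mV`` holds the envelopes in recording units; ``envelopes_norm``
    is filled by :func:`normalize_amplitude` (per-muscle unit maximum across
    all cycles and all conditions of a subject).
    """

    envelopes_mV: np.ndarray
    cycle_durations: np.ndarray
    muscle_names: list[str]
    speed_label: str = ""
    envelopes_norm: np.ndarray | None = None
    excluded_muscles: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.envelopes_mV = np.asarray(self.envelopes_mV, dtype=float)
        if self.envelopes_mV.ndim != 3:
            raise ParameterError("envelopes must be cycles x phase x muscles")
        if np.any(self.envelopes_mV < 0):
            raise ParameterError("envelopes must be non-negative")
        if np.any(np.asarray(self.cycle_durations) <= 0):
            raise ParameterError("cycle durations must be positive")

    @property
    def n_cycles(self) -> int:
        return self.envelopes_mV.shape[0]

    @property
    def n_phase(self) -> int:
        return self.envelopes_mV.shape[1]

    def cycle_average(self, normalized: bool = False) -> np.ndarray:
        """Ensemble average across cycles; shape (phase, muscles)."""
        data = self.envelopes_norm if normalized else self.envelopes_mV
        if data is None:
            raise ParameterError("normalized envelopes not yet computed")
        return data.mean(axis=0)

    def select_cycles(self, keep: np.ndarray) -> "EnvelopeTensor":
        return EnvelopeTensor(
            self.envelopes_mV[keep],
            np.asarray(self.cycle_durations)[keep],
            list(self.muscle_names),
            self.speed_label,
            None if self.envelopes_norm is None else self.envelopes_norm[keep],
            list(self.excluded_muscles),
        )


@dataclass
class QualityReport:
    """Per-trial quality-control outcome."""

    artifact_frequencies: list[float] = field(default_factory=list)
    cycle_muscle_r: np.ndarray | None = None  # cycles x muscles
    flagged_cycles: list[int] = field(default_factory=list)
    flag_reasons: dict[int, str] = field(default_factory=dict)
    excluded_cycles: list[int] = field(default_factory=list)
    excluded_muscles: list[str] = field(default_factory=list)
    n_cycles: int = 0
    subject_excluded: bool = False

    @property
    def excluded_fraction(self) -> float:
        return len(self.excluded_cycles) / self.n_cycles if self.n_cycles else 0.0

    def to_rows(self, muscle_names: list[str]) -> list[dict]:
        rows = []
        if self.cycle_muscle_r is None:
            return rows
        for c in range(self.cycle_muscle_r.shape[0]):
            for m, name in enumerate(muscle_names):
                rows.append(
                    {
                        "cycle": c,
                        "muscle": name,
                        "r": float(self.cycle_muscle_r[c, m]),
                        "flagged": c in self.flagged_cycles,
                        "reason": self.flag_reasons.get(c, ""),
                    }
                )
        return rows


def _check_band(rate: float, *edges: float) -> None:
    for e in edges:
        if not 0 < e < rate / 2:
            raise ParameterError(
                f"frequency {e} Hz outside (0, Nyquist={rate / 2} Hz)"
            )


def bandpass_filter(
    x: np.ndarray, rate: float, low: float = 30.0, high: float = 400.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the first axis."""
    _check_band(rate, low, high)
    if low >= high:
        raise ParameterError("low edge must be below high edge")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def lowpass_filter(x: np.ndarray, rate: float, cutoff: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the first axis."""
    _check_band(rate, cutoff)
    sos = sps.butter(order, cutoff, btype="lowpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=0)


def detect_spectral_artifacts(
    recording: EmgRecording,
    *,
    fmin: float = 20.0,
    fmax: float | None = None,
    prominence_factor: float = 10.0,
    channel_fraction: float = 1.0,
    neighborhood_hz: float = 10.0,
) -> list[float]:
    """Find narrowband frequencies contaminating (nearly) all channels.

    Welch periodograms (1-s windows, 50% overlap) are scanned per channel for
    bins whose power exceeds ``prominence_factor`` times the median power of a
    +/- ``neighborhood_hz`` neighborhood. A frequency is reported when at
    least ``channel_fraction`` of the channels carry such a peak at the same
    bin (within one bin); contiguous qualifying bins merge into one frequency
    at the power-weighted center.
    """
    rate = recording.sampling_rate
    nper = int(rate)  # 1-s windows
    if recording.samples.shape[0] < 2 * nper:
        raise InsufficientDataError("recording shorter than the spectral window")
    f, pxx = sps.welch(
        recording.samples, fs=rate, nperseg=nper, noverlap=nper // 2, axis=0
    )
    if fmax is None:
        fmax = rate / 2 - 1.0
    half_bw = max(1, int(round(neighborhood_hz / (f[1] - f[0]))))
    n_chan = pxx.shape[1]
    peak_mask = np.zeros_like(pxx, dtype=bool)
    for j in range(n_chan):
        p = pxx[:, j]
        for i in range(len(f)):
            if not fmin <= f[i] <= fmax:
                continue
            lo, hi = max(0, i - half_bw), min(len(f), i + half_bw + 1)
            neighborhood = np.delete(p[lo:hi], i - lo)
            if neighborhood.size and p[i] > prominence_factor * np.median(neighborhood):
                peak_mask[i, j] = True
    # tolerate one-bin misalignment between channels
    dilated = peak_mask | np.roll(peak_mask, 1, axis=0) | np.roll(peak_mask, -1, axis=0)
    shared = dilated.mean(axis=1) >= channel_fraction
    shared &= peak_mask.any(axis=1)
    freqs: list[float] = []
    i = 0
    total_power = pxx.sum(axis=1)
    while i < len(shared):
        if shared[i]:
            j = i
            while j + 1 < len(shared) and shared[j + 1]:
                j += 1
            w = total_power[i : j + 1]
            freqs.append(float(np.average(f[i : j + 1], weights=w)))
            i = j + 1
        else:
            i += 1
    return freqs


def apply_notch(x: np.ndarray, rate: float, freq: float, q: float = 30.0) -> np.ndarray:
    """Zero-phase second-order IIR notch at ``freq`` along the first axis."""
    _check_band(rate, freq)
    b, a = sps.iirnotch(freq, q, fs=rate)
    return sps.filtfilt(b, a, np.asarray(x, dtype=float), axis=0)


def rectify_and_envelope(
    x: np.ndarray, rate: float, cutoff: float = 10.0, order: int = 4
) -> np.ndarray:
    """Full-wave rectification followed by a zero-phase low-pass envelope.

    Tiny negative excursions from low-pass ringing are clipped to zero so the
    envelope satisfies the non-negativity invariant.
    """
    env = lowpass_filter(np.abs(np.asarray(x, dtype=float)), rate, cutoff, order)
    return np.clip(env, 0.0, None)


def segment_and_normalize(
    envelopes: np.ndarray,
    events: GaitEvents,
    rate: float,
    n_phase: int = 200,
    muscle_names: list[str] | None = None,
    speed_label: str = "",
) -> EnvelopeTensor:
    """Cut envelopes at touchdowns and resample every cycle to ``n_phase`` points.

    Interpolation is linear over normalized phase, so cycles of different raw
    length land on a common phase grid.
    """
    envelopes = np.asarray(envelopes, dtype=float)
    if envelopes.ndim == 1:
        envelopes = envelopes[:, None]
    if envelopes.ndim != 2:
        raise ParameterError("envelopes must be (time, muscles) with time first")
    if n_phase < 2:
        raise ParameterError("n_phase must be >= 2")
    n_samples = envelopes.shape[0]
    duration = n_samples / rate
    times = events.touchdown_times
    if times[0] < -0.5 / rate or times[-1] > duration + 0.5 / rate:
        raise ParameterError("gait events fall outside the recording")
    cycles = []
    durations = []
    phase_grid = np.linspace(0.0, 1.0, n_phase)
    for t0, t1 in zip(times[:-1], times[1:]):
        i0 = int(round(t0 * rate))
        i1 = min(int(round(t1 * rate)), n_samples - 1)
        if i1 - i0 < 3:
            raise DegenerateCycleError(
                f"cycle [{t0:.3f}, {t1:.3f}] s spans fewer than 4 samples"
            )
        seg = envelopes[i0 : i1 + 1]
        src = np.linspace(0.0, 1.0, seg.shape[0])
        cyc = np.empty((n_phase, seg.shape[1]))
        for m in range(seg.shape[1]):
            cyc[:, m] = np.interp(phase_grid, src, seg[:, m])
        cycles.append(cyc)
        durations.append(t1 - t0)
    if muscle_names is None:
        muscle_names = [f"ch{m}" for m in range(envelopes.shape[1])]
    return EnvelopeTensor(
        np.stack(cycles), np.asarray(durations), list(muscle_names), speed_label
    )


def normalize_amplitude(tensors: list[EnvelopeTensor]) -> list[EnvelopeTensor]:
    """Per-muscle unit-maximum normalization across all cycles of all conditions.

    Each muscle's envelope is divided by its maximum over every cycle of every
    condition tensor of the subject, so the normalized maximum of each
    non-zero muscle is exactly 1. An all-zero muscle cannot be normalized; it
    is flagged on every tensor's ``excluded_muscles`` instead of raising.
    Idempotent: renormalizing normalized data changes nothing.
    """
    if not tensors:
        raise ParameterError("need at least one condition tensor")
    names = tensors[0].muscle_names
    for t in tensors[1:]:
        if t.muscle_names != names:
            raise ParameterError("all conditions must share the muscle set and order")
    maxima = np.max(
        [t.envelopes_mV.max(axis=(0, 1)) for t in tensors], axis=0
    )
    zero = maxima <= 0
    divisor = np.where(zero, 1.0, maxima)
    for t in tensors:
        t.envelopes_norm = t.envelopes_mV / divisor
        t.excluded_muscles = [n for n, z in zip(names, zero) if z]
    return tensors


def detect_outlier_cycles(
    tensor: EnvelopeTensor, threshold: float = 0.6
) -> QualityReport:
    """Flag cycles poorly correlated with the ensemble-average envelope.

    For every cycle and muscle, the Pearson r between that cycle's envelope
    and the all-cycle ensemble average is computed; a cycle is flagged when
    its minimum r across muscles falls strictly below ``threshold`` (a single
    bad channel taints the whole cycle). Zero-variance envelopes have no
    defined r and flag the cycle outright.
    """
    if tensor.n_cycles < 3:
        raise InsufficientCyclesError("outlier detection needs >= 3 cycles")
    data = tensor.envelopes_mV
    ensemble = data.mean(axis=0)  # phase x muscles
    n_c, _, n_m = data.shape
    r = np.full((n_c, n_m), np.nan)
    reasons: dict[int, str] = {}
    flagged: list[int] = []
    for c in range(n_c):
        bad = False
        for m in range(n_m):
            x, y = data[c, :, m], ensemble[:, m]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                bad = True
                reasons[c] = "zero-variance envelope"
                continue
            r[c, m] = np.corrcoef(x, y)[0, 1]
        min_r = np.nanmin(r[c]) if not np.all(np.isnan(r[c])) else np.nan
        if bad or (np.isfinite(min_r) and min_r < threshold):
            flagged.append(c)
            reasons.setdefault(c, f"min r {min_r:.3f} < {threshold}")
    return QualityReport(
        cycle_muscle_r=r,
        flagged_cycles=flagged,
        flag_reasons=reasons,
        excluded_cycles=list(flagged),  # non-interactive: auto-exclude
        excluded_muscles=list(tensor.excluded_muscles),
        n_cycles=n_c,
    )


def apply_quality_gate(
    report: QualityReport, config: PipelineConfig | None = None
) -> QualityReport:
    """Mark the subject excluded when too many cycles were discarded."""
    frac = config.subject_exclusion_fraction if config else 0.5
    report.subject_excluded = report.excluded_fraction > frac
    return report


def detect_touchdown_from_heel(
    heel_height: np.ndarray,
    rate: float,
    refractory_s: float = 0.3,
    min_prominence: float = 0.25,
) -> GaitEvents:
    """Touchdown events at local minima of the vertical heel-marker trace.

    Minima closer together than ``refractory_s`` are merged (deepest wins),
    and a minimum must be prominent by at least ``min_prominence`` of the
    trace's range, which rejects jitter from marker noise.
    """
    heel_height = np.asarray(heel_height, dtype=float)
    distance = max(1, int(round(refractory_s * rate)))
    prominence = min_prominence * float(np.ptp(heel_height))
    minima, _ = sps.find_peaks(-heel_height, distance=distance, prominence=prominence)
    if minima.size < 2:
        raise InsufficientCyclesError("fewer than 2 heel-height minima found")
    return GaitEvents(minima / rate)


def preprocess_trial(
    recording: EmgRecording,
    events: GaitEvents,
    config: PipelineConfig,
) -> tuple[EnvelopeTensor, QualityReport]:
    """Run the full per-trial chain (band-pass through outlier exclusion).

    Returns the envelope tensor with flagged cycles already removed and the
    quality report (artifact frequencies, per-cycle correlations, exclusions).
    Amplitude normalization is a separate, cross-condition step.
    """
    config.validate_rate(recording.sampling_rate)
    x = bandpass_filter(
        recording.samples, recording.sampling_rate, config.band_low_hz, config.band_high_hz
    )
    filtered = EmgRecording(
        recording.sampling_rate, recording.channel_names, x, dict(recording.metadata)
    )
    try:
        artifact_freqs = detect_spectral_artifacts(filtered)
    except InsufficientDataError:
        artifact_freqs = []
    for freq in artifact_freqs:
        x = apply_notch(x, recording.sampling_rate, freq, config.notch_q)
    env = rectify_and_envelope(x, recording.sampling_rate, config.envelope_cutoff_hz)
    tensor = segment_and_normalize(
        env,
        events,
        recording.sampling_rate,
        config.n_phase,
        muscle_names=recording.channel_names,
        speed_label=str(recording.metadata.get("speed", "")),
    )
    quality = detect_outlier_cycles(tensor, config.outlier_threshold)
    quality.artifact_frequencies = [float(f) for f in artifact_freqs]
    quality = apply_quality_gate(quality, config)
    if quality.subject_excluded:
        # too few usable cycles to analyze; keep the tensor intact so the
        # caller can still inspect it, and let the flag veto the indicators
        return tensor, quality
    keep = np.setdiff1d(np.arange(tensor.n_cycles), quality.excluded_cycles)
    return tensor.select_cycles(keep), quality
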