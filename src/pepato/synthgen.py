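"""Synthetic EMG cohorts with known ground truth.

Raw-like surface EMG is built from the same generative structure the
analysis assumes: each muscle's envelope over the gait cycle is a
non-negative combination of a few basic Gaussian-burst activation patterns
(envelope = W* @ P*), modulated per cycle by multiplicative gain noise, and
used to amplitude-modulate a band-limited (30--400 Hz) Gaussian carrier so
that rectification + 10 Hz low-pass recovers the envelope. Cycle durations
jitter around their mean; optional line-frequency contamination and
corrupted cycles exercise the artifact-detection and quality-control
stages. Every random draw is fixed by the spec seed, and the realized
per-cycle ground-truth envelopes are returned for exact oracles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ParameterError
from .io_eurobench import (
    MUSCLE_CODES,
    EmgRecording,
    GaitEvents,
    write_emg_csv,
    write_gait_events,
)
from .preprocessing import bandpass_filter

#: Default burst centers (% of cycle) of the four canonical locomotor modules:
#: weight acceptance, push-off, early swing, late swing.
DEFAULT_CENTERS = (5.0, 30.0, 60.0, 85.0)
DEFAULT_WIDTH_RANGE = (8.0, 12.0)  # FWHM, % of cycle

#: Default muscle weighting of the four modules (muscles in MUSCLE_CODES
#: order): quadriceps at weight acceptance, triceps surae at push-off,
#: tibialis anterior in early swing, hamstrings in late swing.
DEFAULT_WEIGHTS = np.array(
    [
        # M1    M2    M3    M4
        [0.10, 1.00, 0.05, 0.10],  # Sol
        [0.10, 0.90, 0.05, 0.10],  # GaLa
        [0.30, 0.05, 1.00, 0.20],  # TiAn
        [1.00, 0.10, 0.20, 0.10],  # ReFe
        [0.90, 0.10, 0.10, 0.05],  # VaLa
        [0.95, 0.10, 0.10, 0.05],  # VaMe
        [0.20, 0.10, 0.10, 1.00],  # SeTe
        [0.15, 0.15, 0.05, 0.90],  # BiFe
    ]
)


def gaussian_burst(center: float, width: float, n_phase: int = 200) -> np.ndarray:
    """Periodic Gaussian burst over the cycle; ``width`` is the FWHM in %."""
    phase = np.linspace(0.0, 100.0, n_phase, endpoint=False)
    sd = width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    delta = (phase - center + 50.0) % 100.0 - 50.0
    return np.exp(-0.5 * (delta / sd) ** 2)


@dataclass
class SyntheticSpec:
    """Generative description of one synthetic trial/subject."""

    n_muscles: int = 8
    n_modules: int = 4
    weights: np.ndarray | None = None          # m x n, defaults to DEFAULT_WEIGHTS
    burst_centers: tuple[float, ...] = DEFAULT_CENTERS     # % of cycle
    burst_widths: tuple[float, ...] | None = None          # FWHM %; None -> drawn 8-12
    burst_amplitude_mV: float = 0.5
    n_cycles: int = 10
    cycle_duration_s: float = 1.1
    cycle_jitter_s: float = 0.05
    sampling_rate: float = 2000.0
    noise_cv: float = 0.10                     # multiplicative envelope gain CV
    line_frequency_hz: float | None = None     # e.g. 50.0 or 155.0
    line_amplitude_mV: float = 0.0
    corrupted_cycles: tuple[int, ...] = ()
    n_phase: int = 200
    muscle_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weights is None:
            if (self.n_muscles, self.n_modules) != DEFAULT_WEIGHTS.shape:
                raise ParameterError(
                    "provide `weights` explicitly for non-default m or n"
                )
            self.weights = DEFAULT_WEIGHTS.copy()
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.n_muscles, self.n_modules):
            raise ParameterError("weights must be (n_muscles, n_modules)")
        if np.any(self.weights < 0):
            raise ParameterError("weights must be non-negative")
        if len(self.burst_centers) != self.n_modules:
            raise ParameterError("one burst center per module")
        if any(not 0 <= c < 100 for c in self.burst_centers):
            raise ParameterError("burst centers must lie in [0, 100)")
        if self.burst_widths is not None and len(self.burst_widths) != self.n_modules:
            raise ParameterError("one burst width per module")
        if self.noise_cv < 0:
            raise ParameterError("noise_cv must be >= 0")
        if self.muscle_names is None:
            if self.n_muscles == len(MUSCLE_CODES):
                self.muscle_names = tuple(f"R_{c}" for c in MUSCLE_CODES)
            else:
                self.muscle_names = tuple(f"R_ch{i}" for i in range(self.n_muscles))
        if any(c < 0 or c >= self.n_cycles for c in self.corrupted_cycles):
            raise ParameterError("corrupted cycle index out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if "weights" in data and data["weights"] is not None:
            data["weights"] = np.asarray(data["weights"], dtype=float)
        for key in ("burst_centers", "burst_widths", "corrupted_cycles", "muscle_names"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["weights"] = self.weights.tolist()
        for key in ("burst_centers", "burst_widths", "corrupted_cycles", "muscle_names"):
            if data[key] is not None:
                data[key] = list(data[key])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class GroundTruth:
    """Realized generative quantities of one trial, for exact oracles."""

    weights: np.ndarray            # m x n (W*)
    patterns: np.ndarray           # n x n_phase (P*, unit maximum)
    burst_centers: np.ndarray      # % of cycle
    burst_widths: np.ndarray       # FWHM, % of cycle
    gains: np.ndarray              # n_cycles x m multiplicative noise field
    cycle_envelopes: np.ndarray    # n_cycles x n_phase x m, mV (incl. gains)
    corrupted_cycles: tuple[int, ...] = ()


#: Lead-in/lead-out around the gait events so filter edges stay outside cycles.
_PAD_S = 0.5


def generate_trial(
    spec: SyntheticSpec, **metadata
) -> tuple[EmgRecording, GaitEvents, GroundTruth]:
    """Synthesize one raw-like EMG trial with its gait events and truth."""
    rng = np.random.default_rng(spec.seed)
    m, n = spec.n_muscles, spec.n_modules
    if spec.burst_widths is None:
        widths = rng.uniform(*DEFAULT_WIDTH_RANGE, size=n)
    else:
        widths = np.asarray(spec.burst_widths, dtype=float)
    patterns = np.stack(
        [gaussian_burst(c, w, spec.n_phase) for c, w in zip(spec.burst_centers, widths)]
    )
    durations = np.maximum(
        rng.normal(spec.cycle_duration_s, spec.cycle_jitter_s, size=spec.n_cycles),
        0.2,
    )
    rate = spec.sampling_rate
    boundaries = _PAD_S + np.concatenate([[0.0], np.cumsum(durations)])
    total = boundaries[-1] + _PAD_S
    n_samples = int(round(total * rate))
    t = np.arange(n_samples) / rate

    gains = np.maximum(rng.normal(1.0, spec.noise_cv, size=(spec.n_cycles, m)), 0.05)
    base = spec.burst_amplitude_mV * patterns.T @ spec.weights.T  # n_phase x m
    cycle_envelopes = gains[:, None, :] * base[None, :, :]

    # corrupted cycles: random unrelated burst structure per muscle
    for c in spec.corrupted_cycles:
        bad = np.stack(
            [
                gaussian_burst(rng.uniform(0, 100), rng.uniform(5, 15), spec.n_phase)
                for _ in range(m)
            ],
            axis=1,
        )
        cycle_envelopes[c] = spec.burst_amplitude_mV * (0.2 + 1.5 * bad)

    # envelope at every raw sample (piecewise per cycle over its own phase)
    envelope_t = np.zeros((n_samples, m))
    phase_grid = np.linspace(0.0, 1.0, spec.n_phase, endpoint=False)
    for c in range(spec.n_cycles):
        i0 = int(round(boundaries[c] * rate))
        i1 = int(round(boundaries[c + 1] * rate))
        local = (np.arange(i0, i1) / rate - boundaries[c]) / durations[c]
        for mu in range(m):
            envelope_t[i0:i1, mu] = np.interp(
                local, phase_grid, cycle_envelopes[c, :, mu], period=1.0
            )
    # low resting activity outside the cycles keeps filters well conditioned
    envelope_t[envelope_t == 0] = 0.02 * spec.burst_amplitude_mV

    carrier = rng.standard_normal((n_samples, m))
    carrier = bandpass_filter(carrier, rate, 30.0, min(400.0, rate / 2 - 1))
    # scale so rectify+low-pass of the carrier alone ~ 1 (E|N(0,s)| = s*sqrt(2/pi))
    carrier /= carrier.std(axis=0, keepdims=True) * np.sqrt(2.0 / np.pi)
    samples = envelope_t * carrier

    if spec.line_frequency_hz is not None and spec.line_amplitude_mV > 0:
        line = spec.line_amplitude_mV * np.sin(2 * np.pi * spec.line_frequency_hz * t)
        samples = samples + line[:, None]

    recording = EmgRecording(
        rate, list(spec.muscle_names), samples, {"synthetic": True, **metadata}
    )
    events = GaitEvents(boundaries)
    truth = GroundTruth(
        weights=spec.weights.copy(),
        patterns=patterns,
        burst_centers=np.asarray(spec.burst_centers, dtype=float),
        burst_widths=widths,
        gains=gains,
        cycle_envelopes=cycle_envelopes,
        corrupted_cycles=tuple(spec.corrupted_cycles),
    )
    return recording, events, truth


@dataclass
class SyntheticSubject:
    subject_id: str
    spec: SyntheticSpec
    trials: dict[str, tuple[EmgRecording, GaitEvents, GroundTruth]] = field(
        default_factory=dict
    )


def generate_cohort(
    spec: SyntheticSpec,
    n_subjects: int,
    between_subject_variability: float = 0.1,
    speeds: tuple[str, ...] = ("4",),
    seed: int | None = None,
) -> list[SyntheticSubject]:
    """Draw a cohort by jittering the template spec per subject.

    Subject-level variability perturbs the weights multiplicatively, shifts
    the burst centers (sd = 25 * variability, % of cycle) and scales the
    burst widths; each subject then generates one trial per speed.
    """
    if n_subjects < 2:
        raise ParameterError("a cohort needs at least 2 subjects")
    if between_subject_variability < 0:
        raise ParameterError("variability must be >= 0")
    master = np.random.default_rng(spec.seed if seed is None else seed)
    base_widths = (
        np.asarray(spec.burst_widths, dtype=float)
        if spec.burst_widths is not None
        else np.full(spec.n_modules, float(np.mean(DEFAULT_WIDTH_RANGE)))
    )
    subjects: list[SyntheticSubject] = []
    v = between_subject_variability
    for s in range(n_subjects):
        w = spec.weights * np.maximum(
            master.normal(1.0, v, size=spec.weights.shape), 0.0
        )
        centers = tuple(
            float(c + master.normal(0.0, 25.0 * v)) % 100.0 for c in spec.burst_centers
        )
        widths = tuple(
            float(np.clip(wd * max(master.normal(1.0, v), 0.3), 3.0, 40.0))
            for wd in base_widths
        )
        subject = SyntheticSubject(subject_id=f"S{s + 1:02d}", spec=spec)
        for speed in speeds:
            sub_spec = dataclasses.replace(
                spec,
                weights=w,
                burst_centers=centers,
                burst_widths=widths,
                seed=int(master.integers(0, 2**31 - 1)),
            )
            subject.trials[speed] = generate_trial(
                sub_spec, subject=subject.subject_id, speed=speed
            )
        subject.spec = sub_spec
        subjects.append(subject)
    return subjects


def write_trial(
    recording: EmgRecording, events: GaitEvents, out_dir: str | Path, prefix: str = "trial"
) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    emg_path = out_dir / f"{prefix}_emg.csv"
    ev_path = out_dir / f"{prefix}_events.csv"
    write_emg_csv(recording, emg_path)
    write_gait_events(events, ev_path)
    return emg_path, ev_path


def write_cohort(subjects: list[SyntheticSubject], out_dir: str | Path) -> Path:
    """Write a cohort as one directory per subject, one trial per speed."""
    out_dir = Path(out_dir)
    for subject in subjects:
        sdir = out_dir / subject.subject_id
        for speed, (recording, events, _) in subject.trials.items():
            write_trial(recording, events, sdir, prefix=f"speed_{speed}")
    return out_dir
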