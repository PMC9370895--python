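"""On-disk artifacts: EMG trials, gait events, configuration, PI reports.

File dialect
------------
All tabular artifacts are comma-separated UTF-8 text with a mandatory header
row; EMG time is in seconds in the first column. Channel columns are named
``<side>_<musclecode>`` (e.g. ``R_Sol``) using the conventional lower-limb
abbreviations. Structured artifacts (configuration, PI reports, charts,
synthetic specs) are YAML.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ChannelMismatchError,
    FormatError,
    InsufficientCyclesError,
    ParameterError,
)

log = logging.getLogger(__name__)

#: Muscle codes the default pipeline knows about (distal -> proximal).
MUSCLE_CODES = ("Sol", "GaLa", "TiAn", "ReFe", "VaLa", "VaMe", "SeTe", "BiFe")

SIDES = ("L", "R")

#: Relative tolerance on sampling-interval uniformity.
RATE_TOLERANCE = 1e-6


def parse_channel_name(name: str) -> tuple[str, str]:
    """Split ``"R_Sol"`` into ``("R", "Sol")``; raise on malformed names."""
    parts = name.split("_", 1)
    if len(parts) != 2 or parts[0] not in SIDES or not parts[1]:
        raise FormatError(f"channel name {name!r} is not of the form <side>_<muscle>")
    return parts[0], parts[1]


@dataclass
class EmgRecording:
    """A multi-channel surface-EMG trial.

    Attributes
    ----------
    sampling_rate : float
        Samples per second (Hz).
    channel_names : list of str
        Ordered channel identifiers ``<side>_<musclecode>``, unique.
    samples : ndarray, shape (n_samples, n_channels)
        Raw EMG in mV.
    metadata : dict
        Free-form trial metadata (subject id, speed in km/h, condition label).
    """

    sampling_rate: float
    channel_names: list[str]
    samples: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        if len(self.channel_names) != len(set(self.channel_names)):
            raise FormatError("channel names must be unique")
        if len(self.channel_names) < 2:
            raise FormatError("a recording needs at least 2 channels")
        if self.samples.ndim != 2 or self.samples.shape[1] != len(self.channel_names):
            raise FormatError("samples must be (time, channels) matching channel_names")
        if not np.all(np.isfinite(self.samples)):
            bad = int(np.argwhere(~np.isfinite(self.samples))[0, 0])
            raise FormatError(f"non-finite sample value at row {bad}")
        for name in self.channel_names:
            parse_channel_name(name)

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.sampling_rate

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise ChannelMismatchError(f"channel {name!r} not present") from None
        return self.samples[:, idx]


@dataclass
class GaitEvents:
    """Ordered foot-touchdown times (seconds) delimiting gait cycles."""

    touchdown_times: np.ndarray
    side: str = "R"

    def __post_init__(self) -> None:
        self.touchdown_times = np.asarray(self.touchdown_times, dtype=float)
        if self.touchdown_times.size < 2:
            raise InsufficientCyclesError(
                "need at least 2 touchdown events (1 complete cycle)"
            )
        if not np.all(np.diff(self.touchdown_times) > 0):
            raise FormatError("touchdown times must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return self.touchdown_times.size - 1

    @property
    def cycle_durations(self) -> np.ndarray:
        return np.diff(self.touchdown_times)


@dataclass
class PipelineConfig:
    """Tunable parameters of the processing chain.

    Defaults follow the standard surface-EMG practice for gait: 30--400 Hz
    band-pass, 10 Hz envelope low-pass, 200 phase points per cycle, outlier
    threshold r < 0.6, subject exclusion above 50% discarded cycles.
    """

    band_low_hz: float = 30.0
    band_high_hz: float = 400.0
    envelope_cutoff_hz: float = 10.0
    n_phase: int = 200
    outlier_threshold: float = 0.6
    subject_exclusion_fraction: float = 0.5
    module_number_method: str = "best_linear_fit"
    vaf_threshold: float = 0.90
    fixed_n_modules: int = 4
    cluster_mean_distance: float = 0.8
    cluster_max_distance: float = 2.0
    notch_q: float = 30.0
    nmf_restarts: int = 10
    selection_restarts: int = 3
    random_seed: int = 0
    chart_path: str | None = None
    interactive: bool = False

    _METHODS = ("best_linear_fit", "vaf_threshold", "fixed")

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ParameterError("band edges must satisfy 0 < low < high")
        if self.module_number_method not in self._METHODS:
            raise ParameterError(
                f"module_number_method must be one of {self._METHODS}"
            )
        for name in ("outlier_threshold", "subject_exclusion_fraction", "vaf_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ParameterError(f"{name} must be in (0, 1]")
        if self.n_phase < 2:
            raise ParameterError("n_phase must be >= 2")

    def validate_rate(self, sampling_rate: float) -> None:
        if self.band_high_hz >= sampling_rate / 2:
            raise ParameterError(
                f"band_high_hz {self.band_high_hz} not below Nyquist of {sampling_rate} Hz"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class PiReport:
    """The two groups of performance indicators plus a quality summary.

    Group 1 (motor modules): number of modules, reconstruction VAF, per-module
    FWHM and center of activity (% cycle), similarity to reference clusters.
    Group 2 (spinal maps): lumbar/sacral timing of maximal activation and
    FWHM (% cycle), co-activation index, waveform correlation with reference.
    """

    n_modules: int | None = None                       # P1.1
    vaf: float | None = None                           # P1.2
    fwhm_modules: list[float] | None = None            # P1.3, % cycle
    coa_modules: list[float | None] | None = None      # P1.4, % cycle (circular)
    module_assignments: list[dict] | None = None       # P1.5
    timing_max: dict[str, float] | None = None         # P2.1 {lumbar, sacral}
    fwhm_map: dict[str, float] | None = None           # P2.2
    coactivation_index: float | None = None            # P2.3
    map_similarity: dict[str, float] | None = None     # P2.4
    quality: dict | None = None

    def has_p1(self) -> bool:
        return self.n_modules is not None

    def has_p2(self) -> bool:
        return self.coactivation_index is not None or self.timing_max is not None


def read_emg_csv(
    path: str | Path, expected_channels: list[str] | None = None, **metadata
) -> EmgRecording:
    """Load an EMG trial from CSV (time in s, channels in mV).

    The sampling rate is taken from ``metadata['sampling_rate']`` when given,
    otherwise inferred from the time column; a sampling interval that is
    non-uniform beyond 1 ppm (or non-monotonic) is a format error.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: need a time column and >= 2 channels")
    time = df.iloc[:, 0].to_numpy(dtype=float)
    channel_names = list(df.columns[1:])
    if expected_channels is not None:
        missing = [c for c in expected_channels if c not in channel_names]
        if missing:
            raise ChannelMismatchError(f"{path}: missing channels {missing}")
        channel_names = list(expected_channels)
    samples = df[channel_names].to_numpy(dtype=float)

    dt = np.diff(time)
    if np.any(dt <= 0):
        bad = int(np.argwhere(dt <= 0)[0, 0]) + 1
        raise FormatError(f"{path}: non-monotonic/repeated timestamp at row {bad}")
    dt0 = float(np.median(dt))
    if np.max(np.abs(dt - dt0)) > RATE_TOLERANCE * dt0 + 1e-12:
        raise FormatError(f"{path}: non-uniform sampling interval")
    rate = metadata.pop("sampling_rate", None)
    if rate is None:
        rate = 1.0 / dt0
    elif abs(1.0 / dt0 - rate) > RATE_TOLERANCE * rate:
        raise FormatError(
            f"{path}: metadata rate {rate} Hz disagrees with time column ({1.0 / dt0:.6f} Hz)"
        )
    if not np.all(np.isfinite(samples)):
        bad = int(np.argwhere(~np.isfinite(samples))[0, 0])
        raise FormatError(f"{path}: non-finite sample at row {bad}")
    return EmgRecording(float(rate), channel_names, samples, metadata)


def write_emg_csv(recording: EmgRecording, path: str | Path) -> None:
    t = np.arange(recording.samples.shape[0]) / recording.sampling_rate
    df = pd.DataFrame(recording.samples, columns=recording.channel_names)
    df.insert(0, "time", t)
    df.to_csv(path, index=False, float_format="%.9g")


def read_gait_events(path: str | Path, side: str = "R") -> GaitEvents:
    """Read touchdown times (seconds) from a one-column CSV or a YAML list."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if isinstance(data, dict):
            side = data.get("side", side)
            times = data.get("touchdown_times", data.get("times"))
        else:
            times = data
        if times is None:
            raise FormatError(f"{path}: no touchdown times found")
        times = np.asarray(times, dtype=float)
    else:
        df = pd.read_csv(path)
        times = df.iloc[:, 0].to_numpy(dtype=float)
    if times.size < 2:
        raise InsufficientCyclesError(f"{path}: fewer than 2 touchdown events")
    if not np.all(np.diff(times) > 0):
        raise FormatError(f"{path}: touchdown times not strictly increasing")
    return GaitEvents(times, side=side)


def write_gait_events(events: GaitEvents, path: str | Path) -> None:
    pd.DataFrame({"touchdown_time_s": events.touchdown_times}).to_csv(
        path, index=False, float_format="%.9g"
    )


def _clean(value):
    """Make report values YAML-serializable (native floats/ints/lists)."""
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, np.ndarray):
        return [_clean(v) for v in value.tolist()]
    if isinstance(value, (list, tuple)):
        return [_clean(v) for v in value]
    if isinstance(value, dict):
        return {k: _clean(v) for k, v in value.items()}
    return value


def write_pi_report(report: PiReport, out_dir: str | Path) -> list[Path]:
    """Write one YAML file per PI group plus a per-cycle quality CSV.

    Returns the list of files written. A report lacking one group writes
    only the other group's file (with a logged warning).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if report.has_p1():
        p1 = {
            "p1_1_n_modules": _clean(report.n_modules),
            "p1_2_vaf": _clean(report.vaf),
            "p1_3_fwhm_percent": _clean(report.fwhm_modules),
            "p1_4_coa_percent": _clean(report.coa_modules),
            "p1_5_similarity": _clean(report.module_assignments),
        }
        f = out_dir / "pi_modules.yaml"
        with open(f, "w", encoding="utf-8") as fh:
            yaml.safe_dump(p1, fh, sort_keys=False)
        written.append(f)
    else:
        log.warning("PI report lacks the motor-module group; pi_modules.yaml not written")
    if report.has_p2():
        p2 = {
            "p2_1_timing_max_percent": _clean(report.timing_max),
            "p2_2_fwhm_percent": _clean(report.fwhm_map),
            "p2_3_coactivation_index": _clean(report.coactivation_index),
            "p2_4_similarity_r": _clean(report.map_similarity),
        }
        f = out_dir / "pi_spinalmap.yaml"
        with open(f, "w", encoding="utf-8") as fh:
            yaml.safe_dump(p2, fh, sort_keys=False)
        written.append(f)
    else:
        log.warning("PI report lacks the spinal-map group; pi_spinalmap.yaml not written")
    if report.quality is not None:
        rows = report.quality.get("per_cycle")
        if rows:
            f = out_dir / "quality_flags.csv"
            pd.DataFrame(rows).to_csv(f, index=False)
            written.append(f)
        f = out_dir / "quality_summary.yaml"
        summary = {k: _clean(v) for k, v in report.quality.items() if k != "per_cycle"}
        with open(f, "w", encoding="utf-8") as fh:
            yaml.safe_dump(summary, fh, sort_keys=False)
        written.append(f)
    return written


def read_pi_report(out_dir: str | Path) -> PiReport:
    """Inverse of :func:`write_pi_report` (lossless to float precision)."""
    out_dir = Path(out_dir)
    report = PiReport()
    p1 = out_dir / "pi_modules.yaml"
    if p1.exists():
        with open(p1, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        report.n_modules = d.get("p1_1_n_modules")
        report.vaf = d.get("p1_2_vaf")
        report.fwhm_modules = d.get("p1_3_fwhm_percent")
        report.coa_modules = d.get("p1_4_coa_percent")
        report.module_assignments = d.get("p1_5_similarity")
    p2 = out_dir / "pi_spinalmap.yaml"
    if p2.exists():
        with open(p2, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        report.timing_max = d.get("p2_1_timing_max_percent")
        report.fwhm_map = d.get("p2_2_fwhm_percent")
        report.coactivation_index = d.get("p2_3_coactivation_index")
        report.map_similarity = d.get("p2_4_similarity_r")
    qs = out_dir / "quality_summary.yaml"
    if qs.exists():
        with open(qs, encoding="utf-8") as fh:
            report.quality = yaml.safe_load(fh)
        qf = out_dir / "quality_flags.csv"
        if qf.exists():
            report.quality["per_cycle"] = pd.read_csv(qf).to_dict("records")
    return report
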