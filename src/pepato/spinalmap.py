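"""Spinal maps of motoneuron-pool activation.

Cycle-averaged muscle envelopes (in mV) are projected onto the rostrocaudal
axis of the lumbosacral cord using a myotomal innervation chart: each of the
six segments L2..S2 is split into six slices (36 subsegments), and the
activation of subsegment j is the mean envelope of the muscles it
innervates, S_j(t) = sum_i EMG_i(t) / m_j. Segment waveforms average the six
slices; the upper-lumbar group is the sum of the L3 and L4 segment waveforms
and the sacral group the sum of S1 and S2 (L2 and L5 are excluded from the
groups: L5 to reduce overlap between the groups, L2 because it contains far
fewer motoneurons than L3-L4).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ParameterError, PreconditionError, SchemaError, UndefinedMetricError
from .io_eurobench import MUSCLE_CODES

SEGMENTS = ("L2", "L3", "L4", "L5", "S1", "S2")
SLICES_PER_SEGMENT = 6
N_SUBSEGMENTS = len(SEGMENTS) * SLICES_PER_SEGMENT  # 36
LUMBAR_SEGMENTS = ("L3", "L4")
SACRAL_SEGMENTS = ("S1", "S2")


@dataclass
class InnervationChart:
    """Myotomal chart: 36 rostrocaudal subsegments -> innervating muscles.

    Subsegments are ordered rostral to caudal: L2 slice 1..6, L3 slice 1..6,
    ... S2 slice 1..6.
    """

    muscles_per_subsegment: list[frozenset[str]]
    known_muscles: tuple[str, ...] = MUSCLE_CODES
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.muscles_per_subsegment) != N_SUBSEGMENTS:
            raise SchemaError(
                f"chart must have exactly {N_SUBSEGMENTS} subsegments, "
                f"got {len(self.muscles_per_subsegment)}"
            )
        covered: set[str] = set()
        for j, muscles in enumerate(self.muscles_per_subsegment):
            unknown = set(muscles) - set(self.known_muscles)
            if unknown:
                raise SchemaError(
                    f"subsegment {self.subsegment_name(j)} names unknown muscles {sorted(unknown)}"
                )
            covered |= set(muscles)
        missing = set(self.known_muscles) - covered
        if missing:
            raise SchemaError(f"muscles never innervated by the chart: {sorted(missing)}")

    @staticmethod
    def subsegment_name(j: int) -> str:
        return f"{SEGMENTS[j // SLICES_PER_SEGMENT]}.{j % SLICES_PER_SEGMENT + 1}"

    def segment_rows(self, segment: str) -> slice:
        i = SEGMENTS.index(segment)
        return slice(i * SLICES_PER_SEGMENT, (i + 1) * SLICES_PER_SEGMENT)


@dataclass
class SpinalMap:
    """36 x n_phase motoneuron-activation matrix plus group waveforms."""

    activation: np.ndarray                   # 36 x n_phase, mV
    segment_waveforms: dict[str, np.ndarray]  # mean of each segment's 6 slices
    lumbar: np.ndarray                        # L3 + L4 segment waveforms
    sacral: np.ndarray                        # S1 + S2 segment waveforms
    warnings: list[str] | None = None


def load_innervation_chart(path: str | Path | None = None) -> InnervationChart:
    """Load a chart from YAML, or the chart shipped with the package.

    Schema: a mapping with keys ``provenance`` (free text) and ``subsegments``
    — a list of 36 entries ``{segment: L2..S2, slice: 1..6, muscles: [codes]}``
    in rostrocaudal order.
    """
    if path is None:
        ref = resources.files("pepato").joinpath("data/innervation_chart.yaml")
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict) or "subsegments" not in data:
        raise SchemaError("chart YAML must contain a 'subsegments' list")
    entries = data["subsegments"]
    if len(entries) != N_SUBSEGMENTS:
        raise SchemaError(
            f"chart must list {N_SUBSEGMENTS} subsegments, got {len(entries)}"
        )
    muscles_per: list[frozenset[str]] = []
    for j, e in enumerate(entries):
        seg, sl = SEGMENTS[j // SLICES_PER_SEGMENT], j % SLICES_PER_SEGMENT + 1
        if e.get("segment") != seg or int(e.get("slice", -1)) != sl:
            raise SchemaError(
                f"subsegment {j}: expected segment {seg} slice {sl}, "
                f"got {e.get('segment')} slice {e.get('slice')}"
            )
        muscles_per.append(frozenset(e.get("muscles", [])))
    known = tuple(data.get("known_muscles", MUSCLE_CODES))
    return InnervationChart(muscles_per, known, str(data.get("provenance", "")))


def compute_spinal_map(
    envelopes: np.ndarray,
    muscle_names: list[str],
    chart: InnervationChart,
) -> SpinalMap:
    """Project cycle-averaged mV envelopes onto the 36 subsegments.

    ``envelopes`` is (n_phase, n_muscles); ``muscle_names`` may carry side
    prefixes (``R_Sol``), matched against chart codes by suffix. A chart
    muscle absent from the recording reduces that subsegment's divisor m_j
    (with a warning) rather than failing.
    """
    envelopes = np.asarray(envelopes, dtype=float)
    if envelopes.ndim != 2 or envelopes.shape[1] != len(muscle_names):
        raise ParameterError("envelopes must be (n_phase, n_muscles)")
    code_of = {}
    for i, name in enumerate(muscle_names):
        code = name.split("_", 1)[1] if "_" in name else name
        code_of.setdefault(code, []).append(i)
    n_phase = envelopes.shape[0]
    activation = np.zeros((N_SUBSEGMENTS, n_phase))
    warnings: list[str] = []
    missing_seen: set[str] = set()
    for j, muscles in enumerate(chart.muscles_per_subsegment):
        cols: list[int] = []
        for code in muscles:
            if code in code_of:
                cols.extend(code_of[code])
            elif code not in missing_seen:
                missing_seen.add(code)
                warnings.append(f"chart muscle {code} absent from recording")
        if cols:
            activation[j] = envelopes[:, cols].mean(axis=1)
    segment_waveforms = {
        seg: activation[chart.segment_rows(seg)].mean(axis=0) for seg in SEGMENTS
    }
    lumbar = sum(segment_waveforms[s] for s in LUMBAR_SEGMENTS)
    sacral = sum(segment_waveforms[s] for s in SACRAL_SEGMENTS)
    return SpinalMap(activation, segment_waveforms, lumbar, sacral, warnings)


def timing_of_max(waveform: np.ndarray) -> float:
    """Phase (% of cycle) of the global maximum; earliest sample wins ties."""
    w = np.asarray(waveform, dtype=float)
    if w.ndim != 1:
        raise ParameterError("waveform must be 1-D")
    if w.max() <= 0:
        raise UndefinedMetricError("timing undefined for a non-positive waveform")
    return float(100.0 * int(np.argmax(w)) / w.size)


def coactivation_index(lumbar: np.ndarray, sacral: np.ndarray) -> float:
    """Co-activation index of two cyclic waveforms.

    Both waveforms are normalized to unit maximum; per sample, with
    H = max(pair) and L = min(pair), the contribution is ((H + L)/2)*(L/H)
    (zero where H = 0), and the CI is the mean contribution over the cycle.
    High values mean both groups are strongly active together; low values
    mean low activity or alternation.
    """
    a = np.asarray(lumbar, dtype=float)
    b = np.asarray(sacral, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("waveforms must be 1-D with equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise PreconditionError("waveforms must be non-negative")
    if a.max() > 0:
        a = a / a.max()
    if b.max() > 0:
        b = b / b.max()
    high = np.maximum(a, b)
    low = np.minimum(a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = ((high + low) / 2.0) * (low / high)
    term[high == 0] = 0.0
    return float(term.mean())


def map_similarity(subject: np.ndarray, reference: np.ndarray) -> float:
    """Pearson correlation of a subject group waveform with the reference."""
    s = np.asarray(subject, dtype=float)
    r = np.asarray(reference, dtype=float)
    if s.shape != r.shape:
        raise ParameterError("waveforms must have equal length")
    if np.ptp(s) == 0 or np.ptp(r) == 0:
        raise UndefinedMetricError("similarity undefined for constant waveform")
    return float(np.corrcoef(s, r)[0, 1])
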