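"""End-to-end orchestration: raw trial -> envelopes -> indicators.

`process_subject` runs the pre-processing chain on every condition of one
subject, applies the cross-condition amplitude normalization, extracts the
motor modules, computes the spinal map, and assembles a
:class:`~pepato.io_eurobench.PiReport` per condition. Reference-dependent
indicators (P1.5, P2.4) are filled separately by
:func:`pepato.reference.evaluate_against_reference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import preprocessing, spinalmap, synergy
from .errors import PepatoError
from .io_eurobench import EmgRecording, GaitEvents, PipelineConfig, PiReport
from .preprocessing import EnvelopeTensor, QualityReport
from .spinalmap import InnervationChart, SpinalMap
from .synergy import SynergyDecomposition


@dataclass
class ProcessedTrial:
    """Everything derived from one condition (speed) of one subject."""

    tensor: EnvelopeTensor
    quality: QualityReport
    decomposition: SynergyDecomposition | None = None
    fwhm_modules: list[float] | None = None
    coa_modules: list[float | None] | None = None
    spinal_map: SpinalMap | None = None
    report: PiReport | None = None


@dataclass
class ProcessedSubject:
    subject_id: str
    trials: dict[str, ProcessedTrial] = field(default_factory=dict)

    @property
    def speeds(self) -> list[str]:
        return list(self.trials)


def process_subject(
    subject_id: str,
    conditions: dict[str, tuple[EmgRecording, GaitEvents]],
    config: PipelineConfig | None = None,
    chart: InnervationChart | None = None,
) -> ProcessedSubject:
    """Run the full pipeline for one subject across all their conditions.

    Amplitude normalization is shared across conditions (per-muscle maximum
    over all strides of all speeds), as required for comparable weights.
    A condition whose quality gate excludes the subject keeps its quality
    report but gets no indicators.
    """
    config = config or PipelineConfig()
    chart = chart or spinalmap.load_innervation_chart(config.chart_path)
    subject = ProcessedSubject(subject_id)
    tensors = []
    for speed, (recording, events) in conditions.items():
        tensor, quality = preprocessing.preprocess_trial(recording, events, config)
        subject.trials[speed] = ProcessedTrial(tensor=tensor, quality=quality)
        tensors.append(tensor)
    preprocessing.normalize_amplitude(tensors)
    for speed, trial in subject.trials.items():
        if trial.quality.subject_excluded:
            trial.report = PiReport(quality=_quality_dict(trial))
            continue
        analyze_trial(trial, config, chart)
    return subject


def analyze_trial(
    trial: ProcessedTrial, config: PipelineConfig, chart: InnervationChart
) -> ProcessedTrial:
    """Motor modules + spinal map + indicator report for one condition."""
    tensor = trial.tensor
    n = synergy.select_module_number(
        tensor,
        config.module_number_method,
        vaf_threshold=config.vaf_threshold,
        fixed_n=config.fixed_n_modules,
        seed=config.random_seed,
        restarts=config.selection_restarts,
    )
    dec = synergy.extract_synergies(
        tensor, n, seed=config.random_seed, restarts=config.nmf_restarts
    )
    trial.decomposition = dec
    fwhm = []
    coa: list[float | None] = []
    for pattern in dec.patterns_avg:
        try:
            width, _ = synergy.compute_fwhm(pattern)
        except PepatoError:
            width = float("nan")
        fwhm.append(width)
        value, defined = synergy.compute_coa(np.clip(pattern, 0, None))
        coa.append(value if defined else None)
    trial.fwhm_modules = fwhm
    trial.coa_modules = coa

    cycle_avg = tensor.cycle_average(normalized=False)  # phase x muscles, mV
    smap = spinalmap.compute_spinal_map(cycle_avg, tensor.muscle_names, chart)
    trial.spinal_map = smap

    timing = {}
    fwhm_map = {}
    for name, wave in (("lumbar", smap.lumbar), ("sacral", smap.sacral)):
        try:
            timing[name] = spinalmap.timing_of_max(wave)
        except PepatoError:
            timing[name] = float("nan")
        try:
            fwhm_map[name], _ = synergy.compute_fwhm(wave)
        except PepatoError:
            fwhm_map[name] = float("nan")
    ci = spinalmap.coactivation_index(smap.lumbar, smap.sacral)

    trial.report = PiReport(
        n_modules=dec.n_modules,
        vaf=dec.vaf_total,
        fwhm_modules=fwhm,
        coa_modules=coa,
        timing_max=timing,
        fwhm_map=fwhm_map,
        coactivation_index=ci,
        quality=_quality_dict(trial),
    )
    return trial


def _quality_dict(trial: ProcessedTrial) -> dict:
    q = trial.quality
    return {
        "artifact_frequencies_hz": [float(f) for f in q.artifact_frequencies],
        "n_cycles": q.n_cycles,
        "excluded_cycles": [int(c) for c in q.excluded_cycles],
        "excluded_fraction": q.excluded_fraction,
        "excluded_muscles": list(q.excluded_muscles),
        "subject_excluded": bool(q.subject_excluded),
        "per_cycle": q.to_rows(trial.tensor.muscle_names),
    }
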