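"""Reference sets: control-cohort models for similarity indicators.

A reference set bundles (i) the k-means cluster model of the cohort's motor
modules in the Z-scored 2m feature space, (ii) per-speed ensemble-average
lumbar and sacral activation waveforms, and (iii) the cohort distributions
(median and quartiles) of every performance indicator. Evaluating a new
subject against a reference fills the similarity indicators: the cluster
assignment with pattern/weight similarities per module, and the Pearson
correlation of the subject's lumbar/sacral waveforms with the ensemble
averages.

On disk, a reference is a directory: ``clusters.yaml`` (cluster model),
``waveforms_<speed>.csv`` (ensemble group waveforms), ``pi_distributions.csv``
and ``metadata.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import matching, spinalmap
from .errors import BuildError, ConfigurationError, PepatoError
from .io_eurobench import PiReport
from .matching import ReferenceClusters
from .pipeline import ProcessedSubject

SCHEMA_TAG = "pepato-reference-1"


@dataclass
class ReferenceSet:
    clusters: ReferenceClusters
    #: speed -> {"lumbar": waveform, "sacral": waveform} ensemble averages
    waveforms: dict[str, dict[str, np.ndarray]]
    #: long-format rows: indicator, speed, median, q1, q3, n
    pi_distributions: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _collect_modules(subjects: list[ProcessedSubject]) -> tuple[np.ndarray, np.ndarray]:
    weights, patterns = [], []
    muscle_sets = set()
    for subject in subjects:
        for trial in subject.trials.values():
            if trial.decomposition is None:
                continue
            muscle_sets.add(tuple(trial.tensor.muscle_names))
            dec = trial.decomposition
            for i in range(dec.n_modules):
                weights.append(dec.W[:, i])
                patterns.append(dec.patterns_avg[i])
    if len(muscle_sets) > 1:
        raise BuildError(f"inconsistent muscle sets across subjects: {muscle_sets}")
    if not weights:
        raise BuildError("no decomposed modules found among the subjects")
    return np.stack(weights), np.stack(patterns)


def _pi_rows(subject: ProcessedSubject, speed: str) -> dict[str, float]:
    trial = subject.trials[speed]
    report = trial.report
    rows: dict[str, float] = {}
    if report is None or report.n_modules is None:
        return rows
    rows["p1_1_n_modules"] = float(report.n_modules)
    rows["p1_2_vaf"] = float(report.vaf)
    for i, v in enumerate(report.fwhm_modules or []):
        rows[f"p1_3_fwhm_m{i + 1}"] = float(v)
    for i, v in enumerate(report.coa_modules or []):
        if v is not None:
            rows[f"p1_4_coa_m{i + 1}"] = float(v)
    if report.timing_max:
        for g, v in report.timing_max.items():
            rows[f"p2_1_timing_{g}"] = float(v)
    if report.fwhm_map:
        for g, v in report.fwhm_map.items():
            rows[f"p2_2_fwhm_{g}"] = float(v)
    if report.coactivation_index is not None:
        rows["p2_3_ci"] = float(report.coactivation_index)
    return rows


def build_reference(
    subjects: list[ProcessedSubject],
    k: int = 4,
    seed: int = 0,
    metadata: dict | None = None,
) -> ReferenceSet:
    """Build a reference set from a processed control cohort.

    Clusters are fitted on the pooled modules of every subject and speed;
    ensemble waveforms and PI distributions are computed per speed.
    Deterministic for fixed inputs and seed.
    """
    if len(subjects) < 2:
        raise BuildError("a reference needs at least 2 processed subjects")
    weights, patterns = _collect_modules(subjects)
    clusters = matching.fit_reference_clusters(weights, patterns, k, seed=seed)

    speeds = sorted({s for subject in subjects for s in subject.speeds})
    waveforms: dict[str, dict[str, np.ndarray]] = {}
    rows = []
    for speed in speeds:
        lumbar, sacral = [], []
        for subject in subjects:
            trial = subject.trials.get(speed)
            if trial is None or trial.spinal_map is None:
                continue
            lumbar.append(trial.spinal_map.lumbar)
            sacral.append(trial.spinal_map.sacral)
            for name, value in _pi_rows(subject, speed).items():
                rows.append({"indicator": name, "speed": speed, "value": value})
        if lumbar:
            waveforms[speed] = {
                "lumbar": np.mean(lumbar, axis=0),
                "sacral": np.mean(sacral, axis=0),
            }
    df = pd.DataFrame(rows)
    if df.empty:
        raise BuildError("no indicator values available to build distributions")
    dist = (
        df.groupby(["indicator", "speed"])["value"]
        .agg(
            median="median",
            q1=lambda v: float(np.percentile(v, 25)),
            q3=lambda v: float(np.percentile(v, 75)),
            n="count",
        )
        .reset_index()
    )
    return ReferenceSet(clusters, waveforms, dist, metadata or {"label": "cohort"})


def evaluate_against_reference(
    subject: ProcessedSubject, reference: ReferenceSet, speed: str
) -> PiReport:
    """Fill the reference-dependent indicators of one condition's report."""
    trial = subject.trials.get(speed)
    if trial is None:
        raise ConfigurationError(f"subject has no condition at speed {speed!r}")
    if speed not in reference.waveforms:
        raise ConfigurationError(f"reference has no data at speed {speed!r}")
    report = trial.report or PiReport()
    if trial.decomposition is not None:
        assignments = []
        dec = trial.decomposition
        for i in range(dec.n_modules):
            vec = matching.build_feature_vector(
                dec.W[:, i], dec.patterns_avg[i], reference.clusters.stats
            )
            assignment = matching.assign_module(
                vec, reference.clusters, pattern=dec.patterns_avg[i], weights=dec.W[:, i]
            )
            assignments.append(assignment.as_dict())
        report.module_assignments = assignments
    if trial.spinal_map is not None:
        ref_waves = reference.waveforms[speed]
        sims = {}
        for group, wave in (
            ("lumbar", trial.spinal_map.lumbar),
            ("sacral", trial.spinal_map.sacral),
        ):
            try:
                sims[group] = spinalmap.map_similarity(wave, ref_waves[group])
            except PepatoError:
                sims[group] = float("nan")
        report.map_similarity = sims
    trial.report = report
    return report


def save_reference(reference: ReferenceSet, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matching.save_clusters(reference.clusters, out_dir / "clusters.yaml")
    for speed, waves in reference.waveforms.items():
        pd.DataFrame(
            {"lumbar": waves["lumbar"], "sacral": waves["sacral"]}
        ).to_csv(out_dir / f"waveforms_{speed}.csv", index=False, float_format="%.12g")
    reference.pi_distributions.to_csv(
        out_dir / "pi_distributions.csv", index=False, float_format="%.12g"
    )
    meta = {"schema": SCHEMA_TAG, **reference.metadata}
    with open(out_dir / "metadata.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return out_dir


def load_reference(in_dir: str | Path) -> ReferenceSet:
    in_dir = Path(in_dir)
    with open(in_dir / "metadata.yaml", encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    if meta.get("schema") != SCHEMA_TAG:
        raise ConfigurationError(f"unknown reference schema {meta.get('schema')!r}")
    clusters = matching.load_clusters(in_dir / "clusters.yaml")
    waveforms = {}
    for path in sorted(in_dir.glob("waveforms_*.csv")):
        speed = path.stem.removeprefix("waveforms_")
        df = pd.read_csv(path)
        waveforms[speed] = {
            "lumbar": df["lumbar"].to_numpy(),
            "sacral": df["sacral"].to_numpy(),
        }
    dist = pd.read_csv(in_dir / "pi_distributions.csv")
    meta.pop("schema", None)
    return ReferenceSet(clusters, waveforms, dist, meta)
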