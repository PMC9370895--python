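"""Group-comparison utilities for performance-indicator tables.

Non-parametric policy throughout: Mann-Whitney U for independent groups,
Wilcoxon matched-pairs for related groups, the Watson-Williams F test for
circular quantities (center of activity, timing of maximal activation), and
Benjamini-Hochberg step-up correction across a PI family. Circular inputs
may be given in degrees or in % of the gait cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, ParameterError

ALPHA_DEFAULT = 0.05


@dataclass
class GroupComparison:
    indicator: str
    test: str
    statistic: float
    p_value: float
    adjusted_p: float | None = None
    reject: bool | None = None
    note: str = ""

    def adjust(self, adjusted_p: float, alpha: float = ALPHA_DEFAULT) -> None:
        self.adjusted_p = float(min(1.0, max(adjusted_p, self.p_value)))
        self.reject = self.adjusted_p < alpha


def compare_groups(
    values_a, values_b, kind: str = "independent", indicator: str = ""
) -> GroupComparison:
    """Two-sided rank test between two samples of a linear indicator.

    ``kind='independent'`` runs the Mann-Whitney U test, ``kind='paired'``
    the Wilcoxon matched-pairs signed-rank test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("need at least 3 observations per group")
    if kind == "independent":
        res = sst.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann_whitney"
    elif kind == "paired":
        if a.size != b.size:
            raise ParameterError("paired comparison requires equal lengths")
        if np.allclose(a, b):
            return GroupComparison(indicator, "wilcoxon_paired", 0.0, 1.0,
                                   note="identical samples")
        res = sst.wilcoxon(a, b, alternative="two-sided")
        name = "wilcoxon_paired"
    else:
        raise ParameterError("kind must be 'independent' or 'paired'")
    return GroupComparison(indicator, name, float(res.statistic), float(res.pvalue))


def _to_radians(angles: np.ndarray, unit: str) -> np.ndarray:
    if unit == "radians":
        return angles
    if unit == "degrees":
        return np.deg2rad(angles)
    if unit == "percent":  # % of gait cycle
        return angles * 2 * np.pi / 100.0
    raise ParameterError("unit must be 'radians', 'degrees' or 'percent'")


def circular_mean(angles, unit: str = "degrees") -> float:
    """Circular mean, returned in the input unit, wrapped to one cycle."""
    a = _to_radians(np.asarray(angles, dtype=float), unit)
    mean = np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a))) % (2 * np.pi)
    if unit == "degrees":
        return float(np.rad2deg(mean))
    if unit == "percent":
        return float(100.0 * mean / (2 * np.pi))
    return float(mean)


def _kappa_from_r(r: float) -> float:
    """Maximum-likelihood von Mises concentration for a resultant length r."""
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r**3 - 4 * r**2 + 3 * r)


def watson_williams(
    angles_a, angles_b, unit: str = "degrees", indicator: str = ""
) -> GroupComparison:
    """Watson-Williams two-sample test for a common circular mean direction.

    Standard one-way F form with the concentration correction factor
    1 + 3/(8*kappa); kappa is estimated from the mean within-group resultant
    length. The test assumes reasonably concentrated von Mises samples; when
    the pooled resultant length is small (< 0.45) a warning note is attached
    because the F approximation degrades.
    """
    a = _to_radians(np.asarray(angles_a, dtype=float), unit)
    b = _to_radians(np.asarray(angles_b, dtype=float), unit)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("need at least 3 angles per group")
    n1, n2 = a.size, b.size
    n = n1 + n2
    r1 = float(np.hypot(np.sum(np.cos(a)), np.sum(np.sin(a))))
    r2 = float(np.hypot(np.sum(np.cos(b)), np.sum(np.sin(b))))
    pooled = np.concatenate([a, b])
    r_all = float(np.hypot(np.sum(np.cos(pooled)), np.sum(np.sin(pooled))))
    rw = (r1 + r2) / n  # mean within-group resultant length
    note = ""
    if rw < 1e-12:
        note = "resultant length ~ 0: circular means undefined"
        return GroupComparison(indicator, "watson_williams", np.nan, np.nan, note=note)
    if rw < 0.45:
        note = "low concentration (rw < 0.45): F approximation unreliable"
        warnings.warn(note, stacklevel=2)
    kappa = _kappa_from_r(min(rw, 1 - 1e-12))
    correction = 1 + 3 / (8 * kappa)
    num = (n - 2) * (r1 + r2 - r_all)
    den = n - (r1 + r2)
    if den <= 0:
        return GroupComparison(indicator, "watson_williams", 0.0, 1.0, note="degenerate")
    f = max(correction * num / den, 0.0)
    p = float(sst.f.sf(f, 1, n - 2))
    return GroupComparison(indicator, "watson_williams", float(f), p, note=note)


def benjamini_hochberg(
    p_values, alpha: float = ALPHA_DEFAULT
) -> tuple[np.ndarray, np.ndarray]:
    """Step-up false-discovery-rate adjustment.

    Returns (adjusted p-values, reject flags at ``alpha``); adjusted values
    are monotone and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ParameterError("p values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return adjusted, reject


def adjust_family(
    comparisons: list[GroupComparison], alpha: float = ALPHA_DEFAULT
) -> list[GroupComparison]:
    """BH-adjust a family of comparisons in place (one PI group at a time)."""
    valid = [c for c in comparisons if np.isfinite(c.p_value)]
    if valid:
        adjusted, _ = benjamini_hochberg([c.p_value for c in valid], alpha)
        for c, ap in zip(valid, adjusted):
            c.adjust(ap, alpha)
    return comparisons
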