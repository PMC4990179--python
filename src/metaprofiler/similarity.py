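"""Profile-similarity pseudometrics and the gradient/threshold classification.

Six pseudometrics compare two equal-length, non-negative enrichment curves:

==========================  ==============================================
RATIO_AREA                  total area of curve 1 over curve 2
DIFF_POS_MAX                difference between the peak positions
RATIO_MAX_MAX               peak height of curve 1 over curve 2
RATIO_INTERSECT             area under the pointwise minimum over the area
                            under the pointwise maximum, in [0, 1]
RATIO_NORMALIZED_INTERSECT  RATIO_INTERSECT after dividing each curve by its
                            own mean (scale-free shape comparison)
SPEARMAN_CORRELATION        rank correlation of paired positions
==========================  ==============================================

Each metric carries editable validity thresholds guarding against extreme
values from near-empty curves (e.g. a peak-position difference is
meaningless when neither curve has an appreciable peak); a result failing
its guard is returned as an explicit *undefined* value with a reason, never
a silent NaN.

The RATIO_INTERSECT of the moderate- against the high-activity group profile
classifies a factor's occupancy response to transcriptional activity:
values at or above the cutoff (default 0.85) mean the profiles are nearly
interchangeable — occupancy has saturated before maximal activity, a
"threshold effect" — while lower values mean occupancy still grows with
activity, a "gradient effect".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

METRIC_NAMES = (
    "RATIO_AREA",
    "DIFF_POS_MAX",
    "RATIO_MAX_MAX",
    "RATIO_INTERSECT",
    "RATIO_NORMALIZED_INTERSECT",
    "SPEARMAN_CORRELATION",
)

#: default validity thresholds (curve units); editable per call
DEFAULT_THRESHOLDS = {"min_peak": 1.0, "min_area": 1.0}


@dataclass(frozen=True)
class PseudometricResult:
    name: str
    value: float | None
    thresholds_used: dict = field(default_factory=dict)
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class EffectClass:
    """Occupancy-response classification of one factor at one region class."""

    label: str  # "gradient", "threshold" or "unclassifiable"
    ratio_intersect: float | None
    cutoff: float = 0.85


def _check_pair(p1, p2) -> tuple[np.ndarray, np.ndarray]:
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    if p1.shape != p2.shape or p1.ndim != 1:
        raise ValueError(f"curves must be 1-D and equal length, got {p1.shape} vs {p2.shape}")
    if (p1 < 0).any() or (p2 < 0).any():
        raise ValueError("pseudometrics are defined on non-negative curves")
    return p1, p2


def _result(name, value, thresholds, reason=None) -> PseudometricResult:
    return PseudometricResult(
        name=name,
        value=None if reason else float(value),
        thresholds_used=dict(thresholds),
        undefined_reason=reason,
    )


def ratio_area(p1, p2, min_area: float = DEFAULT_THRESHOLDS["min_area"]) -> PseudometricResult:
    """Total area of the first curve over the second."""
    p1, p2 = _check_pair(p1, p2)
    th = {"min_area": min_area}
    a2 = p2.sum()
    if a2 < min_area:
        return _result("RATIO_AREA", None, th, f"area of second curve {a2:g} < {min_area:g}")
    return _result("RATIO_AREA", p1.sum() / a2, th)


def _argmax_median(p: np.ndarray) -> float:
    """Peak position; the median index when the maximum is tied."""
    ties = np.flatnonzero(p == p.max())
    return float(np.median(ties))


def diff_pos_max(p1, p2, min_peak: float = DEFAULT_THRESHOLDS["min_peak"]) -> PseudometricResult:
    """Signed distance (positions) between the two peak summits."""
    p1, p2 = _check_pair(p1, p2)
    th = {"min_peak": min_peak}
    if p1.max() < min_peak or p2.max() < min_peak:
        return _result(
            "DIFF_POS_MAX", None, th,
            f"peak height below {min_peak:g} in at least one curve",
        )
    return _result("DIFF_POS_MAX", _argmax_median(p1) - _argmax_median(p2), th)


def ratio_max_max(p1, p2, min_peak: float = DEFAULT_THRESHOLDS["min_peak"]) -> PseudometricResult:
    """Peak height of the first curve over the second."""
    p1, p2 = _check_pair(p1, p2)
    th = {"min_peak": min_peak}
    if p2.max() < min_peak:
        return _result("RATIO_MAX_MAX", None, th, f"peak of second curve below {min_peak:g}")
    return _result("RATIO_MAX_MAX", p1.max() / p2.max(), th)


def ratio_intersect(p1, p2) -> PseudometricResult:
    """Area of the pointwise minimum over the area of the pointwise maximum.

    Symmetric; 1 for identical curves, 0 for disjoint supports.
    """
    p1, p2 = _check_pair(p1, p2)
    total = np.maximum(p1, p2).sum()
    if total == 0:
        return _result("RATIO_INTERSECT", None, {}, "both curves are all-zero")
    return _result("RATIO_INTERSECT", np.minimum(p1, p2).sum() / total, {})


def ratio_normalized_intersect(p1, p2) -> PseudometricResult:
    """RATIO_INTERSECT of the mean-normalised curves (scale-invariant)."""
    p1, p2 = _check_pair(p1, p2)
    m1, m2 = p1.mean(), p2.mean()
    if m1 == 0 or m2 == 0:
        return _result("RATIO_NORMALIZED_INTERSECT", None, {}, "a curve has zero mean")
    inner = ratio_intersect(p1 / m1, p2 / m2)
    return _result("RATIO_NORMALIZED_INTERSECT", inner.value, {})


def spearman_correlation(p1, p2) -> PseudometricResult:
    """Spearman rank correlation of the paired position values."""
    p1, p2 = _check_pair(p1, p2)
    if np.all(p1 == p1[0]) or np.all(p2 == p2[0]):
        return _result("SPEARMAN_CORRELATION", None, {}, "a curve is constant (zero variance)")
    rho = stats.spearmanr(p1, p2).statistic
    return _result("SPEARMAN_CORRELATION", rho, {})


def compute_all(p1, p2, thresholds: dict | None = None) -> dict[str, PseudometricResult]:
    """All six pseudometrics for one curve pair."""
    th = dict(DEFAULT_THRESHOLDS, **(thresholds or {}))
    return {
        "RATIO_AREA": ratio_area(p1, p2, min_area=th["min_area"]),
        "DIFF_POS_MAX": diff_pos_max(p1, p2, min_peak=th["min_peak"]),
        "RATIO_MAX_MAX": ratio_max_max(p1, p2, min_peak=th["min_peak"]),
        "RATIO_INTERSECT": ratio_intersect(p1, p2),
        "RATIO_NORMALIZED_INTERSECT": ratio_normalized_intersect(p1, p2),
        "SPEARMAN_CORRELATION": spearman_correlation(p1, p2),
    }


def classify_effect(profile_moderate, profile_high, cutoff: float = 0.85) -> EffectClass:
    """Classify occupancy response from the moderate- and high-activity profiles.

    RATIO_INTERSECT at or above ``cutoff`` -> "threshold" (occupancy
    saturated); below -> "gradient" (occupancy tracks activity); undefined
    RATIO_INTERSECT -> "unclassifiable".
    """
    ri = ratio_intersect(profile_moderate, profile_high)
    if not ri.defined:
        return EffectClass(label="unclassifiable", ratio_intersect=None, cutoff=cutoff)
    label = "threshold" if ri.value >= cutoff else "gradient"
    return EffectClass(label=label, ratio_intersect=ri.value, cutoff=cutoff)
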