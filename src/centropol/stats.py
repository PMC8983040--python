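"""Angular statistics for rotational-polarity data.

Relative angles between a subject azimuth and a reference azimuth are
binned into four 90-degree quadrants measured clockwise from the
reference (Q1 centred on it, Q2 = 45-135 degrees clockwise, ...) and
tested against uniformity with a Pearson chi-square on 3 degrees of
freedom.  Circular summaries, a two-sample Kolmogorov-Smirnov comparison
and Monte-Carlo calibration of the chi-square test complete the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .angles import circular_mean_deg, normalize_deg
from .errors import ParameterError

QUADRANT_EDGES_DEG = (-45.0, 45.0, 135.0, 225.0, 315.0)


@dataclass
class AngleRecord:
    """One measured relative angle.

    kind "A": azimuth of the marker in the procentriole measured from the
    parent long-axis direction.  kind "B": azimuth of the procentriole
    attachment measured clockwise from the parent-marker centroid.
    """

    particle_id: str
    angle_deg: float
    kind: str = "B"

    def __post_init__(self):
        if self.kind not in ("A", "B"):
            raise ParameterError(f"kind must be 'A' or 'B', got {self.kind!r}")
        self.angle_deg = float(normalize_deg(self.angle_deg))


@dataclass
class QuadrantCounts:
    counts: tuple  # (Q1, Q2, Q3, Q4)
    n: int

    def __post_init__(self):
        if sum(self.counts) != self.n:
            raise ParameterError("quadrant counts must sum to n")


@dataclass
class PolarityTestResult:
    chi2: float
    df: int
    p_value: float
    expected: tuple
    small_sample_warning: bool = False


def relative_angle(subject_azimuth_deg, reference_azimuth_deg,
                   orientation: str = "clockwise"):
    """Normalized relative angle in [0, 360) under the stated orientation.

    Azimuths follow the mathematical (counterclockwise-positive, distal
    view) convention; "clockwise" therefore returns
    ``(reference - subject) mod 360``.  Shifting the reference by delta
    shifts every output by -delta (mod 360) for the counterclockwise
    orientation and +delta for the clockwise one.
    """
    s = np.asarray(subject_azimuth_deg, dtype=float)
    r = np.asarray(reference_azimuth_deg, dtype=float)
    if orientation == "clockwise":
        out = normalize_deg(r - s)
    elif orientation == "counterclockwise":
        out = normalize_deg(s - r)
    else:
        raise ParameterError(f"unknown orientation {orientation!r}")
    return float(out) if out.ndim == 0 else out


def assign_quadrants(angles_deg) -> np.ndarray:
    """Quadrant index 1..4 per angle; Q1 = [-45, 45) about the reference.

    Edges are half-open and left-inclusive: an angle exactly on an edge
    (45, 135, ...) falls in the higher quadrant.
    """
    a = normalize_deg(np.asarray(angles_deg, dtype=float))
    return (normalize_deg(a + 45.0) // 90.0).astype(int) + 1


def quadrant_chi2(angles_deg):
    """Quadrant binning plus Pearson chi-square against uniformity.

    Returns ``(QuadrantCounts, PolarityTestResult)``.  n < 20 (expected
    counts below 5) sets a small-sample warning on the result rather than
    raising.
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size < 1:
        raise ParameterError("need at least one angle")
    q = assign_quadrants(a)
    counts = tuple(int(np.sum(q == k)) for k in (1, 2, 3, 4))
    n = int(a.size)
    expected = n / 4.0
    chi2 = float(sum((c - expected) ** 2 / expected for c in counts))
    p = float(sps.chi2.sf(chi2, df=3))
    return (QuadrantCounts(counts=counts, n=n),
            PolarityTestResult(chi2=chi2, df=3, p_value=p,
                               expected=(expected,) * 4,
                               small_sample_warning=n < 20))


@dataclass
class CircularSummary:
    mean_deg: float
    resultant: float
    axial_mean_deg: float  # angle-doubled summary for bimodal (Q1/Q3) alignment
    axial_resultant: float
    mean_undefined: bool


def circular_summary(angles_deg) -> CircularSummary:
    """Vector-sum circular mean / resultant, plus the axial (doubled) summary."""
    a = np.asarray(angles_deg, dtype=float)
    if a.size < 1:
        raise ParameterError("need at least one angle")
    mean, r = circular_mean_deg(a)
    mean2, r2 = circular_mean_deg(normalize_deg(2.0 * a))
    axial_mean = float("nan") if np.isnan(mean2) else normalize_deg(mean2 / 2.0)
    return CircularSummary(mean_deg=mean, resultant=r,
                           axial_mean_deg=float(axial_mean), axial_resultant=r2,
                           mean_undefined=bool(r < 1e-12 or np.isnan(mean)))


def ks_two_sample(values_a, values_b):
    """Two-sample Kolmogorov-Smirnov D statistic and p-value."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("both samples need at least 2 values")
    res = sps.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Monte-Carlo calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    rejection_rate: float
    ci_low: float  # normal-approximation 95% binomial CI
    ci_high: float
    n: int
    reps: int
    alpha: float


def mc_calibrate(quadrant_probs, n: int, reps: int, alpha: float = 0.05,
                 seed: int = 0) -> CalibrationResult:
    """Rejection rate of the quadrant chi-square under stated quadrant odds.

    Draws ``reps`` multinomial cohorts of size ``n`` from
    ``quadrant_probs`` and reports the fraction rejected at ``alpha``,
    with a 95% binomial confidence interval.
    """
    p = np.asarray(quadrant_probs, dtype=float)
    if p.shape != (4,) or not np.isclose(p.sum(), 1.0):
        raise ParameterError("quadrant_probs must be 4 probabilities summing to 1")
    if n < 1 or reps < 1:
        raise ParameterError("n and reps must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, p, size=reps)
    expected = n / 4.0
    chi2 = ((counts - expected) ** 2 / expected).sum(axis=1)
    crit = sps.chi2.isf(alpha, df=3)
    rate = float(np.mean(chi2 > crit))
    half = 1.96 * np.sqrt(max(rate * (1 - rate), 1e-12) / reps)
    return CalibrationResult(rejection_rate=rate,
                             ci_low=max(rate - half, 0.0),
                             ci_high=min(rate + half, 1.0),
                             n=n, reps=reps, alpha=alpha)


def power_noncentral_chi2(quadrant_probs, n: int, alpha: float = 0.05) -> float:
    """Approximate power via the noncentral chi-square with
    lambda = n * sum((p_i - 1/4)^2 / (1/4))."""
    p = np.asarray(quadrant_probs, dtype=float)
    lam = n * float(np.sum((p - 0.25) ** 2 / 0.25))
    crit = sps.chi2.isf(alpha, df=3)
    return float(sps.ncx2.sf(crit, df=3, nc=lam))


def sample_quadrant_angles(quadrant_probs, n: int, rng) -> np.ndarray:
    """Clockwise relative angles drawn quadrant-wise (uniform within each)."""
    p = np.asarray(quadrant_probs, dtype=float)
    q = rng.choice(4, size=n, p=p / p.sum())
    centers = np.array([0.0, 90.0, 180.0, 270.0])
    return normalize_deg(centers[q] + rng.uniform(-45.0, 45.0, size=n))
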