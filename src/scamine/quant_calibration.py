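"""Impurity correction, internal-standard normalization and weighted calibration.

The quantitative chain is: per-scan isobaric impurity correction of the
reporter vector, integration of the corrected per-channel EICs, normalization
of each analyte area to the co-eluting heavy-isotope internal standard (IS)
measured in its own tPRM transition, a 1/x-weighted linear calibration with
Grubbs outlier screening on residuals, S/N-based LOD/LOQ, and back-calculation
of absolute amounts with calibration-range flags.

Weighting by 1/x ("1/c" on nominal amount — the two notations mean the same
thing here) places more emphasis on the low end of the 4-decade calibration
range, where single-cell amounts actually sit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .channels import CHANNEL_NAMES, CHANNELS, Channel
from .reporter_extraction import (
    Eic,
    Ms2Scan,
    ReporterReading,
    eic_from_points,
    extract_reporters,
    integrate_eic,
)

# ---------------------------------------------------------------------------
# Impurity correction
# ---------------------------------------------------------------------------


@dataclass
class ImpurityMatrix:
    """Channel cross-talk matrix: entry (i, j) is the fraction of channel j's
    reporter signal observed in channel i.

    Columns may sum to less than 1 (isotope envelope mass falling outside the
    monitored channels is simply lost); the diagonal must stay >= 0.85.
    """

    channels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.channels)
        if self.values.shape != (n, n):
            raise ValueError("impurity matrix must be square over the channels")
        if np.any(self.values < 0):
            raise ValueError("impurity fractions must be nonnegative")
        if np.any(np.diag(self.values) < 0.85):
            raise ValueError("impurity matrix diagonal must be >= 0.85")
        if np.any(self.values.sum(axis=0) > 1 + 1e-9):
            raise ValueError("impurity matrix columns must sum to <= 1")

    @classmethod
    def identity(cls, channels: tuple[str, ...] = CHANNEL_NAMES) -> "ImpurityMatrix":
        return cls(channels, np.eye(len(channels)))

    @classmethod
    def default(cls, channels: tuple[str, ...] = CHANNEL_NAMES) -> "ImpurityMatrix":
        """Vendor-CoA-like defaults: ±1 Da isotope impurities of a few percent,
        ±2 Da below 0.3 %.

        In the m/z-ordered channel list a ±1 Da isotope lands two positions
        away (the +1 Da isotopologue of 126 has the same composition as the
        127C reporter), so the off-diagonals sit at index offsets ±2 and ±4.
        """
        n = len(channels)
        m = np.zeros((n, n))
        minus2, minus1, plus1, plus2 = 0.002, 0.04, 0.03, 0.003
        for j in range(n):
            m[j, j] = 1.0 - (minus2 + minus1 + plus1 + plus2)
            for off, frac in ((-4, minus2), (-2, minus1), (2, plus1), (4, plus2)):
                if 0 <= j + off < n:
                    m[j + off, j] = frac
        return cls(tuple(channels), m)

    def mix(self, ideal: np.ndarray) -> np.ndarray:
        """Forward-mix an ideal per-channel vector: observed = M · ideal."""
        return self.values @ np.asarray(ideal, dtype=float)


def correct_impurities(reading: ReporterReading, m: ImpurityMatrix) -> ReporterReading:
    """Undo isobaric cross-talk: solve M·x = observed, clamping negatives to 0.

    An identity matrix returns the reading unchanged.  Ill-conditioned
    matrices (condition number > 1e6) are rejected.
    """
    obs = reading.vector(m.channels)
    if np.array_equal(m.values, np.eye(len(m.channels))):
        corrected = obs
    else:
        if np.linalg.cond(m.values) > 1e6:
            raise ValueError("impurity matrix is singular or ill-conditioned")
        corrected = np.linalg.solve(m.values, obs)
        corrected = np.clip(corrected, 0.0, None)
    return ReporterReading(
        reading.scan_id, reading.rt, dict(zip(m.channels, corrected.tolist()))
    )


# ---------------------------------------------------------------------------
# Internal-standard normalization and weighted calibration
# ---------------------------------------------------------------------------


def normalize_to_is(analyte_area: float, is_area: float) -> float | None:
    """Response = analyte area / IS area; ``None`` (flagged missing, never a
    silent 0) when the IS area is nonpositive."""
    if is_area <= 0:
        return None
    return analyte_area / is_area


@dataclass
class CalibrationPoint:
    """One calibration level: nominal amount x (fmol) vs IS-normalized
    response y (dimensionless)."""

    x: float
    y: float
    included: bool = True

    def __post_init__(self) -> None:
        if self.x <= 0:
            raise ValueError("nominal amount must be > 0")
        if self.y < 0:
            raise ValueError("response must be >= 0")


@dataclass
class CalibrationCurve:
    analyte: str
    slope: float
    intercept: float
    r: float
    range: tuple[float, float]
    n_points: int
    residuals: np.ndarray = field(repr=False)
    points: list[CalibrationPoint] = field(repr=False)
    lod_amol: float | None = None
    loq_amol: float | None = None


def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    wm = w / w.sum()
    mx, my = wm @ x, wm @ y
    sxy = wm @ ((x - mx) * (y - my))
    sxx = wm @ ((x - mx) ** 2)
    syy = wm @ ((y - my) ** 2)
    if sxx <= 0 or syy <= 0:
        raise ValueError("degenerate calibration data (zero variance)")
    return float(sxy / math.sqrt(sxx * syy))


def fit_weighted(
    points: list[CalibrationPoint],
    analyte: str = "",
    min_points: int = 5,
    weighting: str = "1/x",
) -> CalibrationCurve:
    """1/x-weighted least-squares line through the included points.

    Minimizes sum w_i (y_i - a - b x_i)^2 with w_i = 1/x_i; R is the Pearson
    correlation weighted with the same weights.  ``weighting='unit'`` gives
    the ordinary unweighted fit.
    """
    used = [p for p in points if p.included]
    if len(used) < min_points:
        raise ValueError(f"{len(used)} points; >= {min_points} required")
    x = np.array([p.x for p in used])
    y = np.array([p.y for p in used])
    if np.unique(x).size < 2:
        raise ValueError("all nominal amounts are equal")
    if weighting == "1/x":
        w = 1.0 / x
    elif weighting == "unit":
        w = np.ones_like(x)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    a, b = float(res.params[0]), float(res.params[1])
    r = _weighted_pearson(x, y, w)
    return CalibrationCurve(
        analyte=analyte, slope=b, intercept=a, r=r,
        range=(float(x.min()), float(x.max())), n_points=len(used),
        residuals=y - (a + b * x), points=list(points),
    )


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """One-outlier Grubbs critical value from the t distribution."""
    t = sps.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_outlier(residuals: np.ndarray, alpha: float = 0.05) -> int | None:
    """Index of the single most extreme residual if it fails Grubbs' test.

    At most one point is flagged per call; ties on |r - mean| keep the first
    occurrence.  Zero spread means no outlier is detectable.
    """
    r = np.asarray(residuals, dtype=float)
    n = r.size
    if n < 4:
        raise ValueError("Grubbs test requires n >= 4")
    sd = r.std(ddof=1)
    if sd == 0:
        return None
    dev = np.abs(r - r.mean())
    idx = int(np.argmax(dev))
    g = dev[idx] / sd
    return idx if g > grubbs_critical(n, alpha) else None


def calibrate_analyte(
    points: list[CalibrationPoint],
    analyte: str = "",
    loq_fmol: float | None = None,
    alpha: float = 0.05,
    max_outliers: int = 2,
    min_points: int = 5,
) -> CalibrationCurve:
    """Full calibration: below-LOQ exclusion, fit, iterative Grubbs screening
    of residuals (at most ``max_outliers`` removals), refit."""
    pts = [CalibrationPoint(p.x, p.y, p.included) for p in points]
    if loq_fmol is not None:
        for p in pts:
            if p.x < loq_fmol:
                p.included = False
    curve = fit_weighted(pts, analyte, min_points)
    for _ in range(max_outliers):
        used = [p for p in pts if p.included]
        if len(used) <= min_points or len(used) < 4:
            break
        # an essentially perfect fit leaves only floating-point noise in the
        # residuals; Grubbs on that noise would discard a valid level
        y_scale = max(abs(p.y) for p in used)
        if np.max(np.abs(curve.residuals)) <= 1e-9 * max(y_scale, 1e-300):
            break
        idx = grubbs_outlier(curve.residuals, alpha)
        if idx is None:
            break
        used[idx].included = False
        curve = fit_weighted(pts, analyte, min_points)
    return curve


def lod_loq(noise_sd: float, response_per_amol: float) -> tuple[float, float]:
    """LOD and LOQ (amol) at signal-to-noise 3 and 10.

    ``response_per_amol`` is the peak-height response per amol of analyte;
    LOQ/LOD = 10/3 exactly by construction.
    """
    if response_per_amol <= 0:
        raise ValueError("response_per_amol must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lod = 3.0 * noise_sd / response_per_amol
    loq = 10.0 * noise_sd / response_per_amol
    return lod, loq


BELOW_LOQ = "below_LOQ"
IN_RANGE = "in_range"
ABOVE_ULOQ = "above_ULOQ"


def back_calculate(response: float, curve: CalibrationCurve) -> tuple[float, str]:
    """Invert the calibration line and flag against the calibration range."""
    if curve.slope == 0:
        raise ValueError("calibration slope is zero")
    amount = (response - curve.intercept) / curve.slope
    lo, hi = curve.range
    if amount < lo:
        flag = BELOW_LOQ
    elif amount > hi:
        flag = ABOVE_ULOQ
    else:
        flag = IN_RANGE
    return amount, flag


def repeatability_rsd(amounts: list[float]) -> float:
    """Relative standard deviation (%) of replicate amounts, sample SD (n-1)."""
    a = np.asarray(amounts, dtype=float)
    if a.size < 3:
        raise ValueError("repeatability requires >= 3 replicates")
    mean = a.mean()
    if mean == 0:
        raise ValueError("mean amount is zero; RSD undefined")
    return float(100.0 * a.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# Scan-level pipeline helpers
# ---------------------------------------------------------------------------


def corrected_channel_eics(
    scans: list[Ms2Scan],
    target_id: str,
    impurity: ImpurityMatrix,
    channels: tuple[Channel, ...] = CHANNELS,
    tol_mda: float = 5.0,
) -> dict[str, Eic]:
    """Impurity-corrected per-channel EICs for one target's scans.

    Correction is applied to the reporter vector of every scan before the
    traces are assembled, mirroring "correct, then integrate".
    """
    mine = sorted((s for s in scans if s.target_id == target_id), key=lambda s: s.rt)
    if not mine:
        raise ValueError(f"no scans for target {target_id!r}")
    traces: dict[str, list[tuple[float, float]]] = {c.name: [] for c in channels}
    for s in mine:
        reading = correct_impurities(extract_reporters(s, channels, tol_mda), impurity)
        for name in traces:
            traces[name].append((s.rt, reading.intensities[name]))
    return {name: eic_from_points(target_id, name, pts) for name, pts in traces.items()}


def target_areas(
    scans: list[Ms2Scan],
    target_id: str,
    impurity: ImpurityMatrix,
    channels: tuple[Channel, ...] = CHANNELS,
    tol_mda: float = 5.0,
    window_fwhms: float = 2.0,
) -> dict[str, float]:
    """Integrated corrected reporter areas per channel for one target.

    All channels of a multiplexed analyte co-elute, so a shared integration
    window (apex ± ``window_fwhms``·FWHM, clipped to the trace span) is taken
    from the most intense channel (normally the carrier).
    """
    eics = corrected_channel_eics(scans, target_id, impurity, channels, tol_mda)
    ref = max(eics.values(), key=lambda e: e.area)
    if ref.apex_rt is None:
        return {name: 0.0 for name in eics}
    if ref.fwhm is None:
        raise ValueError(f"reference trace for {target_id!r} has undefined FWHM")
    lo_span, hi_span = ref.rt_span
    lo = max(lo_span, ref.apex_rt - window_fwhms * ref.fwhm)
    hi = min(hi_span, ref.apex_rt + window_fwhms * ref.fwhm)
    return {name: integrate_eic(e, (lo, hi)) for name, e in eics.items()}
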