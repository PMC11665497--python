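"""Reporter-ion extraction from centroided MS2 scans.

Every multiplexed analyte produces one MS2 spectrum per scan cycle in which the
TMT10plex reporter cations (m/z ~126-131) carry the per-channel quantitative
signal.  This module matches centroid peaks to reporter channels, assembles
per-channel extracted ion chromatograms (EICs), and derives the chromatographic
descriptors (apex, FWHM, area, noise) that the calibration machinery consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import CHANNELS, Channel


@dataclass
class Ms2Scan:
    """One centroided MS2 scan tied to a tPRM target or DDA feature.

    Peaks are (m/z, intensity) tuples sorted by m/z with nonnegative
    intensities; ``rt`` is in minutes.
    """

    scan_id: str
    target_id: str
    rt: float
    precursor_mz: float
    peaks: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        mzs = [p[0] for p in self.peaks]
        if any(b < a for a, b in zip(mzs, mzs[1:])):
            raise ValueError(f"scan {self.scan_id}: peaks not sorted by m/z")
        if any(p[1] < 0 for p in self.peaks):
            raise ValueError(f"scan {self.scan_id}: negative peak intensity")


@dataclass
class ReporterReading:
    """Per-channel reporter intensities for one scan (0 when no peak matched)."""

    scan_id: str
    rt: float
    intensities: dict[str, float]

    def vector(self, channel_names: tuple[str, ...]) -> np.ndarray:
        return np.array([self.intensities[c] for c in channel_names], dtype=float)


@dataclass
class Eic:
    """Extracted ion chromatogram of one reporter channel for one target.

    ``fwhm`` is ``None`` when no peak could be characterised (flat or
    single-point trace); ``area`` is the trapezoidal integral over the full
    trace and is 0 for an all-zero trace.
    """

    target_id: str
    channel: str
    points: list[tuple[float, float]]
    apex_rt: float | None = None
    apex_intensity: float = 0.0
    fwhm: float | None = None
    area: float = 0.0

    @property
    def rt_span(self) -> tuple[float, float]:
        return (self.points[0][0], self.points[-1][0])


@dataclass
class NoiseEstimate:
    """Sample standard deviation of intensities in a peak-free RT window."""

    channel: str
    window: tuple[float, float]
    sd_intensity: float
    n_points: int


def extract_reporters(
    scan: Ms2Scan,
    channels: tuple[Channel, ...] = CHANNELS,
    tol_mda: float = 5.0,
) -> ReporterReading:
    """Match centroid peaks to reporter channels within an absolute tolerance.

    Each peak is assigned to at most one channel — the channel whose reporter
    m/z is nearest — and each channel keeps the most intense peak assigned to
    it.  An absolute (mDa) tolerance is used rather than ppm because the N/C
    isotopologue spacing is a fixed ~6.3 mDa across the reporter range.

    Raises
    ------
    ValueError
        If ``tol_mda`` is not positive, no channels are given, or the
        tolerance reaches the minimum adjacent reporter spacing (at which
        point nearest-channel assignment itself can tie).
    """
    if tol_mda <= 0:
        raise ValueError("tol_mda must be > 0")
    if not channels:
        raise ValueError("no channels configured")
    if len(channels) > 1:
        mzs_sorted = sorted(c.reporter_mz for c in channels)
        spacing = min(b - a for a, b in zip(mzs_sorted, mzs_sorted[1:])) * 1000.0
        if tol_mda >= spacing:
            raise ValueError(
                f"tolerance {tol_mda} mDa >= minimum reporter spacing "
                f"{spacing:.2f} mDa: channel assignment would be ambiguous"
            )
    tol = tol_mda * 1e-3
    ch_mz = np.array([c.reporter_mz for c in channels])
    best: dict[str, float] = {c.name: 0.0 for c in channels}
    for mz, intensity in scan.peaks:
        j = int(np.argmin(np.abs(ch_mz - mz)))
        if abs(ch_mz[j] - mz) <= tol:
            name = channels[j].name
            if intensity > best[name]:
                best[name] = intensity
    return ReporterReading(scan.scan_id, scan.rt, best)


def _fwhm_interpolated(rts: np.ndarray, ys: np.ndarray) -> float | None:
    """FWHM by linear interpolation at half-maximum on both flanks."""
    k = int(np.argmax(ys))
    half = ys[k] / 2.0
    if ys[k] <= 0:
        return None
    left = None
    for i in range(k, 0, -1):
        if ys[i - 1] < half <= ys[i]:
            frac = (half - ys[i - 1]) / (ys[i] - ys[i - 1])
            left = rts[i - 1] + frac * (rts[i] - rts[i - 1])
            break
    right = None
    for i in range(k, len(ys) - 1):
        if ys[i + 1] < half <= ys[i]:
            frac = (ys[i] - half) / (ys[i] - ys[i + 1])
            right = rts[i] + frac * (rts[i + 1] - rts[i])
            break
    if left is None or right is None:
        return None
    return right - left


def build_eic(
    scans: list[Ms2Scan],
    target_id: str,
    channel: str,
    channels: tuple[Channel, ...] = CHANNELS,
    tol_mda: float = 5.0,
) -> Eic:
    """Assemble the reporter EIC of one channel across a target's scans.

    Only scans whose ``target_id`` matches contribute; points are ordered by
    RT.  An all-zero trace yields an Eic with area 0 and ``fwhm`` flagged
    ``None`` rather than an exception.
    """
    mine = sorted((s for s in scans if s.target_id == target_id), key=lambda s: s.rt)
    if not mine:
        raise ValueError(f"no scans for target {target_id!r}")
    pts = []
    for s in mine:
        reading = extract_reporters(s, channels, tol_mda)
        pts.append((s.rt, reading.intensities[channel]))
    return eic_from_points(target_id, channel, pts)


def eic_from_points(
    target_id: str, channel: str, pts: list[tuple[float, float]]
) -> Eic:
    """Build an Eic (apex, FWHM, full-trace area) from an RT-ordered trace."""
    rts = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    area = float(np.trapezoid(ys, rts)) if len(pts) > 1 else 0.0
    if np.all(ys == 0):
        return Eic(target_id, channel, pts, apex_rt=None, apex_intensity=0.0,
                   fwhm=None, area=0.0)
    k = int(np.argmax(ys))
    fwhm = _fwhm_interpolated(rts, ys)
    return Eic(target_id, channel, pts, apex_rt=float(rts[k]),
               apex_intensity=float(ys[k]), fwhm=fwhm, area=area)


def integrate_eic(eic: Eic, window: tuple[float, float]) -> float:
    """Trapezoidal integral of the trace restricted to ``window`` (intensity·min).

    Window edges falling between samples are handled by linear interpolation,
    which makes integration exactly additive over adjacent windows.
    """
    lo, hi = window
    if hi < lo:
        raise ValueError(f"inverted integration window {window}")
    span = eic.rt_span
    if lo < span[0] or hi > span[1]:
        raise ValueError(f"window {window} outside trace span {span}")
    if hi == lo:
        return 0.0
    rts = np.array([p[0] for p in eic.points])
    ys = np.array([p[1] for p in eic.points])
    inside = (rts > lo) & (rts < hi)
    xs = np.concatenate(([lo], rts[inside], [hi]))
    vals = np.concatenate(
        ([np.interp(lo, rts, ys)], ys[inside], [np.interp(hi, rts, ys)])
    )
    return float(np.trapezoid(vals, xs))


def estimate_noise(eic: Eic, peak_free_window: tuple[float, float]) -> NoiseEstimate:
    """Noise as the sample SD of intensities in a peak-free RT window.

    The window must be disjoint from the peak region (apex ± 2·FWHM) and
    contain at least 5 trace points.
    """
    lo, hi = peak_free_window
    if hi <= lo:
        raise ValueError(f"invalid noise window {peak_free_window}")
    if eic.apex_rt is not None and eic.fwhm is not None:
        peak_lo = eic.apex_rt - 2 * eic.fwhm
        peak_hi = eic.apex_rt + 2 * eic.fwhm
        if lo < peak_hi and hi > peak_lo:
            raise ValueError(
                f"noise window {peak_free_window} overlaps peak region "
                f"({peak_lo:.3f}, {peak_hi:.3f})"
            )
    ys = [y for rt, y in eic.points if lo <= rt <= hi]
    if len(ys) < 5:
        raise ValueError(f"noise window contains {len(ys)} points; >=5 required")
    sd = float(np.std(ys, ddof=1))
    return NoiseEstimate(eic.channel, peak_free_window, sd, len(ys))


def resolution(eic1: Eic, eic2: Eic) -> float:
    """Chromatographic peak resolution Rs = 1.18·|Δapex| / (FWHM₁ + FWHM₂)."""
    for e in (eic1, eic2):
        if e.fwhm is None or e.apex_rt is None:
            raise ValueError(f"EIC for {e.target_id}/{e.channel} has undefined FWHM")
    return 1.18 * abs(eic2.apex_rt - eic1.apex_rt) / (eic1.fwhm + eic2.fwhm)
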