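"""Azimuthal-scan ingestion, peak detection, indexing and asymmetry reading.

The experimental input is a Renninger scan: intensity of the reference
reflection versus azimuth Φ.  The processing chain is

    read_scan → detect_peaks → correct_offset → index_peaks → fit_profile
    → read_asymmetry

Each isolated MD peak is fitted, on log-transformed intensities, with a
Gaussian on a sloping baseline

    log10 I(Φ) = A exp(−(Φ−Φ0)²/2σ²) + a + b (Φ−Φ0).

The baseline slope ``b`` is the asymmetry readout: b < 0 means the left
shoulder is higher (HL), b > 0 means LH.  The relative uncertainty σ_b/|b|
is the reliability; observations above a configurable cutoff (default 50%)
are rejected.  Aufhellung dips are detected but never asymmetry-read.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Model
from scipy.ndimage import median_filter
from scipy.signal import find_peaks, peak_widths

from .sfactor import AsymmetryLabel
from . import mdgeom

__all__ = [
    "AzimuthalScan",
    "PeakRecord",
    "ProfileFit",
    "AsymmetryObservation",
    "OffsetResult",
    "ScanParseError",
    "read_scan",
    "detect_peaks",
    "correct_offset",
    "index_peaks",
    "fit_profile",
    "read_asymmetry",
    "read_scan_asymmetries",
]

#: default peak-to-event matching tolerance, degrees
MATCH_TOL = 0.3

#: default reliability cutoff, fraction
RELIABILITY_CUTOFF = 0.5

#: counts floor applied before the log transform
COUNTS_FLOOR = 0.5


class ScanParseError(ValueError):
    pass


@dataclass
class AzimuthalScan:
    """A measured (or synthetic) azimuthal scan."""

    phi: np.ndarray        # degrees, strictly increasing
    counts: np.ndarray     # non-negative intensities
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.phi.shape != self.counts.shape or self.phi.ndim != 1:
            raise ValueError("phi and counts must be 1-D arrays of equal length")
        if np.any(np.diff(self.phi) <= 0):
            raise ValueError("phi must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.phi) < 50:
            warnings.warn(f"scan has only {len(self.phi)} samples", stacklevel=2)

    @property
    def step(self) -> float:
        return float(np.median(np.diff(self.phi)))


@dataclass
class PeakRecord:
    """One detected peak (or Aufhellung dip) and its fitting window."""

    phi0: float
    window: tuple          # (phi_lo, phi_hi)
    prominence: float
    is_dip: bool = False
    assigned_events: list = field(default_factory=list)
    overlap: bool = False


@dataclass
class ProfileFit:
    """Log-Gaussian + sloping-baseline fit of one MD peak."""

    amplitude: float
    center: float          # degrees
    width: float           # Gaussian sigma, degrees
    a: float               # baseline intercept (log10 counts)
    b: float               # baseline slope per degree of log10 intensity
    b_stderr: float
    success: bool
    n_points: int = 0
    n_floored: int = 0

    @property
    def label(self) -> AsymmetryLabel:
        if not self.success or self.b == 0.0:
            return AsymmetryLabel.INDETERMINATE
        return AsymmetryLabel.HL if self.b < 0 else AsymmetryLabel.LH

    @property
    def reliability(self) -> float:
        """σ_b / |b| as a fraction (inf for b = 0 or failed fits)."""
        if not self.success or self.b == 0.0:
            return math.inf
        return self.b_stderr / abs(self.b)


@dataclass
class AsymmetryObservation:
    """One asymmetry reading, ready for model comparison."""

    H: tuple | None
    g: int | None
    phi_obs: float
    b: float
    sigma_b: float
    label: AsymmetryLabel
    reliability: float
    accepted: bool
    flags: set = field(default_factory=set)


@dataclass
class OffsetResult:
    offset: float
    n_matched: int
    period: float
    ambiguous: bool = False
    alternatives: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

def read_scan(path: str, meta: dict | None = None) -> AzimuthalScan:
    """Read a two-column (azimuth deg, counts) text scan.

    Whitespace- or comma-delimited; ``#`` starts a comment.  Non-monotone
    azimuths are sorted and exact duplicates averaged, each with a warning.
    """
    phis, counts = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.replace(",", " ").split()
            if len(parts) < 2:
                raise ScanParseError(f"{path}:{ln}: expected at least 2 columns")
            try:
                phis.append(float(parts[0]))
                counts.append(float(parts[1]))
            except ValueError as exc:
                raise ScanParseError(f"{path}:{ln}: non-numeric data") from exc
    if not phis:
        raise ScanParseError(f"{path}: empty scan")
    phi = np.array(phis)
    cts = np.array(counts)
    if np.any(np.diff(phi) < 0):
        warnings.warn(f"{path}: azimuths not monotone; sorting", stacklevel=2)
        order = np.argsort(phi, kind="stable")
        phi, cts = phi[order], cts[order]
    if np.any(np.diff(phi) == 0):
        warnings.warn(f"{path}: duplicate azimuths averaged", stacklevel=2)
        uniq, inv = np.unique(phi, return_inverse=True)
        summed = np.bincount(inv, weights=cts)
        n = np.bincount(inv)
        phi, cts = uniq, summed / n
    return AzimuthalScan(phi=phi, counts=cts, meta=dict(meta or {}))


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

def detect_peaks(scan: AzimuthalScan, min_prominence: float,
                 min_separation: float = 0.3, include_dips: bool = False,
                 baseline_window: float = 1.0,
                 max_half_width: float = 2.0,
                 max_fwhm: float = 1.0) -> list[PeakRecord]:
    """Find local maxima (and optionally Aufhellung dips) above the baseline.

    The baseline is a rolling median over ``baseline_window`` degrees; peaks
    must exceed ``min_prominence`` counts over it.  Fitting windows extend to
    ± max(3 × FWHM estimate, min_separation), capped at ``max_half_width``;
    records whose windows intersect (in particular any two peaks closer than
    ``min_separation``) are flagged as overlapping.

    An asymmetric MD profile has genuine secondary extrema — its shoulders.
    A maximum at least twice less prominent than a peak whose window contains
    it is absorbed into that peak, and minima inside a maximum's window are
    never reported as Aufhellung dips.
    """
    step = scan.step
    size = max(3, int(round(baseline_window / step)) | 1)
    baseline = median_filter(scan.counts, size=size, mode="nearest")
    resid = scan.counts - baseline

    records = []
    for sign, is_dip in ((1.0, False),) + (((-1.0, True),) if include_dips else ()):
        # dips must genuinely fall below the baseline; without the height
        # constraint any flat stretch between two strong peaks would count
        kw = {"height": min_prominence} if is_dip else {}
        idx, props = find_peaks(sign * resid, prominence=min_prominence,
                                distance=5, **kw)
        if len(idx) == 0:
            continue
        widths = peak_widths(sign * resid, idx, rel_height=0.5)[0] * step
        for i, w, prom in zip(idx, widths, props["prominences"]):
            if w > max_fwhm:
                # slow baseline undulation, not an MD line
                continue
            half = min(max(3.0 * w, min_separation), max_half_width)
            records.append(PeakRecord(
                phi0=float(scan.phi[i]),
                window=(float(scan.phi[i] - half), float(scan.phi[i] + half)),
                prominence=float(prom), is_dip=is_dip))
    maxima = [r for r in records if not r.is_dip]

    def absorbed(r):
        return any(m is not r and m.prominence >= 2.0 * r.prominence
                   and m.window[0] <= r.phi0 <= m.window[1] for m in maxima)

    records = [r for r in records if not (
        (r.is_dip and any(m.window[0] <= r.phi0 <= m.window[1] for m in maxima))
        or (not r.is_dip and absorbed(r)))]
    records.sort(key=lambda r: r.phi0)
    for r1, r2 in zip(records, records[1:]):
        if r2.window[0] < r1.window[1]:
            r1.overlap = r2.overlap = True
    return records


# ---------------------------------------------------------------------------
# offset correction and indexing
# ---------------------------------------------------------------------------

def _match_count(peak_phis, event_phis, offset, tol):
    n = 0
    for p in peak_phis:
        d = np.min(np.abs((event_phis + offset - p + 180.0) % 360.0 - 180.0))
        if d <= tol:
            n += 1
    return n


def correct_offset(peaks, predicted_events, search_range: float = 30.0,
                   match_tol: float = MATCH_TOL, grid_step: float = 0.05) -> OffsetResult:
    """Azimuth offset maximizing peak–event matches.

    Scans offsets over ± ``search_range`` on a coarse grid, then refines the
    best offset as the mean matched residual.  Offsets are equivalent modulo
    the period of the predicted event pattern (reported in ``period``); an
    optimum tied within one match by a non-equivalent offset sets the
    ``ambiguous`` flag and lists the alternatives.
    """
    if len(peaks) < 3 or len(predicted_events) < 3:
        raise ValueError("need at least 3 peaks and 3 predicted events")
    peak_phis = np.array([p.phi0 for p in peaks])
    event_phis = np.array([ev.phi for ev in predicted_events])
    period = mdgeom.scan_period(predicted_events, tol=max(grid_step / 4, 1e-3))

    offsets = np.arange(-search_range, search_range + grid_step / 2, grid_step)
    counts = np.array([_match_count(peak_phis, event_phis, o, match_tol)
                       for o in offsets])
    best = int(np.argmax(counts))

    def refine(off0):
        # mean of nearest residual per matched peak
        d = (peak_phis[:, None] - (event_phis[None, :] + off0) + 180.0) % 360.0 - 180.0
        res = []
        for row in d:
            j = np.argmin(np.abs(row))
            if abs(row[j]) <= match_tol:
                res.append(row[j])
        return off0 + float(np.mean(res)) if res else off0

    best_off = refine(float(offsets[best]))
    n_best = _match_count(peak_phis, event_phis, best_off, match_tol)

    alts = []
    for o, c in zip(offsets, counts):
        if c >= counts[best] - 1:
            oo = refine(float(o))
            if _period_distinct(oo, best_off, period, 2 * match_tol) and \
                    all(_period_distinct(oo, a, period, 2 * match_tol) for a in alts):
                alts.append(oo)
    canonical = (best_off + period / 2.0) % period - period / 2.0
    return OffsetResult(offset=canonical, n_matched=n_best, period=period,
                        ambiguous=bool(alts), alternatives=alts)


def _period_distinct(o1, o2, period, tol):
    d = abs((o1 - o2 + period / 2.0) % period - period / 2.0)
    return d > tol


def index_peaks(peaks, events, tol_phi: float = MATCH_TOL,
                offset: float = 0.0) -> tuple[list, list]:
    """Assign each peak the events within ``tol_phi`` of its centre.

    ``offset`` is added to the predicted azimuths first (apply the value from
    :func:`correct_offset`).  Peaks with more than one candidate event are
    flagged as overlapping; peaks with none are returned separately.
    """
    unassigned = []
    for pk in peaks:
        pk.assigned_events = []
        for ev in events:
            d = abs((ev.phi + offset - pk.phi0 + 180.0) % 360.0 - 180.0)
            if d <= tol_phi:
                pk.assigned_events.append(ev)
        if len(pk.assigned_events) > 1:
            pk.overlap = True
        elif not pk.assigned_events:
            unassigned.append(pk)
    return [p for p in peaks if p.assigned_events], unassigned


# ---------------------------------------------------------------------------
# profile fitting and asymmetry reading
# ---------------------------------------------------------------------------

def _profile(x, amplitude, center, sigma, a, b):
    return amplitude * np.exp(-((x - center) ** 2) / (2 * sigma ** 2)) \
        + a + b * (x - center)


_PROFILE_MODEL = Model(_profile)


def fit_profile(scan: AzimuthalScan, window, center_hint: float | None = None,
                max_floored_fraction: float = 0.2,
                refine_window: bool = True) -> ProfileFit:
    """Fit log10(counts) in ``window`` with a Gaussian + sloping baseline.

    Zero/negative counts are floored at 0.5 before the log transform; windows
    with more than 20% floored points are rejected.  The window is re-centred
    once to ±5σ of the first fit.  The slope standard error comes from the
    fit covariance; a missing covariance marks the fit as failed.
    """
    lo, hi = window
    mask = (scan.phi >= lo) & (scan.phi <= hi)
    x = scan.phi[mask]
    y_raw = scan.counts[mask]
    if len(x) < 8:
        return ProfileFit(0, np.nan, np.nan, np.nan, np.nan, np.nan,
                          success=False, n_points=len(x))
    floored = y_raw < COUNTS_FLOOR
    if floored.mean() > max_floored_fraction:
        return ProfileFit(0, np.nan, np.nan, np.nan, np.nan, np.nan,
                          success=False, n_points=len(x), n_floored=int(floored.sum()))
    if floored.any():
        warnings.warn("zero/negative counts floored at 0.5 before log transform",
                      stacklevel=2)
    y = np.log10(np.maximum(y_raw, COUNTS_FLOOR))

    def run(x, y, counts):
        med = float(np.median(y))
        c0 = center_hint if center_hint is not None and x[0] <= center_hint <= x[-1] \
            else float(x[np.argmax(y)])
        amp0 = float(np.max(y) - med)
        sig0 = max((x[-1] - x[0]) / 10.0, 2 * scan.step)
        params = _PROFILE_MODEL.make_params(
            amplitude=dict(value=max(amp0, 1e-3)),
            center=dict(value=c0, min=x[0], max=x[-1]),
            sigma=dict(value=sig0, min=scan.step / 2, max=(x[-1] - x[0])),
            a=dict(value=med), b=dict(value=0.0))
        # counting statistics: sigma(log10 I) = 1 / (sqrt(I) ln 10)
        weights = math.log(10.0) * np.sqrt(np.maximum(counts, COUNTS_FLOOR))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return _PROFILE_MODEL.fit(y, params, x=x, weights=weights)

    def has_errorbars(r):
        e = r.params["b"].stderr
        return r.success and e is not None and np.isfinite(e)

    try:
        res = run(x, y, y_raw)
        if refine_window:
            sig = float(res.params["sigma"].value)
            c = float(res.params["center"].value)
            m2 = (scan.phi >= c - 5 * sig) & (scan.phi <= c + 5 * sig)
            if m2.sum() >= 8:
                x2 = scan.phi[m2]
                y2 = np.log10(np.maximum(scan.counts[m2], COUNTS_FLOOR))
                res2 = run(x2, y2, scan.counts[m2])
                # keep the wide-window fit if the refined one loses its
                # covariance (degenerate restart at the optimum)
                if has_errorbars(res2) or not has_errorbars(res):
                    res, x = res2, x2
    except Exception:
        return ProfileFit(0, np.nan, np.nan, np.nan, np.nan, np.nan,
                          success=False, n_points=len(x))
    bpar = res.params["b"]
    ok = has_errorbars(res)
    return ProfileFit(
        amplitude=float(res.params["amplitude"].value),
        center=float(res.params["center"].value),
        width=float(res.params["sigma"].value),
        a=float(res.params["a"].value),
        b=float(bpar.value),
        b_stderr=float(bpar.stderr) if ok else np.nan,
        success=bool(ok), n_points=len(x), n_floored=int(floored.sum()))


def read_asymmetry(fit: ProfileFit, cutoff: float = RELIABILITY_CUTOFF,
                   phi_obs: float | None = None) -> AsymmetryObservation:
    """Turn a successful profile fit into an asymmetry observation.

    Label from sign(b) (negative → HL, positive → LH); the observation is
    rejected when the reliability σ_b/|b| exceeds ``cutoff``.
    """
    if not fit.success:
        raise ValueError("cannot read asymmetry from a failed fit")
    rel = fit.reliability
    label = fit.label
    return AsymmetryObservation(
        H=None, g=None,
        phi_obs=fit.center if phi_obs is None else phi_obs,
        b=fit.b, sigma_b=fit.b_stderr, label=label,
        reliability=rel,
        accepted=bool(label is not AsymmetryLabel.INDETERMINATE and rel <= cutoff))


# ---------------------------------------------------------------------------
# pipeline convenience
# ---------------------------------------------------------------------------

def read_scan_asymmetries(scan: AzimuthalScan, events, min_prominence: float,
                          min_separation: float = 0.3,
                          tol_phi: float = MATCH_TOL,
                          cutoff: float = RELIABILITY_CUTOFF,
                          search_range: float = 30.0,
                          known_offset: float | None = None) -> dict:
    """Full chain: detect → correct offset → index → fit → read.

    Returns {"observations": [...], "offset": OffsetResult | float,
    "peaks": [...], "unassigned": [...]}.  Overlapped peaks and dips are never
    asymmetry-read; multi-event peaks are flagged and skipped.
    """
    peaks = detect_peaks(scan, min_prominence, min_separation, include_dips=True)
    if known_offset is None:
        off = correct_offset([p for p in peaks if not p.is_dip], events,
                             search_range=search_range, match_tol=tol_phi)
        offset = off.offset
    else:
        off = float(known_offset)
        offset = off
    indexed, unassigned = index_peaks(peaks, events, tol_phi=tol_phi, offset=offset)
    observations = []
    for pk in indexed:
        if pk.overlap or pk.is_dip:
            continue
        ev = pk.assigned_events[0]
        if "DIP" in ev.flags or ev.g not in (-1, 1):
            continue
        fit = fit_profile(scan, pk.window, center_hint=pk.phi0)
        if not fit.success:
            continue
        obs = read_asymmetry(fit, cutoff=cutoff)
        obs.H = ev.H
        obs.g = ev.g
        observations.append(obs)
    return {"observations": observations, "offset": off,
            "peaks": peaks, "unassigned": unassigned}
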