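"""Renninger-scan geometry: MD event azimuths, excitation geometry g,
minimum excitation energies, Bragg-cone lines and pattern symmetry.

During an azimuthal (Renninger) scan the crystal rotates about the
diffraction vector G* of the reference reflection, which is kept on its Bragg
condition.  A secondary reciprocal-lattice point H* crosses the Ewald sphere
twice per revolution: entering (g = −1) and exiting (g = +1), under the
clockwise-positive rotation convention with G* toward the observer.

Writing H* = H∥ ĝ + H⊥ and the incident wavevector k0 = k∥ ĝ + k⊥ û(Φ) with
k∥ = −|G*|/2 and k⊥ = (1/λ² − |G*|²/4)^{1/2}, the crossing condition
|k0 + H*| = 1/λ reduces to

    cos(Φ − φ_H) = −( |H*|²/2 + k∥ H∥ ) / ( k⊥ |H⊥| )  ≡  rhs,

with φ_H the azimuth of H⊥.  Two solutions exist when |rhs| < 1, one tangent
crossing when |rhs| = 1, none otherwise.  The azimuth origin Φ = 0 is where
the chosen reference lattice direction's in-plane projection points upstream
(toward the source), matching the standard experimental convention.

The crystal Cartesian frame is the standard reciprocal setting (a* along x,
b* in the x–y plane); this is the single fixed convention of the package.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from ._data import HC_KEV_ANGSTROM
from .crystal import CrystalModel, UnitCell, energy_to_wavelength

__all__ = [
    "ScanGeometry",
    "MDEvent",
    "BCLine",
    "CrossingSet",
    "event_azimuths",
    "enumerate_events",
    "minimum_energy",
    "bc_line",
    "find_systematic",
    "mirror_positions",
    "scan_period",
    "track_energy",
    "coincidence_energy",
]

#: |rhs| within this of 1 counts as a tangent (grazing) crossing.
TANGENT_TOL = 1e-8


@dataclass(frozen=True)
class ScanGeometry:
    """Azimuthal-scan configuration.

    ``reference_direction`` is a real-space lattice direction [uvw]; Φ = 0 is
    the azimuth at which its projection onto the scan plane points upstream.
    ``clockwise_positive`` fixes the rotation sense (clockwise, viewed with
    G* toward the observer, is the positive sense by default).
    """

    G: tuple
    E: float                       # keV
    reference_direction: tuple = (1, 0, 0)
    clockwise_positive: bool = True

    def with_energy(self, E_keV: float) -> "ScanGeometry":
        return ScanGeometry(self.G, E_keV, self.reference_direction,
                            self.clockwise_positive)


@dataclass
class MDEvent:
    """One Ewald-sphere crossing of a secondary reflection."""

    H: tuple
    GH: tuple
    phi: float                     # degrees in [0, 360)
    g: int                         # −1 entering, +1 exiting, 0 tangent
    E_min: float                   # keV
    psi: float = float("nan")      # filled by sfactor.annotate_events
    predicted: object = None       # AsymmetryLabel
    W: float = float("nan")        # |F_H F_{G−H}|
    flags: set = field(default_factory=set)


@dataclass
class BCLine:
    """Sampled Bragg-cone line ω(Φ) of one reflection, split into its two
    solution branches; each branch may carry the g value of its crossing
    with the reference line ω = θ_G."""

    H: tuple
    branches: list                 # [{"g": int|None, "points": [(phi, omega)]}]


@dataclass
class CrossingSet:
    """Solutions of the azimuthal crossing equation for one H."""

    solutions: list                # [(phi_deg, g)]
    axial: bool = False            # H parallel to G: no azimuthal solution
    tangent: bool = False

    def __iter__(self):
        return iter(self.solutions)

    def __len__(self):
        return len(self.solutions)


# ---------------------------------------------------------------------------
# frames
# ---------------------------------------------------------------------------

def _frame(geom: ScanGeometry, cell: UnitCell):
    """(ĝ, ê1, ê2, k∥, k⊥, λ); ê1 is the beam's in-plane direction at Φ = 0."""
    lam = energy_to_wavelength(geom.E)
    qG = cell.qvec(geom.G)
    qGn = np.linalg.norm(qG)
    if qGn == 0:
        raise ValueError("reference reflection G must be non-zero")
    if lam * qGn / 2.0 > 1.0:
        raise ValueError(
            f"G = {tuple(geom.G)} not excitable at {geom.E} keV (sin theta > 1)")
    ghat = qG / qGn
    r = cell.direction(geom.reference_direction)
    rperp = r - (r @ ghat) * ghat
    if np.linalg.norm(rperp) < 1e-12 * np.linalg.norm(r):
        raise ValueError("reference_direction is parallel to G*")
    e1 = -rperp / np.linalg.norm(rperp)          # upstream at Phi = 0
    e2 = np.cross(ghat, e1)
    if not geom.clockwise_positive:
        e2 = -e2
    kpar = -qGn / 2.0
    kperp = math.sqrt(max(1.0 / lam**2 - qGn**2 / 4.0, 0.0))
    return ghat, e1, e2, kpar, kperp, lam


def _decompose(cell: UnitCell, H, ghat, e1, e2):
    qH = cell.qvec(H)
    Hpar = float(qH @ ghat)
    Hperp = qH - Hpar * ghat
    Hperp_n = float(np.linalg.norm(Hperp))
    phiH = math.degrees(math.atan2(float(Hperp @ e2), float(Hperp @ e1)))
    return qH, Hpar, Hperp_n, phiH


# ---------------------------------------------------------------------------
# crossings
# ---------------------------------------------------------------------------

def event_azimuths(geom: ScanGeometry, cell: UnitCell, H,
                   tangent_tol: float = TANGENT_TOL) -> CrossingSet:
    """Azimuth(s) and geometry g at which H crosses the Ewald sphere.

    Returns a :class:`CrossingSet`: two (Φ, g) pairs for a regular crossing
    (g = −1 on the entering branch Φ = φ_H + A, g = +1 on the exiting branch
    Φ = φ_H − A, A = arccos(rhs)), a single (Φ, 0) pair flagged tangent when
    |rhs| = 1 within ``tangent_tol``, or none.  H parallel to G is the axial
    case: excited at every azimuth whenever excitable, no azimuthal solution.
    """
    H = tuple(int(v) for v in H)
    if H == (0, 0, 0) or H == tuple(int(v) for v in geom.G):
        raise ValueError("H must differ from 0 and from G")
    ghat, e1, e2, kpar, kperp, lam = _frame(geom, cell)
    qH, Hpar, Hperp_n, phiH = _decompose(cell, H, ghat, e1, e2)
    qH2 = float(qH @ qH)
    if Hperp_n < 1e-12 * math.sqrt(qH2):
        return CrossingSet(solutions=[], axial=True)
    rhs = -(qH2 / 2.0 + kpar * Hpar) / (kperp * Hperp_n)
    if abs(rhs) > 1.0 + tangent_tol:
        return CrossingSet(solutions=[])
    if abs(abs(rhs) - 1.0) <= tangent_tol:
        A = 0.0 if rhs > 0 else 180.0
        return CrossingSet(solutions=[((phiH + A) % 360.0, 0)], tangent=True)
    A = math.degrees(math.acos(rhs))
    return CrossingSet(solutions=[((phiH - A) % 360.0, +1),
                                  ((phiH + A) % 360.0, -1)])


def minimum_energy(cell: UnitCell, G, H) -> float:
    """Lowest X-ray energy (keV) at which the MD event of H can occur.

    At E_min the two azimuthal solutions coalesce (|rhs| = 1); slightly above
    it they separate as O(ΔE^{1/2}).  For H parallel to G (axial case) there
    is no azimuthal crossing and +inf is returned.
    """
    qG = cell.qvec(G)
    qGn = float(np.linalg.norm(qG))
    ghat = qG / qGn
    qH = cell.qvec(H)
    Hpar = float(qH @ ghat)
    Hperp = float(np.linalg.norm(qH - Hpar * ghat))
    if Hperp < 1e-10 * np.linalg.norm(qH):
        return math.inf
    C = (float(qH @ qH) / 2.0 - qGn * Hpar / 2.0) / Hperp
    return HC_KEV_ANGSTROM * math.sqrt(C * C + qGn * qGn / 4.0)


def branch_azimuth(geom: ScanGeometry, cell: UnitCell, H, g: int,
                   E_keV: float | None = None) -> float | None:
    """Azimuth of the g = ±1 branch of H (degrees), or None if not excited."""
    g2 = geom if E_keV is None else geom.with_energy(E_keV)
    for phi, gg in event_azimuths(g2, cell, H):
        if gg == g:
            return phi
    return None


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def enumerate_events(geom: ScanGeometry, cell: UnitCell, q_max: float,
                     model: CrystalModel | None = None,
                     w_min: float = 1e-3) -> list[MDEvent]:
    """All MD events with |H*| ≤ q_max excitable at the scan energy.

    When a ``model`` is given, each event is annotated with its triplet phase,
    weight W = |F_H F_{G−H}| and predicted label, and events whose W falls
    below ``w_min`` (electrons², unobservable crossings of extinct
    reflections) are dropped.  Events are sorted by azimuth.
    """
    if q_max <= 0:
        raise ValueError("q_max must be positive")
    G = tuple(int(v) for v in geom.G)
    hmax = [int(math.floor(q_max * L)) + 1 for L in (cell.a, cell.b, cell.c)]
    events = []
    for h in range(-hmax[0], hmax[0] + 1):
        for k in range(-hmax[1], hmax[1] + 1):
            for l in range(-hmax[2], hmax[2] + 1):
                H = (h, k, l)
                if H == (0, 0, 0) or H == G or cell.q(H) > q_max:
                    continue
                xs = event_azimuths(geom, cell, H)
                if not len(xs):
                    continue
                emin = minimum_energy(cell, G, H)
                GH = tuple(g - hh for g, hh in zip(G, H))
                for phi, g in xs:
                    ev = MDEvent(H=H, GH=GH, phi=phi, g=g, E_min=emin)
                    if xs.tangent:
                        ev.flags.add("NEAR_TANGENT")
                    events.append(ev)
    if model is not None:
        from .sfactor import annotate_events
        annotate_events(model, G, geom.E, events)
        # keep Aufhellung dips (W ~ 0): they are observable as intensity dips
        events = [ev for ev in events if ev.W >= w_min or "DIP" in ev.flags]
    events.sort(key=lambda ev: ev.phi)
    # postcondition: every event satisfies the Ewald condition
    for ev in events:
        resid = ewald_residual(geom, cell, ev)
        if resid > 1e-9 / energy_to_wavelength(geom.E):
            raise AssertionError(f"Ewald residual {resid} too large for {ev.H}")
    return events


def ewald_residual(geom: ScanGeometry, cell: UnitCell, ev: MDEvent) -> float:
    """| |k0(Φ) + H*| − 1/λ | at the event azimuth (Å⁻¹)."""
    ghat, e1, e2, kpar, kperp, lam = _frame(geom, cell)
    phi = math.radians(ev.phi)
    k0 = kpar * ghat + kperp * (math.cos(phi) * e1 + math.sin(phi) * e2)
    return abs(float(np.linalg.norm(k0 + cell.qvec(ev.H))) - 1.0 / lam)


# ---------------------------------------------------------------------------
# Bragg-cone lines
# ---------------------------------------------------------------------------

def bc_line(geom: ScanGeometry, cell: UnitCell, H, phi_grid) -> BCLine:
    """Bragg-cone line ω(Φ) of H over ``phi_grid`` (degrees).

    ω is the incidence angle referred to the plane normal to G*, so the
    reference reflection's own BC line is the horizontal ω = θ_G.  At each Φ
    the beam direction is k̂0 = −sin ω ĝ + cos ω û(Φ) and ω solves the Bragg
    condition of H; azimuths without a solution in (0°, 90°) are omitted.
    Each branch is coloured with the g of its crossing of ω = θ_G, when the
    crossing exists on the sampled grid.
    """
    H = tuple(int(v) for v in H)
    ghat, e1, e2, kpar, kperp, lam = _frame(geom, cell)
    qG = cell.qvec(geom.G)
    theta_G = math.degrees(math.asin(lam * float(np.linalg.norm(qG)) / 2.0))
    qH, Hpar, Hperp_n, phiH = _decompose(cell, H, ghat, e1, e2)
    qH2 = float(qH @ qH)
    Rv = -lam * qH2 / 2.0

    branches = [{"g": None, "points": []}, {"g": None, "points": []}]
    for phi in phi_grid:
        Qc = Hperp_n * math.cos(math.radians(phi - phiH))
        M = math.hypot(Qc, Hpar)
        if M < 1e-15 or abs(Rv) > M:
            continue
        phi0 = math.atan2(-Hpar, Qc)
        acos = math.acos(Rv / M)
        for idx, om in enumerate((phi0 + acos, phi0 - acos)):
            om_deg = math.degrees(math.atan2(math.sin(om), math.cos(om)))
            if 0.0 < om_deg < 90.0:
                branches[idx]["points"].append((float(phi), om_deg))

    # colour each branch by the g of its omega = theta_G crossing
    crossings = {phi: g for phi, g in event_azimuths(geom, cell, H)} \
        if H != tuple(geom.G) else {}
    for br in branches:
        pts = br["points"]
        for (p1, o1), (p2, o2) in zip(pts, pts[1:]):
            if (o1 - theta_G) * (o2 - theta_G) <= 0 and abs(p2 - p1) < 5 * 360:
                pc = p1 + (p2 - p1) * (theta_G - o1) / ((o2 - o1) or 1e-30)
                if crossings:
                    g = min(crossings, key=lambda c: _circ_abs(c - pc))
                    if _circ_abs(g - pc) < 0.5:
                        br["g"] = crossings[g]
    return BCLine(H=H, branches=branches)


def _circ_abs(d: float) -> float:
    return abs((d + 180.0) % 360.0 - 180.0)


def _circ_signed(d: float) -> float:
    x = (d + 180.0) % 360.0 - 180.0
    return x if x != -180.0 else 180.0


# ---------------------------------------------------------------------------
# pattern analysis: systematic events, mirrors, period, energy tracking
# ---------------------------------------------------------------------------

def find_systematic(geom: ScanGeometry, cell: UnitCell, events,
                    tol_phi: float = 0.05,
                    test_energy: float | None = None) -> list[dict]:
    """Group co-azimuthal events; tag SYSTEMATIC vs COINCIDENTAL.

    A group of ≥2 events within ``tol_phi`` is SYSTEMATIC when its members
    remain co-azimuthal at a second test energy (default 2% above the scan
    energy), COINCIDENTAL otherwise.  Flags are added onto the events and the
    groups are returned as dicts {"kind", "phi", "events"}.
    """
    if not events:
        return []
    E2 = test_energy if test_energy is not None else geom.E * 1.02
    evs = sorted(events, key=lambda e: e.phi)
    groups, cur = [], [evs[0]]
    for ev in evs[1:]:
        if ev.phi - cur[-1].phi <= tol_phi:
            cur.append(ev)
        else:
            groups.append(cur)
            cur = [ev]
    groups.append(cur)
    # wrap-around: merge first and last group across 360
    if len(groups) > 1 and (360.0 - groups[-1][-1].phi + groups[0][0].phi) <= tol_phi:
        groups[0] = groups.pop() + groups[0]

    out = []
    gid = 0
    for grp in groups:
        if len(grp) < 2:
            continue
        phis2 = [branch_azimuth(geom, cell, ev.H, ev.g, E_keV=E2) for ev in grp]
        co2 = (all(p is not None for p in phis2) and
               max(_circ_abs(p - phis2[0]) for p in phis2) <= tol_phi)
        kind = "SYSTEMATIC" if co2 else "COINCIDENTAL"
        for ev in grp:
            ev.flags.add(f"{kind}:{gid}")
            ev.flags.add("OVERLAP")
        out.append({"kind": kind, "phi": float(np.mean([e.phi for e in grp])),
                    "events": grp})
        gid += 1
    return out


def _event_keys(events):
    """(phi, g, class) triples; the class collapses symmetry mates (same
    minimum energy ⇒ same |H*| and same projection on G).  Aufhellung dips
    are observationally symmetric, so their g is ignored (set to 0): the
    scan pattern period is that of the observable intensity profile."""
    return [(ev.phi, 0 if "DIP" in ev.flags else ev.g, round(ev.E_min, 6))
            for ev in events]


def _multiset_matches(keys, mapped, tol):
    """True when ``mapped`` is a per-element permutation of ``keys`` within
    ``tol`` degrees in azimuth (exact in g and class)."""
    buckets: dict = {}
    for phi, g, c in keys:
        buckets.setdefault((g, c), []).append(phi)
    for v in buckets.values():
        v.sort()
    for phi, g, c in mapped:
        lst = buckets.get((g, c))
        if not lst:
            return False
        i = bisect_left(lst, phi)
        best, besti = math.inf, None
        # nearest neighbours in sorted order plus the wrap-around ends
        for j in {max(i - 1, 0), min(i, len(lst) - 1), 0, len(lst) - 1}:
            d = _circ_abs(lst[j] - phi)
            if d < best:
                best, besti = d, j
        if best > tol:
            return False
        lst.pop(besti)
    return all(not v for v in buckets.values())


def mirror_positions(events, tol: float = 1e-3) -> list[float]:
    """Azimuths (degrees in [0, 360)) about which the event pattern is
    reflection-symmetric.

    Reflection about Φ_m maps an event (Φ, g) to (2Φ_m − Φ, −g) of the same
    symmetry class; a verified mirror map (defined modulo 180°) contributes
    the two positions Φ_m and Φ_m + 180.
    """
    if not events:
        return []
    keys = _event_keys(events)
    cands = set()
    phis = [k[0] for k in keys]
    p0 = phis[0]
    for p in phis:
        cands.add(round(((p0 + p) / 2.0) % 180.0, 6))
    verified = []
    for m in sorted(cands):
        if any(abs(m - v) < tol for v in verified):
            continue
        mapped = [(((2 * m - phi) % 360.0), -g, c) for phi, g, c in keys]
        if _multiset_matches(keys, mapped, tol):
            verified.append(m)
    out = sorted({v % 360.0 for v in verified} | {(v + 180.0) % 360.0 for v in verified})
    return out


def scan_period(events, tol: float = 1e-3) -> float:
    """Smallest angular period (degrees) under which the (Φ, g, class)
    multiset maps onto itself; 360 when the pattern has no sub-period."""
    if not events:
        return 360.0
    keys = _event_keys(events)
    phis = sorted(k[0] for k in keys)
    cands = sorted({round((p - phis[0]) % 360.0, 6) for p in phis} - {0.0})
    for p in cands:
        if p <= tol:
            continue
        if abs(360.0 / p - round(360.0 / p)) > 1e-6:
            continue
        mapped = [(((phi + p) % 360.0), g, c) for phi, g, c in keys]
        if _multiset_matches(keys, mapped, tol):
            return p
    return 360.0


def track_energy(events_E1, events_E2) -> dict:
    """Match events of two scans of the same G by (H, g) and report ΔΦ.

    Returns {"matched": [(ev1, ev2, dphi)], "unmatched_1": [...],
    "unmatched_2": [...]}; for non-tangent events of well-separated crossings
    the sign of ΔΦ follows the event's g when the secondary reciprocal point
    lies outside the sphere of diameter G* (the usual case; see docs).
    """
    index = {}
    for ev in events_E2:
        index.setdefault((ev.H, ev.g), []).append(ev)
    matched, un1 = [], []
    for ev in events_E1:
        lst = index.get((ev.H, ev.g))
        if lst:
            ev2 = min(lst, key=lambda e: _circ_abs(e.phi - ev.phi))
            lst.remove(ev2)
            matched.append((ev, ev2, _circ_signed(ev2.phi - ev.phi)))
        else:
            un1.append(ev)
    un2 = [e for lst in index.values() for e in lst]
    return {"matched": matched, "unmatched_1": un1, "unmatched_2": un2}


def coincidence_energy(cell: UnitCell, G, H1, H2, E_start: float,
                       window: float = 1.0, step: float = 0.001) -> float | None:
    """Nearest energy above ``E_start`` (keV) at which the azimuths of the
    nearest crossing branches of H1 and H2 coincide.

    The branch pair is the (g1, g2) combination closest in azimuth at
    ``E_start``; the azimuth difference is then driven to zero by bracketing
    at ``step`` keV resolution followed by root refinement.  Returns None if
    no coincidence occurs within ``window`` keV.
    """
    H1 = tuple(int(v) for v in H1)
    H2 = tuple(int(v) for v in H2)
    if H1 == H2:
        return E_start
    geom = ScanGeometry(G=tuple(G), E=E_start,
                        reference_direction=_any_reference(cell, G))

    x1 = event_azimuths(geom, cell, H1)
    x2 = event_azimuths(geom, cell, H2)
    if not len(x1) or not len(x2):
        raise ValueError("both H1 and H2 must be excitable at E_start")
    (g1, g2) = min(((gg1, gg2) for _, gg1 in x1 for _, gg2 in x2),
                   key=lambda p: _circ_abs(
                       dict((g, phi) for phi, g in x1)[p[0]]
                       - dict((g, phi) for phi, g in x2)[p[1]]))

    def diff(E):
        p1 = branch_azimuth(geom, cell, H1, g1, E_keV=E)
        p2 = branch_azimuth(geom, cell, H2, g2, E_keV=E)
        if p1 is None or p2 is None:
            return None
        return _circ_signed(p1 - p2)

    prev_e, prev_d = E_start, diff(E_start)
    e = E_start
    while e < E_start + window:
        e = min(e + step, E_start + window)
        d = diff(e)
        if d is None:
            break
        if prev_d is not None and (d == 0.0 or d * prev_d < 0):
            if d == 0.0:
                return e
            return float(brentq(lambda x: diff(x), prev_e, e, xtol=1e-9))
        prev_e, prev_d = e, d
    return None


def _any_reference(cell: UnitCell, G):
    """Some real-space direction not parallel to G* (for internal frames)."""
    qG = cell.qvec(G)
    for cand in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
        r = cell.direction(cand)
        c = np.cross(r, qG)
        if np.linalg.norm(c) > 1e-9 * np.linalg.norm(r) * np.linalg.norm(qG):
            return cand
    raise ValueError("degenerate cell")
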