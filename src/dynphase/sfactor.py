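"""Structure factors, triplet phases and the line-profile asymmetry rule.

The observable in a Renninger scan is the HL/LH asymmetry of each multiple
diffraction (MD) peak, which for profiles dominated by the second-order
dynamical term is fixed by the excitation geometry g = ±1 and the triplet
phase invariant

    Ψ = δ_H + δ_{G−H} − δ_G = arg( F_H F_{G−H} / F_G ),

with G the reference reflection, H the secondary and G−H the coupling
reflection.  The sign rule implemented here is

    HL  ⇔  g · cos Ψ > 0,      LH  ⇔  g · cos Ψ < 0,

with an INDETERMINATE band around |cos Ψ| = 0 where the asymmetry is not
readable.  Events where |F_G| ≫ |F_H F_{G−H}| are dominated by Aufhellung
(an intensity dip) and the rule is not trustworthy; :func:`aufhellung_flag`
classifies this regime.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .crystal import CrystalModel, UnitCell, energy_to_wavelength

__all__ = [
    "AsymmetryLabel",
    "ProfileRegime",
    "ReflectionAmplitude",
    "TripletPhase",
    "structure_factor",
    "triplet_phase",
    "predict_asymmetry",
    "phase_vs_energy",
    "compare_model_phases",
    "flip_events",
    "aufhellung_flag",
    "polarization_warning",
    "annotate_events",
    "circular_difference",
]

#: |F| below this (electrons) is treated as vanishing; configurable per call.
F_EPSILON = 1e-6

#: |cos Ψ| below this gives an INDETERMINATE asymmetry prediction.
COS_TOL = 0.05


class AsymmetryLabel(str, enum.Enum):
    HL = "HL"
    LH = "LH"
    INDETERMINATE = "INDETERMINATE"


class ProfileRegime(str, enum.Enum):
    DIP = "DIP"                  # Aufhellung-dominated: |F_G| >> |F_H F_GH|
    VALID_RULE = "VALID_RULE"    # |F_G| << |F_H F_GH|: asymmetry rule reliable
    NEUTRAL = "NEUTRAL"
    UNDEFINED = "UNDEFINED"      # both amplitudes vanish


@dataclass(frozen=True)
class ReflectionAmplitude:
    """Complex structure factor F = |F| e^{iδ} of one hkl at one energy."""

    hkl: tuple
    F: complex
    s: float          # sinθ/λ, Å⁻¹
    E: float          # keV

    @property
    def magnitude(self) -> float:
        return abs(self.F)

    @property
    def phase(self) -> float:
        """δ in degrees, branch (−180, 180]."""
        return _to_branch(math.degrees(np.angle(self.F)))


@dataclass(frozen=True)
class TripletPhase:
    """Triplet phase invariant of one MD event."""

    G: tuple
    H: tuple
    psi: float        # degrees in (−180, 180]; nan when undefined
    W: float          # |F_H F_{G−H}|, electrons²
    FG_mag: float     # |F_G|, electrons
    FH_mag: float = float("nan")   # |F_H|, electrons
    undefined: bool = False

    @property
    def GH(self) -> tuple:
        return tuple(int(g) - int(h) for g, h in zip(self.G, self.H))


def _to_branch(deg: float) -> float:
    """Map an angle in degrees onto (−180, 180]."""
    d = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if d == -180.0 else d


def circular_difference(d1: float, d2: float) -> float:
    """|d1 − d2| on the circle, reported in [0, 180] degrees."""
    return abs(_to_branch(d1 - d2))


# ---------------------------------------------------------------------------
# structure factors
# ---------------------------------------------------------------------------

def structure_factor(model: CrystalModel, hkl, E_keV: float) -> ReflectionAmplitude:
    """F(hkl, E) = Σ_sites Σ_components occ · f(s, E) · e^{−B s²} · e^{2πi h·r}."""
    hkl = tuple(int(v) for v in hkl)
    if hkl == (0, 0, 0):
        raise ValueError("hkl = (0,0,0) has no diffraction vector")
    s = model.cell.s(hkl)
    h = np.asarray(hkl, dtype=float)
    F = 0j
    for st in model.sites:
        geom = math.exp(-st.B * s * s) * np.exp(2j * math.pi * float(h @ np.asarray(st.frac)))
        F += st.effective_f(s, E_keV) * geom
    return ReflectionAmplitude(hkl=hkl, F=complex(F), s=s, E=E_keV)


def triplet_phase(model: CrystalModel, G, H, E_keV: float,
                  f_eps: float = F_EPSILON) -> TripletPhase:
    """Ψ = arg(F_H F_{G−H} / F_G) in degrees, branch (−180, 180].

    If any involved |F| is below ``f_eps`` the phase is undefined: ``psi`` is
    NaN and the ``undefined`` flag is set (no exception), so that downstream
    Aufhellung/flagging logic can still use W and |F_G|.
    """
    G = tuple(int(v) for v in G)
    H = tuple(int(v) for v in H)
    GH = tuple(g - h for g, h in zip(G, H))
    FG = structure_factor(model, G, E_keV)
    FH = structure_factor(model, H, E_keV)
    FGH = structure_factor(model, GH, E_keV)
    W = FH.magnitude * FGH.magnitude
    if min(FG.magnitude, FH.magnitude, FGH.magnitude) < f_eps:
        return TripletPhase(G=G, H=H, psi=float("nan"), W=W,
                            FG_mag=FG.magnitude, FH_mag=FH.magnitude,
                            undefined=True)
    psi = _to_branch(math.degrees(np.angle(FH.F * FGH.F / FG.F)))
    return TripletPhase(G=G, H=H, psi=psi, W=W, FG_mag=FG.magnitude,
                        FH_mag=FH.magnitude)


def predict_asymmetry(g: int, psi_deg: float, tol: float = COS_TOL) -> AsymmetryLabel:
    """Asymmetry label from the sign rule HL ⇔ g·cos Ψ > 0."""
    if g not in (-1, 1):
        raise ValueError("excitation geometry g must be -1 or +1")
    if psi_deg is None or math.isnan(psi_deg):
        return AsymmetryLabel.INDETERMINATE
    c = math.cos(math.radians(psi_deg))
    if abs(c) < tol:
        return AsymmetryLabel.INDETERMINATE
    return AsymmetryLabel.HL if g * c > 0 else AsymmetryLabel.LH


# ---------------------------------------------------------------------------
# phase scans and model comparison
# ---------------------------------------------------------------------------

def phase_vs_energy(model: CrystalModel, G, energies) -> list[tuple[float, float]]:
    """δ_G(E) over ``energies`` (keV), unwrapped continuously along the scan."""
    deltas = [structure_factor(model, G, e).phase for e in energies]
    unwrapped = np.unwrap(np.asarray(deltas, dtype=float), period=360.0)
    return list(zip([float(e) for e in energies], [float(d) for d in unwrapped]))


def _laue_rotations(model: CrystalModel) -> list[np.ndarray]:
    """Laue-group rotation parts acting on hkl (includes Friedel inversion)."""
    mats = {tuple(np.eye(3, dtype=int).ravel())}
    for op in model.symmetry_ops:
        # op.rot is scaled by Op.DEN; for hkl we need the transpose action
        r = (np.array(op.rot, dtype=float) / op.DEN).astype(int)
        mats.add(tuple(r.T.ravel()))
    out = []
    for m in list(mats):
        r = np.array(m, dtype=int).reshape(3, 3)
        out.append(r)
        out.append(-r)
    uniq = {tuple(r.ravel()) for r in out}
    return [np.array(u, dtype=int).reshape(3, 3) for u in uniq]


def independent_reflections(model: CrystalModel, q_max: float) -> list[tuple]:
    """Symmetry-independent hkl with 0 < Q ≤ q_max, one representative per
    Laue orbit (Friedel pairs always merged), sorted by Q."""
    cell = model.cell
    rots = _laue_rotations(model)
    hmax = [int(math.floor(q_max * L)) + 1 for L in (cell.a, cell.b, cell.c)]
    seen, reps = set(), []
    for h in range(-hmax[0], hmax[0] + 1):
        for k in range(-hmax[1], hmax[1] + 1):
            for l in range(-hmax[2], hmax[2] + 1):
                hkl = (h, k, l)
                if hkl == (0, 0, 0) or hkl in seen or cell.q(hkl) > q_max:
                    continue
                orbit = {tuple(int(x) for x in (R @ hkl)) for R in rots}
                seen |= orbit
                reps.append(max(orbit))
    reps.sort(key=cell.q)
    return reps


def compare_model_phases(modelA: CrystalModel, modelB: CrystalModel, E_keV: float,
                         q_max: float, threshold: float = 5.0) -> list[dict]:
    """Reflections whose phase differs between two models by more than
    ``threshold`` degrees (circular difference), sorted by Q.

    Returns one record per symmetry-independent hkl with keys
    ``hkl, Q, ddelta, F_A, F_B``.
    """
    if not modelA.cell.is_close(modelB.cell):
        raise ValueError("models must share the same unit cell")
    out = []
    for hkl in independent_reflections(modelA, q_max):
        fa = structure_factor(modelA, hkl, E_keV)
        fb = structure_factor(modelB, hkl, E_keV)
        if min(fa.magnitude, fb.magnitude) < F_EPSILON:
            continue
        dd = circular_difference(fa.phase, fb.phase)
        if dd > threshold:
            out.append({"hkl": hkl, "Q": modelA.cell.q(hkl), "ddelta": dd,
                        "F_A": fa.magnitude, "F_B": fb.magnitude})
    return out


def flip_events(modelA: CrystalModel, modelB: CrystalModel, G, E_keV: float,
                events) -> list[tuple]:
    """Events whose predicted asymmetry flips between two models.

    Returns (event, Ψ_A, Ψ_B, W) for the subset with cos Ψ_A · cos Ψ_B < 0;
    W is |F_H F_{G−H}| of model A.
    """
    out = []
    for ev in events:
        ta = triplet_phase(modelA, G, ev.H, E_keV)
        tb = triplet_phase(modelB, G, ev.H, E_keV)
        if ta.undefined or tb.undefined:
            continue
        ca = math.cos(math.radians(ta.psi))
        cb = math.cos(math.radians(tb.psi))
        if ca * cb < 0:
            out.append((ev, ta.psi, tb.psi, ta.W))
    return out


def aufhellung_flag(t: TripletPhase, ratio_threshold: float = 10.0) -> ProfileRegime:
    """Classify the MD profile regime from |F_G| versus W = |F_H F_{G−H}|.

    An extinct secondary (|F_H| ~ 0) diffracts nothing and produces no
    observable feature at all: UNDEFINED, not a dip.  A dip requires a
    diffracting secondary whose rescattering weight W is negligible against
    |F_G| (forbidden coupling, or |F_G| >> W).
    """
    if not math.isnan(t.FH_mag) and t.FH_mag < 1.0 and t.W < F_EPSILON:
        return ProfileRegime.UNDEFINED
    if t.W < F_EPSILON:
        return ProfileRegime.UNDEFINED if t.FG_mag < F_EPSILON else ProfileRegime.DIP
    ratio = t.FG_mag / t.W
    if ratio > ratio_threshold:
        return ProfileRegime.DIP
    if ratio < 1.0 / ratio_threshold:
        return ProfileRegime.VALID_RULE
    return ProfileRegime.NEUTRAL


def polarization_warning(cell: UnitCell, H, GH, E_keV: float,
                         tol: float = 2.0) -> dict:
    """Warn when θ_H or θ_{G−H} is within ``tol`` degrees of 45°.

    Near 45° the polarization factor suppresses the second-order term and the
    asymmetry rule can fail.  Returns a dict with the Bragg angles and flags
    ``warn`` / ``unreachable``.
    """
    lam = energy_to_wavelength(E_keV)
    out = {"theta_H": None, "theta_GH": None, "warn": False, "unreachable": False}
    for key, hkl in (("theta_H", H), ("theta_GH", GH)):
        x = lam * cell.q(hkl) / 2.0
        if x > 1.0:
            out["unreachable"] = True
            continue
        theta = math.degrees(math.asin(x))
        out[key] = theta
        if abs(theta - 45.0) <= tol:
            out["warn"] = True
    return out


def annotate_events(model: CrystalModel, G, E_keV: float, events,
                    cos_tol: float = COS_TOL,
                    aufhellung_ratio: float = 10.0):
    """Fill Ψ, predicted label, W and the DIP flag on a list of MD events.

    Events are duck-typed: they need mutable ``psi``, ``predicted``, ``W`` and
    a ``flags`` set, plus ``H`` and ``g`` (as produced by
    :func:`dynphase.mdgeom.enumerate_events`).  Returns the same list.
    """
    for ev in events:
        t = triplet_phase(model, G, ev.H, E_keV)
        ev.psi = t.psi
        ev.W = t.W
        regime = aufhellung_flag(t, ratio_threshold=aufhellung_ratio)
        if regime is ProfileRegime.DIP:
            ev.flags.add("DIP")
        if t.undefined or ev.g not in (-1, 1):
            ev.predicted = AsymmetryLabel.INDETERMINATE
        else:
            ev.predicted = predict_asymmetry(ev.g, t.psi, tol=cos_tol)
    return events
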