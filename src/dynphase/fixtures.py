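"""Synthetic azimuthal scans with known ground truth, and packaged toy models.

The scan generator renders each MD event as a multiplicative peak on a slowly
drifting baseline.  The line shape is phenomenological — a symmetric Gaussian
plus a Gaussian-derivative antisymmetric term — chosen only to realize the
correct asymmetry sense: the antisymmetric term carries the sign
−sign(g cos Ψ) scaled by |cos Ψ|, so events with g·cos Ψ > 0 come out with
the higher-then-lower (HL) shoulder order and a negative fitted baseline
slope.  It is *not* the dynamical-theory profile; see the methods note.

Aufhellung-flagged events are rendered as intensity dips and carry no
asymmetry.  Poisson noise is applied last, from a single explicitly seeded
generator (no global random state).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import crystal as _crystal
from .crystal import CrystalModel, UnitCell, add_bond_charges, neighbor_pairs, site, species
from .sfactor import AsymmetryLabel, predict_asymmetry
from .scan import AzimuthalScan

__all__ = ["SimulationConfig", "simulate_scan", "toy_structures",
           "SI_CELL_A", "SI_ATOM_B", "SI_BOND_B", "AMINO_LITERATURE_B"]

#: silicon conventional cell edge, Å
SI_CELL_A = 5.431
#: isotropic B of the silicon atomic sites, Å² (room-temperature value)
SI_ATOM_B = 0.4668
#: isotropic B of the bond-charge sites, Å²; smeared bond charge, calibrated
#: so the bond-charge model gives |F_222| = 6.5 e at 8 keV
SI_BOND_B = 3.726

#: per-site "literature" B factors (Å²) of the mock amino cell, used as the
#: z = 1 endpoint of B-factor interpolation
AMINO_LITERATURE_B = {"N": 2.0, "H1": 5.5, "H2": 4.0, "H3": 5.0, "O": 6.0}


@dataclass
class SimulationConfig:
    """Ground-truth description of a synthetic azimuthal scan.

    ``events`` need azimuth, g, Ψ and flags (as produced by
    ``mdgeom.enumerate_events`` + ``sfactor.annotate_events``); ``offset`` is
    added to every event azimuth, emulating an unknown sample azimuth.
    """

    events: list
    baseline_counts: float = 1000.0
    peak_height: float = 3.0        # peak factor above baseline, dimensionless
    # antisymmetric fraction; keep peak_height*asym_strength*e^{-1/2} < 1 so
    # the multiplicative profile stays positive on the lower-shoulder side
    asym_strength: float = 0.35
    asym_width: float = 3.0         # shoulder width, units of the core sigma
    fwhm: float = 0.12              # degrees
    offset: float = 0.0             # degrees
    dip_depth: float = 0.5
    drift_amplitude: float = 0.02   # relative slow baseline drift
    drift_period: float = 45.0      # degrees
    noise: bool = True
    seed: int = 0
    geom: object = None             # optional ScanGeometry bookkeeping


def simulate_scan(cfg: SimulationConfig, phi_grid) -> tuple[AzimuthalScan, pd.DataFrame]:
    """Render a synthetic scan and its ground-truth table.

    Returns (scan, truth); truth has one row per event with columns
    H, phi_true, g, psi, label, kind.  The noiseless curve is deterministic;
    Poisson noise is reproducible from ``cfg.seed``.
    """
    phi = np.asarray(phi_grid, dtype=float)
    sigma = cfg.fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    curve = np.ones_like(phi)
    rows = []
    for ev in cfg.events:
        center = ev.phi + cfg.offset
        u = (phi - center) / sigma
        gauss = np.exp(-0.5 * u * u)
        is_dip = "DIP" in ev.flags
        if is_dip:
            curve *= 1.0 - cfg.dip_depth * gauss
            label = AsymmetryLabel.INDETERMINATE
        else:
            cospsi = math.cos(math.radians(ev.psi)) if np.isfinite(ev.psi) else 0.0
            sgn = -np.sign(ev.g * cospsi)
            # extended shoulders: the asymmetry reaches several core widths
            # out, as in measured MD profiles
            v = u / cfg.asym_width
            asym = cfg.asym_strength * abs(cospsi) * sgn * v * np.exp(-0.5 * v * v)
            curve *= 1.0 + cfg.peak_height * (gauss + asym)
            label = predict_asymmetry(ev.g, ev.psi) if ev.g in (-1, 1) \
                else AsymmetryLabel.INDETERMINATE
        rows.append({"H": ev.H, "phi_true": center, "g": ev.g,
                     "psi": ev.psi, "label": label.value,
                     "kind": "dip" if is_dip else "peak"})
    drift = 1.0 + cfg.drift_amplitude * np.sin(2 * np.pi * phi / cfg.drift_period)
    expected = cfg.baseline_counts * drift * np.maximum(curve, 1e-9)
    if cfg.noise:
        rng = np.random.default_rng(cfg.seed)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    scan = AzimuthalScan(phi=phi, counts=counts,
                         meta={"offset_true": cfg.offset, "seed": cfg.seed})
    return scan, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# packaged toy structures
# ---------------------------------------------------------------------------

def _silicon_sites(sp, B):
    fcc = [(0, 0, 0), (0, .5, .5), (.5, 0, .5), (.5, .5, 0)]
    sites = []
    for i, t in enumerate(fcc):
        sites.append(site(f"SiA{i}", sp, t, B=B))
        sites.append(site(f"SiB{i}", sp, tuple((np.array(t) + 0.25) % 1.0), B=B))
    return tuple(sites)


def toy_structures() -> dict:
    """Named toy models used throughout the tests and examples.

    - ``si_spherical``: diamond silicon with neutral spherical Si atoms; the
      222 reflection is geometrically extinct (|F| = 0).
    - ``si_bond_charge``: Si⁴⁺ at the atomic sites plus one 2-electron charge
      (scattering as two hydrogens) at the midpoint of each of the 16 covalent
      bonds per cell; gives the non-zero 222 amplitude.
    - ``amino_mock``: a small orthorhombic P1 cell with an amino-like
      donor/acceptor group (N + 3 H) plus a carbonyl-like oxygen placed half a
      cell away from the nitrogen along a, so that odd-h reflections nearly
      cancel and their phases become genuinely susceptible to the transferred
      charge — the feature the (x, z) model grids need.
    """
    cell = UnitCell(SI_CELL_A, SI_CELL_A, SI_CELL_A)
    si_sph = CrystalModel(cell=cell, sites=_silicon_sites(species("Si"), SI_ATOM_B),
                          name="si_spherical")
    si_ion = CrystalModel(cell=cell, sites=_silicon_sites(species("Si4+"), SI_ATOM_B),
                          name="si_ionic")
    bonds = neighbor_pairs(si_ion, 2.2, 2.5)
    si_bc = add_bond_charges(si_ion, bonds, electrons_per_bond=2, bond_B=SI_BOND_B)
    si_bc = si_bc.with_sites(si_bc.sites, name="si_bond_charge")

    acell = UnitCell(6.0, 7.5, 9.0)
    mean_b = float(np.mean(list(AMINO_LITERATURE_B.values())))
    amino = CrystalModel(cell=acell, sites=(
        site("N", "N", (0.150, 0.200, 0.250), B=mean_b),
        site("H1", "H", (0.310, 0.205, 0.255), B=mean_b),   # ~0.96 Å along a
        site("H2", "H", (0.145, 0.335, 0.260), B=mean_b),   # ~1.0 Å along b
        site("H3", "H", (0.155, 0.210, 0.361), B=mean_b),   # ~1.0 Å along c
        site("O", "O", (0.655, 0.275, 0.310), B=mean_b),    # anti-phase to N for odd h
    ), name="amino_mock")
    return {"si_spherical": si_sph, "si_bond_charge": si_bc, "amino_mock": amino}


def amino_model(x: float, z: float) -> CrystalModel:
    """Charge-transfer + B-interpolated variant of the mock amino cell.

    Composition order: the charge transfer (x electrons from each H to the
    N³⁻-forming acceptor) is applied first, then the B factors are
    interpolated between the uniform mean (z = 0) and the per-site literature
    values (z = 1).
    """
    base = toy_structures()["amino_mock"]
    m = _crystal.apply_charge_transfer(base, ["H1", "H2", "H3"], "N", x,
                                       acceptor_ion=species("N3-"))
    return _crystal.interpolate_bfactors(m, z, AMINO_LITERATURE_B)


def select_isolated_events(events, n: int, min_gap: float = 1.6,
                           prefer=None) -> list:
    """Greedy subset of at most ``n`` events pairwise separated by
    ``min_gap`` degrees (the readable, non-overlapping peaks an
    experimenter would retain).  ``prefer`` optionally ranks candidates
    (higher first)."""
    ranked = sorted(events, key=(lambda e: -prefer(e)) if prefer else (lambda e: e.phi))
    sel = []
    for ev in ranked:
        gap = min((min(abs(ev.phi - o.phi), 360.0 - abs(ev.phi - o.phi))
                   for o in sel), default=360.0)
        if gap > min_gap:
            sel.append(ev)
        if len(sel) >= n:
            break
    sel.sort(key=lambda e: e.phi)
    return sel


def amino_acd_scenario(x_true: float = 0.2, z_true: float = 0.5,
                       E_keV: float = 8.048, G=(0, 2, 6), q_max: float = 0.9,
                       n_events: int = 18):
    """Ready-made parameter-recovery scenario on the mock amino cell.

    Returns (geom, events, truth_model) where ``events`` are well-separated
    MD events annotated with the truth model's triplet phases, preferring
    events whose predicted asymmetry flips between the x = 0 and x = 1
    endpoint models (the susceptible ones).
    """
    from . import mdgeom, sfactor

    truth = amino_model(x_true, z_true)
    geom = mdgeom.ScanGeometry(G=tuple(G), E=E_keV, reference_direction=(1, 0, 0))
    evs = mdgeom.enumerate_events(geom, truth.cell, q_max, model=truth, w_min=0.05)
    m0 = amino_model(0.0, z_true)
    m1 = amino_model(1.0, z_true)

    def score(ev):
        if abs(math.cos(math.radians(ev.psi))) < 0.15:
            return -1.0
        t0 = sfactor.triplet_phase(m0, geom.G, ev.H, E_keV)
        t1 = sfactor.triplet_phase(m1, geom.G, ev.H, E_keV)
        c0 = math.cos(math.radians(t0.psi))
        c1 = math.cos(math.radians(t1.psi))
        susceptible = c0 * c1 < 0 and min(abs(c0), abs(c1)) > 0.1
        return 1.0 if susceptible else 0.0

    sel = select_isolated_events([e for e in evs if score(e) >= 0], n_events,
                                 min_gap=1.6, prefer=score)
    return geom, sel, truth
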