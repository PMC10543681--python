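"""Crystal structures, atomic/ionic scattering factors and model generators.

A :class:`CrystalModel` is the structural hypothesis under test: a unit cell
plus a list of (possibly composite) atomic sites, each with fractional
coordinates, occupancies and an isotropic displacement factor B (Å²).  Model
generators (:func:`apply_charge_transfer`, :func:`interpolate_bfactors`,
:func:`add_bond_charges`) derive families of alternative models from a base
structure — ionic models parametrised by a transferred charge ``x``, B-factor
interpolation parametrised by ``z``, and bond-charge models that place
point-like electron pairs on covalent bonds.

Scattering factors follow the standard decomposition
``f(s, E) = f0(s) + f'(E) + i f''(E)`` with ``f0`` a four-Gaussian
Cromer–Mann sum and the anomalous terms linearly interpolated on a per-species
resonance table.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from ._data import (
    HC_KEV_ANGSTROM,
    ION_ALIASES,
    ION_CROMER_MANN,
    ION_PARENT_ELEMENT,
    RESONANCE_GRID_KEV,
)

logger = logging.getLogger("dynphase")

__all__ = [
    "UnitCell",
    "Species",
    "Site",
    "CrystalModel",
    "UnknownSpeciesError",
    "CifParseError",
    "species",
    "load_cif",
    "scattering_factor",
    "apply_charge_transfer",
    "interpolate_bfactors",
    "add_bond_charges",
    "neighbor_pairs",
    "energy_to_wavelength",
    "wavelength_to_energy",
    "write_model_table",
    "read_model_table",
]

#: fractional-coordinate tolerance used when merging symmetry-equivalent sites
SITE_MERGE_TOL = 1e-4


class UnknownSpeciesError(ValueError):
    """Species label with no Cromer–Mann coefficients available."""


class CifParseError(ValueError):
    """CIF file missing required items or unreadable."""


# ---------------------------------------------------------------------------
# unit cell
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Unit-cell geometry; lengths in Å, angles in degrees.

    The Cartesian setting is the standard reciprocal one: a* along x and
    b* in the x–y plane.  Reciprocal-vector moduli use the crystallographic
    1/d convention (no 2π), so ``q(hkl) = 1/d_hkl`` in Å⁻¹.
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if np.linalg.det(self.direct_matrix) <= 0:
            raise ValueError("cell metric is not positive definite")

    @property
    def direct_matrix(self) -> np.ndarray:
        """3x3 matrix with the direct basis vectors a, b, c as *columns*."""
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        ca, cb, cg = np.cos([al, be, ga])
        sa = math.sin(al)
        # setting with c along z and b in the y-z plane, which puts a* along x
        # and b* in the x-y plane
        v = math.sqrt(max(1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg, 0.0))
        avec = np.array([self.a * v / sa, self.a * (cg - cb * ca) / sa, self.a * cb])
        bvec = np.array([0.0, self.b * sa, self.b * ca])
        cvec = np.array([0.0, 0.0, self.c])
        return np.column_stack([avec, bvec, cvec])

    @property
    def reciprocal_matrix(self) -> np.ndarray:
        """3x3 matrix with a*, b*, c* as columns (1/d convention)."""
        return np.linalg.inv(self.direct_matrix).T

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.direct_matrix)))

    def qvec(self, hkl) -> np.ndarray:
        """Cartesian reciprocal vector of ``hkl`` in Å⁻¹."""
        return self.reciprocal_matrix @ np.asarray(hkl, dtype=float)

    def q(self, hkl) -> float:
        """Diffraction-vector modulus 1/d in Å⁻¹."""
        return float(np.linalg.norm(self.qvec(hkl)))

    def d_spacing(self, hkl) -> float:
        return 1.0 / self.q(hkl)

    def s(self, hkl) -> float:
        """sinθ/λ = 1/(2 d_hkl) in Å⁻¹."""
        return 0.5 * self.q(hkl)

    def direction(self, uvw) -> np.ndarray:
        """Cartesian vector of the real-space lattice direction [uvw]."""
        return self.direct_matrix @ np.asarray(uvw, dtype=float)

    def is_close(self, other: "UnitCell", rtol: float = 1e-6) -> bool:
        mine = (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)
        theirs = (other.a, other.b, other.c, other.alpha, other.beta, other.gamma)
        return bool(np.allclose(mine, theirs, rtol=rtol))


# ---------------------------------------------------------------------------
# species and scattering factors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Species:
    """A scattering species: Cromer–Mann f0 plus a resonance (f', f'') table.

    ``resonance_table`` is an (n, 3) array of (E keV, f', f'') rows with
    strictly increasing energies; the anomalous terms of ions are those of the
    parent free atom, per the free-atom-core approximation.
    """

    label: str
    cm_a: tuple
    cm_b: tuple
    cm_c: float
    n_electrons: int
    resonance_table: np.ndarray = field(repr=False)

    def __post_init__(self):
        tab = np.asarray(self.resonance_table, dtype=float)
        if tab.ndim != 2 or tab.shape[1] != 3:
            raise ValueError("resonance_table must be (n, 3): E, f', f''")
        if not np.all(np.diff(tab[:, 0]) > 0):
            raise ValueError("resonance_table energies must be strictly increasing")
        object.__setattr__(self, "resonance_table", tab)
        f00 = self.f0(0.0)
        if abs(f00 - self.n_electrons) > 0.05:
            raise ValueError(
                f"{self.label}: f0(0) = {f00:.3f} differs from electron count "
                f"{self.n_electrons} by more than 0.05"
            )

    def f0(self, s) -> float | np.ndarray:
        """Spherical atomic form factor at s = sinθ/λ (Å⁻¹), in electrons."""
        s2 = np.square(np.asarray(s, dtype=float))
        a = np.asarray(self.cm_a)
        b = np.asarray(self.cm_b)
        val = np.sum(a * np.exp(-np.outer(s2.ravel(), b)), axis=-1) + self.cm_c
        return float(val[0]) if np.isscalar(s) or np.asarray(s).ndim == 0 else val.reshape(np.shape(s))

    def anomalous(self, E_keV: float) -> tuple[float, float]:
        """(f', f'') at E by linear interpolation; zeros outside the table."""
        tab = self.resonance_table
        if len(tab) == 0 or not tab[0, 0] <= E_keV <= tab[-1, 0]:
            warnings.warn(
                f"{self.label}: {E_keV} keV outside resonance table span; "
                "using f' = f'' = 0",
                stacklevel=2,
            )
            return 0.0, 0.0
        f1 = float(np.interp(E_keV, tab[:, 0], tab[:, 1]))
        f2 = float(np.interp(E_keV, tab[:, 0], tab[:, 2]))
        return f1, f2


_ION_RE = re.compile(r"^([A-Z][a-z]?)(\d+)([+-])$")

_species_cache: dict[tuple, Species] = {}


def species(label: str, resonance_grid=None) -> Species:
    """Build a :class:`Species` from a label such as ``"Si"``, ``"Si4+"``, ``"N3-"``.

    Neutral elements use gemmi's embedded Cromer–Mann coefficients; ions use
    the packaged ionic coefficient sets.  Resonance tables are built from the
    Cromer–Liberman free-atom data of the parent element on ``resonance_grid``
    (a (start, stop, step) keV triple, default 2–30 keV every 0.02 keV).
    """
    grid = RESONANCE_GRID_KEV if resonance_grid is None else tuple(resonance_grid)
    key = (label, grid)
    if key in _species_cache:
        return _species_cache[key]

    canonical = ION_ALIASES.get(label, label)
    if canonical in ION_CROMER_MANN:
        coefs = ION_CROMER_MANN[canonical]
        a, b, c = tuple(coefs["a"]), tuple(coefs["b"]), coefs["c"]
        parent = ION_PARENT_ELEMENT[label]
        m = _ION_RE.match(label)
        charge = int(m.group(2)) * (1 if m.group(3) == "+" else -1)
        nel = gemmi.Element(parent).atomic_number - charge
    else:
        m = _ION_RE.match(label)
        if m:
            raise UnknownSpeciesError(
                f"no Cromer-Mann coefficients packaged for ion {label!r}; "
                "neutral-plus-offset approximations are not provided"
            )
        el = gemmi.Element(label)
        if el.atomic_number == 0:
            raise UnknownSpeciesError(f"unknown element symbol {label!r}")
        it92 = el.it92
        if it92 is None:
            raise UnknownSpeciesError(f"no Cromer-Mann coefficients for {label!r}")
        a, b, c = tuple(it92.a), tuple(it92.b), it92.c
        parent = el.name
        nel = el.atomic_number

    z = gemmi.Element(parent).atomic_number
    energies = np.arange(grid[0], grid[1] + 0.5 * grid[2], grid[2])
    rows = []
    for e in energies:
        f1, f2 = gemmi.cromer_liberman(z=z, energy=e * 1e3)
        rows.append((e, f1, f2))
    sp = Species(label=label, cm_a=a, cm_b=b, cm_c=c, n_electrons=nel,
                 resonance_table=np.array(rows))
    _species_cache[key] = sp
    return sp


def scattering_factor(sp: Species, s: float, E_keV: float) -> complex:
    """Complex scattering amplitude f0(s) + f'(E) + i f''(E), in electrons."""
    if s < 0:
        raise ValueError("s = sin(theta)/lambda must be non-negative")
    f1, f2 = sp.anomalous(E_keV)
    return complex(sp.f0(s) + f1, f2)


# ---------------------------------------------------------------------------
# sites and models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Site:
    """One atomic site: a composition list [(Species, occupancy)], fractional
    coordinates in [0, 1) and isotropic B in Å²."""

    components: tuple          # ((Species, occupancy), ...)
    frac: tuple                # (x, y, z)
    B: float = 0.0
    label: str = ""

    def __post_init__(self):
        comps = tuple((sp, float(occ)) for sp, occ in self.components)
        for sp, occ in comps:
            if not 0.0 <= occ <= 1.0:
                raise ValueError(f"occupancy {occ} outside [0, 1] on site {self.label!r}")
        if self.B < 0:
            raise ValueError("B must be >= 0")
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "frac", tuple(float(x) % 1.0 for x in self.frac))

    def effective_f(self, s: float, E_keV: float) -> complex:
        """Occupancy-weighted scattering factor of the composite site."""
        return sum(occ * scattering_factor(sp, s, E_keV) for sp, occ in self.components)


def site(label, comp, frac, B=0.0) -> Site:
    """Convenience constructor: ``comp`` is a Species, a label string, or a
    list of (species-or-label, occupancy) pairs."""
    if isinstance(comp, (str, Species)):
        comp = [(comp, 1.0)]
    comps = tuple((species(sp) if isinstance(sp, str) else sp, occ) for sp, occ in comp)
    return Site(components=comps, frac=tuple(frac), B=float(B), label=label)


@dataclass(frozen=True)
class CrystalModel:
    """A unit cell plus the full unit-cell content (sites), the structural
    hypothesis being tested.  ``symmetry_ops`` (gemmi.Op triplets) are kept
    only for reflection-set enumeration; the site list is always expanded."""

    cell: UnitCell
    sites: tuple
    name: str = ""
    symmetry_ops: tuple = ()

    def __post_init__(self):
        if not self.sites:
            raise ValueError("model must contain at least one site")
        object.__setattr__(self, "sites", tuple(self.sites))

    @property
    def mean_B(self) -> float:
        """Unweighted mean of the site B factors, Å²."""
        return float(np.mean([st.B for st in self.sites]))

    def with_sites(self, sites, name=None) -> "CrystalModel":
        return CrystalModel(cell=self.cell, sites=tuple(sites),
                            name=self.name if name is None else name,
                            symmetry_ops=self.symmetry_ops)


# ---------------------------------------------------------------------------
# CIF reading
# ---------------------------------------------------------------------------

def _cif_number(block, tag):
    val = block.find_value(tag)
    if val is None:
        return None
    return gemmi.cif.as_number(val)


def load_cif(path: str) -> CrystalModel:
    """Load a crystal model from a CIF file (core dictionary items).

    Symmetry operators, when present, are expanded so that the site list
    contains the full unit-cell content; symmetry-equivalent duplicates are
    merged at 1e-4 fractional tolerance.  Missing occupancies default to 1.0
    and missing B factors to 0 Å², each with a logged warning.
    """
    try:
        doc = gemmi.cif.read(str(path))
        block = doc.sole_block()
    except Exception as exc:  # gemmi raises RuntimeError/ValueError
        raise CifParseError(f"cannot parse CIF {path}: {exc}") from exc

    cellvals = [_cif_number(block, f"_cell_length_{t}") for t in "abc"]
    angvals = [_cif_number(block, f"_cell_angle_{t}") for t in ("alpha", "beta", "gamma")]
    if any(v is None for v in cellvals):
        raise CifParseError(f"{path}: missing _cell_length_* items")
    angvals = [90.0 if v is None else v for v in angvals]
    cell = UnitCell(*cellvals, *angvals)

    def loop_strings(tag):
        return [gemmi.cif.as_string(v) for v in block.find_loop(tag)]

    def loop_numbers(tag):
        return [gemmi.cif.as_number(v) for v in block.find_loop(tag)]

    sym_strings = (loop_strings("_symmetry_equiv_pos_as_xyz")
                   or loop_strings("_space_group_symop_operation_xyz"))
    ops = [gemmi.Op(s) for s in sym_strings] or [gemmi.Op("x,y,z")]

    labels = loop_strings("_atom_site_label")
    types = loop_strings("_atom_site_type_symbol")
    fx = loop_numbers("_atom_site_fract_x")
    fy = loop_numbers("_atom_site_fract_y")
    fz = loop_numbers("_atom_site_fract_z")
    occ = loop_numbers("_atom_site_occupancy")
    bis = loop_numbers("_atom_site_B_iso_or_equiv")
    uis = loop_numbers("_atom_site_U_iso_or_equiv")

    if not fx:
        raise CifParseError(f"{path}: no _atom_site_fract_* loop")
    n = len(fx)
    if not labels:
        labels = [f"site{i}" for i in range(n)]
    if not types:
        # fall back to the leading element symbol of the label
        types = [re.match(r"[A-Z][a-z]?", lab).group(0) for lab in labels]
    if not occ:
        logger.warning("%s: no _atom_site_occupancy; defaulting to 1.0", path)
        occ = [1.0] * n
    if not bis:
        if uis:
            bis = [8 * math.pi**2 * u for u in uis]
        else:
            logger.warning("%s: no _atom_site_B_iso_or_equiv; defaulting to 0", path)
            bis = [0.0] * n

    sites = []
    for i in range(n):
        sp = species(types[i].strip())
        base = np.array([fx[i], fy[i], fz[i]], dtype=float)
        equivalents = []
        for op in ops:
            pos = np.array(op.apply_to_xyz(list(base))) % 1.0
            if not any(_frac_close(pos, q) for q in equivalents):
                equivalents.append(pos)
        for j, pos in enumerate(equivalents):
            lab = labels[i] if len(equivalents) == 1 else f"{labels[i]}_{j}"
            sites.append(site(lab, [(sp, occ[i])], pos, B=bis[i]))

    ops_out = tuple(ops) if len(ops) > 1 else ()
    return CrystalModel(cell=cell, sites=tuple(sites),
                        name=str(path), symmetry_ops=ops_out)


def _frac_close(p, q, tol=SITE_MERGE_TOL):
    d = np.abs(np.asarray(p) - np.asarray(q))
    d = np.minimum(d, 1.0 - d)
    return bool(np.all(d < tol))


# ---------------------------------------------------------------------------
# model generators
# ---------------------------------------------------------------------------

def _resolve_selector(model: CrystalModel, sel) -> list[int]:
    """Site selector: an int index, a label string, or an iterable of either."""
    if isinstance(sel, (int, np.integer)):
        return [int(sel)]
    if isinstance(sel, str):
        idx = [i for i, st in enumerate(model.sites) if st.label == sel]
        if not idx:
            raise KeyError(f"no site labelled {sel!r}")
        return idx
    out = []
    for s_ in sel:
        out.extend(_resolve_selector(model, s_))
    return out


def apply_charge_transfer(model: CrystalModel, donor_sites, acceptor_site,
                          x: float, acceptor_ion: Species) -> CrystalModel:
    """Ionic model with ``x`` electrons transferred from each donor hydrogen.

    Donors (single-component hydrogen sites) get occupancy ``1 - x``; the
    acceptor becomes a composite site occupied by the neutral species with
    fraction ``1 - x`` and by ``acceptor_ion`` with fraction ``x``, so the
    effective factors are ``(1-x) f_H`` and ``(1-x) f_neutral + x f_ion``.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError("charge transfer x must lie in [0, 1]")
    donors = set(_resolve_selector(model, donor_sites))
    acceptors = _resolve_selector(model, acceptor_site)
    if len(acceptors) != 1:
        raise ValueError("acceptor_site must resolve to exactly one site")
    acceptor = acceptors[0]

    new_sites = []
    for i, st in enumerate(model.sites):
        if i in donors:
            if len(st.components) != 1 or st.components[0][0].n_electrons != 1:
                raise ValueError(f"donor site {st.label!r} is not a single-component hydrogen site")
            sp, occ0 = st.components[0]
            new_sites.append(replace(st, components=((sp, occ0 * (1.0 - x)),)))
        elif i == acceptor:
            (neutral, occ0), = st.components
            new_sites.append(replace(
                st, components=((neutral, occ0 * (1.0 - x)), (acceptor_ion, occ0 * x))))
        else:
            new_sites.append(st)
    return model.with_sites(new_sites, name=f"{model.name}|x={x:g}")


def interpolate_bfactors(model: CrystalModel, z: float, literature_B: dict) -> CrystalModel:
    """Replace every site B with ``(1 - z) <B> + z B0``, ``z`` in [0, 1].

    ``literature_B`` maps site label (or index) to the literature value B0
    (Å²) and must cover every site; ``<B>`` is the model's current mean B.
    """
    if not 0.0 <= z <= 1.0:
        raise ValueError("z must lie in [0, 1]")
    meanB = model.mean_B
    new_sites = []
    for i, st in enumerate(model.sites):
        if st.label in literature_B:
            b0 = literature_B[st.label]
        elif i in literature_B:
            b0 = literature_B[i]
        else:
            raise KeyError(f"literature_B missing site {st.label!r} (index {i})")
        new_sites.append(replace(st, B=(1.0 - z) * meanB + z * float(b0)))
    return model.with_sites(new_sites, name=f"{model.name}|z={z:g}")


def neighbor_pairs(model: CrystalModel, dmin: float, dmax: float) -> list[tuple]:
    """All (i, j, translation) with nearest-image distance in [dmin, dmax] Å.

    Each bond is listed once (i <= j; for i == j only translations in one
    half-space).  This is an enumeration helper for building explicit bond
    lists, not a bonding heuristic.
    """
    D = model.cell.direct_matrix
    fracs = [np.array(st.frac) for st in model.sites]
    out = []
    shifts = [np.array(t) for t in np.ndindex(3, 3, 3)]
    for i in range(len(fracs)):
        for j in range(i, len(fracs)):
            for sh in shifts:
                t = sh - 1
                if i == j and tuple(t) <= (0, 0, 0):
                    continue
                d = np.linalg.norm(D @ (fracs[j] + t - fracs[i]))
                if dmin <= d <= dmax:
                    out.append((i, j, tuple(int(v) for v in t)))
    return out


def add_bond_charges(model: CrystalModel, bonds, electrons_per_bond: int = 2,
                     position_fraction: float = 0.5, bond_B: float | None = None,
                     cutoff: float = 3.0, charge_species: Species | None = None) -> CrystalModel:
    """Place point charges on bonds, each scattering as ``electrons_per_bond``
    hydrogen atoms at ``position_fraction`` along the bond (default midpoint).

    ``bonds`` is a list of (i, j) or (i, j, translation) site-index pairs; a
    bare (i, j) pair is resolved to the nearest periodic image of j, and it is
    an error if no image lies within ``cutoff`` Å.  Switching the host atoms
    to their ionic form (e.g. Si4+) is the caller's responsibility.
    """
    if not 0.0 < position_fraction < 1.0:
        raise ValueError("position_fraction must lie in (0, 1)")
    if electrons_per_bond < 0:
        raise ValueError("electrons_per_bond must be >= 0")
    hyd = charge_species if charge_species is not None else species("H")
    bB = model.mean_B if bond_B is None else float(bond_B)
    D = model.cell.direct_matrix

    new_sites = list(model.sites)
    for k, bond in enumerate(bonds):
        if len(bond) == 3:
            i, j, t = bond
            t = np.asarray(t, dtype=float)
        else:
            i, j = bond
            ri = np.array(model.sites[i].frac)
            rj = np.array(model.sites[j].frac)
            best, bestd = None, np.inf
            for sh in np.ndindex(3, 3, 3):
                t_ = np.array(sh) - 1
                d = np.linalg.norm(D @ (rj + t_ - ri))
                if d < bestd:
                    best, bestd = t_, d
            if bestd > cutoff:
                raise ValueError(
                    f"bond ({i}, {j}): no periodic image within {cutoff} Å "
                    f"(nearest at {bestd:.2f} Å)")
            t = best
        ri = np.array(model.sites[i].frac)
        rj = np.array(model.sites[j].frac) + t
        pos = ri + position_fraction * (rj - ri)
        if electrons_per_bond > 0:
            comps = tuple((hyd, 1.0) for _ in range(int(electrons_per_bond)))
            new_sites.append(Site(components=comps, frac=tuple(pos % 1.0),
                                  B=bB, label=f"bond{k}"))
    return model.with_sites(new_sites, name=f"{model.name}+bonds")


# ---------------------------------------------------------------------------
# energy / wavelength and the flat model table
# ---------------------------------------------------------------------------

def energy_to_wavelength(E_keV: float) -> float:
    """λ = hc/E with hc = 12.3984 keV·Å."""
    if E_keV <= 0:
        raise ValueError("energy must be positive")
    return HC_KEV_ANGSTROM / E_keV


def wavelength_to_energy(lam_A: float) -> float:
    if lam_A <= 0:
        raise ValueError("wavelength must be positive")
    return HC_KEV_ANGSTROM / lam_A


def write_model_table(model: CrystalModel, path: str) -> None:
    """Write the flat one-site-per-line text representation of a model."""
    with open(path, "w") as fh:
        fh.write(f"# cell {model.cell.a:.6f} {model.cell.b:.6f} {model.cell.c:.6f} "
                 f"{model.cell.alpha:.4f} {model.cell.beta:.4f} {model.cell.gamma:.4f}\n")
        fh.write("# label species:occupancy[+...] x y z B\n")
        for st in model.sites:
            comp = "+".join(f"{sp.label}:{occ:.6g}" for sp, occ in st.components)
            x, y, z = st.frac
            fh.write(f"{st.label or '-'} {comp} {x:.6f} {y:.6f} {z:.6f} {st.B:.4f}\n")


def read_model_table(path: str) -> CrystalModel:
    sites, cell = [], None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# cell"):
                vals = [float(v) for v in line.split()[2:8]]
                cell = UnitCell(*vals)
            if not line or line.startswith("#"):
                continue
            lab, comp, x, y, z, B = line.split()
            comps = []
            for token in comp.split("+"):
                spl, occ = token.rsplit(":", 1)
                comps.append((species(spl), float(occ)))
            sites.append(Site(components=tuple(comps),
                              frac=(float(x), float(y), float(z)),
                              B=float(B), label=lab))
    if cell is None:
        raise ValueError(f"{path}: missing '# cell' header line")
    return CrystalModel(cell=cell, sites=tuple(sites), name=str(path))
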