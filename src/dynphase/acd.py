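"""Asymmetry comparison diagrams (ACDs).

An ACD compares the set of observed MD profile asymmetries against the
asymmetries predicted by a two-parameter family of model structures, one
match/mismatch matrix per grid point (x, z).  Typical usage pairs a
charge-transfer parameter x with a B-factor interpolation parameter z.
INDETERMINATE predictions (|cos Ψ| inside the tolerance band, or vanishing
amplitudes) are marked unresolvable, never counted as mismatches, matching
the convention that only readable asymmetries are coloured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crystal import CrystalModel
from .mdgeom import minimum_energy
from .sfactor import COS_TOL, AsymmetryLabel, predict_asymmetry, triplet_phase

__all__ = ["ModelGrid", "ACDMatrix", "CompatibleRegion", "build_acd",
           "susceptible_events", "compatible_region", "restrict", "acd_to_frame",
           "plot_acd"]

MATCH, MISMATCH, UNRESOLVABLE = 1, -1, 0


@dataclass
class ModelGrid:
    """A 2-parameter family of crystal models."""

    x_values: tuple
    z_values: tuple
    generator: object           # callable (x, z) -> CrystalModel

    def __post_init__(self):
        self.x_values = tuple(float(v) for v in self.x_values)
        self.z_values = tuple(float(v) for v in self.z_values)
        if not self.x_values or not self.z_values:
            raise ValueError("grids must be non-empty")
        if list(self.x_values) != sorted(self.x_values) or \
                list(self.z_values) != sorted(self.z_values):
            raise ValueError("grid values must be sorted ascending")


@dataclass
class ACDMatrix:
    """Match/mismatch codes over (x, z, observation)."""

    x_values: tuple
    z_values: tuple
    event_index: list            # [(H, g)] in observation order
    labels: list                 # observed AsymmetryLabel per observation
    codes: np.ndarray            # int8 (nx, nz, nobs): 1 match, -1 mismatch, 0 unresolvable
    psi: np.ndarray              # float (nx, nz, nobs)
    pred: np.ndarray = field(default=None)   # int8: +1 HL, -1 LH, 0 indeterminate


@dataclass
class CompatibleRegion:
    points: list                 # [(x, z)] with zero mismatches
    uninformative: bool = False  # every cell unresolvable: vacuous match

    def __contains__(self, xz):
        return any(np.isclose(x, xz[0]) and np.isclose(z, xz[1])
                   for x, z in self.points)

    def __len__(self):
        return len(self.points)


_PRED_CODE = {AsymmetryLabel.HL: 1, AsymmetryLabel.LH: -1,
              AsymmetryLabel.INDETERMINATE: 0}


def build_acd(observations, grid: ModelGrid, G, E_keV: float,
              cos_tol: float = COS_TOL) -> ACDMatrix:
    """Predicted-vs-observed asymmetry codes over the model grid.

    ``observations`` are accepted asymmetry readings (reliability cutoff
    already applied); dip-flagged or indeterminate observations are excluded
    from the matrix.  An observation whose H is not excitable at ``E_keV``
    raises an error naming the event.
    """
    obs = [o for o in observations
           if o.accepted and o.label is not AsymmetryLabel.INDETERMINATE
           and "DIP" not in o.flags]
    if not obs:
        raise ValueError("no accepted, determinate observations to compare")
    cell = grid.generator(grid.x_values[0], grid.z_values[0]).cell
    for o in obs:
        if minimum_energy(cell, G, o.H) > E_keV:
            raise ValueError(f"observed event H={o.H} not excitable at {E_keV} keV")

    nx, nz, no = len(grid.x_values), len(grid.z_values), len(obs)
    codes = np.zeros((nx, nz, no), dtype=np.int8)
    psis = np.full((nx, nz, no), np.nan)
    preds = np.zeros((nx, nz, no), dtype=np.int8)
    for i, x in enumerate(grid.x_values):
        for j, z in enumerate(grid.z_values):
            model = grid.generator(x, z)
            if not isinstance(model, CrystalModel):
                raise TypeError("grid generator must return CrystalModel")
            for k, o in enumerate(obs):
                t = triplet_phase(model, G, o.H, E_keV)
                psis[i, j, k] = t.psi
                if t.undefined:
                    codes[i, j, k] = UNRESOLVABLE
                    continue
                pred = predict_asymmetry(o.g, t.psi, tol=cos_tol)
                preds[i, j, k] = _PRED_CODE[pred]
                if pred is AsymmetryLabel.INDETERMINATE:
                    codes[i, j, k] = UNRESOLVABLE
                else:
                    codes[i, j, k] = MATCH if pred is o.label else MISMATCH
    return ACDMatrix(x_values=grid.x_values, z_values=grid.z_values,
                     event_index=[(o.H, o.g) for o in obs],
                     labels=[o.label for o in obs],
                     codes=codes, psi=psis, pred=preds)


def susceptible_events(acd: ACDMatrix) -> list:
    """Events whose determinate predicted label changes across the grid."""
    if acd.codes.shape[0] * acd.codes.shape[1] < 2:
        raise ValueError("susceptibility needs at least 2 grid points")
    out = []
    for k, key in enumerate(acd.event_index):
        p = acd.pred[:, :, k]
        det = p[p != 0]
        if det.size and (det.min() != det.max()):
            out.append(key)
    return out


def compatible_region(acd: ACDMatrix) -> CompatibleRegion:
    """Grid points whose retained cells contain no mismatch.

    When every cell of every observation is unresolvable the whole grid
    matches vacuously and the region is flagged uninformative.
    """
    pts = []
    for i, x in enumerate(acd.x_values):
        for j, z in enumerate(acd.z_values):
            if not np.any(acd.codes[i, j, :] == MISMATCH):
                pts.append((x, z))
    uninformative = bool(np.all(acd.codes == UNRESOLVABLE))
    return CompatibleRegion(points=pts, uninformative=uninformative)


def restrict(acd: ACDMatrix, subset) -> ACDMatrix:
    """ACD restricted to a subset of its events (e.g. the susceptible ones)."""
    idx = [k for k, key in enumerate(acd.event_index) if key in set(subset)]
    if not idx:
        raise ValueError("subset selects no events")
    return ACDMatrix(x_values=acd.x_values, z_values=acd.z_values,
                     event_index=[acd.event_index[k] for k in idx],
                     labels=[acd.labels[k] for k in idx],
                     codes=acd.codes[:, :, idx], psi=acd.psi[:, :, idx],
                     pred=acd.pred[:, :, idx])


def acd_to_frame(acd: ACDMatrix) -> pd.DataFrame:
    """Long-format export: one row per (x, z, event) cell."""
    rows = []
    for i, x in enumerate(acd.x_values):
        for j, z in enumerate(acd.z_values):
            for k, (H, g) in enumerate(acd.event_index):
                rows.append({"x": x, "z": z, "H": "".join(map(str, H)), "g": g,
                             "observed": acd.labels[k].value,
                             "psi": acd.psi[i, j, k],
                             "code": int(acd.codes[i, j, k])})
    return pd.DataFrame(rows)


def plot_acd(acd: ACDMatrix, path: str) -> None:
    """Render the ACD as a grid of per-model match matrices (presentation only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nx, nz, no = acd.codes.shape
    side = int(np.ceil(np.sqrt(no)))
    fig, axes = plt.subplots(nz, nx, figsize=(1.2 * nx, 1.2 * nz),
                             squeeze=False)
    for i in range(nx):
        for j in range(nz):
            tile = np.full(side * side, np.nan)
            tile[:no] = acd.codes[i, j, :]
            ax = axes[nz - 1 - j][i]
            ax.imshow(tile.reshape(side, side), vmin=-1, vmax=1, cmap="PiYG")
            ax.set_xticks([])
            ax.set_yticks([])
            if j == 0:
                ax.set_xlabel(f"x={acd.x_values[i]:g}", fontsize=6)
            if i == 0:
                ax.set_ylabel(f"z={acd.z_values[j]:g}", fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
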