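"""Scattering-factor data: ionic Cromer–Mann coefficients and physical constants.

Neutral-element four-Gaussian coefficients and the Cromer–Liberman anomalous
factors f'(E), f''(E) are taken at run time from gemmi's compiled-in copies of
the standard international tabulations.  This module only embeds what that
build of gemmi does not expose: the handful of *ionic* coefficient sets the
toolkit needs, transcribed from the same tabulation.

``"N3-"`` is a special case: the standard tabulation carries no entry for the
nitride anion, so the label is mapped to the published F1- coefficient set
(the isoelectronic 10-electron halide anion) as a documented stand-in shape.
Any other unknown species label raises ``UnknownSpeciesError`` — silent
neutral-plus-charge-offset approximations are deliberately not provided.
"""

from __future__ import annotations

#: hc in keV·Å, used for every energy/wavelength conversion in the package.
HC_KEV_ANGSTROM = 12.3984

#: Default energy grid (keV) for building per-species resonance tables from
#: the Cromer–Liberman data.  Dense enough for linear interpolation at the
#: 0.01 keV level away from edges; callers may request finer custom grids.
RESONANCE_GRID_KEV = (2.0, 30.0, 0.02)

# Four-Gaussian coefficients (a1..a4, b1..b4, c) for ions, from the standard
# international tabulation of X-ray scattering factors.  b in Å²; f0(s) is in
# electrons with s = sinθ/λ in Å⁻¹ and f0(0) = Σa + c = electron count.
ION_CROMER_MANN = {
    "Si4+": {
        "a": (4.43918, 3.20345, 1.19453, 0.41653),
        "b": (1.64167, 3.43757, 0.21490, 6.65365),
        "c": 0.746297,
    },
    "O1-": {
        "a": (4.19160, 1.63969, 1.52673, -20.307),
        "b": (12.8573, 4.17236, 47.0179, -0.01404),
        "c": 21.9412,
    },
    "F1-": {
        "a": (3.63220, 3.51057, 1.26064, 0.940706),
        "b": (5.27756, 14.7353, 0.442258, 47.3437),
        "c": 0.653396,
    },
    "H1-": {
        "a": (0.897661, 0.565616, 0.415815, 0.116973),
        "b": (53.1368, 15.1870, 186.576, 3.56709),
        "c": 0.002389,
    },
}

# Documented stand-in: nitride anion rendered with the isoelectronic F1- shape.
ION_ALIASES = {"N3-": "F1-"}

#: Electron counts for the embedded ionic species (for validity checks and for
#: the resonance-table element assignment: anomalous factors are those of the
#: parent free atom).
ION_PARENT_ELEMENT = {"Si4+": "Si", "O1-": "O", "F1-": "F", "H1-": "H", "N3-": "N"}
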