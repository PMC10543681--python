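# dynphase

A toolkit for structure refinement of single crystals via dynamic
multiple-diffraction (MD) phase measurements.

In an azimuthal (Renninger) scan a crystal rotates about the diffraction
vector **G** of a weak reference reflection held on its Bragg condition.
Each time a secondary reciprocal-lattice point **H** crosses the Ewald
sphere, a three-beam MD event perturbs the reference intensity with a
characteristically *asymmetric* line profile.  For events dominated by the
second-order dynamical term, the observable higher–lower (HL) or
lower–higher (LH) shoulder order is fixed by the excitation geometry
g = ±1 (entering/exiting the sphere) and the triplet phase invariant

```
Ψ = δ_H + δ_{G−H} − δ_G = arg( F_H F_{G−H} / F_G ),

HL  ⇔  g · cos Ψ > 0,        LH  ⇔  g · cos Ψ < 0.
```

Because each asymmetry is a one-bit measurement of a structure-invariant
phase, a list of indexed asymmetries discriminates between competing model
structures — ionic models, bonding charges, per-site Debye–Waller factors —
beyond what intensities alone resolve.  `dynphase` covers the whole
workflow for experiment design and analysis:

- **crystal** — CIF loading with symmetry expansion, Cromer–Mann and
  anomalous (f′, f″) scattering factors for atoms and ions, and model
  generators: charge transfer `x` (H → acceptor ion), B-factor
  interpolation `B_n(z) = (1−z)⟨B⟩ + z B_{0,n}`, and point bond charges.
- **sfactor** — structure factors, single-reflection phases δ(E), triplet
  phases Ψ, the asymmetry sign rule, model–model phase comparison and
  asymmetry-flip prediction, Aufhellung (dip) classification, and the
  45°-Bragg-angle polarization warning.
- **mdgeom** — Renninger-scan geometry: event azimuths and g from the
  Ewald-crossing equation, minimum excitation energies, Bragg-cone (BC)
  lines ω(Φ), systematic/coincidental event grouping, pattern period and
  mirror positions, event tracking versus energy, coincidence energies.
- **scan** — azimuthal-scan ingestion, peak/dip detection, azimuth offset
  correction, event indexing with overlap flagging, and asymmetry reading
  by log-Gaussian + sloping-baseline fits with a reliability cutoff.
- **acd** — asymmetry comparison diagrams: predicted vs observed labels
  over an (x, z) model grid, susceptible-event selection and the compatible
  parameter region.
- **fixtures** — synthetic azimuthal scans with known ground truth and
  packaged toy structures (diamond silicon with/without bond charges, a
  mock amino-group cell for charge-transfer grids).

## Worked example: bond charges in silicon

The silicon 222 reflection is geometrically extinct for spherical atoms;
its observed intensity comes from electron density on the covalent bonds.
The packaged bond-charge model (Si⁴⁺ at the diamond sites, one 2-electron
charge at each of the 16 bond midpoints) makes 222 weak but non-zero, so
every MD event on its Renninger scan carries a readable triplet phase:

```python
from dynphase import fixtures, mdgeom, sfactor

model = fixtures.toy_structures()["si_bond_charge"]
F = sfactor.structure_factor(model, (2, 2, 2), 8.0)
print(f"|F_222| = {F.magnitude:.2f} e,  delta_222 = {F.phase:.1f} deg")

t = sfactor.triplet_phase(model, (2, 2, 2), (5, 1, 3), 8.0)
print(f"Psi(513) = {t.psi:.1f} deg,  W = |F_H F_GH| = {t.W:.0f} e^2")

geom = mdgeom.ScanGeometry(G=(2, 2, 2), E=8.0, reference_direction=(1, -1, 0))
events = mdgeom.enumerate_events(geom, model.cell, 1.29, model=model, w_min=100.0)
for ev in [e for e in events if e.phi < 15 and "DIP" not in e.flags][:5]:
    print(f"H={ev.H}  Phi={ev.phi:6.2f}  g={ev.g:+d}  Psi={ev.psi:7.1f}  {ev.predicted.value}")
```

prints

```
|F_222| = 6.50 e,  delta_222 = -90.0 deg
Psi(513) = -174.5 deg,  W = |F_H F_GH| = 1293 e^2
H=(1, -3, 3)  Phi=  0.67  g=+1  Psi= -174.7  LH
H=(1, 1, -1)  Phi=  5.77  g=-1  Psi= -175.9  HL
H=(4, 0, 4)  Phi=  6.48  g=+1  Psi=    3.0  HL
H=(5, -3, 3)  Phi=  6.98  g=+1  Psi= -173.4  LH
H=(1, -3, -1)  Phi=  9.43  g=+1  Psi= -174.5  LH
```

Reading the first line of the table: the secondary reflection (1, −3, 3)
is excited 0.67° into the scan while *exiting* the Ewald sphere (g = +1);
its triplet phase is close to 180°, so cos Ψ < 0 and the peak must show the
LH shoulder order.  Every Ψ on this scan is close to 0° or 180° — the
signature of a centrosymmetric charge distribution — and the small
deviations come from anomalous scattering at 8 keV.  An experimenter
compares such predicted labels against fitted baseline slopes of the
measured log-intensity profiles (negative slope = HL) and keeps the models
whose predictions match.

The same workflow is available from the shell:

```
dynphase events --toy si_bond_charge --g 2,2,2 --energy 8.0 --ref 1,-1,0 -o events.csv
dynphase simulate --config sim.json -o scan.txt --truth truth.csv
dynphase index --toy si_bond_charge --scan scan.txt --g 2,2,2 --energy 8.0 \
    --ref 1,-1,0 --prominence 300 -o observations.csv
dynphase acd --obs observations.csv --g 0,2,6 --energy 8.048 \
    --xgrid 0:1:0.1 --zgrid 0:1:0.1
```

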