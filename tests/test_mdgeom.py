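"""Tests for Renninger-scan geometry: crossings, tangency, BC lines and
pattern symmetry, each against an independent brute-force oracle where the
spec of the operation allows one."""

import math

import numpy as np
import pytest

from dynphase.crystal import UnitCell, energy_to_wavelength
from dynphase.mdgeom import (
    ScanGeometry,
    bc_line,
    branch_azimuth,
    coincidence_energy,
    enumerate_events,
    event_azimuths,
    ewald_residual,
    find_systematic,
    minimum_energy,
    mirror_positions,
    scan_period,
    track_energy,
)


def _brute_crossings(geom, cell, H, step=1e-5, coarse=0.01):
    """Independent oracle: scan |k0(phi) + H*| - 1/lambda for sign changes.

    The incident beam is built from explicit rotation about G*, not from the
    analytic decomposition under test.
    """
    lam = energy_to_wavelength(geom.E)
    qG = cell.qvec(geom.G)
    ghat = qG / np.linalg.norm(qG)
    r = cell.direction(geom.reference_direction)
    rperp = r - (r @ ghat) * ghat
    e1 = -rperp / np.linalg.norm(rperp)
    e2 = np.cross(ghat, e1)
    theta = math.asin(lam * np.linalg.norm(qG) / 2.0)

    def f(phi_deg):
        p = math.radians(phi_deg)
        khat = -math.sin(theta) * ghat + math.cos(theta) * (
            math.cos(p) * e1 + math.sin(p) * e2)
        return np.linalg.norm(khat / lam + cell.qvec(H)) - 1.0 / lam

    out = []
    grid = np.arange(0.0, 360.0 + coarse, coarse)
    vals = np.array([f(p) for p in grid])
    for i in np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]:
        lo, hi = grid[i], grid[i + 1]
        while hi - lo > step:
            mid = 0.5 * (lo + hi)
            if f(lo) * f(mid) <= 0:
                hi = mid
            else:
                lo = mid
        phi = 0.5 * (lo + hi)
        g = -1 if f(phi + 10 * step) - f(phi - 10 * step) < 0 else +1
        out.append((phi % 360.0, g))
    return sorted(out)


class TestEventAzimuths:
    def test_silicon_220_sits_on_the_mirror_azimuths(self, si_geom):
        cell = UnitCell(5.431, 5.431, 5.431)
        xs = event_azimuths(si_geom, cell, (2, 2, 0))
        phis = sorted(p % 360.0 for p, _ in xs)
        assert phis == pytest.approx([0.0, 180.0], abs=1e-9)

    def test_silicon_513_exits_near_nine_degrees(self, si_geom):
        cell = UnitCell(5.431, 5.431, 5.431)
        sols = {g: p for p, g in event_azimuths(si_geom, cell, (5, 1, 3))}
        assert sols[+1] == pytest.approx(9.43, abs=0.05)

    @pytest.mark.parametrize("cellpar,G,H,E", [
        ((5.431, 5.431, 5.431, 90, 90, 90), (2, 2, 2), (5, 1, 3), 8.0),
        ((5.431, 5.431, 5.431, 90, 90, 90), (2, 2, 2), (1, 1, -1), 8.0),
        ((6.0, 7.5, 9.0, 90, 90, 90), (0, 2, 6), (1, 1, 3), 8.048),
        ((6.3, 7.1, 8.2, 84, 96, 99), (1, 2, 0), (2, -1, 1), 10.0),
    ])
    def test_analytic_azimuths_match_brute_force_oracle(self, cellpar, G, H, E):
        cell = UnitCell(*cellpar)
        geom = ScanGeometry(G=G, E=E, reference_direction=(1, -1, 0))
        analytic = sorted((p, g) for p, g in event_azimuths(geom, cell, H))
        brute = _brute_crossings(geom, cell, H)
        assert len(analytic) == len(brute) > 0
        for (pa, ga), (pb, gb) in zip(analytic, brute):
            assert pa == pytest.approx(pb, abs=1e-4)
            assert ga == gb

    def test_axial_secondary_reported_not_solved(self, si_geom):
        cell = UnitCell(5.431, 5.431, 5.431)
        xs = event_azimuths(si_geom, cell, (1, 1, 1))
        assert xs.axial and len(xs) == 0

    def test_H_equal_G_rejected(self, si_geom):
        with pytest.raises(ValueError):
            event_azimuths(si_geom, UnitCell(5.431, 5.431, 5.431), (2, 2, 2))

    def test_reference_rotation_rigidly_shifts_pattern(self):
        cell = UnitCell(5.431, 5.431, 5.431)
        g1 = ScanGeometry(G=(2, 2, 2), E=8.0, reference_direction=(1, -1, 0))
        g2 = ScanGeometry(G=(2, 2, 2), E=8.0, reference_direction=(0, 1, -1))
        shifts = set()
        for H in [(5, 1, 3), (3, 1, 3), (1, 1, -1), (4, 0, 4)]:
            s1 = {g: p for p, g in event_azimuths(g1, cell, H)}
            s2 = {g: p for p, g in event_azimuths(g2, cell, H)}
            for g in s1:
                shifts.add(round((s2[g] - s1[g]) % 360.0, 6))
        assert len(shifts) == 1      # one rigid rotation for every event


class TestMinimumEnergy:
    def test_solutions_coalesce_at_threshold(self):
        cell = UnitCell(5.431, 5.431, 5.431)
        G, H = (2, 2, 2), (5, 1, 3)
        emin = minimum_energy(cell, G, H)
        geom = ScanGeometry(G=G, E=emin * (1 + 1e-6), reference_direction=(1, -1, 0))
        xs = list(event_azimuths(geom, cell, H, tangent_tol=0.0))
        assert len(xs) == 2
        d = abs(xs[0][0] - xs[1][0])
        assert min(d, 360.0 - d) < 0.5

    def test_not_excited_below_threshold(self):
        cell = UnitCell(5.431, 5.431, 5.431)
        G, H = (2, 2, 2), (5, 1, 3)
        emin = minimum_energy(cell, G, H)
        geom = ScanGeometry(G=G, E=emin * (1 - 1e-4), reference_direction=(1, -1, 0))
        assert len(event_azimuths(geom, cell, H)) == 0

    def test_agrees_with_bisection_on_discriminant(self):
        cell = UnitCell(6.0, 7.5, 9.0)
        G, H = (0, 2, 6), (1, 1, 3)
        emin = minimum_energy(cell, G, H)

        def excited(E):
            geom = ScanGeometry(G=G, E=E, reference_direction=(1, 0, 0))
            return len(event_azimuths(geom, cell, H, tangent_tol=0.0)) == 2

        # bracket from just above the reference reflection's own threshold
        lo = 12.3984 * cell.q(G) / 2.0 * (1 + 1e-9)
        hi = 30.0
        assert not excited(lo) and excited(hi)
        while hi - lo > 1e-9:
            mid = 0.5 * (lo + hi)
            if excited(mid):
                hi = mid
            else:
                lo = mid
        assert emin == pytest.approx(0.5 * (lo + hi), abs=1e-6)

    def test_axial_case_unbounded(self):
        cell = UnitCell(5.431, 5.431, 5.431)
        assert minimum_energy(cell, (2, 2, 2), (1, 1, 1)) == math.inf


class TestEnumerate:
    def test_qmax_below_smallest_reflection_is_empty(self, si_geom):
        cell = UnitCell(5.431, 5.431, 5.431)
        assert enumerate_events(si_geom, cell, 0.05) == []

    def test_every_event_satisfies_ewald_condition(self, si_geom, si_events):
        lam = energy_to_wavelength(si_geom.E)
        cell = UnitCell(5.431, 5.431, 5.431)
        for ev in si_events[:50]:
            assert ewald_residual(si_geom, cell, ev) < 1e-9 / lam

    def test_sixty_degree_period_of_silicon_222(self, si_events):
        # the period of the peak pattern; Aufhellung dips are excluded (their
        # mirror images can be crossings of extinct secondaries, hence absent)
        peaks = [e for e in si_events if "DIP" not in e.flags]
        assert scan_period(peaks, tol=1e-3) == pytest.approx(60.0)

    def test_aufhellung_dips_at_zero_and_sixty(self, si_events):
        dips = sorted(e.phi % 60.0 for e in si_events if "DIP" in e.flags)
        assert any(abs(p) < 1e-6 or abs(p - 60) < 1e-6 for p in dips)


class TestBCLines:
    def test_reference_line_is_horizontal_at_theta_G(self, si_geom):
        cell = UnitCell(5.431, 5.431, 5.431)
        lam = energy_to_wavelength(si_geom.E)
        theta_G = math.degrees(math.asin(lam * cell.q((2, 2, 2)) / 2))
        line = bc_line(si_geom, cell, (2, 2, 2), np.arange(0, 360, 5.0))
        pts = [o for br in line.branches for _, o in br["points"]]
        assert len(pts) == 72
        assert np.allclose(pts, theta_G, atol=1e-9)

    def test_crossings_of_reference_line_reproduce_event_azimuths(self, si_geom):
        cell = UnitCell(5.431, 5.431, 5.431)
        lam = energy_to_wavelength(si_geom.E)
        theta_G = math.degrees(math.asin(lam * cell.q((2, 2, 2)) / 2))
        H = (5, 1, 3)
        events = {g: p for p, g in event_azimuths(si_geom, cell, H)}
        line = bc_line(si_geom, cell, H, np.arange(0, 360, 0.02))
        found = {}
        for br in line.branches:
            pts = br["points"]
            for (p1, o1), (p2, o2) in zip(pts, pts[1:]):
                if (o1 - theta_G) * (o2 - theta_G) <= 0 and p2 - p1 < 1.0:
                    pc = p1 + (p2 - p1) * (theta_G - o1) / (o2 - o1)
                    found[min(events, key=lambda g: abs(events[g] - pc))] = pc
        for g, p in found.items():
            assert p == pytest.approx(events[g], abs=1e-3)
        assert set(found) == {+1, -1}

    def test_single_point_grid_at_event_azimuth(self, si_geom):
        cell = UnitCell(5.431, 5.431, 5.431)
        lam = energy_to_wavelength(si_geom.E)
        theta_G = math.degrees(math.asin(lam * cell.q((2, 2, 2)) / 2))
        phi513 = branch_azimuth(si_geom, cell, (5, 1, 3), +1)
        line = bc_line(si_geom, cell, (5, 1, 3), [phi513])
        omegas = [o for br in line.branches for _, o in br["points"]]
        assert min(abs(o - theta_G) for o in omegas) < 1e-6


class TestSystematic:
    def test_silicon_513_pair_is_systematic(self, si_geom, si_bc, si_events_window):
        groups = find_systematic(si_geom, si_bc.cell, si_events_window, tol_phi=0.05)
        near_nine = [g for g in groups if abs(g["phi"] - 9.43) < 0.1]
        assert near_nine and near_nine[0]["kind"] == "SYSTEMATIC"
        assert {e.H for e in near_nine[0]["events"]} == {(5, 1, 3), (1, -3, -1)}

    def test_313_331_pair_is_coincidental(self, si_geom, si_bc, si_events_window):
        groups = find_systematic(si_geom, si_bc.cell, si_events_window, tol_phi=0.4)
        near_thirty = [g for g in groups
                       if {e.H for e in g["events"]} >= {(3, 1, 3), (3, 3, 1)}]
        assert near_thirty and near_thirty[0]["kind"] == "COINCIDENTAL"

    def test_empty_event_list(self, si_geom, si_bc):
        assert find_systematic(si_geom, si_bc.cell, [], tol_phi=0.1) == []


class TestMirrorsAndPeriod:
    def test_silicon_222_has_twelve_mirror_positions(self, si_events):
        peaks = [e for e in si_events if "DIP" not in e.flags]
        assert len(mirror_positions(peaks, tol=1e-3)) == 12

    def test_orthorhombic_026_reference_has_four_mirrors(self):
        # the event set must be closed under H -> G-H (the coupling partner
        # sits exactly 180 degrees away), so enumerate every excitable H
        cell = UnitCell(6.0, 7.5, 9.0)
        E = 5.0
        geom = ScanGeometry(G=(0, 2, 6), E=E, reference_direction=(1, 0, 0))
        evs = enumerate_events(geom, cell, 2.0 / energy_to_wavelength(E))
        assert scan_period(evs, tol=1e-3) == pytest.approx(180.0)
        assert len(mirror_positions(evs, tol=1e-3)) == 4

    def test_triclinic_general_axis_has_no_mirrors(self):
        cell = UnitCell(6.3, 7.1, 8.2, 84.0, 96.0, 99.0)
        geom = ScanGeometry(G=(1, 2, 0), E=10.0, reference_direction=(0, 0, 1))
        evs = enumerate_events(geom, cell, 0.45)
        assert len(evs) > 10
        assert mirror_positions(evs, tol=1e-3) == []


class TestEnergyTracking:
    @pytest.mark.parametrize("cellpar,G", [
        ((5.431, 5.431, 5.431, 90, 90, 90), (2, 2, 2)),
        ((6.0, 7.5, 9.0, 90, 90, 90), (0, 2, 6)),
        ((5.8, 7.2, 8.8, 90, 90, 90), (1, 1, 2)),
    ])
    def test_sign_law_outside_diameter_sphere(self, cellpar, G):
        """MD events move with the sign of g as E grows whenever the secondary
        reciprocal point lies outside the sphere of diameter G*; points inside
        it move the opposite way."""
        cell = UnitCell(*cellpar)
        ref = (1, 0, 0) if G != (2, 2, 2) else (1, -1, 0)
        geom = ScanGeometry(G=G, E=8.0, reference_direction=ref)
        e1 = enumerate_events(geom, cell, 0.8)
        e2 = enumerate_events(geom.with_energy(8.2), cell, 0.8)
        tracked = track_energy(e1, e2)
        assert len(tracked["matched"]) > 20
        qG = cell.qvec(G)
        for ev1, ev2, dphi in tracked["matched"]:
            if ev1.g == 0 or abs(dphi) > 90.0:
                continue
            qH = cell.qvec(ev1.H)
            ball = float(qH @ (qH - qG))      # <0 inside the diameter sphere
            if abs(ball) < 1e-9 or abs(dphi) < 1e-9:
                continue
            expected = ev1.g if ball > 0 else -ev1.g
            assert np.sign(dphi) == expected, (ev1.H, ev1.g, dphi, ball)

    def test_equal_energies_give_zero_shift(self, si_geom):
        cell = UnitCell(5.431, 5.431, 5.431)
        evs = enumerate_events(si_geom, cell, 0.7)
        tracked = track_energy(evs, enumerate_events(si_geom, cell, 0.7))
        assert all(d == 0.0 for _, _, d in tracked["matched"])

    def test_event_below_threshold_is_unmatched(self):
        cell = UnitCell(5.431, 5.431, 5.431)
        G, H = (2, 2, 2), (5, 1, 3)
        emin = minimum_energy(cell, G, H)
        g_lo = ScanGeometry(G=G, E=emin * 0.999, reference_direction=(1, -1, 0))
        g_hi = ScanGeometry(G=G, E=emin * 1.01, reference_direction=(1, -1, 0))
        lo = [e for e in enumerate_events(g_lo, cell, 1.1) if e.H == H]
        hi = [e for e in enumerate_events(g_hi, cell, 1.1) if e.H == H]
        assert lo == [] and len(hi) == 2
        tracked = track_energy(lo, hi)
        assert len(tracked["unmatched_2"]) >= 2


class TestCoincidence:
    def test_same_reflection_returns_start(self):
        cell = UnitCell(5.431, 5.431, 5.431)
        assert coincidence_energy(cell, (2, 2, 2), (3, 1, 3), (3, 1, 3), 8.0) == 8.0

    def test_root_agrees_with_fine_energy_scan(self):
        cell = UnitCell(5.431, 5.431, 5.431)
        G, H1, H2 = (2, 2, 2), (3, 1, 3), (3, 3, 1)
        Ec = coincidence_energy(cell, G, H1, H2, 8.0)
        assert Ec is not None
        geom = ScanGeometry(G=G, E=8.0, reference_direction=(1, -1, 0))
        # residual separation at the root, via an independent re-evaluation
        p1 = branch_azimuth(geom, cell, H1, +1, E_keV=Ec)
        p2 = branch_azimuth(geom, cell, H2, -1, E_keV=Ec)
        assert abs((p1 - p2 + 180) % 360 - 180) < 1e-6
        # 0.1 eV scan brackets the same root
        seps = []
        for E in np.arange(Ec - 0.002, Ec + 0.002, 1e-4):
            q1 = branch_azimuth(geom, cell, H1, +1, E_keV=E)
            q2 = branch_azimuth(geom, cell, H2, -1, E_keV=E)
            seps.append((q1 - q2 + 180) % 360 - 180)
        assert min(np.abs(seps)) < 5e-3
        assert np.sign(seps[0]) != np.sign(seps[-1])
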