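"""Shared fixtures: toy structures, silicon Renninger-scan geometry, events."""

import warnings

import numpy as np
import pytest

from dynphase import crystal, fixtures, mdgeom

SI_G = (2, 2, 2)
SI_E = 8.0
SI_REF = (1, -1, 0)


@pytest.fixture(scope="session")
def toys():
    return fixtures.toy_structures()


@pytest.fixture(scope="session")
def si_bc(toys):
    return toys["si_bond_charge"]


@pytest.fixture(scope="session")
def si_geom():
    return mdgeom.ScanGeometry(G=SI_G, E=SI_E, reference_direction=SI_REF)


@pytest.fixture(scope="session")
def si_events(si_geom, si_bc):
    """Annotated full-revolution MD event list of the Si 222 scan at 8 keV."""
    q_max = 2.0 / crystal.energy_to_wavelength(SI_E)
    return mdgeom.enumerate_events(si_geom, si_bc.cell, q_max, model=si_bc,
                                   w_min=100.0)


@pytest.fixture(scope="session")
def si_events_window(si_geom, si_bc, si_events):
    """The [0, 60) degree window, with systematic/overlap flags filled."""
    evs = [e for e in si_events if 0.0 <= e.phi < 60.0]
    mdgeom.find_systematic(si_geom, si_bc.cell, evs, tol_phi=0.05)
    return evs


@pytest.fixture(scope="session")
def si_scan(si_events_window):
    """One synthetic Si 222 scan with a 7.3 degree azimuth offset."""
    cfg = fixtures.SimulationConfig(events=si_events_window, offset=7.3, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scn, truth = fixtures.simulate_scan(cfg, np.arange(-2.0, 64.0, 0.005))
    return scn, truth, cfg


@pytest.fixture(scope="session")
def amino_scenario():
    return fixtures.amino_acd_scenario()
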