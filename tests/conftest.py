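from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

import lysodimer as ld


@pytest.fixture(scope="session")
def hl() -> ld.Structure:
    """Synthetic wild-type lysozyme stand-in (130 residues, 4 disulfides)."""
    return ld.synthetic_hl_structure(mutant=False)


@pytest.fixture(scope="session")
def hl_mutant() -> ld.Structure:
    return ld.synthetic_hl_structure(mutant=True)


@pytest.fixture(scope="session")
def hl_pair() -> tuple[ld.Structure, ld.Structure]:
    """Wild-type / variant stand-in pair at the published 1.87 A backbone RMSD."""
    return ld.synthetic_hl_pair(target_backbone_rmsd=1.87, seed=0)


@pytest.fixture(scope="session")
def harmonic_pull() -> SimpleNamespace:
    """200 slow harmonic-potential pulls plus exact reference profile.

    Shared across the Jarzynski recovery, Jensen-bound and cumulant tests;
    fixed seed, stiff spring (50 kcal/mol/A^2) swept 10 A at 0.25 A/ns.
    """
    potential = ld.ToyPotential.harmonic(1.0)
    protocol = ld.PullingProtocol(k_s=50.0, v=0.25, z0=0.0, temperature=300.0)
    params = ld.LangevinParams(gamma=0.2, dt=2.5e-4, temperature=300.0, seed=42)
    logs = ld.simulate_pulling(potential, protocol, params, n_traces=200, span=10.0,
                               output_stride=16)
    grid = np.linspace(0.0, 10.0, 101)
    traces = [ld.work_trace(lg, protocol, grid) for lg in logs]
    profile = ld.jarzynski_profile(traces, protocol.kT)
    reference = ld.stiff_spring_free_energy(potential, protocol, grid)
    return SimpleNamespace(
        potential=potential, protocol=protocol, params=params, logs=logs,
        grid=grid, traces=traces, profile=profile, reference=reference,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
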