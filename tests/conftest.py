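import numpy as np
import pytest

import mdligand as ml


@pytest.fixture(scope="session")
def demo():
    """The deterministic demo complex (topology, trajectory, ground truth)."""
    return ml.demo_fixture(0)


@pytest.fixture(scope="session")
def recovery_run():
    """Isotropic-fluctuation run for RMSF recovery checks.

    200 residues, sigma = 0.02 nm per coordinate, 2000 stationary frames,
    no correlated blocks (superposition absorbs part of any spatially
    coherent cluster motion, so the isotropic benchmark keeps residues
    independent).  The residue count is large because fitting to the mean
    structure removes ~(1 + 3 r_i^2/<r^2>)/N of each residue's variance --
    an O(1/N) finite-size bias that is largest at the ends of the extended
    synthetic chain.
    """
    spec = ml.SyntheticSpec(
        n_residues=200, n_frames=2000, fluct_sigma=0.02, seed=11
    )
    top = ml.build_topology(spec)
    traj, gt = ml.generate_trajectory(top, spec)
    return spec, top, traj, gt


@pytest.fixture(scope="session")
def covariance_run():
    """Block-correlated run for covariance recovery: a rho = 1 triple, a
    rho = -0.8 pair, everything else independent."""
    spec = ml.SyntheticSpec(
        n_residues=60,
        n_frames=2000,
        fluct_sigma=0.02,
        correlation_blocks=[
            ml.CorrelationBlock((10, 11, 12), 1.0),
            ml.CorrelationBlock((20, 21), -0.8),
        ],
        seed=11,
    )
    top = ml.build_topology(spec)
    traj, gt = ml.generate_trajectory(top, spec)
    return spec, top, traj, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def point_topology(
    n, radius=1.7, charge=0.0, sigma=0.34, epsilon=0.086, element="C"
):
    """Bare n-atom topology (single residue) for closed-form energy checks."""
    from mdligand.model import Atom, Residue, SystemTopology

    radii = np.broadcast_to(np.asarray(radius, dtype=float), (n,))
    charges = np.broadcast_to(np.asarray(charge, dtype=float), (n,))
    sigmas = np.broadcast_to(np.asarray(sigma, dtype=float), (n,))
    epsilons = np.broadcast_to(np.asarray(epsilon, dtype=float), (n,))
    elements = (
        [element] * n if isinstance(element, str) else list(element)
    )
    atoms = [
        Atom(i, f"{elements[i]}{i + 1}", elements[i], 0, "UNK",
             float(charges[i]), float(sigmas[i]), float(epsilons[i]),
             float(radii[i]))
        for i in range(n)
    ]
    return SystemTopology(
        atoms, [Residue(0, "UNK", tuple(range(n)), 1)], {"protein": (0,)}
    )
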