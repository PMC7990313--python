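"""Shared fixtures: ideal-geometry peptides and latent-mode trajectories.

Everything is generated programmatically at test time; heavyweight builders
are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

from pepdyn.model import Species
from pepdyn.synthetic import (
    BackboneSpec,
    LatentModeSpec,
    build_mixture,
    build_peptide,
    build_two_strand_sheet,
    combine_chains,
    hairpin_conformation,
    simulate,
)


@pytest.fixture(scope="session")
def helix15():
    """Ideal 15-residue poly-Ala alpha-helix."""
    return build_peptide(BackboneSpec("A" * 15, conformation="helix"))


@pytest.fixture(scope="session")
def strand10():
    """Single fully extended 10-mer (no bonding partner)."""
    return build_peptide(BackboneSpec("A" * 10, conformation="strand"))


@pytest.fixture(scope="session")
def hairpin20():
    """Strand / 4-residue turn / strand hairpin."""
    return build_peptide(
        BackboneSpec("A" * 20, conformation=hairpin_conformation(20, turn_start=8, turn_len=4))
    )


@pytest.fixture(scope="session")
def sheet_dimer():
    """Two-chain antiparallel beta-sheet (chains A, B)."""
    return build_two_strand_sheet(8)


@pytest.fixture(scope="session")
def small_mixture():
    """2 Abeta42 + 2 SST14 chains, sparsely placed in a 12 nm box."""
    return build_mixture(2, Species.ABETA42, 2, Species.SST14, box=12.0, seed=1)


def make_group_system(n_chains=4, n_res=8, spacing=2.0):
    """n identical coil chains side by side, labelled A, B, C, ..."""
    tmpl = build_peptide(BackboneSpec("A" * n_res, conformation="coil"))
    parts = [
        (chr(ord("A") + k), tmpl, tmpl.coords + np.array([spacing * k, 0.0, 0.0]))
        for k in range(n_chains)
    ]
    return combine_chains(parts)


def latent_mode_trajectory(
    groups=(("A", "B"), ("C",), ("D",)),
    n_res=8,
    sigma_mode=0.1,
    noise_sd=0.004,
    n_frames=2000,
    seed=7,
    modes_per_group=2,
):
    """Coherent latent modes on the C-alpha atoms of each chain group plus
    isotropic noise: the parameter-recovery workhorse."""
    n_chains = sum(len(g) for g in groups)
    system = make_group_system(n_chains=n_chains, n_res=n_res)
    rng = np.random.default_rng(seed)
    modes = []
    for gi, g in enumerate(groups):
        atoms = np.concatenate(
            [system.select(chains=[lab], names="CA").indices for lab in g]
        )
        for mi in range(modes_per_group):
            modes.append(
                LatentModeSpec.coherent(
                    f"m{gi}_{mi}", atoms, rng.standard_normal(3), sigma=sigma_mode, tau=10.0
                )
            )
    traj, gt = simulate(
        system, modes=modes, noise_sd=noise_sd, n_frames=n_frames, dt=1.0, seed=seed
    )
    group_of = {lab: gi for gi, g in enumerate(groups) for lab in g}
    return traj, gt, group_of


@pytest.fixture(scope="session")
def recovery_traj():
    return latent_mode_trajectory()


def rand_index(a, b) -> float:
    """Pair-counting agreement between two labelings."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    agree = 0
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            agree += (a[i] == a[j]) == (b[i] == b[j])
    return agree / total
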