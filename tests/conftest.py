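import numpy as np
import pytest

from oxescape.brownian import (LigandDynamics, ReplicateDesign,
                               make_fixture_set, make_variant_pair)


@pytest.fixture(scope="session")
def variant_pair():
    return make_variant_pair()


@pytest.fixture(scope="session")
def bundle(tmp_path_factory, variant_pair):
    """Two-variant synthetic bundle at 25% of the study durations.

    Session-scoped: several test modules re-analyze the same bundle.
    """
    narrow, wide = variant_pair
    out = tmp_path_factory.mktemp("bundle")
    manifest = make_fixture_set(
        {"narrow": narrow, "wide": wide}, out, seed=42,
        design=ReplicateDesign(), time_scale=0.25,
        dynamics=LigandDynamics())
    return out, manifest


def toy_trajectory(coords, atom_names=None, resids=None, resnames=None,
                   chains=None, elements=None, ligands=None, site=None,
                   dt_ns=0.2):
    """Hand-built Trajectory for unit tests; coords is (frames, atoms, 3)."""
    from oxescape.trajectory import Topology, Trajectory

    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    topo = Topology(
        atom_ids=np.arange(1, n + 1),
        atom_names=np.array(atom_names or ["C"] * n),
        residue_ids=np.array(resids if resids is not None else np.arange(1, n + 1)),
        residue_names=np.array(resnames or ["RES"] * n),
        chain_ids=np.array(chains or ["A"] * n),
        elements=np.array(elements or [""] * n),
        ligand_selectors={k: np.asarray(v) for k, v in (ligands or {}).items()},
        site_selector=None if site is None else np.asarray(site),
    )
    times = np.arange(coords.shape[0]) * dt_ns
    return Trajectory(topology=topo, times=times, coords=coords)
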