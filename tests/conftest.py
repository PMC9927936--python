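import numpy as np
import pytest

from gpcrtraj import AtomRecord, Trajectory
from gpcrtraj.synthetic import SyntheticSpec, simulate_trajectory


def pdb_atom_line(serial, name, resname, chain, resid, x, y, z,
                  altloc=" ", icode=" ", element=None, hetero=False):
    """Hand-rolled fixed-column PDB ATOM/HETATM line for raw-text fixtures."""
    record = "HETATM" if hetero else "ATOM  "
    name_field = name if len(name) == 4 else f" {name:<3s}"
    element = element or name[0]
    return (
        f"{record}{serial:5d} {name_field}{altloc}{resname:<3s} {chain}"
        f"{resid:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


def make_pdb_text(models):
    """models: list of lists of ATOM lines -> multi-model PDB text."""
    out = []
    for i, lines in enumerate(models, start=1):
        out.append(f"MODEL     {i:4d}")
        out.extend(lines)
        out.append("ENDMDL")
    out.append("END")
    return "\n".join(out) + "\n"


def simple_trajectory(coords, atom_specs=None, interval=1.0):
    """Trajectory from raw coords (n_frames, n_atoms, 3) with generic CA topology."""
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    if atom_specs is None:
        atom_specs = [("A", i + 1, "ALA", "CA", "C", False) for i in range(n_atoms)]
    records = [
        AtomRecord(i + 1, aname, rname, rid, chain, elem, het)
        for i, (chain, rid, rname, aname, elem, het) in enumerate(atom_specs)
    ]
    return Trajectory(records, coords, frame_interval_ns=interval)


@pytest.fixture(scope="session")
def small_synthetic():
    """A short default-condition synthetic trajectory shared across tests."""
    spec = SyntheticSpec(n_frames=60, seed=11, include_ligand=True)
    traj, gt = simulate_trajectory(spec)
    return spec, traj, gt


@pytest.fixture(scope="session")
def noiseless_synthetic():
    """Jitter-free run: planted values should be recovered exactly."""
    spec = SyntheticSpec(n_frames=40, seed=5, noise_sd_A=0.0, include_ligand=True)
    traj, gt = simulate_trajectory(spec)
    return spec, traj, gt
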