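import numpy as np
import pytest

from sarm1tk import DualEffectorParams


@pytest.fixture
def biphasic_params():
    """Activator with a self-inhibitory limb two orders above its Ka."""
    return DualEffectorParams(
        vmax=18.12, km=70.0, x_act=10.0, y_res=0.1, ka=1.0, ki=100.0,
        n_act=1.0, n_inh=1.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20210608)


def random_valid_params(rng, n=1):
    """Seeded draws of valid dual-effector parameter sets."""
    out = []
    for _ in range(n):
        out.append(
            DualEffectorParams(
                vmax=float(rng.uniform(0.5, 50)),
                km=float(rng.uniform(10, 500)),
                x_act=float(rng.uniform(0, 50)),
                y_res=float(rng.uniform(0.01, 1.0)),
                ka=float(10 ** rng.uniform(-1, 3)),
                ki=float(10 ** rng.uniform(-1, 4)),
                n_act=float(rng.uniform(0.5, 4)),
                n_inh=float(rng.uniform(0.5, 4)),
            )
        )
    return out if n > 1 else out[0]


def write_toy_pdb(path, coords, chain="A", start_resnum=1, resname="ALA"):
    """Minimal single-chain Cα-only PDB for structure tests."""
    lines = []
    for i, (x, y, z) in enumerate(np.asarray(coords, float)):
        lines.append(
            "ATOM  %5d  CA  %3s %s%4d    %8.3f%8.3f%8.3f  1.00  0.00           C"
            % (i + 1, resname, chain, start_resnum + i, x, y, z)
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
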