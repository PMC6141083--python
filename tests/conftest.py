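"""Shared fixtures: small structures built programmatically and one
session-scoped default pulling run reused by the slower tests."""

from __future__ import annotations

import numpy as np
import pytest

from metox.structure import Atom, Structure, ParamTable
from metox.synth import gen_tripeptide


@pytest.fixture(scope="session")
def param_table() -> ParamTable:
    return ParamTable.default()


@pytest.fixture()
def tripeptide() -> Structure:
    return gen_tripeptide()


def make_water(origin, resid: int = 1, chain: str = "W") -> list[Atom]:
    """TIP3P-like water heavy/H atoms at an arbitrary origin."""
    o = np.asarray(origin, dtype=float)
    return [
        Atom(0, "OH2", "O", "HOH", resid, chain, o),
        Atom(0, "H1", "H", "HOH", resid, chain, o + [0.9572, 0.0, 0.0]),
        Atom(0, "H2", "H", "HOH", resid, chain,
             o + [-0.2400, 0.9266, 0.0]),
    ]


@pytest.fixture()
def four_atom_pdb(tmp_path):
    """A 4-atom single-model PDB file written with exact fixed columns."""
    lines = [
        "ATOM      1  N   ALA A   1      11.104  13.207   2.100  1.00  0.00           N",
        "ATOM      2  CA  ALA A   1      12.560  13.300   2.000  1.00  0.00           C",
        "ATOM      3  C   ALA A   1      13.123  14.650   2.455  1.00  0.00           C",
        "ATOM      4  O   ALA A   1      12.440  15.676   2.409  1.00  0.00           O",
        "END",
    ]
    path = tmp_path / "four_atoms.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def default_pulling_run():
    """One seed-1 constant-velocity pulling run with default model and
    protocol; shared by trace-shape, regression and rupture tests."""
    from metox.pulling import build_toy_model, run_cv_pulling, PullParams

    model = build_toy_model(seed=1)
    trace, traj = run_cv_pulling(model, PullParams(), seed=1,
                                 sasa_n_points=480)
    return model, trace, traj
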