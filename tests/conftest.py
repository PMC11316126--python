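"""Shared fixtures: synthetic lattices and analyzed pipeline results.

Expensive pipeline runs are session-scoped so individual tests stay
cheap; everything is generated programmatically — no stored coordinate
files.
"""

from __future__ import annotations

import numpy as np
import pytest

from crossbeta import LatticeSpec, build_lattice
from crossbeta.config import RunConfig
from crossbeta.pipeline import analyze


MODEL_SEQUENCE = "LYIQNL"


@pytest.fixture(scope="session")
def class3_lattice():
    return build_lattice(LatticeSpec(class_id=3, sequence=MODEL_SEQUENCE))


@pytest.fixture(scope="session")
def class8_lattice():
    return build_lattice(LatticeSpec(class_id=8, sequence="LYIQWL"))


@pytest.fixture(scope="session")
def class3_result(class3_lattice):
    return analyze(class3_lattice, RunConfig(), with_energies=True)


@pytest.fixture(scope="session")
def class1_result():
    s = build_lattice(LatticeSpec(class_id=1, sequence=MODEL_SEQUENCE))
    return analyze(s, RunConfig(), with_energies=True)


@pytest.fixture(scope="session")
def class8_result(class8_lattice):
    return analyze(class8_lattice, RunConfig(), with_energies=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240809)


def make_minimal_pdb(path, cell="CRYST1   10.000   10.000   10.000  90.00  90.00  90.00 P 1           1"):
    lines = [
        cell,
        "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C",
        "END",
    ]
    path.write_text("\n".join(lines) + "\n")
    return path
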