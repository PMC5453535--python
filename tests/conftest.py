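"""Shared fixtures: synthetic models and randomized multi-residue scenes."""

from __future__ import annotations

import numpy as np
import pytest

from smnprofiler.structure_io import Model, StructureEnsemble
from smnprofiler.synthetic import _arg, _asp, _gln_acceptor, _his, _lys

TEMPLATES = {
    "ASP": _asp,
    "LYS": _lys,
    "ARG": _arg,
    "HIS": _his,
    "GLN": _gln_acceptor,
}


def random_model(rng: np.random.Generator, n_residues: int = 10,
                 box: float = 25.0, index: int = 1) -> Model:
    """A scene of template residues at random positions in a cubic box.

    Dense enough that charged pairs and donor/acceptor pairs regularly fall
    inside and outside the detection cutoffs, which is what the brute-force
    oracle comparisons need.
    """
    names = list(TEMPLATES)
    residues = []
    for i in range(n_residues):
        res_type = names[rng.integers(len(names))]
        origin = tuple(rng.uniform(0.0, box, 3).round(3))
        residues.append(TEMPLATES[res_type]("A" if i % 2 else "B", i + 1, origin))
    return Model(index=index, residues=residues)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def crowded_model(rng):
    return random_model(rng, n_residues=14, box=22.0)


@pytest.fixture
def crowded_ensemble(rng):
    models = [random_model(rng, n_residues=10, box=20.0, index=k + 1) for k in range(5)]
    return StructureEnsemble(pdb_id="scene", models=models)
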