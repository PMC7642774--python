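import math

import numpy as np
import pytest

from mrprep import CoarseModel, make_ideal_helix


def model_from_ca(ca, names=None, residue_index=None, label="toy"):
    """Minimal CoarseModel from a Cα trace (no Cβ/O atoms)."""
    ca = np.asarray(ca, dtype=float).reshape(-1, 3)
    n = ca.shape[0]
    if names is None:
        names = tuple(["ALA"] * n)
    if residue_index is None:
        residue_index = np.arange(1, n + 1)
    nan = math.nan
    return CoarseModel(
        residue_index=residue_index,
        residue_name=names,
        ca=ca,
        cb=np.full((n, 3), nan),
        o=np.full((n, 3), nan),
        b_ca=np.zeros(n),
        b_cb=np.full(n, nan),
        b_o=np.full(n, nan),
        label=label,
    )


def collinear_chain(n, spacing=3.8):
    """n residues on the z axis at the given spacing."""
    ca = np.zeros((n, 3))
    ca[:, 2] = spacing * np.arange(n)
    return model_from_ca(ca, label="collinear")


@pytest.fixture
def helix20():
    return make_ideal_helix(20)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
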