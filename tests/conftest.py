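"""Shared fixtures: tiny hand-built molecules and small synthetic datasets."""

import numpy as np
import pytest

from nmrkrr.representations import RepParams
from nmrkrr.structures import Dataset, LabelRecord, Structure
from nmrkrr.synthetic import OracleParams, label_dataset, gen_structures


@pytest.fixture
def h2():
    return Structure("h2", ("H", "H"), np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.74]]))


@pytest.fixture
def water():
    # experimental-ish geometry: O at origin, O–H 0.9572 Å, H–O–H 104.5°
    ang = np.deg2rad(104.5)
    return Structure("h2o", ("O", "H", "H"), np.array([
        [0.0, 0.0, 0.0],
        [0.9572, 0.0, 0.0],
        [0.9572 * np.cos(ang), 0.9572 * np.sin(ang), 0.0],
    ]))


@pytest.fixture
def methane():
    d = 1.09 / np.sqrt(3.0)
    return Structure("ch4", ("C", "H", "H", "H", "H"), np.array([
        [0.0, 0.0, 0.0], [d, d, d], [d, -d, -d], [-d, d, -d], [-d, -d, d],
    ]))


def only_param(d: Dataset, param: str) -> Dataset:
    """Dataset restricted to one parameter's labels (cuts representation cost)."""
    return Dataset(dict(d.structures), [r for r in d.labels if r.param == param])


@pytest.fixture(scope="session")
def rp_default():
    return RepParams()


@pytest.fixture(scope="session")
def tiny_dataset():
    """12 labelled structures — big enough for 5-fold ensembles, fast."""
    structures = gen_structures(12, seed=21)
    return label_dataset(structures, OracleParams(seed=21))


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random rotation (QR of a Gaussian matrix) plus translation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(scale=5.0, size=3)
    return q, t


def transform(s: Structure, q: np.ndarray, t: np.ndarray) -> Structure:
    return Structure(s.id, s.elements, s.coords @ q.T + t)
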