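import numpy as np
import pandas as pd
import pytest

from coelute.io_profiles import AnnotationTable, ProfileMatrix, Separation


@pytest.fixture
def small_matrix() -> ProfileMatrix:
    values = np.array(
        [
            [0.0, 1.0, 5.0, 2.0, 0.0],
            [3.0, 4.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 2.0, 6.0],
        ]
    )
    return ProfileMatrix(
        separation=Separation.SEC, replicate=1, proteins=["A", "B", "C"], values=values
    )


def make_annotations(
    proteins, compartment="cytosol", mass=50.0, exclude_tm=False
) -> AnnotationTable:
    n = len(proteins)
    as_list = lambda v: list(v) if isinstance(v, (list, tuple, np.ndarray)) else [v] * n
    return AnnotationTable(
        pd.DataFrame(
            {
                "compartment": as_list(compartment),
                "monomer_mass_kda": as_list(mass),
                "exclude_tm": as_list(exclude_tm),
            },
            index=pd.Index(proteins, name="protein_id"),
        )
    )


@pytest.fixture
def annotations_factory():
    return make_annotations


def gaussian_profile(n, mus, sigmas, amps):
    x = np.arange(1, n + 1, dtype=float)
    out = np.zeros(n)
    for mu, s, a in zip(np.atleast_1d(mus), np.atleast_1d(sigmas), np.atleast_1d(amps)):
        out += a * np.exp(-((x - mu) ** 2) / (2 * s**2))
    return out
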