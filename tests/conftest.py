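import numpy as np
import pandas as pd
import pytest

from methylstate.io import BetaMatrix, GeneModel, ProbeAnnotation, SampleDesign
from methylstate.simulate import generate, small_config


@pytest.fixture()
def toy_matrix() -> tuple[BetaMatrix, ProbeAnnotation, SampleDesign]:
    """Three probes, two samples per condition, hand-chosen betas."""
    probes = pd.Index(["cg1", "cg2", "cg3"], name="probe_id")
    beta = pd.DataFrame(
        {
            "a1": [0.10, 0.50, 0.90],
            "a2": [0.10, 0.50, 0.90],
            "b1": [0.10, 0.50, 0.90],
            "b2": [0.10, 0.50, 0.90],
        },
        index=probes,
    )
    annotation = ProbeAnnotation(
        pd.DataFrame({"chrom": ["chr1", "chr1", "chr2"], "pos": [99, 500, 42]},
                     index=probes)
    )
    design = SampleDesign({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
    return BetaMatrix(beta), annotation, design


@pytest.fixture()
def toy_genes() -> list[GeneModel]:
    return [
        GeneModel("gplus", "chr1", "+", 1000, 2000),
        GeneModel("gminus", "chr1", "-", 2000, 1000),
    ]


@pytest.fixture(scope="session")
def small_bundle():
    """A 6k-CpG / 400-gene noise-free bundle shared across tests."""
    import dataclasses

    cfg = dataclasses.replace(small_config(11), noise_sd=0.0)
    return generate(cfg)


@pytest.fixture(scope="session")
def small_noisy_bundle():
    """Same scale with the default logit-noise model."""
    return generate(small_config(23))


def random_annotation(rng: np.random.Generator, n: int, chroms=("chr1", "chr2")) -> ProbeAnnotation:
    probes = pd.Index([f"cg{i:05d}" for i in range(n)], name="probe_id")
    return ProbeAnnotation(
        pd.DataFrame(
            {
                "chrom": rng.choice(chroms, size=n),
                "pos": rng.integers(0, 50_000, size=n),
            },
            index=probes,
        )
    )
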