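import numpy as np
import pandas as pd
import pytest

from plsassay import (
    ExpressionMatrix,
    GeneSet,
    PrognosticSignature,
    RankedList,
    build_signature,
)


@pytest.fixture
def toy_signature() -> PrognosticSignature:
    return build_signature(
        GeneSet("poor", ("P1", "P2", "P3")),
        GeneSet("good", ("G1", "G2", "G3")),
        GeneSet("hk", ("H1", "H2")),
    )


@pytest.fixture
def counts_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    genes = ["P1", "P2", "P3", "G1", "G2", "G3", "H1", "H2", "B1", "B2"]
    samples = ["s1", "s2", "s3", "s4"]
    values = pd.DataFrame(
        rng.integers(10, 1000, size=(len(genes), len(samples))).astype(float),
        index=genes,
        columns=samples,
    )
    meta = pd.DataFrame({"condition": ["case", "case", "ref", "ref"]}, index=samples)
    return ExpressionMatrix(values=values, scale="counts", sample_meta=meta)


def make_ranked(n: int = 20, seed: int = 0) -> RankedList:
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n)]
    return RankedList.from_unsorted(genes, rng.normal(0, 1, n))
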