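import numpy as np
import pytest

from microclone.core import CountMatrix, MutationCall


def make_matrix(alt_rows, depth_rows, chrom="chr1", samples=None):
    """Small CountMatrix from lists of per-sample alt/depth vectors."""
    alt = np.asarray(alt_rows)
    depth = np.asarray(depth_rows)
    n, s = alt.shape
    calls = [MutationCall(chrom, 100 + 10 * i, "C", "T") for i in range(n)]
    samples = samples or [f"s{j + 1}" for j in range(s)]
    return CountMatrix(calls, samples, alt, depth)


@pytest.fixture
def mk_matrix():
    return make_matrix


@pytest.fixture(scope="session")
def toy_annotation():
    from microclone.synthetic import make_toy_annotation

    return make_toy_annotation(n_genes=400, seed=3)
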