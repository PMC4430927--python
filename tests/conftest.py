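import numpy as np
import pytest

import methylpc as mp
from methylpc.io import MethylationMatrix


@pytest.fixture(scope="session")
def cohort():
    """Default study-scale synthetic cohort (seed 0) with its PCA fit."""
    cfg = mp.default_config(seed=0)
    matrix, meta, annotation, genes, truth = mp.simulate_cohort(cfg)
    result = mp.fit_pca(matrix)
    return {
        "config": cfg,
        "matrix": matrix,
        "meta": meta,
        "annotation": annotation,
        "genes": genes,
        "truth": truth,
        "result": result,
    }


@pytest.fixture()
def toy_matrix():
    """3 probes x 2 samples with a single variance direction.

    Covariance is [[1,-1],[-1,1]] (1/(N-1) convention), eigenvalues {2,0},
    PC1 = (1,-1)/sqrt(2), projections (sqrt2, -sqrt2, 0)."""
    X = np.array([[1.0, -1.0], [-1.0, 1.0], [0.0, 0.0]])
    return MethylationMatrix(["p1", "p2", "p3"], ["s1", "s2"], X)


def random_matrix(seed, n=50, m=10, offset=False):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, m))
    if offset:
        X = X + rng.choice([-2.0, 2.0], size=n)[:, None]
    return MethylationMatrix(
        [f"p{i}" for i in range(n)], [f"s{j}" for j in range(m)], X
    )
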