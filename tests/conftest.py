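import numpy as np
import pytest

import ranktype as rt


@pytest.fixture
def tiny_expression() -> rt.ExpressionMatrix:
    """4 genes x 4 samples with unambiguous per-column orderings."""
    values = np.array([
        [1.0, 4.0, 2.0, 8.0],
        [2.0, 3.0, 1.0, 4.0],
        [3.0, 2.0, 4.0, 2.0],
        [4.0, 1.0, 3.0, 1.0],
    ])
    return rt.ExpressionMatrix(["g1", "g2", "g3", "g4"], ["s1", "s2", "s3", "s4"], values)


@pytest.fixture(scope="session")
def small_cohort():
    """A small 4-class cohort: quick to generate, strong planted structure."""
    spec = rt.SyntheticSpec(n_genes=500, n_samples=120, markers_per_subtype=20, seed=11)
    X, truth = rt.generate(spec)
    return spec, X, truth


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """The small cohort fitted once; shared by classifier/metric tests."""
    spec, X, truth = small_cohort
    return rt.fit_pipeline(X, truth.labels)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Zero noise, zero gene-level batch shift: planted reversals are exact."""
    batches = [
        rt.BatchSpec("batch1", 27, "identity", (), shift_sd=0.0),
        rt.BatchSpec("batch2", 27, "affine", (2.0, 1.0), shift_sd=0.0),
        rt.BatchSpec("batch3", 26, "power", (0.7,), shift_sd=0.0),
    ]
    spec = rt.SyntheticSpec(n_genes=300, n_samples=80, markers_per_subtype=10,
                            batches=batches, noise_sd=0.0, seed=5)
    X, truth = rt.generate(spec)
    return spec, X, truth


def perfect_pairs(X, truth, subtype, limit=5):
    """(up, down) marker pairs whose indicator is exactly 1 in the subtype
    and 0 everywhere else."""
    R = rt.rank_transform(X)
    row = {g: i for i, g in enumerate(R.gene_ids)}
    in_s = np.array([truth.labels[s] == subtype for s in R.sample_ids])
    out = []
    for u in truth.markers[subtype]["up"]:
        for d in truth.markers[subtype]["down"]:
            ind = R.ranks[row[u]] > R.ranks[row[d]]
            if ind[in_s].all() and not ind[~in_s].any():
                out.append((u, d))
                if len(out) == limit:
                    return out
    return out


@pytest.fixture(scope="session")
def synthetic_fit():
    """Default study conditions, batch 3 held out, fitted once per session."""
    spec = rt.SyntheticSpec(seed=1)
    train, test, truth = rt.make_train_test(spec, ["batch3"])
    labels = {s: truth.labels[s] for s in train.sample_ids}
    result = rt.fit_pipeline(train, labels)
    return spec, train, test, truth, result


def planted_marker_pair(truth: rt.SyntheticTruth, subtype: str) -> tuple[str, str]:
    """An (up, down) marker pair of a subtype, for oriented-feature checks."""
    return truth.markers[subtype]["up"][0], truth.markers[subtype]["down"][0]
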