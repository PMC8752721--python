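import numpy as np
import pandas as pd
import pytest

from keyreg import ExpressionData, SimulationSpec, simulate_regulators


@pytest.fixture(scope="session")
def small_dataset():
    """20 regulators (5 planted), 40 samples, strong effect."""
    spec = SimulationSpec(
        n_samples=40,
        n_regulators=20,
        n_bona_fide=5,
        targets_min=3,
        targets_max=10,
        effect_size=3.0,
        seed=7,
    )
    return simulate_regulators(spec)


@pytest.fixture
def two_group_expr():
    """Deterministic continuous matrix with one clearly shifted gene."""
    rng = np.random.default_rng(11)
    n = 12
    values = rng.normal(5.0, 1.0, size=(30, n))
    values[0, n // 2:] += 4.0
    samples = [f"S{i}" for i in range(n)]
    ann = pd.DataFrame({"group": ["A"] * (n // 2) + ["B"] * (n // 2)}, index=samples)
    df = pd.DataFrame(values, index=[f"G{i}" for i in range(30)], columns=samples)
    return ExpressionData(values=df, annotations=ann, kind="continuous")


def make_counts(n_genes=40, n_per_group=6, fold_genes=(), fold=1.0, seed=0, mean=50.0,
                dispersion=0.1):
    """NB-distributed two-group count data with optional planted fold changes."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    base = rng.uniform(mean / 2, mean * 2, size=n_genes)
    mu = np.tile(base[:, None], (1, n))
    for g in fold_genes:
        mu[g, n_per_group:] *= fold
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    samples = [f"S{i}" for i in range(n)]
    ann = pd.DataFrame({"group": ["A"] * n_per_group + ["B"] * n_per_group},
                       index=samples)
    df = pd.DataFrame(counts.astype(float), index=[f"G{i}" for i in range(n_genes)],
                      columns=samples)
    return ExpressionData(values=df, annotations=ann, kind="counts")
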