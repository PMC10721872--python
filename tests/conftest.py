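import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from krdsig import ExpressionMatrix, GeneSignature, SurvivalTable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """2 genes x 2 samples with values [[1, 3], [2, 2]]."""
    return ExpressionMatrix(["g1", "g2"], ["s1", "s2"], [[1.0, 3.0], [2.0, 2.0]])


def random_matrix(
    rng: np.random.Generator,
    n_genes: int,
    n_samples: int,
    modality: str = "bulk",
) -> ExpressionMatrix:
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    if modality == "bulk":
        values = rng.normal(5.0, 2.0, (n_genes, n_samples))
        return ExpressionMatrix(genes, samples, values, "bulk", "normalized")
    values = rng.uniform(0.0, 4.0, (n_genes, n_samples))
    return ExpressionMatrix(genes, samples, values, "scrna", "log2_tpm10p1")


def toy_screen_dataset():
    """Six genes over 100 samples where exactly g1 (up) and g2 (down) are
    built to pass both the DE and survival filters.

    A latent frailty u drives survival; g1/g2 load on both the group
    contrast and u, g3 is differentially expressed but independent of u,
    g4 tracks u but not the groups, g5/g6 are pure noise.
    """
    rng = np.random.default_rng(123)
    n = 100
    group = np.array([1.0] * 50 + [0.0] * 50)
    u = rng.normal(size=n)
    eps = lambda s: rng.normal(0.0, s, size=n)
    values = np.vstack(
        [
            3.0 * group + 2.0 * u + eps(0.3),          # g1: DE up + survival
            10.0 - 3.0 * group - 2.0 * u + eps(0.3),   # g2: DE down + survival
            3.0 * group + eps(1.0),                    # g3: DE only
            2.0 * u + eps(0.3),                        # g4: survival only
            eps(1.0),                                  # g5: noise
            eps(1.0),                                  # g6: noise
        ]
    )
    samples = [f"s{j:03d}" for j in range(n)]
    matrix = ExpressionMatrix(
        [f"g{i}" for i in range(1, 7)], samples, values, "bulk", "normalized"
    )
    labels = pd.DataFrame(
        {"sample": samples,
         "label": np.where(group == 1, "mutation_like", "wildtype_like")}
    )
    hazard = 1e-3 * np.exp(1.5 * u)
    times = rng.exponential(1.0 / hazard)
    survival = SurvivalTable(samples, times, np.ones(n, dtype=int))
    return matrix, labels, survival


@pytest.fixture
def toy_screen():
    return toy_screen_dataset()


@pytest.fixture
def simple_signature() -> GeneSignature:
    return GeneSignature("SIG", ["g1", "g2"], ["g3"])
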