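import numpy as np
import pandas as pd
import pytest

from relapsig import (
    CnvSpec,
    ExpressionSpec,
    FeatureMatrix,
    PipelineConfig,
    SyntheticSpec,
    VariantSpec,
    generate_cohort,
)


@pytest.fixture(scope="session")
def labels40():
    return {
        f"S{i:02d}": ("relapse" if i <= 20 else "relapse_free") for i in range(1, 41)
    }


@pytest.fixture(scope="session")
def y40():
    return np.array([1] * 20 + [0] * 20)


def tiny_spec(seed: int = 0, effect: float = 2.0) -> SyntheticSpec:
    """Small cohort for fast end-to-end tests (two matrix types)."""
    return SyntheticSpec(
        n_relapse=20,
        n_free=20,
        matrices={
            "gene": ExpressionSpec(120, 6, effect, 0.5, 3, 1, prefix="GENE"),
            "mirna": ExpressionSpec(80, 5, effect, 0.5, 3, 1, prefix="MIR"),
        },
        cnv=CnvSpec(n_altered=4, amplitude=0.6, penetrance=0.8),
        variants=VariantSpec(n_genes=60, n_signal_genes=8),
        seed=seed,
    )


@pytest.fixture()
def tiny_bundle():
    return generate_cohort(tiny_spec(seed=3))


@pytest.fixture()
def fast_config():
    return PipelineConfig(mc_reps=25, boot_reps=200, ace_forests=5, ace_trees=30,
                          seed=0)


def matrix_from_array(X, data_type="gene", prefix="F", sample_ids=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_feat, n_samp = X.shape
    if sample_ids is None:
        sample_ids = [f"S{i:02d}" for i in range(1, n_samp + 1)]
    ids = [f"{prefix}{i:03d}" for i in range(1, n_feat + 1)]
    return FeatureMatrix(data_type, pd.DataFrame(X, index=ids, columns=sample_ids))
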