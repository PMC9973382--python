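import numpy as np
import pandas as pd
import pytest

from panhallmark.io_formats import ExpressionMatrix, SignatureSet
from panhallmark.synthdata import (AlterationSpec, CohortConfig, PlantedEffect,
                                   generate_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_expression(rng):
    """50 genes x 10 samples with 3 disjoint signatures of 8 genes."""
    genes = [f"G{i:03d}" for i in range(50)]
    values = pd.DataFrame(rng.lognormal(3, 1, size=(50, 10)), index=genes,
                          columns=[f"S{j}" for j in range(10)])
    sigs = [SignatureSet(f"SIG{k}", tuple(genes[8 * k: 8 * k + 8]))
            for k in range(3)]
    return ExpressionMatrix(values), sigs


def make_cohort(seed=0, delta=0.0, frequency=0.3, n_types=4, n_per_subtype=25,
                affected_types=None, n_alterations=3, n_signatures=4):
    types = [f"TT{i + 1:02d}" for i in range(n_types)]
    if affected_types is None:
        affected_types = tuple(types[:2])
    alterations = []
    for k in range(n_alterations):
        effects = ()
        if k == 0 and delta != 0:
            effects = (PlantedEffect("SIG01", delta, tuple(affected_types)),)
        alterations.append(AlterationSpec(f"ALT{k + 1:02d}", "mutation",
                                          frequency, effects))
    cfg = CohortConfig(n_tumor_types=n_types, subtypes_per_type=2,
                       samples_per_subtype=n_per_subtype, n_genes=200,
                       n_signatures=n_signatures, genes_per_signature=15,
                       alterations=alterations, seed=seed)
    return cfg, generate_cohort(cfg)


@pytest.fixture
def null_cohort():
    return make_cohort(seed=1, delta=0.0)[1]
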