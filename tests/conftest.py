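import numpy as np
import pandas as pd
import pytest

from gliomamap import synthetic


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Planted 60/22/18 cohort sequenced at effectively infinite depth."""
    return synthetic.generate_planted_cohort(
        n_patients=2, samples_per_patient=6, seed=4, depth=None, detect_min_alt=1
    )


@pytest.fixture(scope="session")
def noisy_cohort():
    """Planted cohort at depth 500 with a detection threshold of 3 alt reads."""
    return synthetic.generate_planted_cohort(
        n_patients=4, samples_per_patient=6, seed=11, depth=500, detect_min_alt=3
    )


@pytest.fixture(scope="session")
def planted_expression():
    """40-sample expression matrix with effect 2, noise 1 over 4 gene sets."""
    _, _, truth = synthetic.generate_planted_cohort(
        n_patients=5, samples_per_patient=8, seed=3, depth=None, detect_min_alt=1
    )
    gene_sets = synthetic.default_gene_sets(1000, 50)
    expr = synthetic.generate_expression(
        truth, gene_sets, n_genes=1000, effect=2.0, noise_sd=1.0, seed=3
    )
    return expr, gene_sets, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_calls(carriers: dict[str, set[str]], patient: str = "P1") -> pd.DataFrame:
    """Variant-call table from an explicit variant -> carrier-set map."""
    rows = []
    for key, samples in carriers.items():
        for sid in samples:
            rows.append(
                {
                    "patient_id": patient,
                    "sample_id": sid,
                    "variant_key": key,
                    "vaf": 0.25,
                    "alt_reads": 25,
                    "depth": 100,
                    "class": "SNV",
                }
            )
    return pd.DataFrame(rows)
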