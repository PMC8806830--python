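import numpy as np
import pandas as pd
import pytest

import irlpair as ir


@pytest.fixture(scope="session")
def cohort():
    """Default prognostic synthetic cohort (the package's study conditions)."""
    return ir.generate_cohort(ir.default_config(seed=11))


@pytest.fixture(scope="session")
def valid_pairs(cohort):
    pm = ir.build_pair_matrix(cohort.expression, cohort.truth.de_lnc_ids)
    return ir.filter_valid_pairs(pm)


@pytest.fixture(scope="session")
def fitted(cohort, valid_pairs):
    """Signature fitted on the default cohort's training half."""
    train, test = ir.split_train_test(cohort.clinical.index, cohort.clinical, seed=7)
    model, details = ir.fit_signature(valid_pairs, cohort.clinical, train, seed=7)
    return {"train": train, "test": test, "model": model, "details": details}


@pytest.fixture()
def toy_expr():
    """3 genes x 4 samples with hand-checkable orderings (one tie)."""
    values = pd.DataFrame(
        {
            "A-01": [5.0, 2.0, 7.0],
            "B-01": [1.0, 1.0, 0.5],
            "C-01": [3.0, 3.0, 3.0],
            "D-01": [0.0, 4.0, 4.0],
        },
        index=["G1", "G2", "G3"],
    )
    classes = pd.Series("tumor", index=values.columns)
    return ir.ExpressionMatrix(values, classes)


def make_expression(values: np.ndarray, n_tumor: int, gene_ids=None):
    """Wrap a raw array as an ExpressionMatrix with the first n_tumor tumors."""
    n_genes, n_samples = values.shape
    genes = gene_ids if gene_ids is not None else [f"G{i}" for i in range(n_genes)]
    cols = [f"S{i:04d}-01" for i in range(n_tumor)] + [
        f"S{i:04d}-11" for i in range(n_tumor, n_samples)
    ]
    df = pd.DataFrame(values, index=genes, columns=cols)
    classes = pd.Series(["tumor"] * n_tumor + ["normal"] * (n_samples - n_tumor),
                        index=cols)
    return ir.ExpressionMatrix(df, classes)
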