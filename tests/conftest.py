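import numpy as np
import pandas as pd
import pytest

from mir172tx import expression, synthetic
from mir172tx.io_formats import ExpressionMatrix


@pytest.fixture(scope="session")
def small_study():
    """One default-parameter synthetic study at 1,000 genes."""
    cfg = synthetic.SimulationConfig(n_genes=1000, seed=0)
    counts, sheet, annot, truth = synthetic.simulate_counts(cfg)
    return counts, sheet, annot, truth


@pytest.fixture(scope="session")
def small_fpkm(small_study):
    counts, sheet, annot, truth = small_study
    return expression.compute_fpkm(counts, annot)


@pytest.fixture(scope="session")
def exp1_libraries(small_study):
    _, sheet, _, _ = small_study
    return list(
        sheet.data.loc[sheet.data["genotype"].isin(["WT", "miR172OX"]), "library_id"]
    )


def expr_with_correlation(pairs: dict[str, np.ndarray], n_libs: int) -> ExpressionMatrix:
    """Build an ExpressionMatrix whose log2(FPKM+1) rows equal the given
    profiles exactly (profiles must be non-negative)."""
    libs = [f"L{j}" for j in range(n_libs)]
    rows = {g: np.exp2(v) - 1.0 for g, v in pairs.items()}
    return ExpressionMatrix(pd.DataFrame(rows, index=libs).T)


@pytest.fixture
def make_expr():
    return expr_with_correlation
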