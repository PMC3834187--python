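import numpy as np
import pandas as pd
import pytest

from methpanel.expression_screen import (
    ROLE_NORMAL,
    ROLE_TREATED,
    ROLE_TUMOR,
    ROLE_UNTREATED,
    ExpressionMatrix,
)


def random_expression_matrix(
    rng: np.random.Generator,
    n_elements: int = 50,
    n_pairs: int = 11,
    n_tumors: int = 7,
    n_normals: int = 4,
    fold_spread: float = 1.5,
) -> ExpressionMatrix:
    """A structureless random matrix for oracle-equivalence checks: log-normal
    intensities with per-sample noise wide enough that the 2-fold filter fires
    on a nontrivial subset of elements."""
    n_genes = max(1, int(0.7 * n_elements))
    genes = [f"G{i:03d}" for i in range(n_genes)]
    gene_map = pd.Series(
        {f"E{i:03d}": genes[i % n_genes] for i in range(n_elements)}, name="gene"
    )
    samples = []
    for p in range(n_pairs):
        samples.append((f"P{p:02d}_u", ROLE_UNTREATED, "BL", f"P{p:02d}"))
        samples.append((f"P{p:02d}_t", ROLE_TREATED, "BL", f"P{p:02d}"))
    samples += [(f"T{j:02d}", ROLE_TUMOR, "BL", "") for j in range(n_tumors)]
    samples += [(f"N{j:02d}", ROLE_NORMAL, "normal", "") for j in range(n_normals)]
    sheet = pd.DataFrame(
        samples, columns=["sample_id", "role", "subtype", "pair_id"]
    ).set_index("sample_id")
    values = pd.DataFrame(
        2.0 ** rng.normal(8.0, fold_spread, size=(n_elements, len(sheet))),
        index=gene_map.index,
        columns=sheet.index,
    )
    return ExpressionMatrix(values=values, gene_map=gene_map, samples=sheet)


@pytest.fixture
def cell_line_matrix():
    from methpanel.msp_calls import load_cell_line_fixture

    return load_cell_line_fixture()
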