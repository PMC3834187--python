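"""Methylation-specific PCR (MSP) call matrices.

MSP runs two primer pairs per gene on bisulfite-converted DNA, one specific
for the methylated and one for the unmethylated allele.  A sample/gene
combination is read from the gel as M (only the methylated reaction
amplifies), U (only the unmethylated) or U/M (both: partial methylation).
A gene's cell-line methylation frequency counts both M and U/M calls as
methylated, over non-missing calls, and candidate genes are carried forward
to quantitative analysis when that frequency strictly exceeds a threshold
(70 % by default).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from ._util import round_half_away

CALL_U = "U"
CALL_M = "M"
CALL_UM = "U/M"
VALID_CALLS = frozenset({CALL_U, CALL_M, CALL_UM})
METHYLATED_CALLS = frozenset({CALL_M, CALL_UM})


class MspCallMatrix:
    """Genes x samples matrix of categorical MSP calls (U, M, U/M, missing)."""

    def __init__(self, calls: pd.DataFrame):
        calls = calls.copy()
        stacked = calls.stack(future_stack=True).dropna()
        bad = set(stacked.unique()) - VALID_CALLS
        if bad:
            raise ValueError(f"invalid MSP call tokens: {sorted(bad)}")
        self.calls = calls

    @property
    def genes(self) -> list[str]:
        return list(self.calls.index)

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)

    @classmethod
    def from_tsv(cls, path) -> "MspCallMatrix":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if "gene" not in df.columns:
            raise ValueError(f"{path}: MSP call matrix must have a 'gene' column")
        df = df.set_index("gene")
        df = df.replace({"": np.nan, "NA": np.nan, "-": np.nan})
        return cls(df)

    def to_tsv(self, path) -> None:
        self.calls.reset_index(names="gene").to_csv(path, sep="\t", index=False, na_rep="")

    def counts(self, gene: str) -> tuple[int, int]:
        """(n_methylated, n_non_missing) for one gene."""
        if gene not in self.calls.index:
            raise KeyError(f"gene {gene!r} not in call matrix")
        row = self.calls.loc[gene].dropna()
        if row.empty:
            raise ValueError(f"gene {gene!r} has no non-missing calls")
        n_meth = int(row.isin(METHYLATED_CALLS).sum())
        return n_meth, int(len(row))


def methylation_frequency(matrix: MspCallMatrix, gene: str) -> int:
    """Percent of non-missing calls that are methylated (M or U/M), rounded
    to the nearest integer with ties away from zero."""
    n_meth, n_total = matrix.counts(gene)
    return int(round_half_away(100.0 * n_meth / n_total))


def frequency_table(matrix: MspCallMatrix) -> pd.DataFrame:
    """Per-gene frequency report: gene, n_meth, n_total, percent (exact and
    rounded), sorted by descending frequency with alphabetic tie-break."""
    rows = []
    for gene in matrix.genes:
        n_meth, n_total = matrix.counts(gene)
        exact = 100.0 * n_meth / n_total
        rows.append(
            {
                "gene": gene,
                "n_meth": n_meth,
                "n_total": n_total,
                "percent_exact": exact,
                "percent": int(round_half_away(exact)),
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["percent_exact", "gene"], ascending=[False, True], ignore_index=True
    )


def filter_frequent_genes(matrix: MspCallMatrix, threshold_percent: float = 70.0) -> list[str]:
    """Genes whose exact (unrounded) methylation frequency strictly exceeds
    the threshold, most frequent first."""
    table = frequency_table(matrix)
    keep = table[table["percent_exact"] > threshold_percent]
    return keep["gene"].tolist()


def pooled_cohort_frequency(
    counts: pd.DataFrame,
    series: str,
    gene: str,
    exclude_subtypes: tuple[str, ...] = ("healthy_control",),
) -> tuple[int, int, int]:
    """Pool per-subtype positivity counts into a cohort-level frequency.

    ``counts`` needs columns series, gene, subtype, n_positive, n_total.
    Returns ``(percent, n_positive, n_total)`` with the percent rounded to
    integer (ties away from zero).
    """
    rows = counts[
        (counts["series"] == series)
        & (counts["gene"] == gene)
        & (~counts["subtype"].isin(exclude_subtypes))
    ]
    if rows.empty:
        raise KeyError(f"no counts for series={series!r}, gene={gene!r}")
    pos = int(rows["n_positive"].sum())
    total = int(rows["n_total"].sum())
    return int(round_half_away(100.0 * pos / total)), pos, total


# ---------------------------------------------------------------------------
# Packaged cell-line reference data


def load_cell_line_fixture() -> MspCallMatrix:
    """MSP calls for 28 candidate genes across 18 B-cell lymphoma cell lines,
    as published in the source study's cell-line table."""
    path = resources.files("methpanel.data") / "table2_msp_calls.tsv"
    return MspCallMatrix.from_tsv(path)


def load_published_cell_line_frequencies() -> pd.Series:
    """The published per-gene methylation percentages accompanying the
    cell-line call matrix (for cross-checking recomputation)."""
    path = resources.files("methpanel.data") / "table2_published_frequencies.tsv"
    df = pd.read_csv(path, sep="\t")
    return df.set_index("gene")["methylation_pct"]


def load_cohort_counts() -> pd.DataFrame:
    """Published qMSP positivity counts (test and validation series) per gene
    and disease subtype, including combined-panel and healthy-control rows.
    Columns: series, gene, subtype, n_positive, n_total."""
    path = resources.files("methpanel.data") / "table3_qmsp_counts.tsv"
    return pd.read_csv(path, sep="\t")
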