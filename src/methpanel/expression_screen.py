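"""Candidate-gene nomination from a drug-reactivation expression screen.

Genes silenced by promoter methylation can be reactivated by treating cell
lines with a DNA-methyltransferase inhibitor (5-aza-2'-deoxycytidine)
combined with an HDAC inhibitor (trichostatin A).  The screen nominates
methylation candidates as genes that are (a) at least ``min_fold``
up-regulated by the drug treatment in at least ``min_lines`` treated/untreated
cell-line pairs and (b) expressed at a lower median level in tumors than in
healthy controls.  The intersection is ranked by degree of tumor
downregulation (log2 ratio of medians, most negative first) and the top N
genes are carried forward.

Intensities are linear-scale and strictly positive; fold changes are ratios
of treated over untreated within each cell-line pair.  Array elements
(probes) map many-to-one onto gene symbols: a gene enters a selection set if
any of its elements passes, and is ranked by its most-downregulated element.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROLE_UNTREATED = "cell_line_untreated"
ROLE_TREATED = "cell_line_treated"
ROLE_TUMOR = "tumor"
ROLE_NORMAL = "normal"
ROLES = (ROLE_UNTREATED, ROLE_TREATED, ROLE_TUMOR, ROLE_NORMAL)


class PairingError(ValueError):
    """A treated sample without exactly one untreated partner (or vice versa)."""


@dataclass
class ExpressionMatrix:
    """Element x sample matrix of positive linear intensities.

    ``values``: DataFrame indexed by element id, columns are sample ids.
    ``gene_map``: Series mapping element id -> gene symbol.
    ``samples``: sample sheet indexed by sample id with columns
    role (one of {cell_line_untreated, cell_line_treated, tumor, normal}),
    subtype and pair_id (shared by the two members of a cell-line pair).
    """

    values: pd.DataFrame
    gene_map: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.values.index.name = "element_id"
        self.values.columns.name = "sample_id"
        self.gene_map.index.name = "element_id"
        if not (self.values.to_numpy() > 0).all():
            raise ValueError("expression intensities must be strictly positive")
        if not self.values.index.equals(self.gene_map.index):
            self.gene_map = self.gene_map.reindex(self.values.index)
            if self.gene_map.isna().any():
                raise ValueError("gene_map does not cover all elements")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples sheet missing entries for: {sorted(missing)}")
        bad_roles = set(self.samples["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown sample roles: {sorted(bad_roles)}")

    def columns_with_role(self, role: str) -> list[str]:
        return [s for s in self.values.columns if self.samples.loc[s, "role"] == role]

    def treated_pairs(self) -> list[tuple[str, str]]:
        """(untreated, treated) sample-id pairs matched via pair_id."""
        cells = self.samples[self.samples["role"].isin([ROLE_UNTREATED, ROLE_TREATED])]
        pairs = []
        for pair_id, grp in cells.groupby("pair_id"):
            untreated = grp.index[grp["role"] == ROLE_UNTREATED].tolist()
            treated = grp.index[grp["role"] == ROLE_TREATED].tolist()
            if len(untreated) != 1 or len(treated) != 1:
                raise PairingError(
                    f"pair {pair_id!r} must have exactly one treated and one untreated "
                    f"sample (found {len(treated)} treated, {len(untreated)} untreated)"
                )
            pairs.append((untreated[0], treated[0]))
        if not pairs:
            raise PairingError("matrix contains no treated/untreated cell-line pairs")
        return sorted(pairs)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_tsv(cls, values_path, samples_path) -> "ExpressionMatrix":
        df = pd.read_csv(values_path, sep="\t")
        if "element_id" not in df.columns or "gene" not in df.columns:
            raise ValueError(
                f"{values_path}: expression TSV must have 'element_id' and 'gene' columns"
            )
        df = df.set_index("element_id")
        gene_map = df.pop("gene")
        values = df.astype(float)
        if values.isna().any().any():
            raise ValueError(f"{values_path}: non-numeric or missing intensities")
        samples = pd.read_csv(samples_path, sep="\t").set_index("sample_id")
        return cls(values=values, gene_map=gene_map, samples=samples)

    def to_tsv(self, values_path, samples_path) -> None:
        out = self.values.copy()
        out.insert(0, "gene", self.gene_map)
        out.reset_index(names="element_id").to_csv(values_path, sep="\t", index=False)
        self.samples.reset_index(names="sample_id").to_csv(samples_path, sep="\t", index=False)


@dataclass
class ScreenResult:
    """Outcome of the two-filter screen with ranking."""

    upregulated: set[str]
    downregulated: set[str]
    candidates: pd.DataFrame  # columns gene, score, rank; ascending score
    top_n: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "n_upregulated_genes": len(self.upregulated),
            "n_downregulated_genes": len(self.downregulated),
            "n_candidates": len(self.candidates),
            "n_selected": len(self.top_n),
        }

    def write(self, candidates_path, summary_path=None) -> None:
        self.candidates.to_csv(candidates_path, sep="\t", index=False)
        if summary_path is not None:
            with open(summary_path, "w") as fh:
                json.dump(self.summary(), fh, indent=2)


def select_upregulated(
    matrix: ExpressionMatrix, min_fold: float = 2.0, min_lines: int = 6
) -> set[str]:
    """Genes with >= ``min_fold`` treated/untreated induction in >= ``min_lines`` pairs.

    Both bounds are inclusive; fold changes are computed per element and the
    gene passes if any of its elements does.
    """
    pairs = matrix.treated_pairs()
    if len(pairs) < min_lines:
        raise ValueError(
            f"matrix has {len(pairs)} treated/untreated pairs; min_lines={min_lines} requires "
            "at least that many"
        )
    folds = pd.DataFrame(
        {t: matrix.values[t] / matrix.values[u] for u, t in pairs}
    )
    n_up = (folds >= min_fold).sum(axis=1)
    passing_elements = n_up.index[n_up >= min_lines]
    return set(matrix.gene_map.loc[passing_elements])


def select_downregulated(matrix: ExpressionMatrix) -> set[str]:
    """Genes whose median tumor intensity is strictly below the median control
    intensity for at least one element."""
    tumor_cols = matrix.columns_with_role(ROLE_TUMOR)
    normal_cols = matrix.columns_with_role(ROLE_NORMAL)
    if not tumor_cols or not normal_cols:
        raise ValueError("matrix must contain at least one tumor and one normal sample")
    med_tumor = matrix.values[tumor_cols].median(axis=1)
    med_normal = matrix.values[normal_cols].median(axis=1)
    passing_elements = med_tumor.index[med_tumor < med_normal]
    return set(matrix.gene_map.loc[passing_elements])


def downregulation_scores(matrix: ExpressionMatrix, genes: set[str]) -> pd.Series:
    """Per-gene log2(median tumor / median control) of the most-downregulated
    element (the minimum over the gene's elements)."""
    tumor_cols = matrix.columns_with_role(ROLE_TUMOR)
    normal_cols = matrix.columns_with_role(ROLE_NORMAL)
    med_tumor = matrix.values[tumor_cols].median(axis=1)
    med_normal = matrix.values[normal_cols].median(axis=1)
    elem_score = np.log2(med_tumor / med_normal)
    per_gene = elem_score.groupby(matrix.gene_map).min()
    return per_gene.loc[sorted(genes)]


def rank_and_select(
    up_set: set[str],
    down_set: set[str],
    matrix: ExpressionMatrix,
    top_n: int = 30,
) -> ScreenResult:
    """Intersect the two filters, rank by degree of downregulation and keep
    the ``top_n`` most-downregulated genes (all if fewer).

    Ordering is ascending in the log2 median-ratio score (most negative =
    strongest downregulation) with lexicographic gene-symbol tie-breaks.
    """
    intersection = up_set & down_set
    if not intersection:
        logger.warning("screen intersection is empty; no candidates to rank")
        empty = pd.DataFrame(columns=["gene", "score", "rank"])
        return ScreenResult(upregulated=up_set, downregulated=down_set, candidates=empty)
    scores = downregulation_scores(matrix, intersection)
    order = sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))
    candidates = pd.DataFrame(
        {
            "gene": [g for g, _ in order],
            "score": [s for _, s in order],
            "rank": np.arange(1, len(order) + 1),
        }
    )
    return ScreenResult(
        upregulated=up_set,
        downregulated=down_set,
        candidates=candidates,
        top_n=candidates["gene"].head(top_n).tolist(),
    )


def run_screen(
    matrix: ExpressionMatrix,
    min_fold: float = 2.0,
    min_lines: int = 6,
    top_n: int = 30,
) -> ScreenResult:
    """Convenience wrapper: both filters plus ranking in one call."""
    up = select_upregulated(matrix, min_fold=min_fold, min_lines=min_lines)
    down = select_downregulated(matrix)
    return rank_and_select(up, down, matrix, top_n=top_n)
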