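"""Biomarker-panel performance: combined calls, sensitivity/specificity, ROC.

A sample is panel-positive when one or more of the panel genes is scored
methylated.  Sensitivity is the percent of cases called positive and
specificity the percent of controls called negative, both rounded to integer
percent (ties away from zero, so 54/61 reports as 89 %).  For threshold-free
evaluation the panel score is the sum of the per-gene PMR values; the
empirical ROC curve is traced over all distinct scores and its area equals
the Mann-Whitney two-sample statistic (probability that a random case
outscores a random control, ties counted 1/2) — the trapezoidal area under
the curve and the pair-counting statistic are required to agree to 1e-12.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._util import round_half_away

logger = logging.getLogger(__name__)

DEFAULT_PANEL = ("DSP", "FZD8", "KCNH2", "PPP1R14A")


def panel_call(gene_calls: Mapping[str, bool], panel: Sequence[str] = DEFAULT_PANEL) -> bool:
    """Positive iff any panel gene is called methylated; a gene missing from
    ``gene_calls`` is treated as negative (logged)."""
    if not panel:
        raise ValueError("panel must be non-empty")
    result = False
    for gene in panel:
        if gene not in gene_calls:
            logger.info("panel gene %s missing from calls; treated as negative", gene)
            continue
        result = result or bool(gene_calls[gene])
    return result


def sensitivity_specificity(
    case_calls: Sequence[bool], control_calls: Sequence[bool]
) -> tuple[int, int]:
    """(sensitivity %, specificity %) as integers, ties rounded away from zero."""
    if len(case_calls) == 0 or len(control_calls) == 0:
        raise ValueError("need at least one case and one control")
    sens = 100.0 * sum(bool(c) for c in case_calls) / len(case_calls)
    spec = 100.0 * sum(not bool(c) for c in control_calls) / len(control_calls)
    return int(round_half_away(sens)), int(round_half_away(spec))


def panel_score(
    pmr_values: Mapping[str, float], panel: Sequence[str] = DEFAULT_PANEL
) -> float:
    """Sum of the panel genes' PMR values; a missing gene contributes 0
    (logged)."""
    total = 0.0
    for gene in panel:
        if gene not in pmr_values:
            logger.info("panel gene %s missing from PMR vector; contributes 0", gene)
            continue
        total += float(pmr_values[gene])
    return total


def roc_curve(case_scores, control_scores) -> pd.DataFrame:
    """Empirical ROC: one operating point per distinct score threshold
    (higher score = more disease-like), from (0, 0) to (1, 1)."""
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("need at least one score per group")
    thresholds = np.unique(np.concatenate([cases, controls]))[::-1]
    points = [(0.0, 0.0)]
    for thr in thresholds:
        tpr = float(np.mean(cases >= thr))
        fpr = float(np.mean(controls >= thr))
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return pd.DataFrame(points, columns=["fpr", "tpr"])


def mann_whitney_auc(case_scores, control_scores) -> float:
    """AUC as the tie-aware Mann-Whitney statistic via midranks."""
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    ranks = rankdata(np.concatenate([cases, controls]))
    u = ranks[: len(cases)].sum() - len(cases) * (len(cases) + 1) / 2.0
    return float(u / (len(cases) * len(controls)))


def roc_auc(case_scores, control_scores) -> tuple[pd.DataFrame, float]:
    """(roc points, AUC).  The trapezoidal area under the empirical curve is
    cross-checked against the Mann-Whitney statistic; a disagreement beyond
    1e-12 indicates an internal error and raises."""
    curve = roc_curve(case_scores, control_scores)
    auc = mann_whitney_auc(case_scores, control_scores)
    trapezoid = float(np.trapezoid(curve["tpr"], curve["fpr"]))
    if abs(trapezoid - auc) > 1e-12:
        raise RuntimeError(
            f"trapezoidal ROC area {trapezoid!r} disagrees with Mann-Whitney AUC {auc!r}"
        )
    return curve, auc


@dataclass
class PanelEvaluation:
    """Cohort-level panel performance."""

    per_sample: pd.DataFrame  # sample_id, group, panel_call, panel_score
    sensitivity: int
    specificity: int
    roc: pd.DataFrame
    auc: float
    n_cases: int
    n_controls: int
    panel: tuple[str, ...] = DEFAULT_PANEL

    def summary(self) -> dict:
        return {
            "panel": list(self.panel),
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "sensitivity_percent": self.sensitivity,
            "specificity_percent": self.specificity,
            "auc": self.auc,
        }

    def write(self, summary_path, roc_path=None) -> None:
        with open(summary_path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)
        if roc_path is not None:
            self.roc.to_csv(roc_path, sep="\t", index=False)


def evaluate_panel(
    scored_pmrs: pd.DataFrame,
    case_samples: Sequence[str],
    control_samples: Sequence[str],
    panel: Sequence[str] = DEFAULT_PANEL,
) -> PanelEvaluation:
    """Evaluate a panel on a scored PMR table.

    ``scored_pmrs`` needs columns sample_id, gene, pmr, call (from
    :func:`methpanel.qmsp.score_table`).  Case/control membership is given
    explicitly so failed samples are simply absent from both lists.
    """
    panel = tuple(panel)
    rows = []
    for sample_id, grp in scored_pmrs.groupby("sample_id"):
        calls = dict(zip(grp["gene"], grp["call"]))
        pmrs = dict(zip(grp["gene"], grp["pmr"]))
        rows.append(
            {
                "sample_id": sample_id,
                "panel_call": panel_call(calls, panel),
                "panel_score": panel_score(pmrs, panel),
            }
        )
    per_sample = pd.DataFrame(rows).set_index("sample_id")
    missing = (set(case_samples) | set(control_samples)) - set(per_sample.index)
    if missing:
        raise ValueError(f"scored PMR table lacks samples: {sorted(missing)}")

    case_calls = per_sample.loc[list(case_samples), "panel_call"].tolist()
    control_calls = per_sample.loc[list(control_samples), "panel_call"].tolist()
    sens, spec = sensitivity_specificity(case_calls, control_calls)
    curve, auc = roc_auc(
        per_sample.loc[list(case_samples), "panel_score"],
        per_sample.loc[list(control_samples), "panel_score"],
    )
    per_sample = per_sample.reset_index()
    per_sample["group"] = np.where(
        per_sample["sample_id"].isin(set(case_samples)), "case", "control"
    )
    return PanelEvaluation(
        per_sample=per_sample,
        sensitivity=sens,
        specificity=spec,
        roc=curve,
        auc=auc,
        n_cases=len(case_calls),
        n_controls=len(control_calls),
        panel=panel,
    )


def plot_roc(evaluation: PanelEvaluation, path) -> None:
    """Save a ROC plot for a panel evaluation (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(evaluation.roc["fpr"], evaluation.roc["tpr"], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], linestyle=":", color="grey")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {evaluation.auc:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
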