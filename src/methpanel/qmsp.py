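"""Quantitative MSP: from raw Ct plates to percent-of-methylated-reference.

A qMSP plate holds triplicate Ct values per (sample, assay) pair, where the
assays are methylation-specific gene assays plus the ALU-C4 repeat assay used
to normalise for bisulfite-converted DNA input.  Quantities are read off a
standard curve Ct = slope * log10(quantity) + intercept fitted to a dilution
series of universally methylated control DNA.  The percent of methylated
reference is

    PMR = 100 * (median gene qty / median ALU qty)_sample
              / (median gene qty / median ALU qty)_positive control

Amplification after the Ct cutoff (cycle 35 by default) and non-amplifying
wells are censored; a fully censored gene assay gives PMR = 0, while a fully
censored ALU assay invalidates the sample (no input normalisation possible).
Per-gene positivity thresholds are the maximum PMR observed across healthy
controls; scoring is strict (PMR > threshold) by default so that the
threshold-defining control itself remains negative.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

logger = logging.getLogger(__name__)

DEFAULT_CT_CUTOFF = 35.0
REFERENCE_ASSAY = "ALU-C4"
POSITIVE_CONTROL = "POS_CONTROL"
STANDARD_PREFIX = "STD_"
SCORING_RULES = ("strict", "inclusive")


class SampleFailedError(ValueError):
    """Raised when the reference assay is fully censored for a sample."""


class CurveFitError(ValueError):
    """Raised when a standard curve cannot be fitted."""


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration Ct = slope * log10(quantity) + intercept."""

    slope: float
    intercept: float
    r_squared: float = float("nan")


def censor_ct(ct: float | None, cutoff: float = DEFAULT_CT_CUTOFF) -> float:
    """Apply late-amplification censoring: Ct values strictly after the
    cutoff cycle, and non-amplifying wells (None/NaN), become NaN."""
    if ct is None or (isinstance(ct, float) and math.isnan(ct)):
        return float("nan")
    if ct <= 0:
        raise ValueError(f"Ct must be positive, got {ct}")
    return float(ct) if ct <= cutoff else float("nan")


def fit_standard_curve(quantities, cts) -> StandardCurve:
    """Least-squares fit of the dilution series.

    ``quantities`` are input amounts of the methylated control (arbitrary but
    consistent units); ``cts`` the observed cycle thresholds.  Requires at
    least two distinct dilution points and a negative slope (more template
    must amplify earlier).
    """
    q = np.asarray(quantities, dtype=float)
    c = np.asarray(cts, dtype=float)
    mask = ~(np.isnan(q) | np.isnan(c))
    q, c = q[mask], c[mask]
    if len(q) < 2 or len(np.unique(q)) < 2:
        raise CurveFitError("standard curve needs >= 2 distinct dilution points")
    if (q <= 0).any():
        raise CurveFitError("standard quantities must be positive")
    res = _scipy_stats.linregress(np.log10(q), c)
    if res.slope >= 0:
        raise CurveFitError(f"fitted slope {res.slope:.3f} is not negative; check plate layout")
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue**2))


def quantify(ct: float, curve: StandardCurve) -> float:
    """Invert the standard curve; censored (NaN) wells quantify to 0."""
    if ct is None or (isinstance(ct, float) and math.isnan(ct)):
        return 0.0
    return float(10.0 ** ((ct - curve.intercept) / curve.slope))


def pmr_from_quantities(
    gene_sample: float, alu_sample: float, gene_control: float, alu_control: float
) -> float:
    """PMR from median quantities; raises SampleFailedError when the sample
    or control reference quantity is zero."""
    if alu_control <= 0 or gene_control <= 0:
        raise SampleFailedError("positive control must amplify in both assays")
    if alu_sample <= 0:
        raise SampleFailedError("reference assay fully censored; sample failed")
    return 100.0 * (gene_sample / alu_sample) / (gene_control / alu_control)


# ---------------------------------------------------------------------------
# Plate-level driver


def read_plate(path) -> pd.DataFrame:
    """Read a plate CSV with columns sample_id, assay_id, replicate, ct
    (empty ct field = no amplification)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "assay_id": str})
    required = {"sample_id", "assay_id", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate {path} missing columns: {sorted(missing)}")
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    return df


def write_plate(plate: pd.DataFrame, path) -> None:
    plate.to_csv(path, index=False, na_rep="")


def standard_quantity(sample_id: str) -> float | None:
    """Parse the known input quantity from a standard-well sample id of the
    form ``STD_<quantity>``; returns None for non-standard wells."""
    if not sample_id.startswith(STANDARD_PREFIX):
        return None
    m = re.fullmatch(rf"{STANDARD_PREFIX}([0-9.eE+-]+)", sample_id)
    if not m:
        raise ValueError(f"cannot parse standard quantity from sample id {sample_id!r}")
    return float(m.group(1))


def fit_plate_curves(plate: pd.DataFrame) -> dict[str, StandardCurve]:
    """Fit one standard curve per assay from the plate's dilution-series
    wells (sample ids ``STD_<quantity>``).  Standards are fitted before
    censoring so the low end of the dilution series anchors the line."""
    std = plate[plate["sample_id"].str.startswith(STANDARD_PREFIX)]
    curves = {}
    for assay, grp in std.groupby("assay_id"):
        quantities = grp["sample_id"].map(standard_quantity).astype(float)
        curves[assay] = fit_standard_curve(quantities, grp["ct"])
    return curves


def _median_quantity(wells: pd.DataFrame, curve: StandardCurve, cutoff: float) -> float:
    cts = [censor_ct(ct, cutoff) for ct in wells["ct"]]
    quantities = [quantify(ct, curve) for ct in cts]
    return float(np.median(quantities))


def compute_pmr(
    plate: pd.DataFrame,
    gene_assays: list[str] | None = None,
    reference_assay: str = REFERENCE_ASSAY,
    positive_control: str = POSITIVE_CONTROL,
    ct_cutoff: float = DEFAULT_CT_CUTOFF,
    curves: dict[str, StandardCurve] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Compute PMR for every (sample, gene) on the plate.

    Returns ``(pmr_table, failed_samples)`` where the table has columns
    sample_id, gene, pmr (two-decimal reporting is left to writers; values
    are exact).  Samples whose reference assay is fully censored are
    excluded and listed in ``failed_samples``.
    """
    if curves is None:
        curves = fit_plate_curves(plate)
    is_std = plate["sample_id"].str.startswith(STANDARD_PREFIX)
    samples = plate[~is_std]
    if gene_assays is None:
        gene_assays = sorted(set(samples["assay_id"]) - {reference_assay})
    if reference_assay not in set(samples["assay_id"]):
        raise ValueError(f"plate has no wells for reference assay {reference_assay!r}")

    ctrl = samples[samples["sample_id"] == positive_control]
    if ctrl.empty:
        raise ValueError(f"plate has no positive-control wells ({positive_control!r})")
    alu_ctrl = _median_quantity(
        ctrl[ctrl["assay_id"] == reference_assay], curves[reference_assay], ct_cutoff
    )
    if alu_ctrl <= 0:
        raise ValueError("positive control reference assay fully censored; plate invalid")

    rows, failed = [], []
    for sample_id, swells in samples.groupby("sample_id", sort=True):
        alu_q = _median_quantity(
            swells[swells["assay_id"] == reference_assay], curves[reference_assay], ct_cutoff
        )
        for gene in gene_assays:
            gctrl = ctrl[ctrl["assay_id"] == gene]
            if gctrl.empty:
                raise ValueError(f"positive control has no wells for assay {gene!r}")
            gene_ctrl_q = _median_quantity(gctrl, curves[gene], ct_cutoff)
            if gene_ctrl_q <= 0:
                raise ValueError(
                    f"positive control fully censored for assay {gene!r}; plate invalid"
                )
            gwells = swells[swells["assay_id"] == gene]
            if gwells.empty:
                logger.info("sample %s has no wells for assay %s; skipped", sample_id, gene)
                continue
            gene_q = _median_quantity(gwells, curves[gene], ct_cutoff)
            try:
                value = pmr_from_quantities(gene_q, alu_q, gene_ctrl_q, alu_ctrl)
            except SampleFailedError:
                if sample_id not in failed:
                    failed.append(sample_id)
                    logger.warning(
                        "sample %s: reference assay fully censored; sample excluded", sample_id
                    )
                break
            rows.append({"sample_id": sample_id, "gene": gene, "pmr": value})
    table = pd.DataFrame(rows, columns=["sample_id", "gene", "pmr"])
    return table, failed


def derive_thresholds(control_pmrs: pd.DataFrame) -> pd.DataFrame:
    """Per-gene scoring threshold = the highest PMR observed among healthy
    controls.  Input columns: sample_id, gene, pmr."""
    if control_pmrs.empty:
        raise ValueError("cannot derive thresholds from an empty control table")
    thr = control_pmrs.groupby("gene")["pmr"].max().reset_index()
    return thr.rename(columns={"pmr": "threshold"})


def score_sample(pmr_value: float, threshold: float, rule: str = "strict") -> bool:
    """Score one PMR value against a gene threshold.

    ``strict`` (default) calls positive when PMR > threshold, which keeps the
    threshold-defining control negative; ``inclusive`` uses >=.  A PMR equal
    to a positive threshold is negative under the strict rule — reports flag
    such borderline values.
    """
    if rule not in SCORING_RULES:
        raise ValueError(f"scoring rule must be one of {SCORING_RULES}")
    if rule == "strict":
        return pmr_value > threshold
    return pmr_value >= threshold


def score_table(
    pmr_table: pd.DataFrame, thresholds: pd.DataFrame, rule: str = "strict"
) -> pd.DataFrame:
    """Apply per-gene thresholds to a PMR table; adds boolean ``call`` and a
    ``borderline`` flag for values exactly at a positive threshold."""
    thr = thresholds.set_index("gene")["threshold"]
    missing = set(pmr_table["gene"]) - set(thr.index)
    if missing:
        raise ValueError(f"no thresholds for genes: {sorted(missing)}")
    out = pmr_table.copy()
    out["threshold"] = out["gene"].map(thr)
    out["call"] = [
        score_sample(p, t, rule) for p, t in zip(out["pmr"], out["threshold"])
    ]
    out["borderline"] = (out["pmr"] == out["threshold"]) & (out["threshold"] > 0)
    n_border = int(out["borderline"].sum())
    if n_border:
        logger.warning("%d PMR values lie exactly on a positive threshold", n_border)
    return out
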