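"""Bisulfite-sequencing utilities.

Bisulfite treatment deaminates unmethylated cytosine to uracil (read as
thymine after PCR) while 5-methylcytosine is protected.  Sequencing a
bisulfite PCR product therefore shows, at each CpG site, a mixed C/T signal
whose cytosine share estimates the methylated fraction of the template.
This module provides an in-silico converter, the per-site C/(C+T) peak-height
ratio, the three-band site classification used for electropherogram reading
(unmethylated <= 0.20, partial 0.21-0.80, methylated >= 0.81 after rounding
to two decimals), and a conversion-rate QC based on non-CpG cytosines, which
have no biological methylation in mammalian promoters and should read as T
when conversion is complete.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd

from ._util import round_half_away

UNMETHYLATED = "unmethylated"
PARTIAL = "partial"
METHYLATED = "methylated"
UNEVALUABLE = "unevaluable"


def bisulfite_convert(
    seq: str,
    methylated_positions: Iterable[int] = (),
    efficiency: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> str:
    """Convert unmethylated cytosines to thymine with the given efficiency.

    ``methylated_positions`` are 0-based indices of methyl-cytosines, which
    never convert; every position must be a C.  Non-C bases pass through
    unchanged.  ``efficiency`` is the per-cytosine conversion probability.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must be in [0, 1]")
    seq = seq.upper()
    meth = set(methylated_positions)
    for pos in meth:
        if pos < 0 or pos >= len(seq) or seq[pos] != "C":
            raise ValueError(f"methylated position {pos} is not a C residue")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = list(seq)
    for i, base in enumerate(out):
        if base == "C" and i not in meth:
            if efficiency >= 1.0 or rng.random() < efficiency:
                out[i] = "T"
    return "".join(out)


def site_ratio(height_c: float, height_t: float) -> float:
    """Methylation ratio of one CpG site: C / (C + T) peak height.

    Raises when the total signal is zero (the site is unevaluable).
    """
    if height_c < 0 or height_t < 0:
        raise ValueError("peak heights must be non-negative")
    total = height_c + height_t
    if total <= 0:
        raise ValueError("zero total signal: site is unevaluable")
    return height_c / total


def classify_site(ratio: float) -> str:
    """Band a site ratio into unmethylated / partial / methylated.

    The ratio is first rounded to two decimals (ties away from zero), which
    closes the nominal gap between the 0.20 and 0.21 band edges.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"ratio {ratio} outside [0, 1]")
    r = round_half_away(ratio, 2)
    if r <= 0.20:
        return UNMETHYLATED
    if r >= 0.81:
        return METHYLATED
    return PARTIAL


def classify_peak_table(peaks: pd.DataFrame) -> pd.DataFrame:
    """Classify a peak table with columns position, height_c, height_t.

    Sites with zero total signal are flagged ``unevaluable`` with NaN ratio
    instead of raising, so one dead peak does not abort a sample report.
    """
    rows = []
    for rec in peaks.itertuples(index=False):
        total = rec.height_c + rec.height_t
        if total <= 0:
            rows.append({"position": rec.position, "ratio": np.nan, "site_class": UNEVALUABLE})
        else:
            r = site_ratio(rec.height_c, rec.height_t)
            rows.append({"position": rec.position, "ratio": r, "site_class": classify_site(r)})
    return pd.DataFrame(rows, columns=["position", "ratio", "site_class"])


def conversion_rate(original: str, converted: str) -> float:
    """Fraction of non-CpG-context cytosines that read as T after conversion.

    CpG context is judged on the original (unconverted) strand in forward
    orientation: a C immediately followed by G is excluded from the QC since
    it may be legitimately methylated.
    """
    if len(original) != len(converted):
        raise ValueError("original and converted sequences must have equal length")
    original = original.upper()
    converted = converted.upper()
    n_qc = n_conv = 0
    for i, base in enumerate(original):
        if base != "C":
            continue
        if i + 1 < len(original) and original[i + 1] == "G":
            continue
        n_qc += 1
        if converted[i] == "T":
            n_conv += 1
    if n_qc == 0:
        raise ValueError("sequence contains no non-CpG cytosines; conversion QC undefined")
    return n_conv / n_qc


def read_peak_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"position", "height_c", "height_t"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak table {path} missing columns: {sorted(missing)}")
    return df


def write_classification_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False)
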