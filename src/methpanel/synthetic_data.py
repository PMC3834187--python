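"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study design end-to-end: paired treated/untreated
cell-line expression profiles with a planted set of drug-reactivated genes,
tumor cohorts (one per lymphoma subtype) with those same genes downregulated
relative to healthy B-cell controls, promoter sequences with or without an
embedded CpG island, triplicate qMSP Ct plates derived from planted
methylation fractions through a linear standard-curve model with Gaussian Ct
noise, and per-CpG electropherogram peak heights.  All generators are
deterministic given their seed, and with all noise terms at zero every
observable equals its closed-form value from the truth table.

Expression intensities are simulated on the log2 scale (Gaussian noise) and
exponentiated, guaranteeing positivity and making planted fold changes exact
in the noise-free limit.  Non-amplifying qMSP wells carry an explicit no-Ct
token (empty field / NaN) rather than a sentinel cycle number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import cpg_islands
from .expression_screen import (
    ROLE_NORMAL,
    ROLE_TREATED,
    ROLE_TUMOR,
    ROLE_UNTREATED,
    ExpressionMatrix,
)
from .qmsp import POSITIVE_CONTROL, REFERENCE_ASSAY, STANDARD_PREFIX

NORMAL_GROUP = "normal"

DEFAULT_SUBTYPE_COUNTS = {"BL": 7, "DLBCL_ABC": 10, "DLBCL_GCB": 10, "FL": 10}


@dataclass
class SimulationConfig:
    """Study-condition parameters for all generators.

    Cohort sizes default to the study design: 11 treated/untreated cell-line
    pairs, a 37-patient tumor series split over four lymphoma subtypes and
    10 healthy B-cell controls.  The standard-curve geometry (slope -3.32
    cycles per 10-fold dilution = perfect PCR efficiency, intercept 40) and
    the noise magnitudes are generator choices documented in the methods
    note.
    """

    n_cell_lines: int = 11
    n_tumors_per_subtype: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_COUNTS)
    )
    n_controls: int = 10
    n_elements: int = 200
    n_true_targets: int = 10
    reactivation_fold: float = 4.0
    downregulation_fold: float = 4.0
    reactivated_lines: int | None = None  # None = effect planted in every pair
    intensity_noise_sd: float = 0.5  # log2 units
    ct_noise_sd: float = 0.15  # cycles
    conversion_efficiency: float = 1.0
    curve_slope: float = -3.32  # cycles per log10 quantity
    curve_intercept: float = 40.0  # cycles at unit quantity
    dna_input: float = 1000.0  # per-sample template amount, curve units
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_cell_lines": self.n_cell_lines,
            "n_controls": self.n_controls,
            "n_elements": self.n_elements,
            "n_true_targets": self.n_true_targets,
            **{f"n_tumors[{k}]": v for k, v in self.n_tumors_per_subtype.items()},
        }
        for name, value in counts.items():
            if value < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if self.reactivation_fold <= 1 or self.downregulation_fold <= 1:
            raise ValueError("fold changes must be > 1")
        if self.intensity_noise_sd < 0 or self.ct_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0.0 <= self.conversion_efficiency <= 1.0:
            raise ValueError("conversion_efficiency must be in [0, 1]")
        if self.curve_slope >= 0:
            raise ValueError("curve_slope must be negative")
        if self.reactivated_lines is not None and not (
            1 <= self.reactivated_lines <= self.n_cell_lines
        ):
            raise ValueError("reactivated_lines must be in [1, n_cell_lines]")


@dataclass
class TruthTable:
    """Planted signal: per-gene target flag and per-group methylation fraction.

    Fraction columns are named ``frac_<group>``; the healthy-control group
    (``normal``) and all non-target genes carry fraction 0 everywhere.
    """

    table: pd.DataFrame
    groups: list[str]

    def __post_init__(self) -> None:
        frac_cols = [f"frac_{g}" for g in self.groups]
        fracs = self.table[frac_cols].to_numpy()
        if ((fracs < 0) | (fracs > 1)).any():
            raise ValueError("methylation fractions must lie in [0, 1]")
        non_target = ~self.table["is_target"].to_numpy(dtype=bool)
        if fracs[non_target].any():
            raise ValueError("non-target genes must have methylation fraction 0")
        if NORMAL_GROUP in self.groups and self.table[f"frac_{NORMAL_GROUP}"].any():
            raise ValueError("the healthy-control group must have methylation fraction 0")

    @property
    def target_genes(self) -> list[str]:
        return sorted(self.table.index[self.table["is_target"]])

    def fraction(self, gene: str, group: str) -> float:
        return float(self.table.loc[gene, f"frac_{group}"])

    def to_tsv(self, path) -> None:
        self.table.reset_index(names="gene").to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t").set_index("gene")
        groups = [c[len("frac_") :] for c in df.columns if c.startswith("frac_")]
        return cls(table=df, groups=groups)


# ---------------------------------------------------------------------------
# Expression screen inputs


def _gene_and_element_ids(n_elements: int) -> tuple[list[str], pd.Series]:
    """Assign elements to genes; roughly a fifth of genes get a second
    element so the probe->gene collapse is exercised."""
    n_genes = max(1, math.ceil(0.8 * n_elements))
    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    mapping = {}
    for i in range(n_elements):
        gene = genes[i] if i < n_genes else genes[i - n_genes]
        suffix = "e1" if i < n_genes else "e2"
        mapping[f"{gene}_{suffix}"] = gene
    return genes, pd.Series(mapping, name="gene")


def generate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, TruthTable]:
    """Simulate the reactivation screen's expression matrix.

    Target genes are ``reactivation_fold``-induced in treated cell lines
    (all pairs, or ``reactivated_lines`` randomly chosen pairs per gene) and
    ``downregulation_fold``-repressed in every tumor sample relative to
    controls; all effects are planted on the log2 scale before adding
    N(0, intensity_noise_sd) measurement noise and exponentiating.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    genes, gene_map = _gene_and_element_ids(config.n_elements)
    if config.n_true_targets > len(genes):
        raise ValueError(
            f"n_true_targets={config.n_true_targets} exceeds the number of genes "
            f"({len(genes)}) derived from n_elements={config.n_elements}"
        )
    element_ids = list(gene_map.index)
    targets = sorted(rng.choice(genes, size=config.n_true_targets, replace=False))
    is_target_elem = gene_map.isin(targets).to_numpy()

    subtypes = list(config.n_tumors_per_subtype)
    samples = []
    for i in range(config.n_cell_lines):
        pair = f"CL{i + 1:02d}"
        subtype = subtypes[i % len(subtypes)]
        samples.append((f"{pair}_untreated", ROLE_UNTREATED, subtype, pair))
        samples.append((f"{pair}_treated", ROLE_TREATED, subtype, pair))
    for subtype in subtypes:
        for j in range(config.n_tumors_per_subtype[subtype]):
            samples.append((f"{subtype}_T{j + 1:02d}", ROLE_TUMOR, subtype, ""))
    for j in range(config.n_controls):
        samples.append((f"CTRL_N{j + 1:02d}", ROLE_NORMAL, NORMAL_GROUP, ""))
    sheet = pd.DataFrame(
        samples, columns=["sample_id", "role", "subtype", "pair_id"]
    ).set_index("sample_id")

    # Which pairs carry the planted reactivation for each target gene.
    if config.reactivated_lines is None:
        reactivated = {g: set(range(config.n_cell_lines)) for g in targets}
    else:
        reactivated = {
            g: set(
                rng.choice(config.n_cell_lines, size=config.reactivated_lines, replace=False)
            )
            for g in targets
        }

    base = rng.normal(8.0, 1.0, size=config.n_elements)
    up = math.log2(config.reactivation_fold)
    down = math.log2(config.downregulation_fold)
    columns = {}
    for sample_id, row in sheet.iterrows():
        effect = np.zeros(config.n_elements)
        if row["role"] == ROLE_TREATED:
            line_index = int(row["pair_id"][2:]) - 1
            on = np.array(
                [
                    is_target_elem[k] and line_index in reactivated[gene_map.iloc[k]]
                    for k in range(config.n_elements)
                ]
            )
            effect = np.where(on, up, 0.0)
        elif row["role"] == ROLE_TUMOR:
            effect = np.where(is_target_elem, -down, 0.0)
        noise = (
            rng.normal(0.0, config.intensity_noise_sd, size=config.n_elements)
            if config.intensity_noise_sd > 0
            else 0.0
        )
        columns[sample_id] = 2.0 ** (base + effect + noise)
    values = pd.DataFrame(columns, index=element_ids)
    matrix = ExpressionMatrix(values=values, gene_map=gene_map, samples=sheet)

    groups = subtypes + [NORMAL_GROUP]
    truth_rows = []
    for gene in genes:
        row = {"is_target": gene in targets}
        for group in groups:
            if gene in targets and group != NORMAL_GROUP:
                row[f"frac_{group}"] = float(np.round(rng.uniform(0.3, 0.9), 3))
            else:
                row[f"frac_{group}"] = 0.0
        truth_rows.append(row)
    truth = TruthTable(
        table=pd.DataFrame(truth_rows, index=pd.Index(genes, name="gene")), groups=groups
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Promoter sequences


_BACKGROUND = {"p": {"A": 0.27, "C": 0.23, "G": 0.23, "T": 0.27}, "p_g_after_c": 0.02}
_ISLAND = {"p": {"A": 0.16, "C": 0.34, "G": 0.34, "T": 0.16}, "p_g_after_c": 0.45}


def _markov_seq(rng: np.random.Generator, length: int, params: dict) -> str:
    """First-order chain over A/C/G/T; the G-after-C probability controls the
    CpG observed/expected ratio independently of overall GC content."""
    bases = "ACGT"
    p = np.array([params["p"][b] for b in bases])
    p_after_c = p.copy()
    p_after_c[2] = params["p_g_after_c"]
    others = [0, 1, 3]
    p_after_c[others] *= (1.0 - p_after_c[2]) / p_after_c[others].sum()
    cum = np.cumsum(p)
    cum_c = np.cumsum(p_after_c)
    draws = rng.random(length)
    out = []
    prev = ""
    for u in draws:
        table = cum_c if prev == "C" else cum
        prev = bases[int(np.searchsorted(table, u))]
        out.append(prev)
    return "".join(out)


def generate_promoters(
    genes: list[str],
    island_flags: list[bool],
    seed: int = 0,
    upstream: int = cpg_islands.DEFAULT_UPSTREAM,
    downstream: int = cpg_islands.DEFAULT_DOWNSTREAM,
    max_tries: int = 200,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Simulate promoter windows around the TSS, with or without a CpG island.

    Flagged genes embed a 500-800 bp island segment near the TSS whose every
    scanning window satisfies the detection criteria (GC >= 55 %, obs/exp
    >= 0.65); unflagged genes are drawn CpG-depleted (obs/exp ~ 0.1) and are
    verified island-free.  Returns ``(sequences, tss_table)`` where sequences
    are genomic plus-strand (minus-strand promoters are stored
    reverse-complemented, as in a reference assembly) and the BED-like TSS
    table has 0-based half-open columns chrom, start, end, gene, score,
    strand.
    """
    if len(genes) != len(island_flags):
        raise ValueError("need exactly one island flag per gene")
    rng = np.random.default_rng([seed, 1])
    window = cpg_islands.DEFAULT_WINDOW
    length = upstream + downstream
    sequences: dict[str, str] = {}
    rows = []
    for gene, flagged in zip(genes, island_flags):
        for _ in range(max_tries):
            if flagged:
                isl_len = int(rng.integers(500, 801))
                isl_start = int(rng.integers(window, length - isl_len - window))
                island = _markov_seq(rng, isl_len, _ISLAND)
                stats = cpg_islands._SequenceStats(island)
                starts = np.arange(0, isl_len - window + 1)
                if not stats.valid_windows(
                    starts, window, cpg_islands.DEFAULT_GC_MIN, cpg_islands.DEFAULT_OE_MIN
                ).all():
                    continue
                seq = (
                    _markov_seq(rng, isl_start, _BACKGROUND)
                    + island
                    + _markov_seq(rng, length - isl_start - isl_len, _BACKGROUND)
                )
                if cpg_islands.find_cpg_islands(seq):
                    break
            else:
                seq = _markov_seq(rng, length, _BACKGROUND)
                if not cpg_islands.find_cpg_islands(seq):
                    break
        else:
            raise RuntimeError(f"could not generate a conforming promoter for {gene}")
        strand = "+" if rng.random() < 0.5 else "-"
        stored = str(Seq(seq).reverse_complement()) if strand == "-" else seq
        chrom = f"chr_{gene}"
        sequences[chrom] = stored
        rows.append(
            {
                "chrom": chrom,
                "start": 0,
                "end": length,
                "gene": gene,
                "score": 0,
                "strand": strand,
            }
        )
    tss = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "score", "strand"])
    return sequences, tss


def write_promoters(sequences: dict[str, str], tss: pd.DataFrame, fasta_path, tss_path) -> None:
    with open(fasta_path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    tss.to_csv(tss_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# qMSP plates


def generate_qmsp_plate(
    samples: pd.DataFrame,
    truth: TruthTable | None,
    config: SimulationConfig,
    genes: list[str] | None = None,
    replicates: int = 3,
    dilutions: tuple[float, ...] = (10000.0, 1000.0, 100.0, 10.0),
) -> pd.DataFrame:
    """Simulate a qMSP plate as triplicate Ct wells.

    ``samples`` needs columns sample_id and group (a truth-table group);
    an optional ``methylation_fraction`` column overrides the truth lookup
    and an optional ``dna_input`` column overrides ``config.dna_input``.
    The plate includes the gene assays and the ALU-C4 reference for every
    sample, a fully methylated positive control, and a dilution series of
    the universally methylated control for each assay.  Ct values follow
    the linear curve plus N(0, ct_noise_sd); zero-quantity wells never
    amplify (no-Ct token, NaN).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    if genes is None:
        if truth is None:
            raise ValueError("either genes or a truth table must be given")
        genes = truth.target_genes
    assays = list(genes) + [REFERENCE_ASSAY]

    def ct_for(quantity: float) -> float:
        if quantity <= 0:
            return float("nan")
        ct = config.curve_intercept + config.curve_slope * math.log10(quantity)
        if config.ct_noise_sd > 0:
            ct += rng.normal(0.0, config.ct_noise_sd)
        return ct

    rows = []

    def add_wells(sample_id: str, assay: str, quantity: float) -> None:
        for rep in range(1, replicates + 1):
            rows.append(
                {
                    "sample_id": sample_id,
                    "assay_id": assay,
                    "replicate": rep,
                    "ct": ct_for(quantity),
                }
            )

    for q in dilutions:
        for assay in assays:
            add_wells(f"{STANDARD_PREFIX}{q:g}", assay, q)

    for gene in genes:
        add_wells(POSITIVE_CONTROL, gene, config.dna_input)
    add_wells(POSITIVE_CONTROL, REFERENCE_ASSAY, config.dna_input)

    for rec in samples.itertuples(index=False):
        input_amount = float(getattr(rec, "dna_input", config.dna_input))
        for gene in genes:
            if hasattr(rec, "methylation_fraction"):
                fraction = float(rec.methylation_fraction)
            else:
                if truth is None:
                    raise ValueError("truth table required when samples carry no fractions")
                fraction = truth.fraction(gene, rec.group)
            add_wells(rec.sample_id, gene, fraction * input_amount)
        add_wells(rec.sample_id, REFERENCE_ASSAY, input_amount)

    return pd.DataFrame(rows, columns=["sample_id", "assay_id", "replicate", "ct"])


def cohort_sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    """Tumor + healthy-control sample sheet matching the expression cohorts,
    for feeding :func:`generate_qmsp_plate`."""
    rows = []
    for subtype, n in config.n_tumors_per_subtype.items():
        for j in range(n):
            rows.append({"sample_id": f"{subtype}_T{j + 1:02d}", "group": subtype})
    for j in range(config.n_controls):
        rows.append({"sample_id": f"CTRL_N{j + 1:02d}", "group": NORMAL_GROUP})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Electropherogram peak tables


def generate_electropherogram(
    sites: list[int],
    truth_ratios: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    total_height: float = 1000.0,
    non_cpg_positions: list[int] | None = None,
    conversion_efficiency: float = 1.0,
) -> pd.DataFrame:
    """Per-CpG C/T peak heights whose C/(C+T) ratio matches the planted
    methylation ratio in expectation.

    ``noise_sd`` is the peak-height noise as a fraction of ``total_height``.
    Optional non-CpG cytosine positions model conversion QC: with complete
    conversion they emit pure T signal; residual C signal appears as
    ``1 - conversion_efficiency``.
    """
    if len(sites) != len(truth_ratios):
        raise ValueError("need exactly one truth ratio per site")
    if any(not 0.0 <= r <= 1.0 for r in truth_ratios):
        raise ValueError("truth ratios must lie in [0, 1]")
    rng = np.random.default_rng([seed, 3])
    rows = []

    def add(position: int, ratio: float, context: str) -> None:
        hc = total_height * ratio
        ht = total_height * (1.0 - ratio)
        if noise_sd > 0:
            hc += rng.normal(0.0, noise_sd * total_height)
            ht += rng.normal(0.0, noise_sd * total_height)
        rows.append(
            {
                "position": position,
                "height_c": max(hc, 0.0),
                "height_t": max(ht, 0.0),
                "context": context,
            }
        )

    for pos, ratio in zip(sites, truth_ratios):
        add(pos, ratio, "CpG")
    for pos in non_cpg_positions or []:
        add(pos, 1.0 - conversion_efficiency, "CpH")
    return pd.DataFrame(rows, columns=["position", "height_c", "height_t", "context"])
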