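import numpy as np
import pandas as pd
import pytest

from methpanel import qmsp
from methpanel.expression_screen import run_screen
from methpanel.synthetic_data import (
    SimulationConfig,
    TruthTable,
    cohort_sample_sheet,
    generate_electropherogram,
    generate_expression,
    generate_promoters,
    generate_qmsp_plate,
)


def small_config(**overrides):
    defaults = dict(
        n_cell_lines=4,
        n_tumors_per_subtype={"BL": 3, "FL": 3},
        n_controls=3,
        n_elements=20,
        n_true_targets=2,
        seed=7,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def test_config_validation_rejects_bad_values():
    with pytest.raises(ValueError):
        small_config(reactivation_fold=1.0).validate()
    with pytest.raises(ValueError):
        small_config(conversion_efficiency=1.5).validate()
    with pytest.raises(ValueError):
        small_config(intensity_noise_sd=-0.1).validate()
    with pytest.raises(ValueError):
        small_config(n_controls=0).validate()


def test_rejects_more_targets_than_genes():
    with pytest.raises(ValueError, match="n_true_targets"):
        generate_expression(small_config(n_true_targets=30))


def test_noise_free_fold_changes_are_exact():
    """With zero noise every planted target shows exactly the configured
    fold change in every treated/untreated pair, and non-targets show none."""
    config = small_config(intensity_noise_sd=0.0, reactivation_fold=4.0)
    matrix, truth = generate_expression(config)
    targets = set(truth.target_genes)
    for untreated, treated in matrix.treated_pairs():
        fold = matrix.values[treated] / matrix.values[untreated]
        for element, value in fold.items():
            expected = 4.0 if matrix.gene_map[element] in targets else 1.0
            assert value == pytest.approx(expected, rel=1e-12)


def test_noise_free_tumor_downregulation_is_exact():
    config = small_config(intensity_noise_sd=0.0, downregulation_fold=8.0)
    matrix, truth = generate_expression(config)
    tumor = matrix.columns_with_role("tumor")
    normal = matrix.columns_with_role("normal")
    ratio = matrix.values[tumor].median(axis=1) / matrix.values[normal].median(axis=1)
    for element, value in ratio.items():
        expected = 0.125 if matrix.gene_map[element] in set(truth.target_genes) else 1.0
        assert value == pytest.approx(expected, rel=1e-12)


def test_same_seed_reproduces_identical_outputs():
    m1, t1 = generate_expression(small_config())
    m2, t2 = generate_expression(small_config())
    pd.testing.assert_frame_equal(m1.values, m2.values)
    pd.testing.assert_frame_equal(t1.table, t2.table)
    p1 = generate_qmsp_plate(cohort_sample_sheet(small_config()), t1, small_config())
    p2 = generate_qmsp_plate(cohort_sample_sheet(small_config()), t2, small_config())
    pd.testing.assert_frame_equal(p1, p2)
    s1, _ = generate_promoters(["A", "B"], [True, False], seed=3)
    s2, _ = generate_promoters(["A", "B"], [True, False], seed=3)
    assert s1 == s2


def test_truth_table_invariants_enforced():
    bad = pd.DataFrame(
        {"is_target": [False], "frac_BL": [0.5], "frac_normal": [0.0]},
        index=pd.Index(["G"], name="gene"),
    )
    with pytest.raises(ValueError, match="non-target"):
        TruthTable(table=bad, groups=["BL", "normal"])
    bad2 = pd.DataFrame(
        {"is_target": [True], "frac_BL": [0.5], "frac_normal": [0.2]},
        index=pd.Index(["G"], name="gene"),
    )
    with pytest.raises(ValueError, match="healthy-control"):
        TruthTable(table=bad2, groups=["BL", "normal"])


def test_screen_recovers_planted_targets():
    """200 elements, 10 planted targets, default noise: the screen ranks at
    least 9 of the 10 targets within its top-30 list."""
    config = SimulationConfig(seed=42)
    matrix, truth = generate_expression(config)
    result = run_screen(matrix, top_n=30)
    recovered = set(result.top_n) & set(truth.target_genes)
    assert len(recovered) >= 9


def test_promoters_have_study_geometry_and_flags():
    from methpanel.cpg_islands import find_cpg_islands

    genes = [f"G{i}" for i in range(6)]
    flags = [True, True, True, True, False, False]
    seqs, tss = generate_promoters(genes, flags, seed=17)
    assert all(len(s) == 1500 for s in seqs.values())
    assert list(tss["gene"]) == genes
    from Bio.Seq import Seq

    for flag, row in zip(flags, tss.itertuples()):
        seq = seqs[row.chrom]
        if row.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        assert (len(find_cpg_islands(seq)) > 0) is flag


def test_promoter_flag_mismatch_raises():
    with pytest.raises(ValueError):
        generate_promoters(["A", "B"], [True], seed=1)


def test_noise_free_plate_recovers_planted_pmr():
    """Closed-form inversion: with zero Ct noise the whole qMSP pipeline
    returns PMR = 100 x planted fraction, fraction 0 gives censored wells
    and PMR 0, and fraction 1 at control input gives PMR 100."""
    config = small_config(ct_noise_sd=0.0)
    samples = pd.DataFrame(
        {
            "sample_id": ["full", "quarter", "zero"],
            "group": ["BL", "BL", "BL"],
            "methylation_fraction": [1.0, 0.25, 0.0],
        }
    )
    plate = generate_qmsp_plate(samples, None, config, genes=["GENEX"])
    zero_wells = plate[(plate["sample_id"] == "zero") & (plate["assay_id"] == "GENEX")]
    assert zero_wells["ct"].isna().all()
    table, failed = qmsp.compute_pmr(plate)
    assert failed == []
    pmr = table.set_index("sample_id")["pmr"]
    assert pmr["full"] == pytest.approx(100.0, abs=1e-9)
    assert pmr["quarter"] == pytest.approx(25.0, abs=1e-9)
    assert pmr["zero"] == 0.0


def test_control_samples_yield_zero_pmr_for_every_gene():
    config = small_config(ct_noise_sd=0.0)
    _, truth = generate_expression(config)
    sheet = cohort_sample_sheet(config)
    controls = sheet[sheet["group"] == "normal"]
    plate = generate_qmsp_plate(controls, truth, config)
    table, _ = qmsp.compute_pmr(plate)
    table = table[table["sample_id"].str.startswith("CTRL")]
    assert (table["pmr"] == 0.0).all()


def test_electropherogram_ratios_match_truth():
    peaks = generate_electropherogram([1, 2, 3], [1.0, 0.5, 0.0], noise_sd=0.0)
    by_pos = peaks.set_index("position")
    assert by_pos.loc[1, "height_t"] == 0.0
    assert by_pos.loc[2, "height_c"] == by_pos.loc[2, "height_t"]
    assert by_pos.loc[3, "height_c"] == 0.0


def test_electropherogram_non_cpg_positions_convert_fully():
    peaks = generate_electropherogram(
        [10], [0.8], noise_sd=0.0, non_cpg_positions=[11, 12], conversion_efficiency=1.0
    )
    cph = peaks[peaks["context"] == "CpH"]
    assert (cph["height_c"] == 0.0).all()
    partial = generate_electropherogram(
        [10], [0.8], noise_sd=0.0, non_cpg_positions=[11], conversion_efficiency=0.9
    )
    cph = partial[partial["context"] == "CpH"].iloc[0]
    assert cph["height_c"] / (cph["height_c"] + cph["height_t"]) == pytest.approx(0.1)
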