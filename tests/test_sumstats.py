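"""Data layer: reading, validation, harmonization, clumping, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import robustmr as mr
from robustmr.sumstats import write_sumstats


# ---------------------------------------------------------------------------
# reading and validation
# ---------------------------------------------------------------------------


def test_read_write_roundtrip(toy_exposure, tmp_path):
    path = tmp_path / "sumstats.tsv"
    write_sumstats(toy_exposure, path)
    back = mr.read_sumstats(path, trait_label="exposure")
    pd.testing.assert_frame_equal(back.table, toy_exposure.table)


def test_read_with_dialect(tmp_path):
    df = pd.DataFrame(
        {"rsid": ["rs1"], "ea": ["A"], "oa": ["G"], "b": [0.1], "stderr": [0.02], "pval": [0.5]}
    )
    path = tmp_path / "odd.csv"
    df.to_csv(path, index=False)
    ss = mr.read_sumstats(
        path, dialect={"rsid": "SNP", "ea": "EA", "oa": "OA", "b": "BETA",
                       "stderr": "SE", "pval": "P"}
    )
    assert len(ss) == 1 and ss.table.loc[0, "BETA"] == 0.1


def test_missing_mandatory_column_is_config_error(tmp_path):
    path = tmp_path / "bad.tsv"
    pd.DataFrame({"SNP": ["rs1"], "EA": ["A"]}).to_csv(path, sep="\t", index=False)
    with pytest.raises(mr.ConfigError):
        mr.read_sumstats(path)


def test_nonpositive_se_names_offending_snp(toy_exposure):
    bad = toy_exposure.table.copy()
    bad.loc[1, "SE"] = 0.0
    with pytest.raises(mr.ValidationError) as err:
        mr.SummaryStats(bad)
    assert "rs2" in str(err.value)


@pytest.mark.parametrize(
    "column,value",
    [("P", 0.0), ("P", 1.5), ("EA", "X"), ("SNP", "rs1")],
)
def test_invariant_violations_rejected(toy_exposure, column, value):
    bad = toy_exposure.table.copy()
    bad.loc[2, column] = value  # duplicate id for the SNP case
    with pytest.raises(mr.ValidationError):
        mr.SummaryStats(bad)


def test_equal_alleles_rejected(toy_exposure):
    bad = toy_exposure.table.copy()
    bad.loc[0, "OA"] = bad.loc[0, "EA"]
    with pytest.raises(mr.ValidationError):
        mr.SummaryStats(bad)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------


def test_harmonize_identity(toy_exposure, toy_outcome):
    ds = mr.harmonize([toy_exposure], toy_outcome)
    assert ds.n_snps == 3
    np.testing.assert_allclose(ds.outcome_beta, toy_outcome.table["BETA"])
    assert (ds.orientation["action"] == "same").all()


def test_harmonize_swapped_alleles_flip_sign(toy_exposure, toy_outcome):
    swapped = toy_outcome.table.copy()
    swapped.loc[0, ["EA", "OA"]] = ["G", "A"]
    swapped.loc[0, "BETA"] = -0.1
    swapped.loc[0, "EAF"] = 0.8
    ds = mr.harmonize([toy_exposure], mr.SummaryStats(swapped, trait_label="outcome"))
    assert ds.outcome_beta[0] == pytest.approx(0.1)
    assert ds.outcome_eaf[0] == pytest.approx(0.2)


def test_harmonize_strand_complement(toy_exposure, toy_outcome):
    # outcome reports rs1 on the opposite strand: A/G -> T/C, same effect direction
    flipped = toy_outcome.table.copy()
    flipped.loc[0, ["EA", "OA"]] = ["T", "C"]
    ds = mr.harmonize([toy_exposure], mr.SummaryStats(flipped, trait_label="outcome"))
    assert ds.outcome_beta[0] == pytest.approx(0.10)


def test_palindromic_ambiguous_dropped_and_logged(toy_exposure, toy_outcome):
    for tab in (toy_exposure, toy_outcome):
        tab.table.loc[0, ["EA", "OA"]] = ["A", "T"]
        tab.table.loc[0, "EAF"] = 0.50
    ds = mr.harmonize([toy_exposure], toy_outcome)
    assert "rs1" not in set(ds.snp_ids)
    reasons = {d["SNP"]: d["reason"] for d in ds.meta["drop_log"]}
    assert reasons["rs1"] == "palindromic_ambiguous_eaf"


def test_palindromic_informative_eaf_kept(toy_exposure, toy_outcome):
    for tab in (toy_exposure, toy_outcome):
        tab.table.loc[0, ["EA", "OA"]] = ["A", "T"]
        tab.table.loc[0, "EAF"] = 0.2
    ds = mr.harmonize([toy_exposure], toy_outcome)
    assert "rs1" in set(ds.snp_ids)


def test_strict_policy_drops_all_palindromes(toy_exposure, toy_outcome):
    for tab in (toy_exposure, toy_outcome):
        tab.table.loc[0, ["EA", "OA"]] = ["G", "C"]
        tab.table.loc[0, "EAF"] = 0.1
    ds = mr.harmonize([toy_exposure], toy_outcome, palindrome_policy="strict")
    assert "rs1" not in set(ds.snp_ids)


def test_incompatible_alleles_dropped_with_reason(toy_exposure, toy_outcome):
    toy_outcome.table.loc[1, ["EA", "OA"]] = ["A", "C"]  # exposure has C/T
    ds = mr.harmonize([toy_exposure], toy_outcome)
    assert "rs2" not in set(ds.snp_ids)
    assert any(d["reason"] == "incompatible_alleles" for d in ds.meta["drop_log"])


def test_empty_intersection_raises(toy_exposure, toy_outcome):
    toy_outcome.table["SNP"] = ["rsX", "rsY", "rsZ"]
    with pytest.raises(mr.EmptyDatasetError):
        mr.harmonize([toy_exposure], toy_outcome)


def test_harmonize_idempotent(toy_exposure, toy_outcome):
    """A second harmonization pass over the aligned tables applies no flips."""
    swapped = toy_outcome.table.copy()
    swapped.loc[0, ["EA", "OA"]] = ["G", "A"]
    swapped.loc[0, "BETA"] = -0.1
    swapped.loc[0, "EAF"] = 0.8
    ds = mr.harmonize([toy_exposure], mr.SummaryStats(swapped, trait_label="outcome"))
    exposures, outcome = ds.harmonized_tables()
    ds2 = mr.harmonize(exposures, outcome)
    assert (ds2.orientation["action"] == "same").all()
    np.testing.assert_allclose(ds2.outcome_beta, ds.outcome_beta)


def test_orientation_log_reconstructs_original_signs(toy_exposure, toy_outcome):
    swapped = toy_outcome.table.copy()
    swapped.loc[[0, 2], ["EA", "OA"]] = swapped.loc[[0, 2], ["OA", "EA"]].to_numpy()
    swapped.loc[[0, 2], "BETA"] *= -1
    swapped.loc[[0, 2], "EAF"] = 1 - swapped.loc[[0, 2], "EAF"]
    ds = mr.harmonize([toy_exposure], mr.SummaryStats(swapped, trait_label="outcome"))
    flips = ds.orientation.query("source == 'outcome'").set_index("SNP")["action"]
    recovered = ds.outcome_beta.copy()
    mask = flips.loc[list(ds.snp_ids)].isin(["swap", "swap_flipstrand"]).to_numpy()
    recovered[mask] *= -1  # applying the logged flips again restores the input
    np.testing.assert_allclose(recovered, swapped.set_index("SNP").loc[list(ds.snp_ids), "BETA"])


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------


def _random_ld(p, seed, density=0.3):
    rng = np.random.default_rng(seed)
    base = rng.uniform(0, 1, (p, p)) * (rng.random((p, p)) < density)
    r2 = np.triu(base, 1)
    r2 = r2 + r2.T
    np.fill_diagonal(r2, 1.0)
    return r2


def _brute_force_clump(table, ld, r2_threshold):
    """Independent greedy oracle: literal restatement of the selection rule."""
    rows = table.table.sort_values(["P", "SNP"]).to_dict("records")
    idx = {s: i for i, s in enumerate(ld.snp_ids)}
    removed, kept = set(), []
    for row in rows:
        if row["SNP"] in removed:
            continue
        kept.append(row["SNP"])
        for other in ld.snp_ids:
            if other != row["SNP"] and ld.r2[idx[row["SNP"]], idx[other]] > r2_threshold:
                removed.add(other)
    return kept


def _table_for_clump(p, seed):
    rng = np.random.default_rng(seed)
    return mr.SummaryStats(
        pd.DataFrame(
            {
                "SNP": [f"rs{i}" for i in range(p)],
                "EA": ["A"] * p,
                "OA": ["G"] * p,
                "EAF": 0.3,
                "BETA": rng.normal(0, 0.1, p),
                "SE": 0.02,
                "P": rng.uniform(1e-12, 1e-2, p),
                "N": 10000,
            }
        )
    )


def test_clump_identity_ld_keeps_all():
    table = _table_for_clump(10, 1)
    ld = mr.LDMatrix(list(table.snp_ids), np.eye(10))
    assert sorted(mr.clump(table, ld, 0.001)) == sorted(table.snp_ids)


def test_clump_perfect_ld_keeps_best_pvalue():
    table = mr.SummaryStats(
        pd.DataFrame(
            {
                "SNP": ["rsA", "rsB"], "EA": ["A", "A"], "OA": ["G", "G"],
                "EAF": 0.3, "BETA": [0.1, 0.1], "SE": 0.02,
                "P": [1e-9, 1e-5], "N": 1000,
            }
        )
    )
    ld = mr.LDMatrix(["rsA", "rsB"], np.array([[1.0, 1.0], [1.0, 1.0]]))
    assert mr.clump(table, ld, 0.001) == ["rsA"]


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_clump_matches_brute_force_oracle(seed):
    table = _table_for_clump(50, seed)
    ld = mr.LDMatrix(list(table.snp_ids), _random_ld(50, seed + 100))
    for thr in (0.001, 0.1, 0.5):
        assert mr.clump(table, ld, thr) == _brute_force_clump(table, ld, thr)


def test_clump_threshold_above_max_offdiag_keeps_all():
    table = _table_for_clump(20, 5)
    r2 = _random_ld(20, 7)
    ld = mr.LDMatrix(list(table.snp_ids), r2)
    max_off = (r2 - np.eye(20)).max()
    assert sorted(mr.clump(table, ld, max_off + 1e-9)) == sorted(table.snp_ids)


def test_clump_zero_threshold_maximal_independent_set():
    table = _table_for_clump(30, 6)
    ld = mr.LDMatrix(list(table.snp_ids), _random_ld(30, 8))
    kept = mr.clump(table, ld, 0.0)
    idx = {s: i for i, s in enumerate(ld.snp_ids)}
    for a in kept:
        for b in kept:
            if a != b:
                assert ld.r2[idx[a], idx[b]] == 0.0


def test_clump_missing_snp_in_ld_named():
    table = _table_for_clump(3, 9)
    ld = mr.LDMatrix(["rs0", "rs1"], np.eye(2))
    with pytest.raises(mr.ValidationError) as err:
        mr.clump(table, ld, 0.001)
    assert "rs2" in str(err.value)


def test_ld_matrix_validation():
    with pytest.raises(mr.ValidationError):
        mr.LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.2, 1.0]]))  # asymmetric
    with pytest.raises(mr.ValidationError):
        mr.LDMatrix(["a", "b"], np.array([[0.9, 0.5], [0.5, 1.0]]))  # diagonal
    with pytest.raises(mr.ValidationError):
        mr.LDMatrix(["a", "b"], np.array([[1.0, 1.5], [1.5, 1.0]]))  # range


def test_ld_matrix_roundtrip(tmp_path):
    ld = mr.LDMatrix(["rs1", "rs2"], np.array([[1.0, 0.25], [0.25, 1.0]]))
    mr.write_ld_matrix(ld, tmp_path / "ld.tsv")
    back = mr.read_ld_matrix(tmp_path / "ld.tsv")
    assert back.snp_ids == ld.snp_ids
    np.testing.assert_allclose(back.r2, ld.r2)


# ---------------------------------------------------------------------------
# instrument selection
# ---------------------------------------------------------------------------


def test_select_all_at_vacuous_threshold(toy_exposure, toy_outcome):
    ds = mr.harmonize([toy_exposure], toy_outcome)
    assert mr.select_instruments(ds, 1.0).n_snps == 3


def test_select_counts_and_meta():
    tab = pd.DataFrame(
        {
            "SNP": ["rs1", "rs2", "rs3"], "EA": ["A"] * 3, "OA": ["G"] * 3,
            "EAF": 0.3, "BETA": [0.5, 0.2, 0.1], "SE": [0.05, 0.05, 0.05],
            "P": [1e-9, 5e-5, 2e-3], "N": 1000,
        }
    )
    exposure = mr.SummaryStats(tab, trait_label="exposure")
    outcome = mr.SummaryStats(tab.assign(BETA=0.01, P=0.5), trait_label="outcome")
    ds = mr.select_instruments(mr.harmonize([exposure], outcome), 1e-4)
    assert ds.n_snps == 2
    assert ds.meta["p_threshold"] == 1e-4
    assert ds.meta["n_genome_wide"] == 1  # only the 1e-9 SNP is genome-wide


def test_select_recount_matches_raw_table():
    cfg = mr.SimConfig(p=200, beta=0.3, seed=42, gamma_dist=mr.GammaSpec(sd=0.05))
    exposure, outcome, _ = mr.simulate_two_sample(cfg)
    ds = mr.select_instruments(mr.as_harmonized(exposure, outcome), 1e-4)
    independent = int((exposure.table["P"] < 1e-4).sum())
    assert ds.n_snps == independent


def test_select_monotone_in_threshold(strong_ds):
    small = set(mr.select_instruments(strong_ds, 1e-8).snp_ids)
    large = set(mr.select_instruments(strong_ds, 1e-2).snp_ids)
    assert small <= large


def test_select_zero_survivors_raises(toy_exposure, toy_outcome):
    ds = mr.harmonize([toy_exposure], toy_outcome)
    ds.exposure_pvalue = np.full_like(ds.exposure_pvalue, 0.5)
    with pytest.raises(mr.EmptyDatasetError):
        mr.select_instruments(ds, 1e-10)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_select_monotonicity_property(seed):
    ds = mr.as_harmonized(*mr.simulate_two_sample(
        mr.SimConfig(p=30, beta=0.2, seed=seed, gamma_dist=mr.GammaSpec(sd=0.03)))[:2])
    thresholds = [1e-8, 1e-4, 1e-2, 1.0]
    prev = set()
    for thr in thresholds:
        try:
            cur = set(mr.select_instruments(ds, thr).snp_ids)
        except mr.EmptyDatasetError:
            cur = set()
        assert prev <= cur
        prev = cur
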