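"""Profile-likelihood machinery: modes, markers, MVMR, conditional Q, QQ."""

import numpy as np
import pytest

import robustmr as mr

from conftest import make_dataset

TWO_PATHWAY = dict(
    p=150, beta=0.4, seed=2,
    pleiotropy=mr.PleiotropySpec(mode="correlated", tau=0.01, fraction=0.4,
                                 confounder_shift=-0.6),
)


@pytest.fixture(scope="module")
def two_pathway_ds():
    e, o, t = mr.simulate_two_sample(mr.SimConfig(**TWO_PATHWAY))
    return mr.as_harmonized(e, o), t


# ---------------------------------------------------------------------------
# robust_profile / detect_modes
# ---------------------------------------------------------------------------


def test_one_pathway_single_mode_near_truth():
    ds = make_dataset(p=150, beta=0.4, seed=1)
    ms = mr.detect_modes(mr.robust_profile(ds))
    assert len(ms) == 1
    assert ms.modes[0].beta == pytest.approx(0.4, abs=0.05)
    assert not ms.near_zero_flag


def test_profile_reflection_symmetry():
    ds = make_dataset(p=80, beta=0.3, seed=12)
    neg = mr.HarmonizedDataset(ds.snp_ids, ds.exposure_beta, ds.exposure_se,
                               -ds.outcome_beta, ds.outcome_se)
    m1 = mr.detect_modes(mr.robust_profile(ds))
    m2 = mr.detect_modes(mr.robust_profile(neg))
    assert len(m1) == len(m2)
    for a, b in zip(m1.modes, m2.modes):
        assert a.beta == pytest.approx(-b.beta, abs=1e-6)
        assert a.objective == pytest.approx(b.objective, abs=1e-8)


def test_two_pathway_modes_match_fine_grid_oracle(two_pathway_ds):
    ds, truth = two_pathway_ds
    curve = mr.robust_profile(ds)
    ms = mr.detect_modes(curve)
    assert len(ms) == 2
    # independent oracle: exhaustive fine-grid maxima of the same objective
    loss = mr.get_loss("tukey")
    grid = np.arange(-1.0, 1.0, 1e-4)
    g, sg = ds.single_exposure()
    t = (ds.outcome_beta[:, None] - grid[None, :] * g[:, None]) / np.sqrt(
        ds.outcome_se[:, None] ** 2 + grid[None, :] ** 2 * sg[:, None] ** 2
    )
    obj = -loss.rho(t).sum(axis=0)
    local = np.flatnonzero((obj[1:-1] > obj[:-2]) & (obj[1:-1] >= obj[2:])) + 1
    tops = sorted(local, key=lambda i: -obj[i])[:2]
    oracle = sorted(grid[i] for i in tops)
    found = sorted(m.beta for m in ms.modes)
    np.testing.assert_allclose(found, oracle, atol=5e-4)
    # and each sits within 0.05 of its generating pathway's apparent effect
    assert found[0] == pytest.approx(-0.2, abs=0.05)
    assert found[1] == pytest.approx(0.4, abs=0.05)
    assert not ms.near_zero_flag


def test_reverse_direction_raises_near_zero_flag():
    cfg = mr.SimConfig(
        p=400, beta=0.4, seed=3,
        gamma_dist=mr.GammaSpec(kind="spike_slab", sd=0.4, slab_fraction=0.15,
                                spike_sd=0.005),
        pleiotropy=mr.PleiotropySpec(mode="balanced", tau=0.05),
    )
    e, o, _ = mr.simulate_two_sample(cfg)
    forward = mr.select_instruments(mr.as_harmonized(e, o), 1e-4)
    assert not mr.detect_modes(mr.robust_profile(forward)).near_zero_flag
    reversed_ds = mr.select_instruments(mr.as_harmonized(o, e), 1e-4)
    ms = mr.detect_modes(mr.robust_profile(reversed_ds, grid_spec=(-4, 4, 0.002)))
    assert len(ms) >= 2
    assert ms.near_zero_flag


def test_detect_modes_on_concave_curve():
    grid = np.linspace(-1, 1, 2001)
    loglik = -((grid - 0.25) ** 2) * 50
    curve = mr.ProfileCurve(grid=grid, loglik=loglik,
                            modes=[mr.Mode(0.25, 0.0, -100.0)], residuals_at_mode={})
    ms = mr.detect_modes(curve)
    assert len(ms) == 1
    assert ms.modes[0].beta == pytest.approx(0.25)


def test_profile_invariant_to_snp_order():
    ds = make_dataset(p=40, beta=0.3, seed=13)
    perm = np.random.default_rng(0).permutation(40)
    ds_p = mr.HarmonizedDataset(ds.snp_ids[perm], ds.exposure_beta[perm],
                                ds.exposure_se[perm], ds.outcome_beta[perm],
                                ds.outcome_se[perm])
    c1 = mr.robust_profile(ds)
    c2 = mr.robust_profile(ds_p)
    np.testing.assert_allclose(c1.loglik, c2.loglik, rtol=1e-12)


def test_low_prominence_does_not_split_single_pathway():
    ds = make_dataset(p=150, beta=0.4, seed=1)
    ms = mr.detect_modes(mr.robust_profile(ds), min_prominence=1e-9)
    assert len(ms) == 1


def test_profile_errors_when_grid_misses_maximum():
    ds = make_dataset(p=30, beta=0.3, seed=14)
    with pytest.raises(mr.RobustMRError):
        mr.robust_profile(ds, grid_spec=(5.0, 6.0, 0.1))


# ---------------------------------------------------------------------------
# marker SNPs
# ---------------------------------------------------------------------------


def test_marker_snp_exact_fit_included():
    g = np.array([0.5, 0.4])
    G = 0.3 * g
    ds = mr.HarmonizedDataset(np.array(["a", "b"], dtype=object), g,
                              np.full(2, 0.01), G, np.full(2, 0.02))
    assert set(mr.marker_snps(ds, 0.3)) == {"a", "b"}


def test_marker_snp_large_residual_excluded():
    ds = mr.HarmonizedDataset(np.array(["a"], dtype=object), np.array([0.5]),
                              np.array([1e-9]), np.array([0.3 * 0.5 + 5 * 0.02]),
                              np.array([0.02]))
    assert mr.marker_snps(ds, 0.3) == []


def test_marker_sets_partition_pathways(two_pathway_ds):
    ds, truth = two_pathway_ds
    ms = mr.detect_modes(mr.robust_profile(ds))
    modes = sorted((m.beta for m in ms.modes), reverse=True)  # [~0.4, ~-0.2]
    markers_main = set(mr.marker_snps(ds, modes[0], residual_cutoff=2.0))
    markers_conf = set(mr.marker_snps(ds, modes[1], residual_cutoff=2.0))
    valid = set(truth.snp_ids[truth.pathway_label == "valid"])
    conf = set(truth.snp_ids[truth.pathway_label == "confounder"])
    correct = len(markers_main & valid) + len(markers_conf & conf)
    labeled = len(markers_main) + len(markers_conf)
    assert labeled > 0
    assert correct / labeled >= 0.9


# ---------------------------------------------------------------------------
# MVMR
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("loss", ["l2", "tukey"])
def test_mvmr_k1_nests_raps(loss, strong_ds):
    mv = mr.mvmr_fit(strong_ds, loss=loss)
    rp = mr.raps(strong_ds, loss=loss, overdispersion=False)
    assert mv.betas[0] == pytest.approx(rp.beta, abs=1e-8)


def test_mvmr_duplicate_exposure_singular(strong_ds):
    ds = mr.HarmonizedDataset(
        strong_ds.snp_ids,
        np.column_stack([strong_ds.exposure_beta[:, 0]] * 2),
        np.column_stack([strong_ds.exposure_se[:, 0]] * 2),
        strong_ds.outcome_beta, strong_ds.outcome_se,
    )
    with pytest.raises(mr.ConvergenceError):
        mr.mvmr_fit(ds)


def test_mvmr_underidentified():
    ds = make_dataset(p=2, beta=0.3, seed=15)
    ds2 = mr.HarmonizedDataset(
        ds.snp_ids, np.column_stack([ds.exposure_beta[:, 0]] * 2 + [ds.outcome_beta]),
        np.column_stack([ds.exposure_se[:, 0]] * 3),
        ds.outcome_beta, ds.outcome_se,
    )
    with pytest.raises(mr.UnderIdentifiedError):
        mr.mvmr_fit(ds2)


def test_mvmr_zero_mediator_column_equals_univariable(strong_ds):
    p = strong_ds.n_snps
    ds = mr.HarmonizedDataset(
        strong_ds.snp_ids,
        np.column_stack([strong_ds.exposure_beta[:, 0], np.zeros(p)]),
        np.column_stack([strong_ds.exposure_se[:, 0], np.full(p, 1e-3)]),
        strong_ds.outcome_beta, strong_ds.outcome_se,
    )
    mv = mr.mvmr_fit(ds, loss="tukey")
    uni = mr.raps(strong_ds, loss="tukey")
    assert mv.betas[0] == pytest.approx(uni.beta, abs=1e-6)
    assert mv.betas[1] == 0.0


def test_mvmr_irrelevant_instrument_removal(two_pathway_ds=None):
    cfg = mr.SimConfig(p=60, beta=0.0, seed=16, mediation=mr.MediationSpec())
    _, _, _, ds_xmy, _ = mr.simulate_mediation(cfg)
    mv_full = mr.mvmr_fit(ds_xmy, loss="l2")
    # drop the instrument least relevant to every exposure
    strength = (np.abs(ds_xmy.exposure_beta) / ds_xmy.exposure_se).min(axis=1)
    keep = np.ones(ds_xmy.n_snps, dtype=bool)
    keep[np.argmin(strength)] = False
    mv_red = mr.mvmr_fit(ds_xmy.subset(keep), loss="l2")
    for k in range(2):
        assert abs(mv_full.betas[k] - mv_red.betas[k]) < 2 * mv_full.ses[k]


def test_mvmr_bonferroni_divisor(strong_ds):
    mv = mr.mvmr_fit(strong_ds, loss="l2")
    assert mv.bonferroni_significant[0] == (mv.pvalues[0] < 0.05 / 1)


# ---------------------------------------------------------------------------
# conditional Q
# ---------------------------------------------------------------------------


def test_conditional_q_exact_fit_zero():
    rng = np.random.default_rng(17)
    g = rng.normal(0.3, 0.1, (20, 2))
    betas = np.array([0.2, -0.1])
    G = g @ betas
    ds = mr.HarmonizedDataset(np.array([f"s{i}" for i in range(20)], dtype=object),
                              g, np.full((20, 2), 0.01), G, np.full(20, 0.05))
    q, df, pv = mr.conditional_q(ds, betas)
    assert q == pytest.approx(0.0, abs=1e-20)
    assert df == 18
    assert pv == pytest.approx(1.0)


def test_conditional_q_k1_equals_classical_q(strong_ds):
    est = mr.raps(strong_ds, loss="l2")
    q, df, _ = mr.conditional_q(strong_ds, [est.beta])
    g, sg = strong_ds.single_exposure()
    t = (strong_ds.outcome_beta - est.beta * g) / np.sqrt(
        strong_ds.outcome_se**2 + est.beta**2 * sg**2
    )
    assert q == pytest.approx(float(np.sum(t**2)))
    assert df == strong_ds.n_snps - 1


def test_conditional_q_null_calibration():
    """Model-correct K=2 fits: Q ~ chi2(p - K), 5% test near nominal."""
    qs, rej, nrep = [], 0, 300
    for r in range(nrep):
        cfg = mr.SimConfig(p=50, beta=0.0, seed=600_000 + r, mediation=mr.MediationSpec())
        _, _, _, ds_xmy, _ = mr.simulate_mediation(cfg)
        mv = mr.mvmr_fit(ds_xmy, loss="l2")
        qs.append(mv.q_stat)
        rej += mv.q_pvalue < 0.05
    mc_se = np.std(qs, ddof=1) / np.sqrt(nrep)
    assert abs(np.mean(qs) - 48) < 2 * mc_se + 0.5
    assert 0.03 <= rej / nrep <= 0.08


def test_conditional_q_detects_planted_heterogeneity():
    rej, nrep = 0, 200
    for r in range(nrep):
        cfg = mr.SimConfig(p=50, beta=0.0, seed=700_000 + r, mediation=mr.MediationSpec())
        _, _, _, ds, _ = mr.simulate_mediation(cfg)
        contaminated = ds.outcome_beta.copy()
        contaminated[:10] += 5 * ds.outcome_se[:10]  # 20% of SNPs offset
        ds2 = mr.HarmonizedDataset(ds.snp_ids, ds.exposure_beta, ds.exposure_se,
                                   contaminated, ds.outcome_se)
        mv = mr.mvmr_fit(ds2, loss="l2")
        rej += mv.q_pvalue < 0.05
    assert rej / nrep > 0.8


def test_conditional_q_df_error():
    ds = make_dataset(p=1, beta=0.3, seed=18)
    with pytest.raises(mr.UnderIdentifiedError):
        mr.conditional_q(ds, [0.3])


# ---------------------------------------------------------------------------
# QQ diagnostic
# ---------------------------------------------------------------------------


def test_qq_normal_sample_tracks_theoretical():
    rng = np.random.default_rng(2)
    p = 200
    g = rng.normal(0.4, 0.1, p)
    sG = np.full(p, 0.01)
    G = sG * rng.standard_normal(p)  # true beta = 0: residuals exactly N(0,1)
    ds = mr.HarmonizedDataset(np.array([f"s{i}" for i in range(p)], dtype=object),
                              g, np.full(p, 1e-8), G, sG)
    qq = mr.residual_qq(ds, mr.raps(ds, loss="l2"))
    dev = np.abs(qq.table["theoretical_quantile"] - qq.table["observed_t"])
    assert dev.max() < 0.25
    assert qq.shapiro_pvalue > 0.01


def test_qq_constant_residuals():
    g = np.full(5, 0.5)
    G = 0.2 * g + 0.03
    ds = mr.HarmonizedDataset(np.array(list("abcde"), dtype=object), g,
                              np.full(5, 1e-12), G, np.full(5, 0.03))
    est = mr.MREstimate(0.2, 0.01, 0.18, 0.22, 0.01, "IVW", 5)
    qq = mr.residual_qq(ds, est)
    assert np.allclose(qq.table["observed_t"], 1.0)


def test_qq_row_count(strong_ds):
    qq = mr.residual_qq(strong_ds, mr.raps(strong_ds, loss="tukey"))
    assert len(qq.table) == strong_ds.n_snps
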