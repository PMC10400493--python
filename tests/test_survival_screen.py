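import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from kmscreen import (
    SurvivalEndpoint,
    ValidationError,
    bh_adjust,
    candidate_cutoffs,
    cox_binary,
    cox_score_test,
    km_curve,
    logrank_scan,
    logrank_two_group,
    merge_cohorts,
    scan_gene,
    screen,
    select_best,
)
from kmscreen.survival_screen import CutoffScan, _cox_binary_batch, _scan_statistics


def _random_survival(rng, n, censor=0.4):
    t = rng.exponential(40, n)
    c = rng.exponential(40 / censor * (1 - censor), n)
    return np.minimum(t, c), (t <= c).astype(int)


# --- candidate cutoffs -----------------------------------------------------


def test_cutoffs_for_one_to_eight_are_three_to_six():
    cuts = candidate_cutoffs(np.arange(1.0, 9.0))
    np.testing.assert_array_equal(cuts, [3.0, 4.0, 5.0, 6.0])


def test_constant_vector_yields_no_cutoffs():
    assert len(candidate_cutoffs(np.full(10, 7.0))) == 0


@settings(derandomize=True, max_examples=200)
@given(
    st.lists(st.floats(min_value=0.1, max_value=1e4), min_size=4, max_size=40).filter(
        lambda v: len(set(v)) >= 4
    )
)
def test_every_cutoff_splits_into_two_nonempty_groups(values):
    x = np.array(values)
    q1, q3 = np.quantile(x, [0.25, 0.75])
    cuts = candidate_cutoffs(x)
    if len(set(values)) == len(values):
        assert len(cuts) >= 1  # all-distinct values always admit a cutoff
    for c in cuts:
        assert q1 <= c < q3
        assert (x <= c).any() and (x > c).any()


# --- log-rank --------------------------------------------------------------


def test_logrank_matches_hand_computation_on_perfect_separation(toy_survival):
    # six risk tables worked by hand: O-E = -1.85, Var = 0.6775
    time, event, group = toy_survival
    chi2, p = logrank_two_group(time, event, group)
    assert chi2 == pytest.approx(3.4225 / 0.6775, rel=1e-12)


def test_logrank_symmetric_under_group_swap(null_cohort):
    rng = np.random.default_rng(0)
    t, e = _random_survival(rng, 80)
    g = rng.uniform(size=80) > 0.5
    assert logrank_two_group(t, e, g) == pytest.approx(logrank_two_group(t, e, ~g))


def test_single_event_balanced_groups_p_near_one():
    t = np.arange(1.0, 21.0)
    e = np.zeros(20, int)
    e[0] = 1
    g = np.arange(20) % 2 == 0
    chi2, p = logrank_two_group(t, e, g)
    assert p > 0.3


def test_zero_events_is_an_error():
    with pytest.raises(ValidationError, match="no events"):
        logrank_two_group(np.arange(1.0, 5.0), np.zeros(4, int), np.array([1, 1, 0, 0], bool))


def test_vectorized_scan_equals_naive_and_lifelines():
    rng = np.random.default_rng(3)
    n = 90
    x = 100 + np.exp(rng.normal(6, 1, n))
    t, e = _random_survival(rng, n)
    t = np.round(t) + 0.5  # induce event-time ties
    cuts = candidate_cutoffs(x)
    chi2, p, n_low, n_high = _scan_statistics(x, t, e, cuts)
    for i, c in enumerate(cuts):
        ref, _ = logrank_two_group(t, e, x > c)
        assert chi2[i] == pytest.approx(ref, abs=1e-10)
        ll = logrank_test(t[x <= c], t[x > c], e[x <= c], e[x > c])
        assert chi2[i] == pytest.approx(ll.test_statistic, abs=1e-8)
        assert n_low[i] + n_high[i] == n


def test_scan_invariant_under_monotone_transform():
    rng = np.random.default_rng(4)
    n = 60
    x = 100 + np.exp(rng.normal(6, 1, n))
    t, e = _random_survival(rng, n)
    ep = SurvivalEndpoint(t, e)
    s1 = logrank_scan(x, ep)
    s2 = logrank_scan(x**2, ep)  # strictly increasing for positive x
    assert len(s1) == len(s2)
    np.testing.assert_allclose(np.sort(s1.chi2), np.sort(s2.chi2), rtol=1e-9)
    np.testing.assert_allclose(s1.p, s2.p, rtol=1e-9)


# --- BH --------------------------------------------------------------------


def _bh_stepup_reference(p):
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        out[i] = running
    return out


def test_bh_hand_worked_examples():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    np.testing.assert_allclose(bh_adjust([0.3]), [0.3])
    np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError):
        bh_adjust([0.5, 0.0])
    with pytest.raises(ValidationError):
        bh_adjust([1.5])


@settings(derandomize=True, max_examples=200)
@given(
    st.lists(
        st.floats(min_value=1e-10, max_value=1.0, exclude_min=False), min_size=1, max_size=30
    )
)
def test_bh_matches_stepup_reference(pvals):
    np.testing.assert_allclose(bh_adjust(pvals), _bh_stepup_reference(np.array(pvals)), rtol=1e-12)


# --- Cox -------------------------------------------------------------------


def test_cox_binary_matches_lifelines_with_ties():
    rng = np.random.default_rng(5)
    n = 120
    t, e = _random_survival(rng, n)
    t = np.round(t) + 0.5
    g = rng.uniform(size=n) > 0.4
    fit = cox_binary(t, e, g)
    df = pd.DataFrame({"t": t, "e": e, "g": g.astype(float)})
    cpf = CoxPHFitter().fit(df, "t", "e")
    assert fit["beta"] == pytest.approx(cpf.params_["g"], abs=1e-6)
    assert fit["se"] == pytest.approx(cpf.standard_errors_["g"], abs=1e-6)
    assert fit["hr_lo"] < fit["hr"] < fit["hr_hi"]


def test_cox_score_test_equals_logrank_without_ties():
    rng = np.random.default_rng(6)
    n = 100
    t = rng.exponential(40, n)  # continuous: no ties
    e = (rng.uniform(size=n) > 0.3).astype(int)
    g = rng.uniform(size=n) > 0.5
    score = cox_score_test(t, e, g)
    chi2, _ = logrank_two_group(t, e, g)
    assert score == pytest.approx(chi2, rel=1e-6)


def test_batch_cox_agrees_with_scalar_solver():
    rng = np.random.default_rng(7)
    n = 80
    x = 100 + np.exp(rng.normal(6, 1, n))
    t, e = _random_survival(rng, n)
    cuts = candidate_cutoffs(x)
    batch = _cox_binary_batch(x, t, e, cuts)
    for i in range(0, len(cuts), 5):
        ref = cox_binary(t, e, x > cuts[i])
        assert batch["beta"][i] == pytest.approx(ref["beta"], abs=1e-9)
        assert batch["se"][i] == pytest.approx(ref["se"], abs=1e-9)


# --- selection -------------------------------------------------------------


def _make_scan(x, fdr):
    cuts = candidate_cutoffs(x)
    scan = CutoffScan(
        gene="g",
        cutoffs=cuts,
        n_low=np.array([(x <= c).sum() for c in cuts]),
        n_high=np.array([(x > c).sum() for c in cuts]),
        chi2=np.ones(len(cuts)),
        p=np.full(len(cuts), 0.5),
        fdr=np.asarray(fdr, dtype=float),
        q1=float(np.quantile(x, 0.25)),
        q3=float(np.quantile(x, 0.75)),
    )
    return scan, cuts


def test_lowest_fdr_wins_regardless_of_hr():
    rng = np.random.default_rng(8)
    x = np.sort(100 + np.exp(rng.normal(6, 1, 40)))
    t, e = _random_survival(rng, 40)
    ep = SurvivalEndpoint(t, e)
    scan, cuts = _make_scan(x, np.linspace(0.01, 0.9, len(candidate_cutoffs(x))))
    res = select_best(scan, x, ep)
    assert res.selected_cutoff == cuts[0]
    assert res.fdr_at_selected == pytest.approx(0.01)


def test_fdr_tie_broken_by_highest_hazard_ratio():
    rng = np.random.default_rng(9)
    n = 60
    x = 100 + np.exp(rng.normal(6, 1, n))
    # plant a real effect so HR varies across cutoffs
    risk = x > np.median(x)
    t = rng.exponential(np.where(risk, 15, 45))
    e = np.ones(n, int)
    ep = SurvivalEndpoint(t, e)
    scan, cuts = _make_scan(x, np.full(len(candidate_cutoffs(x)), 0.02))
    res = select_best(scan, x, ep)
    hrs = np.array([cox_binary(t, e, x > c)["hr"] for c in cuts])
    assert res.selected_cutoff == cuts[int(np.argmax(hrs))]
    assert res.hr == pytest.approx(hrs.max(), rel=1e-9)


def test_remaining_tie_broken_by_smallest_cutoff():
    x = np.array([10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0] * 3)
    t = np.arange(1.0, 25.0)
    e = np.ones(24, int)
    ep = SurvivalEndpoint(t, e)
    cuts = candidate_cutoffs(x)
    # identical fdr everywhere and a survival pattern independent of x order:
    scan, _ = _make_scan(x, np.full(len(cuts), 0.5))
    res = select_best(scan, x, ep)
    hrs = np.array([cox_binary(t, e, x > c)["hr"] for c in cuts])
    winners = cuts[hrs == hrs.max()]
    assert res.selected_cutoff == winners.min()


# --- screen ----------------------------------------------------------------


@pytest.fixture(scope="module")
def null_screen(null_cohort):
    from kmscreen import simulate_study  # noqa: F401  (fixture provides cohort)

    from kmscreen.io_ingest import ProbeGeneMap

    pmap = ProbeGeneMap(
        pd.Series(
            {p: f"G{i:04d}" for i, p in enumerate(null_cohort.expression.index, start=1)}
        )
    )
    merged = merge_cohorts([null_cohort], pmap)
    return screen(merged, "os")


def test_screen_reports_every_gene_with_valid_fields(null_screen):
    t = null_screen.table
    assert len(t) == 30
    assert (t["hr"].dropna() > 0).all()
    assert t["rank"].tolist() == list(range(1, 31))
    done = t.dropna(subset=["fdr"])
    assert ((done["fdr"] > 0) & (done["fdr"] <= 1)).all()
    assert ((done["p"] > 0) & (done["p"] <= 1)).all()


def test_screen_ranking_order(null_screen):
    t = null_screen.table
    floor = t["passes_floor"].astype(bool).to_numpy()
    assert not np.any(~floor[:-1] & floor[1:])  # floor-passers first
    fp = t[floor]
    risk = (fp["direction"] == "risk").to_numpy()
    assert not np.any(~risk[:-1] & risk[1:])  # risk before protective
    for block in (risk, ~risk):
        fdrs = fp["fdr"].to_numpy()[block]
        assert np.all(np.diff(fdrs) >= -1e-15)


def test_low_cutoff_gene_fails_floor_but_is_retained(null_cohort):
    from kmscreen.io_ingest import CohortBundle, ProbeGeneMap

    b = null_cohort
    expr = b.expression.iloc[:3].copy()
    expr.iloc[2] = expr.iloc[2] / expr.iloc[2].mean() * 150.0  # cutoffs land ~150
    small = CohortBundle(b.cohort_id, b.platform, expr, b.clinical).validate()
    pmap = ProbeGeneMap(pd.Series({p: f"g{i}" for i, p in enumerate(expr.index)}))
    st_ = screen(merge_cohorts([small], pmap), "os")
    assert not st_.table.loc["g2", "passes_floor"]
    assert "g2" in st_.table.index
    # floor affects ranking only, never the statistics
    assert np.isfinite(st_.table.loc["g2", "fdr"])


def test_screen_errors_without_endpoint(null_cohort):
    from kmscreen.io_ingest import CohortBundle, ProbeGeneMap

    clin = null_cohort.clinical.copy()
    clin["os_time_months"] = np.nan
    b = CohortBundle("A", "GPL96", null_cohort.expression, clin)
    pmap = ProbeGeneMap(
        pd.Series({p: f"g{i}" for i, p in enumerate(null_cohort.expression.index)})
    )
    with pytest.raises(ValidationError, match="missing for all samples"):
        screen(merge_cohorts([b], pmap), "os")


def test_planted_gene_detected_in_small_study(small_study):
    merged = merge_cohorts(small_study.cohorts, small_study.probe_map)
    st_ = screen(merged, "os")
    assert st_.table.index[0] == "G0001"
    row = st_.table.loc["G0001"]
    assert row["direction"] == "risk"
    truth_cut = small_study.truth["realized_cutoff"].iloc[0]
    x = merged.expression.loc["G0001"]
    span = x.max() - x.min()
    assert abs(row["selected_cutoff"] - truth_cut) < 0.25 * span


# --- Kaplan-Meier ----------------------------------------------------------


def test_km_matches_hand_computed_product_limit():
    # low group: times 1..6 with censoring at 3 and 5
    x = np.array([1.0] * 6 + [10.0] * 2)
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
    e = np.array([1, 1, 0, 1, 0, 1, 1, 1])
    curves = km_curve(x, 5.0, SurvivalEndpoint(t, e))
    low = curves[curves["group"] == "low"]
    np.testing.assert_allclose(
        low["survival"].to_numpy(), [5 / 6, 2 / 3, 2 / 3, 4 / 9, 4 / 9, 0.0], rtol=1e-12
    )
    np.testing.assert_array_equal(low["n_risk"].to_numpy(), [6, 5, 4, 3, 2, 1])


def test_km_all_events_single_group_steps():
    x = np.array([1.0] * 4 + [10.0] * 4)
    t = np.array([1.0, 2.0, 3.0, 4.0, 9.0, 9.5, 9.7, 9.9])
    e = np.ones(8, int)
    curves = km_curve(x, 5.0, SurvivalEndpoint(t, e))
    low = curves[curves["group"] == "low"]
    np.testing.assert_allclose(low["survival"].to_numpy(), [0.75, 0.5, 0.25, 0.0])


def test_km_all_censored_flat_at_one():
    x = np.array([1.0, 1.0, 1.0, 10.0, 10.0, 10.0])
    t = np.arange(1.0, 7.0)
    e = np.zeros(6, int)
    curves = km_curve(x, 5.0, SurvivalEndpoint(t, e))
    assert (curves["survival"] == 1.0).all()


def test_km_agrees_with_lifelines():
    rng = np.random.default_rng(11)
    n = 60
    x = 100 + np.exp(rng.normal(6, 1, n))
    t, e = _random_survival(rng, n)
    cut = float(np.median(x))
    curves = km_curve(x, cut, SurvivalEndpoint(t, e))
    for name, sel in (("low", x <= cut), ("high", x > cut)):
        kmf = KaplanMeierFitter().fit(t[sel], e[sel])
        ours = curves[curves["group"] == name].set_index("time")["survival"]
        theirs = kmf.survival_function_["KM_estimate"]
        for tt in ours.index:
            assert ours[tt] == pytest.approx(theirs.loc[tt], rel=1e-9)


def test_km_empty_group_is_error():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    t = np.arange(1.0, 5.0)
    e = np.ones(4, int)
    with pytest.raises(ValidationError, match="empty"):
        km_curve(x, 10.0, SurvivalEndpoint(t, e))


# --- end-to-end scan object -----------------------------------------------


def test_scan_gene_consistency(null_cohort):
    x = null_cohort.expression.iloc[0].to_numpy()
    surv, mask = null_cohort.endpoint("os")
    res = scan_gene(x[mask], surv, "g")
    scan = logrank_scan(x[mask], surv, "g")
    assert res.fdr_at_selected == scan.fdr.min()
    assert res.selected_cutoff in scan.cutoffs
    assert res.n_low + res.n_high == len(surv)
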