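"""First-order decay fitting and half-life/m6A-content relations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from m6aclip.halflife import (
    LN2,
    ExponentialDecayModel,
    compare_ratio_strata,
    content_vs_halflife,
    fit_decay,
    halflife_change,
    inter_peak_spacing,
    m6a_content_groups,
)

TIMES = (0.0, 1.0, 2.0, 4.0, 8.0)


def timecourse(tid, values, replicates=1):
    rows = []
    for rep in range(1, replicates + 1):
        for t, v in zip(TIMES, values):
            rows.append({"transcript_id": tid, "time_h": t,
                         "replicate": rep, "abundance": v})
    return pd.DataFrame(rows)


def test_noise_free_exponential_recovered_exactly():
    """A(t) = 100 * 2^(-t/2) must give T1/2 = 2.0000 h."""
    tc = timecourse("tx", [100.0, 70.71, 50.0, 25.0, 6.25], replicates=3)
    res = fit_decay(tc)
    row = res.frame.iloc[0]
    assert row["halflife_h"] == pytest.approx(2.0, abs=5e-4)
    assert row["k"] == pytest.approx(LN2 / 2, rel=1e-3)
    assert row["flag"] == "ok"
    assert row["halflife_h"] == pytest.approx(LN2 / row["k"], rel=1e-12)


def test_constant_abundance_flagged_non_decaying():
    res = fit_decay(timecourse("tx", [50, 50, 50, 50, 50]))
    row = res.frame.iloc[0]
    assert row["flag"] == "non_decaying" or row["k"] == pytest.approx(0, abs=1e-9)
    assert not np.isfinite(row["halflife_h"]) or row["k"] > 0


def test_scale_invariance():
    base = [100.0, 80.0, 55.0, 30.0, 10.0]
    k1 = fit_decay(timecourse("tx", base)).frame.iloc[0]["k"]
    k2 = fit_decay(timecourse("tx", [7.3 * v for v in base])).frame.iloc[0]["k"]
    assert k1 == pytest.approx(k2, rel=1e-12)


def test_too_few_positive_points_rejected():
    res = fit_decay(timecourse("tx", [100, 0, 0, 0, 0]))
    assert res.frame.iloc[0]["flag"] == "insufficient"


def test_size_factors_remove_global_decay_bias(rng):
    """With size factors, a global decaying background leaves k unbiased.

    Every library is scaled by exp(-0.3 t) (total-RNA decay); dividing
    by the emitted factors must recover the per-transcript k within 5%.
    """
    k_true = 0.25
    rows, sf_rows = [], []
    for rep in (1, 2, 3):
        for t in TIMES:
            sf = float(np.exp(-0.3 * t))
            sf_rows.append({"time_h": t, "replicate": rep, "size_factor": sf})
            rows.append({"transcript_id": "tx", "time_h": t, "replicate": rep,
                         "abundance": 500 * np.exp(-k_true * t) * sf})
    res = ExponentialDecayModel(
        pd.DataFrame(rows), size_factors=pd.DataFrame(sf_rows)
    ).fit()
    assert res.frame.iloc[0]["k"] == pytest.approx(k_true, rel=0.05)
    # without the factors the estimate absorbs the background decay
    res_raw = ExponentialDecayModel(pd.DataFrame(rows)).fit()
    assert res_raw.frame.iloc[0]["k"] == pytest.approx(k_true + 0.3, rel=0.05)


def test_reliability_filter_null_and_signal(rng):
    """Constant transcripts pass the FDR<0.05 filter at <= ~5%; decaying
    transcripts essentially always pass."""
    rows = []
    for i in range(150):
        for rep in (1, 2, 3):
            for t in TIMES:
                lam = 400.0  # constant: no decay
                rows.append({"transcript_id": f"null{i:03d}", "time_h": t,
                             "replicate": rep,
                             "abundance": int(rng.poisson(lam))})
    for i in range(30):
        for rep in (1, 2, 3):
            for t in TIMES:
                lam = 400.0 * np.exp(-0.4 * t)
                rows.append({"transcript_id": f"sig{i:03d}", "time_h": t,
                             "replicate": rep,
                             "abundance": int(rng.poisson(lam))})
    reliable = fit_decay(pd.DataFrame(rows)).filter_reliable()
    null_pass = reliable["transcript_id"].str.startswith("null").sum()
    sig_pass = reliable["transcript_id"].str.startswith("sig").sum()
    se = np.sqrt(0.05 * 0.95 / 150)
    assert null_pass / 150 <= 0.05 + 3 * se
    assert sig_pass == 30


def test_rank_correlation_of_recovered_rates(rng):
    """Poisson-noised counts recover the ordering of true decay rates."""
    k_true = rng.uniform(0.05, 1.2, size=120)
    rows = []
    for i, k in enumerate(k_true):
        for rep in (1, 2, 3):
            for t in TIMES:
                rows.append(
                    {"transcript_id": f"t{i:03d}", "time_h": t, "replicate": rep,
                     "abundance": int(rng.poisson(500 * np.exp(-k * t)))}
                )
    frame = fit_decay(pd.DataFrame(rows)).frame.sort_values("transcript_id")
    rho = sps.spearmanr(k_true, frame["k"]).statistic
    assert rho > 0.95


def test_fit_variants_agree_on_clean_data():
    """Nonlinear refinement and replicate-averaged fits agree with the
    pooled OLS fit on noise-free exponential input."""
    tc = timecourse("tx", [100.0, 70.71, 50.0, 25.0, 6.25], replicates=3)
    k_ols = fit_decay(tc).frame.iloc[0]["k"]
    k_nl = ExponentialDecayModel(tc, method="nonlinear").fit().frame.iloc[0]["k"]
    k_avg = ExponentialDecayModel(
        tc, replicate_handling="average"
    ).fit().frame.iloc[0]["k"]
    assert k_nl == pytest.approx(k_ols, rel=1e-4)
    assert k_avg == pytest.approx(k_ols, rel=1e-9)
    with pytest.raises(ValueError):
        ExponentialDecayModel(tc, method="bogus")


def test_drop_zero_tail_rescues_underflowed_chase():
    """All-zero late time points (chase underflow) can be dropped."""
    values = [400.0, 100.0, 25.0, 0.0, 0.0]
    tc = timecourse("tx", values, replicates=3)
    kept = ExponentialDecayModel(tc, drop_zero_tail=True).fit().frame.iloc[0]
    assert kept["flag"] == "ok"
    assert kept["n_points"] == 9  # the two all-zero times were dropped
    assert kept["k"] == pytest.approx(np.log(4), rel=1e-6)


def test_summary_mentions_reliable_count():
    tc = timecourse("tx", [100.0, 70.71, 50.0, 25.0, 6.25], replicates=3)
    text = fit_decay(tc).summary()
    assert "reliable" in text and "T1/2" in text


# ---- m6A content stratification -----------------------------------------

def test_content_groups_partition():
    df = m6a_content_groups(
        pd.DataFrame({"transcript_id": ["a", "b", "c"], "n_peaks": [0, 1, 4]})
    )
    assert list(df["group"]) == ["none", "single", "multiple"]


def test_multi_m6a_transcripts_have_shorter_halflives(rng):
    """Planted coupling (more sites -> faster decay) is recovered as a
    lower median T1/2 with a significant rank-sum p."""
    rows, fits = [], []
    for i in range(120):
        n = int(rng.integers(0, 5))
        k = 0.1 + 0.1 * n + rng.normal(0, 0.01)
        fits.append({"transcript_id": f"t{i}", "halflife_h": LN2 / k})
        rows.append({"transcript_id": f"t{i}", "n_peaks": n})
    groups = m6a_content_groups(pd.DataFrame(rows))
    summary, tests = content_vs_halflife(groups, pd.DataFrame(fits))
    med = summary.set_index("group")["median"]
    assert med["multiple"] < med["none"] / 2
    p = tests.set_index(["group_a", "group_b"]).loc[("multiple", "none"), "p_value"]
    assert p < 0.05


def test_identical_groups_give_uniformish_p(rng):
    """With no coupling the rank-sum p is not systematically small."""
    pvals = []
    for _ in range(40):
        fits = pd.DataFrame(
            {"transcript_id": [f"t{i}" for i in range(60)],
             "halflife_h": rng.uniform(1, 10, size=60)}
        )
        groups = pd.DataFrame(
            {"transcript_id": [f"t{i}" for i in range(60)],
             "group": ["none"] * 30 + ["multiple"] * 30}
        )
        _, tests = content_vs_halflife(groups, fits)
        pvals.append(tests["p_value"].iloc[0])
    assert np.mean(np.array(pvals) < 0.05) < 0.2


# ---- KO half-life change -------------------------------------------------

def test_identical_conditions_give_unit_ratios():
    fits = pd.DataFrame(
        {"transcript_id": ["a", "b"], "halflife_h": [2.0, 5.0]}
    )
    change = halflife_change(fits, fits)
    assert (change["ratio"] == 1.0).all()


def test_ratio_strata_separate_loss_groups(rng):
    rows = []
    for i in range(60):
        n_lost = int(rng.integers(0, 4))
        ratio = np.exp(np.log(1 + 0.8 * n_lost) + rng.normal(0, 0.05))
        rows.append({"transcript_id": f"t{i}", "halflife_wt": 2.0,
                     "halflife_ko": 2.0 * ratio, "ratio": ratio,
                     "n_lost": n_lost})
    change = pd.DataFrame(rows)
    change["n_lost_group"] = np.where(change["n_lost"] >= 2, "multi",
                                      np.where(change["n_lost"] == 1, "single",
                                               "none"))
    strata = compare_ratio_strata(change).set_index("stratum")
    assert strata.loc["multi", "median_ratio"] > 1.5
    assert strata.loc["multi", "wilcoxon_p"] < 0.05
    assert abs(strata.loc["none", "median_ratio"] - 1.0) < 0.1


# ---- inter-peak spacing --------------------------------------------------

def test_median_adjacent_spacing():
    df = inter_peak_spacing({"a": [100, 200, 400], "b": [500]})
    assert list(df["transcript_id"]) == ["a"]
    assert df.iloc[0]["median_spacing"] == 150.0


def test_clustered_sites_on_fast_transcripts_detected(rng):
    from m6aclip.halflife import spacing_vs_halflife

    spacing_rows, fit_rows = [], []
    for i in range(80):
        fast = i < 40
        halflife = rng.uniform(0.5, 2.0) if fast else rng.uniform(6.0, 12.0)
        spacing = rng.uniform(50, 150) if fast else rng.uniform(300, 600)
        spacing_rows.append({"transcript_id": f"t{i}", "n_peaks": 3,
                             "median_spacing": spacing})
        fit_rows.append({"transcript_id": f"t{i}", "halflife_h": halflife})
    out = spacing_vs_halflife(pd.DataFrame(spacing_rows), pd.DataFrame(fit_rows))
    assert out["fast_median_spacing"] < out["slow_median_spacing"]
    assert out["p_value"] < 0.05
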