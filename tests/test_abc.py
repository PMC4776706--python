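import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rangeabc.abc import (
    ReferenceTable,
    bootstrap_observed,
    epanechnikov_weights,
    estimate_parameters,
    gof_2d_pvalue,
    mlr_model_posterior,
    model_choice,
    posterior_predictive_pca,
    power_study,
    rejection,
)
from rangeabc.sumstats import SUMMARY_NAMES


def synthetic_table(n_per_model, shifts, seed=0, param_gen=None):
    """A reference table with Gaussian summary clouds per model, shifted
    along every coordinate by the given per-model offsets."""
    rng = np.random.default_rng(seed)
    frames = []
    for model, shift in shifts.items():
        X = rng.normal(shift, 1.0, size=(n_per_model, 39))
        df = pd.DataFrame(X, columns=list(SUMMARY_NAMES))
        df.insert(0, "model", model)
        df.insert(0, "sim_id", [f"{model}:{i}" for i in range(n_per_model)])
        if param_gen is not None:
            for name, vals in param_gen(rng, n_per_model, X).items():
                df[name] = vals
        frames.append(df)
    params = [] if param_gen is None else list(param_gen(rng, 1, np.zeros((1, 39))).keys())
    return ReferenceTable(pd.concat(frames, ignore_index=True), params)


def gaussian_observed(shift=0.0, seed=1):
    rng = np.random.default_rng(seed)
    return pd.Series(rng.normal(shift, 1.0, 39), index=list(SUMMARY_NAMES))


# ---------------------------------------------------------------------------
# rejection
# ---------------------------------------------------------------------------


def test_rejection_retains_exact_count():
    tab = synthetic_table(1000, {"A": 0.0})
    obs = gaussian_observed()
    for tol, expect in [(0.02, 20), (0.1, 100), (0.013, 13), (1.0, 1000)]:
        idx, d = rejection(tab.summaries, obs, tol)
        assert len(idx) == expect
        assert (np.diff(d) >= 0).all()


def test_rejection_full_table_and_self_match():
    tab = synthetic_table(200, {"A": 0.0})
    obs = tab.summaries.iloc[17]
    idx, d = rejection(tab.summaries, obs, 0.05)
    assert idx[0] == 17
    assert d[0] == pytest.approx(0.0)


def test_rejection_drops_zero_variance_columns_with_warning():
    tab = synthetic_table(100, {"A": 0.0})
    df = tab.df.copy()
    df[SUMMARY_NAMES[0]] = 1.23
    tab2 = ReferenceTable(df, [])
    with pytest.warns(UserWarning, match="zero-variance"):
        idx, _ = rejection(tab2.summaries, gaussian_observed(), 0.1)
    assert len(idx) == 10


def test_rejection_paper_scale_count_contract():
    # the tolerance contract at the study's own settings: 2% of 100,000
    # retains 2,000 and 4% of 50,000 retains 2,000 (checked on cheap rows)
    n1 = int(np.ceil(0.02 * 100_000))
    n2 = int(np.ceil(0.04 * 50_000))
    assert n1 == n2 == 2000


# ---------------------------------------------------------------------------
# multinomial logistic regression model choice
# ---------------------------------------------------------------------------


def test_mlr_identical_models_near_uniform():
    devs = []
    for rep in range(10):
        tab = synthetic_table(300, {"A": 0.0, "B": 0.0}, seed=rep)
        obs = gaussian_observed(seed=100 + rep)
        idx, d = rejection(tab.summaries, obs, 0.5)
        p = mlr_model_posterior(tab.summaries.iloc[idx], tab.models.iloc[idx], d, obs)
        assert p.sum() == pytest.approx(1.0)
        devs.append(abs(p["A"] - 0.5))
    assert np.mean(devs) < 0.05


def test_mlr_discriminates_overlapping_models():
    tab = synthetic_table(300, {"A": 0.0, "B": 1.0}, seed=4)
    obs = gaussian_observed(shift=0.0, seed=5)
    idx, d = rejection(tab.summaries, obs, 0.5)
    assert len(set(tab.models.iloc[idx])) == 2
    p = mlr_model_posterior(tab.summaries.iloc[idx], tab.models.iloc[idx], d, obs)
    assert p["A"] > 0.9


def test_separable_toy_gives_near_certain_choice():
    # model A summaries << model B, observed inside A's cloud: the full
    # rejection + regression loop must return Pr(A) > 0.99
    tab = synthetic_table(300, {"A": 0.0, "B": 8.0})
    obs = gaussian_observed(shift=0.0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model_choice(tab, obs, tolerance=0.4)
    assert res.probabilities["A"].iloc[0] > 0.99


def test_mlr_single_label_warns_probability_one():
    tab = synthetic_table(50, {"A": 0.0})
    obs = gaussian_observed()
    idx, d = rejection(tab.summaries, obs, 0.5)
    with pytest.warns(UserWarning, match="one model"):
        p = mlr_model_posterior(tab.summaries.iloc[idx], tab.models.iloc[idx], d, obs)
    assert p["A"] == 1.0


def test_model_choice_simplex_per_replicate():
    tab = synthetic_table(200, {"A": -1.0, "B": 1.0})
    reps = [gaussian_observed(shift=-1.0, seed=s) for s in range(8)]
    res = model_choice(tab, reps, tolerance=0.25)
    probs = res.probabilities
    assert probs.shape == (8, 2)
    assert np.allclose(probs.sum(axis=1), 1.0)
    assert (probs.values >= 0).all()
    agg = res.aggregate()
    assert set(agg.columns) == {"median", "lo95", "hi95"}
    assert agg.loc["A", "median"] > agg.loc["B", "median"]


def test_epanechnikov_weights_positive_decreasing():
    w = epanechnikov_weights(np.array([0.0, 1.0, 2.0, 3.0]))
    assert (w > 0).all()
    assert (np.diff(w) < 0).all()


# ---------------------------------------------------------------------------
# locus bootstrap
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def mini_panel(mini_world_mod, mini_priors_mod, mini_distances_mod):
    from rangeabc.synthetic import make_pseudo_observed, sample_prior

    rng = np.random.default_rng(21)
    priors = mini_priors_mod
    params = sample_prior(priors, "noLDDnoRC", rng)
    ds = make_pseudo_observed(
        priors.scenario("noLDDnoRC"), params, mini_world_mod, n_loci=24, seed=rng
    )
    return ds


@pytest.fixture(scope="module")
def mini_world_mod():
    from rangeabc.synthetic import load_fixture

    return load_fixture("schematic-old-world-mini")


@pytest.fixture(scope="module")
def mini_priors_mod():
    from rangeabc.synthetic import PriorSpec

    return PriorSpec.load("priors_mini")


@pytest.fixture(scope="module")
def mini_distances_mod(mini_world_mod):
    from rangeabc.landscape import least_cost_distance

    return {
        r: least_cost_distance(mini_world_mod, routing=r)
        for r in ("levant_only", "levant_horn_gibraltar")
    }


def test_bootstrap_full_panel_is_degenerate(mini_panel, mini_distances_mod):
    vecs = bootstrap_observed(
        mini_panel, distances=mini_distances_mod, loci_per_replicate=24, n_replicates=3, seed=0
    )
    assert np.allclose(vecs[0].values, vecs[1].values)
    assert np.allclose(vecs[0].values, vecs[2].values)


def test_bootstrap_replicates_vary_and_are_deterministic(mini_panel, mini_distances_mod):
    a = bootstrap_observed(
        mini_panel, distances=mini_distances_mod, loci_per_replicate=12, n_replicates=12, seed=5
    )
    b = bootstrap_observed(
        mini_panel, distances=mini_distances_mod, loci_per_replicate=12, n_replicates=12, seed=5
    )
    for x, y in zip(a, b):
        assert np.array_equal(x.values, y.values)
    stacked = np.array([v.values for v in a])
    polymorphic_spread = stacked.std(axis=0)
    assert (polymorphic_spread > 0).sum() > 30  # nearly every statistic varies


def test_bootstrap_too_few_loci_errors(mini_panel, mini_distances_mod):
    with pytest.raises(ValueError, match="cannot resample"):
        bootstrap_observed(mini_panel, distances=mini_distances_mod, loci_per_replicate=50)


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------


def _linear_param_table(n=1200, seed=3, noise=0.05):
    """Parameters linearly encoded in the summaries — estimable ground truth."""
    def gen(rng, k, X):
        return {
            "theta1": X[:, 0] * 2.0 + 5.0 + rng.normal(0, noise, k),
            "theta2": -X[:, 1] + 1.0 + rng.normal(0, noise, k),
        }

    return synthetic_table(n, {"A": 0.0}, seed=seed, param_gen=gen)


def test_estimate_parameters_self_consistency():
    tab = _linear_param_table()
    row = tab.df.iloc[40]
    obs = row[list(SUMMARY_NAMES)].astype(float)
    res = estimate_parameters(tab, obs, tolerance=0.05, n_pls=8)
    for name in ("theta1", "theta2"):
        truth = row[name]
        spread = tab.df[name].std()
        assert abs(res.stats.loc[name, "mean"] - truth) < 0.35 * spread
        lo, hi = res.hpdi(name)
        assert lo <= res.stats.loc[name, "median"] <= hi
    assert res.rmse_curve[-1] <= res.rmse_curve[0] + 1e-9


def test_estimate_requires_enough_retained_rows():
    tab = _linear_param_table(n=200)
    obs = gaussian_observed()
    with pytest.raises(ValueError, match="ceil"):
        estimate_parameters(tab, obs, tolerance=0.1)


def test_estimate_truncates_to_prior_support():
    tab = _linear_param_table()
    obs = gaussian_observed(seed=9)
    bounds = {"theta1": (4.9, 5.1), "theta2": (0.9, 1.1)}
    res = estimate_parameters(tab, obs, tolerance=0.06, prior_bounds=bounds)
    for name, (lo, hi) in bounds.items():
        assert res.samples[name].between(lo, hi).all()
        assert lo <= res.stats.loc[name, "hpdi_lo"] <= res.stats.loc[name, "hpdi_hi"] <= hi


def test_hpdi_contains_95_of_weighted_sample():
    tab = _linear_param_table()
    obs = tab.summaries.iloc[0]
    res = estimate_parameters(tab, obs, tolerance=0.06)
    x = res.samples["theta1"].to_numpy()
    w = res.weights / res.weights.sum()
    lo, hi = res.hpdi("theta1")
    mass = w[(x >= lo) & (x <= hi)].sum()
    assert mass >= 0.945


# ---------------------------------------------------------------------------
# power study
# ---------------------------------------------------------------------------


def test_power_identical_models_symmetric():
    tab = synthetic_table(250, {"A": 0.0, "B": 0.0}, seed=11)
    res = power_study(tab, n_pods=40, tolerance=0.3, thresholds=(0.5,), seed=1)[0.5]
    assert abs(res.loc["A", "A"] - res.loc["B", "B"]) < 0.35
    assert res.loc["A"].sum() == pytest.approx(1.0)


def test_power_threshold_monotonicity_and_separated_models():
    tab = synthetic_table(250, {"A": 0.0, "B": 6.0}, seed=12)
    res = power_study(tab, n_pods=30, tolerance=0.3, thresholds=(0.5, 0.85), seed=2)
    for thr in (0.5, 0.85):
        assert res[thr].loc["A", "A"] > 0.9
        assert res[thr].loc["B", "B"] > 0.9
    mis_50 = res[0.5].loc["A", "B"] + res[0.5].loc["B", "A"]
    mis_85 = res[0.85].loc["A", "B"] + res[0.85].loc["B", "A"]
    assert mis_85 <= mis_50 + 1e-9


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------


def _cloud_vectors(n=400, seed=13):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        v = pd.Series(rng.normal(0, 1, 39), index=list(SUMMARY_NAMES))
        out.append(v)
    return out


def test_gof_2d_pvalue_centre_and_tail():
    vecs = _cloud_vectors(n=800)
    pair = (SUMMARY_NAMES[0], SUMMARY_NAMES[1])
    assert gof_2d_pvalue(vecs, (0.0, 0.0), pair) > 0.85
    assert gof_2d_pvalue(vecs, (8.0, 8.0), pair) < 0.01


def test_gof_2d_pvalue_gaussian_hdr_calibration():
    # for a standard bivariate normal the 90% HDR boundary has p ~ 0.10
    vecs = _cloud_vectors(n=2000, seed=14)
    r90 = np.sqrt(stats.chi2.ppf(0.90, df=2))
    pair = (SUMMARY_NAMES[2], SUMMARY_NAMES[3])
    p = gof_2d_pvalue(vecs, (r90, 0.0), pair)
    assert abs(p - 0.10) < 0.04


def test_gof_2d_requires_enough_vectors():
    with pytest.raises(ValueError, match="100"):
        gof_2d_pvalue(_cloud_vectors(n=50), (0, 0), (SUMMARY_NAMES[0], SUMMARY_NAMES[1]))


def test_ppc_envelopes_nested_and_six_pairs():
    vecs = _cloud_vectors(n=300, seed=15)
    obs = vecs[0]
    res = posterior_predictive_pca(vecs[1:], obs)
    assert len(res) == 6  # four PCs give six pair plots
    for v in res.values():
        lv = v["levels"]
        assert lv[0.95] <= lv[0.75] <= lv[0.50]  # nested HDR envelopes
        assert 0.0 <= v["p"] <= 1.0


def test_ppc_self_sample_calibration():
    vecs = _cloud_vectors(n=300, seed=16)
    ps = []
    for k in range(20):
        res = posterior_predictive_pca([v for i, v in enumerate(vecs) if i != k], vecs[k])
        ps.append(np.median([v["p"] for v in res.values()]))
    assert 0.25 < np.median(ps) < 0.75
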