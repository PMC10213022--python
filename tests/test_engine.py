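"""OLS statistics, cross-validation, splitting, GA selection, Williams plot."""

import numpy as np
import pandas as pd
import pytest

from desqspr import (
    DataValidationError,
    Dataset,
    FitError,
    GAConfig,
    SolubilityRecord,
    SynthSpec,
    aard_percent,
    build_design,
    external_validation,
    fit_ols,
    ga_select,
    golbraikh_screen,
    leverage,
    pca_split_advisory,
    q2_loo,
    reference_eeig02d,
    split_by_hbd,
    synth_generate,
    williams_ad,
)

TRUTH = dict(a=1.0372, b=-0.0171, c=0.3067, d=-1.134)


def _random_design(rng, n=10, p=2):
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])
    y = rng.normal(size=n)
    return X, y


# --- design construction ---------------------------------------------------


def test_build_design_shapes_and_columns(noiseless_dataset):
    two = noiseless_dataset.subset(["Phenol", "Guaiacol"])
    X, y = build_design(two, reference_eeig02d(), include_T=False)
    assert list(X.columns) == ["lnP", "EEig02d"]
    assert len(X) == len(two) == len(y)
    # lnP column really is the log of the pressure column
    assert np.allclose(np.exp(X["lnP"]), [r.P_bar for r in two.records])


def test_build_design_requires_descriptor_for_every_donor(noiseless_dataset):
    lookup = {k: v for k, v in reference_eeig02d().items() if k != "Phenol"}
    with pytest.raises(DataValidationError, match="Phenol"):
        build_design(noiseless_dataset, lookup)


def test_nonpositive_solubility_is_rejected_at_the_record():
    with pytest.raises(DataValidationError, match="positive"):
        SolubilityRecord("Phenol", 303.0, 1.0, 0.0, "1:3")


# --- OLS and statistics ----------------------------------------------------


def test_perfect_fit_recovers_the_exact_line():
    X = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
    fit = fit_ols(X, [1.0, 3.0, 5.0])
    assert fit.coef["x"] == pytest.approx(2.0, abs=1e-12)
    assert fit.coef["intercept"] == pytest.approx(1.0, abs=1e-12)
    assert fit.r2 == pytest.approx(1.0) and fit.rmse == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(fit.residuals, 0.0, atol=1e-12)


def test_noiseless_study_design_recovers_generating_coefficients(noiseless_dataset):
    X, y = build_design(noiseless_dataset, reference_eeig02d())
    fit = fit_ols(X, y)
    assert fit.coef["lnP"] == pytest.approx(TRUTH["a"], abs=1e-10)
    assert fit.coef["T"] == pytest.approx(TRUTH["b"], abs=1e-10)
    assert fit.coef["EEig02d"] == pytest.approx(TRUTH["c"], abs=1e-10)
    assert fit.coef["intercept"] == pytest.approx(TRUTH["d"], abs=1e-8)


def test_tiny_noise_gives_tiny_coefficient_error():
    ds = synth_generate(SynthSpec(sigma=1e-8, seed=11))
    X, y = build_design(ds, reference_eeig02d())
    fit = fit_ols(X, y)
    for col, truth in [("lnP", TRUTH["a"]), ("T", TRUTH["b"]), ("EEig02d", TRUTH["c"])]:
        assert abs(fit.coef[col] - truth) < 1e-6


def test_noisy_recovery_within_three_standard_errors(noisy_dataset):
    X, y = build_design(noisy_dataset, reference_eeig02d())
    fit = fit_ols(X, y)
    for col, truth in [
        ("lnP", TRUTH["a"]), ("T", TRUTH["b"]), ("EEig02d", TRUTH["c"]),
        ("intercept", TRUTH["d"]),
    ]:
        assert abs(fit.coef[col] - truth) <= 3 * fit.se[col], col


def test_f_statistic_consistent_with_r2(noisy_dataset):
    X, y = build_design(noisy_dataset, reference_eeig02d())
    fit = fit_ols(X, y)
    expected = (fit.r2 / fit.p) / ((1 - fit.r2) / (fit.n - fit.p - 1))
    assert fit.f_stat == pytest.approx(expected, abs=1e-8)
    assert 0.0 <= fit.r2 <= 1.0 and fit.r2_adj <= fit.r2


def test_refit_is_bitwise_identical(noisy_dataset):
    X, y = build_design(noisy_dataset, reference_eeig02d())
    f1, f2 = fit_ols(X, y), fit_ols(X, y)
    assert (f1.coef == f2.coef).all()
    assert np.array_equal(f1.residuals, f2.residuals)
    assert f1.to_json() == f2.to_json()


def test_rank_deficiency_and_sample_size_errors():
    X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
    with pytest.raises(FitError, match="rank"):
        fit_ols(X, [1.0, 2.0, 3.0, 4.0])
    with pytest.raises(FitError, match="observations"):
        fit_ols(pd.DataFrame({"a": [1.0, 2.0]}), [1.0, 2.0])


# --- LOO cross-validation --------------------------------------------------


def test_q2_is_one_for_exact_linear_data():
    X = pd.DataFrame({"x": np.arange(6.0)})
    assert q2_loo(X, 3.0 * np.arange(6.0) - 1.0) == pytest.approx(1.0)


def test_q2_shortcut_equals_explicit_refit_loop(rng):
    """Hat-matrix shortcut vs brute-force leave-one-out refitting."""
    for _ in range(50):
        n = int(rng.integers(8, 16))
        p = int(rng.integers(1, 4))
        X, y = _random_design(rng, n, p)
        press = 0.0
        for i in range(n):
            keep = [k for k in range(n) if k != i]
            A = np.column_stack([np.ones(n - 1), X.to_numpy()[keep]])
            beta, *_ = np.linalg.lstsq(A, y[keep], rcond=None)
            pred = np.concatenate([[1.0], X.to_numpy()[i]]) @ beta
            press += (y[i] - pred) ** 2
        expected = 1.0 - press / np.sum((y - y.mean()) ** 2)
        assert q2_loo(X, y) == pytest.approx(expected, abs=1e-10)


def test_q2_undefined_for_constant_response():
    X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
    with pytest.raises(FitError, match="constant"):
        q2_loo(X, np.ones(4))


# --- AARD ------------------------------------------------------------------


def test_aard_zero_for_perfect_and_ten_for_10pc_error():
    obs = np.array([1.0, 2.0, 4.0])
    assert aard_percent(obs, obs) == 0.0
    assert aard_percent(1.1 * obs, obs, "ln") == pytest.approx(10.0)


def test_aard_scale_invariance():
    rng = np.random.default_rng(3)
    pred, obs = rng.normal(size=20), rng.normal(size=20) + 5
    assert aard_percent(3.7 * pred, 3.7 * obs, "ln") == pytest.approx(
        aard_percent(pred, obs, "ln")
    )
    # natural scale: multiplying x by lambda shifts ln(x) by ln(lambda)
    shift = np.log(3.7)
    assert aard_percent(pred + shift, obs + shift, "natural") == pytest.approx(
        aard_percent(pred, obs, "natural")
    )


def test_aard_rejects_zero_observations():
    with pytest.raises(FitError, match="zero"):
        aard_percent([1.0, 1.0], [1.0, 0.0], "ln")


# --- external validation and splitting -------------------------------------


def test_external_validation_on_same_rule_is_perfect():
    X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]})
    fit = fit_ols(X, 2.0 * X["x"] + 1.0)
    stats = external_validation(fit, pd.DataFrame({"x": [4.0, 5.0]}), [9.0, 11.0])
    assert stats["r2"] == pytest.approx(1.0)
    assert stats["rmse"] == pytest.approx(0.0, abs=1e-10)


def test_external_validation_degenerate_and_mismatched_inputs():
    X = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
    fit = fit_ols(X, [0.0, 1.0, 2.0])
    with pytest.raises(FitError, match="2 test points"):
        external_validation(fit, pd.DataFrame({"x": [1.0]}), [1.0])
    with pytest.raises(FitError, match="columns"):
        external_validation(fit, pd.DataFrame({"z": [1.0, 2.0]}), [1.0, 2.0])


def test_held_out_donor_validates_close_to_training(noisy_dataset):
    train, test = split_by_hbd(noisy_dataset, ["Furfuryl alcohol", "Diethylene glycol"])
    lookup = reference_eeig02d()
    X, y = build_design(train, lookup)
    fit = fit_ols(X, y)
    X_test, y_test = build_design(test, lookup)
    stats = external_validation(fit, X_test, y_test)
    assert abs(stats["r2"] - fit.r2) < 0.05


def test_donor_wise_split_is_an_exact_partition(noiseless_dataset):
    holdout = {"Furfuryl alcohol", "Diethylene glycol"}
    train, test = split_by_hbd(noiseless_dataset, holdout)
    assert set(test.hbds) == holdout
    assert not holdout & set(train.hbds)
    assert len(train) + len(test) == len(noiseless_dataset)


def test_single_donor_holdout(noiseless_dataset):
    train, test = split_by_hbd(noiseless_dataset, ["Diethylene glycol"])
    assert test.hbds == ["Diethylene glycol"]


def test_split_errors(noiseless_dataset):
    with pytest.raises(DataValidationError, match="empty"):
        split_by_hbd(noiseless_dataset, [])
    with pytest.raises(DataValidationError, match="not in the dataset"):
        split_by_hbd(noiseless_dataset, ["Urea"])
    with pytest.raises(DataValidationError, match="every donor"):
        split_by_hbd(noiseless_dataset, noiseless_dataset.hbds)


# --- PCA split advisory ----------------------------------------------------


def test_pca_advisory_suggests_the_extreme_of_collinear_points():
    assert pca_split_advisory({"a": 0.0, "b": 1.0, "c": 10.0}, n_suggest=1) == ["c"]


def test_pca_advisory_rejects_degenerate_input():
    with pytest.raises(DataValidationError, match="zero variance"):
        pca_split_advisory({"a": 1.0, "b": 1.0, "c": 1.0})
    with pytest.raises(DataValidationError, match="at least 3"):
        pca_split_advisory({"a": 1.0, "b": 2.0})


def test_pca_advisory_is_deterministic_for_the_packaged_donors():
    ref = reference_eeig02d()
    first = pca_split_advisory(ref)
    assert first == pca_split_advisory(ref)
    assert len(first) == 2 and set(first) <= set(ref)


# --- leverage and applicability domain -------------------------------------


def test_leverage_sums_to_parameter_count(rng):
    X, _ = _random_design(rng, n=20, p=3)
    h = leverage(X)
    assert h.sum() == pytest.approx(4.0, abs=1e-8)   # p + 1 with intercept
    assert np.all((h >= 0) & (h <= 1))


def test_point_at_the_predictor_mean_has_minimum_leverage():
    X = pd.DataFrame({"x": [-2.0, -1.0, 0.0, 1.0, 2.0]})   # mean is 0
    h = leverage(X)
    assert h[2] == pytest.approx(1 / 5 + 0.0, abs=1e-12)   # 1/n + 0


def test_duplicated_rows_share_leverage(rng):
    X, _ = _random_design(rng, n=8, p=2)
    X2 = pd.concat([X, X.iloc[[0]]], ignore_index=True)
    h = leverage(X2)
    assert h[0] == pytest.approx(h[8], abs=1e-12)


def test_warning_leverage_is_3p_over_n():
    rng = np.random.default_rng(5)
    X, _ = _random_design(rng, n=30, p=2)
    y = X @ [1.0, -1.0] + rng.normal(0, 0.1, 30)
    ad = williams_ad(fit_ols(X, y), X, y)
    assert ad.h_star == pytest.approx(0.3)   # 3*(2+1)/30


def test_well_behaved_data_is_entirely_in_domain(noisy_dataset):
    X, y = build_design(noisy_dataset, reference_eeig02d())
    ad = williams_ad(fit_ols(X, y), X, y)
    assert all(f == "in-domain" for f in ad.flags)


def test_gross_response_shift_is_flagged_as_outlier(noisy_dataset):
    X, y = build_design(noisy_dataset, reference_eeig02d())
    y = y.copy()
    y.iloc[17] += 10 * 0.1    # ten standard deviations
    ad = williams_ad(fit_ols(X, y), X, y)
    assert ad.flags[17] == "response outlier"


def test_golbraikh_screen():
    assert golbraikh_screen(0.95, 0.9)
    assert not golbraikh_screen(0.55, 0.9)
    assert not golbraikh_screen(0.95, 0.4)


# --- GA descriptor selection -----------------------------------------------


def _decoy_problem(seed, n_decoys=10, sigma=0.05):
    rng = np.random.default_rng(seed)
    ds = synth_generate(SynthSpec(sigma=sigma, seed=seed))
    X, y = build_design(ds, reference_eeig02d())
    for k in range(n_decoys):
        X[f"decoy{k:02d}"] = rng.normal(size=len(X))
    return X, y


def test_single_candidate_is_selected():
    ds = synth_generate(SynthSpec(sigma=0.05, seed=2))
    X, y = build_design(ds, reference_eeig02d())
    res = ga_select(X, y, forced=("lnP", "T"), cfg=GAConfig(seed=3, generations=5))
    assert res.selected == ("EEig02d",)


def test_identical_seeds_give_identical_selections():
    X, y = _decoy_problem(4)
    cfg = GAConfig(seed=99, generations=20)
    r1 = ga_select(X, y, forced=("lnP", "T"), cfg=cfg)
    r2 = ga_select(X, y, forced=("lnP", "T"), cfg=GAConfig(seed=99, generations=20))
    assert r1.selected == r2.selected
    assert r1.fitness == r2.fitness
    assert r1.history == r2.history


def test_ga_finds_the_planted_descriptor_among_decoys():
    X, y = _decoy_problem(6, n_decoys=20)
    res = ga_select(X, y, forced=("lnP", "T"), cfg=GAConfig(seed=1))
    assert res.selected == ("EEig02d",)
    assert res.fitness > 0.9


def test_ga_config_validation():
    with pytest.raises(ValueError, match="seed"):
        GAConfig()
    with pytest.raises(ValueError, match="rates"):
        GAConfig(seed=1, mutation_rate=1.5)
    with pytest.raises(ValueError, match="fitness"):
        GAConfig(seed=1, fitness="aic")
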