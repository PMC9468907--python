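"""Fourth-corner GLM: dominant-species sets, IRLS fit, AICc ladder, ANOVA."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from grazeform.fourthcorner import (
    ENV_VARS,
    TRAITS,
    _aicc,
    _design,
    _logistic_irls,
    anova_resampling,
    build_triplet,
    fit_fourth_corner,
    minimal_cover_set,
    select_env_subset,
    site_species_cover,
)
from grazeform.simulate import SimulationConfig, simulate_survey, simulate_triplet
from grazeform.traits import build_trait_table


# ---------------------------------------------------------------------------
# minimal cover set
# ---------------------------------------------------------------------------

def test_minimal_cover_set_examples():
    covers = pd.Series({"a": 50.0, "b": 30.0, "c": 15.0, "d": 5.0})
    assert minimal_cover_set(covers) == ["a", "b", "c"]  # 80% < 90% <= 95%
    assert minimal_cover_set(pd.Series({"only": 12.0})) == ["only"]
    ten = pd.Series({f"s{i}": 10.0 for i in range(10)})
    assert len(minimal_cover_set(ten)) == 9  # 90% reached exactly at the 9th


def test_minimal_cover_set_tie_break_alphabetical():
    covers = pd.Series({"b": 40.0, "a": 40.0, "c": 20.0})
    assert minimal_cover_set(covers)[:2] == ["a", "b"]


def test_minimal_cover_set_all_zero_errors():
    with pytest.raises(ValueError):
        minimal_cover_set(pd.Series({"a": 0.0}))


@pytest.mark.parametrize("seed", range(25))
def test_minimal_cover_set_is_minimal(seed):
    """Dropping the smallest retained species always falls below 90%."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 15))
    covers = pd.Series(rng.uniform(0.5, 50, n), index=[f"s{i}" for i in range(n)])
    kept = minimal_cover_set(covers)
    share = covers[kept].sum() / covers.sum()
    assert share >= 0.90 - 1e-9
    if len(kept) > 1:
        assert covers[kept[:-1]].sum() / covers.sum() < 0.90


# ---------------------------------------------------------------------------
# triplet construction
# ---------------------------------------------------------------------------

def test_build_triplet_toy(toy):
    table = build_trait_table(toy)
    table["tuft_index"] += np.array([0.01, 0.0, -0.01])  # break constant columns
    table["grazer_use_index"] += np.array([0.01, 0.0, -0.01])
    triplet = build_triplet(toy, table)
    # site A covers: alpha (40+30)/2=35, beta (20+10)/2=15 -> both needed for 90%
    assert triplet.L.loc["A", "alpha"] == 1 and triplet.L.loc["A", "beta"] == 1
    # site B: beta 25, gamma 12.5 -> 25/37.5 = 67% so both retained
    assert triplet.L.loc["B", "beta"] == 1 and triplet.L.loc["B", "gamma"] == 1
    assert np.allclose(triplet.R.mean(), 0, atol=1e-12)
    assert np.allclose(triplet.R.std(ddof=0), 1, atol=1e-12)


def test_site_cover_is_mean_over_quadrats(toy):
    cover = site_species_cover(toy)
    assert cover.loc["A", "alpha"] == pytest.approx(35.0)
    assert cover.loc["B", "gamma"] == pytest.approx(12.5)


def test_retained_species_missing_from_traits_errors(toy):
    table = build_trait_table(toy).drop(index="alpha")
    with pytest.raises(ValueError, match="alpha"):
        build_triplet(toy, table)


def test_study_scale_dominant_set_sizes(study_scale):
    """Dominant-set sizes per site stay in a field-plausible range."""
    survey, _ = study_scale
    triplet = build_triplet(survey, build_trait_table(survey))
    per_site = triplet.L.sum(axis=1)
    assert per_site.min() >= 2
    assert per_site.max() <= 12


# ---------------------------------------------------------------------------
# GLM fit
# ---------------------------------------------------------------------------

def test_irls_matches_statsmodels():
    triplet = simulate_triplet(20, 8, seed=1)
    X, y, _ = _design(triplet, ENV_VARS)
    beta, dev = _logistic_irls(X, y)
    ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    assert np.allclose(beta, ref.params, atol=1e-6)
    assert dev == pytest.approx(ref.deviance, abs=1e-6)


def test_fit_reports_coefficient_matrix_shape():
    triplet = simulate_triplet(20, 8, seed=2)
    m = fit_fourth_corner(triplet, ["map_mm", "ph"])
    assert m.coefficients.shape == (4, 2)
    assert list(m.coefficients.index) == TRAITS
    assert np.isfinite(m.aicc)


def test_nesting_never_decreases_likelihood():
    triplet = simulate_triplet(25, 8, seed=3)
    small = fit_fourth_corner(triplet, ["map_mm"])
    big = fit_fourth_corner(triplet, ["map_mm", "cec"])
    assert big.loglik >= small.loglik - 1e-6


def test_empty_env_subset_rejected():
    triplet = simulate_triplet(10, 5, seed=4)
    with pytest.raises(ValueError):
        fit_fourth_corner(triplet, [])


def test_deviance_invariant_to_relabeling():
    triplet = simulate_triplet(20, 8, seed=5)
    base = fit_fourth_corner(triplet)
    # permute site order and species order
    rng = np.random.default_rng(0)
    sp = rng.permutation(triplet.L.columns)
    si = rng.permutation(triplet.L.index)
    from grazeform.fourthcorner import CommunityTriplet

    shuffled = CommunityTriplet(
        L=triplet.L.loc[si, sp],
        R=triplet.R.loc[si],
        Q=triplet.Q.loc[sp],
        R_scaler=triplet.R_scaler,
        Q_scaler=triplet.Q_scaler,
        site_cover=triplet.site_cover,
    )
    other = fit_fourth_corner(shuffled)
    assert other.deviance == pytest.approx(base.deviance, abs=1e-6)


def test_planted_interaction_sign_recovery_small():
    """Planted tuft x rainfall = 1 recovered with positive sign (quick check)."""
    B = np.zeros((4, 4))
    B[2, 0] = 1.0  # tuft x map_mm
    hits = 0
    for seed in range(10):
        triplet = simulate_triplet(40, 12, B=B, seed=seed)
        m = fit_fourth_corner(triplet)
        hits += m.coefficients.loc["tuft_index", "map_mm"] > 0
    assert hits >= 9


def test_coefficients_shrink_under_null_as_sites_grow():
    means = []
    for n_sites in (30, 200):
        vals = []
        for seed in range(5):
            triplet = simulate_triplet(n_sites, 10, seed=100 + seed)
            m = fit_fourth_corner(triplet)
            vals.append(np.abs(m.coefficients.to_numpy()).mean())
        means.append(np.mean(vals))
    assert means[1] < means[0]


# ---------------------------------------------------------------------------
# AICc and subset selection
# ---------------------------------------------------------------------------

def test_aicc_hand_example():
    # logL = -10, p = 3, n = 20 -> 20 + 6 + 24/16 = 27.5
    assert _aicc(-10.0, 3, 20) == pytest.approx(27.5)


def test_delta_aicc_invariant_to_loglik_shift():
    a1, a2 = _aicc(-10.0, 3, 20), _aicc(-12.0, 4, 20)
    b1, b2 = _aicc(-10.0 + 5, 3, 20), _aicc(-12.0 + 5, 4, 20)
    assert (a1 - a2) == pytest.approx((b1 - b2) + 10 - 10 + 0)  # pure shift cancels in delta
    assert (a1 - a2) == pytest.approx(b1 - b2 + 2 * 5 - 2 * 5)


def test_select_env_subset_ladder():
    triplet = simulate_triplet(25, 10, seed=6)
    sel = select_env_subset(triplet)
    assert len(sel.ladder) == 15  # all non-empty subsets of 4 variables
    assert sel.ladder["delta_AICc"].iloc[0] == 0.0
    assert (sel.ladder["delta_AICc"] >= 0).all()
    full = sel.models[tuple(ENV_VARS)]
    assert sel.best.aicc <= full.aicc + 1e-9
    assert np.isfinite(sel.null_reference_aicc)


# ---------------------------------------------------------------------------
# permutation ANOVA
# ---------------------------------------------------------------------------

def test_anova_p_lower_bound_and_determinism():
    triplet = simulate_triplet(15, 8, seed=7)
    r1 = anova_resampling(triplet, n_iterations=99, seed=5)
    r2 = anova_resampling(triplet, n_iterations=99, seed=5)
    assert r1.p_value >= 1.0 / 100.0
    assert r1.p_value == r2.p_value
    assert r1.statistic == pytest.approx(r2.statistic)


def test_anova_power_on_strong_interaction():
    """|beta| = 1.5 planted interactions are detected at alpha = .05."""
    B = np.zeros((4, 4))
    B[2, 0] = 1.5
    hits = 0
    for seed in range(10):
        triplet = simulate_triplet(40, 12, B=B, seed=300 + seed)
        r = anova_resampling(triplet, n_iterations=99, seed=seed)
        hits += r.p_value <= 0.05
    assert hits >= 9


def test_anova_coarse_iterations_warn(caplog):
    import logging

    triplet = simulate_triplet(10, 5, seed=8)
    with caplog.at_level(logging.WARNING):
        anova_resampling(triplet, n_iterations=9, seed=0)
    assert "coarse" in caplog.text


# ---------------------------------------------------------------------------
# survey-level integration
# ---------------------------------------------------------------------------

def test_survey_level_fourth_corner_recovers_planted_sign():
    B = pd.DataFrame(np.zeros((4, 4)), index=TRAITS, columns=ENV_VARS)
    B.loc["tuft_index", "map_mm"] = 1.0
    hits = 0
    for seed in range(5):
        survey, _ = simulate_survey(
            SimulationConfig(seed=700 + seed, n_sites=40, quadrats_per_site=20, B=B)
        )
        triplet = build_triplet(survey, build_trait_table(survey))
        m = fit_fourth_corner(triplet)
        hits += m.coefficients.loc["tuft_index", "map_mm"] > 0
    assert hits >= 4
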