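"""Power-law fitting: OLS, mixed-effects recovery, ANCOVA, trait terms."""

import numpy as np
import pandas as pd
import pytest

from trophoscale import (
    SpeciesFitError,
    SyntheticConfig,
    doubling_increase_percent,
    fit_across_ancova,
    fit_per_web_ols,
    fit_prey_mass_model,
    fit_species_across_webs,
    fit_trait_lme,
    fit_within_lme,
    fold_increase,
    generate_dataset,
)
from trophoscale.biomass_pipeline import build_within_table


def within_frame(rows):
    df = pd.DataFrame(
        rows,
        columns=["web_id", "ecosystem_type", "log10_prey_biomass",
                 "log10_predator_biomass"],
    )
    df["predator_id"] = [f"p{i}" for i in range(len(df))]
    df["taxon_name"] = df["predator_id"]
    df["ppmr_log10"] = 2.0
    df["omnivory"] = 0.1
    df["trophic_level"] = 3.0
    return df


def synthetic_line(web_id, eco, k, c, xs, noise=None):
    rows = []
    for i, x in enumerate(xs):
        e = 0.0 if noise is None else noise[i]
        rows.append((web_id, eco, x, c + k * x + e))
    return rows


# ---------------------------------------------------------------------------
# per-web OLS
# ---------------------------------------------------------------------------


def test_collinear_points_give_exact_slope():
    df = within_frame(synthetic_line("w1", "marine", 0.75, -0.5, [0.0, 1.0, 2.0]))
    res = fit_per_web_ols(df)
    assert res.k_i.iloc[0] == pytest.approx(0.75, abs=1e-12)
    assert res.c_i.iloc[0] == pytest.approx(-0.5, abs=1e-12)
    assert res.r2.iloc[0] == pytest.approx(1.0)


def test_two_points_give_difference_quotient():
    df = within_frame(synthetic_line("w1", "marine", 0.0, 0.0, [0.0, 2.0]))
    df.loc[1, "log10_predator_biomass"] = 1.0
    res = fit_per_web_ols(df, min_records=2)
    assert res.k_i.iloc[0] == pytest.approx(0.5)


def test_zero_x_variance_web_skipped(caplog):
    df = within_frame(
        [("w1", "marine", 1.0, 0.0), ("w1", "marine", 1.0, 1.0),
         ("w2", "marine", 0.0, 0.0), ("w2", "marine", 1.0, 1.0)]
    )
    with caplog.at_level("INFO", logger="trophoscale"):
        res = fit_per_web_ols(df, min_records=2)
    assert list(res.web_id) == ["w2"]


def test_noise_free_generator_slopes_match_truth():
    cfg = SyntheticConfig(
        n_webs_per_ecosystem=4, ecosystem_types=("marine",), sigma_res=0.0, seed=9
    )
    webs, truth = generate_dataset(cfg)
    table = build_within_table(webs)
    slopes = fit_per_web_ols(table).merge(truth, on="web_id")
    assert np.allclose(slopes.k_i_x, slopes.k_i_y, atol=1e-8)


# ---------------------------------------------------------------------------
# within-web LME
# ---------------------------------------------------------------------------


def test_zero_noise_lme_recovers_slope_exactly():
    cfg = SyntheticConfig(
        n_webs_per_ecosystem=3, sigma_k=0.0, sigma_c=0.0, sigma_res=0.0, seed=5
    )
    webs, _ = generate_dataset(cfg)
    fit = fit_within_lme(build_within_table(webs))
    assert fit.k_bar == pytest.approx(cfg.k_bar_true, abs=1e-6)
    assert fit.sigma_res < 1e-6


def test_lme_recovers_slope_within_own_ci():
    cfg = SyntheticConfig(
        n_webs_per_ecosystem=30,
        ecosystem_types=("freshwater",),
        species_per_web=(30, 30),
        seed=42,
    )
    webs, _ = generate_dataset(cfg)
    fit = fit_within_lme(build_within_table(webs))
    assert fit.ci_k[0] <= 0.75 <= fit.ci_k[1]
    assert fit.sigma_res == pytest.approx(0.3, abs=0.05)


def test_single_ecosystem_skips_interaction_test(small_dataset):
    cfg = SyntheticConfig(n_webs_per_ecosystem=6, ecosystem_types=("marine",), seed=3)
    webs, _ = generate_dataset(cfg)
    fit = fit_within_lme(build_within_table(webs))
    skipped = [c for c in fit.model_comparison if c.get("skipped")]
    assert skipped, "interaction test should be skipped for one ecosystem"


def test_lrt_statistics_nonnegative(small_dataset):
    webs, _, _ = small_dataset
    fit = fit_within_lme(build_within_table(webs))
    for row in fit.model_comparison:
        if "chi2" in row:
            assert row["chi2"] >= -1e-8  # selected model never fits worse


def test_single_web_falls_back_to_ols():
    rng = np.random.default_rng(0)
    xs = rng.uniform(0, 3, 20)
    noise = rng.normal(0, 0.1, 20)
    df = within_frame(synthetic_line("w1", "marine", 0.7, -0.2, xs, noise))
    fit = fit_within_lme(df)
    ols = fit_per_web_ols(df)
    assert fit.k_bar == pytest.approx(ols.k_i.iloc[0], abs=1e-6)


def test_ci_width_shrinks_with_more_webs():
    widths = []
    for n in (8, 32):
        cfg = SyntheticConfig(
            n_webs_per_ecosystem=n, ecosystem_types=("marine",), seed=17
        )
        webs, _ = generate_dataset(cfg)
        fit = fit_within_lme(build_within_table(webs))
        widths.append(fit.ci_k[1] - fit.ci_k[0])
    assert widths[1] < widths[0]


# ---------------------------------------------------------------------------
# trait-augmented LME
# ---------------------------------------------------------------------------


def test_constant_omnivory_column_dropped():
    rng = np.random.default_rng(1)
    rows = []
    for w in range(4):
        xs = rng.uniform(0, 3, 10)
        noise = rng.normal(0, 0.2, 10)
        rows += synthetic_line(f"w{w}", "marine", 0.75, -0.5, xs, noise)
    df = within_frame(rows)
    df["ppmr_log10"] = rng.normal(2, 0.5, len(df))
    df["omnivory"] = 0.25  # constant
    fit, _ = fit_trait_lme(df)
    dropped = [c for c in fit.model_comparison if c.get("dropped") == "constant"]
    assert [c["predictor"] for c in dropped] == ["omnivory"]
    assert not any("omnivory" in t["term"] for t in fit.trait_tests)


def test_injected_ppmr_effect_recovered():
    cfg = SyntheticConfig(
        n_webs_per_ecosystem=30,
        ecosystem_types=("terrestrial",),
        species_per_web=(30, 30),
        ppmr_effect=0.3,
        seed=8,
    )
    webs, _ = generate_dataset(cfg)
    fit, _ = fit_trait_lme(build_within_table(webs))
    assert fit.n_records >= 400
    est = fit.fixed_effects["ppmr_log10"]["estimate"]
    assert est == pytest.approx(0.3, abs=0.05)
    # and the injected effect is detected
    t = [t for t in fit.trait_tests if t["term"] == "ppmr_log10"][0]
    assert t["p"] < 0.05


def test_null_trait_effects_mostly_nonsignificant():
    """Type-I behaviour: with no injected trait effects the trait F-tests
    should rarely reject (20 replicates, per-test alpha 0.05)."""
    hits = {"ppmr": 0, "omn": 0}
    n_rep = 20
    for s in range(n_rep):
        cfg = SyntheticConfig(
            n_webs_per_ecosystem=12, ecosystem_types=("marine",), seed=3000 + s
        )
        webs, _ = generate_dataset(cfg)
        fit, _ = fit_trait_lme(build_within_table(webs))
        for t in fit.trait_tests:
            if t["term"] == "ppmr_log10" and t["p"] < 0.05:
                hits["ppmr"] += 1
            if t["term"] == "omnivory" and t["p"] < 0.05:
                hits["omn"] += 1
    assert hits["ppmr"] <= 2  # ~90% non-significant
    assert hits["omn"] <= 2


def test_partial_residuals_cover_all_records(small_dataset):
    webs, _, _ = small_dataset
    table = build_within_table(webs)
    fit, partial = fit_trait_lme(table)
    expected = table.dropna(subset=["ppmr_log10", "omnivory"])
    assert len(partial) == len(expected)
    assert any(c.startswith("partial_resid_") for c in partial.columns)


# ---------------------------------------------------------------------------
# across-web ANCOVA
# ---------------------------------------------------------------------------


def across_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["web_id", "ecosystem_type", "log10_total_predator_biomass",
                 "log10_total_prey_biomass", "log10_mean_prey_mass",
                 "n_predators"],
    )


def _across_rows(eco, k, c, xs, noise=None, mean_mass=0.0):
    rows = []
    for i, x in enumerate(xs):
        e = 0.0 if noise is None else noise[i]
        rows.append((f"{eco}{i}", eco, c + k * x + e, x, mean_mass, 6))
    return rows


def test_exact_power_law_recovered_across_all_ecosystems():
    xs = np.linspace(-1, 3, 12)
    rows = []
    for eco in ("freshwater", "marine", "terrestrial"):
        rows += _across_rows(eco, 0.66, -0.3, xs)
    fit = fit_across_ancova(across_frame(rows))
    for v in fit.k_by_ecosystem.values():
        assert v["k"] == pytest.approx(0.66, abs=1e-10)
    assert fit.k_bar == pytest.approx(0.66, abs=1e-10)
    inter = fit.model_comparison[0]
    assert inter["F"] == pytest.approx(0.0, abs=1e-9)


def test_interaction_power_with_distinct_slopes():
    """Slopes 0.5 vs 0.9 at sigma 0.05, n=40/group: the F-test should
    essentially always detect the difference (100 replicates)."""
    rng = np.random.default_rng(12)
    detected = 0
    for _ in range(100):
        rows = []
        for eco, k in (("freshwater", 0.5), ("marine", 0.9)):
            xs = rng.uniform(-1, 2, 40)
            noise = rng.normal(0, 0.05, 40)
            rows += _across_rows(eco, k, 0.0, xs, noise)
        fit = fit_across_ancova(across_frame(rows))
        if fit.model_comparison[0]["p"] < 0.05:
            detected += 1
    assert detected >= 95


def test_single_ecosystem_plain_ols():
    xs = np.linspace(0, 2, 10)
    fit = fit_across_ancova(across_frame(_across_rows("marine", 0.7, 0.1, xs)))
    assert fit.k_bar == pytest.approx(0.7, abs=1e-10)
    assert fit.model_comparison[0].get("skipped")


def test_across_fit_on_generated_webs_covers_truth(small_dataset):
    from trophoscale.biomass_pipeline import build_across_table

    webs, _, cfg = small_dataset
    fit = fit_across_ancova(build_across_table(webs))
    lo, hi = fit.ci_k
    assert lo < cfg.k_bar_true < hi


# ---------------------------------------------------------------------------
# prey-mass diagnostic
# ---------------------------------------------------------------------------


def test_constant_prey_mass_slope_zero():
    xs = np.linspace(0, 3, 10)
    rows = []
    for eco in ("freshwater", "marine"):
        rows += _across_rows(eco, 0.7, 0.0, xs, mean_mass=-1.5)
    fit = fit_prey_mass_model(across_frame(rows))
    for v in fit.k_by_ecosystem.values():
        assert v["k"] == pytest.approx(0.0, abs=1e-12)


def test_mass_proportional_to_biomass_slope_one():
    xs = np.linspace(0, 3, 10)
    rows = across_frame(_across_rows("marine", 0.7, 0.0, xs))
    rows["log10_mean_prey_mass"] = rows["log10_total_prey_biomass"] - 2.0
    fit = fit_prey_mass_model(rows)
    assert fit.k_bar == pytest.approx(1.0, abs=1e-10)


def test_outliers_removed_before_prey_mass_fit():
    xs = np.linspace(0, 3, 10)
    frame = across_frame(_across_rows("marine", 0.7, 0.0, xs, mean_mass=-1.5))
    # corrupt one web; removing it as an outlier restores the zero slope
    frame.loc[0, "log10_mean_prey_mass"] = 5.0
    fit = fit_prey_mass_model(frame, outlier_ids=[frame.web_id.iloc[0]])
    assert fit.k_bar == pytest.approx(0.0, abs=1e-12)
    assert fit.n_webs == len(frame) - 1


def test_decoupled_prey_mass_ci_covers_zero():
    """Prey size and prey biomass are generated independently, so the slope
    CI should cover zero in most replicates (10 seeded replicates)."""
    from trophoscale.biomass_pipeline import build_across_table

    covered = 0
    for s in range(10):
        cfg = SyntheticConfig(n_webs_per_ecosystem=12, seed=600 + s)
        webs, _ = generate_dataset(cfg)
        fit = fit_prey_mass_model(build_across_table(webs))
        lo, hi = fit.ci_k
        covered += lo <= 0.0 <= hi
    assert covered >= 8


# ---------------------------------------------------------------------------
# per-species fits
# ---------------------------------------------------------------------------


def _species_rows(name, k, c, xs, noise=None):
    rows = []
    for i, x in enumerate(xs):
        e = 0.0 if noise is None else noise[i]
        rows.append((f"w{i}", "freshwater", x, c + k * x + e))
    df = within_frame(rows)
    df["taxon_name"] = name
    return df


def test_species_injected_slope_recovered_exactly():
    df = _species_rows("Cottus gobio", 0.75, -0.4, np.linspace(0, 3, 10))
    fit = fit_species_across_webs(df, "Cottus gobio")
    assert fit.k_bar == pytest.approx(0.75, abs=1e-12)
    assert fit.n_webs == 10


def test_species_invariant_biomass_gives_zero_slope():
    df = _species_rows("Salmo trutta", 0.0, 1.2, np.linspace(0, 3, 8))
    fit = fit_species_across_webs(df, "Salmo trutta")
    assert fit.k_bar == pytest.approx(0.0, abs=1e-12)


def test_species_noisy_slope_within_ci():
    rng = np.random.default_rng(4)
    df = _species_rows(
        "Gammarus pulex", 0.75, -0.4, rng.uniform(0, 3, 25), rng.normal(0, 0.2, 25)
    )
    fit = fit_species_across_webs(df, "Gammarus pulex")
    assert fit.ci_k[0] <= 0.75 <= fit.ci_k[1]


def test_species_with_too_few_webs_raises():
    df = _species_rows("Rare sp", 0.75, 0.0, [0.0, 1.0, 2.0])
    with pytest.raises(SpeciesFitError, match="Rare sp"):
        fit_species_across_webs(df, "Rare sp")


# ---------------------------------------------------------------------------
# derived identities
# ---------------------------------------------------------------------------


def test_doubling_rule_matches_fit_prediction():
    # for any fitted k, doubling x multiplies y by 2^k
    for k in (0.5, 0.71, 1.0):
        assert doubling_increase_percent(k) == pytest.approx(
            (fold_increase(k, 2.0) - 1.0) * 100.0
        )
    assert doubling_increase_percent(1.0) == pytest.approx(100.0)
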