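"""Generator contracts: bookkeeping, determinism, marginal fidelity,
disease/medication models, training sampling, and code-list flagging."""

import dataclasses
import random

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import chisquare

from prevmap.errors import ConfigError, InputError
from prevmap.synthetic import (
    AtcCodeSpec,
    DiseaseModel,
    assign_disease,
    assign_medication,
    benchmark_config,
    default_code_lists,
    excluded_atc_codes,
    expand_code_range,
    flag_disease_from_codes,
    generate_population,
    load_code_lists,
    read_population,
    retained_atc_codes,
    sample_training_set,
    true_municipal_prevalence,
    write_code_lists,
    write_population,
)

from conftest import small_config


class TestGeneratePopulation:
    def test_size_and_municipality_bookkeeping(self):
        cfg = small_config(n_individuals=1000, n_municipalities=10)
        pop = generate_population(cfg)
        assert len(pop) == 1000
        assert pop["municipality_id"].nunique() == 10
        assert pop["municipality_id"].notna().all()
        assert pop.groupby("municipality_id").size().min() >= 1

    def test_same_seed_byte_identical(self):
        cfg = small_config(n_individuals=800)
        a, b = generate_population(cfg), generate_population(cfg)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_different_seed_differs(self):
        a = generate_population(small_config(seed=1, n_individuals=800))
        b = generate_population(small_config(seed=2, n_individuals=800))
        assert a.to_csv(index=False) != b.to_csv(index=False)

    def test_percentiles_in_range(self, small_pop):
        for col in ("income_percentile", "wealth_percentile"):
            assert small_pop[col].between(1, 100).all()

    def test_indicators_strictly_binary(self, small_pop):
        for col in small_pop.columns:
            if col.startswith(("atc_", "dx_")) or col in ("female", "in_training"):
                assert set(np.unique(small_pop[col])) <= {0, 1}

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            small_config(n_municipalities=0).validate()
        with pytest.raises(ConfigError):
            small_config(training_fraction=1.5).validate()
        cfg = small_config()
        bad = dataclasses.replace(
            cfg, atc_codes=(AtcCodeSpec("B01", None, 0.0, 1.3),)
        )
        with pytest.raises(ConfigError):
            bad.validate()


@pytest.fixture(scope="module")
def national():
    return generate_population(benchmark_config(seed=5))


class TestPopulationMarginals:
    """National-scale marginals at n=100,000 (the reference conditions)."""

    def test_mean_age_near_target(self, national):
        ages = national["age"].to_numpy(float)
        se = ages.std(ddof=1) / np.sqrt(ages.size)
        assert abs(ages.mean() - 40.3) < 3 * se

    def test_covariate_marginals_chisquare(self, national):
        cfg = benchmark_config(seed=5)
        for spec in cfg.covariates:
            observed = national[spec.name].value_counts()
            obs = np.array([observed.get(lvl, 0) for lvl in spec.levels], float)
            exp = np.asarray(spec.probs) * len(national)
            stat, p = chisquare(obs, exp)
            assert p > 0.001, f"{spec.name}: chi2 GOF rejected (p={p:.2e})"

    def test_training_fraction_near_ten_percent(self, national):
        # whole-practice sampling: within one practice of the target
        share = national["in_training"].mean()
        practice_share = (
            national.groupby("practice_id").size().max() / len(national)
        )
        assert abs(share - 0.1) <= practice_share

    def test_true_prevalence_exposed_per_municipality(self, national):
        truth = true_municipal_prevalence(national, "diabetes")
        assert len(truth) == 50
        assert ((truth > 0) & (truth < 1)).all()
        # municipality random effects (sd 0.3) spread the truth
        assert truth.max() / truth.min() > 1.3


class TestAssignDisease:
    def test_intercept_only_prevalence(self, small_pop):
        model = DiseaseModel("flat", np.log(0.10 / 0.90), {}, municipality_sd=0.0)
        dx = assign_disease(small_pop, model, seed=3)
        se = np.sqrt(0.1 * 0.9 / len(small_pop))
        assert abs(dx.mean() - 0.10) < 3 * se

    def test_degenerate_intercept_gives_no_cases(self, small_pop):
        model = DiseaseModel("none", -50.0, {}, municipality_sd=0.0)
        assert assign_disease(small_pop, model, seed=3).sum() == 0

    def test_age_effect_matches_logistic_curve(self):
        pop = generate_population(small_config(n_individuals=60_000, seed=9))
        model = DiseaseModel("aged", -3.0, {"age_s": 4.0}, municipality_sd=0.0)
        dx = assign_disease(pop, model, seed=4)
        ages = pop["age"].to_numpy(float)
        for lo, hi in ((0, 25), (25, 50), (50, 75), (75, 120)):
            band = (ages >= lo) & (ages < hi)
            expected = expit(-3.0 + 4.0 * ages[band] / 100.0)
            emp = dx[band].mean()
            se = np.sqrt((expected * (1 - expected)).sum()) / band.sum()
            assert abs(emp - expected.mean()) < 4 * se

    def test_unknown_covariate_rejected(self, small_pop):
        model = DiseaseModel("bad", 0.0, {"no_such_column": 1.0})
        with pytest.raises(ConfigError):
            assign_disease(small_pop, model, seed=0)


class TestAssignMedication:
    def test_perfect_marker_equals_disease(self, small_pop):
        med = assign_medication(
            small_pop, [AtcCodeSpec("Z01", "diabetes", 1.0, 0.0)], seed=5
        )
        assert (med["atc_Z01"].to_numpy() == small_pop["dx_diabetes"].to_numpy()).all()

    def test_uninformative_code_odds_ratio_one(self):
        pop = generate_population(small_config(n_individuals=50_000, seed=11))
        med = assign_medication(pop, [AtcCodeSpec("Z02", "diabetes", 0.3, 0.3)], seed=6)
        t = pd.crosstab(med["atc_Z02"], pop["dx_diabetes"]).to_numpy().astype(float)
        odds_ratio = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
        se_log_or = np.sqrt((1.0 / t).sum())
        assert abs(np.log(odds_ratio)) < 3.5 * se_log_or

    def test_rare_code_flagged_excluded(self):
        pop = generate_population(benchmark_config(seed=2))
        med = assign_medication(pop, [AtcCodeSpec("Z03", None, 0.0, 0.0004)], seed=7)
        pop2 = pd.concat([pop, med], axis=1)
        n_users = int(med["atc_Z03"].sum())
        assert n_users <= 50  # ~40 expected of 100,000
        assert "Z03" in excluded_atc_codes(pop2)
        assert "Z03" not in retained_atc_codes(pop2)
        assert "A01" in retained_atc_codes(pop2)

    def test_invalid_probability_rejected(self, small_pop):
        with pytest.raises(ConfigError):
            assign_medication(small_pop, [AtcCodeSpec("Z04", None, 0.0, -0.1)], seed=0)


class TestSampleTrainingSet:
    def test_full_fraction_includes_everyone(self, small_pop):
        assert sample_training_set(small_pop, 1.0, seed=1).all()

    def test_equal_practices_exact_share(self):
        # 100 equal practices of 40 -> exactly 10 selected at fraction 0.1
        pop = pd.DataFrame(
            {
                "person_id": range(4000),
                "practice_id": [f"P{i:03d}" for i in range(100) for _ in range(40)],
            }
        )
        flag = sample_training_set(pop, 0.1, seed=3)
        chosen = pop.loc[flag == 1, "practice_id"].nunique()
        assert chosen == 10 and flag.sum() == 400

    def test_unequal_practices_within_one_practice(self, rng):
        sizes = rng.integers(10, 200, size=30)
        pop = pd.DataFrame(
            {
                "practice_id": np.repeat(
                    [f"P{i:02d}" for i in range(30)], sizes
                )
            }
        )
        flag = sample_training_set(pop, 0.1, seed=8)
        target = 0.1 * len(pop)
        assert abs(flag.sum() - target) <= sizes.max()

    def test_cluster_sampling_takes_whole_practices(self, small_pop):
        flag = sample_training_set(small_pop, 0.3, seed=2, cluster=True)
        frac = pd.Series(flag).groupby(small_pop["practice_id"].to_numpy()).mean()
        assert set(np.unique(frac)) <= {0.0, 1.0}

    def test_invalid_fraction_rejected(self, small_pop):
        with pytest.raises(ConfigError):
            sample_training_set(small_pop, 0.0, seed=1)


class TestCodeFlagging:
    def test_single_source_flags(self):
        lists = default_code_lists()
        records = {
            1: [("gp_icpc", "K90")],
            2: [("hospital_icd9", "250")],
            3: [],
            4: [("hospital_icd10", "I634")],  # prefix match inside I60-I69
            5: [("gp_icpc", "R95"), ("hospital_icd9", "414")],
        }
        flags = flag_disease_from_codes(records, lists)
        assert flags.loc[1].tolist() == [0, 1, 0, 0]  # chd, stroke, diabetes, copd
        assert flags.loc[2, "diabetes"] == 1 and flags.loc[2].sum() == 1
        assert flags.loc[3].sum() == 0
        assert flags.loc[4, "stroke"] == 1
        assert flags.loc[5, "copd"] == 1 and flags.loc[5, "chd"] == 1

    def test_order_independent_and_idempotent(self):
        lists = default_code_lists()
        recs = [("gp_icpc", "T90"), ("hospital_icd10", "J41"), ("hospital_icd9", "436")]
        base = flag_disease_from_codes({0: recs}, lists)
        for _ in range(5):
            shuffled = random.Random(0).sample(recs, len(recs))
            again = flag_disease_from_codes({0: shuffled + shuffled}, lists)
            pd.testing.assert_frame_equal(base, again)

    def test_unknown_source_rejected(self):
        with pytest.raises(InputError):
            flag_disease_from_codes({0: [("pharmacy", "X")]}, default_code_lists())

    def test_range_expansion(self):
        assert expand_code_range("I20", "I25") == (
            "I20", "I21", "I22", "I23", "I24", "I25",
        )
        assert expand_code_range("430", "434") == ("430", "431", "432", "433", "434")
        with pytest.raises(InputError):
            expand_code_range("I25", "I20")

    def test_code_list_csv_roundtrip(self, tmp_path):
        lists = default_code_lists()
        path = tmp_path / "codes.csv"
        write_code_lists(lists, path)
        assert load_code_lists(path) == lists


def test_population_csv_roundtrip(small_pop, tmp_path):
    path = tmp_path / "pop.csv"
    write_population(small_pop, path)
    back = read_population(path)
    pd.testing.assert_frame_equal(
        small_pop.reset_index(drop=True), back, check_dtype=False
    )
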