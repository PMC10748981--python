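"""Input model: moment matching, sampling, fitting and the EHR generator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orthosim.input_model import (
    CaseMix,
    EhrRecord,
    FittingError,
    InvalidParameterError,
    LosSpec,
    PROCEDURES,
    REFERENCE_COHORT_COUNTS,
    REFERENCE_COHORT_DELAYED,
    fit_los_parameters,
    frame_to_records,
    ehr_to_frame,
    generate_reference_cohort,
    generate_synthetic_ehr,
    load_ehr_csv,
    load_params,
    lognormal_from_moments,
    sample_los,
    sample_procedure,
    save_ehr_csv,
    save_params,
)


class TestLognormalFromMoments:
    @pytest.mark.parametrize(
        "mean, sd, mu, sigma",
        [
            (4.4, 2.9, 1.3012, 0.6006),  # primary hip replacement
            (16.5, 15.1, 2.4991, 0.7800),  # delayed-discharge stays
        ],
    )
    def test_closed_form_values(self, mean, sd, mu, sigma):
        params = lognormal_from_moments(mean, sd)
        assert params.mu == pytest.approx(mu, abs=1e-4)
        assert params.sigma == pytest.approx(sigma, abs=1e-4)

    def test_degenerate_sd_zero_is_point_mass(self, rng):
        params = lognormal_from_moments(7.3, 0.0)
        assert params.mu == pytest.approx(math.log(7.3))
        assert params.sigma == 0.0
        draws = sample_los(params, rng, size=50)
        assert np.all(draws == pytest.approx(7.3))

    @pytest.mark.parametrize("mean, sd", [(0.0, 1.0), (-2.0, 1.0), (4.0, -0.1)])
    def test_invalid_moments_rejected(self, mean, sd):
        with pytest.raises(InvalidParameterError):
            lognormal_from_moments(mean, sd)

    @given(
        mean=st.floats(0.01, 1000.0),
        cv=st.floats(0.0, 3.0),
    )
    @settings(derandomize=True, max_examples=200)
    def test_moment_round_trip(self, mean, cv):
        """Reconstructed arithmetic moments match the inputs to 1e-9 relative."""
        sd = mean * cv
        params = lognormal_from_moments(mean, sd)
        assert params.mean == pytest.approx(mean, rel=1e-9)
        assert params.sd == pytest.approx(sd, rel=1e-9, abs=1e-9)


class TestSampling:
    @pytest.mark.parametrize(
        "mean, sd", [(4.4, 2.9), (16.5, 15.1), (2.9, 2.1), (7.2, 7.6)]
    )
    def test_sample_moments_match_spec(self, mean, sd, rng):
        """100k draws reproduce the stated mean/SD within 3 standard errors."""
        n = 100_000
        draws = sample_los(lognormal_from_moments(mean, sd), rng, size=n)
        assert np.all(draws > 0)
        se_mean = sd / math.sqrt(n)
        assert draws.mean() == pytest.approx(mean, abs=3 * se_mean)
        # SE of the SD for a lognormal is inflated by its kurtosis; a 4x
        # normal-theory bound is ample at this n.
        assert draws.std(ddof=1) == pytest.approx(sd, rel=0.05)

    def test_sampling_is_reproducible(self):
        params = lognormal_from_moments(4.4, 2.9)
        a = sample_los(params, np.random.default_rng(7), size=10)
        b = sample_los(params, np.random.default_rng(7), size=10)
        assert np.array_equal(a, b)


class TestCaseMix:
    def test_baseline_shares(self, params):
        mix = params.case_mix
        assert mix.primary_share == pytest.approx(0.87)
        assert mix.revision_share == pytest.approx(0.13)
        assert mix.procedure_share("p-UKR") == pytest.approx(0.87 * 0.11)

    def test_invalid_shares_rejected(self):
        with pytest.raises(InvalidParameterError):
            CaseMix(
                primary_share=0.9,
                within_primary={"p-THR": 0.6, "p-TKR": 0.6, "p-UKR": -0.2},
                within_revision={"r-THR": 0.55, "r-TKR": 0.45},
            )

    def test_degenerate_within_class_always_returns_that_label(self, rng):
        mix = CaseMix(
            primary_share=1.0,
            within_primary={"p-THR": 1.0, "p-TKR": 0.0, "p-UKR": 0.0},
            within_revision={"r-THR": 0.5, "r-TKR": 0.5},
        )
        assert all(
            sample_procedure(mix, "primary", rng) == "p-THR" for _ in range(50)
        )

    @pytest.mark.parametrize(
        "surgical_class, label, share",
        [("primary", "p-THR", 0.51), ("revision", "r-THR", 0.55)],
    )
    def test_within_class_shares_converge(self, params, rng, surgical_class, label, share):
        n = 100_000
        draws = [sample_procedure(params.case_mix, surgical_class, rng) for _ in range(n)]
        observed = sum(d == label for d in draws) / n
        assert observed == pytest.approx(share, abs=3 * math.sqrt(share * (1 - share) / n))


class TestFitAndGenerate:
    def test_generate_zero_records(self, params):
        assert generate_synthetic_ehr(params, 0, seed=1) == []

    def test_generate_negative_rejected(self, params):
        with pytest.raises(InvalidParameterError):
            generate_synthetic_ehr(params, -1, seed=1)

    def test_generate_is_seed_deterministic(self, params):
        assert generate_synthetic_ehr(params, 500, seed=9) == generate_synthetic_ehr(
            params, 500, seed=9
        )

    def test_generated_class_shares(self, params):
        records = generate_synthetic_ehr(params, 100_000, seed=2)
        primary = sum(r.procedure.startswith("p-") for r in records) / len(records)
        ukr = sum(r.procedure == "p-UKR" for r in records) / len(records)
        assert primary == pytest.approx(0.87, abs=0.005)
        assert ukr == pytest.approx(0.0957, abs=0.004)

    def test_fit_identical_records(self):
        records = [
            EhrRecord(f"p{i}", "p-THR", 5.0, False) for i in range(10)
        ] + [EhrRecord(f"q{i}", lab, 5.0, False) for i, lab in enumerate(PROCEDURES)]
        with pytest.warns(UserWarning, match="no delayed records"):
            fitted = fit_los_parameters(records)
        assert fitted.los_specs["p-THR"] == LosSpec(5.0, 0.0)
        assert fitted.prop_delayed == 0.0

    def test_fit_missing_category_raises(self):
        records = [EhrRecord("a", "p-THR", 3.0, False)]
        with pytest.raises(FittingError, match="p-TKR"):
            fit_los_parameters(records)

    def test_fit_generate_closure(self, params):
        """Round trip generate -> fit recovers the generating parameters.

        Tolerances are 3 standard errors at the per-category record counts:
        the mean's SE is sd/sqrt(n); the SD's relative SE for a lognormal is
        sqrt((kurtosis - 1) / 4n), which dominates for the heavy-tailed
        revision and delayed categories.
        """
        n = 50_000
        records = generate_synthetic_ehr(params, n, seed=11)
        fitted = fit_los_parameters(records)

        def check(spec, true, n_cat):
            sigma2 = math.log1p((true.sd_days / true.mean_days) ** 2)
            kurt = (
                math.exp(4 * sigma2)
                + 2 * math.exp(3 * sigma2)
                + 3 * math.exp(2 * sigma2)
                - 3
            )
            assert spec.mean_days == pytest.approx(
                true.mean_days, abs=3 * true.sd_days / math.sqrt(n_cat)
            )
            assert spec.sd_days == pytest.approx(
                true.sd_days, rel=3 * math.sqrt((kurt - 1) / (4 * n_cat))
            )

        for label in PROCEDURES:
            n_cat = n * params.case_mix.procedure_share(label) * (1 - params.prop_delayed)
            check(fitted.los_specs[label], params.los_specs[label], n_cat)
        check(fitted.delayed_los, params.delayed_los, n * params.prop_delayed)
        assert fitted.prop_delayed == pytest.approx(params.prop_delayed, abs=0.01)

    def test_reference_cohort_counts_exact(self):
        records = generate_reference_cohort(seed=3)
        assert len(records) == 6912
        assert sum(r.delayed for r in records) == REFERENCE_COHORT_DELAYED
        for label, count in REFERENCE_COHORT_COUNTS.items():
            assert sum(r.procedure == label for r in records) == count
        fitted = fit_los_parameters(records)
        assert fitted.prop_delayed == pytest.approx(529 / 6912)
        assert fitted.prop_delayed == pytest.approx(0.0765, abs=5e-4)


class TestIO:
    def test_params_yaml_round_trip(self, params, tmp_path):
        path = tmp_path / "params.yaml"
        save_params(params, path)
        loaded = load_params(path)
        assert loaded == params

    def test_ehr_csv_round_trip(self, params, tmp_path):
        records = generate_synthetic_ehr(params, 100, seed=4)
        path = tmp_path / "ehr.csv"
        save_ehr_csv(records, path)
        assert path.read_text().splitlines()[0] == "patient_id,procedure,los_days,delayed"
        assert load_ehr_csv(path) == records

    def test_frame_round_trip(self, params):
        records = generate_synthetic_ehr(params, 20, seed=5)
        assert frame_to_records(ehr_to_frame(records)) == records
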