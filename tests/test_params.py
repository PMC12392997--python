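"""Parameter handling: conversions, validation, config I/O, PSA sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ugc_cea import defaults
from ugc_cea.params import (DistributionSpec, ParameterValue, ValidationError,
                            annualize_probability, derive_advanced_mortality,
                            dump_parameter_set, load_parameter_set,
                            rate_to_probability, sample_parameter_set,
                            sample_values, sampling_params)


class TestProbabilityConversions:
    @pytest.mark.parametrize("p_T, T, expected", [
        (0.0, 5, 0.0),
        (0.75, 2, 0.5),                 # 1 - sqrt(0.25)
        (0.2, 5, 0.0436475002),         # brute-force: 1-(1-q)^5 == 0.2
        (1.0, 3, 1.0),
    ])
    def test_annualize(self, p_T, T, expected):
        assert annualize_probability(p_T, T) == pytest.approx(expected, abs=1e-9)

    @given(p=st.floats(0.0, 0.999999), T=st.integers(1, 30))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_annualize_round_trip(self, p, T):
        q = annualize_probability(p, T)
        assert 0.0 <= q <= 1.0
        assert 1.0 - (1.0 - q) ** T == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("bad_p, bad_T", [(-0.1, 1), (1.1, 1), (0.5, 0)])
    def test_annualize_domain(self, bad_p, bad_T):
        with pytest.raises(ValueError):
            annualize_probability(bad_p, bad_T)

    @pytest.mark.parametrize("rate, expected", [
        (0.0, 0.0),
        (0.693147180559945, 0.5),
        (20.0, 1.0),
    ])
    def test_rate_to_probability(self, rate, expected):
        assert rate_to_probability(rate) == pytest.approx(expected, abs=1e-8)

    def test_rate_negative_rejected(self):
        with pytest.raises(ValueError):
            rate_to_probability(-0.01)

    def test_rate_monotone(self):
        rates = np.linspace(0, 3, 50)
        probs = [rate_to_probability(r) for r in rates]
        assert np.all(np.diff(probs) > 0)


class TestAdvancedMortality:
    def test_perfect_survival_gives_zero(self):
        assert derive_advanced_mortality(1.0) == (0.0,) * 6

    def test_constant_hazard_split(self):
        series = derive_advanced_mortality(0.32768)  # 0.8**5
        assert all(q == pytest.approx(0.2, abs=1e-12) for q in series)

    @pytest.mark.parametrize("S5", [0.05, 0.2, 0.5, 0.9])
    def test_round_trip(self, S5):
        series = derive_advanced_mortality(S5)
        surv = np.prod([1.0 - q for q in series[:5]])
        assert surv == pytest.approx(S5, abs=1e-9)
        assert series[5] == series[0]  # constant tail equals first-year value

    def test_domain(self):
        with pytest.raises(ValueError):
            derive_advanced_mortality(0.0)


class TestDistributionSpec:
    def test_triangular_ordering_enforced(self):
        with pytest.raises(ValueError):
            DistributionSpec("triangular", (0.6, 0.3, 0.8))

    def test_positive_shape_enforced(self):
        with pytest.raises(ValueError):
            DistributionSpec("gamma", (-1.0, 0.1))

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            DistributionSpec("lognormal", (0.0, 1.0))

    def test_gamma_recentered_mean_is_base(self):
        pv = defaults.default_costs()["screening_total"]
        shape, rate = sampling_params(pv, "recentered")
        assert shape / rate == pytest.approx(pv.base, rel=1e-12)

    def test_raw_mode_keeps_printed_pair(self):
        pv = defaults.default_costs()["screening_total"]
        assert sampling_params(pv, "raw") == (2.16, 0.003)


class TestSampling:
    def test_triangular_mean(self):
        pv = defaults.default_compliance()["screening"]
        x = sample_values(pv, np.random.default_rng(7), 10_000)
        assert x.mean() == pytest.approx((0.30 + 0.60 + 0.80) / 3, abs=0.01)
        assert x.min() >= 0.30 and x.max() <= 0.80

    def test_sampled_set_is_deterministic_and_valid(self, base_params):
        a = sample_parameter_set(base_params, seed=1)
        b = sample_parameter_set(base_params, seed=1)
        for name, pv in a.named_values().items():
            assert pv.base == b.named_values()[name].base
        a.validate()

    def test_sampling_leaves_structure_unchanged(self, base_params):
        a = sample_parameter_set(base_params, seed=3)
        assert a.transitions.probs == base_params.transitions.probs
        assert a.initial_distribution == base_params.initial_distribution
        assert a.mortality.other_cause == base_params.mortality.other_cause

    def test_samples_respect_truncation(self, base_params):
        rng = np.random.default_rng(11)
        for name, pv in base_params.named_values().items():
            if pv.distribution.truncation is None:
                continue
            lo, hi = pv.distribution.truncation
            x = sample_values(pv, rng, 2000)
            assert x.min() >= lo and x.max() <= hi, name

    def test_utilities_never_exceed_one(self, base_params):
        sampled = sample_parameter_set(base_params, seed=5)
        for name, pv in sampled.utilities.items():
            assert pv.base <= 1.0, name


class TestConfigIO:
    def test_round_trip(self, base_params, tmp_path):
        path = tmp_path / "cfg.yaml"
        dump_parameter_set(base_params, path)
        loaded = load_parameter_set(path)
        assert loaded.test["sensitivity"].base == 0.96
        assert loaded.test["sensitivity"].low == 0.90
        assert loaded.test["sensitivity"].high == 0.99
        assert loaded.wtp == 70653.0
        assert loaded.transitions.probs == base_params.transitions.probs

    def test_default_wtp_filled_in(self, base_params, tmp_path):
        import yaml
        path = tmp_path / "cfg.yaml"
        dump_parameter_set(base_params, path)
        doc = yaml.safe_load(path.read_text())
        del doc["wtp"]
        path.write_text(yaml.safe_dump(doc))
        assert load_parameter_set(path).wtp == 70653.0

    def test_bad_initial_distribution_reported(self, base_params, tmp_path):
        import yaml
        path = tmp_path / "cfg.yaml"
        dump_parameter_set(base_params, path)
        doc = yaml.safe_load(path.read_text())
        doc["initial_distribution"]["healthy"] -= 0.1
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(ValidationError, match="initial_distribution"):
            load_parameter_set(path)

    def test_missing_block_names_offender(self, base_params, tmp_path):
        import yaml
        path = tmp_path / "cfg.yaml"
        dump_parameter_set(base_params, path)
        doc = yaml.safe_load(path.read_text())
        del doc["transitions"]
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(ValidationError, match="transitions"):
            load_parameter_set(path)

    def test_parameter_table_export(self, base_params):
        df = base_params.as_table()
        assert {"name", "base", "low", "high", "family", "params"} <= set(df.columns)
        row = df.set_index("name").loc["compliance.screening"]
        assert row["base"] == 0.60 and row["family"] == "triangular"


class TestValidation:
    def test_utility_range_enforced(self, params):
        params.utilities["healthy"].base = 1.5
        with pytest.raises(ValidationError, match="utilities"):
            params.validate()

    def test_regression_after_intramucosal_rejected(self, params):
        params.transitions.probs["eso_advanced"] = {"eso_early": 0.1}
        with pytest.raises(ValidationError, match="regression"):
            params.validate()

    def test_row_sum_above_one_rejected(self, params):
        params.transitions.probs["healthy"]["eso_mild_dysplasia"] = 0.9
        params.transitions.probs["healthy"]["gastric_cag"] = 0.9
        with pytest.raises(ValidationError, match="sums"):
            params.validate()

    def test_set_value_round_trip(self, base_params):
        ps = base_params.set_value("cost.screening_total", 700.0)
        assert ps.cost_of("screening_total") == 700.0
        assert base_params.cost_of("screening_total") == 651.36

    def test_set_unknown_value(self, base_params):
        with pytest.raises(KeyError):
            base_params.set_value("cost.nonexistent", 1.0)
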