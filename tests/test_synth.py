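"""Generator fidelity: marginals, correlations, regimes, faults, kernel."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adentropy.exceptions import ConfigurationError
from adentropy.preprocess import remove_outliers
from adentropy.synth import (
    INPUT_VARIABLES,
    OUTPUT_VARIABLES,
    GeneratorConfig,
    Marginal,
    PlantDataGenerator,
    default_config,
    generate_records,
    inject_faults,
    read_records,
    true_response,
    write_records,
)

PRINTED_CORRELATIONS = {
    ("feed_solids", "biogas_yield"): 0.90,
    ("feed_solids", "temperature"): 0.85,
    ("feed_solids", "vfa"): 0.60,
}
PRINTED_MOMENTS = {
    "biogas_yield": (79.5, 6.1),
    "temperature": (34.2, 2.5),
    "vfa": (6.3, 1.5),
    "feed_solids": (26.5, 4.2),
}


class TestGeneratorFidelity:
    def test_correlations_match_plant_targets(self, table10k):
        ok = table10k[~table10k.fault_flag]
        for (a, b), r in PRINTED_CORRELATIONS.items():
            assert abs(ok[a].corr(ok[b]) - r) < 0.03, (a, b)

    def test_marginal_moments_within_two_standard_errors(self, table10k):
        ok = table10k[~table10k.fault_flag]
        n = len(ok)
        for var, (mean, sd) in PRINTED_MOMENTS.items():
            assert abs(ok[var].mean() - mean) < 2 * sd / np.sqrt(n), var
            # SE of the sample SD for the realized (non-Gaussian) shape:
            # Var(s^2) ~ (mu4 - sigma^4)/n  =>  SE(s) ~ sqrt(Var(s^2)) / 2 sigma
            dev = ok[var].to_numpy() - ok[var].mean()
            se_sd = np.sqrt(max((dev**4).mean() - dev.var() ** 2, 0.0) / n) / (2 * sd)
            assert abs(ok[var].std() - sd) < 2 * se_sd, var

    def test_fidelity_across_seeds(self, generator):
        """Correlations and output means recover across >= 9/10 seeds."""
        fails = 0
        for seed in range(1, 11):
            ok = generator.generate(5000, seed=seed)
            ok = ok[~ok.fault_flag]
            n = len(ok)
            bad = any(
                abs(ok[a].corr(ok[b]) - r) > 0.03 for (a, b), r in PRINTED_CORRELATIONS.items()
            )
            bad |= any(
                abs(ok[v].mean() - m) > 2 * s / np.sqrt(n)
                for v, (m, s) in PRINTED_MOMENTS.items()
            )
            fails += bad
        assert fails <= 1

    def test_regime_mix_and_cadence(self, table10k):
        mix = table10k.regime.value_counts(normalize=True)
        assert set(mix.index) <= {"steady", "load_fluctuation", "seasonal"}
        assert mix["steady"] > mix["load_fluctuation"] > mix["seasonal"]
        gaps = table10k.timestamp.diff().dropna().unique()
        assert len(gaps) == 1 and gaps[0] == pd.Timedelta(minutes=5)

    def test_reproducibility_bit_identical(self, generator):
        a = generator.generate(500, seed=9)
        b = generator.generate(500, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_independence_case_all_correlations_small(self):
        """With every dependence channel neutral (no correlation targets,
        no regime shifts, no shared non-linear structure) all pairwise
        correlations vanish."""
        zero = tuple((o, 0.0) for o in OUTPUT_VARIABLES)
        config = default_config(
            corr_targets=tuple(),
            regime_effects=tuple((r, zero) for r in ("steady", "load_fluctuation", "seasonal")),
            interaction_share=zero,
            overload_share=zero,
            seasonal_temp_amplitude=0.0,
            load_factor_share=0.0,
        )
        table = PlantDataGenerator(config).generate(5000, seed=3)
        ok = table[~table.fault_flag]
        corr = ok[list(INPUT_VARIABLES + OUTPUT_VARIABLES)].corr().to_numpy()
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_nonlinearity_linear_fit_leaves_more_residual(self, generator):
        """The kernel is genuinely non-linear in the three core drivers."""
        table = generator.generate(4000, seed=5)
        table = table[~table.fault_flag & (table.regime == "steady")]
        core = table[["feed_solids", "organic_matter", "feed_rate"]].to_numpy()
        noise_free, _, _ = true_response(core[:, 0], core[:, 1], core[:, 2])
        X = np.column_stack([core, np.ones(len(core))])
        beta, *_ = np.linalg.lstsq(X, noise_free, rcond=None)
        resid = noise_free - X @ beta
        assert resid.var() > 1e-4 * noise_free.var()


class TestTrueResponse:
    def test_deterministic(self):
        assert true_response(26.5, 28.7, 1.2) == true_response(26.5, 28.7, 1.2)

    def test_monotone_increasing_in_organic_matter(self):
        grid = np.linspace(15, 40, 41)
        for solids in (18.0, 26.5, 35.0):
            biogas, _, _ = true_response(np.full_like(grid, solids), grid, np.full_like(grid, 1.2))
            assert np.all(np.diff(biogas) > 0), solids

    def test_load_fluctuation_raises_vfa(self):
        _, _, vfa_steady = true_response(26.5, 28.7, 1.2, "steady")
        _, _, vfa_load = true_response(26.5, 28.7, 1.2, "load_fluctuation")
        assert vfa_load > vfa_steady

    def test_out_of_range_input_rejected(self):
        with pytest.raises(ValueError, match="range"):
            true_response(60.0, 28.7, 1.2)
        with pytest.raises(ValueError, match="regime"):
            true_response(26.5, 28.7, 1.2, "storm")


class TestFaults:
    def test_zero_rate_returns_table_unchanged(self, table10k):
        out = inject_faults(table10k, 0.0, seed=1)
        pd.testing.assert_frame_equal(out, table10k)

    def test_fault_count_rounds_to_nearest(self, generator):
        table = generator.generate(10_000, seed=2)
        assert int(table.fault_flag.sum()) == 230  # round(10000 * 0.023)

    def test_flagged_records_violate_exactly_the_cleaning_limits(self, table10k):
        flagged = table10k[table10k.fault_flag]
        clean = table10k[~table10k.fault_flag]
        viol = (
            (flagged.temperature > 80)
            | (flagged.feed_solids > 40)
            | (flagged.organic_matter > 50)
            | (flagged.biogas_yield < 0)
        )
        assert viol.all()
        viol_clean = (
            (clean.temperature > 80)
            | (clean.feed_solids > 40)
            | (clean.organic_matter > 50)
            | (clean.biogas_yield < 0)
        )
        assert not viol_clean.any()

    def test_fault_rate_bounds(self, table10k):
        with pytest.raises(ValueError):
            inject_faults(table10k, 0.2, seed=1)


class TestConfigValidation:
    def test_non_psd_input_block_raises(self):
        with pytest.raises(ConfigurationError, match="positive semi-definite"):
            default_config(
                corr_targets=(
                    ("feed_solids", "organic_matter", 0.95),
                    ("feed_solids", "feed_rate", 0.95),
                    ("organic_matter", "feed_rate", -0.95),
                )
            )

    def test_infeasible_output_targets_raise(self):
        with pytest.raises(ConfigurationError):
            default_config(
                corr_targets=(
                    ("feed_solids", "biogas_yield", 0.95),
                    ("organic_matter", "biogas_yield", 0.95),
                )
            )

    def test_bad_mix_and_rate(self):
        with pytest.raises(ConfigurationError):
            default_config(regime_mix=(("steady", 0.9), ("load_fluctuation", 0.9), ("seasonal", -0.8)))
        with pytest.raises(ConfigurationError):
            default_config(fault_rate=0.5)
        with pytest.raises(ConfigurationError):
            Marginal(1.0, -0.5)

    def test_n_below_one_rejected(self, generator):
        with pytest.raises(ValueError):
            generator.generate(0)

    @given(rate=st.floats(min_value=0.0, max_value=0.1))
    @settings(max_examples=20, deadline=None)
    def test_fault_count_always_rounds_n_times_rate(self, rate):
        n = 400
        table = pd.DataFrame(
            {
                "temperature": np.full(n, 34.0),
                "feed_solids": np.full(n, 26.0),
                "organic_matter": np.full(n, 28.0),
                "biogas_yield": np.full(n, 80.0),
                "fault_flag": np.zeros(n, dtype=bool),
            }
        )
        out = inject_faults(table, rate, seed=0)
        assert int(out.fault_flag.sum()) == int(np.floor(n * rate + 0.5))


def test_csv_roundtrip(tmp_path, generator):
    table = generator.generate(200, seed=4)
    path = tmp_path / "records.csv"
    write_records(table, path)
    back = read_records(path)
    assert list(back.columns) == list(table.columns)
    pd.testing.assert_frame_equal(
        back.drop(columns="timestamp"), table.drop(columns="timestamp"), atol=1e-9
    )
    assert (back.timestamp == table.timestamp).all()


def test_outlier_removal_equals_fault_set(table10k):
    cleaned, removed = remove_outliers(table10k)
    assert removed == int(table10k.fault_flag.sum()) == 230
    assert not cleaned.fault_flag.any()
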