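import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dartiso.binning import BinnedTable, CentroidSpectrum, VariableKey, assemble_table
from dartiso.features import (
    NormalizedTable,
    SelectionConfig,
    correlation_matrix,
    multiway_anova,
    normalize,
    refine_per_voltage,
    select_bins,
    weekly_profiles,
)
from dartiso.synthetic import DesignConfig, Fragment, SpectrumModel, generate_design, simulate_spectra


def _table(rows: dict, meta: pd.DataFrame | None = None) -> BinnedTable:
    ab = pd.DataFrame.from_dict(rows, orient="index")
    ab.index.name = "sample_id"
    if meta is None:
        meta = pd.DataFrame(index=ab.index)
    return BinnedTable(abundance=ab, metadata=meta)


class TestSelectBins:
    def _uniform_table(self, n_meeting: int, n_total: int = 10) -> BinnedTable:
        """n_total spectra at one voltage; bin B meets 1% in n_meeting of them."""
        rows = {}
        for i in range(n_total):
            base = 1000.0
            b = 20.0 if i < n_meeting else 1.0  # 2% vs 0.1% of base
            rows[f"s{i}"] = {"100.025_30V": base, "100.050_30V": b}
        return _table(rows)

    def test_bin_meeting_threshold_everywhere_is_retained(self):
        table = self._uniform_table(n_meeting=10)
        got = select_bins(table, SelectionConfig(pct_threshold=1.0, min_spectra=5))
        assert got == [100.025, 100.050]

    def test_boundary_one_below_min_spectra_is_discarded(self):
        table = self._uniform_table(n_meeting=4)
        got = select_bins(table, SelectionConfig(pct_threshold=1.0, min_spectra=5))
        assert got == [100.025]
        got = select_bins(self._uniform_table(n_meeting=5),
                          SelectionConfig(pct_threshold=1.0, min_spectra=5))
        assert got == [100.025, 100.050]

    def test_monotone_in_percent_threshold(self):
        """Raising the percent threshold never adds a bin."""
        rng = np.random.default_rng(3)
        rows = {f"s{i}": {f"{100 + j * 0.025:.3f}_30V": float(rng.lognormal(3, 2))
                          for j in range(12)} for i in range(30)}
        table = _table(rows)
        previous = None
        for pct in (0.3, 1.0, 10.0):
            got = set(select_bins(table, SelectionConfig(pct_threshold=pct, min_spectra=10)))
            if previous is not None:
                assert got <= previous
            previous = got

    def test_generator_catalog_is_recovered_exactly(self):
        """With fragments far above threshold plus a junk noise floor, the
        retained bins are exactly the catalogue bins."""
        design = generate_design(DesignConfig(n_weeks=2, cards_per_week=2))
        frags = [Fragment(110.010, 30, 11.0, (0.0, 0.0, 0.0)),
                 Fragment(120.010, 30, 10.0, (0.3, 0.0, -0.3)),
                 Fragment(130.010, 30, 9.5, (0.0, 0.2, -0.2))]
        model = SpectrumModel(fragments=frags, noise_sd=0.1, week_effect_sd=0.0,
                              shared_week_sd=0.0, n_junk_peaks=5,
                              class_noise_scale=(1.0, 1.0, 1.0))
        spectra = simulate_spectra(design, model, seed=2)
        binned = assemble_table(spectra, design, voltages=[30])
        got = select_bins(binned, SelectionConfig(pct_threshold=1.0, min_spectra=30))
        assert got == [110.025, 120.025, 130.025]

    def test_literal_reading_is_available(self):
        table = self._uniform_table(n_meeting=6, n_total=10)
        # 4 spectra fail; with min_spectra 5 the literal reading keeps the bin
        got = select_bins(table, SelectionConfig(pct_threshold=1.0, min_spectra=5,
                                                 reading="count_failing"))
        assert got == [100.025, 100.050]


class TestRefinePerVoltage:
    def test_fragment_present_at_one_voltage_kept_only_there(self):
        design = generate_design(DesignConfig(n_weeks=2, cards_per_week=2))
        frags = [Fragment(110.010, 30, 11.0, (0.0, 0.0, 0.0)),
                 Fragment(110.010, 60, 11.0, (0.0, 0.0, 0.0)),
                 Fragment(110.010, 90, 11.0, (0.0, 0.0, 0.0)),
                 Fragment(120.010, 30, 10.0, (0.0, 0.0, 0.0))]
        model = SpectrumModel(fragments=frags, noise_sd=0.05, week_effect_sd=0.0,
                              shared_week_sd=0.0, n_junk_peaks=0,
                              class_noise_scale=(1.0, 1.0, 1.0))
        spectra = simulate_spectra(design, model, seed=1)
        binned = assemble_table(spectra, design, voltages=[30, 60, 90])
        cfg = SelectionConfig(pct_threshold=1.0, min_spectra=30)
        keys = refine_per_voltage(binned, select_bins(binned, cfg), cfg)
        assert VariableKey(120.025, 30) in keys
        assert VariableKey(120.025, 60) not in keys
        assert {k for k in keys if k.bin_upper == 110.025} == {
            VariableKey(110.025, v) for v in (30, 60, 90)
        }


class TestNormalize:
    meta = pd.DataFrame(index=pd.Index(["s1"], name="sample_id"))

    def test_ion_current_example(self):
        table = _table({"s1": {"100.025_30V": 10.0, "100.050_30V": 30.0, "100.075_30V": 60.0}},
                       self.meta)
        nt = normalize(table, table.variables(), "ion_current")
        assert nt.values.loc["s1"].tolist() == pytest.approx([0.1, 0.3, 0.6])

    def test_vector_length_three_four_five(self):
        table = _table({"s1": {"100.025_30V": 3.0, "100.050_30V": 4.0}}, self.meta)
        nt = normalize(table, table.variables(), "vector_length")
        assert nt.values.loc["s1"].tolist() == pytest.approx([0.6, 0.8])

    def test_normalization_is_per_voltage(self):
        table = _table({"s1": {"100.025_30V": 10.0, "100.025_60V": 40.0,
                               "100.050_30V": 10.0, "100.050_60V": 10.0}}, self.meta)
        nt = normalize(table, table.variables(), "ion_current")
        assert nt.values.loc["s1", "100.025_30V"] == pytest.approx(0.5)
        assert nt.values.loc["s1", "100.025_60V"] == pytest.approx(0.8)

    def test_denominator_uses_only_selected_bins(self):
        table = _table({"s1": {"100.025_30V": 10.0, "100.050_30V": 30.0,
                               "100.075_30V": 60.0}}, self.meta)
        selected = [VariableKey(100.025, 30), VariableKey(100.050, 30)]
        nt = normalize(table, selected, "ion_current")
        assert nt.values.loc["s1"].tolist() == pytest.approx([0.25, 0.75])
        assert "100.075_30V" not in nt.values.columns

    def test_all_zero_segment_stays_zero(self):
        table = _table({"s1": {"100.025_30V": 0.0, "100.050_30V": 0.0}}, self.meta)
        for scheme in ("ion_current", "vector_length"):
            nt = normalize(table, table.variables(), scheme)
            assert (nt.values.loc["s1"] == 0.0).all()

    def test_invariants_on_random_rows(self):
        """Ion-current rows sum to 1 and vector-length rows have unit norm,
        per voltage, within 1e-12."""
        rng = np.random.default_rng(11)
        n = 1200
        rows = {f"s{i}": {f"{100 + j * 0.025:.3f}_{v}V": float(rng.lognormal(5, 1))
                          for j in range(5) for v in (30, 60, 90)} for i in range(n)}
        table = _table(rows)
        nt_ic = normalize(table, table.variables(), "ion_current")
        nt_vl = normalize(table, table.variables(), "vector_length")
        for v in (30, 60, 90):
            cols = nt_ic.columns_for_voltage(v)
            assert np.allclose(nt_ic.values[cols].sum(axis=1), 1.0, atol=1e-12)
            assert np.allclose(np.sqrt((nt_vl.values[cols] ** 2).sum(axis=1)), 1.0, atol=1e-12)

    def test_base_peak_scale_never_leaks_downstream(self, small_dataset):
        """Selection uses the percent scale, but the normalized values are
        computed from raw abundances: recomputing from the raw table with
        the same variable list gives identical results."""
        _, variables, binned, ntables = small_dataset
        again = normalize(binned, variables, "ion_current")
        pd.testing.assert_frame_equal(again.values, ntables["ion_current"].values)


class TestMultiwayAnova:
    def _ntable(self, values, meta):
        return NormalizedTable(values=values, metadata=meta, scheme="ion_current")

    def test_identical_group_means_give_f_zero_p_one(self):
        meta = pd.DataFrame({"isomer": ["o", "o", "m", "m", "p", "p"] * 2,
                             "week": [1, 2, 1, 2, 1, 2] * 2,
                             "volume": [3.0] * 12},
                            index=[f"s{i}" for i in range(12)])
        # every isomer/week/cell mean is 2, residual variance is nonzero
        y = pd.DataFrame({"a_30V": [1.0, 3.0, 1.0, 3.0, 1.0, 3.0,
                                    3.0, 1.0, 3.0, 1.0, 3.0, 1.0]}, index=meta.index)
        res = multiway_anova(self._ntable(y, meta), factors=("isomer", "week"))
        assert res.loc["a_30V", "F_isomer"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["a_30V", "p_isomer"] == pytest.approx(1.0)

    def test_one_factor_reduction_equals_squared_pooled_t(self):
        """On a two-group toy, the one-way ANOVA F equals the square of the
        pooled-variance t statistic (textbook identity, computed here with
        an independent implementation of the pooled t)."""
        a = np.array([1.0, 2.0, 4.0])
        b = np.array([3.0, 5.0, 6.0])
        meta = pd.DataFrame({"isomer": ["o"] * 3 + ["m"] * 3},
                            index=[f"s{i}" for i in range(6)])
        y = pd.DataFrame({"a_30V": np.concatenate([a, b])}, index=meta.index)
        res = multiway_anova(self._ntable(y, meta), factors=("isomer",))
        # independent oracle: pooled two-sample t from first principles
        sp2 = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        sp2 /= len(a) + len(b) - 2
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert res.loc["a_30V", "F_isomer"] == pytest.approx(t**2, rel=1e-12)
        assert res.loc["a_30V", "df_isomer"] == 1

    def test_matches_statsmodels_on_simulated_data(self, small_dataset):
        """Cross-check the three-factor Type I table against statsmodels."""
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        _, _, _, ntables = small_dataset
        nt = ntables["ion_current"]
        res = multiway_anova(nt)
        var = nt.values.columns[0]
        df = nt.metadata.copy()
        df["y"] = nt.values[var]
        sm_tab = anova_lm(smf.ols("y ~ C(isomer)*C(week)*C(volume)", df).fit(), typ=1)
        assert res.loc[var, "F_isomer"] == pytest.approx(sm_tab.loc["C(isomer)", "F"], rel=1e-9)
        assert res.loc[var, "p_isomer:week"] == pytest.approx(
            sm_tab.loc["C(isomer):C(week)", "PR(>F)"], rel=1e-9)
        assert res.loc[var, "F_isomer:week:volume"] == pytest.approx(
            sm_tab.loc["C(isomer):C(week):C(volume)", "F"], rel=1e-9)

    def test_single_level_factor_is_skipped(self):
        meta = pd.DataFrame({"isomer": ["o", "o", "m", "m"], "week": [1, 1, 1, 1],
                             "volume": [3.0] * 4},
                            index=[f"s{i}" for i in range(4)])
        y = pd.DataFrame({"a_30V": [1.0, 2.0, 3.0, 4.0]}, index=meta.index)
        res = multiway_anova(self._ntable(y, meta))
        assert "F_week" not in res.columns
        assert "F_isomer" in res.columns


class TestWeeklyProfiles:
    def test_single_week_modes_coincide(self, small_dataset):
        _, _, _, ntables = small_dataset
        nt = ntables["ion_current"]
        one_week = NormalizedTable(
            values=nt.values[nt.metadata["week"] == 1],
            metadata=nt.metadata[nt.metadata["week"] == 1],
            scheme=nt.scheme,
        )
        a = weekly_profiles(one_week, "per_week")
        b = weekly_profiles(one_week, "accumulating")
        pd.testing.assert_frame_equal(a, b)

    def test_accumulating_mean_is_grand_mean_of_prefix(self, small_dataset):
        _, _, _, ntables = small_dataset
        nt = ntables["ion_current"]
        acc = weekly_profiles(nt, "accumulating")
        last_week = nt.metadata["week"].max()
        var = nt.values.columns[0]
        got = acc[(acc["week"] == last_week) & (acc["variable"] == var)
                  & (acc["isomer"] == "ortho")]["mean"].iloc[0]
        expected = nt.values.loc[nt.metadata["isomer"] == "ortho", var].mean()
        assert got == pytest.approx(expected)

    def test_constant_data_has_zero_sd(self):
        meta = pd.DataFrame({"isomer": ["o"] * 4, "week": [1, 1, 2, 2]},
                            index=[f"s{i}" for i in range(4)])
        y = pd.DataFrame({"a_30V": [2.0] * 4}, index=meta.index)
        nt = NormalizedTable(values=y, metadata=meta, scheme="ion_current")
        prof = weekly_profiles(nt, "per_week")
        assert (prof["sd"] == 0.0).all()


class TestCorrelationMatrix:
    def test_self_and_negation(self):
        meta = pd.DataFrame(index=[f"s{i}" for i in range(5)])
        x = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        y = pd.DataFrame({"a_30V": x, "b_30V": -x}, index=meta.index)
        nt = NormalizedTable(values=y, metadata=meta, scheme="ion_current")
        corr = correlation_matrix(nt)
        assert corr.loc["a_30V", "a_30V"] == pytest.approx(1.0)
        assert corr.loc["a_30V", "b_30V"] == pytest.approx(-1.0)
        assert np.allclose(corr.values, corr.values.T)

    def test_shared_week_drift_induces_positive_correlation(self):
        """Fragments loading on the shared weekly factor co-move relative to
        the rest of the spectrum (sign check over 10 seeds)."""
        design = generate_design(DesignConfig(n_weeks=8, cards_per_week=2))
        frags = [Fragment(110.010, 30, 10.0, (0.0, 0.0, 0.0), week_loading=1.0),
                 Fragment(120.010, 30, 10.0, (0.0, 0.0, 0.0), week_loading=1.0),
                 Fragment(130.010, 30, 10.0, (0.0, 0.0, 0.0), week_loading=0.0),
                 Fragment(140.010, 30, 10.0, (0.0, 0.0, 0.0), week_loading=0.0)]
        model = SpectrumModel(fragments=frags, noise_sd=0.15, week_effect_sd=0.0,
                              shared_week_sd=0.5, n_junk_peaks=0,
                              class_noise_scale=(1.0, 1.0, 1.0))
        signs = []
        for seed in range(10):
            spectra = simulate_spectra(design, model, seed=seed)
            binned = assemble_table(spectra, design, voltages=[30])
            nt = normalize(binned, binned.variables(), "ion_current")
            corr = correlation_matrix(nt)
            signs.append(corr.loc["110.025_30V", "120.025_30V"])
        assert np.mean(signs) > 0
        assert (np.array(signs) > 0).mean() >= 0.8

    def test_too_few_samples_rejected(self):
        meta = pd.DataFrame(index=["s0", "s1"])
        y = pd.DataFrame({"a_30V": [1.0, 2.0]}, index=meta.index)
        with pytest.raises(ValueError):
            correlation_matrix(NormalizedTable(values=y, metadata=meta, scheme="ion_current"))
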