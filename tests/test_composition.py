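"""CLR transform, bin summaries, correlations and concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from edna_profiler import composition as cp
from edna_profiler.countsqc import CountsTable


def _comp_from_counts(data, **kw):
    t = CountsTable(counts=pd.DataFrame(data), sample_types={})
    return cp.clr_transform(t, **kw)


class TestCLR:
    def test_uniform_proportions_map_to_epsilon(self):
        comp = _comp_from_counts({"s1": [100, 100, 100]})
        assert np.allclose(comp.values["s1"], comp.scalar_offset)
        assert comp.scalar_offset == pytest.approx(0.01)

    def test_closed_form_half_quarter_quarter(self):
        comp = _comp_from_counts({"s1": [500, 250, 250]})
        unshifted = comp.unscaled()["s1"].to_numpy()
        expect = np.array([np.log(0.5), np.log(0.25), np.log(0.25)])
        expect -= expect.mean()
        assert np.allclose(unshifted, expect, atol=1e-9)
        assert unshifted[0] == pytest.approx(0.462, abs=1e-3)
        assert unshifted[1] == pytest.approx(-0.231, abs=1e-3)

    def test_per_sample_clr_sums_to_zero(self):
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(rng.integers(0, 2000, size=(10, 6)))
        comp = cp.clr_transform(CountsTable(counts=counts, sample_types={}))
        un = comp.unscaled()
        for s in comp.samples:
            det = comp.detected[s]
            assert abs(un.loc[det, s].sum()) < 1e-9

    def test_matches_scikit_bio_clr(self):
        """Dual route: our detected-part CLR equals scikit-bio's clr on the
        detected subvector."""
        from skbio.stats.composition import clr as skbio_clr

        comp = _comp_from_counts({"s1": [120, 0, 380, 500]})
        det = comp.detected["s1"]
        p = np.array([120, 380, 500], dtype=float)
        p /= p.sum()
        assert np.allclose(comp.unscaled().loc[det, "s1"], skbio_clr(p))

    def test_scaling_preserves_rank_order(self):
        comp = _comp_from_counts({"s1": [10, 700, 100, 900]})
        vals = comp.values["s1"]
        un = comp.unscaled()["s1"]
        assert list(vals.sort_values().index) == list(un.sort_values().index)

    def test_all_detected_values_positive(self):
        comp = _comp_from_counts({"s1": [1, 5000], "s2": [900, 900]})
        det_vals = comp.values.to_numpy()[comp.detected.to_numpy()]
        assert (det_vals > 0).all()

    def test_sample_with_one_detection_dropped(self):
        with pytest.warns(UserWarning, match="dropped"):
            comp = _comp_from_counts({"s1": [100, 0], "s2": [100, 300]})
        assert comp.samples == ["s2"] and comp.dropped_samples == ["s1"]


class TestSummaries:
    def test_single_positive_sample_sum_equals_average(self):
        comp = _comp_from_counts({"s1": [100, 300], "s2": [0, 0]})
        out = cp.summarize_bins(comp)
        row = out.iloc[0]
        assert row["n_positive"] == 1
        assert row["summed_composition"] == pytest.approx(
            row["average_composition"])

    def test_average_times_n_equals_sum(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.integers(0, 900, size=(7, 9)))
        comp = cp.clr_transform(CountsTable(counts=counts, sample_types={}))
        out = cp.summarize_bins(comp)
        prod = out["average_composition"] * out["n_positive"]
        assert np.allclose(prod, out["summed_composition"])

    def test_ranks_are_permutation(self):
        rng = np.random.default_rng(6)
        counts = pd.DataFrame(rng.integers(1, 900, size=(8, 5)))
        comp = cp.clr_transform(CountsTable(counts=counts, sample_types={}))
        ranks = cp.summarize_bins(comp)["edna_rank"].dropna()
        assert sorted(ranks) == list(range(1, len(ranks) + 1))


class TestCpueCorrelation:
    def test_proportional_gives_r_one(self):
        summed = pd.Series({f"b{i}": 2.0 * np.log(i + 2) for i in range(8)})
        cpue = pd.Series({f"b{i}": float(i + 2) for i in range(8)})
        out = cp.cpue_correlation(summed, cpue)
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_matches_direct_formula_on_toys(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            y = pd.Series(rng.normal(5, 2, 10), index=[f"b{i}" for i in range(10)])
            c = pd.Series(rng.uniform(0.5, 9, 10), index=y.index)
            out = cp.cpue_correlation(y, c)
            x = np.log(100 * c / c.sum())
            xc, yc = x - x.mean(), y - y.mean()
            r = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
            assert out["pearson_r"] == pytest.approx(float(r))

    def test_permuted_y_uncorrelated(self):
        rng = np.random.default_rng(31)
        y = pd.Series(np.arange(1.0, 21.0), index=[f"b{i}" for i in range(20)])
        c = pd.Series(np.exp(y / 4), index=y.index)
        shuffled = pd.Series(rng.permutation(y.values), index=y.index)
        assert abs(cp.cpue_correlation(shuffled, c)["pearson_r"]) < 0.5

    def test_exclusions_and_missing_cpue_dropped(self):
        y = pd.Series({"b1": 1.0, "b2": 2.0, "b3": 3.0, "b4": 4.0, "bx": 9.0})
        c = pd.Series({"b1": 1.0, "b2": 2.0, "b3": 3.0, "b4": np.nan, "bx": 2.0})
        out = cp.cpue_correlation(y, c, exclusions=["bx"])
        assert out["n"] == 3

    def test_too_few_points_errors(self):
        y = pd.Series({"b1": 1.0, "b2": 2.0})
        c = pd.Series({"b1": 1.0, "b2": 2.0})
        with pytest.raises(ValueError, match=">=3"):
            cp.cpue_correlation(y, c)


class TestReplicates:
    def _comp(self, data):
        return _comp_from_counts(data)

    def test_identical_replicates_perfect_concordance(self):
        comp = self._comp({"a": [100, 300, 600], "b": [100, 300, 600]})
        out = cp.replicate_concordance(comp, [("a", "b")])
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["dropout"].empty

    def test_dropout_tallied_with_detected_member_value(self):
        comp = self._comp({"a": [100, 300, 600], "b": [0, 300, 600]})
        out = cp.replicate_concordance(comp, [("a", "b")])
        assert len(out["dropout"]) == 1
        assert out["dropout"].iloc[0]["detected_in"] == "a"

    def test_anticorrelated_pair(self):
        comp = self._comp({"a": [100, 200, 400, 800],
                           "b": [800, 400, 200, 100]})
        out = cp.replicate_concordance(comp, [("a", "b")])
        assert out["pearson_r"] == pytest.approx(-1.0, abs=1e-9)

    def test_no_pairs_warns(self):
        comp = self._comp({"a": [10, 20]})
        with pytest.warns(UserWarning):
            out = cp.replicate_concordance(comp, [("x", "y")])
        assert out["n_pairs"] == 0


class TestSiteContrast:
    def _setup(self):
        counts = pd.DataFrame({
            "s1": [500, 100, 0], "s2": [450, 120, 0],
            "s3": [500, 0, 90], "s4": [480, 0, 110]},
            index=["Sp_shared", "Sp_below", "Sp_above"])
        comp = cp.clr_transform(CountsTable(counts=counts, sample_types={}))
        manifest = pd.DataFrame({
            "sample": ["s1", "s2", "s3", "s4"],
            "site": ["below", "below", "above", "above"]})
        return comp, manifest

    def test_below_only_bin_positive_difference_with_annotation(self):
        comp, manifest = self._setup()
        out = cp.site_contrast(comp, manifest, "below", "above")
        assert out.loc["Sp_below", "difference"] > 0
        assert out.loc["Sp_below", "zero_side"] == "above"
        assert out.loc["Sp_above", "zero_side"] == "below"

    def test_identical_sites_zero_difference(self):
        counts = pd.DataFrame({"s1": [300, 100], "s2": [300, 100]},
                              index=["Sp_a", "Sp_b"])
        comp = cp.clr_transform(CountsTable(counts=counts, sample_types={}))
        manifest = pd.DataFrame({"sample": ["s1", "s2"],
                                 "site": ["below", "above"]})
        out = cp.site_contrast(comp, manifest, "below", "above",
                               min_detections=1)
        assert np.allclose(out["difference"], 0.0)

    def test_unknown_site_errors(self):
        comp, manifest = self._setup()
        with pytest.raises(KeyError):
            cp.site_contrast(comp, manifest, "below", "nowhere")


class TestSampleCorrelation:
    def test_duplicated_sample_perfectly_correlated(self):
        counts = pd.DataFrame({
            "s1": [500, 100, 50, 700], "s2": [500, 100, 50, 700],
            "s3": [10, 900, 400, 30]})
        comp = cp.clr_transform(CountsTable(counts=counts, sample_types={}))
        rho, order = cp.sample_correlation_matrix(comp, min_prevalence=1)
        assert rho.loc["s1", "s2"] == pytest.approx(1.0)
        assert np.allclose(rho, rho.T) and np.allclose(np.diag(rho), 1.0)
        assert sorted(order) == ["s1", "s2", "s3"]

    def test_block_structure_recovered_in_leaf_order(self):
        rng = np.random.default_rng(14)
        base_a = rng.integers(200, 900, size=8)
        base_b = rng.permutation(base_a)
        cols = {}
        for i in range(3):
            cols[f"a{i}"] = base_a + rng.integers(0, 40, 8)
            cols[f"b{i}"] = base_b + rng.integers(0, 40, 8)
        comp = cp.clr_transform(
            CountsTable(counts=pd.DataFrame(cols), sample_types={}))
        _, order = cp.sample_correlation_matrix(comp, min_prevalence=1)
        groups = ["".join(s[0] for s in order)]
        assert groups[0] in ("aaabbb", "bbbaaa")

    def test_too_few_samples_errors(self):
        comp = _comp_from_counts({"s1": [10, 20], "s2": [10, 20]})
        with pytest.raises(ValueError):
            cp.sample_correlation_matrix(comp)


class TestConcordance:
    def test_empty_edna_all_capture_only(self):
        totals = pd.Series(dtype=int)
        capture = pd.Series({"Sp_a": 1.0, "Sp_b": 2.0})
        report, tallies = cp.concordance_classify(totals, capture)
        assert (report["class"] == "capture-only").all()
        assert tallies["concordant_over_50_reads"] == 0

    def test_classes_exhaustive_and_exclusive(self):
        totals = pd.Series({"Sp_a": 100, "Sp_b": 1, "Sp_c": 60, "Sp_flag": 500})
        capture = pd.Series({"Sp_a": 2.0, "Sp_b": 1.0, "Sp_only": 3.0,
                             "Sp_noref": 1.0, "Sp_flag": 0.5})
        report, tallies = cp.concordance_classify(
            totals, capture, no_reference=["Sp_noref"],
            contaminant_flags=["Sp_flag"])
        assert set(report["class"]) <= set(cp.CONCORDANCE_CLASSES)
        assert report.loc["Sp_flag", "class"] == "flagged-contaminant"
        assert report.loc["Sp_noref", "class"] == "no-reference"
        assert report.loc["Sp_c", "class"] == "eDNA-only"
        assert tallies["concordant_over_50_reads"] == 1   # Sp_a only
        assert tallies["concordant_single_read"] == 1     # Sp_b
        assert tallies["edna_only_10_to_49_reads"] == 0
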