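import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ttkit.spikein import (
    NormalizationParams,
    SpikeInNormalizer,
    SpikeInSet,
    antisense_bias,
    antisense_correct,
    cross_contamination,
    depth_normalize,
    estimate_params,
    rpk,
    rpk_to_coverage,
    select_expressed,
    select_reference_non_de,
    sequencing_depth,
    size_factors,
)
from ttkit.synthetic import gen_annotation, gen_counts, gen_spikeins


def make_set(rows):
    return SpikeInSet(pd.DataFrame(
        rows, columns=["spikein_id", "length", "labeled", "sample", "sense", "antisense"]))


class TestParameterEstimators:
    def test_antisense_bias_is_median_of_ratios(self):
        sp = make_set([("s1", 100, True, "j", 100, 5), ("s2", 100, True, "j", 100, 10),
                       ("s3", 100, False, "j", 100, 15)])
        assert antisense_bias(sp, "j") == pytest.approx(0.10)

    def test_no_antisense_signal_gives_zero(self):
        sp = make_set([("s1", 100, True, "j", 50, 0), ("s2", 100, False, "j", 20, 0)])
        assert antisense_bias(sp, "j") == 0.0

    def test_zero_sense_spikeins_excluded_then_error_when_none_left(self):
        sp = make_set([("s1", 100, True, "j", 0, 5), ("s2", 100, True, "j", 100, 10)])
        assert antisense_bias(sp, "j") == pytest.approx(0.10)
        empty = make_set([("s1", 100, True, "j", 0, 5)])
        with pytest.raises(ValueError):
            antisense_bias(empty, "j")

    def test_depth_single_labeled_spikein(self):
        sp = make_set([("s1", 1000, True, "j", 500, 0), ("s2", 500, False, "j", 10, 0)])
        assert sequencing_depth(sp, "j") == pytest.approx(0.5)

    def test_depth_uses_only_labeled(self):
        sp = make_set([("s1", 1000, True, "j", 500, 0), ("s2", 10, False, "j", 10000, 0)])
        assert sequencing_depth(sp, "j") == pytest.approx(0.5)
        unlabeled_only = make_set([("s1", 1000, False, "j", 500, 0)])
        with pytest.raises(ValueError):
            sequencing_depth(unlabeled_only, "j")

    def test_cross_contamination_direct(self):
        sp = make_set([("s1", 1000, True, "j", 500, 0), ("s2", 1000, False, "j", 50, 0)])
        assert cross_contamination(sp, "j", sigma=0.5) == pytest.approx(0.1)
        assert cross_contamination(
            make_set([("s2", 1000, False, "j", 0, 0)]), "j", 0.5) == 0.0

    def test_epsilon_requires_unlabeled(self):
        sp = make_set([("s1", 1000, True, "j", 500, 0)])
        with pytest.raises(ValueError):
            cross_contamination(sp, "j", 0.5)

    def test_identical_samples_rescale_to_unit_sigma(self):
        rows = [(f"s{i}", 100 * i, i < 3, j, 100 * i, 0)
                for i in range(1, 5) for j in ("a", "b")]
        params = estimate_params(make_set(rows))
        assert params.sigma.to_numpy() == pytest.approx([1.0, 1.0])

    def test_c_invariant_to_spikein_order(self):
        rows = [("s1", 100, True, "j", 100, 5), ("s2", 100, True, "j", 200, 30),
                ("s3", 100, False, "j", 50, 10)]
        assert antisense_bias(make_set(rows), "j") == antisense_bias(
            make_set(rows[::-1]), "j")

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_recovery_on_synthetic_spikeins(self, seed):
        """Planted (sigma ratio, c, epsilon) recovered from Poisson counts."""
        sp, truth = gen_spikeins(12, sigma={"a": 1.0, "b": 2.0}, c=0.08,
                                 epsilon=0.02, depth=1e4, seed=seed)
        params = estimate_params(sp, rescale_sigma=False)
        assert params.sigma["b"] / params.sigma["a"] == pytest.approx(2.0, rel=0.10)
        assert params.c["a"] == pytest.approx(0.08, abs=0.02)
        assert params.epsilon["a"] == pytest.approx(0.02, abs=0.01)


class TestAntisenseCorrection:
    def test_zero_bias_is_identity(self):
        assert antisense_correct(50, 5, 0.0) == 50.0

    def test_exact_inversion_of_mixing_model(self):
        # true sense 100, antisense 10, c=0.2 -> observed (102, 30)
        S, A = 100 + 0.2 * 10, 10 + 0.2 * 100
        assert antisense_correct(S, A, 0.2) == pytest.approx(100.0)

    def test_direct_evaluation(self):
        assert antisense_correct(110, 20, 0.1) == pytest.approx(108 / 0.99)

    def test_negative_results_floored(self):
        assert antisense_correct(1, 100, 0.5) == 0.0
        assert antisense_correct(1, 100, 0.5, floor=False) < 0

    def test_c_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            antisense_correct(10, 1, 1.0)

    @given(
        s=st.floats(0, 1e6), a=st.floats(0, 1e6),
        c=st.floats(0, 0.9, allow_nan=False),
    )
    @settings(max_examples=300, deadline=None)
    def test_round_trip_property(self, s, a, c):
        """Correcting both strands of the forward mixing model recovers truth."""
        S, A = s + c * a, a + c * s
        assert antisense_correct(S, A, c, floor=False) == pytest.approx(s, abs=1e-6 * (1 + s))
        assert antisense_correct(A, S, c, floor=False) == pytest.approx(a, abs=1e-6 * (1 + a))


class TestRpk:
    @pytest.mark.parametrize("count, length, expected",
                             [(0, 1000, 0.0), (500, 2500, 200.0), (100, 1000, 100.0)])
    def test_values(self, count, length, expected):
        assert rpk(count, length) == pytest.approx(expected)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            rpk(10, 0)

    def test_coverage_worked_examples(self):
        assert rpk_to_coverage(100, 200, 2) == pytest.approx(10.0)
        assert rpk_to_coverage(20, 200, 2) == pytest.approx(2.0)
        assert rpk_to_coverage(0) == 0.0

    def test_coverage_linearity(self):
        base = rpk_to_coverage(50, 200, 2)
        assert rpk_to_coverage(100, 200, 2) == pytest.approx(2 * base)
        assert rpk_to_coverage(50, 200, 4) == pytest.approx(base / 2)


class TestExpressedSet:
    def test_threshold_inclusive(self):
        table = pd.DataFrame({"r1": [75, 50, 49.5, 10, 0], "r2": [75, 50, 49.5, 10, 0]},
                             index=list("abcde"))
        assert list(select_expressed(table, 100)) == ["a", "b"]
        assert list(select_expressed(table, 20)) == ["a", "b", "c", "d"]
        assert list(select_expressed(table, 0)) == list("abcde")

    def test_unknown_sample_rejected(self):
        table = pd.DataFrame({"r1": [1.0]}, index=["a"])
        with pytest.raises(KeyError):
            select_expressed(table, 10, summarize=["nope"])


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = pd.DataFrame({"a": [5, 9, 2], "b": [5, 9, 2]})
        assert size_factors(m).to_numpy() == pytest.approx([1.0, 1.0])

    def test_doubled_column_closed_form(self):
        m = pd.DataFrame({"a": [10, 100, 4], "b": [20, 200, 8]})
        assert size_factors(m).to_numpy() == pytest.approx(
            [1 / np.sqrt(2), np.sqrt(2)], abs=1e-12)

    def test_zero_rows_excluded_from_median(self):
        m = pd.DataFrame({"a": [10, 0, 4], "b": [20, 5, 8]})
        assert size_factors(m).to_numpy() == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])
        with pytest.raises(ValueError):
            size_factors(pd.DataFrame({"a": [0, 1], "b": [1, 0]}))

    def test_normalized_counts_invariant_to_column_scaling(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.poisson(50, (30, 3)) + 1, columns=list("abc")).astype(float)
        norm1 = m.div(size_factors(m), axis=1)
        scaled = m.copy()
        scaled["b"] *= 7.5
        norm2 = scaled.div(size_factors(scaled), axis=1)
        # rescaling one sample leaves normalized counts unchanged up to one
        # common constant (the geometric-mean reference absorbs lambda^(1/m))
        ratio = (norm2 / norm1).to_numpy()
        assert np.allclose(ratio, ratio.flat[0])
        assert ratio.flat[0] == pytest.approx(7.5 ** (1 / 3))


class TestDepthNormalize:
    def test_scalar_and_matrix(self):
        assert depth_normalize(12.0, 2.0) == 6.0
        df = pd.DataFrame({"a": [2.0, 4.0], "b": [3.0, 9.0]})
        out = depth_normalize(df, pd.Series({"a": 2.0, "b": 3.0}))
        assert out["a"].tolist() == [1.0, 2.0]
        assert out["b"].tolist() == [1.0, 3.0]

    def test_columns_recover_common_scale(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(1, 10, 50)
        sigma = pd.Series({"a": 1.0, "b": 2.5})
        df = pd.DataFrame({j: base * sigma[j] for j in sigma.index})
        out = depth_normalize(df, sigma)
        assert np.allclose(out["a"], out["b"])

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            depth_normalize(1.0, 0.0)


CONTRASTS = {
    "t15": (["ctrl_t15_r1", "ctrl_t15_r2"], ["trt_t15_r1", "trt_t15_r2"]),
    "t30": (["ctrl_t30_r1", "ctrl_t30_r2"], ["trt_t30_r1", "trt_t30_r2"]),
}


@pytest.fixture(scope="module")
def planted():
    _, tus, _, _ = gen_annotation(120, length_range=(20_000, 300_000), seed=3)
    counts, lengths, truth = gen_counts(tus, mean_rpk=50, seed=3)
    return counts, lengths, truth


class TestNonDeSelection:
    def test_planted_reference_recovered(self, planted):
        counts, lengths, truth = planted
        rpks = counts.div(lengths / 1000, axis=0)
        expressed = select_expressed(rpks, 100, ["ctrl_t15_r1", "ctrl_t15_r2"])
        selected = select_reference_non_de(counts, lengths, CONTRASTS, expressed=expressed)
        planted_ref = set(truth.reference_tus)
        candidates = {t for t in expressed if lengths[t] > 50_000}
        assert set(selected) <= planted_ref
        assert len(set(selected)) / len(candidates & planted_ref) >= 0.8

    def test_all_short_tus_error(self, planted):
        counts, lengths, _ = planted
        with pytest.raises(ValueError, match="relax"):
            select_reference_non_de(counts, lengths, CONTRASTS, min_length_bp=10**9)

    def test_identical_conditions_keep_everything(self, planted):
        counts, lengths, _ = planted
        sym = counts.copy()
        for ctrl, trt in CONTRASTS.values():
            sym[trt] = sym[ctrl].to_numpy()
        selected = select_reference_non_de(sym, lengths, CONTRASTS)
        assert len(selected) == (lengths > 50_000).sum()


class TestNormalizerFacade:
    def test_fit_transform_and_params(self):
        sp, _ = gen_spikeins(10, sigma={"a": 1.0, "b": 2.0}, c=0.1, seed=0,
                             noise_free=True)
        norm = SpikeInNormalizer(rescale_sigma=False)
        assert norm.get_params()["rescale_sigma"] is False
        norm.set_params(rescale_sigma=True)
        with pytest.raises(ValueError):
            norm.set_params(bogus=1)
        norm.fit(sp)
        assert set(norm.sigma_.index) == {"a", "b"}
        sense = pd.DataFrame({"a": [110.0], "b": [220.0]})
        anti = pd.DataFrame({"a": [20.0], "b": [40.0]})
        out = norm.transform(sense, anti)
        # equal depth after rescaling: b column twice the reads, half the scale
        assert out["a"].iloc[0] == pytest.approx(out["b"].iloc[0])

    def test_transform_before_fit_rejected(self):
        with pytest.raises(RuntimeError):
            SpikeInNormalizer().transform(pd.DataFrame({"a": [1.0]}))


class TestParamContainer:
    def test_validation_and_round_trip(self, tmp_path):
        params = NormalizationParams(
            sigma=pd.Series({"a": 1.0}), c=pd.Series({"a": 0.1}),
            epsilon=pd.Series({"a": 0.0}))
        path = str(tmp_path / "params.tsv")
        params.to_tsv(path)
        back = NormalizationParams.from_tsv(path)
        assert back.sigma["a"] == 1.0 and back.size_factor["a"] == 1.0
        with pytest.raises(ValueError):
            NormalizationParams(sigma=pd.Series({"a": 1.0}), c=pd.Series({"a": 1.0}),
                                epsilon=pd.Series({"a": 0.0}))
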