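import math

import numpy as np
import pandas as pd
import pytest

from probetrack.impact import (
    ConcordanceResult,
    ExpressionMatrix,
    ImpactConfig,
    aggregate_with_offtargets,
    concordance,
    cpm_normalize,
    group_means,
    normalized_expression,
    offtarget_expression_screen,
    pseudolog,
    strip_id_suffix,
)
from probetrack.tracker import GeneSummary, PredictedGene


def _matrix(data, index=None):
    return ExpressionMatrix(pd.DataFrame(data, index=index))


class TestCpm:
    def test_basic_arithmetic(self):
        m = _matrix({"g1": [2], "g2": [8]})
        cpm = cpm_normalize(m)
        assert cpm.loc[0, "g1"] == pytest.approx(200_000)
        assert cpm.loc[0, "g2"] == pytest.approx(800_000)

    def test_single_expressed_gene_is_1e6(self):
        m = _matrix({"g1": [5], "g2": [0]})
        assert cpm_normalize(m).loc[0, "g1"] == pytest.approx(1e6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 50, size=(10, 6)))
        counts.columns = [f"g{i}" for i in range(6)]
        a = cpm_normalize(ExpressionMatrix(counts))
        b = cpm_normalize(ExpressionMatrix(counts * 2))
        pd.testing.assert_frame_equal(a, b, check_dtype=False)

    def test_rows_sum_to_1e6(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(1, 50, size=(5, 4)))
        counts.columns = list("abcd")
        assert cpm_normalize(ExpressionMatrix(counts)).sum(axis=1).tolist() == (
            pytest.approx([1e6] * 5)
        )

    def test_zero_library_dropped_with_warning(self):
        m = _matrix({"g1": [0, 3], "g2": [0, 1]})
        with pytest.warns(UserWarning, match="zero library"):
            cpm = cpm_normalize(m)
        assert list(cpm.index) == [1]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            _matrix({"g1": [-1]})


class TestPseudolog:
    def test_zero_maps_to_zero(self):
        assert pseudolog(np.array([0.0]))[0] == 0.0

    def test_e_minus_one_maps_to_one(self):
        assert pseudolog(np.array([math.e - 1]))[0] == pytest.approx(1.0)

    def test_monotone(self):
        rng = np.random.default_rng(2)
        x = np.sort(rng.uniform(0, 100, 50))
        y = pseudolog(x)
        assert (np.diff(y) >= 0).all()


class TestAggregate:
    def test_no_offtargets_equals_target_only(self):
        m = _matrix({"t": [3, 0, 5], "o": [1, 1, 1]})
        agg = aggregate_with_offtargets(m, "t", [])
        target_only = normalized_expression(m)["t"]
        pd.testing.assert_series_equal(agg, target_only, check_names=False)

    def test_absent_offtargets_skipped(self):
        m = _matrix({"t": [3, 0, 5], "o": [1, 1, 1]})
        agg = aggregate_with_offtargets(m, "t", ["missing1", "missing2"])
        pd.testing.assert_series_equal(
            agg, normalized_expression(m)["t"], check_names=False
        )

    def test_silent_target_equals_offtarget_profile(self):
        m = _matrix({"t": [0, 0, 0], "o": [4, 0, 9], "bg": [10, 10, 10]})
        agg = aggregate_with_offtargets(m, "t", ["o"])
        pd.testing.assert_series_equal(
            agg, normalized_expression(m)["o"], check_names=False
        )

    def test_aggregated_counts_dominate_target(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.integers(0, 20, size=(20, 3)), columns=["t", "o1", "o2"]
        )
        counts["bg"] = 50
        m = ExpressionMatrix(counts)
        agg = aggregate_with_offtargets(m, "t", ["o1", "o2"])
        assert (agg >= normalized_expression(m)["t"]).all()

    def test_absent_target_raises(self):
        with pytest.raises(KeyError):
            aggregate_with_offtargets(_matrix({"g": [1]}), "t", [])


class TestConcordance:
    def test_identical_nonconstant_vectors(self):
        r = concordance([0, 1, 2], [0, 1, 2])
        assert r.rmse == 0
        assert r.pearson == pytest.approx(1.0)

    def test_zero_variance_gives_nan_pearson(self):
        r = concordance([0, 3, 4], [0, 0, 0])
        assert math.isnan(r.pearson)
        assert r.pearson_missing

    def test_hand_computed_rmse(self):
        r = concordance([0, 3, 4], [0, 0, 0])
        assert r.rmse == pytest.approx(math.sqrt(25 / 3))

    def test_rmse_symmetric(self):
        a, b = [0.5, 2.0, 3.5], [1.0, 0.0, 9.0]
        assert concordance(a, b).rmse == concordance(b, a).rmse

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            concordance([1, 2], [1, 2, 3])

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            concordance([1], [2])

    def test_rmse_zero_iff_identical(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=10)
        b = a.copy()
        b[3] += 1e-3
        assert concordance(a, a.copy()).rmse == 0
        assert concordance(a, b).rmse > 0


class TestGroupMeans:
    def _values(self):
        rng = np.random.default_rng(5)
        return pd.DataFrame(
            rng.normal(size=(17, 3)),
            columns=["g1", "g2", "g3"],
            index=[f"o{i}" for i in range(17)],
        )

    def test_small_group_dropped(self):
        values = self._values()
        labels = ["big"] * 12 + ["small"] * 5
        means = group_means(values, labels, min_size=10)
        assert list(means.index) == ["big"]

    def test_single_group_equals_column_means(self):
        values = self._values()
        means = group_means(values, ["all"] * 17, min_size=10)
        pd.testing.assert_series_equal(
            means.loc["all"], values.mean(), check_names=False
        )

    def test_permutation_invariant(self):
        values = self._values()
        labels = pd.Series((["a"] * 10 + ["b"] * 7), index=values.index)
        perm = values.sample(frac=1, random_state=0).index
        base = group_means(values, labels, min_size=5)
        shuffled = group_means(values.loc[perm], labels.loc[perm], min_size=5)
        pd.testing.assert_frame_equal(base, shuffled)

    def test_modality_filter(self):
        values = self._values()
        labels = ["a"] * 12 + ["b"] * 5
        modality = (["x", "y"] * 9)[:17]
        # group b has fewer than 5 from each modality
        means = group_means(values, labels, min_size=5, modality_labels=modality)
        assert list(means.index) == ["a"]

    def test_all_dropped_raises(self):
        values = self._values()
        with pytest.raises(ValueError, match="minimum size"):
            group_means(values, ["solo"] * 17, min_size=100)


class TestScreen:
    def _summaries(self):
        return [
            GeneSummary(
                target_gene_id="gT",
                target_gene_name="TARGET",
                n_probes=4,
                predicted=[
                    PredictedGene("gT", "TARGET", 4, "protein_coding", True, False),
                    PredictedGene("gHI", "HIGHEXPR", 1, "protein_coding", False, False),
                    PredictedGene("gLO", "LOWEXPR", 1, "protein_coding", False, False),
                    PredictedGene("gNO", "UNDETECTED", 1, "pseudogene", False, False),
                ],
            )
        ]

    def _reference(self):
        return _matrix(
            {
                "TARGET": [5, 5, 5, 5],
                "HIGHEXPR": [500, 400, 600, 500],
                "LOWEXPR": [1, 0, 2, 1],
                "OTHER": [50, 50, 50, 50],
            },
            index=[f"c{i}" for i in range(4)],
        )

    def test_ranking_and_detection(self):
        table = offtarget_expression_screen(self._summaries(), self._reference())
        assert list(table["offtarget_gene"]) == ["HIGHEXPR", "LOWEXPR", "UNDETECTED"]
        assert list(table["detected"]) == [True, True, False]
        assert math.isnan(table["log1p_mean_cpm"].iloc[-1])

    def test_values_are_log1p_mean_cpm(self):
        table = offtarget_expression_screen(self._summaries(), self._reference())
        cpm = cpm_normalize(self._reference())
        expected = float(np.log1p(cpm["HIGHEXPR"].mean()))
        assert table["log1p_mean_cpm"].iloc[0] == pytest.approx(expected)

    def test_observation_permutation_invariant(self):
        ref = self._reference()
        perm = ref.counts.sample(frac=1, random_state=1)
        t1 = offtarget_expression_screen(self._summaries(), self._reference())
        t2 = offtarget_expression_screen(self._summaries(), ExpressionMatrix(perm))
        pd.testing.assert_frame_equal(t1, t2)

    def test_id_suffix_trimmed(self):
        summaries = [
            GeneSummary(
                target_gene_id="gT",
                target_gene_name="TARGET",
                n_probes=1,
                predicted=[
                    PredictedGene(
                        "ENSG0001.7", "ENSG0001.7", 1, "protein_coding", False, False
                    )
                ],
            )
        ]
        ref = _matrix({"ENSG0001": [10, 20], "TARGET": [1, 1]})
        table = offtarget_expression_screen(summaries, ref)
        assert bool(table["detected"].iloc[0])


def test_strip_id_suffix():
    assert strip_id_suffix("ENSG0001.7") == "ENSG0001"
    assert strip_id_suffix("ENSG0001") == "ENSG0001"
    assert strip_id_suffix("NAME-1.2X") == "NAME-1.2X"


class TestAggregationRecovery:
    def test_directional_property_on_synthetic_platforms(self, sim_data, sim_expression):
        x, y, _ = sim_expression
        truth = sim_data.truth
        offtargets_of = {}
        for t in truth.probes.values():
            offtargets_of.setdefault(t.gene_name, set()).update(
                p.gene_name for p in t.planted
            )
        nx = normalized_expression(x)
        ny = normalized_expression(y)
        checked = 0
        for gene, ots in offtargets_of.items():
            ots = sorted(ots)
            if not ots or y.counts[ots].sum().sum() == 0:
                continue
            target_only = concordance(nx[gene], ny[gene])
            aggregated = concordance(
                nx[gene], aggregate_with_offtargets(y, gene, ots)
            )
            assert aggregated.rmse < target_only.rmse
            checked += 1
        assert checked > 0

    def test_nan_to_defined_pearson_for_silent_target(self, sim_data, sim_expression):
        x, y, _ = sim_expression
        truth = sim_data.truth
        silent = [
            g
            for g in {t.gene_name for t in truth.probes.values()}
            if y.counts[g].sum() == 0
            and any(
                t.planted for t in truth.probes.values() if t.gene_name == g
            )
        ]
        assert silent, "fixture should contain a silent target with off-targets"
        gene = silent[0]
        ots = sorted(
            {
                p.gene_name
                for t in truth.probes.values()
                if t.gene_name == gene
                for p in t.planted
            }
        )
        nx = normalized_expression(x)
        ny = normalized_expression(y)
        target_only = concordance(nx[gene], ny[gene])
        aggregated = concordance(nx[gene], aggregate_with_offtargets(y, gene, ots))
        assert target_only.pearson_missing
        assert not aggregated.pearson_missing


class TestReadCountsMatrix:
    def test_delimited_roundtrip(self, tmp_path):
        from probetrack.impact import read_counts_matrix

        counts = pd.DataFrame(
            {"g1": [1, 2], "g2": [3, 4]}, index=["o1", "o2"]
        )
        path = tmp_path / "counts.tsv"
        counts.to_csv(path, sep="\t")
        m = read_counts_matrix(path)
        pd.testing.assert_frame_equal(m.counts, counts)

    def test_mtx_with_sidecars(self, tmp_path):
        from probetrack.impact import read_counts_matrix

        # 10x-style: features x barcodes
        (tmp_path / "m.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n"
            "2 3 3\n1 1 5\n2 2 7\n1 3 1\n"
        )
        (tmp_path / "features.tsv").write_text("g1\tGene1\ng2\tGene2\n")
        (tmp_path / "barcodes.tsv").write_text("b1\nb2\nb3\n")
        m = read_counts_matrix(
            tmp_path / "m.mtx", tmp_path / "features.tsv", tmp_path / "barcodes.tsv"
        )
        assert m.counts.shape == (3, 2)  # observations x genes
        assert m.counts.loc["b1", "g1"] == 5
        assert m.counts.loc["b2", "g2"] == 7

    def test_mtx_requires_sidecars(self, tmp_path):
        from probetrack.impact import read_counts_matrix

        (tmp_path / "m.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n1 1 1\n1 1 1\n"
        )
        with pytest.raises(ValueError, match="sidecar"):
            read_counts_matrix(tmp_path / "m.mtx")


def test_impact_config_validation():
    with pytest.raises(ValueError):
        ImpactConfig(pseudocount=0)
    with pytest.raises(ValueError):
        ImpactConfig(min_group_size=0)
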