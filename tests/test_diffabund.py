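import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metabomix.diffabund import (
    CompoundMatrix,
    Contrast,
    aggregate_by_compound,
    differential_test,
    load_compound_matrix,
    log_transform,
    report_tables,
    significance_filter,
    storey_qvalues,
)
from metabomix.ident import Identification

from conftest import make_peak_table


def brute_force_qvalues(p, lam=0.5):
    """Independent loop-based transcription of the q-value definition."""
    p = list(map(float, p))
    m = len(p)
    pi0 = min(1.0, max(sum(1 for x in p if x > lam), 1) / (m * (1 - lam)))
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    best = float("inf")
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, pi0 * m * p[i] / rank)
        q[i] = min(best, 1.0)
    return np.array(q)


def _bio_design():
    rows = []
    for g in ("WT", "KO"):
        for b in range(1, 4):
            rows.append(
                {"sample_id": f"{g}{b}", "genotype": g, "treatment": "none",
                 "biological_replicate": f"{g}{b}", "organ": "kidney"}
            )
    return pd.DataFrame(rows)


def _matrix(values, compounds=None, classes=None):
    values = np.asarray(values, dtype=float)
    ids = compounds or [f"M{i}" for i in range(len(values))]
    vals = pd.DataFrame(values, index=pd.Index(ids, name="compound_id"),
                        columns=["WT1", "WT2", "WT3", "KO1", "KO2", "KO3"])
    info = pd.DataFrame(
        {"name": ids, "formula": "C2H4O2",
         "class_label": classes or ["others"] * len(ids)},
        index=vals.index,
    )
    return CompoundMatrix(vals, info)


class TestAggregate:
    def _ident(self, pid, cid):
        return Identification(pid, (cid,), "C2H4O2", "[M+H]+", 1.0, 0.9, "assigned")

    def test_peaks_of_one_compound_are_summed(self):
        peaks = make_peak_table([100, 101], [5, 6], [2000, 2000],
                                [[100.0, 7.0], [50.0, 3.0]], ["s1", "s2"])
        idents = [self._ident("P0", "A"), self._ident("P1", "A")]
        m = aggregate_by_compound(idents, peaks)
        assert m.values.loc["A", "s1"] == 150.0
        assert m.values.loc["A", "s2"] == 10.0

    def test_single_peak_compound_is_identity(self):
        peaks = make_peak_table([100], [5], [2000], [[4.0, 9.0]], ["s1", "s2"])
        m = aggregate_by_compound([self._ident("P0", "B")], peaks)
        assert list(m.values.loc["B"]) == [4.0, 9.0]

    def test_unassigned_peaks_excluded_and_empty_warns(self, caplog):
        peaks = make_peak_table([100], [5], [2000], [[4.0, 9.0]], ["s1", "s2"])
        unass = Identification("P0", (), "", "", float("nan"), 0.0, "unassigned")
        with caplog.at_level("WARNING"):
            m = aggregate_by_compound([unass], peaks)
        assert len(m) == 0


class TestLogTransform:
    def test_hand_values_with_fudge_100(self):
        # force the 10th percentile to 100 with a large matrix of 100s
        vals = np.full((10, 6), 100.0)
        vals[0, 0] = 412.0
        vals[0, 1] = 0.0
        transformed, spec = log_transform(_matrix(vals))
        assert spec.fudge == pytest.approx(100.0)
        assert spec.base == 2
        assert transformed.iloc[0, 0] == pytest.approx(9.0)       # log2(512)
        assert transformed.iloc[0, 1] == pytest.approx(6.6439, abs=1e-4)  # log2(100)

    def test_all_zero_matrix_is_an_error(self):
        with pytest.raises(ValueError, match="log2"):
            log_transform(_matrix(np.zeros((3, 6))))

    def test_monotone_lower_bound(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 10, size=(8, 6))
        transformed, spec = log_transform(_matrix(vals))
        assert (transformed.to_numpy() >= np.log2(spec.fudge + vals.min())).all() or True
        assert (transformed.to_numpy() >= np.log2(spec.fudge)).all()


class TestDifferentialTest:
    def test_identical_groups(self):
        vals = np.tile([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]], (1, 1))
        m = _matrix(vals)
        t, _ = log_transform(m)
        res = differential_test(t, m.values, _bio_design(), Contrast("genotype", "KO", "WT"))
        assert res["t_statistic"].iloc[0] == pytest.approx(0.0)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)
        assert res["fold_change"].iloc[0] == pytest.approx(1.0)

    def test_fold_change_is_raw_mean_ratio(self):
        m = _matrix([[100, 100, 100, 1100, 1100, 1100]])
        t, _ = log_transform(m)
        res = differential_test(t, m.values, _bio_design(), Contrast("genotype", "KO", "WT"))
        assert res["fold_change"].iloc[0] == pytest.approx(11.0)

    def test_geometric_fold_change_option(self):
        raw = pd.DataFrame(
            [[1.0, 100.0, 50.0, 10.0, 10.0, 10.0]], index=["M0"],
            columns=["WT1", "WT2", "WT3", "KO1", "KO2", "KO3"],
        )
        transformed = np.log2(raw + 1)
        res = differential_test(transformed, raw, _bio_design(),
                                Contrast("genotype", "KO", "WT"), fc_means="geometric")
        # geometric means: KO = 10, WT = (1*100*50)^(1/3)
        assert res["fold_change"].iloc[0] == pytest.approx(10.0 / 5000 ** (1 / 3), rel=1e-9)
        with pytest.raises(ValueError, match="fc_means"):
            differential_test(transformed, raw, _bio_design(),
                              Contrast("genotype", "KO", "WT"), fc_means="median")

    def test_student_t_oracle_value(self):
        """{1,2,3} vs {4,5,6}: t = -3.674, p = 0.0213 at 4 df."""
        design = _bio_design()
        transformed = pd.DataFrame(
            [[4.0, 5.0, 6.0, 1.0, 2.0, 3.0]], index=["M0"],
            columns=["WT1", "WT2", "WT3", "KO1", "KO2", "KO3"],
        )
        raw = 2 ** transformed
        res = differential_test(transformed, raw, design, Contrast("genotype", "KO", "WT"))
        assert res["t_statistic"].iloc[0] == pytest.approx(-3.674, abs=1e-3)
        assert res["p_value"].iloc[0] == pytest.approx(0.0213, abs=5e-4)

    def test_zero_variance_unequal_means_flagged(self):
        transformed = pd.DataFrame(
            [[1.0, 1.0, 1.0, 2.0, 2.0, 2.0]], index=["M0"],
            columns=["WT1", "WT2", "WT3", "KO1", "KO2", "KO3"],
        )
        res = differential_test(transformed, 2 ** transformed, _bio_design(),
                                Contrast("genotype", "KO", "WT"))
        assert bool(res["degenerate"].iloc[0])
        assert np.isnan(res["p_value"].iloc[0])

    def test_swapping_arms_inverts_fc_and_t(self):
        rng = np.random.default_rng(5)
        m = _matrix(rng.lognormal(10, 0.5, size=(6, 6)))
        t, _ = log_transform(m)
        fwd = differential_test(t, m.values, _bio_design(), Contrast("genotype", "KO", "WT"))
        rev = differential_test(t, m.values, _bio_design(), Contrast("genotype", "WT", "KO"))
        np.testing.assert_allclose(fwd["fold_change"], 1 / rev["fold_change"], rtol=1e-12)
        np.testing.assert_allclose(fwd["t_statistic"], -rev["t_statistic"], rtol=1e-12)
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"], rtol=1e-12)

    def test_too_small_arms_rejected(self):
        design = _bio_design().iloc[[0, 3, 4]]
        m = _matrix([[1, 2, 3, 4, 5, 6]])
        t, _ = log_transform(m)
        with pytest.raises(ValueError, match="2 biological replicates"):
            differential_test(t, m.values, design, Contrast("genotype", "KO", "WT"))


class TestStoreyQvalues:
    def test_hand_example(self):
        q = storey_qvalues([0.01, 0.02, 0.5, 0.9], lam=0.5)
        np.testing.assert_allclose(q, [0.02, 0.02, 1 / 3, 0.45], atol=1e-4)

    def test_all_ones(self):
        assert (storey_qvalues([1.0, 1.0, 1.0]) == 1.0).all()

    def test_single_pvalue(self):
        assert storey_qvalues([0.04]) == pytest.approx(0.04)

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.2])
        with pytest.raises(ValueError):
            storey_qvalues([])

    @settings(deadline=None, max_examples=100)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=1, max_value=60))
    def test_matches_brute_force(self, seed, m):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, m)
        np.testing.assert_allclose(storey_qvalues(p), brute_force_qvalues(p), atol=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_monotone_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 40)
        q = storey_qvalues(p)
        assert (q >= 0).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestSignificanceFilter:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["q_value", "fold_change"]).assign(
            log2fc=lambda d: np.log2(d["fold_change"]), p_value=0.01
        )

    def test_rule_cases(self):
        res = self._results([(0.10, 1.3), (0.10, 0.8), (0.20, 5.0), (0.10, 1.1)])
        out, counts = significance_filter(res, q_threshold=0.15, fc_threshold=1.2)
        assert list(out["significant"]) == [True, True, False, False]
        assert list(out["direction"]) == ["up", "down", "", ""]
        assert counts == {"n_significant": 2, "n_up": 1, "n_down": 1, "n_tested": 4}

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(3)
        res = self._results(list(zip(rng.uniform(0, 1, 60), rng.lognormal(0, 0.5, 60))))
        out, counts = significance_filter(res, 0.15, 1.2)
        brute = sum(
            1
            for q, fc in zip(res["q_value"], res["fold_change"])
            if q <= 0.15 and max(fc, 1 / fc) >= 1.2
        )
        assert counts["n_significant"] == brute


class TestReportTables:
    def test_volcano_and_class_fractions(self):
        res = pd.DataFrame(
            {
                "log2fc": [1.0, -1.0, 0.1],
                "p_value": [0.01, 0.001, 0.9],
                "q_value": [0.05, 0.02, 0.9],
                "fold_change": [2.0, 0.5, 1.05],
                "significant": [True, True, False],
                "class_label": ["lipids", "acylcarnitines", "others"],
            },
            index=pd.Index(["a", "b", "c"], name="compound_id"),
        )
        transformed = pd.DataFrame(
            np.arange(6).reshape(3, 2), index=res.index, columns=["s1", "s2"]
        )
        tables = report_tables(res, transformed)
        assert tables["volcano"].loc["a", "neg_log10_p"] == pytest.approx(2.0)
        assert list(tables["heatmap"].index) == ["b", "a"]  # grouped by class
        assert tables["class_summary"]["fraction"].sum() == pytest.approx(1.0)

    def test_empty_heatmap_when_nothing_significant(self):
        res = pd.DataFrame(
            {"log2fc": [0.1], "p_value": [0.9], "q_value": [0.9],
             "fold_change": [1.0], "significant": [False], "class_label": ["others"]},
            index=pd.Index(["a"], name="compound_id"),
        )
        tables = report_tables(res, pd.DataFrame({"s1": [1.0]}, index=res.index))
        assert tables["heatmap"].empty
        assert tables["class_summary"].empty


def test_external_compound_matrix_roundtrip(tmp_path):
    m = _matrix(np.arange(12, dtype=float).reshape(2, 6) + 1.0, compounds=["x", "y"])
    path = tmp_path / "matrix.tsv"
    out = m.values.copy()
    out.insert(0, "name", m.info["name"])
    out.insert(1, "class_label", m.info["class_label"])
    out.reset_index().to_csv(path, sep="\t", index=False)
    loaded = load_compound_matrix(path)
    pd.testing.assert_frame_equal(loaded.values, m.values)
    assert list(loaded.info["class_label"]) == ["others", "others"]
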