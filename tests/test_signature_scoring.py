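import numpy as np
import pandas as pd
import pytest

from neofunnel import (
    GeneSet,
    NeofunnelError,
    RecordValidationError,
    SurvivalRecord,
    cd4_expression,
    cd8_infiltration_score,
    km_logrank,
    median_stratify,
    spearman,
    ssgsea_score,
    top_marker_gene_set,
)
from neofunnel.signature_scoring import read_gmt, scores_to_series, write_gmt


def matrix_from(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


# ---------------------------------------------------------------------------
# ssGSEA oracle: naive loop, written directly from the running-sum definition
# ---------------------------------------------------------------------------


def ssgsea_oracle(values, genes, set_genes, alpha=0.25):
    order = sorted(range(len(genes)), key=lambda i: (-values[i], i))
    # average ranks, ascending
    asc = sorted(range(len(genes)), key=lambda i: values[i])
    ranks = [0.0] * len(genes)
    i = 0
    while i < len(asc):
        j = i
        while j + 1 < len(asc) and values[asc[j + 1]] == values[asc[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[asc[k]] = avg
        i = j + 1
    in_set = [genes[i] in set_genes for i in range(len(genes))]
    total_w = sum(ranks[i] ** alpha for i in range(len(genes)) if in_set[i])
    n_out = sum(not f for f in in_set)
    es, cum_in, cum_out = 0.0, 0.0, 0.0
    for i in order:
        if in_set[i]:
            cum_in += ranks[i] ** alpha / total_w
        else:
            cum_out += 1.0 / n_out
        es += cum_in - cum_out
    return es


class TestSsgsea:
    def test_matches_direct_oracle_single_sample(self):
        rng = np.random.default_rng(42)
        values = rng.lognormal(1, 1, size=10)
        genes = [f"G{i}" for i in range(10)]
        mat = matrix_from(values.reshape(-1, 1), genes=genes)
        gene_set = GeneSet("s", ("G2", "G5", "G7"))
        (score,) = ssgsea_score(mat, gene_set)
        expected = ssgsea_oracle(values.tolist(), genes, {"G2", "G5", "G7"})
        assert score.score == pytest.approx(expected, rel=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        mat = matrix_from(rng.lognormal(1, 1, size=(20, 5)))
        gene_set = GeneSet("s", ("G1", "G4", "G9"))
        base = [s.score for s in ssgsea_score(mat, gene_set)]
        transformed = [s.score for s in ssgsea_score(np.log1p(mat) * 7 + 3, gene_set)]
        assert transformed == pytest.approx(base)

    def test_gene_row_permutation_invariance(self):
        rng = np.random.default_rng(2)
        mat = matrix_from(rng.lognormal(1, 1, size=(15, 4)))
        gene_set = GeneSet("s", ("G0", "G7"))
        base = [s.score for s in ssgsea_score(mat, gene_set)]
        shuffled = mat.sample(frac=1.0, random_state=3)
        assert [s.score for s in ssgsea_score(shuffled, gene_set)] == pytest.approx(base)

    def test_top_gene_scores_above_bottom_gene(self):
        mat = matrix_from([[10.0], [5.0], [2.0], [1.0]])
        top = ssgsea_score(mat, GeneSet("top", ("G0",)))[0].score
        bottom = ssgsea_score(mat, GeneSet("bottom", ("G3",)))[0].score
        assert top > bottom

    def test_absent_set_is_an_error(self):
        mat = matrix_from([[1.0], [2.0]])
        with pytest.raises(RecordValidationError):
            ssgsea_score(mat, GeneSet("s", ("NOPE",)))

    def test_normalize_maps_to_unit_interval(self):
        rng = np.random.default_rng(4)
        mat = matrix_from(rng.lognormal(1, 1, size=(12, 6)))
        scores = [s.score for s in ssgsea_score(mat, GeneSet("s", ("G1", "G2")), normalize=True)]
        assert min(scores) == 0.0 and max(scores) == 1.0


class TestImmuneScores:
    def test_cd8_score_per_sample(self):
        rng = np.random.default_rng(5)
        mat = matrix_from(
            rng.lognormal(1, 1, size=(10, 7)),
            genes=["CD8A", "CD8B"] + [f"G{i}" for i in range(8)],
        )
        scores = cd8_infiltration_score(mat)
        assert [s.sample for s in scores] == list(mat.columns)
        assert all(s.set_name == "CD8_T" for s in scores)

    def test_cd8_ranks_drive_the_score(self):
        # both signature genes at the top vs at the bottom, same gene universe
        high = [100.0, 90.0, 5.0, 4.0, 3.0, 2.0]
        low = [1.0, 0.5, 5.0, 4.0, 3.0, 2.0]
        mat = matrix_from(
            np.column_stack([high, low]),
            genes=["CD8A", "CD8B", "G0", "G1", "G2", "G3"],
        )
        scores = scores_to_series(cd8_infiltration_score(mat))
        assert scores.iloc[0] > scores.iloc[1]

    def test_cd8_error_when_both_genes_absent(self):
        with pytest.raises(RecordValidationError):
            cd8_infiltration_score(matrix_from([[1.0], [2.0]]))

    def test_cd4_proxy_is_raw_expression(self):
        mat = matrix_from([[3.0, 9.0], [1.0, 2.0]], genes=["CD4", "G0"])
        assert cd4_expression(mat).tolist() == [3.0, 9.0]


class TestTopMarkers:
    def markers(self, n, cluster="apCAF"):
        rng = np.random.default_rng(6)
        return pd.DataFrame(
            {
                "gene": [f"M{i:02d}" for i in range(n)],
                "cluster": cluster,
                "fold_change": rng.uniform(1, 10, size=n).round(3),
            }
        )

    def test_top_20_of_30_by_fold_change(self):
        table = self.markers(30)
        gene_set = top_marker_gene_set(table, "apCAF")
        assert len(gene_set.genes) == 20
        expected = set(table.nlargest(20, "fold_change")["gene"])
        assert set(gene_set.genes) == expected

    def test_exactly_20_rows_all_kept(self):
        gene_set = top_marker_gene_set(self.markers(20), "apCAF")
        assert len(gene_set.genes) == 20

    def test_tie_at_cutoff_breaks_alphabetically(self):
        table = pd.DataFrame(
            {
                "gene": ["B", "A", "C"],
                "cluster": "c",
                "fold_change": [5.0, 2.0, 2.0],
            }
        )
        gene_set = top_marker_gene_set(table, "c", n=2)
        assert gene_set.genes == ("B", "A")

    def test_fewer_rows_than_requested_warns_and_returns_all(self, caplog):
        gene_set = top_marker_gene_set(self.markers(5), "apCAF")
        assert len(gene_set.genes) == 5

    def test_gmt_round_trip(self, tmp_path):
        sets = [GeneSet("a", ("G1", "G2")), GeneSet("b", ("G3",))]
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        assert read_gmt(path) == sets


class TestSpearman:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [6, 4, 2], -1.0),
            ([1, 2, 3], [1, 1, 2], 0.8660254),  # average-rank tie handling
        ],
    )
    def test_known_values(self, x, y, expected):
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(expected, abs=1e-6)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert spearman(x, y) == spearman(y, x)
        assert abs(spearman(x, y)[0]) <= 1.0

    def test_constant_vector_is_an_error(self):
        with pytest.raises(NeofunnelError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMedianStratify:
    def test_even_count_splits_in_half(self):
        high, low = median_stratify({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        assert set(low) == {"a", "b"} and set(high) == {"c", "d"}

    def test_odd_count_median_goes_low(self):
        high, low = median_stratify({"a": 1.0, "b": 2.0, "c": 3.0})
        assert set(low) == {"a", "b"} and set(high) == {"c"}

    def test_constant_scores_degenerate(self):
        with pytest.raises(NeofunnelError):
            median_stratify({"a": 1.0, "b": 1.0})


# ---------------------------------------------------------------------------
# Log-rank oracle: direct evaluation of the pooled risk tables
# ---------------------------------------------------------------------------


def logrank_oracle(times_a, times_b):
    """All-events two-group log-rank chi-square, from first principles."""
    event_times = sorted(set(times_a) | set(times_b))
    o_minus_e, var = 0.0, 0.0
    for t in event_times:
        n_a = sum(1 for x in times_a if x >= t)
        n_b = sum(1 for x in times_b if x >= t)
        d_a = times_a.count(t)
        d_b = times_b.count(t)
        n, d = n_a + n_b, d_a + d_b
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def records(times, events, prefix):
    return [
        SurvivalRecord(f"{prefix}{i}", t, bool(e))
        for i, (t, e) in enumerate(zip(times, events))
    ]


class TestKmLogrank:
    def test_identical_groups_give_null_statistic(self):
        recs = records([1, 2, 3, 4], [1, 1, 1, 1], "a") + records(
            [1, 2, 3, 4], [1, 1, 1, 1], "b"
        )
        groups = ([r.sample for r in recs[:4]], [r.sample for r in recs[4:]])
        _, chi2, p = km_logrank(groups, recs)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_risk_table_oracle(self):
        times_a, times_b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        recs = records(times_a, [1] * 3, "a") + records(times_b, [1] * 3, "b")
        groups = (["a0", "a1", "a2"], ["b0", "b1", "b2"])
        _, chi2, _ = km_logrank(groups, recs)
        assert chi2 == pytest.approx(logrank_oracle(times_a, times_b), rel=1e-9)

    def test_km_first_step_is_n_minus_1_over_n(self):
        recs = records([1.0, 2.0, 3.0, 4.0, 5.0], [1] * 5, "a") + records(
            [9.0], [1], "b"
        )
        groups = (["a0", "a1", "a2", "a3", "a4"], ["b0"])
        curves, _, _ = km_logrank(groups, recs)
        high = curves["high"]
        assert high.loc[high["time"] == 1.0, "survival"].item() == pytest.approx(4 / 5)

    def test_no_censoring_km_equals_empirical_survival(self):
        rng = np.random.default_rng(8)
        times = np.round(rng.exponential(10, size=20), 3).tolist()
        recs = records(times, [1] * 20, "a") + records([1.0], [1], "b")
        groups = ([f"a{i}" for i in range(20)], ["b0"])
        curves, _, _ = km_logrank(groups, recs)
        curve = curves["high"]
        for t, s in zip(curve["time"], curve["survival"]):
            if t == 0:
                continue
            empirical = sum(1 for x in times if x > t) / len(times)
            assert s == pytest.approx(empirical, abs=1e-12)

    def test_km_curve_starts_at_one_and_never_increases(self):
        groups, recs = (["a0", "a1", "a2"], ["b0", "b1"]), records(
            [2.0, 5.0, 7.0], [1, 0, 1], "a"
        ) + records([3.0, 6.0], [1, 1], "b")
        curves, _, _ = km_logrank(groups, recs)
        for curve in curves.values():
            s = curve["survival"].to_numpy()
            assert s[0] == 1.0
            assert np.all(np.diff(s) <= 1e-12)

    def test_empty_group_rejected(self):
        recs = records([1.0], [1], "a")
        with pytest.raises(NeofunnelError):
            km_logrank((["a0"], []), recs)
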