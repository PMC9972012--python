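import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sting_sclc import (
    ExpressionMatrix,
    GeneSetCollection,
    NEReference,
    correlate_scores,
    ihc_score,
    ne_score,
    read_ne_reference,
    score_panel,
    ssgsea_score,
    write_ne_reference,
)
from sting_sclc.scoring import ScoringError


def ssgsea_oracle(expr: np.ndarray, in_set: np.ndarray, tau: float) -> float:
    """Independent rank-by-rank running-sum enumeration of the ssGSEA area."""
    n = len(expr)
    # descending expression; ties broken by descending input position
    order = sorted(range(n), key=lambda i: (-expr[i], -i))
    in_ranked = [bool(in_set[i]) for i in order]
    rank_val = list(range(n, 0, -1))
    denom = sum(rank_val[j] ** tau for j in range(n) if in_ranked[j])
    n_out = n - sum(in_ranked)
    total, cum_in, cum_out = 0.0, 0.0, 0.0
    for j in range(n):
        if in_ranked[j]:
            cum_in += rank_val[j] ** tau / denom
        else:
            cum_out += 1.0 / n_out
        total += cum_in - cum_out
    return total


def _matrix(rng, n_genes, n_samples):
    df = pd.DataFrame(
        rng.gamma(2.0, 2.0, size=(n_genes, n_samples)),
        index=[f"G{i:02d}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return ExpressionMatrix(df, "linear")


class TestSsgsea:
    def test_top_genes_score_positive_and_matches_oracle(self):
        rng = np.random.default_rng(1)
        m = _matrix(rng, 8, 1)
        top3 = m.values["s0"].nlargest(3).index.tolist()
        gs = GeneSetCollection({"TOP": top3})
        score = ssgsea_score(m, "TOP", gs, normalize=False).values.iloc[0, 0]
        in_set = m.values.index.isin(top3)
        expected = ssgsea_oracle(m.values["s0"].to_numpy(), in_set, 0.25)
        assert score == pytest.approx(expected, abs=1e-12)
        assert score > 0

    def test_tau_zero_single_top_gene_is_unweighted_ks(self):
        # one set gene at the top rank, tau=0: oracle equals the direct
        # enumeration of the unweighted running sum
        expr = np.array([10.0, 8.0, 6.0, 4.0, 2.0, 1.0])
        in_set = np.array([True, False, False, False, False, False])
        df = pd.DataFrame({"s0": expr}, index=[f"G{i}" for i in range(6)])
        m = ExpressionMatrix(df, "linear")
        gs = GeneSetCollection({"ONE": ["G0"]})
        got = ssgsea_score(m, "ONE", gs, tau=0.0, normalize=False).values.iloc[0, 0]
        assert got == pytest.approx(ssgsea_oracle(expr, in_set, 0.0), abs=1e-12)
        # hit at rank 1: running sum is 1 - i/5 at position i -> area = 6 - 15/5
        assert got == pytest.approx(sum(1 - i / 5 for i in range(6)), abs=1e-12)

    @pytest.mark.parametrize("n_genes", range(3, 11))
    @pytest.mark.parametrize("n_samples", [1, 2, 3])
    def test_oracle_agreement_exhaustive_sizes(self, n_genes, n_samples):
        rng = np.random.default_rng(n_genes * 10 + n_samples)
        m = _matrix(rng, n_genes, n_samples)
        for set_size in range(1, n_genes):
            members = list(m.values.index[:set_size])
            gs = GeneSetCollection({"S": members})
            got = ssgsea_score(m, "S", gs, normalize=False).values["S"]
            in_set = m.values.index.isin(members)
            for j, s in enumerate(m.values.columns):
                exp = ssgsea_oracle(m.values[s].to_numpy(), in_set, 0.25)
                assert got[s] == pytest.approx(exp, abs=1e-10)

    def test_identical_samples_get_identical_scores(self):
        df = pd.DataFrame({"a": [5.0, 3, 1, 8], "b": [5.0, 3, 1, 8]},
                          index=["G0", "G1", "G2", "G3"])
        m = ExpressionMatrix(df, "linear")
        gs = GeneSetCollection({"S": ["G0", "G3"]})
        vals = ssgsea_score(m, "S", gs, normalize=False).values["S"]
        assert vals["a"] == vals["b"]

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng, 30, 4)
        gs = GeneSetCollection({"S": list(m.values.index[5:12])})
        base = ssgsea_score(m, "S", gs, normalize=False).values["S"]
        squashed = ExpressionMatrix(np.log1p(m.values * 7.0), "linear")
        got = ssgsea_score(squashed, "S", gs, normalize=False).values["S"]
        np.testing.assert_allclose(base.to_numpy(), got.to_numpy(), atol=1e-12)

    def test_no_overlap_is_an_error(self, tiny_matrix):
        gs = GeneSetCollection({"S": ["NOPE"]})
        with pytest.raises(ScoringError):
            ssgsea_score(tiny_matrix, "S", gs)

    def test_single_sample_normalization_refused(self):
        rng = np.random.default_rng(4)
        m = _matrix(rng, 6, 1)
        gs = GeneSetCollection({"S": list(m.values.index[:2])})
        with pytest.raises(ScoringError):
            ssgsea_score(m, "S", gs, normalize=True)


class TestNeScore:
    def test_formula_arithmetic(self, toy_reference):
        # engineered correlations: exact formula check via the definition
        sample = pd.Series(toy_reference.ne_profile, index=toy_reference.gene_ids)
        score = ne_score(sample, toy_reference)
        r_ne = np.corrcoef(sample, toy_reference.ne_profile)[0, 1]
        r_non = np.corrcoef(sample, toy_reference.nonne_profile)[0, 1]
        assert score == pytest.approx((r_ne - r_non) / 2, abs=1e-12)
        assert r_ne == pytest.approx(1.0)
        assert score > 0  # sample equal to the NE profile scores NE-positive

    def test_antisymmetric_under_profile_swap(self, toy_reference):
        rng = np.random.default_rng(5)
        sample = pd.Series(rng.normal(5, 2, 12), index=toy_reference.gene_ids)
        assert ne_score(sample, toy_reference) == pytest.approx(
            -ne_score(sample, toy_reference.swapped()), abs=1e-12
        )

    def test_bounds_over_random_profiles(self, toy_reference):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            sample = pd.Series(rng.normal(0, 1, 12), index=toy_reference.gene_ids)
            assert -1.0 <= ne_score(sample, toy_reference) <= 1.0

    def test_min_overlap_enforced(self, toy_reference):
        sample = pd.Series([1.0, 2.0], index=toy_reference.gene_ids[:2])
        with pytest.raises(ScoringError, match="shared"):
            ne_score(sample, toy_reference)

    def test_constant_sample_rejected(self, toy_reference):
        sample = pd.Series(np.ones(12), index=toy_reference.gene_ids)
        with pytest.raises(ScoringError, match="variance"):
            ne_score(sample, toy_reference)


class TestScorePanel:
    def test_shape_and_tags(self, toy_reference):
        rng = np.random.default_rng(8)
        genes = [f"G{i:02d}" for i in range(20)] + toy_reference.gene_ids
        df = pd.DataFrame(rng.gamma(2, 2, size=(32, 5)), index=genes,
                          columns=[f"s{j}" for j in range(5)])
        m = ExpressionMatrix(df, "linear")
        gs = GeneSetCollection({"A": genes[:5], "B": genes[5:11]})
        t = score_panel(m, gs, ["A", "B"], ref=toy_reference)
        assert t.values.shape == (5, 3)
        assert t.method_tags == {"A": "ssgsea", "B": "ssgsea", "NE": "ne_correlation"}

    def test_sample_permutation_permutes_rows_only(self, toy_reference):
        rng = np.random.default_rng(9)
        genes = [f"G{i:02d}" for i in range(20)] + toy_reference.gene_ids
        df = pd.DataFrame(rng.gamma(2, 2, size=(32, 5)), index=genes,
                          columns=[f"s{j}" for j in range(5)])
        m = ExpressionMatrix(df, "linear")
        perm = ExpressionMatrix(df[["s3", "s0", "s4", "s1", "s2"]], "linear")
        gs = GeneSetCollection({"A": genes[:5]})
        t1 = score_panel(m, gs, ["A"], ref=toy_reference).values
        t2 = score_panel(perm, gs, ["A"], ref=toy_reference).values
        pd.testing.assert_frame_equal(t1.sort_index(), t2.sort_index())

    def test_planted_immune_subtype_scores_higher(self, default_cohort):
        cfg, m, labels, gs, ref = default_cohort
        t = score_panel(m, gs, ["IMMUNE_SIM_01", "IMMUNE_SIM_02"], ref=None)
        by = t.values.groupby(labels).mean()
        for col in ["IMMUNE_SIM_01", "IMMUNE_SIM_02"]:
            assert by.loc["STING-high", col] > by.loc["STING-low", col]


class TestCorrelateScores:
    def test_perfect_linear(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r, p = correlate_scores(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = correlate_scores(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        x = np.array([1.0, 4, 2, 8, 5, 7])
        y = np.array([2.0, 3, 1, 9, 4, 6])
        r, p = correlate_scores(x, y)
        brute = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(brute, abs=1e-12)
        assert 0 < p <= 1

    def test_constant_vector_rejected(self):
        with pytest.raises(ScoringError):
            correlate_scores([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestIhcScore:
    @pytest.mark.parametrize("i,e,expected", [(3, 4, 12), (0, 4, 0), (0, 0, 0), (2, 3, 6)])
    def test_products(self, i, e, expected):
        assert ihc_score(i, e) == expected

    @given(st.integers(0, 3), st.integers(0, 3), st.integers(0, 4), st.integers(0, 4))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_each_argument(self, i1, i2, e1, e2):
        if i1 <= i2 and e1 <= e2:
            assert ihc_score(i1, e1) <= ihc_score(i2, e2)

    @pytest.mark.parametrize("i,e", [(4, 2), (-1, 0), (1, 5)])
    def test_out_of_range_rejected(self, i, e):
        with pytest.raises(ValueError):
            ihc_score(i, e)


def test_ne_reference_roundtrip(tmp_path, toy_reference):
    p = tmp_path / "ref.tsv"
    write_ne_reference(toy_reference, p)
    back = read_ne_reference(p)
    assert back.gene_ids == toy_reference.gene_ids
    np.testing.assert_allclose(back.ne_profile, toy_reference.ne_profile)
    np.testing.assert_allclose(back.nonne_profile, toy_reference.nonne_profile)
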