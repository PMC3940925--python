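"""Coexpression scoring: marginals, Z, pair scores, selection and Fisher filters.

The manual-arithmetic oracle writes the specificity algebra out longhand on
a 3-entity × 2-tissue toy matrix, independent of the package's vectorized
path.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from paralomir import coexpression as cx
from paralomir.families import ParalogFamily


def _inputs(counts: pd.DataFrame, min_reads=0):
    return cx.build_inputs(counts, counts.iloc[0:0], counts, min_reads=min_reads)


class TestBuildInputs:
    def test_q_is_per_tissue_read_fraction(self):
        m = pd.DataFrame([[100.0, 300.0]], index=["a"], columns=["t1", "t2"])
        inputs = _inputs(m)
        assert inputs.Q.tolist() == [0.25, 0.75]

    def test_single_tissue_q_is_one(self):
        m = pd.DataFrame([[10.0]], index=["a"], columns=["t1"])
        assert _inputs(m).Q.tolist() == [1.0]

    def test_reads_filter_is_strictly_greater(self):
        m = pd.DataFrame([[50.0], [51.0]], index=["a", "b"], columns=["t1"])
        inputs = _inputs(m, min_reads=50)
        assert list(inputs.kept) == ["b"]

    def test_t_equals_row_sums(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.integers(0, 500, size=(8, 5)).astype(float),
                         index=[f"g{i}" for i in range(8)],
                         columns=[f"t{j}" for j in range(5)])
        inputs = _inputs(m)
        brute = {g: sum(m.loc[g]) for g in m.index}
        assert {g: inputs.T[g] for g in m.index} == brute
        assert abs(inputs.Q.sum() - 1.0) < 1e-9

    def test_tissue_mismatch_raises(self):
        a = pd.DataFrame([[1.0]], index=["a"], columns=["t1"])
        b = pd.DataFrame([[1.0]], index=["b"], columns=["t2"])
        with pytest.raises(ValueError, match="tissues"):
            cx.build_inputs(a, b, a)


class TestSpecificityZ:
    def test_zero_reads_gives_zero_z(self, toy_counts):
        toy = toy_counts.copy()
        toy.loc["e1", "t1"] = 0.0
        inputs = _inputs(toy)
        assert cx.specificity_z(inputs, "e1", "t1") == 0.0

    def test_manual_arithmetic_oracle(self, toy_counts):
        """Longhand evaluation of the enrichment z on the toy matrix."""
        inputs = _inputs(toy_counts)
        # tissue totals (100, 60), grand 160 -> Q = (0.625, 0.375)
        q1 = 100.0 / 160.0
        t_e1, t_e2 = 60.0, 45.0
        z_e1_t1 = (50.0 - t_e1 * q1) / math.sqrt(t_e1 * q1 * (1 - q1))
        z_e2_t1 = (40.0 - t_e2 * q1) / math.sqrt(t_e2 * q1 * (1 - q1))
        assert cx.specificity_z(inputs, "e1", "t1") == pytest.approx(z_e1_t1, rel=1e-12)
        assert cx.specificity_z(inputs, "e2", "t1") == pytest.approx(z_e2_t1, rel=1e-12)
        # below-expectation cells truncate to zero
        assert cx.specificity_z(inputs, "e1", "t2") == 0.0

    def test_unknown_entity_raises(self, toy_counts):
        with pytest.raises(KeyError):
            cx.specificity_z(_inputs(toy_counts), "nope", "t1")


class TestCoexpressionScore:
    def test_zero_minor_reads_give_zero_scores_everywhere(self, toy_counts):
        toy = toy_counts.copy()
        toy.loc["e2"] = 0.0
        inputs = _inputs(toy)
        scores = cx.coexpression_score(inputs, "e1", "e2")
        assert (scores == 0.0).all()

    def test_manual_arithmetic_oracle(self, toy_counts):
        inputs = _inputs(toy_counts)
        q1 = 0.625
        z_e1 = (50.0 - 60.0 * q1) / math.sqrt(60.0 * q1 * (1 - q1))
        z_e2 = (40.0 - 45.0 * q1) / math.sqrt(45.0 * q1 * (1 - q1))
        assert cx.coexpression_score(inputs, "e1", "e2", "t1") == pytest.approx(
            z_e1 * z_e2, rel=1e-12
        )
        # e1 and e2 are both depleted in t2, so the pair scores 0 there
        assert cx.coexpression_score(inputs, "e1", "e2", "t2") == 0.0

    @given(seed=st.integers(0, 200))
    def test_permutation_equivariance(self, seed):
        """Permuting tissue columns permutes Z and scores identically."""
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.integers(0, 300, size=(4, 5)).astype(float),
                         index=list("abcd"), columns=[f"t{j}" for j in range(5)])
        if m.to_numpy().sum() == 0:
            return
        perm = rng.permutation(5)
        permuted = m.iloc[:, perm]
        s1 = cx.coexpression_score(_inputs(m), "a", "b")
        s2 = cx.coexpression_score(_inputs(permuted), "a", "b")
        assert np.allclose(s1.iloc[perm].to_numpy(), s2.to_numpy())


class TestSelectTopDecile:
    def test_ten_distinct_scores_flag_one(self):
        s = pd.Series(np.arange(1.0, 11.0))
        sel = cx.select_top_decile(s)
        assert sel["selected"].sum() == 1
        assert sel.loc[s.idxmax(), "selected"]

    def test_ties_at_cutoff_all_included(self):
        s = pd.Series([100.0, 50.0, 50.0] + list(np.arange(1.0, 18.0)))
        sel = cx.select_top_decile(s)
        assert sel["selected"].sum() == 3

    def test_zero_scores_never_selected(self):
        s = pd.Series([0.0] * 9 + [5.0])
        sel = cx.select_top_decile(s)
        assert sel["selected"].sum() == 1

    def test_matches_sorting_oracle_on_random_vectors(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            n = int(rng.integers(1, 60))
            vals = rng.choice([0.0, 1.0, 2.5, 7.0, 7.0, 11.0, 42.0], size=n)
            s = pd.Series(vals)
            sel = cx.select_top_decile(s)
            k = max(1, math.ceil(0.1 * n))
            cutoff = np.sort(vals)[::-1][k - 1]
            expected = (vals >= cutoff) & (vals > 0)
            assert (sel["selected"].to_numpy() == expected).all()


class TestFisher:
    def test_balanced_table_has_p_one(self):
        assert cx.fisher_exact_p(5, 5, 5, 5) == pytest.approx(1.0)

    def test_diagonal_table_matches_enumeration(self):
        # support is a in {0..10}; only a=10 and a=0 are as unlikely as observed
        assert cx.fisher_exact_p(10, 0, 0, 10) == pytest.approx(2.0 / 184756.0, rel=1e-12)

    def test_all_zero_table_is_degenerate_p_one(self):
        assert cx.fisher_exact_p(0, 0, 0, 0) == 1.0
        assert cx.fisher_exact_batch(np.array([[0, 0, 0, 0]]))[0] == 1.0

    def test_batch_agrees_with_scalar(self):
        rng = np.random.default_rng(3)
        tabs = rng.integers(0, 30, size=(50, 4))
        batch = cx.fisher_exact_batch(tabs)
        scalar = [cx.fisher_exact_p(*t) for t in tabs]
        assert np.allclose(batch, scalar, rtol=1e-12)

    def test_minor_filter_passes_planted_tissue(self):
        tissues = [f"t{i}" for i in range(5)]
        counts = pd.DataFrame(
            {
                "minorA": [100, 0, 0, 0, 0],
                "minorB": [0, 100, 0, 0, 0],
            },
            index=tissues,
        ).T.astype(float)
        inputs = cx.build_inputs(counts, counts.iloc[0:0], counts, min_reads=0)
        fam = ParalogFamily("fam", ["pA", "pB"], {"pA": "minorA", "pB": "minorB"})
        out = cx.fisher_minor_filter(fam, inputs, {"pA": "minorA", "pB": "minorB"})
        flags = out.set_index(["precursor_id", "tissue"])["fisher_pass"]
        assert flags[("pA", "t0")] and flags[("pB", "t1")]
        assert not flags[("pA", "t2")]


class TestDiscriminationReport:
    def _family_setup(self):
        tissues = [f"t{i}" for i in range(10)]
        rows = {
            "major": [3000, 3000] + [10] * 8,
            "minorA": [150, 0, 0, 0, 0, 0, 0, 0, 0, 0],
            "minorB": [0, 150, 0, 0, 0, 0, 0, 0, 0, 0],
        }
        background = {f"bg{i}": [500] * 10 for i in range(4)}
        counts = pd.DataFrame({**rows, **background}, index=tissues).T.astype(float)
        major = counts.loc[["major"]]
        minor = counts.loc[["minorA", "minorB"]]
        inputs = cx.build_inputs(major, minor, counts, min_reads=50)
        fam = ParalogFamily("major", ["pA", "pB"], {"pA": "minorA", "pB": "minorB"})
        return fam, inputs

    def test_member_passing_both_filters_is_called_contributor(self):
        fam, inputs = self._family_setup()
        report = cx.discrimination_report(
            [fam], inputs, {"major": "major"}, {"pA": "minorA", "pB": "minorB"}
        )
        calls = report.contributors().set_index("tissue")["precursor_id"]
        assert calls["t0"] == "pA"
        assert calls["t1"] == "pB"
        rows = report.rows.set_index(["precursor_id", "tissue"])
        assert rows.loc[("pA", "t0"), "score"] > rows.loc[("pB", "t0"), "score"]

    def test_indistinguishable_family_reported_unresolved(self):
        fam, inputs = self._family_setup()
        fam.indistinguishable = True
        report = cx.discrimination_report(
            [fam], inputs, {"major": "major"}, {"pA": "minorA", "pB": "minorB"}
        )
        assert not report.rows["contributor_call"].any()
        assert "indistinguishable" in report.unresolved.iloc[0]["reason"]

    def test_selected_top10_implies_high_rank(self):
        fam, inputs = self._family_setup()
        report = cx.discrimination_report(
            [fam], inputs, {"major": "major"}, {"pA": "minorA", "pB": "minorB"}
        )
        sel = report.rows[report.rows["selected_top10"]]
        assert len(sel) and (sel["rank_percentile"] <= 10 + 1e-9).all()
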