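"""Arm assignment, quantification, normalization and arm-usage ratios."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from paralomir import expression
from paralomir.io import PrecursorAnnotation, ReadMappingTable


def _table(rows, tissues=None):
    df = pd.DataFrame(rows, columns=["precursor_id", "start", "count", "tissue"])
    return ReadMappingTable(records=df, tissues=tissues or list(pd.unique(df["tissue"])))


def _ann(pid="mir-a", length=70):
    return PrecursorAnnotation(pid, "A" * length, mature_records=[])


class TestAssignArms:
    def test_argmax_defines_major_and_opposite_arm_minor(self):
        reads = _table(
            [("mir-a", 5, 100, "liver"), ("mir-a", 6, 3, "liver"), ("mir-a", 48, 10, "liver")]
        )
        prof, = expression.assign_arms(reads, [_ann()])
        assert (prof.major_position, prof.major_arm) == (5, "5p")
        assert (prof.minor_position, prof.minor_arm) == (48, "3p")

    def test_single_arm_reads_flagged_with_zero_minor(self):
        reads = _table([("mir-a", 5, 100, "liver")])
        prof, = expression.assign_arms(reads, [_ann()])
        assert prof.minor_position is None
        assert prof.minor_total == 0
        assert "single_arm" in prof.flags

    def test_no_reads_flagged_all_zero(self):
        reads = _table([("mir-b", 5, 1, "liver")])
        profs = expression.assign_arms(reads, [_ann("mir-a"), _ann("mir-b")])
        by_id = {p.precursor_id: p for p in profs}
        assert "no_reads" in by_id["mir-a"].flags
        assert by_id["mir-a"].precursor_counts.sum() == 0

    def test_argmax_tie_resolves_to_five_prime_most(self):
        reads = _table([("mir-a", 7, 50, "liver"), ("mir-a", 5, 50, "liver")])
        prof, = expression.assign_arms(reads, [_ann()])
        assert prof.major_position == 5

    def test_planted_argmax_recovered_on_random_fixtures(self):
        """Brute-force argmax over all positions equals the assignment, 100 fixtures."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_starts = rng.integers(2, 8)
            starts = rng.choice(np.arange(1, 71), size=n_starts, replace=False)
            rows = []
            for s in starts:
                for t in ("t1", "t2"):
                    rows.append(("mir-a", int(s), int(rng.integers(0, 500)), t))
            reads = _table(rows, tissues=["t1", "t2"])
            prof, = expression.assign_arms(reads, [_ann()])
            totals = {}
            for pid, s, c, t in rows:
                totals[s] = totals.get(s, 0) + c
            best = min([s for s in totals if totals[s] == max(totals.values())])
            assert prof.major_position == best


class TestQuantify:
    def test_levels_sum_correctly(self):
        reads = _table(
            [("mir-a", 5, 100, "liver"), ("mir-a", 6, 3, "liver"), ("mir-a", 48, 10, "liver")]
        )
        profs = expression.assign_arms(reads, [_ann()])
        vals = {
            level: expression.quantify(reads, profs, level=level).values.iloc[0, 0]
            for level in ("precursor", "major", "minor")
        }
        assert vals == {"precursor": 113, "major": 100, "minor": 10}

    def test_identical_tissues_give_identical_columns(self):
        rows = [("mir-a", 5, 7, t) for t in ("t1", "t2")] + [("mir-a", 48, 3, t) for t in ("t1", "t2")]
        reads = _table(rows, tissues=["t1", "t2"])
        profs = expression.assign_arms(reads, [_ann()])
        m = expression.quantify(reads, profs, level="precursor").values
        assert (m["t1"] == m["t2"]).all()

    def test_unknown_level_rejected(self):
        reads = _table([("mir-a", 5, 1, "t1")])
        profs = expression.assign_arms(reads, [_ann()])
        with pytest.raises(ValueError, match="level"):
            expression.quantify(reads, profs, level="hairpin")


class TestNormalize:
    def test_rpm_definition(self):
        m = expression.ExpressionMatrix(pd.DataFrame({"t1": [50.0]}, index=["a"]))
        out = expression.normalize(m, {"t1": 1_000_000})
        assert out.values.iloc[0, 0] == 50.0
        assert out.scale == "rpm"

    def test_zero_total_with_reads_is_impossible_state(self):
        m = expression.ExpressionMatrix(pd.DataFrame({"t1": [5.0]}, index=["a"]))
        with pytest.raises(ValueError, match="zero library total"):
            expression.normalize(m, {"t1": 0})

    def test_zero_total_with_zero_counts_gives_zeros(self):
        m = expression.ExpressionMatrix(pd.DataFrame({"t1": [0.0]}, index=["a"]))
        out = expression.normalize(m, {"t1": 0})
        assert out.values.iloc[0, 0] == 0.0

    @given(k=st.floats(min_value=0.1, max_value=1000.0), seed=st.integers(0, 100))
    def test_scale_equivariance(self, k, seed):
        """Multiplying a tissue's counts and total by k leaves RPM unchanged."""
        rng = np.random.default_rng(seed)
        base = pd.DataFrame(rng.integers(0, 100, size=(4, 2)).astype(float),
                            index=list("abcd"), columns=["t1", "t2"])
        totals = {"t1": float(base["t1"].sum()), "t2": float(base["t2"].sum())}
        if totals["t1"] == 0 or totals["t2"] == 0:
            return
        out1 = expression.normalize(expression.ExpressionMatrix(base), totals)
        scaled = base.copy()
        scaled["t1"] *= k
        out2 = expression.normalize(
            expression.ExpressionMatrix(scaled), {"t1": totals["t1"] * k, "t2": totals["t2"]}
        )
        assert np.allclose(out1.values.to_numpy(), out2.values.to_numpy())

    def test_full_partition_columns_sum_to_scale(self):
        """When the matrix holds all reads, each RPM column sums to 1e6."""
        rng = np.random.default_rng(5)
        base = pd.DataFrame(rng.integers(1, 100, size=(6, 3)).astype(float),
                            index=[f"g{i}" for i in range(6)], columns=["t1", "t2", "t3"])
        out = expression.normalize(expression.ExpressionMatrix(base), base.sum(axis=0))
        assert np.allclose(out.values.sum(axis=0), 1e6, rtol=1e-6)


class TestArmRatios:
    def _profiles(self, major, minor, tissues=("t1", "t2")):
        zeros = pd.Series(0, index=list(tissues))
        return [
            expression.ArmProfile(
                "mir-a", 5, "5p", 48,
                major_counts=pd.Series(major, index=list(tissues)),
                minor_counts=pd.Series(minor, index=list(tissues)),
                precursor_counts=zeros,
            )
        ]

    def test_high_ratio_pair(self):
        table = expression.arm_ratios(self._profiles([200, 200], [1, 0]))
        assert table.iloc[0]["ratio"] == 400.0
        assert table.iloc[0]["ratio"] > 400 - 1  # lands in the top ratio bin

    def test_infinite_ratio_sentinel_when_minor_absent(self):
        table = expression.arm_ratios(self._profiles([100, 100], [0, 0]))
        assert math.isinf(table.iloc[0]["ratio"])

    def test_arm_switch_tissue_flagged(self):
        table = expression.arm_ratios(self._profiles([90, 10], [20, 30]))
        assert table.iloc[0]["ratio"] == 2.0
        assert table.iloc[0]["arm_switch_tissues"] == "t2"

    def test_min_total_filter_is_strict(self):
        assert len(expression.arm_ratios(self._profiles([25, 25], [1, 1]))) == 0
        assert len(expression.arm_ratios(self._profiles([26, 25], [1, 1]))) == 1

    def test_planted_switch_tissues_recovered(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            tissues = [f"t{i}" for i in range(6)]
            major = rng.integers(10, 100, size=6)
            minor = rng.integers(0, 150, size=6)
            profs = [
                expression.ArmProfile(
                    "mir-a", 5, "5p", 48,
                    major_counts=pd.Series(major, index=tissues),
                    minor_counts=pd.Series(minor, index=tissues),
                    precursor_counts=pd.Series(major + minor, index=tissues),
                )
            ]
            table = expression.arm_ratios(profs, min_total=0)
            expected = {t for t, mj, mi in zip(tissues, major, minor) if mi > mj}
            got = set(filter(None, table.iloc[0]["arm_switch_tissues"].split(",")))
            assert got == expected


def test_major_position_dominates_every_other_start(sim):
    """The major start's cross-tissue total is maximal for every precursor."""
    profiles = expression.assign_arms(sim.reads, sim.annotations)
    recs = sim.reads.records
    for prof in profiles:
        if prof.major_position is None:
            continue
        sub = recs[recs["precursor_id"] == prof.precursor_id]
        totals = sub.groupby("start")["count"].sum()
        assert totals[prof.major_position] == totals.max()
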