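import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transdiv import (
    CountMatrix,
    call_de,
    compute_de,
    expression_ratio,
    overlap_partition,
    to_frequencies,
)

from conftest import random_count_matrix


def brute_force_partition(m: CountMatrix, up=2.0, down=0.5, min_count=3):
    """Independent per-gene reclassification: plain loops, no reuse of the
    implementation's vectorized path."""
    totals = {c: m.counts[c].sum() for c in m.condition_ids}
    patterns = {}
    n_excluded = 0
    for g in m.gene_ids:
        syms = []
        excluded = False
        xc = m.counts.loc[g, m.control_id]
        for t in m.treatment_ids:
            xt = m.counts.loc[g, t]
            if max(xt, xc) < min_count or (min_count == 0 and xt + xc == 0):
                excluded = True
                break
            pc = xc / totals[m.control_id]
            pt = xt / totals[t]
            if pc == 0:
                syms.append("+")  # positive treatment freq, ratio -> inf
            else:
                r = pt / pc
                syms.append("+" if r >= up else ("-" if r <= down else "0"))
        if excluded:
            n_excluded += 1
        else:
            key = tuple(syms)
            patterns[key] = patterns.get(key, 0) + 1
    return patterns, n_excluded


class TestFrequencies:
    def test_normalization(self):
        df = pd.DataFrame({"A": [2, 2], "B": [1, 3]}, index=["g1", "g2"])
        f = to_frequencies(CountMatrix(counts=df, control_id="A"))
        assert f.freqs["A"].tolist() == [0.5, 0.5]
        assert f.freqs["B"].tolist() == [0.25, 0.75]

    def test_columns_sum_to_one(self):
        m = random_count_matrix(np.random.default_rng(5), 50, 6)
        f = to_frequencies(m)
        assert np.allclose(f.freqs.sum(axis=0), 1.0, atol=1e-12)


class TestExpressionRatio:
    def test_basic_arithmetic(self):
        df = pd.DataFrame(
            {"C": [2, 5, 0, 0], "T": [4, 5, 3, 0]},
            index=["g1", "g2", "g3", "g4"],
        )
        f = to_frequencies(CountMatrix(counts=df, control_id="C"))
        # equal depths (7 vs 12) -> correct for them explicitly
        r = expression_ratio(f, "T", "C")
        assert r["g1"] == pytest.approx((4 / 12) / (2 / 7))
        assert r["g2"] == pytest.approx((5 / 12) / (5 / 7))
        assert math.isinf(r["g3"])  # expressed only under treatment
        assert math.isnan(r["g4"])  # absent from both libraries

    def test_identical_profile_gives_unity(self):
        df = pd.DataFrame({"C": [3, 7], "T": [3, 7]}, index=["a", "b"])
        f = to_frequencies(CountMatrix(counts=df, control_id="C"))
        assert expression_ratio(f, "T", "C").tolist() == [1.0, 1.0]

    def test_pseudocount_policy_is_finite(self):
        df = pd.DataFrame({"C": [0, 10], "T": [5, 5]}, index=["a", "b"])
        f = to_frequencies(CountMatrix(counts=df, control_id="C"))
        r = expression_ratio(f, "T", "C", policy="pseudocount", pseudo=0.1)
        assert np.isfinite(r).all()

    def test_unknown_condition(self):
        df = pd.DataFrame({"C": [1], "T": [1]}, index=["a"])
        f = to_frequencies(CountMatrix(counts=df, control_id="C"))
        with pytest.raises(KeyError):
            expression_ratio(f, "X", "C")


class TestCallDe:
    @pytest.mark.parametrize(
        "ratio,expected",
        [
            (2.0, "up"),  # boundary inclusive
            (0.5, "down"),  # boundary inclusive
            (1.0, "unchanged"),
            (1.99, "unchanged"),
            (0.51, "unchanged"),
            (np.inf, "up"),
            (0.0, "down"),
        ],
    )
    def test_threshold_rule(self, ratio, expected):
        calls = call_de(pd.Series([ratio], index=["g"]))
        assert calls["g"] == expected

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            call_de(pd.Series([1.0]), up_threshold=0.9)
        with pytest.raises(ValueError):
            call_de(pd.Series([1.0]), down_threshold=1.5)

    def test_monotonicity_in_thresholds(self):
        rng = np.random.default_rng(11)
        r = pd.Series(rng.lognormal(0, 1, size=500))
        n_up = [
            (call_de(r, up_threshold=u) == "up").sum() for u in (1.5, 2.0, 3.0)
        ]
        assert n_up[0] >= n_up[1] >= n_up[2]
        n_dn = [
            (call_de(r, down_threshold=d) == "down").sum()
            for d in (0.7, 0.5, 0.3)
        ]
        assert n_dn[0] >= n_dn[1] >= n_dn[2]


class TestComputeDe:
    def test_hand_worked_single_treatment(self, small_counts):
        de = compute_de(small_counts)
        assert de.ratios.loc["g1", "E"] == pytest.approx(2.5)
        assert de.ratios.loc["g3", "E"] == pytest.approx(0.4)
        assert de.calls["E"].tolist() == [
            "up", "unchanged", "down", "unchanged", "unchanged",
        ]

    def test_min_count_excludes_sparse_genes(self):
        df = pd.DataFrame(
            {"C": [0, 1, 100], "T": [2, 0, 100]}, index=["a", "b", "c"]
        )
        m = CountMatrix(counts=df, control_id="C")
        de = compute_de(m, min_count=3)
        assert de.calls["T"].tolist() == ["excluded", "excluded", "unchanged"]

    def test_raw_count_mode_differs_under_unequal_depths(self):
        df = pd.DataFrame({"C": [10, 90], "T": [30, 270]}, index=["a", "b"])
        m = CountMatrix(counts=df, control_id="C")
        freq = compute_de(m, ratio_on="frequencies")
        raw = compute_de(m, ratio_on="counts")
        assert freq.calls["T"].tolist() == ["unchanged", "unchanged"]
        assert raw.calls["T"].tolist() == ["up", "up"]


class TestOverlapPartition:
    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            m = random_count_matrix(
                rng, int(rng.integers(2, 100)), int(rng.integers(2, 6))
            )
            de = compute_de(m)
            part = overlap_partition(de)
            expected, n_excl = brute_force_partition(m)
            assert part.pattern_counts == expected
            assert part.n_excluded == n_excl

    def test_no_change_means_all_zero_pattern(self):
        df = pd.DataFrame(
            {c: [10, 20, 30] for c in ["C", "A", "B"]}, index=["x", "y", "z"]
        )
        part = overlap_partition(compute_de(CountMatrix(counts=df, control_id="C")))
        assert part.pattern_counts == {("0", "0"): 3}
        tables = part.direction_tables()
        assert tables["upregulated"].empty
        assert tables["downregulated"].empty

    def test_all_plus_pattern_leads_up_block(self):
        df = pd.DataFrame(
            {"C": [10, 10, 50], "A": [40, 10, 30], "B": [40, 25, 25]},
            index=["g1", "g2", "g3"],
        )
        part = overlap_partition(compute_de(CountMatrix(counts=df, control_id="C")))
        up = part.direction_tables()["upregulated"]
        assert up.iloc[0]["pattern"] == "++"

    def test_empty_treatment_set_rejected(self, small_counts):
        with pytest.raises(ValueError):
            overlap_partition(compute_de(small_counts), [])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_partition_completeness(self, seed):
        """Every gene lands in exactly one pattern or is excluded."""
        rng = np.random.default_rng(seed)
        m = random_count_matrix(
            rng, int(rng.integers(1, 60)), int(rng.integers(2, 7))
        )
        part = overlap_partition(compute_de(m))
        assert part.n_genes == len(m.gene_ids)
        assert all(
            len(p) == len(m.treatment_ids) for p in part.pattern_counts
        )

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10_000), scale=st.integers(2, 20))
    def test_scale_invariance_of_frequency_ratios(self, seed, scale):
        """Multiplying one library by an integer leaves frequency-based
        ratios, calls and partitions unchanged (read filter disabled, as
        it deliberately operates on raw read evidence)."""
        rng = np.random.default_rng(seed)
        m = random_count_matrix(rng, 30, 4)
        scaled = m.counts.copy()
        lib = m.condition_ids[1]
        scaled[lib] = scaled[lib] * scale
        m2 = CountMatrix(counts=scaled, control_id=m.control_id)
        de1 = compute_de(m, min_count=0)
        de2 = compute_de(m2, min_count=0)
        pd.testing.assert_frame_equal(de1.ratios, de2.ratios)
        assert de1.calls.equals(de2.calls)
        assert (
            overlap_partition(de1).pattern_counts
            == overlap_partition(de2).pattern_counts
        )
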