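import math

import numpy as np
import pytest

from snrnatail.endcall import EndCall
from snrnatail.tailstats import (
    aggregate_replicates,
    cumulative_end_distribution,
    compute_profile,
    mean_tail_base,
    percent_extended,
    percent_mature,
    percent_truncated,
    tail_composition_matrix,
)


def calls_from(ends_tails, gene_id="U1", n_reads=1):
    """Build EndCalls from (templated_end, tail) pairs."""
    return [
        EndCall(gene_id=gene_id, templated_end=e, tail=t, n_reads=n_reads)
        for e, t in ends_tails
    ]


def calls_from_apparent(apparents, gene_id="U1"):
    return calls_from([(a, "") for a in apparents], gene_id)


class TestCumulativeDistribution:
    def test_direct_counts(self):
        calls = calls_from_apparent([0] * 80 + [1] * 10 + [2] * 10)
        df = cumulative_end_distribution(calls)
        by_pos = df.set_index("position")["cumulative_pct"]
        assert math.isclose(by_pos[0], 80.0)
        assert math.isclose(by_pos[1], 90.0)
        assert math.isclose(by_pos[2], 100.0)

    def test_below_window_excluded_and_counted(self):
        calls = calls_from_apparent([-6, 0, 0])
        df = cumulative_end_distribution(calls, window_start=-5)
        assert df.attrs["n_excluded"] == 1
        assert df.attrs["n_in_window"] == 2
        assert math.isclose(df["cumulative_pct"].iloc[-1], 100.0)

    def test_degenerate_step_function(self):
        df = cumulative_end_distribution(calls_from_apparent([0, 0, 0]))
        assert math.isclose(df.set_index("position")["cumulative_pct"][0], 100.0)

    def test_nondecreasing_and_ends_at_100(self):
        rng = np.random.default_rng(0)
        calls = calls_from_apparent(rng.integers(-5, 8, size=200).tolist())
        df = cumulative_end_distribution(calls)
        assert (np.diff(df["cumulative_pct"]) >= -1e-12).all()
        assert math.isclose(df["cumulative_pct"].iloc[-1], 100.0)

    def test_templated_vs_apparent_modes(self):
        calls = calls_from([(0, "AAA"), (1, "")])
        app = cumulative_end_distribution(calls, "apparent").set_index("position")
        tem = cumulative_end_distribution(calls, "templated").set_index("position")
        assert math.isclose(app["cumulative_pct"][1], 50.0)  # apparent ends: 3 and 1
        assert math.isclose(tem["cumulative_pct"][1], 100.0)  # templated: 0 and 1

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            cumulative_end_distribution(calls_from_apparent([-8]))


class TestPercentages:
    def test_percent_mature_direct(self):
        assert math.isclose(percent_mature(calls_from_apparent([0, 0, 1, -1])), 50.0)

    def test_percent_mature_requires_no_tail(self):
        # a mature-positioned end with a tail is extended, not mature
        calls = calls_from([(0, ""), (0, "A")])
        assert math.isclose(percent_mature(calls), 50.0)
        assert math.isclose(percent_extended(calls), 50.0)

    def test_percent_extended_direct(self):
        assert math.isclose(percent_extended(calls_from_apparent([0, 1, 2, -1])), 50.0)

    def test_all_mature_and_all_extended_edges(self):
        assert math.isclose(percent_extended(calls_from_apparent([0, 0])), 0.0)
        assert math.isclose(percent_mature(calls_from_apparent([3, 3])), 0.0)

    def test_partition_identity(self):
        rng = np.random.default_rng(1)
        calls = calls_from(
            [(int(e), "A" * int(t)) for e, t in zip(rng.integers(-5, 6, 300), rng.integers(0, 4, 300))]
        )
        total = percent_mature(calls) + percent_extended(calls) + percent_truncated(calls)
        assert math.isclose(total, 100.0)

    def test_read_weighting_differs_from_molecule(self):
        calls = [
            EndCall("U1", 0, "", n_reads=9),
            EndCall("U1", 1, "", n_reads=1),
        ]
        assert math.isclose(percent_mature(calls, weighting="molecule"), 50.0)
        assert math.isclose(percent_mature(calls, weighting="read"), 90.0)


class TestTailMatrix:
    def test_direct_counts(self):
        mat = tail_composition_matrix(calls_from([(0, "AA"), (0, "AU"), (0, "")]))
        assert math.isclose(mat.loc[1, "A"], 200 / 3)
        assert math.isclose(mat.loc[2, "A"], 100 / 3)
        assert math.isclose(mat.loc[2, "U"], 100 / 3)
        assert mat.loc[3:, :].to_numpy().sum() == 0

    def test_tailless_gives_zero_matrix(self):
        mat = tail_composition_matrix(calls_from([(0, ""), (1, "")]))
        assert mat.to_numpy().sum() == 0

    def test_row_sums_nonincreasing(self):
        rng = np.random.default_rng(2)
        calls = calls_from(
            [(0, "".join(rng.choice(list("ACGU"), size=int(rng.integers(0, 10))))) for _ in range(200)]
        )
        row_sums = tail_composition_matrix(calls).sum(axis=1).to_numpy()
        assert (np.diff(row_sums) <= 1e-12).all()

    def test_tailed_denominator(self):
        calls = calls_from([(0, "A"), (0, "")])
        mat_all = tail_composition_matrix(calls, denominator="all")
        mat_tailed = tail_composition_matrix(calls, denominator="tailed")
        assert math.isclose(mat_all.loc[1, "A"], 50.0)
        assert math.isclose(mat_tailed.loc[1, "A"], 100.0)


class TestMeanTailBase:
    def test_mean_adenosines(self):
        assert math.isclose(mean_tail_base(calls_from([(0, "AA"), (0, ""), (0, "A")]), "A"), 1.0)

    def test_mean_uridines_and_mixed(self):
        calls = calls_from([(0, "AU"), (0, "U")])
        assert math.isclose(mean_tail_base(calls, "U"), 1.0)
        assert math.isclose(mean_tail_base(calls, "A"), 0.5)

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError):
            mean_tail_base(calls_from([(0, "A")]), "T")


class TestAggregateReplicates:
    def test_mean_and_sem_closed_form(self):
        agg = aggregate_replicates([10, 20, 30])
        assert math.isclose(agg["mean"], 20.0)
        assert math.isclose(agg["sem"], 5.7735, rel_tol=1e-4)
        assert agg["n"] == 3

    def test_single_replicate_flagged(self):
        agg = aggregate_replicates([10])
        assert math.isnan(agg["sem"]) and agg["flag"] == "sem_undefined"

    def test_sem_scales_linearly(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=6)
        assert math.isclose(
            aggregate_replicates(3.5 * x)["sem"], 3.5 * aggregate_replicates(x)["sem"]
        )


class TestProfile:
    def test_profile_bundles_consistent_statistics(self):
        calls = calls_from([(0, ""), (0, "A"), (1, ""), (-1, ""), (-7, "")])
        p = compute_profile(calls, "U1", sample_id="s1")
        assert p.n_transcripts == 4
        assert p.n_excluded == 1
        assert math.isclose(p.pct_mature + p.pct_extended + p.pct_truncated, 100.0)
        assert math.isclose(p.mean_A, 0.25)
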