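import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fishloop.distance_core import DistanceSummary
from fishloop.loop_call import (
    CallConfig,
    cluster_candidates,
    evaluate_against_reference,
    f1_score,
    filter_candidates,
    finalize_loops,
    select_summit,
)

from conftest import make_annotation


def _results(rows):
    """rows: (i, j, t, fdr) for a single 25 Kb region; tested, p == fdr/2."""
    return pd.DataFrame(
        [
            {"region_id": "r1", "i": i, "j": j, "tested": True,
             "n_case": 50, "n_ctrl": 500,
             "mean_case": 400.0 + (10.0 if t > 0 else -10.0), "mean_ctrl": 400.0,
             "t_stat": t, "p_value": fdr / 2, "fdr": fdr}
            for i, j, t, fdr in rows
        ]
    )


def _summary(cf_by_pair, ann):
    rows = [
        {"region_id": "r1", "i": i, "j": j, "genomic_dist": (j - i) * 25_000,
         "n_obs": 100, "mean_dist": 400.0, "contact_freq": cf}
        for (i, j), cf in cf_by_pair.items()
    ]
    return DistanceSummary(pd.DataFrame(rows), cutoff=300.0, ann=ann)


class TestFilterCandidates:
    def test_negative_t_low_fdr_kept(self):
        out = filter_candidates(_results([(4, 12, -2.1, 0.05)]))
        assert len(out) == 1

    def test_positive_t_dropped_despite_fdr(self):
        assert filter_candidates(_results([(4, 12, 2.0, 0.01)])).empty

    def test_fdr_boundary_strict(self):
        assert filter_candidates(_results([(4, 12, -2.1, 0.10)])).empty
        assert len(filter_candidates(_results([(4, 12, -2.1, 0.0999)]))) == 1

    def test_untested_never_kept(self):
        res = _results([(4, 12, -2.1, 0.01)])
        res["tested"] = False
        assert filter_candidates(res).empty


class TestClusterCandidates:
    def _cluster(self, pairs, n=20):
        ann = make_annotation(n, resolution=25_000)
        cands = _results([(i, j, -2.0, 0.01) for i, j in pairs])
        return cluster_candidates(cands, ann)

    def test_within_gap_merged(self):
        out = self._cluster([(4, 12), (5, 13)])
        assert out["cluster_id"].nunique() == 1

    def test_beyond_gap_split(self):
        out = self._cluster([(4, 12), (9, 12)])
        assert out["cluster_id"].nunique() == 2

    def test_single_linkage_chain(self):
        # A~B and B~C but A and C four bins apart: one transitive cluster
        out = self._cluster([(4, 12), (6, 12), (8, 12)])
        assert out["cluster_id"].nunique() == 1
        assert set(out["cluster_size"]) == {3}

    @given(
        st.lists(
            st.tuples(st.integers(0, 11), st.integers(0, 11)).map(
                lambda ij: (min(ij), max(ij) + 12)
            ),
            min_size=1, max_size=20, unique=True,
        )
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_brute_force_components(self, pairs):
        out = self._cluster(pairs, n=30)
        # oracle: BFS connected components on the Chebyshev<=2 graph
        idx = list(out[["i", "j"]].itertuples(index=False, name=None))
        adj = {
            a: {
                b for b in range(len(idx)) if b != a
                and abs(idx[a][0] - idx[b][0]) <= 2 and abs(idx[a][1] - idx[b][1]) <= 2
            }
            for a in range(len(idx))
        }
        seen, components = {}, 0
        for start in range(len(idx)):
            if start in seen:
                continue
            stack = [start]
            while stack:
                node = stack.pop()
                if node in seen:
                    continue
                seen[node] = components
                stack.extend(adj[node])
            components += 1
        expected = pd.Series(seen).sort_index()
        got = out["cluster_id"]
        # same partition (labels may differ)
        assert expected.groupby(expected).groups.keys() is not None
        pairs_same = lambda lab: {tuple(sorted(np.flatnonzero(lab == v))) for v in set(lab)}
        assert pairs_same(expected.to_numpy()) == pairs_same(got.to_numpy())


class TestSelectSummit:
    def test_minimal_fdr_wins(self):
        cluster = _results([(4, 12, -2.0, 0.05), (5, 13, -3.0, 0.01)])
        cluster["cluster_size"] = 2
        assert tuple(select_summit(cluster)[["i", "j"]]) == (5, 13)

    def test_singleton(self):
        cluster = _results([(4, 12, -2.0, 0.05)])
        assert select_summit(cluster)["i"] == 4

    def test_fdr_tie_broken_by_p(self):
        cluster = _results([(4, 12, -2.0, 0.02), (5, 13, -2.0, 0.02)])
        cluster.loc[0, "p_value"] = 0.002
        cluster.loc[1, "p_value"] = 0.001
        assert select_summit(cluster)["i"] == 5


class TestFinalizeLoops:
    def _run(self, rows, cfs):
        ann = make_annotation(20, resolution=25_000)
        cands = cluster_candidates(_results(rows), ann)
        return finalize_loops(cands, _summary(cfs, ann), CallConfig())

    def test_summit_cf_boundary_inclusive(self):
        out = self._run(
            [(4, 12, -2.0, 0.01), (5, 13, -2.5, 0.005)],
            {(4, 12): 0.2, (5, 13): 0.35},
        )
        assert len(out) == 1 and out.iloc[0]["flag"] == "summit"
        assert out.iloc[0]["contact_freq"] == pytest.approx(0.35)

    def test_singleton_below_half_dropped(self):
        assert self._run([(4, 12, -2.0, 0.01)], {(4, 12): 0.40}).empty

    def test_singleton_at_half_kept(self):
        out = self._run([(4, 12, -2.0, 0.01)], {(4, 12): 0.50})
        assert len(out) == 1 and out.iloc[0]["flag"] == "singleton"

    def test_exactly_one_third_kept_for_summit(self):
        out = self._run(
            [(4, 12, -2.0, 0.01), (5, 13, -2.5, 0.005)],
            {(4, 12): 0.9, (5, 13): 1 / 3},
        )
        assert len(out) == 1  # summit is the min-FDR member (5,13), CF = 1/3

    def test_at_most_one_loop_per_cluster_and_subset(self):
        rows = [(4, 12, -2.0, 0.01), (5, 13, -2.5, 0.005), (10, 18, -2.2, 0.02)]
        out = self._run(rows, {(4, 12): 0.9, (5, 13): 0.9, (10, 18): 0.9})
        assert len(out) == out["cluster_id"].nunique()
        called = set(map(tuple, out[["i", "j"]].itertuples(index=False)))
        assert called <= {(i, j) for i, j, _, _ in rows}

    def test_fdr_cap_monotonicity_of_candidates(self):
        rows = [(4, 12, -2.0, 0.01), (5, 13, -2.5, 0.08), (10, 18, -2.2, 0.15)]
        strict = filter_candidates(_results(rows), CallConfig(fdr_max=0.05))
        loose = filter_candidates(_results(rows), CallConfig(fdr_max=0.10))
        s = set(map(tuple, strict[["i", "j"]].itertuples(index=False)))
        l = set(map(tuple, loose[["i", "j"]].itertuples(index=False)))
        assert s <= l


class TestEvaluate:
    def _frame(self, anchors, fdr=None):
        df = pd.DataFrame(anchors, columns=["a_start", "b_start"])
        df.insert(0, "chrom", "chr1")
        if fdr is not None:
            df["fdr"] = fdr
        return df

    def test_published_benchmark_arithmetic(self):
        # 35 reference loops; 16 calls of which 14 match one reference each
        refs = self._frame([(k * 1_000_000, k * 1_000_000 + 300_000) for k in range(35)])
        calls = self._frame(
            [(k * 1_000_000 + 10_000, k * 1_000_000 + 300_000) for k in range(14)]
            + [(90_000_000 + k, 95_000_000 + k) for k in range(2)]
        )
        ev = evaluate_against_reference(calls, refs, tolerance=25_000)
        assert ev.precision == pytest.approx(0.875)
        assert ev.recall == pytest.approx(0.400)
        assert round(ev.f1, 3) == 0.549

    def test_identity(self):
        refs = self._frame([(100, 500), (900, 1500)])
        ev = evaluate_against_reference(refs.copy(), refs, tolerance=0)
        assert (ev.precision, ev.recall, ev.f1) == (1.0, 1.0, 1.0)

    def test_empty_calls_convention(self):
        refs = self._frame([(100, 500)])
        ev = evaluate_against_reference(refs.iloc[:0], refs, tolerance=10)
        assert (ev.precision, ev.recall, ev.f1) == (0.0, 0.0, 0.0)

    def test_each_reference_matched_once(self):
        refs = self._frame([(1000, 5000)])
        calls = self._frame([(1000, 5000), (1001, 5001)], fdr=[0.01, 0.001])
        ev = evaluate_against_reference(calls, refs, tolerance=10)
        assert ev.n_matched == 1 and ev.precision == 0.5 and ev.recall == 1.0

    def test_chromosome_must_agree(self):
        refs = self._frame([(1000, 5000)])
        calls = self._frame([(1000, 5000)])
        calls["chrom"] = "chr2"
        assert evaluate_against_reference(calls, refs, tolerance=10).n_matched == 0


def test_f1_harmonic_mean():
    assert f1_score(1.0, 1.0) == 1.0
    assert f1_score(0.0, 0.0) == 0.0
    assert f1_score(0.875, 0.4) == pytest.approx(2 * 0.875 * 0.4 / 1.275)
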