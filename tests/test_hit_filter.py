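"""Best-hit selection, threshold policies and the antidefense merge."""
import numpy as np
import pandas as pd
import pytest

from viroscape.hit_filter import (
    ANTIDEFENSEFINDER_POLICY,
    DBAPIS_POLICY,
    DEFENSEFINDER_POLICY,
    FilterPolicy,
    apply_policy,
    best_hit_per_query,
    compute_cluster_stats,
    merge_antidefense,
)


def hit_row(query="q1", target="t1", fident=0.5, qcov=0.5, tcov=0.5,
            alntmscore=0.7, evalue=1e-5, alnlen=150, **extra):
    return dict(query=query, target=target, fident=fident, qcov=qcov,
                tcov=tcov, alntmscore=alntmscore, evalue=evalue,
                alnlen=alnlen, **extra)


def hits_frame(rows):
    return pd.DataFrame(rows)


class TestBestHitPerQuery:
    def test_identity_times_qcov_wins(self):
        # 0.9*0.5 = 0.45 loses to 0.7*0.7 = 0.49
        df = hits_frame([
            hit_row(target="a", fident=0.9, qcov=0.5),
            hit_row(target="b", fident=0.7, qcov=0.7),
        ])
        assert list(best_hit_per_query(df)["target"]) == ["b"]

    def test_single_hit_kept(self):
        df = hits_frame([hit_row()])
        assert len(best_hit_per_query(df)) == 1

    def test_ties_break_by_tm_then_target(self):
        df = hits_frame([
            hit_row(target="b", fident=0.8, qcov=0.5, alntmscore=0.7),
            hit_row(target="a", fident=0.5, qcov=0.8, alntmscore=0.7),
            hit_row(target="c", fident=0.8, qcov=0.5, alntmscore=0.9),
        ])
        assert list(best_hit_per_query(df)["target"]) == ["c"]
        df2 = df[df["target"] != "c"]
        assert list(best_hit_per_query(df2)["target"]) == ["a"]

    def test_one_row_per_query(self, rng):
        df = hits_frame([
            hit_row(query=f"q{rng.integers(5)}", target=f"t{i}",
                    fident=float(rng.uniform(0, 1)), qcov=float(rng.uniform(0, 1)))
            for i in range(50)
        ])
        best = best_hit_per_query(df)
        assert sorted(best["query"]) == sorted(df["query"].unique())


MEMBERSHIP = {"q1": "SC1", "q2": "SC1", "q3": "SC2"}


class TestApplyPolicy:
    def test_defensefinder_worked_example(self):
        hits = hits_frame([
            hit_row(query="q1", alntmscore=0.66, evalue=1e-4, qcov=0.62, tcov=0.60)
        ])
        stats = pd.DataFrame(
            {"cluster_id": ["SC1"], "target": ["t1"], "mean_tm": [0.51],
             "mean_alnlen": [150.0]}
        )
        kept = apply_policy(hits, DEFENSEFINDER_POLICY, stats, MEMBERSHIP)
        assert len(kept) == 1

    def test_tm_exactly_at_bound_fails(self):
        """All bounds are strict: alignment TM of exactly 0.65 is rejected."""
        hits = hits_frame([
            hit_row(query="q1", alntmscore=0.65, evalue=1e-4, qcov=0.9, tcov=0.9)
        ])
        stats = pd.DataFrame(
            {"cluster_id": ["SC1"], "target": ["t1"], "mean_tm": [0.9],
             "mean_alnlen": [200.0]}
        )
        assert apply_policy(hits, DEFENSEFINDER_POLICY, stats, MEMBERSHIP).empty

    def test_dbapis_policy_skips_evalue(self):
        hits = hits_frame([
            hit_row(query="q1", alntmscore=0.7, evalue=5.0, qcov=0.55, tcov=0.55)
        ])
        stats = pd.DataFrame(
            {"cluster_id": ["SC1"], "target": ["t1"], "mean_tm": [0.52],
             "mean_alnlen": [120.0]}
        )
        assert len(apply_policy(hits, DBAPIS_POLICY, stats, MEMBERSHIP)) == 1
        # the same hit fails the AntiDefenseFinder policy on E-value
        assert apply_policy(hits, ANTIDEFENSEFINDER_POLICY, stats, MEMBERSHIP).empty

    def test_average_coverage_is_mean_of_q_and_t(self):
        # avg = (0.62 + 0.60)/2 = 0.61 > 0.6 passes; (0.62+0.56)/2 = 0.59 fails
        stats = pd.DataFrame(
            {"cluster_id": ["SC1"], "target": ["t1"], "mean_tm": [0.9],
             "mean_alnlen": [200.0]}
        )
        ok = hits_frame([hit_row(query="q1", alntmscore=0.7, qcov=0.62, tcov=0.60)])
        bad = hits_frame([hit_row(query="q1", alntmscore=0.7, qcov=0.62, tcov=0.56)])
        assert len(apply_policy(ok, DEFENSEFINDER_POLICY, stats, MEMBERSHIP)) == 1
        assert apply_policy(bad, DEFENSEFINDER_POLICY, stats, MEMBERSHIP).empty

    def test_missing_cluster_stats_fails_hit(self):
        hits = hits_frame([hit_row(query="q3", alntmscore=0.9, qcov=0.9, tcov=0.9)])
        stats = pd.DataFrame(
            {"cluster_id": ["SC1"], "target": ["t1"], "mean_tm": [0.9],
             "mean_alnlen": [200.0]}
        )
        assert apply_policy(hits, DEFENSEFINDER_POLICY, stats, MEMBERSHIP).empty

    def test_cluster_stats_computed_over_members(self):
        hits = hits_frame([
            hit_row(query="q1", target="t1", alntmscore=0.8, alnlen=100),
            hit_row(query="q2", target="t1", alntmscore=0.4, alnlen=200),
            hit_row(query="q3", target="t1", alntmscore=0.9, alnlen=50),
        ])
        stats = compute_cluster_stats(hits, MEMBERSHIP)
        row = stats[(stats["cluster_id"] == "SC1") & (stats["target"] == "t1")]
        assert row["mean_tm"].iloc[0] == pytest.approx(0.6)
        assert row["mean_alnlen"].iloc[0] == pytest.approx(150.0)


def random_hits(rng, n=120, n_queries=12, n_targets=6):
    rows = [
        hit_row(
            query=f"q{rng.integers(n_queries)}",
            target=f"t{rng.integers(n_targets)}",
            fident=float(rng.uniform(0, 1)),
            qcov=float(rng.uniform(0, 1)),
            tcov=float(rng.uniform(0, 1)),
            alntmscore=float(rng.uniform(0, 1)),
            evalue=float(10 ** rng.uniform(-8, 1)),
            alnlen=int(rng.integers(20, 400)),
        )
        for _ in range(n)
    ]
    membership = {f"q{i}": f"SC{i % 4}" for i in range(n_queries)}
    return hits_frame(rows), membership


def random_policy(rng):
    return FilterPolicy(
        name="rand",
        tm_min=float(rng.uniform(0, 0.9)),
        evalue_max=None if rng.random() < 0.3 else float(10 ** rng.uniform(-6, 0)),
        avg_cov_min=float(rng.uniform(0, 0.9)),
        cluster_tm_min=float(rng.uniform(0, 0.9)),
        intracluster_alnlen_min=None if rng.random() < 0.3 else float(rng.uniform(0, 300)),
    )


def tighten(policy, rng):
    ev = policy.evalue_max
    al = policy.intracluster_alnlen_min
    return policy.tightened(
        tm_min=min(1.0, policy.tm_min + float(rng.uniform(0, 0.1))),
        evalue_max=None if ev is None else ev * float(rng.uniform(0.1, 1.0)),
        avg_cov_min=min(1.0, policy.avg_cov_min + float(rng.uniform(0, 0.1))),
        cluster_tm_min=min(1.0, policy.cluster_tm_min + float(rng.uniform(0, 0.1))),
        intracluster_alnlen_min=None if al is None else al + float(rng.uniform(0, 50)),
    )


class TestPolicyProperties:
    def test_monotone_and_idempotent_over_random_policies(self, rng):
        """Tightening any bound shrinks the surviving set; filtering twice
        equals filtering once."""
        for _ in range(60):
            hits, membership = random_hits(rng)
            stats = compute_cluster_stats(hits, membership)
            p1 = random_policy(rng)
            p2 = tighten(p1, rng)
            kept1 = apply_policy(hits, p1, stats, membership)
            kept2 = apply_policy(hits, p2, stats, membership)
            key = lambda df: set(map(tuple, df[["query", "target", "alntmscore"]].itertuples(index=False)))
            assert key(kept2) <= key(kept1)
            again = apply_policy(kept1, p1, stats, membership)
            pd.testing.assert_frame_equal(again, kept1)


class TestMergeAntidefense:
    def test_best_tm_wins_across_sources(self):
        adf = hits_frame([hit_row(query="q1", target="a", alntmscore=0.7)])
        dbapis = hits_frame([hit_row(query="q1", target="b", alntmscore=0.8)])
        merged = merge_antidefense(adf, dbapis)
        assert list(merged["target"]) == ["b"]
        assert list(merged["source"]) == ["dbapis"]

    def test_query_in_one_source_only(self):
        adf = hits_frame([hit_row(query="q1", target="a")])
        dbapis = hits_frame([hit_row(query="q2", target="b")])
        merged = merge_antidefense(adf, dbapis)
        assert sorted(merged["query"]) == ["q1", "q2"]

    def test_tm_tie_prefers_antidefensefinder(self):
        adf = hits_frame([hit_row(query="q1", target="a", alntmscore=0.7)])
        dbapis = hits_frame([hit_row(query="q1", target="b", alntmscore=0.7)])
        merged = merge_antidefense(adf, dbapis)
        assert list(merged["source"]) == ["antidefensefinder"]


def test_policy_validation():
    with pytest.raises(ValueError):
        FilterPolicy("bad", tm_min=1.5, evalue_max=None, avg_cov_min=0.5,
                     cluster_tm_min=0.5)
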