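"""Best-hit selection and threshold filtering of structure-search hits.

Screens of a viral structure set against defense-system and antidefense
model libraries first keep, per query, the hit with the best identity
fraction times query coverage, then apply a named threshold policy in
which every bound is a strict inequality: minimum alignment TM-score,
maximum E-value (skippable for sources searched without one), minimum
average alignment coverage ((qcov + tcov)/2), minimum cluster-average
TM-score, and optionally a minimum intracluster alignment length. Cluster
averages are taken over all hits from members of the query's structural
cluster to the same target model. Hits from the two antidefense sources
are merged afterwards by best TM-score per query.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: columns apply_policy needs on a hit table
HIT_COLUMNS = ("query", "target", "fident", "qcov", "tcov", "alntmscore",
               "evalue", "alnlen")


@dataclass(frozen=True)
class FilterPolicy:
    """A named set of strict thresholds for structure-search hits.

    ``evalue_max`` and ``intracluster_alnlen_min`` may be ``None``, in
    which case the corresponding criterion is skipped (the dbAPIS library
    is searched without an E-value bound).
    """

    name: str
    tm_min: float
    evalue_max: float | None
    avg_cov_min: float
    cluster_tm_min: float
    intracluster_alnlen_min: float | None = None

    def __post_init__(self) -> None:
        for attr in ("tm_min", "avg_cov_min", "cluster_tm_min"):
            v = getattr(self, attr)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.name}: {attr}={v} outside [0, 1]")
        if self.evalue_max is not None and self.evalue_max < 0:
            raise ValueError(f"{self.name}: negative evalue_max")
        if self.intracluster_alnlen_min is not None and self.intracluster_alnlen_min < 0:
            raise ValueError(f"{self.name}: negative intracluster_alnlen_min")

    def tightened(self, **changes: float) -> "FilterPolicy":
        """Copy with some bounds replaced (used to build stricter policies)."""
        return replace(self, **changes)


DEFENSEFINDER_POLICY = FilterPolicy(
    name="defensefinder",
    tm_min=0.65,
    evalue_max=1e-3,
    avg_cov_min=0.6,
    cluster_tm_min=0.5,
    intracluster_alnlen_min=None,
)

ANTIDEFENSEFINDER_POLICY = FilterPolicy(
    name="antidefensefinder",
    tm_min=0.65,
    evalue_max=1e-3,
    avg_cov_min=0.5,
    cluster_tm_min=0.5,
    intracluster_alnlen_min=100,
)

# dbAPIS models are searched without an E-value bound
DBAPIS_POLICY = FilterPolicy(
    name="dbapis",
    tm_min=0.65,
    evalue_max=None,
    avg_cov_min=0.5,
    cluster_tm_min=0.5,
    intracluster_alnlen_min=100,
)

POLICIES: dict[str, FilterPolicy] = {
    p.name: p for p in (DEFENSEFINDER_POLICY, ANTIDEFENSEFINDER_POLICY, DBAPIS_POLICY)
}


def best_hit_per_query(hits: pd.DataFrame) -> pd.DataFrame:
    """Per query, the hit maximising identity fraction x query coverage.

    Ties break by higher TM-score, then lexicographically smaller target
    id. Returns one row per query, sorted by query id.
    """
    if hits.empty:
        return hits.copy()
    scored = hits.assign(_score=hits["fident"] * hits["qcov"])
    scored = scored.sort_values(
        ["query", "_score", "alntmscore", "target"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    best = scored.drop_duplicates("query", keep="first").drop(columns="_score")
    return best.reset_index(drop=True)


def compute_cluster_stats(
    hits: pd.DataFrame, membership: Mapping[str, str]
) -> pd.DataFrame:
    """Per (structural cluster, target) mean TM-score and alignment length.

    Averages run over all hits from any member of the cluster to that
    target model. Queries absent from ``membership`` raise.
    """
    missing = [q for q in hits["query"].unique() if q not in membership]
    if missing:
        raise KeyError(f"queries without cluster membership: {missing[:5]}")
    df = hits.assign(cluster_id=hits["query"].map(membership))
    stats = (
        df.groupby(["cluster_id", "target"], sort=True)
        .agg(mean_tm=("alntmscore", "mean"), mean_alnlen=("alnlen", "mean"))
        .reset_index()
    )
    return stats


def apply_policy(
    hits: pd.DataFrame,
    policy: FilterPolicy,
    cluster_stats: pd.DataFrame,
    membership: Mapping[str, str],
) -> pd.DataFrame:
    """Hits surviving every strict inequality of ``policy``.

    A hit must satisfy TM-score > tm_min, E-value < evalue_max (when
    set), (qcov + tcov)/2 > avg_cov_min, cluster mean TM > cluster_tm_min
    and, when set, cluster mean alignment length > intracluster_alnlen_min.
    Hits whose (cluster, target) pair is missing from ``cluster_stats``
    fail the cluster-level criteria and are dropped with a warning.
    """
    if hits.empty:
        return hits.copy()
    df = hits.assign(_cluster=hits["query"].map(dict(membership)))
    stats = cluster_stats.rename(columns={"cluster_id": "_cluster"})
    df = df.merge(stats, on=["_cluster", "target"], how="left")
    n_missing = int(df["mean_tm"].isna().sum())
    if n_missing:
        logger.warning(
            "policy %s: %d hits lack cluster statistics and fail cluster criteria",
            policy.name, n_missing,
        )
    keep = df["alntmscore"] > policy.tm_min
    if policy.evalue_max is not None:
        keep &= df["evalue"] < policy.evalue_max
    keep &= (df["qcov"] + df["tcov"]) / 2.0 > policy.avg_cov_min
    keep &= df["mean_tm"].notna() & (df["mean_tm"] > policy.cluster_tm_min)
    if policy.intracluster_alnlen_min is not None:
        keep &= df["mean_alnlen"].notna() & (
            df["mean_alnlen"] > policy.intracluster_alnlen_min
        )
    out = hits.loc[keep.to_numpy()].reset_index(drop=True)
    return out


_SOURCE_RANK = {"antidefensefinder": 0, "dbapis": 1}


def merge_antidefense(
    hits_adf: pd.DataFrame, hits_dbapis: pd.DataFrame
) -> pd.DataFrame:
    """Combine the two antidefense sources, keeping the best hit per query.

    Both inputs must already be policy-filtered. Per query the hit with
    the maximal TM-score wins; ties favour the AntiDefenseFinder source,
    then the lexicographically smaller target id. A ``source`` column is
    added when absent.
    """
    a = hits_adf.copy()
    b = hits_dbapis.copy()
    if "source" not in a.columns:
        a["source"] = "antidefensefinder"
    if "source" not in b.columns:
        b["source"] = "dbapis"
    merged = pd.concat([a, b], ignore_index=True)
    if merged.empty:
        return merged
    merged["_rank"] = merged["source"].map(_SOURCE_RANK).fillna(2)
    merged = merged.sort_values(
        ["query", "alntmscore", "_rank", "target"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    best = merged.drop_duplicates("query", keep="first").drop(columns="_rank")
    return best.reset_index(drop=True)
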