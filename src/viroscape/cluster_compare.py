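"""Comparison of sequence-level and structure-level clusterings.

Structure searches link many protein pairs that sequence searches miss;
summarised at the cluster level this becomes a set of unordered
cluster-to-cluster relationships. This module counts those relationships
from all-vs-all hit tables, cross-tabulates per-protein host-type labels
between the two clustering levels, and reports the relationship gain of
structure over sequence search.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .types import ClusterPair, HostTypeLabel

logger = logging.getLogger(__name__)

UNPAIRED = "unpaired"


def count_cluster_pairs(
    hits: Iterable[tuple[str, str]] | pd.DataFrame,
    membership: Mapping[str, str],
) -> list[ClusterPair]:
    """Unique unordered cluster pairs linked by >= 1 hit.

    ``hits`` is an iterable of (query_id, target_id) or a DataFrame with
    ``query``/``target`` columns; ``membership`` maps protein -> cluster.
    Self-hits and within-cluster hits contribute nothing. The result is
    sorted by pair key; ``evidence_count`` counts supporting hits.
    """
    if isinstance(hits, pd.DataFrame):
        hits = zip(hits["query"], hits["target"])
    counts: dict[tuple[str, str], int] = {}
    for query, target in hits:
        try:
            ca = membership[query]
        except KeyError:
            raise KeyError(f"protein {query!r} not found in cluster membership") from None
        try:
            cb = membership[target]
        except KeyError:
            raise KeyError(f"protein {target!r} not found in cluster membership") from None
        if ca == cb:
            continue
        key = (ca, cb) if ca < cb else (cb, ca)
        counts[key] = counts.get(key, 0) + 1
    return [
        ClusterPair(a, b, evidence_count=n) for (a, b), n in sorted(counts.items())
    ]


def transition_table(
    labels_seq: Mapping[str, HostTypeLabel],
    labels_struct: Mapping[str, HostTypeLabel],
    membership_seq: Mapping[str, str],
    membership_struct: Mapping[str, str],
) -> pd.DataFrame:
    """Per-protein cross-tabulation of sequence vs structure host type.

    Rows are sequence-cluster labels, columns structure-cluster labels.
    Proteins present at only one level fall into an ``unpaired`` margin
    (row or column) with a logged warning. Cell values are protein counts.
    """
    proteins = sorted(set(membership_seq) | set(membership_struct))
    rows = []
    n_unpaired = 0
    for pid in proteins:
        if pid in membership_seq:
            seq_label = labels_seq[membership_seq[pid]].key()
        else:
            seq_label = UNPAIRED
            n_unpaired += 1
        if pid in membership_struct:
            struct_label = labels_struct[membership_struct[pid]].key()
        else:
            struct_label = UNPAIRED
            n_unpaired += 1
        rows.append((seq_label, struct_label))
    if n_unpaired:
        logger.warning("transition table: %d proteins present at one level only", n_unpaired)
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows, columns=["sequence", "structure"])
    table = pd.crosstab(df["sequence"], df["structure"])
    return table.sort_index(axis=0).sort_index(axis=1)


def transition_fractions(table: pd.DataFrame) -> pd.DataFrame:
    """Row-normalised transition table (fractions per sequence-level label)."""
    if table.empty:
        return table
    return table.div(table.sum(axis=1), axis=0)


@dataclass(frozen=True)
class RelationshipGain:
    """Ratio |structure pairs| / |sequence pairs|, flagged when infinite."""

    ratio: float
    infinite: bool
    n_struct: int
    n_seq: int


def relationship_gain(
    pairs_struct: Iterable[ClusterPair], pairs_seq: Iterable[ClusterPair]
) -> RelationshipGain:
    """How many more unique cluster relationships structure search finds."""
    n_struct = len({p.key for p in pairs_struct})
    n_seq = len({p.key for p in pairs_seq})
    if n_seq == 0:
        ratio = math.inf if n_struct else math.nan
        return RelationshipGain(ratio, True, n_struct, n_seq)
    return RelationshipGain(n_struct / n_seq, False, n_struct, n_seq)
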