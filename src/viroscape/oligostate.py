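"""Oligomeric-state inference from structure-search hits to PDB chains.

A query's likely assembly state is taken from the annotated oligomeric
states of its PDB chain hits: hits below a TM-score floor (0.5, the
conventional same-fold cutoff) are discarded, the remaining hits vote with
their TM-score as weight, and the state with the largest summed weight
wins. Independently, a query is flagged homo-oligomeric if any hit chain
occurs more than once in its assembly, and hetero-oligomeric if any hit
assembly contains more than one distinct chain type.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .types import OligoAnnotation, OligoCall

logger = logging.getLogger(__name__)

Hit = tuple[str, float]  # (pdb_chain_id, tm_score)


def classify_homo_hetero(
    hits: Iterable[Hit], annotations: Mapping[str, OligoAnnotation]
) -> tuple[bool, bool]:
    """(homo_flag, hetero_flag) from a query's thresholded hits.

    The flags are independent: a query hitting both a homotrimer chain and
    a chain of a mixed assembly is both homo- and hetero-oligomeric. Hit
    chains missing from the annotation table are skipped with a warning.
    """
    homo = hetero = False
    for chain_id, _tm in hits:
        ann = annotations.get(chain_id)
        if ann is None:
            logger.warning("no oligomeric annotation for chain %s; skipped", chain_id)
            continue
        if ann.assembly_copies_of_chain > 1:
            homo = True
        if ann.distinct_chain_types_in_assembly > 1:
            hetero = True
    return homo, hetero


def infer_state(
    query_id: str,
    hits: Iterable[Hit],
    annotations: Mapping[str, OligoAnnotation],
    tm_min: float = 0.5,
) -> OligoCall:
    """TM-score-weighted vote over the annotated states of a query's hits.

    Hits with TM-score below ``tm_min`` are discarded; surviving hits sum
    their TM-score into their chain's state label, and the label with the
    largest total wins. Ties break by number of supporting hits, then by
    lexicographically smaller label. No surviving annotated hit -> state
    ``None``.
    """
    weights: dict[str, float] = {}
    counts: dict[str, int] = {}
    kept: list[Hit] = []
    for chain_id, tm in hits:
        if tm < tm_min:
            continue
        ann = annotations.get(chain_id)
        if ann is None:
            logger.warning("no oligomeric annotation for chain %s; skipped", chain_id)
            continue
        label = ann.state_label
        weights[label] = weights.get(label, 0.0) + tm
        counts[label] = counts.get(label, 0) + 1
        kept.append((chain_id, tm))
    if not weights:
        return OligoCall(query_id, None, {})
    best = min(weights, key=lambda s: (-weights[s], -counts[s], s))
    homo, hetero = classify_homo_hetero(kept, annotations)
    return OligoCall(query_id, best, weights, homo_flag=homo, hetero_flag=hetero)


def infer_states(
    hits: pd.DataFrame,
    annotations: Mapping[str, OligoAnnotation],
    tm_min: float = 0.5,
    membership: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Vectorised state calls for a hit table.

    ``hits`` needs columns ``query``, ``target`` and ``alntmscore``. With
    ``membership`` (protein -> cluster) the vote pools all hits of a
    cluster's members and the call is per cluster; otherwise per query.
    Returns a table with columns query, state, homo_flag, hetero_flag.
    """
    required = {"query", "target", "alntmscore"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table lacks columns: {sorted(missing)}")
    if membership is not None:
        group_of = {q: membership[q] for q in hits["query"].unique()}
        keys = hits["query"].map(group_of)
    else:
        keys = hits["query"]
    rows = []
    for key, sub in hits.groupby(keys, sort=True):
        call = infer_state(
            str(key), zip(sub["target"], sub["alntmscore"]), annotations, tm_min
        )
        rows.append((call.query_id, call.state_label, call.homo_flag, call.hetero_flag))
    return pd.DataFrame(rows, columns=["query", "state", "homo_flag", "hetero_flag"])


def annotations_from_table(df: pd.DataFrame) -> dict[str, OligoAnnotation]:
    """Build the chain -> annotation mapping from a table with columns
    pdb_chain_id, copies, distinct_chains."""
    return {
        str(r.pdb_chain_id): OligoAnnotation(
            str(r.pdb_chain_id), int(r.copies), int(r.distinct_chains)
        )
        for r in df.itertuples(index=False)
    }
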