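"""Shared fixtures and independent brute-force oracles.

The oracles re-derive each rule from its plain statement (enumeration,
groupby-sum-argmax, naive tuple scans) without touching the code paths
they check.
"""
from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
import pytest

from viroscape.types import (
    ClusterLevel,
    ClusterRecord,
    GeneFeature,
    HostDomain,
    Neighborhood,
    ProteinRecord,
)

DOMS = ("bacteria", "archaea", "eukaryota")


# ------------------------------------------------------- host-typing oracle

def oracle_host_label(b: int, a: int, e: int, u: int) -> str:
    """Direct evaluation of the minority rule on a composition vector.

    Integer arithmetic throughout: 1% of N with ceiling is ceil(N/100).
    """
    n = b + a + e + u
    counts = {d: c for d, c in zip(DOMS, (b, a, e)) if c > 0}
    if not counts:
        return "undefined"
    threshold = max(3, -(-n // 100))
    modal = max(counts.values())
    qualifying = sorted(
        d for d, c in counts.items() if c == modal or c >= threshold
    )
    if len(qualifying) >= 2:
        return "hetero(" + "+".join(qualifying) + ")"
    return f"mono({qualifying[0]})"


def composition_cluster(b: int, a: int, e: int, u: int):
    """A cluster + protein records realising a (b, a, e, u) composition."""
    records = {}
    members = []
    for dom, count in zip((*DOMS, "undefined"), (b, a, e, u)):
        hd = HostDomain(dom)
        for i in range(count):
            pid = f"{dom[0]}{i}"
            members.append(pid)
            records[pid] = ProteinRecord(pid, 1, frozenset({hd}))
    cluster = ClusterRecord("C", ClusterLevel.SEQUENCE, tuple(members), members[0])
    return cluster, records


# -------------------------------------------------------- oligostate oracle

def oracle_infer_state(states_tms: list[tuple[str, float]], tm_min: float = 0.5):
    """groupby-sum-argmax on (state, tm) pairs, ties by count then label."""
    df = pd.DataFrame(states_tms, columns=["state", "tm"])
    df = df[df["tm"] >= tm_min]
    if df.empty:
        return None
    agg = df.groupby("state")["tm"].agg(["sum", "count"])
    order = sorted(agg.itertuples(), key=lambda r: (-r.sum, -r.count, r.Index))
    return order[0].Index


# ---------------------------------------------------------- ta-miner oracle

def _gap(prev: GeneFeature, nxt: GeneFeature) -> int:
    return nxt.start - prev.end - 1


def _oracle_occurrences(nbh, fams, gap_max, same_strand):
    k = len(fams)
    out = []
    for i in range(len(nbh.genes) - k + 1):
        run = nbh.genes[i : i + k]
        if [g.family_label for g in run] != list(fams):
            continue
        if same_strand and len({g.strand for g in run}) > 1:
            continue
        if all(_gap(run[j], run[j + 1]) <= gap_max for j in range(k - 1)):
            out.append(run)
    return out


def oracle_mine(neighborhoods, gap_max=100, flank_gap_min=100, presence_min=0.5,
                min_species=6, max_len=4, same_strand=True):
    """Naive enumeration over the full family universe with direct rule checks."""
    species = {n.species_id for n in neighborhoods}
    if len(species) < min_species:
        return []
    n_ctx = len(neighborhoods)
    universe = sorted({g.family_label for n in neighborhoods for g in n.genes})
    conserved = {
        f for f in universe
        if sum(f in {g.family_label for g in n.genes} for n in neighborhoods) / n_ctx
        >= presence_min
    }
    targets = {
        g.family_label for n in neighborhoods for g in n.genes if g.is_target
    }

    def supports(nbh, fams):
        for run in _oracle_occurrences(nbh, fams, gap_max, same_strand):
            s, e = run[0].start, run[-1].end
            ok = True
            for g in nbh.genes:
                if g.family_label in conserved and g.family_label not in fams:
                    if g.end < s:
                        d = s - g.end - 1
                    elif g.start > e:
                        d = g.start - e - 1
                    else:
                        d = 0
                    if d <= flank_gap_min:
                        ok = False
                        break
            if ok:
                return True
        return False

    freq_cache: dict[tuple, float] = {}

    def freq(fams):
        if fams not in freq_cache:
            freq_cache[fams] = sum(supports(n, fams) for n in neighborhoods) / n_ctx
        return freq_cache[fams]

    results = []
    for k in range(2, max_len + 1):
        for fams in product(universe, repeat=k):
            if not (set(fams) & targets):
                continue
            sup = [n for n in neighborhoods if supports(n, fams)]
            if not sup:
                continue
            sp = {n.species_id for n in sup}
            if len(sp) < min_species:
                continue
            best_ext = max(
                [freq((x,) + fams) for x in universe]
                + [freq(fams + (x,)) for x in universe]
            )
            f = len(sup) / n_ctx
            results.append((
                fams,
                frozenset(n.context_id for n in sup),
                len(sp),
                f,
                best_ext,
                f - best_ext,
            ))
    results.sort(key=lambda r: (-r[5], -r[3], len(r[0]), r[0]))
    return results


def random_neighborhoods(rng: np.random.Generator, n_contexts: int, n_species: int,
                         max_genes: int = 8, n_families: int = 5):
    """Random small genomic-context instances for oracle comparison."""
    fams = [f"f{i}" for i in range(n_families)]
    out = []
    for ci in range(n_contexts):
        ctx = f"c{ci}"
        sp = f"s{int(rng.integers(n_species))}"
        n_genes = int(rng.integers(2, max_genes + 1))
        pos = 1
        genes = []
        for oi in range(n_genes):
            start = pos if oi == 0 else pos + int(rng.integers(0, 251)) + 1
            end = start + int(rng.integers(100, 500))
            genes.append(GeneFeature(
                ctx, sp, oi, start, end,
                "+" if rng.random() < 0.7 else "-",
                fams[int(rng.integers(n_families))],
                bool(rng.random() < 0.25),
            ))
            pos = end
        out.append(Neighborhood(ctx, sp, tuple(genes)))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
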