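"""Seeded generators for every input table the pipeline consumes.

The generators emulate the real study's inputs at desk scale: a viral
protein set with virus->host mappings whose domain mixture follows the
observed host distribution (bacteria-dominated, with eukaryotic, rare
archaeal and a few percent unresolvable hosts); sequence clusters with
minority-host injections placed just above or below the heterohost
threshold; structure-search hit tables whose TM-scores stochastically
favour a known true oligomeric state; and genomic-context windows with a
planted same-strand bicistron (closely spaced, <= 100 nt) flanked by
per-context decoy families at > 100 nt.

Every generator is a pure function of its :class:`SimConfig` — the same
config (seed included) yields byte-identical tables — and each draws from
its own seed substream, so changing one generator's parameters never
perturbs another's output.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as vio
from .host_typing import heterohost_threshold
from .types import (
    ClusterLevel,
    ClusterRecord,
    GeneFeature,
    HostDomain,
    Neighborhood,
    oligo_state_label,
)

# fixed substream tags so generators stay independent of one another
_STREAM_CLUSTERS = 11
_STREAM_OLIGO = 22
_STREAM_NEIGHBORHOODS = 33

_LINEAGE_OF = {
    HostDomain.BACTERIA: "Bacteria; Pseudomonadota; Gammaproteobacteria",
    HostDomain.ARCHAEA: "Archaea; Euryarchaeota; Methanococci",
    HostDomain.EUKARYOTA: "Eukaryota; Chordata; Mammalia",
}

OLIGO_STATES = ("monomer", "homodimer", "homotrimer", "homotetramer", "hetero-2-mer")
_STATE_COUNTS = {
    "monomer": (1, 1),
    "homodimer": (2, 1),
    "homotrimer": (3, 1),
    "homotetramer": (4, 1),
    "hetero-2-mer": (1, 2),
}


class ConfigError(ValueError):
    """A simulation config inconsistent with what it promises to produce."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study conditions.

    Host mixture defaults follow the observed per-protein host
    distribution of the real dataset (79.9% bacteria, 15.4% eukaryota,
    1.1% archaea; the remainder host-undefined). The planted bicistron
    uses internal gaps within the 100-nt operon spacing rule and decoy
    flanks beyond it.
    """

    seed: int = 0
    # cluster tables
    n_clusters: int = 60
    cluster_size_mean: float = 12.0
    host_mixture: Mapping[str, float] = field(
        default_factory=lambda: {
            "bacteria": 0.799, "eukaryota": 0.154, "archaea": 0.011,
            "undefined": 0.036,
        }
    )
    minority_inject_rate: float = 0.3
    big_cluster_count: int = 2  # large clusters exercising the 1%-of-N branch
    big_cluster_size: int = 400
    # oligostate hits
    n_queries: int = 500
    hit_noise_sd: float = 0.05
    # genomic contexts
    n_contexts: int = 20
    n_species: int = 8
    planted_pattern: tuple[str, ...] = ("toxin_cand", "antitoxin_cand")
    internal_gap_range: tuple[int, int] = (0, 100)
    flank_gap_range: tuple[int, int] = (150, 400)
    decoy_family_pool: int = 40
    conserved_flank: tuple[str, int] | None = None
    assert_recoverable: bool = False

    def __post_init__(self) -> None:
        total = sum(self.host_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"host_mixture sums to {total}, not 1")
        for name in ("internal_gap_range", "flank_gap_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ConfigError(f"invalid {name}: ({lo}, {hi})")
        if len(self.planted_pattern) < 2:
            raise ConfigError("planted_pattern needs >= 2 families")
        if self.assert_recoverable:
            if self.internal_gap_range[1] > 100:
                raise ConfigError(
                    "internal gaps may exceed the 100-nt spacing rule; "
                    "planted pattern would not be recoverable"
                )
            if self.flank_gap_range[0] <= 100:
                raise ConfigError("decoy flanks must start beyond 100 nt")
            if self.n_species < 6:
                raise ConfigError("fewer than 6 species cannot pass the species gate")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


# ------------------------------------------------------------------ clusters

@dataclass(frozen=True)
class SimulatedClusters:
    proteins: pd.DataFrame  # protein_id, virus_taxid
    host_map: dict[int, list[str]]
    clusters: list[ClusterRecord]
    truth: dict[str, str]  # cluster_id -> host-type label key


def gen_cluster_tables(cfg: SimConfig) -> SimulatedClusters:
    """Clusters with host compositions drawn from the configured mixture.

    A ``minority_inject_rate`` fraction of defined-host clusters receives
    minority members of a second domain, sized just above or just below
    (50/50) the heterohost threshold max(3, ceil(N/100)); the resulting
    true label is recorded. A few large clusters exercise the 1%-of-N
    branch of the threshold.
    """
    rng = cfg.rng(_STREAM_CLUSTERS)
    domains = sorted(cfg.host_mixture)
    probs = np.array([cfg.host_mixture[d] for d in domains])
    defined = [d for d in domains if d != "undefined"]

    proteins: list[tuple[str, int | None]] = []
    host_map: dict[int, list[str]] = {}
    clusters: list[ClusterRecord] = []
    truth: dict[str, str] = {}
    taxid = 100000
    pidx = 0

    def add_protein(domain: str) -> str:
        nonlocal taxid, pidx
        pid = f"P{pidx:06d}"
        pidx += 1
        taxid += 1
        if domain == "undefined":
            # half the undefined viruses lack a mapping entry entirely,
            # the rest are recorded as infecting other viruses
            if rng.random() < 0.5:
                proteins.append((pid, None))
            else:
                host_map[taxid] = ["Viruses; Duplodnaviria; Caudoviricetes"]
                proteins.append((pid, taxid))
        else:
            host_map[taxid] = [_LINEAGE_OF[HostDomain(domain)]]
            proteins.append((pid, taxid))
        return pid

    for ci in range(cfg.n_clusters):
        cid = f"SC{ci:05d}"
        if ci < cfg.big_cluster_count:
            base_size = cfg.big_cluster_size
            base = "bacteria"
        else:
            base_size = int(rng.poisson(cfg.cluster_size_mean)) + 1
            base = domains[int(rng.choice(len(domains), p=probs))]
        member_ids = [add_protein(base) for _ in range(base_size)]
        label = "undefined" if base == "undefined" else f"mono({base})"

        if base != "undefined" and rng.random() < cfg.minority_inject_rate:
            minority = defined[int(rng.choice(len(defined)))]
            while minority == base:
                minority = defined[int(rng.choice(len(defined)))]
            # threshold depends on the final size; solve by iteration
            m = heterohost_threshold(base_size)
            for _ in range(5):
                m_new = heterohost_threshold(base_size + m)
                if m_new == m:
                    break
                m = m_new
            above = bool(rng.random() < 0.5)
            m_used = m if above else m - 1
            if m_used >= 1 and base_size >= 2 * m_used:
                member_ids.extend(add_protein(minority) for _ in range(m_used))
                if above:
                    names = "+".join(sorted([base, minority]))
                    label = f"hetero({names})"
        clusters.append(
            ClusterRecord(cid, ClusterLevel.SEQUENCE, tuple(member_ids), member_ids[0])
        )
        truth[cid] = label

    proteins_df = pd.DataFrame(proteins, columns=["protein_id", "virus_taxid"])
    proteins_df["virus_taxid"] = proteins_df["virus_taxid"].astype("Int64")
    return SimulatedClusters(proteins_df, host_map, clusters, truth)


# --------------------------------------------------------------- oligo hits

@dataclass(frozen=True)
class SimulatedOligo:
    hits: pd.DataFrame  # m8 columns + alntmscore
    annotations: pd.DataFrame  # pdb_chain_id, copies, distinct_chains
    truth: dict[str, str]  # query -> true state label


def gen_oligo_hits(cfg: SimConfig, chains_per_state: int = 6) -> SimulatedOligo:
    """Hit tables whose true state's TM-scores dominate the decoys'.

    Per query, hits to chains of the true state draw TM-scores around
    0.78 and outnumber hits to two decoy states drawn around 0.62, both
    jittered with ``hit_noise_sd``; summed TM-score voting then recovers
    the truth for almost every query.
    """
    rng = cfg.rng(_STREAM_OLIGO)
    chain_pool: dict[str, list[str]] = {}
    ann_rows = []
    for si, state in enumerate(OLIGO_STATES):
        copies, distinct = _STATE_COUNTS[state]
        assert oligo_state_label(copies, distinct) == state
        ids = [f"{1000 + si * 10 + k}X_A" for k in range(chains_per_state)]
        chain_pool[state] = ids
        ann_rows.extend((cid, copies, distinct) for cid in ids)
    annotations = pd.DataFrame(
        ann_rows, columns=["pdb_chain_id", "copies", "distinct_chains"]
    )

    rows = []
    truth: dict[str, str] = {}
    for qi in range(cfg.n_queries):
        query = f"Q{qi:05d}"
        true_state = OLIGO_STATES[int(rng.integers(len(OLIGO_STATES)))]
        truth[query] = true_state
        decoys = rng.choice(
            [s for s in OLIGO_STATES if s != true_state], size=2, replace=False
        )
        emit = [(true_state, int(rng.poisson(4)) + 2, 0.78)]
        emit += [(d, int(rng.poisson(1.5)), 0.62) for d in decoys]
        for state, n_hits, tm_base in emit:
            for _ in range(n_hits):
                chain = chain_pool[state][int(rng.integers(chains_per_state))]
                tm = float(np.clip(rng.normal(tm_base, cfg.hit_noise_sd), 0.05, 0.99))
                alnlen = int(rng.integers(80, 400))
                rows.append((
                    query, chain, round(float(rng.uniform(0.1, 0.9)), 4), alnlen,
                    int(rng.integers(0, 50)), int(rng.integers(0, 5)),
                    1, alnlen, 1, alnlen,
                    round(float(10 ** rng.uniform(-10, -2)), 12),
                    int(rng.integers(50, 900)), round(tm, 4),
                ))
    hits = pd.DataFrame(rows, columns=list(vio.M8_COLUMNS) + ["alntmscore"])
    return SimulatedOligo(hits, annotations, truth)


# ------------------------------------------------------------ neighborhoods

@dataclass(frozen=True)
class SimulatedNeighborhoods:
    neighborhoods: list[Neighborhood]
    truth_pattern: tuple[str, ...]


def gen_neighborhoods(cfg: SimConfig) -> SimulatedNeighborhoods:
    """Context windows with a planted same-strand bicistron.

    Each window carries the planted pattern (internal gaps from
    ``internal_gap_range``) surrounded on each side by 1-3 decoy genes
    with per-context families from a pool large enough that none becomes
    conserved, at gaps from ``flank_gap_range``. The first planted gene is
    the target. With ``conserved_flank`` set, the named family is also
    inserted right after the pattern at the given gap in every context.
    """
    rng = cfg.rng(_STREAM_NEIGHBORHOODS)
    species = [f"SP{si:03d}" for si in range(cfg.n_species)]
    glo, ghi = cfg.internal_gap_range
    flo, fhi = cfg.flank_gap_range
    out: list[Neighborhood] = []
    for ci in range(cfg.n_contexts):
        ctx = f"CTX{ci:04d}"
        sp = species[ci % cfg.n_species]
        # (family, strand, gap before gene, is_target)
        plan: list[tuple[str, str, int, bool]] = []
        for _ in range(int(rng.integers(1, 4))):
            plan.append((
                f"dec{int(rng.integers(cfg.decoy_family_pool)):03d}",
                "+" if rng.random() < 0.5 else "-",
                int(rng.integers(flo, fhi + 1)), False,
            ))
        for gi, fam in enumerate(cfg.planted_pattern):
            gap = int(rng.integers(flo, fhi + 1)) if gi == 0 else int(rng.integers(glo, ghi + 1))
            plan.append((fam, "+", gap, gi == 0))
        if cfg.conserved_flank is not None:
            fam, gap = cfg.conserved_flank
            plan.append((fam, "+", int(gap), False))
        for _ in range(int(rng.integers(1, 4))):
            plan.append((
                f"dec{int(rng.integers(cfg.decoy_family_pool)):03d}",
                "+" if rng.random() < 0.5 else "-",
                int(rng.integers(flo, fhi + 1)), False,
            ))
        pos = 1 + int(rng.integers(0, 100))
        genes = []
        for oi, (fam, strand, gap, is_target) in enumerate(plan):
            start = pos if oi == 0 else pos + gap + 1
            length = int(rng.integers(200, 901))
            end = start + length - 1
            genes.append(GeneFeature(ctx, sp, oi, start, end, strand, fam, is_target))
            pos = end
        out.append(Neighborhood(ctx, sp, tuple(genes)))
    return SimulatedNeighborhoods(out, tuple(cfg.planted_pattern))


# ---------------------------------------------------------------- PDB stubs

def model_stub_text(chains: Mapping[str, Sequence[float]]) -> str:
    """Minimal PDB text with one C-alpha per residue carrying pLDDT in the
    B-factor column (the layout predicted-model files use)."""
    lines = []
    serial = 1
    for chain_id, plddts in chains.items():
        for ri, b in enumerate(plddts, start=1):
            lines.append(
                f"ATOM  {serial:5d}  CA  ALA {chain_id}{ri:4d}    "
                f"{ri * 3.8:8.3f}{0.0:8.3f}{0.0:8.3f}{1.00:6.2f}{b:6.2f}"
                f"           C"
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_model_stub(path: str | Path, chains: Mapping[str, Sequence[float]]) -> None:
    Path(path).write_text(model_stub_text(chains))


# ------------------------------------------------------------------ simulate

def simulate(cfg: SimConfig, outdir: str | Path) -> None:
    """Write every synthetic table plus the ground truth to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_c = gen_cluster_tables(cfg)
    sim_o = gen_oligo_hits(cfg)
    sim_n = gen_neighborhoods(cfg)
    vio.write_tsv(sim_c.proteins, outdir / "proteins.tsv")
    vio.write_host_map(sim_c.host_map, outdir / "hostmap.tsv")
    vio.write_cluster_table(sim_c.clusters, outdir / "clusters.tsv")
    vio.write_m8(sim_o.hits, outdir / "oligo_hits.m8")
    vio.write_tsv(sim_o.annotations, outdir / "oligo_annotations.tsv")
    vio.write_neighborhoods(sim_n.neighborhoods, outdir / "neighborhoods.tsv")
    truth = {
        "cluster_host_labels": sim_c.truth,
        "oligo_states": sim_o.truth,
        "planted_pattern": list(sim_n.truth_pattern),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
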