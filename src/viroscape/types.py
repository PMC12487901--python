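"""Core domain types shared across the pipeline.

These are thin, validated containers: a viral protein with its resolved
host domain(s), a cluster at the sequence or structure level, one row of a
structure-search result, per-model confidence scores, an annotated genomic
window, and the candidate gene patterns mined from it.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class HostDomain(enum.Enum):
    """Cellular superkingdom of a virus's host.

    ``UNDEFINED`` covers viruses with no resolvable host: taxid missing
    from the mapping, no taxonomy id at all, or a recorded host that is
    itself a virus (virophages, phage satellites).
    """

    BACTERIA = "bacteria"
    ARCHAEA = "archaea"
    EUKARYOTA = "eukaryota"
    UNDEFINED = "undefined"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The three defined cellular domains (everything but UNDEFINED).
DEFINED_DOMAINS = frozenset(
    {HostDomain.BACTERIA, HostDomain.ARCHAEA, HostDomain.EUKARYOTA}
)


@dataclass(frozen=True)
class ProteinRecord:
    """A viral protein together with its source virus and resolved hosts."""

    protein_id: str
    virus_taxid: int | None
    host_domains: frozenset[HostDomain]
    annotation: str | None = None
    length: int | None = None

    def __post_init__(self) -> None:
        if not self.host_domains:
            raise ValueError(f"{self.protein_id}: host_domains must be non-empty")
        if HostDomain.UNDEFINED in self.host_domains and len(self.host_domains) > 1:
            raise ValueError(
                f"{self.protein_id}: undefined host excludes defined domains"
            )
        if self.length is not None and self.length <= 0:
            raise ValueError(f"{self.protein_id}: length must be positive")


@dataclass(frozen=True)
class HostOverride:
    """Manual curation rule: a virus lineage name forced to a host domain."""

    lineage_pattern: str
    forced_domain: HostDomain

    def matches(self, virus_lineage: str | None) -> bool:
        if virus_lineage is None:
            return False
        return virus_lineage.strip().lower() == self.lineage_pattern.strip().lower()


class ClusterLevel(enum.Enum):
    SEQUENCE = "sequence"
    STRUCTURE = "structure"


@dataclass(frozen=True)
class ClusterRecord:
    """A sequence- or structure-level cluster of viral proteins."""

    cluster_id: str
    level: ClusterLevel
    member_ids: tuple[str, ...]
    representative_id: str

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError(f"{self.cluster_id}: cluster has no members")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValueError(f"{self.cluster_id}: duplicate member ids")
        if self.representative_id not in self.member_ids:
            raise ValueError(
                f"{self.cluster_id}: representative {self.representative_id!r} "
                "is not a member"
            )

    @property
    def size(self) -> int:
        return len(self.member_ids)


class HostTypeKind(enum.Enum):
    MONO = "mono"
    HETERO = "hetero"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class HostTypeLabel:
    """Mono-/heterohost classification of a cluster.

    ``domains`` is a singleton for mono labels, has >= 2 members for hetero
    labels (never containing UNDEFINED), and is empty for host-undefined
    clusters.
    """

    kind: HostTypeKind
    domains: frozenset[HostDomain]

    def __post_init__(self) -> None:
        if self.kind is HostTypeKind.MONO and len(self.domains) != 1:
            raise ValueError("mono label needs exactly one domain")
        if self.kind is HostTypeKind.HETERO:
            if len(self.domains) < 2:
                raise ValueError("hetero label needs >= 2 domains")
            if not self.domains <= DEFINED_DOMAINS:
                raise ValueError("hetero label may contain only defined domains")
        if self.kind is HostTypeKind.UNDEFINED and self.domains:
            raise ValueError("undefined label carries no domains")

    def key(self) -> str:
        """Compact, deterministic string form, e.g. ``hetero(bacteria+eukaryota)``."""
        if self.kind is HostTypeKind.UNDEFINED:
            return "undefined"
        names = "+".join(sorted(d.value for d in self.domains))
        return f"{self.kind.value}({names})"

    @classmethod
    def mono(cls, domain: HostDomain) -> "HostTypeLabel":
        return cls(HostTypeKind.MONO, frozenset({domain}))

    @classmethod
    def hetero(cls, domains: frozenset[HostDomain] | set[HostDomain]) -> "HostTypeLabel":
        return cls(HostTypeKind.HETERO, frozenset(domains))

    @classmethod
    def undefined(cls) -> "HostTypeLabel":
        return cls(HostTypeKind.UNDEFINED, frozenset())


@dataclass(frozen=True)
class ClusterPair:
    """An unordered pair of distinct clusters linked by >= 1 structure hit."""

    cluster_a: str
    cluster_b: str
    evidence_count: int = 1

    def __post_init__(self) -> None:
        if self.cluster_a == self.cluster_b:
            raise ValueError("self-pairs are not allowed")
        if self.cluster_a > self.cluster_b:
            a, b = self.cluster_b, self.cluster_a
            object.__setattr__(self, "cluster_a", a)
            object.__setattr__(self, "cluster_b", b)
        if self.evidence_count < 1:
            raise ValueError("evidence_count must be positive")

    @property
    def key(self) -> tuple[str, str]:
        return (self.cluster_a, self.cluster_b)


@dataclass(frozen=True)
class ModelQuality:
    """Confidence scores of one predicted model (monomer or homodimer).

    pLDDT values live on the 0-100 scale; pTM/ipTM/pDockQ on 0-1. ipTM is
    only meaningful for homodimers and is required there.
    """

    model_id: str
    kind: str  # "monomer" | "homodimer"
    chain_mean_plddt: tuple[float, ...]
    mean_plddt: float
    ptm: float | None = None
    iptm: float | None = None
    pdockq: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("monomer", "homodimer"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        for v in (*self.chain_mean_plddt, self.mean_plddt):
            if not (0.0 <= v <= 100.0) or math.isnan(v):
                raise ValueError(f"{self.model_id}: pLDDT {v} outside [0, 100]")
        if self.kind == "homodimer" and self.iptm is None:
            raise ValueError(f"{self.model_id}: homodimer requires ipTM")
        if self.kind == "monomer" and self.iptm is not None:
            raise ValueError(f"{self.model_id}: monomer carries no ipTM")
        for name in ("ptm", "iptm", "pdockq"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.model_id}: {name}={v} outside [0, 1]")


class ConfidenceTier(enum.Enum):
    """Homodimer interface-confidence tier derived from ipTM."""

    NONE = "none"
    CONFIDENT = "confident"
    GOOD = "good"


@dataclass(frozen=True)
class OligoAnnotation:
    """Oligomeric-state annotation of one PDB chain in its assembly."""

    pdb_chain_id: str
    assembly_copies_of_chain: int
    distinct_chain_types_in_assembly: int

    def __post_init__(self) -> None:
        if self.assembly_copies_of_chain < 1:
            raise ValueError("assembly copies must be >= 1")
        if self.distinct_chain_types_in_assembly < 1:
            raise ValueError("distinct chain types must be >= 1")

    @property
    def state_label(self) -> str:
        return oligo_state_label(
            self.assembly_copies_of_chain, self.distinct_chain_types_in_assembly
        )


_HOMO_NAMES = {2: "homodimer", 3: "homotrimer", 4: "homotetramer",
               5: "homopentamer", 6: "homohexamer"}


def oligo_state_label(copies: int, distinct_chains: int) -> str:
    """Canonical state label from chain copy number and chain-type count.

    ``monomer`` when both are 1; ``homoN-mer`` style names when a single
    chain type occurs in several copies; ``hetero-N-mer`` (N = number of
    distinct chain types) otherwise.
    """
    if copies < 1 or distinct_chains < 1:
        raise ValueError("counts must be >= 1")
    if distinct_chains == 1:
        if copies == 1:
            return "monomer"
        return _HOMO_NAMES.get(copies, f"homo-{copies}-mer")
    return f"hetero-{distinct_chains}-mer"


@dataclass(frozen=True)
class OligoCall:
    """TM-score-weighted oligomeric-state call for one query (or cluster)."""

    query_id: str
    state_label: str | None
    weight_table: dict[str, float] = field(default_factory=dict, hash=False)
    homo_flag: bool = False
    hetero_flag: bool = False


@dataclass(frozen=True)
class GeneFeature:
    """One gene row of a genomic-context window.

    Coordinates are 1-based inclusive nucleotides; the intergenic distance
    between consecutive genes is ``start(next) - end(prev) - 1``.
    """

    context_id: str
    species_id: str
    order_index: int
    start: int
    end: int
    strand: str
    family_label: str
    is_target: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"{self.context_id}[{self.order_index}]: bad interval "
                f"({self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.order_index < 0:
            raise ValueError("order_index must be >= 0")


@dataclass(frozen=True)
class Neighborhood:
    """The ordered genes of one genomic window, containing >= 1 target."""

    context_id: str
    species_id: str
    genes: tuple[GeneFeature, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"{self.context_id}: empty neighborhood")
        starts = [g.start for g in self.genes]
        orders = [g.order_index for g in self.genes]
        if orders != sorted(orders) or len(set(orders)) != len(orders):
            raise ValueError(f"{self.context_id}: order_index not strictly increasing")
        if starts != sorted(starts):
            raise ValueError(f"{self.context_id}: genes not ordered by start")

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(g.family_label for g in self.genes)


@dataclass(frozen=True)
class Community:
    """A structure-similarity community with its annotation brightness."""

    community_id: str
    median_brightness: float
    member_count: int
    member_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.median_brightness <= 100.0):
            raise ValueError("median_brightness is a percentage in [0, 100]")
        if self.member_count < 1:
            raise ValueError("member_count must be positive")
        if self.member_ids and len(self.member_ids) != self.member_count:
            raise ValueError("member_count must equal |member_ids|")


@dataclass(frozen=True)
class PatternCandidate:
    """A candidate conserved gene pattern (length >= 2) with its support.

    ``freq`` is the fraction of contexts supporting the pattern under the
    full rule set (order, <= gap_max internal spacing, same strand, and no
    conserved out-of-pattern gene within flank_gap_min of an occurrence).
    ``occurrence_freq`` drops the flank conditions and is anti-monotone in
    pattern length. ``score = freq - best_extension_freq``.
    """

    families: tuple[str, ...]
    supporting_contexts: frozenset[str]
    species_support: int
    freq: float
    occurrence_freq: float
    best_extension_freq: float
    score: float

    def __post_init__(self) -> None:
        if len(self.families) < 2:
            raise ValueError("a pattern has >= 2 families")
        for v in (self.freq, self.occurrence_freq, self.best_extension_freq):
            if not (0.0 <= v <= 1.0):
                raise ValueError("frequencies live in [0, 1]")
        if not (-1.0 - 1e-12 <= self.score <= 1.0 + 1e-12):
            raise ValueError("score lives in [-1, 1]")
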