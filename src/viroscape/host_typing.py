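"""Host-domain assignment of viral proteins and host typing of clusters.

Each viral protein inherits the host(s) of its source virus through a
virus->host mapping table (virus taxid -> semicolon-delimited host lineage,
superkingdom first). A cluster of homologous proteins is then labelled
*monohost* when its defined-host members all come from viruses infecting a
single cellular domain, *heterohost* when a minority domain clears the
misannotation guard -- at least ``min_count`` proteins or ``min_fraction``
of the total cluster size, whichever is bigger -- and *host-undefined* only
when no member has a defined host.
"""
from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .types import (
    DEFINED_DOMAINS,
    ClusterRecord,
    HostDomain,
    HostOverride,
    HostTypeLabel,
    ProteinRecord,
)

logger = logging.getLogger(__name__)

_SUPERKINGDOMS = {
    "bacteria": HostDomain.BACTERIA,
    "archaea": HostDomain.ARCHAEA,
    "eukaryota": HostDomain.EUKARYOTA,
    "eukarya": HostDomain.EUKARYOTA,
    # a host that is itself a virus yields no defined cellular domain
    "viruses": HostDomain.UNDEFINED,
}


class LineageParseError(ValueError):
    """A host lineage string whose superkingdom rank cannot be interpreted."""


@dataclass(frozen=True)
class RecordError:
    """A per-record problem encountered while assigning hosts to a table."""

    protein_id: str
    virus_taxid: int | None
    message: str


def parse_lineage_domain(lineage: str) -> HostDomain:
    """Map a semicolon-delimited host lineage to its superkingdom domain.

    The superkingdom is the first rank of the lineage string. Host lineages
    rooted at *Viruses* resolve to :attr:`HostDomain.UNDEFINED`.
    """
    if lineage is None:
        raise LineageParseError("lineage is missing")
    first = str(lineage).split(";")[0].strip().lower()
    if not first:
        raise LineageParseError(f"empty lineage string: {lineage!r}")
    try:
        return _SUPERKINGDOMS[first]
    except KeyError:
        raise LineageParseError(
            f"unrecognized superkingdom {first!r} in lineage {lineage!r}"
        ) from None


def assign_host(
    virus_taxid: int | None,
    host_map: Mapping[int, Sequence[str]],
    overrides: Iterable[HostOverride] = (),
    virus_lineage: str | None = None,
) -> frozenset[HostDomain]:
    """Resolve the host domain(s) of one virus.

    Parameters
    ----------
    virus_taxid
        NCBI taxonomy id of the virus; ``None`` when the record lacks one.
    host_map
        virus_taxid -> list of host lineage strings (a virus may have
        several recorded hosts).
    overrides
        Manual curation rules keyed on the virus lineage *name*
        (case-insensitive exact match); they take precedence over the map.
    virus_lineage
        The virus's own lineage/organism name, used only for overrides.

    Returns
    -------
    frozenset of HostDomain; ``{UNDEFINED}`` when the taxid is missing,
    absent from the map, or every recorded host is itself a virus.
    """
    for ov in overrides:
        if ov.matches(virus_lineage):
            return frozenset({ov.forced_domain})
    if virus_taxid is None:
        return frozenset({HostDomain.UNDEFINED})
    lineages = host_map.get(virus_taxid)
    if not lineages:
        return frozenset({HostDomain.UNDEFINED})
    domains = {parse_lineage_domain(lin) for lin in lineages}
    defined = domains & DEFINED_DOMAINS
    if defined:
        return frozenset(defined)
    return frozenset({HostDomain.UNDEFINED})


def assign_hosts_table(
    proteins: pd.DataFrame,
    host_map: Mapping[int, Sequence[str]],
    overrides: Iterable[HostOverride] = (),
) -> tuple[dict[str, ProteinRecord], list[RecordError]]:
    """Assign hosts to every protein of a table; collect per-record errors.

    ``proteins`` needs columns ``protein_id`` and ``virus_taxid``
    (nullable); an optional ``virus_lineage`` column feeds the overrides.
    Malformed lineage strings yield a :class:`RecordError` for that row
    (the protein falls back to host-undefined) and processing continues.
    """
    overrides = tuple(overrides)
    records: dict[str, ProteinRecord] = {}
    errors: list[RecordError] = []
    has_lineage = "virus_lineage" in proteins.columns
    for row in proteins.itertuples(index=False):
        pid = str(row.protein_id)
        taxid = getattr(row, "virus_taxid", None)
        taxid = None if pd.isna(taxid) else int(taxid)
        lineage = str(row.virus_lineage) if has_lineage and not pd.isna(row.virus_lineage) else None
        try:
            domains = assign_host(taxid, host_map, overrides, lineage)
        except LineageParseError as exc:
            errors.append(RecordError(pid, taxid, str(exc)))
            domains = frozenset({HostDomain.UNDEFINED})
        records[pid] = ProteinRecord(pid, taxid, domains)
    if errors:
        logger.warning("host assignment: %d malformed records", len(errors))
    return records, errors


def heterohost_threshold(
    cluster_size: int, min_count: int = 3, min_fraction: float = 0.01
) -> int:
    """Minority-domain count needed to qualify: max(min_count, ceil(f*N)).

    The fractional part uses exact rational arithmetic so that e.g. 1% of
    300 is exactly 3, untouched by binary floating point.
    """
    frac = math.ceil(Fraction(str(min_fraction)) * cluster_size)
    return max(min_count, frac)


def count_domains(
    member_ids: Iterable[str], protein_records: Mapping[str, ProteinRecord]
) -> Counter:
    """Per-domain member counts; a multi-host protein counts once per domain."""
    counts: Counter = Counter()
    for pid in member_ids:
        try:
            rec = protein_records[pid]
        except KeyError:
            raise KeyError(f"member {pid!r} has no protein record") from None
        for d in rec.host_domains:
            if d in DEFINED_DOMAINS:
                counts[d] += 1
    return counts


def classify_cluster_host_type(
    cluster: ClusterRecord,
    protein_records: Mapping[str, ProteinRecord],
    min_count: int = 3,
    min_fraction: float = 0.01,
) -> HostTypeLabel:
    """Label a cluster mono-, hetero- or undefined-host.

    Let N be the total cluster size (undefined-host members included) and
    T = max(min_count, ceil(min_fraction * N)). Counting members per
    defined domain, the modal domain always qualifies (ties: all modal
    domains qualify); every other domain qualifies iff its count >= T. Two
    or more qualifying domains give a hetero label, one gives mono, and a
    cluster whose members are all host-undefined is labelled undefined.
    """
    if cluster.size == 0:  # unreachable via ClusterRecord, kept for raw use
        raise ValueError("empty cluster")
    counts = count_domains(cluster.member_ids, protein_records)
    if not counts:
        return HostTypeLabel.undefined()
    threshold = heterohost_threshold(cluster.size, min_count, min_fraction)
    modal_count = max(counts.values())
    qualifying = {
        d for d, c in counts.items() if c == modal_count or c >= threshold
    }
    if len(qualifying) >= 2:
        return HostTypeLabel.hetero(qualifying)
    return HostTypeLabel.mono(next(iter(qualifying)))


def classify_clusters(
    clusters: Iterable[ClusterRecord],
    protein_records: Mapping[str, ProteinRecord],
    min_count: int = 3,
    min_fraction: float = 0.01,
) -> dict[str, HostTypeLabel]:
    return {
        c.cluster_id: classify_cluster_host_type(c, protein_records, min_count, min_fraction)
        for c in clusters
    }


@dataclass(frozen=True)
class HostDistribution:
    """Cluster- and protein-level host-type distribution summary."""

    cluster_counts: pd.DataFrame  # columns: label, kind, count
    protein_table: pd.DataFrame  # columns: protein_id, protein_hosts, cluster_label
    heterohost_protein_fraction: float


def host_distribution(
    clusters: Sequence[ClusterRecord],
    labels: Mapping[str, HostTypeLabel],
    protein_records: Mapping[str, ProteinRecord],
) -> HostDistribution:
    """Tabulate host-type composition at cluster and protein level.

    Returns cluster counts per label, the per-protein (protein host,
    cluster host type) table behind the inner/outer ring view, and the
    fraction of proteins sitting in heterohost clusters.
    """
    label_counter: Counter = Counter()
    rows = []
    n_proteins = 0
    n_hetero = 0
    for cl in clusters:
        label = labels[cl.cluster_id]
        label_counter[label.key()] += 1
        is_het = label.kind.value == "hetero"
        for pid in cl.member_ids:
            rec = protein_records[pid]
            hosts = "+".join(sorted(d.value for d in rec.host_domains))
            rows.append((pid, hosts, label.key()))
            n_proteins += 1
            n_hetero += is_het
    cluster_counts = pd.DataFrame(
        sorted(label_counter.items()), columns=["label", "count"]
    )
    cluster_counts["kind"] = cluster_counts["label"].str.split("(").str[0]
    protein_table = pd.DataFrame(
        rows, columns=["protein_id", "protein_hosts", "cluster_label"]
    )
    fraction = n_hetero / n_proteins if n_proteins else 0.0
    return HostDistribution(cluster_counts, protein_table, fraction)
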