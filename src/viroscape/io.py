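"""Readers and writers for the pipeline's tabular dialects.

All tables are plain TSV. Structure-search results use the conventional
twelve-column tabular ("m8") layout, optionally extended with TM-score,
LDDT and coverage columns. Writing is deterministic: fixed column order,
``\\n`` line endings, ``%g``-style floats — so that identical inputs give
byte-identical files.
"""
from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .hit_filter import FilterPolicy
from .types import (
    ClusterLevel,
    ClusterRecord,
    Community,
    GeneFeature,
    HostDomain,
    HostOverride,
    Neighborhood,
)

#: the twelve standard columns of tabular search output; identity is a
#: fraction in [0, 1] (foldseek-style fident)
M8_COLUMNS = (
    "query", "target", "fident", "alnlen", "mismatch", "gapopen",
    "qstart", "qend", "tstart", "tend", "evalue", "bits",
)
M8_EXTRA_COLUMNS = ("alntmscore", "lddt", "qcov", "tcov")

NEIGHBORHOOD_COLUMNS = (
    "context_id", "species_id", "order_index", "start", "end", "strand",
    "family", "is_target",
)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV dump (no index, LF endings, trimmed floats)."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n",
              float_format="%.6g")


# ---------------------------------------------------------------- clusters

def read_cluster_table(
    path: str | Path, level: ClusterLevel | str = ClusterLevel.SEQUENCE
) -> list[ClusterRecord]:
    """Cluster membership TSV (cluster_id, protein_id, is_representative)."""
    if isinstance(level, str):
        level = ClusterLevel(level)
    df = pd.read_csv(path, sep="\t", dtype={"cluster_id": str, "protein_id": str})
    members: dict[str, list[str]] = defaultdict(list)
    reps: dict[str, str] = {}
    for row in df.itertuples(index=False):
        members[row.cluster_id].append(row.protein_id)
        if bool(row.is_representative):
            reps[row.cluster_id] = row.protein_id
    out = []
    for cid, mids in members.items():
        rep = reps.get(cid, mids[0])
        out.append(ClusterRecord(cid, level, tuple(mids), rep))
    return out


def write_cluster_table(clusters: Iterable[ClusterRecord], path: str | Path) -> None:
    rows = [
        (c.cluster_id, pid, pid == c.representative_id)
        for c in clusters
        for pid in c.member_ids
    ]
    write_tsv(
        pd.DataFrame(rows, columns=["cluster_id", "protein_id", "is_representative"]),
        path,
    )


def membership_map(clusters: Iterable[ClusterRecord]) -> dict[str, str]:
    """protein_id -> cluster_id over a clustering level."""
    out: dict[str, str] = {}
    for c in clusters:
        for pid in c.member_ids:
            if pid in out:
                raise ValueError(f"protein {pid!r} appears in two clusters")
            out[pid] = c.cluster_id
    return out


# ---------------------------------------------------------------- host map

def read_host_map(path: str | Path) -> dict[int, list[str]]:
    """Virus->host TSV (virus_taxid, host_lineage); multiple rows per taxid."""
    df = pd.read_csv(path, sep="\t", dtype={"virus_taxid": "Int64", "host_lineage": str})
    out: dict[int, list[str]] = defaultdict(list)
    for row in df.itertuples(index=False):
        if pd.isna(row.virus_taxid):
            continue
        out[int(row.virus_taxid)].append(row.host_lineage)
    return dict(out)


def write_host_map(host_map: Mapping[int, Sequence[str]], path: str | Path) -> None:
    rows = [(t, lin) for t in sorted(host_map) for lin in host_map[t]]
    write_tsv(pd.DataFrame(rows, columns=["virus_taxid", "host_lineage"]), path)


def read_overrides(path: str | Path) -> list[HostOverride]:
    """Host overrides from TSV (lineage, domain) or a YAML list of pairs."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
        items = [(d["lineage"], d["domain"]) for d in data]
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        items = list(zip(df["lineage"], df["domain"]))
    return [HostOverride(lineage, HostDomain(domain)) for lineage, domain in items]


# ---------------------------------------------------------------- hit tables

def read_m8(path: str | Path, extra_columns: Sequence[str] = ()) -> pd.DataFrame:
    """Headerless twelve-column search output plus optional appended columns.

    Appended columns beyond those named in ``extra_columns`` get generic
    ``extra<i>`` names; fewer than twelve columns is an error.
    """
    df = pd.read_csv(path, sep="\t", header=None)
    n = df.shape[1]
    if n < len(M8_COLUMNS):
        raise ValueError(f"{path}: {n} columns, expected >= {len(M8_COLUMNS)}")
    names = list(M8_COLUMNS) + list(extra_columns)
    names += [f"extra{i}" for i in range(n - len(names))]
    if len(names) != n:
        raise ValueError(
            f"{path}: {n} columns but {len(names)} names requested"
        )
    df.columns = names
    return df.astype({"query": str, "target": str})


def write_m8(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, header=False, lineterminator="\n",
              float_format="%.6g")


# ------------------------------------------------------------ neighborhoods

def read_neighborhoods(path: str | Path) -> list[Neighborhood]:
    """Genomic-context TSV, one gene per row, grouped into windows."""
    df = pd.read_csv(path, sep="\t", dtype={"context_id": str, "species_id": str,
                                            "family": str, "strand": str})
    out = []
    for (ctx, sp), sub in df.groupby(["context_id", "species_id"], sort=True):
        sub = sub.sort_values("order_index")
        genes = tuple(
            GeneFeature(
                context_id=ctx,
                species_id=sp,
                order_index=int(r.order_index),
                start=int(r.start),
                end=int(r.end),
                strand=r.strand,
                family_label=r.family,
                is_target=bool(r.is_target),
            )
            for r in sub.itertuples(index=False)
        )
        out.append(Neighborhood(ctx, sp, genes))
    return out


def write_neighborhoods(neighborhoods: Iterable[Neighborhood], path: str | Path) -> None:
    rows = [
        (g.context_id, g.species_id, g.order_index, g.start, g.end, g.strand,
         g.family_label, g.is_target)
        for nbh in sorted(neighborhoods, key=lambda n: (n.context_id, n.species_id))
        for g in nbh.genes
    ]
    write_tsv(pd.DataFrame(rows, columns=list(NEIGHBORHOOD_COLUMNS)), path)


def read_gff3_neighborhoods(
    path: str | Path,
    family_attribute: str = "family",
    target_attribute: str = "is_target",
    species_attribute: str = "species",
) -> list[Neighborhood]:
    """Genomic contexts from a GFF3 file (one context per seqid).

    Gene rows (type ``gene`` or ``CDS``) carry the family label, target
    flag and species in their attribute column.
    """
    records: defaultdict[tuple[str, str], list[GeneFeature]] = defaultdict(list)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in ("gene", "CDS"):
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if family_attribute not in attr:
                raise ValueError(f"GFF3 row lacks {family_attribute!r}: {line!r}")
            species = attr.get(species_attribute, seqid)
            key = (seqid, species)
            records[key].append(
                GeneFeature(
                    context_id=seqid,
                    species_id=species,
                    order_index=len(records[key]),
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    family_label=attr[family_attribute],
                    is_target=attr.get(target_attribute, "false").lower()
                    in ("1", "true", "yes"),
                )
            )
    out = []
    for (ctx, sp), genes in sorted(records.items()):
        genes = sorted(genes, key=lambda g: g.start)
        genes = tuple(
            GeneFeature(g.context_id, g.species_id, i, g.start, g.end, g.strand,
                        g.family_label, g.is_target)
            for i, g in enumerate(genes)
        )
        out.append(Neighborhood(ctx, sp, genes))
    return out


# ------------------------------------------------------------- annotations

def read_oligo_annotations(path: str | Path) -> pd.DataFrame:
    """Chain oligostate TSV (pdb_chain_id, copies, distinct_chains)."""
    return pd.read_csv(path, sep="\t", dtype={"pdb_chain_id": str})


def read_communities(path: str | Path) -> list[Community]:
    """Community metadata TSV (community_id, median_brightness, member_count)."""
    df = pd.read_csv(path, sep="\t", dtype={"community_id": str})
    return [
        Community(r.community_id, float(r.median_brightness), int(r.member_count))
        for r in df.itertuples(index=False)
    ]


def read_scores(path: str | Path) -> pd.DataFrame:
    """Model score table (model_id, ptm, iptm, pdockq, mean_plddt) as TSV/JSON."""
    path = Path(path)
    if path.suffix == ".json":
        return pd.read_json(path)
    return pd.read_csv(path, sep="\t", dtype={"model_id": str})


def read_policies(path: str | Path) -> dict[str, FilterPolicy]:
    """Named hit-filter policies from a YAML mapping."""
    data = yaml.safe_load(Path(path).read_text())
    out = {}
    for name, block in data.items():
        out[name] = FilterPolicy(
            name=name,
            tm_min=block["tm_min"],
            evalue_max=block.get("evalue_max"),
            avg_cov_min=block["avg_cov_min"],
            cluster_tm_min=block["cluster_tm_min"],
            intracluster_alnlen_min=block.get("intracluster_alnlen_min"),
        )
    return out
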