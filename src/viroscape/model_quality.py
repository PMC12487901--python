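"""Model-confidence parsing and triage for predicted structures.

Predicted models store per-residue pLDDT in the coordinate B-factor field;
homodimer predictions additionally carry pTM/ipTM scores in a side table.
This module extracts per-chain and overall mean pLDDT from PDB files,
tiers homodimers by ipTM (>= 0.5 "confident", >= 0.8 "good"), flags
dimer-over-monomer pLDDT gains (max across the two chains, strict > 5
units by default), and summarises matched-pair comparisons against another
model database.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gemmi

from .types import ConfidenceTier, ModelQuality


def mean_plddt_from_model(model_file: str | Path) -> tuple[list[float], float]:
    """Per-chain and overall mean pLDDT of a predicted model.

    Reads the B-factor column of a PDB file. Per chain, the mean is taken
    over C-alpha atoms (one value per residue); chains without any
    C-alpha fall back to all atoms. The overall mean is over all residues
    of all chains, not a mean of chain means.

    Raises
    ------
    ValueError
        If the file contains no atoms.
    """
    structure = gemmi.read_structure(str(model_file))
    if not structure or not len(structure[0]):
        raise ValueError(f"{model_file}: model contains no chains")
    chain_means: list[float] = []
    residue_values: list[float] = []
    for chain in structure[0]:
        values: list[float] = []
        for residue in chain:
            ca = residue.find_atom("CA", "*")
            if ca is not None:
                values.append(ca.b_iso)
            elif len(residue):
                values.append(sum(a.b_iso for a in residue) / len(residue))
        if not values:
            continue
        chain_means.append(sum(values) / len(values))
        residue_values.extend(values)
    if not residue_values:
        raise ValueError(f"{model_file}: no atom records with B-factors")
    return chain_means, sum(residue_values) / len(residue_values)


def quality_from_model(
    model_file: str | Path,
    model_id: str,
    kind: str = "monomer",
    ptm: float | None = None,
    iptm: float | None = None,
    pdockq: float | None = None,
) -> ModelQuality:
    """Build a :class:`ModelQuality` from a model file plus score-table values."""
    chain_means, overall = mean_plddt_from_model(model_file)
    return ModelQuality(
        model_id=model_id,
        kind=kind,
        chain_mean_plddt=tuple(chain_means),
        mean_plddt=overall,
        ptm=ptm,
        iptm=iptm,
        pdockq=pdockq,
    )


def tier_homodimer(
    mq: ModelQuality, confident_min: float = 0.5, good_min: float = 0.8
) -> ConfidenceTier:
    """ipTM tier of a homodimer: good >= 0.8, confident >= 0.5, else none.

    Boundaries are inclusive; every good model is also confident.
    """
    if mq.kind != "homodimer":
        raise ValueError(f"{mq.model_id}: tiering applies to homodimers")
    if mq.iptm is None:
        raise ValueError(f"{mq.model_id}: ipTM missing")
    if mq.iptm >= good_min:
        return ConfidenceTier.GOOD
    if mq.iptm >= confident_min:
        return ConfidenceTier.CONFIDENT
    return ConfidenceTier.NONE


@dataclass(frozen=True)
class DimerGain:
    """pLDDT gain of a homodimer over its monomer prediction."""

    model_id: str
    gain: float
    flagged: bool


def dimer_gain(
    monomer_mq: ModelQuality, dimer_mq: ModelQuality, delta: float = 5.0
) -> DimerGain:
    """Gain = max(dimer chain mean pLDDTs) - monomer mean; flag iff gain > delta.

    The comparison is strict, so a gain of exactly ``delta`` is not
    flagged. The dimer must have exactly two chains.
    """
    if dimer_mq.kind != "homodimer":
        raise ValueError(f"{dimer_mq.model_id}: second argument must be a homodimer")
    if len(dimer_mq.chain_mean_plddt) != 2:
        raise ValueError(
            f"{dimer_mq.model_id}: homodimer must have 2 chains, "
            f"found {len(dimer_mq.chain_mean_plddt)}"
        )
    gain = max(dimer_mq.chain_mean_plddt) - monomer_mq.mean_plddt
    return DimerGain(monomer_mq.model_id, gain, gain > delta)


@dataclass(frozen=True)
class MatchedPairSummary:
    """Summary of a matched-pair pLDDT comparison between two databases."""

    n_pairs: int
    frac_higher: float  # fraction with our pLDDT strictly higher
    frac_gain_over_delta: float  # fraction with difference > delta


def matched_pair_compare(
    pairs: Sequence[tuple[float, float]] | Iterable[tuple[float, float]],
    delta: float = 5.0,
) -> MatchedPairSummary:
    """Compare matched model pairs (ours, theirs) by mean pLDDT.

    ``pairs`` must already be restricted to near-identical protein matches
    (the matching itself happens upstream of this package). Returns the
    fraction where our model scores strictly higher and the fraction where
    it scores more than ``delta`` pLDDT units higher.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("matched-pair comparison needs at least one pair")
    n = len(pairs)
    higher = sum(1 for ours, theirs in pairs if ours > theirs)
    over = sum(1 for ours, theirs in pairs if ours - theirs > delta)
    return MatchedPairSummary(n, higher / n, over / n)
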