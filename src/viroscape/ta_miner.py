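"""Mining conserved bicistronic gene patterns with toxin-antitoxin traits.

Type II toxin-antitoxin (TA) systems are small bicistronic operons: two
closely spaced co-transcribed genes conserved together across genomes.
Starting from genomic-context windows around target proteins of poorly
annotated ("dark") structure communities, the miner screens for such
patterns with four rules:

(i)   the genes of a pattern appear in a fixed order (contiguous run);
(ii)  intergenic distances inside the pattern are at most ``gap_max``
      (100 nt), while conserved genes outside the pattern must sit more
      than ``flank_gap_min`` (100 nt) away from any occurrence;
(iii) neighborhood conservation is restricted to the pattern's genes --
      operationalised through the same flank-distance rule, with
      "conserved" meaning present in at least ``presence_min`` (50%) of
      contexts;
(iv)  the pattern's frequency advantage over its best single-gene
      extension -- ``score = freq(P) - max_ext freq(P+1 gene)`` -- ranks
      the candidates.

Only contexts drawn from at least ``min_species`` (6) distinct species are
screened, and a candidate must keep that many distinct supporting species.
Pattern genes are required on the same strand by default (operonic
reading); this is configurable.

Note that the flank-inclusive frequency is not anti-monotone in pattern
length: a conserved gene 50 nt downstream of a pair kills the pair's
support but not the triple's. The plain occurrence frequency (rules i-ii
only) is anti-monotone and is reported alongside.
"""
from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

from .types import Community, GeneFeature, Neighborhood, PatternCandidate


def prefilter_communities(
    communities: Iterable[Community],
    brightness_max: float = 5.0,
    min_members: int = 5,
) -> list[Community]:
    """Dark communities worth screening: median functional brightness
    strictly below ``brightness_max`` percent and at least ``min_members``
    protein members."""
    return [
        c
        for c in communities
        if c.median_brightness < brightness_max and c.member_count >= min_members
    ]


def species_gate(
    neighborhoods: Sequence[Neighborhood], min_species: int = 6
) -> list[Neighborhood]:
    """All-or-nothing gate on species diversity.

    The full set passes iff it spans at least ``min_species`` distinct
    species; otherwise nothing is screened and an empty list returns.
    """
    species = {n.species_id for n in neighborhoods}
    if len(species) >= min_species:
        return list(neighborhoods)
    return []


def intergenic_distance(prev: GeneFeature, nxt: GeneFeature) -> int:
    """Nucleotides between two genes: start(next) - end(prev) - 1.

    Negative for overlapping genes.
    """
    return nxt.start - prev.end - 1


def pattern_occurrences(
    neighborhood: Neighborhood,
    families: Sequence[str],
    gap_max: int = 100,
    same_strand: bool = True,
) -> list[tuple[int, tuple[GeneFeature, ...]]]:
    """All runs of consecutive genes matching ``families`` in order.

    A run qualifies when every internal intergenic distance is at most
    ``gap_max`` nucleotides and (by default) all genes share a strand.
    Returns (start index, genes) per occurrence.
    """
    k = len(families)
    if k < 2:
        raise ValueError("a pattern has at least two families")
    genes = neighborhood.genes
    out: list[tuple[int, tuple[GeneFeature, ...]]] = []
    for i in range(len(genes) - k + 1):
        run = genes[i : i + k]
        if tuple(g.family_label for g in run) != tuple(families):
            continue
        if same_strand and len({g.strand for g in run}) > 1:
            continue
        if any(
            intergenic_distance(run[j], run[j + 1]) > gap_max for j in range(k - 1)
        ):
            continue
        out.append((i, run))
    return out


def conservation_profile(
    neighborhoods: Sequence[Neighborhood], presence_min: float = 0.5
) -> set[str]:
    """Families present in at least ``presence_min`` (inclusive) of contexts."""
    if not neighborhoods:
        return set()
    presence: defaultdict[str, int] = defaultdict(int)
    for nbh in neighborhoods:
        for fam in set(nbh.families):
            presence[fam] += 1
    n = len(neighborhoods)
    return {fam for fam, c in presence.items() if c / n >= presence_min}


def _distance_to_span(gene: GeneFeature, span_start: int, span_end: int) -> int:
    """Nucleotide gap between a gene and a coordinate span (0 if touching
    or overlapping)."""
    if gene.end < span_start:
        return span_start - gene.end - 1
    if gene.start > span_end:
        return gene.start - span_end - 1
    return 0


def _context_supports(
    neighborhood: Neighborhood,
    families: Sequence[str],
    conserved: set[str],
    gap_max: int,
    flank_gap_min: int,
    same_strand: bool,
) -> bool:
    """Does this context support the pattern under the full rule set?

    True iff some occurrence exists such that every gene of a conserved
    family outside the pattern lies strictly more than ``flank_gap_min``
    nucleotides from the occurrence span.
    """
    fam_set = set(families)
    outside = [
        g for g in neighborhood.genes
        if g.family_label in conserved and g.family_label not in fam_set
    ]
    for _i, run in pattern_occurrences(neighborhood, families, gap_max, same_strand):
        span_start, span_end = run[0].start, run[-1].end
        if all(
            _distance_to_span(g, span_start, span_end) > flank_gap_min
            for g in outside
        ):
            return True
    return False


def _enumerate_tuples(
    neighborhoods: Sequence[Neighborhood], min_len: int, max_len: int
) -> set[tuple[str, ...]]:
    """All contiguous family tuples of the given lengths observed anywhere."""
    tuples: set[tuple[str, ...]] = set()
    for nbh in neighborhoods:
        fams = nbh.families
        for k in range(min_len, max_len + 1):
            for i in range(len(fams) - k + 1):
                tuples.add(fams[i : i + k])
    return tuples


def mine_patterns(
    neighborhoods: Sequence[Neighborhood],
    gap_max: int = 100,
    flank_gap_min: int = 100,
    presence_min: float = 0.5,
    min_species: int = 6,
    max_len: int = 4,
    same_strand: bool = True,
) -> list[PatternCandidate]:
    """Rank candidate conserved gene patterns anchored on target genes.

    Enumerates every in-order contiguous family tuple of length 2..max_len
    that includes the family of a target gene; computes its support
    frequency over contexts under the full rule set; scores it against its
    best single-gene extension; and returns candidates with at least
    ``min_species`` distinct supporting species, ranked by score
    descending, then frequency, then shorter length, then lexicographic
    family tuple. No qualifying candidate -> empty list.
    """
    neighborhoods = species_gate(neighborhoods, min_species)
    if not neighborhoods:
        return []
    n_contexts = len(neighborhoods)
    conserved = conservation_profile(neighborhoods, presence_min)
    target_families = {
        g.family_label for nbh in neighborhoods for g in nbh.genes if g.is_target
    }
    if not target_families:
        return []

    candidates = {
        t
        for t in _enumerate_tuples(neighborhoods, 2, max_len)
        if target_families & set(t)
    }
    # extensions of candidates may exceed max_len by one
    extension_pool = _enumerate_tuples(neighborhoods, 3, max_len + 1)

    support_cache: dict[tuple[str, ...], tuple[frozenset[str], float]] = {}

    def support(families: tuple[str, ...]) -> tuple[frozenset[str], float]:
        if families not in support_cache:
            ctx = frozenset(
                nbh.context_id
                for nbh in neighborhoods
                if _context_supports(
                    nbh, families, conserved, gap_max, flank_gap_min, same_strand
                )
            )
            support_cache[families] = (ctx, len(ctx) / n_contexts)
        return support_cache[families]

    def occurrence_freq(families: tuple[str, ...]) -> float:
        n = sum(
            1
            for nbh in neighborhoods
            if pattern_occurrences(nbh, families, gap_max, same_strand)
        )
        return n / n_contexts

    species_of = {nbh.context_id: nbh.species_id for nbh in neighborhoods}

    results: list[PatternCandidate] = []
    for families in candidates:
        ctx, freq = support(families)
        if not ctx:
            continue
        n_species = len({species_of[c] for c in ctx})
        if n_species < min_species:
            continue
        k = len(families)
        best_ext = 0.0
        for ext in extension_pool:
            if len(ext) != k + 1:
                continue
            if ext[:k] == families or ext[1:] == families:
                best_ext = max(best_ext, support(ext)[1])
        results.append(
            PatternCandidate(
                families=families,
                supporting_contexts=ctx,
                species_support=n_species,
                freq=freq,
                occurrence_freq=occurrence_freq(families),
                best_extension_freq=best_ext,
                score=freq - best_ext,
            )
        )
    results.sort(key=lambda c: (-c.score, -c.freq, len(c.families), c.families))
    return results
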