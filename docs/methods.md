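# Methods

This note documents the models and procedures viroscape implements, the
parameters that matter, the synthetic study conditions the test suite
runs under, and the design choices made where the rules left room.

## Host assignment and cluster host typing

A viral protein's host domain is the superkingdom (first rank) of the
host lineage its source virus maps to in a virus–host table. Three cases
yield *host undefined*: no taxonomy id on the record, a taxid absent from
the mapping, and a recorded host that is itself a virus (virophages,
phage satellites). A virus with hosts in several domains contributes one
count to each domain — the mapping can legitimately list several hosts,
and collapsing to a "primary" host would require information the table
does not carry. Manual curation overrides are matched on the virus
lineage name, exact and case-insensitive, and take precedence over the
mapping.

A cluster of N members (undefined-host members included in N) is labelled
from its per-domain counts with the minority threshold

    T = max(min_count, ⌈min_fraction · N⌉),  defaults min_count = 3,
    min_fraction = 0.01.

The modal defined domain always qualifies; a non-modal domain qualifies
iff its count ≥ T. Two or more qualifying domains ⇒ heterohost; exactly
one ⇒ monohost; no defined domain at all ⇒ host undefined. The threshold
exists to keep isolated host misannotations from inflating heterohost
counts; it is a count in whole proteins, so the 1 % term is a ceiling.
The ceiling is evaluated in exact rational arithmetic: in binary floating
point `0.01 * 300` is slightly above 3 and would otherwise push the
threshold to 4 for clusters of exactly 300.

Two tie/edge decisions are deliberate: when two domains share the modal
count, both qualify (the label is heterohost) — the symmetric choice is
the only deterministic one that does not privilege an arbitrary domain;
and only defined domains can ever qualify, while undefined members still
count toward N.

## Cluster-to-cluster relationships and transitions

Hits are treated as undirected: a relationship between clusters is
symmetric, so pairs are stored with a canonical ordering, self-hits and
within-cluster hits are discarded, and the count of supporting hits is
kept as evidence. No score thresholds are applied here — thresholding
belongs to hit generation or to the filtering module, which keeps the
counting a pure set operation and makes the structure/sequence gain ratio
well defined on any pair of hit tables over the same cluster universe.
An empty sequence-level pair set makes the ratio infinite; this is
reported with an explicit flag rather than an exception.

The transition table is a per-protein cross-tabulation of host-type
labels between the sequence and structure clustering levels. Proteins
present at only one level land in an `unpaired` margin with a logged
warning, so the margins always conserve protein counts.

## Model confidence

Per-residue pLDDT (0–100) is read from the B-factor column of PDB files,
one Cα per residue; chains without Cα atoms fall back to the mean over
all atoms of each residue. The overall mean is over residues, not a mean
of chain means, so chains of unequal length are weighted by their length.

Homodimer confidence tiers use ipTM with inclusive boundaries: ≥ 0.8
*good*, ≥ 0.5 *confident*, else none — "thresholds set to x" is read as
the cutoff being attained; the boundaries are parameters for anyone who
wants them strict. The dimer-over-monomer gain is
`max(chain means of the dimer) − monomer mean`, flagged when strictly
greater than 5 pLDDT units; the max makes the gain invariant under chain
order, and the strict inequality means a gain of exactly 5 is not
flagged. Matched-pair database comparisons report the fraction of pairs
where our model's mean pLDDT is strictly higher and the fraction where
the difference exceeds 5 units; the second is necessarily ≤ the first.
pDockQ values are carried through from upstream score tables, never
computed.

## Oligomeric-state inference

Hits of a query (or of all members of a cluster, in cluster mode) to
annotated PDB chains are thresholded at TM ≥ 0.5 — the conventional
same-fold cutoff — and the surviving hits vote with their TM-score as
weight, summed per state label. The winning label is the weight argmax;
ties break by number of supporting hits, then lexicographically — a
deterministic order chosen because weighted voting alone does not define
one. State labels derive from the annotation's (copies, distinct chain
types) pair: `monomer` for (1, 1), `homodimer`/`homotrimer`/… for a
single chain type in several copies, `hetero-N-mer` with N distinct chain
types otherwise. Independently, the homo-flag records any hit chain with
copies > 1 and the hetero-flag any hit assembly with more than one chain
type; the flags are a union over hits and can both hold. Plain TM-score
summation is used, with no per-state normalisation by hit count: the
weighted vote is a "most common state" weighted by similarity, and
normalising would reduce it to a best-single-hit rule.

## Hit filtering

Per query, the kept hit maximises identity fraction × query coverage
(ties: higher TM-score, then smaller target id). A policy then applies
strict inequalities: TM-score, optional E-value, average alignment
coverage, cluster-average TM-score, optional intracluster alignment
length. Three named policies ship: the defense screen (TM > 0.65,
E < 1e-3, coverage > 0.6, cluster TM > 0.5) and the two antidefense
screens (coverage > 0.5, cluster TM > 0.5, intracluster alignment length
> 100, with the E-value bound applying to one source and dropped for the
other, which is searched without E-values).

Two terms needed operational definitions. *Average alignment coverage*
is the mean of query and target coverage — the two coverages are what
search tools emit per hit, and their mean is the symmetric summary.
*Cluster average TM-score* and *intracluster alignment length* are means
over all hits from members of the query's structural cluster to the same
target model; hits whose cluster lacks such statistics fail the
cluster-level criteria (with a warning) rather than passing by default.
All bounds are strict because the screen definitions use strict
inequality symbols throughout; this makes filtering monotone (tightening
any bound can only shrink the surviving set) and idempotent.

## TA-candidate pattern mining

Screening starts from dark structure communities (median functional
brightness < 5 %, ≥ 5 members) and genomic-context windows around target
proteins; only window sets spanning ≥ 6 distinct species are screened at
all (an all-or-nothing gate — the point is cross-species conservation,
and fewer species cannot establish it).

A pattern is an ordered tuple of ≥ 2 gene-family labels containing at
least one target gene's family. An *occurrence* in a context is a run of
consecutive genes matching the tuple in order, all on one strand (operons
are co-transcribed; the strand requirement can be switched off), with
every internal intergenic distance ≤ 100 nt. Intergenic distance is
`start(next) − end(prev) − 1` on 1-based inclusive coordinates, negative
for overlapping genes; the ≤ comparison therefore admits overlaps.

A family is *conserved* when present in ≥ 50 % of contexts (inclusive;
configurable) — "conserved" had to be quantified somewhere, and presence
in half the windows is the natural majority reading. A context *supports*
a pattern when some occurrence has every gene of a conserved out-of-pattern
family strictly more than 100 nt away from the occurrence span. This
single distance rule operationalises both the "conserved genes outside
the pattern should be far" requirement and the "conservation restricted
to the pattern" criterion, and it applies to all conserved out-of-pattern
genes in the window, not only those adjacent to the occurrence.

`freq(P)` is supporting contexts over total contexts (contexts, not
species, as denominator; the distinct supporting-species count is
reported separately and gates candidates at ≥ 6). The score is

    score(P) = freq(P) − max over one-gene left/right extensions of freq,

a global ranking across the context set: a self-contained bicistron keeps
a high score because no extension of it is ever valid, while a pattern
that is really a fragment of a longer conserved module is cancelled by
its extension's frequency. Candidates are ranked by score, then
frequency, then shorter length, then lexicographic families.

One property deserves a caveat: the flank-inclusive `freq` is **not**
anti-monotone in pattern length — a conserved gene 50 nt downstream of a
pair suppresses the pair's support but not the triple's, which is exactly
the behaviour that shifts the call from (X, Y) to (X, Y, Z). The plain
occurrence frequency (order + spacing + strand only) *is* anti-monotone,
is exposed on every candidate as `occurrence_freq`, and is the quantity
the anti-monotonicity property tests assert.

## Synthetic study conditions

The generators are pure functions of a `SimConfig`; the same config and
seed give byte-identical tables, and each generator draws from its own
seed substream so changing one table's parameters never perturbs another.

*Cluster tables* (default 60 clusters, mean size 12, two 400-member
clusters to exercise the 1 %-of-N branch): per-protein host mixture
79.9 % bacteria, 15.4 % eukaryota, 1.1 % archaea, 3.6 % undefined — the
host distribution observed in the real protein set. 30 % of defined-host
clusters receive a minority injection sized exactly at, or one below, the
heterohost threshold of the final cluster size (50/50), so the truth
labels probe the boundary rather than easy cases. Undefined viruses are
split between missing mapping rows and hosts recorded as viruses.

*Oligostate hits* (default 500 queries): each query's true state emits
Poisson(4)+2 hits with TM ~ N(0.78, 0.05) against two decoy states with
Poisson(1.5) hits at TM ~ N(0.62, 0.05), clipped to (0.05, 0.99). The
true state's expected summed weight (≈ 4.7) dominates each decoy's
(≈ 0.9), so weighted voting recovers the truth for ≈ 99 % of queries; the
residual errors are queries whose decoy draw happens to outweigh a thin
true-hit draw, which is the intended hard case.

*Genomic contexts* (default 20 contexts over 8 species): each window is
1–3 decoy genes, the planted same-strand bicistron (internal gap uniform
on [0, 100] nt, first gene flagged as target), and 1–3 more decoys, with
all flank gaps uniform on [150, 400] nt. Decoy families are drawn
per-context from a 40-family pool, so no decoy becomes conserved at 20
contexts. `conserved_flank=(family, gap)` plants an additional conserved
gene right after the pattern in every context for the adversarial
variant. Setting `assert_recoverable=True` makes configurations that
violate the recovery preconditions (internal gaps beyond 100 nt, flanks
within 100 nt, fewer than 6 species) a configuration error; without it
they are legal conditions used to demonstrate the failure modes.

What the generators do **not** emulate: real sequence or structure
content (models are minimal Cα stubs carrying pLDDT), overlapping gene
annotations, unequal context lengths per species, correlated host
misannotation, or hit-score correlations beyond the state-dependent TM
means. Passing tests therefore demonstrate that the rules are implemented
exactly and recover planted signal under clean conditions — not that the
thresholds are optimal for noisy real annotations.

## Numerical and degenerate-input choices

Thresholds that compare floats to stated cutoffs use the cutoffs exactly
(inclusive for ipTM tiers, strict for the filter policies and the 5-unit
gain). Empty inputs are errors where a summary would be meaningless
(matched pairs, models without atoms, empty clusters) and empty results
where "nothing found" is an answer (pattern mining, hit filtering). All
rankings specify total orders (documented tie-breaks), so every output is
deterministic and invariant to input order. Problem sizes in the test
suite and acceptance script (≤ 30-member exhaustive compositions, 500
oligostate queries, 100 mining instances, 100 recovery runs) are chosen
so the complete check runs in well under a minute each on one CPU while
leaving the binomial margins of the recovery assertions comfortable.

## Known limitations

- Host resolution stops at the superkingdom rank; finer host taxonomy is
  neither stored nor needed by the rules.
- The GFF3 reader expects one context per seqid with family/target/species
  carried in attributes; it is a convenience for GCsnap-style exports,
  not a general GFF3 engine.
- Cluster-mode oligostate calls pool hits uniformly over members; no
  per-member weighting is attempted.
- The miner enumerates contiguous patterns only; interleaved conserved
  pairs (with foreign genes inside) are out of scope by construction,
  since the ≤ 100-nt internal spacing rule effectively forces adjacency.
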