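# viroscape

Downstream analysis for large viral protein structure datasets: host-domain
typing of protein clusters, sequence-vs-structure clustering comparison,
model-confidence triage, oligomeric-state inference from structure-search
hits, defense/antidefense hit filtering, and mining of conserved
bicistronic gene patterns with toxin–antitoxin characteristics.

It is written for structural bioinformaticians who already have the heavy
artifacts — sequence/structure cluster files, all-vs-all and database
structure-search hit tables (m8), predicted models with per-residue pLDDT
in the B-factor field, virus→host mapping tables, genomic-context tables —
and need the reproducible analysis layer on top of them. Seeded synthetic
generators emulate every input table with planted ground truth, so the
whole pipeline is testable at desk scale.

## What it computes

**Host typing.** Each viral protein inherits the host superkingdom
(bacteria, archaea, eukaryota) of its source virus via a virus–host
mapping; viruses without a mapping, without a taxid, or recorded as
infecting other viruses are *host undefined*. A cluster of N homologous
proteins is **heterohost** when a minority host domain reaches

```
T = max(min_count, ⌈min_fraction · N⌉)        (defaults: 3 and 1%)
```

members — a guard against isolated host misannotations; otherwise it is
**monohost** of its modal domain, or **host undefined** when no member has
a defined host.

**Cluster comparison.** Unique unordered cluster-to-cluster relationships
implied by a hit table (self- and within-cluster hits excluded), the
structure/sequence relationship-gain ratio, and a per-protein transition
table of host-type labels between the two clustering levels.

**Model confidence.** Per-chain and overall mean pLDDT from PDB files
(Cα B-factors); homodimer tiers by ipTM (≥ 0.5 *confident*, ≥ 0.8 *good*);
dimer-over-monomer gains (max across the two chains, flagged when
strictly > 5 pLDDT units); matched-pair database comparisons (fraction of
models scoring higher, fraction gaining > 5 units).

**Oligomeric state.** Hits to annotated PDB chains below TM-score 0.5 are
discarded; remaining hits vote with their TM-score as weight and the
state with the largest summed weight wins (ties: more supporting hits,
then lexicographic label). A query is homo-oligomeric if any hit chain
occurs more than once in its assembly, hetero-oligomeric if any hit
assembly mixes chain types.

**Hit filtering.** Per query, the hit maximising identity × query
coverage is kept, then a named policy of strict thresholds is applied —
e.g. the defense-system screen (TM > 0.65, E < 1e-3, mean(qcov, tcov) >
0.6, cluster-average TM > 0.5) or the antidefense screen (coverage > 0.5,
intracluster alignment length > 100, E-value bound for one of the two
sources only), with the two antidefense sources merged by best TM-score
per query.

**TA-candidate mining.** Within genomic-context windows from ≥ 6 species,
candidate gene patterns must occur in fixed order on one strand with
internal intergenic gaps ≤ 100 nt, keep conserved out-of-pattern genes
> 100 nt away, and are scored by `freq(P) − max` over one-gene extensions
of `freq` — the signature of a self-contained bicistronic module.

## Worked example

Generate a synthetic dataset and run the pipeline:

```
$ viroscape simulate --seed 42 --out demo
$ viroscape classify-clusters --clusters demo/clusters.tsv \
      --hosts demo/hostmap.tsv --proteins demo/proteins.tsv -o demo/labels.tsv
wrote 60 cluster labels to demo/labels.tsv
$ head -4 demo/labels.tsv
cluster_id      kind    label
SC00000 hetero  hetero(bacteria+eukaryota)
SC00001 mono    mono(bacteria)
SC00002 mono    mono(eukaryota)
```

`SC00000` is a 400-member bacterial cluster carrying a 5-protein
eukaryotic minority: 5 ≥ max(3, ⌈1% · 405⌉) = 5, so it is heterohost;
a 4-member minority would have left it mono(bacteria).

```
$ viroscape mine-ta --neighborhoods demo/neighborhoods.tsv -o demo/candidates.tsv
1 pattern candidates
$ head -2 demo/candidates.tsv
families        freq    best_extension_freq     score   species_support context_support
toxin_cand|antitoxin_cand       1       0       1       8       20
```

The planted bicistron is the only candidate: present in all 20 contexts
(freq 1), no extension is ever valid (score 1), supported by all 8
species.

```
$ viroscape oligostate --hits demo/oligo_hits.m8 \
      --annotations demo/oligo_annotations.tsv -o demo/states.tsv
wrote 500 state calls to demo/states.tsv
$ head -3 demo/states.tsv
query   state   homo_flag       hetero_flag
Q00000  homotrimer      True    False
Q00001  homotrimer      True    False
```

Each call is the TM-weighted modal state of that query's hits;
`homo_flag` records that the hit chains occur multiple times in their
assemblies.

The same functionality is available as a library
(`viroscape.classify_cluster_host_type`, `viroscape.mine_patterns`,
`viroscape.infer_state`, …); see the docstrings and `docs/methods.md`.

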