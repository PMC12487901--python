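"""Conserved bicistronic-pattern mining: rules, oracle and planted recovery."""
import numpy as np
import pytest

from conftest import oracle_mine, random_neighborhoods
from viroscape.synthetic_data import SimConfig, gen_neighborhoods
from viroscape.ta_miner import (
    conservation_profile,
    intergenic_distance,
    mine_patterns,
    pattern_occurrences,
    prefilter_communities,
    species_gate,
)
from viroscape.types import Community, GeneFeature, Neighborhood


def nbh(gene_rows, ctx="c1", sp="s1"):
    """Build a neighborhood from (family, start, end, strand, is_target)."""
    genes = tuple(
        GeneFeature(ctx, sp, i, start, end, strand, fam, tgt)
        for i, (fam, start, end, strand, tgt) in enumerate(gene_rows)
    )
    return Neighborhood(ctx, sp, genes)


class TestPrefilterCommunities:
    @pytest.mark.parametrize(
        "brightness, members, kept",
        [
            (4.9, 5, True),
            (5.0, 5, False),  # strictly below 5%
            (1.0, 4, False),  # too few members
            (0.0, 100, True),
        ],
    )
    def test_dark_and_large_enough(self, brightness, members, kept):
        c = Community("comm1", brightness, members)
        assert (prefilter_communities([c]) == [c]) is kept


class TestSpeciesGate:
    def _contexts(self, n_species, n_contexts=10):
        return [
            nbh([("x", 1, 300, "+", True)], ctx=f"c{i}", sp=f"s{i % n_species}")
            for i in range(n_contexts)
        ]

    def test_enough_species_pass_all(self):
        nbhs = self._contexts(8)
        assert species_gate(nbhs) == nbhs

    def test_too_few_species_pass_nothing(self):
        assert species_gate(self._contexts(5)) == []

    def test_species_counted_once(self):
        # 12 contexts over exactly 6 species still passes
        assert len(species_gate(self._contexts(6, 12))) == 12


class TestPatternOccurrences:
    def test_gap_within_limit(self):
        n = nbh([("X", 1, 300, "+", True), ("Y", 341, 600, "+", False)])
        occs = pattern_occurrences(n, ("X", "Y"))
        assert len(occs) == 1
        assert intergenic_distance(n.genes[0], n.genes[1]) == 40

    def test_gap_over_limit(self):
        n = nbh([("X", 1, 300, "+", True), ("Y", 452, 600, "+", False)])
        assert intergenic_distance(n.genes[0], n.genes[1]) == 151
        assert pattern_occurrences(n, ("X", "Y")) == []

    def test_order_matters(self):
        n = nbh([("Y", 1, 300, "+", False), ("X", 341, 600, "+", True)])
        assert pattern_occurrences(n, ("X", "Y")) == []

    def test_strand_requirement_configurable(self):
        n = nbh([("X", 1, 300, "+", True), ("Y", 341, 600, "-", False)])
        assert pattern_occurrences(n, ("X", "Y")) == []
        assert len(pattern_occurrences(n, ("X", "Y"), same_strand=False)) == 1

    def test_boundary_gap_of_exactly_100_allowed(self):
        n = nbh([("X", 1, 300, "+", True), ("Y", 401, 600, "+", False)])
        assert intergenic_distance(n.genes[0], n.genes[1]) == 100
        assert len(pattern_occurrences(n, ("X", "Y"))) == 1


class TestConservationProfile:
    def _contexts(self, family_lists):
        return [
            nbh(
                [(f, 1 + 500 * i, 300 + 500 * i, "+", False)
                 for i, f in enumerate(fams)],
                ctx=f"c{j}", sp=f"s{j}",
            )
            for j, fams in enumerate(family_lists)
        ]

    def test_presence_fractions(self):
        ctxs = self._contexts([["A", "B"]] * 9 + [["B"]])
        conserved = conservation_profile(ctxs)
        assert conserved == {"A", "B"}
        ctxs = self._contexts([["A"]] + [["B"]] * 9)
        assert conservation_profile(ctxs) == {"B"}

    def test_boundary_inclusive(self):
        ctxs = self._contexts([["A"]] * 5 + [["B"]] * 5)
        assert conservation_profile(ctxs, presence_min=0.5) == {"A", "B"}


def planted_contexts(n_ctx=20, n_species=8, flank_fam=None, flank_gap=50,
                     internal_gap=40):
    """Hand-built windows: decoy - X - Y (- optional flank) - decoy."""
    out = []
    for i in range(n_ctx):
        genes = []
        pos = 1
        genes.append((f"dec{i}", pos, pos + 299, "+", False))
        start = pos + 299 + 200 + 1
        genes.append(("X", start, start + 299, "+", True))
        start2 = start + 299 + internal_gap + 1
        genes.append(("Y", start2, start2 + 299, "+", False))
        prev_end = start2 + 299
        if flank_fam is not None:
            fs = prev_end + flank_gap + 1
            genes.append((flank_fam, fs, fs + 299, "+", False))
            prev_end = fs + 299
        ds = prev_end + 300 + 1
        genes.append((f"dex{i}", ds, ds + 299, "-", False))
        out.append(nbh(genes, ctx=f"c{i}", sp=f"s{i % n_species}"))
    return out


class TestMinePatterns:
    def test_planted_pair_is_rank_one(self):
        cands = mine_patterns(planted_contexts())
        assert cands[0].families == ("X", "Y")
        assert cands[0].freq == 1.0
        assert cands[0].best_extension_freq < cands[0].freq

    def test_conserved_flank_shifts_to_triple(self):
        """A conserved gene 50 nt downstream of Y kills (X, Y) support; the
        extended pattern (X, Y, Z) wins instead."""
        cands = mine_patterns(planted_contexts(flank_fam="Z", flank_gap=50))
        assert cands[0].families == ("X", "Y", "Z")
        pair = [c for c in cands if c.families == ("X", "Y")]
        assert not pair or pair[0].freq == 0.0  # pair support vanished

    def test_conserved_flank_beyond_100nt_is_harmless(self):
        cands = mine_patterns(planted_contexts(flank_fam="Z", flank_gap=150))
        assert cands[0].families == ("X", "Y")
        assert cands[0].freq == 1.0
        # (X, Y, Z) is no valid extension either: its internal gap exceeds
        # the 100-nt spacing rule, so the pair keeps a perfect score
        assert cands[0].best_extension_freq == 0.0
        assert cands[0].score == 1.0

    def test_five_species_yields_nothing(self):
        assert mine_patterns(planted_contexts(n_species=5)) == []

    def test_deterministic_and_order_invariant(self, rng):
        ctxs = planted_contexts()
        perm = [ctxs[i] for i in rng.permutation(len(ctxs))]
        a = mine_patterns(ctxs)
        b = mine_patterns(perm)
        assert [(c.families, c.freq, c.score) for c in a] == [
            (c.families, c.freq, c.score) for c in b
        ]

    def test_matches_bruteforce_on_random_instances(self, rng):
        """Full agreement with a naive enumerator on random neighborhoods."""
        for trial in range(40):
            nbhs = random_neighborhoods(
                rng,
                n_contexts=int(rng.integers(4, 13)),
                n_species=int(rng.integers(2, 6)),
                max_genes=8,
                n_families=int(rng.integers(3, 6)),
            )
            kwargs = dict(
                gap_max=int(rng.integers(50, 200)),
                flank_gap_min=100,
                presence_min=float(rng.uniform(0.3, 0.8)),
                min_species=int(rng.integers(1, 4)),
                max_len=3,
                same_strand=bool(rng.random() < 0.7),
            )
            got = mine_patterns(nbhs, **kwargs)
            expected = oracle_mine(nbhs, **kwargs)
            assert [
                (c.families, c.supporting_contexts, c.species_support,
                 c.freq, c.best_extension_freq, pytest.approx(c.score))
                for c in got
            ] == expected

    def test_occurrence_support_is_anti_monotone(self, rng):
        """Occurrence frequency (order + spacing + strand) never grows when
        a pattern is extended by one gene."""
        from viroscape.ta_miner import pattern_occurrences

        for trial in range(20):
            nbhs = random_neighborhoods(rng, n_contexts=8, n_species=4)
            cands = mine_patterns(nbhs, min_species=1, max_len=3)
            fams_universe = {g.family_label for n in nbhs for g in n.genes}
            def occ_freq(t):
                return sum(
                    bool(pattern_occurrences(n, t)) for n in nbhs
                ) / len(nbhs)
            for c in cands:
                for f in fams_universe:
                    assert occ_freq((f,) + c.families) <= c.occurrence_freq
                    assert occ_freq(c.families + (f,)) <= c.occurrence_freq


class TestSyntheticRecovery:
    def test_default_generator_recovers_planted_pattern(self):
        sim = gen_neighborhoods(SimConfig(seed=42))
        cands = mine_patterns(sim.neighborhoods)
        assert cands[0].families == sim.truth_pattern

    def test_wide_internal_gaps_break_recovery(self):
        sim = gen_neighborhoods(SimConfig(seed=42, internal_gap_range=(150, 200)))
        cands = mine_patterns(sim.neighborhoods)
        assert all(c.families != sim.truth_pattern for c in cands)
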