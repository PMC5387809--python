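"""GA operators, generation mechanics and crossover provenance."""

import itertools

import numpy as np
import pytest

from aptaselect import ga, seqio
from aptaselect.errors import InputError
from aptaselect.seqio import AptamerSequence, BitChromosome, encode_bits


def seq(name, region):
    return AptamerSequence(name, region)


class TestCrossover:
    def test_published_single_cut_reconstructs_offspring(self, gen1, gen2):
        """PSAG117 x PSAG112 cut after base 10 (bit 20) yields PSAG28."""
        child = ga.crossover(
            encode_bits(gen1.sequence_by_name("PSAG117")),
            encode_bits(gen1.sequence_by_name("PSAG112")),
            [20],
        )
        assert (
            seqio.decode_bits(child).variable_region
            == gen2.sequence_by_name("PSAG28").variable_region
        )

    def test_reproduction_copies_parent(self, gen1, gen2):
        """Zero cuts = reproduction; PSAG119 carried unchanged is PSAG212."""
        p119 = encode_bits(gen1.sequence_by_name("PSAG119"))
        assert ga.crossover(p119, encode_bits(seq("o", "A" * 24)), []) == p119
        assert (
            gen1.sequence_by_name("PSAG119").variable_region
            == gen2.sequence_by_name("PSAG212").variable_region
        )

    def test_identical_parents_any_cuts_is_identity(self):
        chrom = encode_bits("ATGCATGCATGC")
        cuts = list(range(1, len(chrom)))
        assert ga.crossover(chrom, chrom, cuts) == chrom

    def test_alternation_between_parents(self):
        a = BitChromosome((0,) * 8)
        b = BitChromosome((1,) * 8)
        child = ga.crossover(a, b, [2, 5])
        assert child.bits == (0, 0, 1, 1, 1, 0, 0, 0)
        child_b_first = ga.crossover(a, b, [2, 5], take_first_from="B")
        assert child_b_first.bits == (1, 1, 0, 0, 0, 1, 1, 1)

    @pytest.mark.parametrize("cuts", [[0], [48], [5, 5], [7, 3]])
    def test_invalid_cuts_rejected(self, cuts):
        chrom = encode_bits("A" * 24)
        with pytest.raises(InputError):
            ga.crossover(chrom, chrom, cuts)


class TestMutate:
    def test_rate_zero_is_identity(self):
        chrom = encode_bits("ATGCATGC")
        out, flipped = ga.mutate(chrom, 0.0, np.random.default_rng(0))
        assert out == chrom and flipped == ()

    def test_rate_one_is_complement(self):
        chrom = encode_bits("ATGCATGC")
        out, flipped = ga.mutate(chrom, 1.0, np.random.default_rng(0))
        assert out.bits == tuple(1 - b for b in chrom.bits)
        assert len(flipped) == len(chrom)

    def test_flip_fraction_matches_binomial(self):
        """At rate 0.5 over 10,000 bits the flip count sits within 3 sigma."""
        chrom = BitChromosome((0,) * 10_000)
        out, flipped = ga.mutate(chrom, 0.5, np.random.default_rng(123))
        n, p = 10_000, 0.5
        sigma = (n * p * (1 - p)) ** 0.5
        assert abs(len(flipped) - n * p) < 3 * sigma
        assert sum(out.bits) == len(flipped)


class TestSelection:
    def test_single_parent_self_pairs(self):
        config = ga.GAConfig(n_offspring=1, rng_seed=0)
        pairs = ga.select_parent_pairs([seq("a", "AT")], None, 3, config)
        assert pairs == [(seq("a", "AT"), seq("a", "AT"))] * 3

    def test_zero_fitness_parent_never_drawn(self):
        config = ga.GAConfig(
            n_offspring=1, selection_scheme="fitness_proportional", rng_seed=0
        )
        parents = [seq("a", "AT"), seq("b", "GC")]
        pairs = ga.select_parent_pairs(
            parents, {"a": 1.0, "b": 0.0}, 50, config
        )
        drawn = {p.name for pair in pairs for p in pair}
        assert drawn == {"a"}

    def test_all_zero_fitness_rejected(self):
        config = ga.GAConfig(
            n_offspring=1, selection_scheme="fitness_proportional", rng_seed=0
        )
        with pytest.raises(InputError):
            ga.select_parent_pairs(
                [seq("a", "AT")], {"a": 0.0}, 1, config
            )

    def test_empty_parent_list_rejected(self):
        with pytest.raises(InputError):
            ga.select_parent_pairs([], None, 1, ga.GAConfig(n_offspring=1))

    def test_uniform_slot_frequencies(self):
        """Empirical slot frequencies over 10,000 draws within 3 sigma of 1/4."""
        config = ga.GAConfig(n_offspring=1, rng_seed=7)
        parents = [seq(n, "ATGC") for n in "abcd"]
        pairs = ga.select_parent_pairs(parents, None, 5000, config)
        counts = {n: 0 for n in "abcd"}
        for pa, pb in pairs:
            counts[pa.name] += 1
            counts[pb.name] += 1
        n, p = 10_000, 0.25
        sigma = (n * p * (1 - p)) ** 0.5
        for c in counts.values():
            assert abs(c - n * p) < 3 * sigma


class TestNextGeneration:
    @pytest.mark.parametrize("n_parents,n_offspring", [(5, 20), (4, 12)])
    def test_offspring_count(self, gen1, n_parents, n_offspring):
        parents = gen1.sequences()[:n_parents]
        config = ga.GAConfig(n_offspring=n_offspring, rng_seed=1)
        gen = ga.next_generation(parents, None, config, generation_index=2)
        assert len(gen.offspring) == n_offspring
        assert len(gen.lineage) == n_offspring
        assert gen.offspring[7].name == "PSAG28"

    def test_same_seed_reproduces_generation(self, gen2_parents):
        config = ga.GAConfig(n_offspring=12, rng_seed=42)
        a = ga.next_generation(gen2_parents, None, config)
        b = ga.next_generation(gen2_parents, None, config)
        assert a == b

    def test_lineage_references_parents(self, gen2_parents):
        config = ga.GAConfig(n_offspring=12, rng_seed=3)
        gen = ga.next_generation(gen2_parents, None, config)
        names = {p.name for p in gen.parents}
        for rec in gen.lineage:
            assert rec.parent_a in names and rec.parent_b in names

    def test_no_mutation_offspring_positions_are_parental(self, gen2_parents):
        """With mutation off and base-boundary cuts, every offspring base
        matches one of its two recorded parents at that position."""
        config = ga.GAConfig(
            n_offspring=30, n_crossover_points=2, mutation_rate=0.0,
            rng_seed=9, base_boundary_cuts=True,
        )
        gen = ga.next_generation(gen2_parents, None, config)
        by_name = {p.name: p for p in gen.parents}
        for child, rec in zip(gen.offspring, gen.lineage):
            pa = by_name[rec.parent_a].variable_region
            pb = by_name[rec.parent_b].variable_region
            for i, base in enumerate(child.variable_region):
                assert base in (pa[i], pb[i])

    def test_no_mutation_offspring_bits_are_parental(self, gen2_parents):
        """With bit-boundary cuts the parental invariant holds per *bit*:
        a cut between the two bits of one base may create a base absent in
        both parents, but never a non-parental bit."""
        config = ga.GAConfig(
            n_offspring=30, n_crossover_points=2, mutation_rate=0.0, rng_seed=9
        )
        gen = ga.next_generation(gen2_parents, None, config)
        by_name = {p.name: p for p in gen.parents}
        for child, rec in zip(gen.offspring, gen.lineage):
            ca = encode_bits(by_name[rec.parent_a]).bits
            cb = encode_bits(by_name[rec.parent_b]).bits
            for i, bit in enumerate(encode_bits(child).bits):
                assert bit in (ca[i], cb[i])

    def test_dedup_yields_distinct_offspring(self, gen2_parents):
        config = ga.GAConfig(
            n_offspring=8, mutation_rate=0.05, rng_seed=11, dedup=True
        )
        gen = ga.next_generation(gen2_parents, None, config)
        regions = [c.variable_region for c in gen.offspring]
        assert len(set(regions)) == len(regions)


def brute_force_min_mutations(offspring, parents, max_cuts):
    """Independent exhaustive enumeration over pairs and cut placements."""
    n = len(offspring)
    best = n + 1
    for a, b in itertools.product(parents, repeat=2):
        for k in range(max_cuts + 1):
            for cuts in itertools.combinations(range(1, n), k):
                bounds = (0,) + cuts + (n,)
                template = "".join(
                    (a if i % 2 == 0 else b)[lo:hi]
                    for i, (lo, hi) in enumerate(zip(bounds, bounds[1:]))
                )
                best = min(
                    best,
                    sum(x != y for x, y in zip(offspring, template)),
                )
    return best


class TestExplainOffspring:
    def test_published_offspring_single_cut(self, gen1, gen2, gen2_parents):
        report = ga.explain_offspring(
            gen2.sequence_by_name("PSAG28"), gen2_parents, max_cut_points=1
        )
        assert report.min_mutations == 0
        assert ("PSAG117", "PSAG112", (10,), ()) in report.best_explanations

    def test_published_reproduction(self, gen2, gen2_parents):
        report = ga.explain_offspring(
            gen2.sequence_by_name("PSAG212"), gen2_parents, max_cut_points=1
        )
        assert report.min_mutations == 0
        pa, pb, cuts, muts = report.best_explanations[0]
        assert cuts == () and pa == "PSAG119" and muts == ()

    def test_point_mutant_of_parent(self, gen2_parents):
        parent = gen2_parents[0]
        region = list(parent.variable_region)
        region[5] = "A" if region[5] != "A" else "G"
        mutant = AptamerSequence("mut", "".join(region))
        report = ga.explain_offspring(mutant, gen2_parents, max_cut_points=0)
        assert report.min_mutations == 1
        assert report.best_explanations[0][2] == ()

    def test_length_mismatch_rejected(self, gen2_parents):
        with pytest.raises(InputError):
            ga.explain_offspring(
                AptamerSequence("short", "ATGC"), gen2_parents
            )

    def test_agrees_with_brute_force_on_toy_regions(self):
        """Exhaustive cross-check on length-6 regions, up to 2 cuts."""
        rng = np.random.default_rng(2024)
        bases = np.array(list("ATGC"))
        parents = [
            AptamerSequence(f"p{i}", "".join(rng.choice(bases, 6)))
            for i in range(3)
        ]
        for _ in range(25):
            child_region = "".join(rng.choice(bases, 6))
            child = AptamerSequence("c", child_region)
            report = ga.explain_offspring(child, parents, max_cut_points=2)
            expected = brute_force_min_mutations(
                child_region,
                [p.variable_region for p in parents],
                max_cuts=2,
            )
            assert report.min_mutations == expected
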