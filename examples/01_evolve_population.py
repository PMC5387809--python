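"""Breed a next-generation candidate pool from the four strongest binders.

The four generation-1 aptamers with the largest QCM signals act as parents;
their QCM frequency changes (Hz) are the fitness, so stronger binders are
drawn more often. Crossover operates on the 2-bit chromosome of the 24-nt
variable region.
"""

from aptaselect import GAConfig, datasets, next_generation, write_fasta

gen1 = datasets.load_generation(1)
parents = [gen1.sequence_by_name(n) for n in datasets.GENERATION2_PARENTS]
qcm = datasets.load_qcm(1).set_index("name")["delta_f_mean"]
fitness = {p.name: float(qcm[p.name]) for p in parents}

config = GAConfig(
    n_offspring=12,
    n_crossover_points=1,
    selection_scheme="fitness_proportional",
    rng_seed=42,
)
gen = next_generation(parents, fitness, config, generation_index=2)

print(write_fasta(gen.offspring))
for rec in gen.lineage[:3]:
    print(
        f"{rec.offspring_name}: {rec.parent_a} x {rec.parent_b}, "
        f"cuts at bits {rec.cut_points or '(none: reproduction)'}"
    )
# Each offspring is a recombination of two parent chromosomes; the lineage
# records which parents and where the chromosome switched between them.
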