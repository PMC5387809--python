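"""Rank docking scores and pick candidates for synthesis.

Docking scores come from external rigid-body docking rescored with the
ZRANK energy function; a lower (more negative) ZRANK predicts a better
aptamer-protein complex. Selection takes the top k of the ranking, and
the experimental-vs-simulated rank concordance is summarized.
"""

from aptaselect import compare_rankings, datasets, rank_by_zrank, select_top_k

ranked = rank_by_zrank(datasets.load_generation(2).scores())
for name, zrank, rank in ranked.entries:
    print(f"rank {rank:2d}  {name:8s}  ZRANK {zrank:g}")
print("selected for synthesis:", select_top_k(ranked, 3))

qcm1 = datasets.load_qcm(1)
exp = qcm1.sort_values("rank_experiment")["name"].tolist()
sim = qcm1.sort_values("rank_simulation")["name"].tolist()
concord = compare_rankings(exp, sim)
print(
    f"\ngeneration 1 QCM vs docking ranks: {concord.exact_matches} exact "
    f"matches, Spearman rho {concord.spearman_rho:.3f}, "
    f"closest pairs {concord.closest}"
)
# A negative rho means the docking ranking largely disagrees with the
# experimental QCM ranking - docking screens candidates, it does not
# replace the binding assay.
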