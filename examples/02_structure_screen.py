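"""Eliminate candidates that fold into no secondary structure.

A candidate whose dot-bracket string is all dots (every base unpaired) has
no stem-loop to present a binding interface and is dropped before docking.
The auxiliary max-base-pairing folder is also shown on one sequence.
"""

from aptaselect import datasets, filter_population, nussinov_fold

gen2 = datasets.load_generation(2)
outcome = filter_population(gen2.structures())

print(f"kept   ({len(outcome.kept)}): {', '.join(outcome.kept)}")
print(f"removed({len(outcome.removed)}): {', '.join(outcome.removed)}")
for name in outcome.removed:
    print(f"  {name}: {outcome.reasons[name]}")

seq = gen2.sequence_by_name("PSAG28").full_sequence
fold = nussinov_fold(seq, min_loop=3)
print(f"\nmax-pairing fold of PSAG28 ({fold.n_pairs} pairs):")
print(seq)
print(fold.dotbracket)
# The removed candidates fold into all-dots structures (no base pairs); the
# folder output is a combinatorial screen, not a free-energy prediction.
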