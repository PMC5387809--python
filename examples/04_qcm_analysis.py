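"""QCM analytics: frequency changes, Sauerbrey mass, and fold changes.

A quartz crystal microbalance reports binding as a drop in resonance
frequency; the Sauerbrey relation converts it linearly to adsorbed mass.
Candidates are compared as fold changes over the benchmark aptamer.
"""

from aptaselect import SauerbreyParams, datasets, fold_change
from aptaselect.biosensor import sauerbrey_mass_ng

qcm = datasets.load_qcm(2).set_index("name")
ref = qcm.loc[datasets.BENCHMARK_NAME, "delta_f_mean"]

params = SauerbreyParams(f0=7.995e6)  # 8 MHz-class crystal
for name, row in qcm.iterrows():
    mass = sauerbrey_mass_ng(-row["delta_f_mean"], params)
    fc = fold_change(row["delta_f_mean"], ref)
    print(
        f"{name:10s} |df| = {row['delta_f_mean']:6.1f} +/- "
        f"{row['delta_f_sd']:4.1f} Hz  ->  {mass:6.1f} ng adsorbed, "
        f"{fc:4.2f}x benchmark"
    )
# The best candidate produces about twice the benchmark's signal; the mass
# column converts the frequency drop with the published crystal constants.
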