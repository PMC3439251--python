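"""Which features are over- or under-represented in each stability class?

Runs the Fisher-exact enrichment screen (4 PTMs, 9 domain types, the
destabilizing N-degron and 15 disorder type x level indicators) against
the planted classes of a synthetic benchmark and prints the significant
hits. E-values are Bonferroni-corrected p-values (p x 29 tests); an
E-value below 0.05 marks a feature whose prevalence in the class genuinely
differs from the background.
"""

from stabnet.features import enrichment_analysis
from stabnet.simulate import FixtureConfig, simulate_dataset

dataset = simulate_dataset(FixtureConfig(n_stable=400, n_unstable=420), seed=3)

for target in ("unstable", "stable"):
    print(f"\n=== {target} class vs all others ===")
    results = enrichment_analysis(
        dataset.annotations, dataset.sequences, dataset.labels, target
    )
    hits = sorted(
        (r for r in results if r.e_value < 0.05), key=lambda r: r.e_value
    )
    for r in hits:
        print(f"  {r.feature_name:>22}  {r.direction:>5}-represented  E = {r.e_value:.2e}")

print(
    "\nthe benchmark plants PTMs in stable proteins and transmembrane/"
    "\nsignal-peptide domains plus destabilizing N-termini in unstable ones,"
    "\nso those features should lead the two lists with opposite directions."
)
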