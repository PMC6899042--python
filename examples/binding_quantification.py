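"""Co-IP densitometry: input-normalized binding folds versus wild type.

Simulates a 10-replicate band-intensity table for wild-type titin fragment
and two HCM-associated mutants with known binding folds, then quantifies:
each lane's IP band is normalized to its input band, folds are expressed
versus the mean wild-type ratio (so WT = 1.00 AU exactly), and each mutant is
tested against WT with a two-sided pooled Student's t-test.
"""

from cardiomvp import DensitometrySpec, quantify, simulate_densitometry

spec = DensitometrySpec(n_replicates=10, noise_sigma=0.25, input_cv=0.1, seed=42)
table = simulate_densitometry(
    spec,
    conditions=[("WT", 1.0), ("E29783V", 9.23), ("D30994N", 1.58)],
)
print(f"simulated table: {len(table)} rows "
      f"({table['condition'].nunique()} conditions x {spec.n_replicates} replicates)\n")

result = quantify(table, reference="WT")
print(result.summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nmean_fold is binding in arbitrary units (WT == 1.00 AU by construction); "
      "stars mark significance vs WT (*: P<0.01, ***: P<0.001). The estimates "
      "should sit near the simulated truths 9.23 and 1.58 AU.")
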