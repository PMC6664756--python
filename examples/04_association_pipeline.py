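"""Discover the TF-drug association planted in a synthetic cohort.

Simulates a small study (genome, motifs, ChIP peaks, accessible SNPs, Hi-C
domains and one loop, genotype/expression/EC50 cohort) in which
site-destroying SNPs of one TF drive the expression of ten genes whose
expression in turn drives one drug's EC50.  The pipeline scores every
within-peak SNP, ranks binding-change SNPs, finds each drug's
phenotype-associated SNPs, and tests every TF-drug pair.
"""

from tfimpact.association import results_frame
from tfimpact.pipeline import run_study
from tfimpact.synthetic import simulate_study

study = simulate_study(seed=7)
run = run_study(study, seed=7)

print(f"universe: {len(run.universe)} accessible SNPs")
for tf, pool in run.peak_pools.items():
    print(f"  {tf}: {len(pool)} SNPs in peaks, "
          f"{len(run.binding_sets[tf])} binding-change SNPs")
for drug, snps in run.pheno_sets.items():
    print(f"  {drug}: {len(snps)} phenotype-associated SNPs")
print()
print(results_frame(run.results).to_string(index=False,
                                           float_format=lambda x: f"{x:.3g}"))
print()
print(f"planted causal pair: ({study.truth['causal_tf']}, "
      f"{study.truth['causal_drug']})")
print("The planted pair should top the table with a tiny hypergeometric p")
print("and utility p score near 0 (random within-peak SNP sets almost never")
print("match its enrichment); every other pair should be non-significant.")
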