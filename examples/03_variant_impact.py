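"""Score variant impact on TF binding with allele-window delta scores.

Builds 501-bp allele windows for two kinds of SNPs — ones that destroy a
planted consensus binding site and matched SNPs in motif-free background —
scores both alleles with a calibrated occupancy model, and reports how well
the absolute score difference separates the two groups (AUROC), mirroring
evaluation against allele-specific binding data.
"""

from tfimpact.asb import auroc
from tfimpact.stap import CalibratedStap, LinearCalibration, OccupancyModel
from tfimpact.synthetic import gen_asb_benchmark, random_pwm
from tfimpact.variant import impact_from_allele_scores

pwm = random_pwm(width=8, consensus_prob=0.85, seed=21, name="demo_motif")
predictor = CalibratedStap(
    OccupancyModel(pwm, tau=2.0, eT=3.0), LinearCalibration.identity()
)

pairs, labels = gen_asb_benchmark(pwm, n_per_class=200, seed=22)
scores = [
    impact_from_allele_scores(predictor.score(major), predictor.score(minor))
    for major, minor in pairs
]

destroyers = [s for s, l in zip(scores, labels) if l == 1]
background = [s for s, l in zip(scores, labels) if l == 0]
print(f"mean delta score, site-destroying SNPs: {sum(destroyers)/len(destroyers):.3f}")
print(f"mean delta score, background SNPs:      {sum(background)/len(background):.4f}")
print(f"AUROC (destroyer vs background):        {auroc(scores, labels):.3f}")
print()
print("A site-destroying SNP changes the occupancy of its window between")
print("alleles, so its delta score is large; background SNPs barely move")
print("the score.  AUROC near 1 means the ranking separates them cleanly.")
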