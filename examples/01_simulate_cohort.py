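"""Generate a synthetic surgical cohort and look at its structure.

The generator draws rs6265-style genotypes in Hardy-Weinberg proportions,
assigns each patient a latent postoperative "insult" whose log-odds fall
by ~0.9 per G allele carried, and simulates six correlated test scores at
baseline, day 7 and month 3 with a shared practice effect.
"""

from pocdkit import SimConfig, generate_cohort, hwe_chi_square

cfg = SimConfig(seed=42)  # defaults: 99 patients, 25 controls, p_G = 0.51
cohort = generate_cohort(cfg)

patients = cohort[cohort.arm == "patient"]
counts = [int((patients.genotype == k).sum()) for k in (0, 1, 2)]
hwe = hwe_chi_square(counts)

print(f"cohort: {len(patients)} patients + {(cohort.arm == 'control').sum()} controls")
print(f"patient genotype counts (AA, AG, GG): {tuple(counts)}")
print(f"HWE chi2 = {hwe.chi2:.3f} (p = {hwe.p:.2f})  "
      "-- non-significant: the draw is consistent with equilibrium")
print(f"latent insults at day 7: {int(patients.truth_insult.sum())} "
      f"({100 * patients.truth_insult.mean():.1f}% of patients)")
print("The insult fraction tracks logit^-1(-0.095 - 0.9 g): carrying G is protective.")
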