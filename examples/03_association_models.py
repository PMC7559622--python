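"""Fit all four genetic models to the bundled published genotype counts.

The bundled tables are genotype-by-POCD-status counts at day 7 and month
3 from a published elderly-surgery cohort genotyped at BDNF rs6265.  An
OR below 1 with a CI excluding 1 means G-allele carriage is associated
with lower POCD risk under that inheritance model.
"""

from pocdkit import association_report
from pocdkit.datasets import consistency_report, rs6265_day7_table, \
    rs6265_month3_table

report = association_report(rs6265_day7_table(), rs6265_month3_table())
cols = ["timepoint", "model", "OR_95CI", "p", "significant"]
print(report[cols].to_string(index=False))

print("\nAt day 7 the additive (OR 0.41) and dominant (OR 0.35) models are")
print("significant; no month-3 model is.  The HWE rows are the 1-df")
print("equilibrium diagnostic on the pooled genotypes at each timepoint.")

print("\nAudit of the published summary values against their own counts:")
for d in consistency_report():
    print(" -", d)
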