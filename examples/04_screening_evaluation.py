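"""Screening evaluation of a synthetic first-trimester cohort.

The cohort generator mimics a screening population where only the
traced-arc (AI-line) length separates term from spontaneous-preterm
deliveries; the evaluation converts lengths to multiples of the
median, runs the group t tests, and compares the three methods'
AUROCs with paired DeLong tests.
"""

from cervitrace import generate_cohort
from cervitrace.screening import cohort_summary, evaluate_cohort

cohort = generate_cohort(n_term=1585, n_32_36=68, n_lt32=11, seed=42)

print(cohort_summary(cohort).to_string(index=False))
print()

report = evaluate_cohort(cohort)
print("group means (mm):")
for method in ("single", "two", "ai"):
    col = f"cl_{method}_mm"
    term = cohort.group("term")[col].mean()
    ptb = cohort.table.loc[cohort.table.outcome != "term", col].mean()
    print(f"  {method:>6}-line: term {term:5.1f}  sPTB<37 {ptb:5.1f}")
print()

print("AUROC for sPTB <37 weeks (shorter length => higher risk):")
for method in ("single", "two", "ai"):
    r = report["roc"][method]
    print(f"  {method:>6}-line: {100 * r.auroc:4.1f}% "
          f"(95% CI {100 * r.ci_low:.1f}-{100 * r.ci_high:.1f})")
print()

for name, cmp in report["roc_comparisons"].items():
    print(f"paired DeLong {name}: delta AUROC {cmp.delta_auroc:+.3f}, "
          f"p = {cmp.p_value:.2e}")
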