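"""Screen inferred subclone abundances for outcome prediction and combine
T / MRD / cytogenetics into survival risk strata.

Runs the full default study end to end: per-patient clustering and
classification, signature-matrix construction, bulk deconvolution,
Bonferroni-corrected Cox screening on OS and EFS, median split of the
total outcome-predictive abundance T, Kaplan-Meier comparison, and the
multivariate Cox model with MRD-negative / normal-cytogenetics reference
levels.
"""

import warnings

warnings.filterwarnings("ignore")

from clonerisk.pipeline import run_default_study

study, res = run_default_study(seed=1)

screen = res["screen"]
print(f"screened {len(screen)} merged subclones; "
      f"selected (adj p<0.01 on OS and EFS): {res['selected_subclones']}")
for s in res["selected_subclones"]:
    prov = res["signature"].provenance[s]
    print(f"  {s}: labels={sorted(set(map(str, prov['labels'])))} "
          f"hr_os={screen.loc[s, 'hr_os']:.2f}")

print(f"\nT = total abundance of selected subclones; "
      f"median split -> log-rank p = {res['km_T']['p']:.2e}")
print("\nmultivariate Cox (binary T / MRD / cytogenetics):")
print(res["multivariate"].round(4).to_string())
nest = res["nested_improvement"]
print(f"\nadding T to MRD+cytogenetics: LRT chi2={nest['statistic']:.1f}, "
      f"p={nest['p']:.2e}")
# The selected subclones are the planted expanded/transforming populations;
# high total abundance T marks significantly worse survival even after
# controlling for MRD and cytogenetic risk.
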