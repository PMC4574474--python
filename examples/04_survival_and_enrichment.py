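"""Relate subtypes to outcome: Kaplan-Meier, log-rank, Cox HR, Fisher tests.

Uses the planted-subtype cohort, where one subtype carries a 2.5x hazard
and most of the MSI-positive samples.
"""

import pandas as pd

from breakgene import clinical as clin
from breakgene import synthetic_cohort as sim

cohort = sim.simulate_cohort(sim.scenario("subtypes", seed=7))
labels = cohort.truth.subtype_labels  # use planted labels for a clean read
clinical = cohort.clinical

summary = clin.km_logrank(labels, clinical)
print(f"log-rank across {len(summary.n_per_group)} subtypes: "
      f"chi2={summary.chi2:.1f}, p={summary.p_value:.2e}")
for lab in sorted(summary.n_per_group):
    print(f"  subtype {lab}: n={summary.n_per_group[lab]}, "
          f"median OS {summary.medians[lab]:.0f} days")

poor = (labels == 2).astype(int)  # the high-hazard subtype vs the rest
hr = clin.cox_hr(poor, clinical)
print(f"poor-prognosis subtype vs rest: HR={hr['hr']:.2f} "
      f"(95% CI {hr['ci_low']:.2f}-{hr['ci_high']:.2f}), p={hr['p_value']:.2e}")

msi = clin.fisher_enrichment(clinical.table["msi_status"], poor, sided="two")
print(f"MSI enrichment in the poor subtype: OR={msi['odds_ratio']:.1f}, "
      f"p={msi['p_value']:.2e}, table={msi['table'].tolist()}")

# The high-hazard subtype shows a markedly shorter median overall survival,
# a hazard ratio well above 1 with a CI excluding 1, and a strong excess of
# MSI-positive samples, mirroring how a poor-prognosis genomic subtype
# presents in a real cohort.
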