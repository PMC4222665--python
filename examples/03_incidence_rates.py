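"""Stratified incidence rates per 1000 residents with exact Poisson CIs.

Average annual rates reuse the single census-year denominator for all study
years (the surveillance convention); per-year rates divide each year's new
cases by that year's residents in each 5-year age band.
"""

import warnings

from pneumoclass import (
    GeneratorConfig, average_annual_rates, generate, per_year_rates,
    run_pipeline, trend_report,
)

bundle, _ = generate(GeneratorConfig(seed=7, n_patients=26239))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    cohort, _ = run_pipeline(bundle)

avg = average_annual_rates(cohort, bundle.population)
totals = avg[(avg.age_group == "total") & (avg.gender == "total")]
print("average annual incidence per 1000 residents (95% CI):")
for r in totals.itertuples(index=False):
    print(f"  {r.subtype:4s} {r.rate_per_1000:4.1f}  "
          f"({r.ci_low:.1f}-{r.ci_high:.1f})   events={r.events}")
# At the study scale (~26,000 episodes, 1,056,000 residents, 3 years) the
# three subtypes sit near 0.7 / 2.1 / 5.4 per 1000 resident-years.

print("\nper-year rates for the oldest band (90+):")
py = per_year_rates(cohort, bundle.population)
old = py[py.age_group == "90+"]
for r in old[old.subtype == "CAP"].itertuples(index=False):
    print(f"  CAP {r.year}: {r.rate_per_1000:5.1f} ({r.ci_low:.1f}-{r.ci_high:.1f})")

rep = trend_report(py)
flagged = rep[rep.ci_nonoverlap]
print(f"\nstrata whose first/last-year CIs do not overlap: {len(flagged)}")
# With a constant generator hazard no stratum should separate; planting a
# rate increase in one band flags exactly that band.
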