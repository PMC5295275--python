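"""Score-stratified dose trends on a synthetic nationwide tract dataset.

Generates 5000 synthetic census tracts whose pollutant concentrations
rise with the non-white and poverty fractions, doses every tract with the
inhalation dose model (exposure factor 1, pooled national weighted age),
groups tracts by their 1-10 environmental-justice scores, and prints the
mean benzene dose per poverty score normalised to percent of the maximum.
A rising percent column is the disproportionate-dose signal the analysis
is designed to surface; strata with poverty score above 7 are excluded as
too small to interpret.
"""

from ejdose import (
    apply_exclusion,
    default_inhalation_table,
    group_mean_by_score,
    normalize_to_percent,
    per_tract_add,
)
from ejdose.synthetic import GeneratorConfig, generate

records = generate(GeneratorConfig(n_tracts=5000, seed=1))
doses = per_tract_add(records, default_inhalation_table())

summary = group_mean_by_score(doses, records, indicator="poverty")
kept, excluded = apply_exclusion(summary)
trend = normalize_to_percent(kept)

benzene = trend[trend["chemical"] == "benzene"]
print("Mean benzene ADD by poverty score (percent of maximum):")
print(
    benzene[["poverty_score", "n_tracts", "mean_add", "percent"]]
    .to_string(index=False, float_format=lambda v: f"{v:.4g}")
)
print()
print(
    f"{excluded['n_tracts'].sum()} tract-strata observations were set aside "
    "(poverty score > 7 or empty stratum)."
)
low = benzene.iloc[0]["percent"]
print(
    f"Mean dose climbs from {low:.1f}% of the maximum at poverty score 1 "
    "to 100% at the top retained score: tracts with more low-income "
    "residents receive systematically higher modelled doses."
)
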