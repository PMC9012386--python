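"""Cardiovascular-risk profile of the concordance groups.

Scores every eligible person with the packaged synthetic chart-style
10-year risk model, then compares mean risk in the missed,
over-diagnosed and consistent non-hypertension groups against the
consistent-hypertension group (Welch t tests, Bonferroni-adjusted
within each country) for the second-reading rule.
"""

import bpscreen as b

config = b.CohortConfig(n_regions=2, countries_per_region=3,
                        n_per_country=[4000] * 6, seed=21)
cohort, _ = b.apply_eligibility(b.generate_cohort(config))

risk = b.score(cohort)  # synthetic coefficient set; swap in your own via YAML
classified = b.classify(cohort, ["second"])
merged = classified.merge(risk[["person_id", "risk"]], on="person_id")
stats = b.compare_by_country(merged)

ok = stats[stats.status == "ok"]
cols = ["country", "group", "n_group", "mean_risk", "ratio_pct",
        "p_value", "p_bonferroni"]
print(ok[cols].round(4).to_string(index=False))
print("\nratio_pct is the group's mean 10-year risk as % of the consistent-"
      "\nhypertension mean: missed cases typically sit below 100%, i.e. the"
      "\npeople a shortcut rule misses carry somewhat lower cardiometabolic"
      "\nrisk than those it catches.")
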