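"""Generate the three synthetic survey tables and summarize them.

Writes CAHW, veterinarian and farmer microdata (CSV + provenance
sidecars) under results/surveys/ and prints the descriptive statistics
the downstream models consume: pooled success rates by round, procedure
means, and the farmer sow/litter summaries.
"""

from pathlib import Path

from swineval import (
    CohortConfig,
    FarmerConfig,
    descriptive_summary,
    generate_cahw_cohort,
    generate_farmer_survey,
    generate_vet_cohort,
    write_survey,
)

SEED = 1
OUT = Path("results/surveys")


def pooled_rate(records, rnd):
    sub = records[records["round"] == rnd]
    return sub["successes"].sum() / sub["procedures"].sum()


def main() -> None:
    cahw = generate_cahw_cohort(CohortConfig.cahw_default(seed=SEED))
    vets = generate_vet_cohort(CohortConfig.vet_default(seed=SEED))
    farmers = generate_farmer_survey(FarmerConfig(seed=SEED))
    for records, cfg, name in (
        (cahw, CohortConfig.cahw_default(seed=SEED), "cahw"),
        (vets, CohortConfig.vet_default(seed=SEED), "vet"),
        (farmers, FarmerConfig(seed=SEED), "farmer"),
    ):
        csv_path, _ = write_survey(records, cfg, OUT, name)
        print(f"wrote {csv_path} ({len(records)} records)")

    print("\nCAHW pooled success rate: "
          f"baseline {pooled_rate(cahw, 'baseline'):.1%}, "
          f"endline {pooled_rate(cahw, 'endline'):.1%}")
    print("Veterinarian pooled success rate: "
          f"baseline {pooled_rate(vets, 'baseline'):.1%}, "
          f"endline {pooled_rate(vets, 'endline'):.1%}")
    print("Veterinarian mean procedures/month: "
          f"baseline {vets.loc[vets['round'] == 'baseline', 'procedures'].mean():.2f}, "
          f"endline {vets.loc[vets['round'] == 'endline', 'procedures'].mean():.2f}")

    summary = descriptive_summary(
        farmers, ["sow_age_months", "parity", "first_time", "ai_success",
                  "full_term", "piglet_count"])
    print("\nFarmer survey summary:")
    print(summary.round(3).to_string())
    summary.to_csv(OUT / "farmer_descriptives.csv")


if __name__ == "__main__":
    main()
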