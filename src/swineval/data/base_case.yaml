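# Base-case configuration: published program parameters, the itemized
# cost ledger, and the published computed values used by the
# reproduction harness as comparison references.

baseline_success_rate: 0.488
endline_success_rate: 0.748
round_odds_ratio: 1.51
full_term_rate: 0.796
doses_distributed: 7540
farmers_served: 3421
litter_size: 7.99
price_per_piglet: 11.21
multiplier_type1: 1.16
multiplier_type2: 7.20

costs:
  - label: Salaries
    amount: 12000
    currency: USD
  - label: Travel
    amount: 23040
    currency: USD
  - label: Training/workshops
    amount: 16015
    currency: USD
  - label: Flights
    amount: 94948
    currency: USD
  - label: Vets fees
    amount: 15834
    currency: USD
  - label: Swine semen doses
    amount: 29312
    currency: USD

# Published values (USD unless a rate/ratio). Keys are the canonical row
# labels understood by swineval.reporting.reproduce_paper_tables.
reference:
  adjusted_success_rate: 0.5900
  incremental_rate: 0.1020
  total_successful_ai: 4489
  total_ft_pregnancies: 3574
  total_piglets: 28553
  total_income: 320074.79
  income_per_farmer: 93.56
  incremental_successful_ai: 769
  incremental_ft_pregnancies: 612
  incremental_piglets: 4893
  incremental_income: 54850
  incremental_income_per_farmer: 16.03
  direct_total: 320075
  indirect_total: 51212
  induced_total: 1933252
  combined_total: 2304538
  direct_incremental: 54850
  indirect_incremental: 8776
  induced_incremental: 331294
  combined_incremental: 394919
  attributable_share: 0.171
  total_cost: 191149
  roi_direct: 0.675
  benefit_cost_ratio_direct: 1.68
  benefit_cost_ratio_combined: 12.06
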