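"""Independent straight-line re-derivation of the economic model.

Pure-Python arithmetic with no imports from the package under test:
every quantity is written out directly from its definition so the
composed pipeline can be checked against an implementation that shares
no code with it.
"""


def impact_oracle(p0, or_value, ft, doses, farmers, litter, price, m1, m2,
                  scope_rate=None):
    """All model outputs from first principles. ``scope_rate`` defaults
    to the adjusted rate (the 'adjusted' policy)."""
    odds0 = p0 / (1.0 - p0)
    p_adj = odds0 * or_value / (1.0 + odds0 * or_value)
    delta = p_adj - p0
    rate = p_adj if scope_rate is None else scope_rate

    total_ai = doses * rate
    total_ft = total_ai * ft
    total_piglets = total_ft * litter
    total_income = total_piglets * price

    inc_ai = doses * delta
    inc_ft = inc_ai * ft
    inc_piglets = inc_ft * litter
    inc_income = inc_piglets * price

    return {
        "adjusted_success_rate": p_adj,
        "incremental_rate": delta,
        "total_successful_ai": total_ai,
        "total_ft_pregnancies": total_ft,
        "total_piglets": total_piglets,
        "total_income": total_income,
        "incremental_successful_ai": inc_ai,
        "incremental_ft_pregnancies": inc_ft,
        "incremental_piglets": inc_piglets,
        "incremental_income": inc_income,
        "direct_total": total_income,
        "indirect_total": total_income * (m1 - 1.0),
        "induced_total": total_income * (m2 - m1),
        "combined_total": total_income * m2,
        "direct_incremental": inc_income,
        "indirect_incremental": inc_income * (m1 - 1.0),
        "induced_incremental": inc_income * (m2 - m1),
        "combined_incremental": inc_income * m2,
        "income_per_farmer": total_income / farmers,
        "incremental_income_per_farmer": inc_income / farmers,
        "attributable_share": inc_income / total_income if total_income else 0.0,
    }


def roi_oracle(benefit, cost):
    return {"roi": (benefit - cost) / cost, "benefit_cost_ratio": benefit / cost}
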