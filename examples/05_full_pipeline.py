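"""The whole pipeline in one call: simulate, estimate, budget, phenology.

Equivalent to `floralwastage report --out <dir>` on the command line.
"""

from floralwastage import RunConfig, run_pipeline

cfg = RunConfig(seed=42, bootstrap=500)
res = run_pipeline(cfg)

est = res["estimates"]
for _, row in est.iterrows():
    print(
        f"{row.resource}: {row.percent_uncollected:.0f}% uncollected "
        f"(95% CI {row.ci_low:.0f}-{row.ci_high:.0f}%)"
    )

pooled = res["budget_pooled"]
print(f"pooled over {pooled['n_days']} study days:")
print(f"  supply      {pooled['supply_kg_sugar_per_ha_h']:.2f} kg sugar ha^-1 h^-1 "
      f"({pooled['supply_colony_equiv_per_ha_h']:.2f} CE)")
print(f"  uncollected {pooled['uncollected_kg_sugar_per_ha_h']:.2f} kg sugar ha^-1 h^-1 "
      f"({pooled['uncollected_colony_equiv_per_ha_h']:.2f} CE)")
print(f"  per insect  {pooled['supply_uL_per_insect_h']:.0f} uL h^-1 "
      f"({pooled['supply_g_sugar_per_insect_h']*1000:.0f} mg sugar h^-1)")
print(f"edge/interior insect ratio: {res['insect_edge_interior_ratio']:.2f}")
print(f"mean daily VPD: {res['vpd_daily']['vpd_kpa'].mean():.2f} kPa")
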