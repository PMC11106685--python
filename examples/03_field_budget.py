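"""Field-scale nectar supply, per-insect supply and colony equivalents.

Uses study-scale grand means (46 racemes m^-2, 7 flowers per raceme,
1.1 insects per 50 m^2 transect, secretion 0.10 uL == 47.1 ug sugar per
flower per hour, accessible-flower accumulation 33.6 ug) to chain the
budget arithmetic for a typical study day.
"""

from floralwastage import (
    colony_equivalents,
    community_composition,
    day_budget,
    packaged_community_table,
)

b = day_budget(
    day="typical",
    raceme_counts_per_m2=[46.0],
    flowers_per_raceme=[7.0],
    transect_counts=[1.1],
    secretion_uL_flower_h=0.10,
    secretion_ug_sugar_flower_h=47.1,
    uncollected_ug_sugar_flower_h=33.6,
)
print(f"flower density:        {b.flowers_per_m2:.0f} flowers m^-2")
print(f"insect density:        {b.insects_per_m2:.3f} insects m^-2")
print(f"sugar supply:          {b.supply_kg_sugar_per_ha_h:.2f} kg ha^-1 h^-1"
      f" = {b.supply_colony_equiv_per_ha_h:.2f} colony equivalents ha^-1 h^-1")
print(f"uncollected sugar:     {b.uncollected_kg_sugar_per_ha_h:.2f} kg ha^-1 h^-1"
      f" = {b.uncollected_colony_equiv_per_ha_h:.2f} CE ha^-1 h^-1")
print(f"per-insect supply:     {b.supply_uL_per_insect_h:.0f} uL insect^-1 h^-1")

# colony equivalents directly: a sugar flux as a fraction of the 1186 g
# lifetime sugar intake of one Bombus terrestris colony
print(f"0.14 kg ha^-1 h^-1 = {colony_equivalents(0.14):.2f} CE ha^-1 h^-1")

# who collects it: the observed transect community
comp = community_composition(packaged_community_table())
print(
    f"{comp['total']} insects observed: {comp['honeybee_pct']:.0f}% honeybees, "
    f"{comp['bumblebee_pct']:.0f}% bumblebees "
    f"({comp['honeybee_plus_bumblebee_pct']:.0f}% together)"
)
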