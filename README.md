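# floralwastage

How much of the nectar and pollen produced by a mass-flowering crop do
flower-visiting insects actually collect?  `floralwastage` is an analysis
pipeline for answering that question from field data of the kind gathered
in paired-flower exclusion studies on oilseed rape (*Brassica napus*):
nectar drained from insect-accessible and gauze-bagged flowers,
haemocytometer pollen counts from fresh and spent anthers, insect transect
walks, and quadrat flower-density surveys.  It is written for pollination
ecologists who want the whole chain — instrument readings to
field-scale sugar budgets — as tested, scriptable Python.

## The statistics in brief

**Uncollected fraction.**  Bagged flowers accumulate nectar at the plant's
secretion rate; open flowers keep only what insects leave.  Per-flower
sugar accumulation rates (µg flower⁻¹ h⁻¹, from capillary volume ×
Brix-to-sugar conversion × 60/interval) are averaged into one cell mean
per (study day, period, location, treatment) and modelled as

  y ~ treatment (+ location), random intercepts for year and site-within-year,

fitted by the package's own REML (profiled variance ratios, closed-form
GLS).  The wastage statistic is the ratio of estimated marginal means,
100 × EMM(accessible)/EMM(inaccessible); pollen analogously uses a
log-link negative-binomial regression of summed corner-square counts on
anthesis stage, 100 × EMM(end)/EMM(begin).  Uncertainty comes from a
cluster bootstrap resampling whole study days; model simplification uses
likelihood-ratio tests on ML fits.

**Budget.**  Per study day: flower density = mean racemes m⁻² × mean
flowers raceme⁻¹; insect density = mean transect count / 50 m²; supply
per m² h = flower density × bagged-flower secretion rate; per-insect
supply = supply / insect density; kg sugar ha⁻¹ h⁻¹ = µg flower⁻¹ h⁻¹ ×
flowers m⁻² × 10⁻⁵; colony equivalents = kg ha⁻¹ h⁻¹ × 1000 / 1186 g
(the lifetime sugar intake of a *Bombus terrestris* colony).

**Phenology.**  Each crop's planted area is spread uniformly over its
bloom months; monthly sums show when mass-flowering resources peak.

A synthetic-data module generates complete studies with the real design's
nested structure (year / site / day / plant pair) so the entire pipeline
runs and can be validated without any field data.

## Worked example

```python
from floralwastage import RunConfig, run_pipeline

res = run_pipeline(RunConfig(seed=42, bootstrap=500))
print(res["estimates"][["resource", "percent_uncollected", "ci_low", "ci_high"]])
```

prints (seed 42):

```
nectar sugar: 70% uncollected (95% CI 64-76%)
pollen: 18% uncollected (95% CI 15-22%)
pooled over 20 study days:
  supply      0.14 kg sugar ha^-1 h^-1 (0.12 CE)
  uncollected 0.10 kg sugar ha^-1 h^-1 (0.08 CE)
  per insect  1728 uL h^-1 (851 mg sugar h^-1)
```

The synthetic study was generated with a true uncollected-nectar fraction
of 69% and pollen fraction of 19%; the fitted estimates (70%, 18%) recover
them within the bootstrap CIs.  The budget lines say a hectare of bloom
secretes 0.14 kg of nectar sugar per hour, of which 0.10 kg goes
uncollected — about a tenth of a bumblebee colony's lifetime sugar intake
left on the table per hectare-hour — and each observed forager has about
1.7 mL of nectar per hour available to it, far beyond what one insect can
carry.

The `examples/` directory has one short script per capability
(conversions, wastage estimation, budgeting, phenology, full pipeline),
and the same stages are exposed as a thin CLI:

```bash
floralwastage simulate --seed 1 --out data/
floralwastage report --out results/ --seed 1 --bootstrap 1000
```

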