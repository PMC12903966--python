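# stoichlim

Soil enzyme stoichiometry, stoichiometric microbial carbon-use efficiency, and
soil organic carbon (SOC) fraction accounting for grassland-restoration soil
cohorts.

## The scientific problem

Degraded grasslands lose soil carbon, and restoring them raises the question
of *mechanism*: does restoration rebuild SOC by relieving the nitrogen
limitation of the soil microbial community, shifting microbial metabolism and
routing carbon into the stable mineral-associated pool?  Answering it requires
chaining several community-level calculations over plot-scale soil data:

1. **Ecoenzymatic vector analysis.**  With C-acquisition activities
   (β-glucosidase βG, cellobiohydrolase CBH), N-acquisition activities
   (N-acetyl-glucosaminidase NAG, leucine aminopeptidase LAP, urease UE) and
   P-acquisition activity (phosphatase AP), each sample maps to

   $$x = \frac{\ln(\mathrm{βG{+}CBH})}{\ln \mathrm{AP}}, \qquad
     y = \frac{\ln(\mathrm{βG{+}CBH})}{\ln(\mathrm{NAG{+}LAP{+}UE})}$$

   with vector angle $= \mathrm{deg}\,\mathrm{atan2}(x, y)$ and length
   $= \sqrt{x^2+y^2}$.  Angles below 45° indicate microbial N limitation,
   above 45° P limitation; longer vectors indicate stronger C limitation.

2. **Stoichiometric carbon-use efficiency.**  With the enzyme ratio
   $\mathrm{EEA}_{C:N} = \mathrm{βG}/(\mathrm{NAG{+}LAP})$, biomass ratio
   $B_{C:N} = \mathrm{MBC}/\mathrm{MBN}$ and resource ratio
   $R_{C:N} = \mathrm{DOC}/\mathrm{TDN}$,

   $$S_{C:N} = \frac{1}{\mathrm{EEA}_{C:N}}\cdot\frac{B_{C:N}}{R_{C:N}},
     \qquad
     \mathrm{CUE}_{ST} = \mathrm{CUE}_{max}\,\frac{S_{C:N}}{S_{C:N}+K_N}$$

   with $\mathrm{CUE}_{max}=0.6$ (thermodynamic ceiling) and $K_N=0.5$
   (half-saturation), so $\mathrm{CUE}_{ST}(K_N)=0.3$ exactly.

3. **Carbon accounting.**  Areal stocks
   $\mathrm{SOC\ stock\ [kg\,m^{-2}]} = \mathrm{SOC}\times BD \times
   \mathrm{depth}$, microbial biomass by fumigation differencing, and the
   POC (particulate, >53 µm) / MAOC (mineral-associated, <53 µm) split.

4. **Inference.**  One-way ANOVA with Tukey HSD letters, Pearson correlation
   networks, random-forest predictor importance (%IncMSE, 1000 trees), and a
   recursive path analysis (standardized coefficients, ML chi-square) of
   angle → CUE_ST → POC → MAOC → SOC stock.

Because plot-level field data of this kind are typically unpublished, the
package ships a first-class synthetic cohort generator that reproduces the
study design (3 treatments — degraded, passive restoration, active
restoration — × 2 depth layers × 3 replicate plots) with right-skewed,
positive variables and treatment effects encoding the reported percent
changes.  Every analysis stage is therefore testable end to end.

## Worked example

```python
from stoichlim import EnzymeActivitySet, vector_metrics, cue_from_sample

act = EnzymeActivitySet(bg=100, cbh=40, nag=40, lap=30, ue=60, ap=600)
m = vector_metrics(act)
print(f"angle = {m.angle_deg:.2f} deg, length = {m.length:.3f}, "
      f"class = {m.limitation_class}")

res = cue_from_sample(doc=60, tdn=5, mbc=120, mbn=15, bg=100, nag=40, lap=30)
print(f"s_cn = {res.s_cn:.4f}, cue_st = {res.cue_st:.4f}")
```

prints

```
angle = 37.27 deg, length = 1.276, class = N-limited
s_cn = 0.4667, cue_st = 0.2897
```

The angle below 45° classifies this community as N-limited; its
$S_{C:N}=0.467$ sits just below the half-saturation constant, so CUE_ST
(0.29) is just below $\mathrm{CUE}_{max}/2$.

The full pipeline runs from the shell:

```bash
stoichlim run-all --seed 20220801 --out-dir results/
```

writing `cohort.csv`, `metrics.csv`, `cue.csv`, `stocks.csv`,
`summaries.csv`, `correlations.csv`, `importance.csv`, `path_fit.csv`, a
`run_log.txt` and a `manifest.json` that together make the run reproducible
bit for bit.  The same stages are available as numbered narrative drivers
under `analysis/` (`01_simulate_cohort.py` … `06_path_analysis.py`); on the
default seed they show active restoration raising the vector angle (22.1° →
26.3° in topsoil), collapsing CUE_ST (−60%), and separating SOC stock, POC
and MAOC from the degraded control with distinct Tukey letters, while
passive restoration raises the angle but leaves the C pools statistically
indistinguishable from degraded.

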