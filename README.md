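# fraglands

Forward-time landscape genetics of butterfly populations along urban
density gradients: how anthropogenic fragmentation erodes population
persistence and genetic diversity, and how dispersal ability mediates
the damage.

Urbanisation divides butterfly habitat (green spaces) into fragments
embedded in a resistant matrix of buildings, roads and forest.
`fraglands` simulates this system end to end for a mobile butterfly such
as the small cabbage white:

* **landscape** — synthetic land-cover rasters along transects from a
  city centre, with per-zone class composition drawn from
  urbanisation-level ranges; resistance mapping; green-patch extraction
  and stepwise habitat-site placement (3 sites per patch ≥ 5 ha, 1 per
  1–5 ha patch, remainder random).
* **connectivity** — least-cost cost-distances on the 8-connected pixel
  graph (edge = step length x mean resistance of both pixels) and the
  site x site cost matrix, truncated at a dispersal budget in
  cost-metres (`B` cost-metres buy `B/r` metres at resistance `r`).
* **simulator** — a generation-stepped, site-occupancy individual-based
  model: Poisson(300) clutches with 99% birth mortality, multiple
  paternity with linear cost kernels, Mendelian inheritance at 500
  biallelic SNP loci, 95% adult mortality, sex-specific juvenile
  dispersal budgets (females 4000 / males 1350 cost-metres; a reduced
  scenario halves both).
* **genetics** — observed and expected heterozygosity
  (H_obs = mean_i h_i, H_exp = mean_i 2 p_i q_i), the dominant-marker
  (AFLP) estimator q = sqrt(f) from band-absence frequencies, per-zone
  summaries and nearest-neighbour pooled estimates.
* **analysis** — replicate summaries with 95% CIs (mu ± 1.96 σ/√n),
  decline tables at generations 10 and 100, one-way ANOVA with Scheffé
  post-hoc tests, and the diversity–distance gradient regression on
  centred-reduced values.
* **synthetic_data** — reproducible scenario presets (the full
  four-transect geometry, a small single-transect variant, a two-patch
  toy) and an AFLP-like dominant-marker generator with a controllable
  urban-gradient signal.

The model and its defaults are documented in [docs/methods.md](docs/methods.md).

## Worked example

Run three short replicates on the small preset and summarise them:

```python
from fraglands import run_study

study = run_study("single-transect-small", seed=3, n_generations=30)
series = study["normal"]
for zone in series.zones:
    s = series.summarize(zone, 30, "N")
    h = series.summarize(zone, 30, "H_obs")
    print(f"{zone:9s} N = {s.mean:5.1f} ± {s.sd:4.2f}   H_obs = {h.mean:.3f}")
```

which prints (seed 3):

```
A-high    N =  20.0 ± 0.00   H_obs = 0.267
A-medium  N =  20.0 ± 0.00   H_obs = 0.377
A-low     N =  20.0 ± 0.00   H_obs = 0.385
```

On this miniature transect every zone is small enough that the normal
female budget (4000 cost-metres) keeps all 20 sites per zone occupied,
but the drift gradient is already visible: all zones start at the
Hardy–Weinberg maximum H_obs = 0.5, and after 30 generations the
city-centre zone, whose sites sit in small mutually isolated demes, has
drifted to markedly lower diversity than the suburban and rural zones.
The full `"marseille-like"` preset (12 zones, ~1650 sites, 5 runs x 100
generations x 2 dispersal scenarios) shows the full-scale
pattern, including the persistence gradient: rural zones stay near full
occupancy with >75% of initial H_obs after 100 generations, downtown
occupancy drops below 85 within 10 generations (below 40 with halved
budgets) and loses well over half of its initial observed
heterozygosity.

The same workflow is scriptable from the shell:

```sh
fraglands generate-landscape --preset marseille-like --seed 1 --out out/
fraglands simulate --preset single-transect-small --seed 11 --out out/
fraglands analyse --series out/series_normal.csv --out out/analysis/
```

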