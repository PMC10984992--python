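# vscpipe

Vertical structural complexity (VSC) of plant communities: plot-level
metrics, environmental driver attribution, and spatial upscaling, with a
fully synthetic survey generator for end-to-end testing.

## Scientific problem

The vertical arrangement of plant canopies — how tall a community grows and
how evenly its biomass is layered — shapes light capture, microclimate and
habitat structure. Across steep environmental gradients such as the Tibetan
Plateau, communities range from multi-layered forests to centimetre-scale
alpine deserts, and a recurring question is which environmental factors
control that structure: *resource* factors that plants consume or depend on
directly (temperature as energy, water availability, soil nutrients) or
*non-resource* conditions that constrain growth without being consumed
(oxygen partial pressure, wind, temperature fluctuation, radiation).

`vscpipe` implements that analysis chain:

1. **Metrics** (`vscpipe.metrics`) — three plot-level VSC metrics:
   - `height_max`: tallest plant in the plot;
   - `height_var`: coefficient of variation of plant heights
     (sample SD / mean);
   - `height_even`: Shannon evenness of plant material across height
     classes, normalised by ln(number of classes). Shares per class are
     basal-area fractions in woody plots and combined relative-height /
     relative-coverage importance values in grassland plots. Class widths
     default to 1 m (forest), 0.10 m (shrubland) and 0.01 m (grasslands).
2. **Driver attribution** (`vscpipe.drivers`) — Pearson screening of 13
   candidate environmental variables down to a non-collinear working set,
   bidirectional stepwise AIC regression per vegetation type, LMG relative
   importance (averaging incremental R² over all predictor orderings),
   variance inflation factors, a resource vs non-resource decomposition of
   explained variance, bootstrap size-matching across vegetation types, and
   Moran's I for spatial autocorrelation of residuals.
3. **Spatial upscaling** (`vscpipe.upscale`) — ordinary kriging of
   environmental point samples onto grids (weighted-least-squares variogram
   fitting, exact at sample locations) and random-forest prediction of the
   three metrics onto raster stacks with hold-out validation.
4. **Synthetic surveys** (`vscpipe.synthetic`) — a generator producing
   plot-level plant records (2,013 plots across forest, shrubland, meadow,
   steppe and desert regimes by default) whose metrics follow configurable
   linear environmental effects, so every stage can be validated against a
   known ground truth.
5. **I/O and CLI** (`vscpipe.io`, `vscpipe.cli`) — CSV plot/environment
   tables, ESRI ASCII raster grids, a pipeline driver and the `vsc`
   command-line tool.

See `docs/methods.md` for definitions, assumptions and limitations.

## Worked example

```python
from vscpipe import (
    PlantRecord, Plot, compute_vsc, SyntheticConfig, generate_plots,
    generate_env_table, vsc_table, screen_variables, stepwise_select,
)

# --- plot-level metrics on a four-tree forest plot -----------------------
plot = Plot(
    plot_id="F001",
    veg_type="forest",
    records=[
        PlantRecord(species="Abies", height=21.5, dbh=38.0),
        PlantRecord(species="Abies", height=14.2, dbh=24.5),
        PlantRecord(species="Betula", height=9.8, dbh=16.0),
        PlantRecord(species="Betula", height=4.1, dbh=7.5),
    ],
)
res = compute_vsc(plot)
print(f"height_max  = {res.height_max:.2f} m")
print(f"height_var  = {res.height_var:.4f}")
print(f"height_even = {res.height_even:.4f}  ({res.n_classes} occupied 1 m classes)")
```

```
height_max  = 21.50 m
height_var  = 0.5921
height_even = 0.7060  (4 occupied 1 m classes)
```

```python
# --- driver attribution on a synthetic survey ----------------------------
cfg = SyntheticConfig(seed=42)          # 2,013 plots in five regimes
plots = generate_plots(cfg)
vsc = vsc_table(plots)
env = generate_env_table(plots)

screen = screen_variables(env)          # 13 candidates -> 9 kept
print("kept:", screen.kept)

forest = (vsc.merge(env[["plot_id"] + screen.kept], on="plot_id")
             .query("veg_type == 'forest'"))
m = stepwise_select(forest["height_max"], forest[screen.kept],
                    response="height_max")
print("selected:", m.selected_vars)
print(f"R2 = {m.r2_total:.3f}; resource share = {m.resource_share:.1f}%")
for var, share in sorted(m.r2_by_var.items(), key=lambda kv: -kv[1]):
    print(f"  {var:10s} {share:.3f}")
```

```
kept: ['MAT', 'AI', 'pH', 'SOC', 'TN', 'T_diurnal', 'PO2', 'UR', 'Wind']
selected: ['MAT', 'AI', 'TN', 'T_diurnal', 'Wind']
R2 = 0.450; resource share = 88.2%
  AI         0.383
  Wind       0.044
  T_diurnal  0.009
  TN         0.007
  MAT        0.007
```

In this run the forest canopy height is driven mainly by water availability
(the aridity index AI), with resource variables together accounting for
88.2% of the explained variance — while in the harsher desert regime the
same analysis attributes most explained variance to non-resource conditions
(oxygen partial pressure, wind).

The same pipeline is available from the command line:

```bash
vsc all --out results/run1 --seed 42          # simulate -> report
vsc drivers --vsc vsc.csv --env env.csv --bootstrap 237x100 --out models/
vsc upscale --vsc vsc.csv --env env.csv --raster rasters/ --seed 1 --out maps/
```

## Repository layout

```
src/vscpipe/     package (registry, metrics, synthetic, drivers, upscale, raster, io, cli)
tests/           pytest suite (unit, property and acceptance tests)
scripts/         acceptance.py — end-to-end run with JSON summary
docs/methods.md  methods note: definitions, assumptions, limitations
```
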