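# mottle

Quantifying wing colour and pattern variability — within and between
species — from calibrated specimen photographs, and testing ecological
explanations for it while controlling for phylogeny.

Aposematic (warningly coloured) animals are expected to be uniform:
predators learn a consistent signal faster.  Camouflaged animals can
afford, or even benefit from, being variable.  Testing that prediction
across many species requires (1) objective phenotype measurement from
images, (2) a statistic for *within*-species variability, and (3) a
comparative test that does not mistake shared ancestry for ecology.
`mottle` implements that pipeline end to end for wing images of moths
(or any taxon photographed against a grey standard), plus a synthetic
data generator with known ground truth so every stage is testable
without museum downloads.

## What it computes

**Image metrics.**  Images are normalised to a middle-grey standard
(≈40% reflectance), resampled to 10 px/mm, and reduced per wing ROI to
six metrics: mean hue, saturation and brightness (hexcone HSV), and
three granularity descriptors from a Fourier band-pass energy spectrum
over 100 scale bands (0.1–10 mm) —

* dominance (maxPower): energy of the most energetic scale band,
* marking size (maxFreq): the scale of that band, in mm,
* contrast (sumPower): energy summed over all bands.

**Trait table.**  Per species × wing × metric: the mean
x̄ (interspecific variation) and the coefficient of variation
cv = s/x̄ (intraspecific variability).

**Comparative test.**  Each trait column is tested against each
ecological factor (anti-predator strategy, diel-activity, diet) with a
simulation-based phylogenetic ANOVA: the observed one-way F is compared
with F statistics of traits simulated under Brownian motion on the
ultrametric phylogeny,

&nbsp;&nbsp;&nbsp;&nbsp;p = (1 + #{F_sim ≥ F_obs}) / (nsim + 1),

with Holm-corrected simulation-null post hoc contrasts and η² =
SSB/(SSB+SSW) effect sizes.  Results are summarised as an effect-size
heatmap (metric × statistic rows, hypothesis × wing columns) with
significance flags.

See `docs/methods.md` for the models, numerical conventions and
limitations.

## Worked example

A small synthetic study: 16 species (8 aposematic-like, 8
camouflaged-like), 15 specimens each.  The camouflaged generators carry
3.5× the within-species marking-scale dispersion — the only parameter
that differs between groups.

```python
import pandas as pd
from mottle import PipelineConfig, run_pipeline
from mottle.pipeline import SyntheticBlock

config = PipelineConfig(
    out_dir="demo_out",
    seed=7,
    nsim=500,
    make_figure=False,
    synthetic=SyntheticBlock(n_per_group=8, n_specimens=15, wings=["forewing"]),
)
summary = run_pipeline(config)
strategy_cv = summary.query("hypothesis == 'strategy' and stat == 'cv'")
print(strategy_cv[["metric", "eta2", "p_phylo", "p_holm_family", "significant"]]
      .sort_values("eta2", ascending=False).to_string(index=False))
```

prints

```
      metric     eta2  p_phylo  p_holm_family  significant
marking_size 0.620093 0.001996       0.013972         True
   dominance 0.400382 0.001996       0.013972         True
   wing_area 0.099586 0.123752       0.618762        False
         hue 0.077146 0.209581       0.838323        False
    contrast 0.065932 0.257485       0.838323        False
  brightness 0.037503 0.381238       0.838323        False
  saturation 0.013814 0.612774       0.838323        False
```

Reading this: the designed effect is recovered — within-species marking
size is far more variable in camouflaged-like species (η² = 0.62,
simulation p at its floor of 1/501, significant after Holm within the
strategy × cv family).  Pattern dominance also reaches significance:
with more dispersed marking scales the peak-band energy disperses too,
an emergent consequence of the single designed difference.  Colour
metrics and wing area, whose generators are identical between groups,
stay at noise level.  All intermediate tables (`metrics.csv`,
`traits.csv`, `results.csv`, `posthoc.csv`, `summary.csv`) are written
to `demo_out/`.

The same pipeline runs from the command line over a YAML config, with
subcommands for each stage (`generate`, `metrics`, `aggregate`, `test`,
`summarize`, `all`):

```sh
mottle all --config study.yaml
```

For real data, the config's `manifest` block points at a specimen CSV
(image/mask paths, px-per-mm, grey-card rectangle), a Newick tree and a
species-factor CSV; see `mottle/io.py` docstrings for the exact layout.

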