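# pulseratchet

Quantification of **pulsatile apical constriction and ratcheting** from
per-cell area time series and confocal image stacks.

During tissue invagination — the canonical example being ventral furrow
formation in the gastrulating *Drosophila* embryo — epithelial cells shrink
their apical surface through repeated actomyosin contraction pulses. After
each pulse the surface either relaxes back (non-ratcheted pulsation) or is
stabilized at the constricted state (*ratcheting*), so that area is lost
incrementally. This package provides the analysis chain used to quantify
that behavior from segmentation-derived per-cell measurements, for
developmental biologists working with EDGE-style per-cell feature exports
and confocal stacks of curved epithelia.

## What it computes

For a per-cell apical-area trace A(t) (μm², sampled every few seconds):

- **Constriction rate** r(t) = −ΔA/Δt (μm²/min; positive while the cell
  constricts), finite differences at interval midpoints, optionally
  smoothed with a centered moving mean.
- **Pulse detection**: strict local maxima of the unsmoothed rate (and of
  the inverted rate for expansion peaks); only positive peaks count. The
  per-cell **mean peak constriction/expansion rate** is the group-level
  readout.
- **Ratchet statistic**: after removing a least-squares cubic trend,
  pulsation peaks (local maxima and minima of the residual) are located and
  the mean difference in area between consecutive peaks is expressed as a
  percentage of the initial area. Negative values mean the surface shrinks
  incrementally with every pulse (a ratchet); values near zero mean the
  surface relaxes back.
- **Behavioral categories**: the smoothed area ratio 7 min after onset
  classifies each cell as *constricted* (< 0.5), *impaired* (0.5–1) or
  *expanded* (> 1).
- **Group statistics**: fold changes of rates relative to the control-group
  mean, pooled t-tests, one-way ANOVA with Tukey post hoc, and the
  conservative effect size d = (x̄₁ − x̄₂)/(2·s_max) with s_max the maximal
  group SD of the dataset and |d| < 0.5 treated as not significant.

On the imaging side: a grid-based **surface projection** (per grid unit,
the z-profile's intensity peak defines a height map, which is
Gaussian-smoothed and used to mean-project the slices around the surface,
with a half-grid-offset second pass to suppress grid artifacts), the two
background rules (lowest-plane mean; stack mean minus one SD), ~4 μm apical
mean projections, whole-stack intensity fold-change time courses, per-cell
mean intensities within label images, cell area/anisotropy from second
moments, and Pearson colocalization.

Because no raw data from the original study are public, a first-class
synthetic-data module generates pulsatile traces, behavioral-class cohorts,
surface phantoms and labeled movies with known ground truth; every analysis
stage is validated against it.

## Worked example

```python
from pulseratchet.synthetic import (control_cohort_params,
                                    knockdown_cohort_params, gen_cohort)
from pulseratchet.model import ConstrictionDynamicsModel

control, _ = gen_cohort(control_cohort_params(n_cells=100, seed=1))
kd, _ = gen_cohort(knockdown_cohort_params(n_cells=100, seed=2))
for t in control: t.meta["group"] = "control"
for t in kd:      t.meta["group"] = "knockdown"

res = ConstrictionDynamicsModel(control + kd).fit()
print(res.summary())
```

```
Constriction dynamics summary
================================================================
cells: 200 (0 excluded by tracked-duration rule)

Peak pulsation rates (μm²/min, per-cell means):
    group     polarity  mean_um2_per_min  sd_um2_per_min  n_cells
  control constriction              9.94            1.06      100
  control    expansion              3.18            0.75      100
knockdown constriction              8.78            1.56      100
knockdown    expansion              3.80            1.53      100

categories [control] (n=100): constricted 100%, impaired 0%, expanded 0%
categories [knockdown] (n=100): constricted 50%, impaired 44%, expanded 6%

Ratchet statistic (% initial area per pulse interval):
   category  mean_pct  sd_pct  n_cells
constricted    -10.90    1.49      150
   expanded      1.88    0.53        6
   impaired     -3.99    2.04       44
```

The control cohort recovers its target peak constriction rate
(9.94 ± 1.06 vs the 9.9 ± 1.1 μm²/min it was generated with), the
knockdown cohort reproduces its 50/44/6% class mixture exactly, and
ratcheted (constricted) cells score strongly negative on the ratchet
statistic while expanding cells do not. Comparing control cells against the
knockdown cells with deficient constriction (impaired + expanded):

```python
deficient = [t for t in kd if t.meta["class"] in ("impaired", "expanded")]
for t in deficient: t.meta["group"] = "deficient"
cmp = ConstrictionDynamicsModel(control + deficient).fit() \
        .compare_rates("control", "deficient")
# constriction: fold 0.78 (−22%), expansion: fold 1.49 (+49%)
# ratio_of_changes: 2.2  — the expansion-rate defect dominates
```

A command-line interface mirrors the library
(`pulseratchet simulate-traces | analyze-traces | simulate-stack |
project-surface | quantify-intensity | stats | blind-order`); every
subcommand takes `--seed`, `--config` (YAML) and `--out`, and all file
writes are atomic.

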