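# octvol

Volumetry of arbitrary retinal entities from OCT B-scan contour
annotations, with the complete agreement-validation statistics used to
qualify such measurements, and a synthetic phantom generator so the whole
pipeline is testable without clinical data.

The measurement rule is deliberately simple: on every B-scan where the
entity of interest is visible, its perimeter is traced as a closed
polygon; the traced cross-sectional areas are summed and multiplied by the
inter-scan distance,

```
volume [mm^3] = sum(area_i [mm^2]) * scan_spacing [mm]
```

Two protocols are provided:

* **free** — sum the areas as drawn (e.g. a foveal cavity or foveoschisis
  space traced on each scan where it appears);
* **circular_roi** — first truncate every contour at the two vertical
  chord borders of a foveal circle (default 1000 µm diameter), so the
  summed slabs reproduce the cylinder over that circle (central retinal
  volume).

## Package layout

| module | contents |
| --- | --- |
| `octvol.annotation_io` | JSON annotation-stack format, paired-measurement CSVs, result serialization (round-trip safe) |
| `octvol.geometry` | shoelace polygon area, simplicity validation, circle-chord half-widths, vertical-strip clipping |
| `octvol.volumetry` | `entity_volume` (free) and `foveal_volume` (circular ROI) slab sums |
| `octvol.agreement` | Bland–Altman bias/CR/LOA with CIs, power for agreement designs (closed-form integration + Monte-Carlo oracle), plot data |
| `octvol.phantom` | parametric shapes (ellipsoid, slab/cylinder, paraboloid pit, lens) with closed-form volumes, raster rendering, simulated noisy observers |
| `octvol.cli` | the `octvol` command-line interface |

## CLI

```bash
# measure a labelled entity in an annotation stack (free protocol)
octvol measure --input stack.json --label FS --out result.csv

# central retinal volume inside the 1 mm foveal circle
octvol measure --input stack.json --label retina \
    --roi-radius-mm 0.5 --roi-auto-center --out rv.json

# Bland–Altman agreement of paired volumes (subject,value_a,value_b CSV)
octvol agreement --pairs pairs.csv --out ba.json --round 4

# power of an agreement study at clinical limit delta
octvol power --bias -0.0021 --sd 0.0057 --delta 0.01 --n 30 --out power.json

# phantoms with known analytic volume
octvol simulate --shape lens --params h=0.2,R=0.5 --spacing 0.12 \
    --n-scans 49 --out stack.json --seed 2024
octvol simulate-study --subjects 30 --obs1-noise 0.02 --obs2-noise 0.02 \
    --sessions 2 --seed 2024 --out pairs/
```

Exit codes are 0 (success), 1 (runtime error), 2 (usage error).  Every
command writes a `.meta.json` sidecar with the tool version, parameters
and SHA-256 hashes of its inputs; re-running with identical inputs and
seed reproduces outputs byte for byte.

## Agreement statistics

For paired differences `d = a - b` (in the order the comparison is
named): bias = mean(d), s = sample SD, CR = 1.96·s, LOA = bias ± CR,
bias CI = bias ± 1.96·s/√n, LOA CI = LOA ± 1.96·SE with
SE = √(3s²/n).  `loa_se_mode="table1"` switches the LOA SE to 3s/√n, a
convention seen in some published tables.  `agreement_from_summary`
reconstructs the full result from a published (bias, CR, n) triple for
internal-consistency checks of reported tables.

`agreement_power` answers: with differences ~ Normal(bias, sd²) and n
pairs, what is the probability that both LOA confidence intervals fall
inside the clinical agreement band (−δ, +δ)?  The `approximate` method
integrates the exact sampling distributions of the mean and SD; the
`monte_carlo` method simulates the full estimator pipeline and serves as
the oracle.

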