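# microquant

Single-cell quantification of myeloid-cell marker co-expression in
multiplex immunofluorescence images of post-mortem human brain tissue.

## The problem

Microglia and perivascular macrophages — the Iba1-positive myeloid cells of
the brain — are heterogeneous: the classical "activation" marker HLA-DR
captures only part of that heterogeneity, so studies co-label HLA-DR with
additional markers of interest (MOIs such as P2RY12, TMEM119, CD74, CD206,
CD32, CD163, L-Ferritin) and ask how marker expression co-occurs at the
single-cell level. In manually counted immunofluorescence sections the
practical single-cell measurement is the **point intensity (PI)**: the 8-bit
grey value (0–255) of one pixel placed on each Iba1-positive cell body, in
each channel. `microquant` implements that measurement protocol and the full
statistical battery built on it:

- **Background and positivity.** Per channel, background is the mean grey
  value of ≥ 5 sampled background points. A cell is Iba1-positive iff
  PI ≥ background + 20 grey values; HLA-DR/MOI positivity uses a per-marker
  threshold in the 20–40 range (inclusive comparison).
- **Validation of the single pixel.** For each cell, 10 pixels are
  re-sampled at random within the soma; the Pearson correlation between the
  10-point mean and the original PI (banded weak ≤ 0.3 < moderate < 0.8 ≤
  strong) quantifies how well one pixel represents the cell.
- **Abundance.** Percent of Iba1-positive cells immunoreactive per marker,
  per donor and region; grey vs white matter by paired t-test; Spearman
  correlations against donor age and post-mortem delay; Iba1-positive cell
  density (cells/mm²) inside a polygonal region of interest; a
  morphology × marker cross-tabulation over the five microglial
  morphologies (ramified, hypertrophic, dystrophic, rod, amoeboid).
- **Co-labelling.** Pooled Pearson correlation of HLA-DR and MOI PIs,
  repeated on the top decile of either marker and with/without 8-bit
  saturated (PI = 255) cells; binarisation of each Iba1-positive cell into
  HLA-DR^high/low × MOI^high/low against per-marker thresholds above
  background; chi-square test of independence on the resulting 2×2 counts
  (n_hh, n_hl, n_lh, n_ll); and unpaired t-tests on the per-donor
  conditional percentages (e.g. %MOI-high within HLA-DR-high vs within
  HLA-DR-low).

Because the original specimens cannot ship with code, the package includes a
first-class synthetic generator: cells with the five morphology classes are
placed without overlap, given jointly planted HLA-DR/MOI high–low states
whose dependence is an explicit **log odds ratio** (the unique 2×2 table
with the requested marginals and odds ratio, found by root finding), and
rendered into 4-channel 8-bit TIFFs (flat background + morphology-specific
shape templates + Gaussian noise, clipped at 255). Every downstream stage is
tested against this planted truth.

## Worked example

```python
import pandas as pd
from microquant import simulate, quantify, colabel, abundance

# simulate three donors (GM), render and measure them
frames, bgs = [], []
for i in range(3):
    cfg = simulate.SimulationConfig(
        n_cells=200, case_id=f"C{i}", dependence_log_odds=1.5, seed=10 + i,
    )
    truth = simulate.generate_cells(cfg)
    image = simulate.render_image(truth, cfg)
    points = simulate.make_background_points(truth, cfg)
    backgrounds = {
        ch: quantify.estimate_background(image, ch, grp[["row", "col"]].to_numpy())
        for ch, grp in points.groupby("channel")
    }
    frames.append(quantify.measure_cells(image, truth, backgrounds))
    bgs.append({m: backgrounds[m].value for m in ("hla_dr", "moi")})
cells = pd.concat(frames, ignore_index=True)

print(f"Iba1-positive: {cells['iba1_positive'].sum()} of {len(cells)} cells")
report = colabel.pearson_pooled(cells[cells["iba1_positive"]])
print(f"pooled Pearson r = {report.r:.3f} ({report.band}), p = {report.p:.2e}")

bg = {m: sum(b[m] for b in bgs) / 3 for m in ("hla_dr", "moi")}
cat = colabel.categorize_highlow(cells, bg)
counts = colabel.fourway_counts(cat)
print(f"four-way counts: hh={counts.n_hh} hl={counts.n_hl} "
      f"lh={counts.n_lh} ll={counts.n_ll}")
chi2 = colabel.chi_square_independence(counts)
print(f"chi-square = {chi2['chi2']:.1f} (df={chi2['df']}), p = {chi2['p']:.2e}")
cond = colabel.conditional_proportion_test(cat)
print(f"%MOI-high | HLA-DR-high = {cond['mean_group_high']:.1f}%, "
      f"| HLA-DR-low = {cond['mean_group_low']:.1f}%  "
      f"(t = {cond['t']:.2f}, p = {cond['p']:.4f})")
```

Output:

```
Iba1-positive: 576 of 600 cells
pooled Pearson r = 0.333 (moderate), p = 2.16e-16
four-way counts: hh=174 hl=134 lh=60 ll=208
chi-square = 69.1 (df=1), p = 9.33e-17
%MOI-high | HLA-DR-high = 56.6%, | HLA-DR-low = 22.6%  (t = 9.23, p = 0.0008)
```

Reading it: with a planted log odds ratio of 1.5 between the HLA-DR-high
and MOI-high states, the pooled PI correlation is only moderate (single
pixels are noisy), but the categorical analysis recovers the dependence —
the chi-square firmly rejects independence, and MOI-high cells are ~2.5×
more frequent inside the HLA-DR-high population than outside it. The
observed four-way counts give an empirical log odds ratio of
`counts.log_odds_ratio()` ≈ 1.5.

The same analyses are available from the shell:

```sh
microquant simulate --out fix/ --n-cells 150 --seed 1
microquant quantify --tiff fix/image.tif --cells fix/cells.csv \
    --background fix/background.csv --out quantified.csv
microquant analyze-colabel --cells quantified.csv --out colabel.json
microquant report --config run.yaml     # full multi-donor pipeline
```

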