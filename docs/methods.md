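# Methods

## The measurement model

All quantities derive from **point intensities** (PIs): the 8-bit grey
value (0–255) of a single pixel at a manually placed cell-body coordinate,
one per channel (Hoechst, Iba1, HLA-DR, one marker of interest). Coordinates
are 0-based `(row, col)` throughout, and there is no interpolation or
neighbourhood averaging — the single-pixel read is the protocol, and its
known weakness is addressed explicitly by the validation operation (below)
and by the categorical analysis rather than by smoothing.

**Background.** Per channel and image, the background estimate is the
arithmetic mean of ≥ 5 sampled background pixels. The protocol does not
prescribe how the five measurements combine, so the mean is a package
choice; it is the estimator a rater averaging readings would use. Whether
background points are shared across channels or chosen per channel is
configurable; per-channel is the default since autofluorescence differs by
fluorophore.

**Positivity.** A cell is Iba1-positive iff
`PI_iba1 ≥ background + 20` grey values; HLA-DR/MOI positivity uses a
per-marker threshold, documented range 20–40 (values outside warn but do
not fail). The comparison is **inclusive** (≥) at the boundary: "N grey
values above background" does not pin the boundary case, and an inclusive
rule makes the threshold itself attainable, which the tests assert exactly.

**High/low categorisation.** Among Iba1-positive cells, each marker is
binarised as high iff `PI ≥ background + t_high`. `t_high` is per-marker
configuration with default 40 — the top of the positivity range — because
in practice it was determined per marker from the original images and never
recorded; the invariant `t_high ≥ positivity threshold` is enforced when
both are supplied. The four-way counts (n_hh, n_hl, n_lh, n_ll) always sum
to the Iba1-positive total in scope.

**Statistics.** Pooled Pearson correlations (two-sided p; the protocol does
not state sidedness, two-sided is the conservative default) with the
strength banding weak |r| ≤ 0.3, moderate 0.3 < |r| < 0.8, strong
|r| ≥ 0.8. The printed band boundaries overlap at 0.3 and 0.8; boundaries
are assigned to the *lower* band at 0.3 and to *strong* at 0.8, i.e. each
printed "≤/≥" is honoured and the tie-break is flagged by the banding
function's documented rule. Top-decile subsets use the nearest-rank rule
`k = ceil(n/10)` with all ties at the cut included, so the subset is never
smaller than a tenth. Saturation sensitivity removes whole cells (either
PI = 255), since a correlation needs paired observations. The chi-square
test on the 2×2 table is Pearson's without Yates continuity correction by
default (a flag enables it); expected counts below 5 warn and recommend an
exact test, which is deliberately not performed (the categorical analysis
is defined as chi-square). Conditional proportions are compared across
donors with the pooled-variance Student t-test (two-sided, unpaired); a
Welch flag exists for unequal variances. GM/WM abundance uses a paired
t-test with pairwise deletion of donors missing a region; demographics use
Spearman with average ranks on ties; summaries use the sample SD (n−1),
which is what reproduces the bundled cohort's printed 12.01 and 6.268.

**Degenerate inputs.** Zero variance in a correlation or fewer than 3
paired observations yields an `undefined` flag (NaN r) rather than an
error; an all-zero paired-difference vector reports t = 0, p = 1 exactly;
a constant non-zero difference vector is flagged `degenerate` with NaN p;
an expected chi-square count of 0 is an error.

## The validation protocol

To quantify how well one pixel represents a cell, 10 distinct pixels are
re-sampled uniformly at random (without replacement, seed-deterministic)
inside the soma disk of each cell and their mean is correlated with the
original PI, per marker. With zero within-cell variance the mean equals the
single read and r = 1; as within-soma pixel noise grows, r falls — the test
suite asserts both, and the default validation cohort size is 148 cells
(about 30 per donor across six donors, matching the design the protocol
uses).

## The synthetic generator

The generator emulates one counting field per donor/region: default
1024 × 1024 px at 1 µm/px (≈ 1 mm², the size of a white-matter counting
region) with 150 cells (≈ 143 cells/mm², a realistic Iba1 density in aged
human cortex in thin sections).

- **Joint states.** HLA-DR-high and MOI-high states are drawn from the
  unique 2×2 distribution with the configured marginals and log odds
  ratio, obtained by Brent root finding on the high/high cell (closed
  marginal constraints make the log odds ratio strictly monotone in it).
  Iba1 positivity is independent Bernoulli (default 0.95: manual counting
  occasionally marks a cell that fails the intensity threshold). Default
  marginals 0.5 (HLA-DR) and 0.4 (MOI) with log OR 1.0 plant a clear but
  incomplete overlap, the regime the co-labelling battery is designed to
  distinguish from independence.
- **Intensities.** Latent amplitudes above background are state-conditional
  Gaussians (defaults: negative 8, positive 120, SD 15 grey values over a
  background of 20, noise SD 4) truncated at 0. Nothing quantitative is
  published about the real intensity distributions, so these are free
  configuration: they are chosen to separate the states cleanly at the
  default thresholds while leaving a realistic false-positive tail from
  the negative state (emulating tissue autofluorescence).
- **Placement.** Cell centers are uniform with a hard minimum pairwise
  distance (default 12 px) via rejection sampling over a hash grid;
  clearly impossible densities fail fast with the density limit named, and
  a sampling stall fails after a bounded number of draws.
- **Rendering.** Per channel: flat background + per-cell shape template +
  independent Gaussian pixel noise, clipped to [0, 255] and rounded to
  uint8. The pixel at each cell center carries exactly the cell's latent
  amplitude, so noise-free renders are exactly decodable. Templates are
  procedural per morphology class — ramified (small soma, thin branched
  random-walk processes), hypertrophic (enlarged soma, thick bipolar
  processes), dystrophic (fragmented, beaded processes), rod (elongated
  soma parallel to the row axis), amoeboid (bare perinuclear disk) — and
  identical across marker channels for a given cell. Class identity, not
  pixel-accurate realism, is the goal; there is no PSF/optics model, no
  vessel channel, and no z-dimension.
- **Determinism.** All randomness flows from `SimulationConfig.seed`
  through separate named streams (cells, render, background points), so
  tables and rasters are byte-reproducible.

**What the generator does not emulate** — and hence what passing tests do
not show about real tissue: optical blur and bleed-through between
channels, spatially varying background/illumination, true morphology
ambiguity (classes are planted, never inferred from pixels), rater
placement error, and biological intensity distributions. Tests against the
generator validate the *measurement and inference machinery*, not any
biological claim.

## Problem sizes and calibration checks

The statistical battery is verified at the sizes where its guarantees are
sharp: marginal/dependence recovery at n = 10,000 states; type-I error of
the chi-square and conditional t-tests over 1,000 simulated datasets of
1,000 cells (must land in 5 % ± 2 % at α = 0.05); power ≥ 95 % and
direction consistency over 200 replicates at log OR 1.5, n = 2,000;
Pearson recovery of ρ ∈ {0, 0.5, 0.9} at n = 10,000 within ± 0.05. Image
renders in the suite use 300–600 cells per field, which is where the
pixel-level contracts (exact decodability, saturation, conservation) are
fully exercised; the pure-counts simulations use direct multinomial draws
from the same joint-state machinery, which is the component under test.

## Known limitations

- The ROI boundary rule (half-open, top/left inclusive) is implemented by
  a 10⁻⁷-pixel down-right shift before strict polygon containment; exact
  for axis-aligned edges, a consistent tie-break for oblique ones.
- The bundled 11-donor cohort is metadata only (age, sex, post-mortem
  delay, fixation); per-donor marker percentages from tissue are not
  reproducible without specimens and are out of scope.
- Morphology classification from pixels is out of scope; morphology is an
  annotation column (planted by the generator or supplied by a rater).
- No multiple-testing correction is applied across markers, matching the
  analysis design this package reproduces (each marker is reported at its
  nominal p); sex-stratified analyses are not implemented (cohorts this
  small cannot support them).
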