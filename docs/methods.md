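# Methods

This note documents the models behind `translocscreen`, the defaults
and why they were chosen, what the synthetic data does and does not
emulate, and the numerical decisions a user auditing results should
know about.

## The assay model

A cell expressing a GFP-tagged steroid receptor distributes a total
receptor signal `G` between nucleus and cytoplasm. We model the
nuclear fraction as a Hill function of treatment dose `d`:

```
f(d) = f_min + (f_max - f_min) * d^h / (ec50^h + d^h)
```

with defaults `f_min = 0.25`, `f_max = 0.90`, `ec50 = 10`, `h = 1.5`.
The functional form is a modeling choice — receptor-occupancy
phenomenology — not a fitted curve; it guarantees monotonicity in dose
(property-tested) and gives a concentration-dependent translocation
of the kind the assay is designed to detect. Doses are unitless
multipliers (water-sample concentration factors; hormone controls use
the same axis).

For a cell with nucleus area `A_n` and cytoplasm area `A_c`, uniform
partitioning gives the analytic intensity ratio

```
N/C(f) = (f / A_n) / ((1 - f) / A_c)
```

which is the ground truth every measurement is scored against.

## Synthetic micrographs

Fields emulate a high-content confocal reader at 300 nm effective
pixel size (2x2-binned camera), 16-bit, 512x512 px by default. Cells
are perturbed ellipses (nucleus strictly inside the cell footprint,
no overlap between cells, rejection-sampled placement) with radii
10 ± 1 px (nucleus) and 17 ± 1.5 px (cell) — a ~6 µm nucleus in a
~10 µm adherent-cell footprint — about 50 cells per field, 2 fields
per well and n = 4 replicate wells per treatment. Per-field cell
counts and exposure are not constrained by any published value; these
are package choices of a plausibly realistic density for subconfluent
adherent cultures.

The DNA channel renders each nucleus at its cell's stain intensity
(default 400 ± 40 counts); the GFP channel spreads `f(d)·G` uniformly
over nucleus pixels and `(1-f(d))·G` over cytoplasm pixels
(`G` = 250,000 ± 25,000 counts by default). Noise is a switchable
ladder, applied in this order: Gaussian PSF blur (σ = 0.8 px),
constant background offset (20 counts), Poisson shot noise on the
expected counts, Gaussian read noise (σ = 2), then clipping and
integer quantization at the bit depth. "SNR" in the benchmarks means
`sqrt(signal)` of the shot-noise-limited signal level, so SNR 10 and
SNR 20 correspond to 100- and 400-count compartments.

What the simulator does **not** emulate: optics-accurate PSFs,
autofluorescence, photobleaching, cell-cycle or morphology
heterogeneity beyond the stated jitter, mitotic/apoptotic figures,
plate-edge or spatial gradients, and sample-extraction chemistry.
Tests passing on this data show the *estimators* are correct and
well-calibrated under a controlled noise model; they do not certify
performance on real micrographs with uncorrected artifacts.

## Segmentation

Nuclei: Gaussian smoothing (σ = 1 px) → global Otsu threshold on the
DNA channel → hole filling → optional distance-transform watershed
split of touching nuclei (peak separation 7 px) → area filter
(80–2500 px) → border-touching nuclei removed by default. A blank
image yields an empty labeling with a warning, not an exception.

Cytoplasm: each nucleus seeds a cell region flooded into the GFP
foreground (watershed on a constant surface = geodesic nearest-seed
assignment inside the mask; the flood order is deterministic), capped
at 12 px Euclidean distance from the nucleus. The GFP foreground uses
a robust background threshold (median + 4·MAD of the smoothed
channel) rather than Otsu, because after translocation the channel is
not bimodal in the useful sense — bright nuclei would absorb the
whole Otsu foreground and the dim cytoplasm would be lost. On
noise-free images (MAD = 0) the cut falls back to half the typical
foreground level, which crosses a blurred step edge at the true
boundary. A nucleus with no foreground to grow into keeps a minimal
1-px ring so the record survives to QC with a `degenerate_cyto` flag
rather than disappearing. Fragments disconnected from their nucleus
by the expansion cap are discarded.

## Measurement

Compartment means are taken on **collared** regions: the nucleus
eroded by 2 px, the cytoplasm excluding a 2-px ring around the
nucleus and a 4-px ring inside the segmented cell's outer edge
(falling back to the full compartment when the collar would be
empty). Rationale: PSF + smoothing blur mixes signal across the
nuclear boundary and the segmented outline overshoots a blurred edge
by 1–2 px, and because compartments are uniform in expectation, a
collared mean is unbiased while the uncollared one is not — at high
nuclear fractions the uncollared bias on N/C reaches tens of
percent. Reported areas remain the full segmented compartments.
Background is the median intensity outside all cells, subtracted
before the means (switchable); a ratio is never formed when the
cytoplasm mean is non-positive — the record carries a flag and NaN.

QC flags: `too_small` (nucleus < 50 px), `border`, `degenerate_cyto`
(cytoplasm < 20 px), `saturated` (any GFP pixel at the bit-depth
maximum), `low_signal` (either compartment mean ≤ 1 count after
background correction). Flagged cells are excluded before wells are
aggregated, and the rejection tally is reported.

## Plate statistics

Cells are pooled across fields within a well (mean by default, median
available); wells with fewer than a configured minimum of kept cells
are excluded. Each well's mean N/C ratio is divided by the mean of
the vehicle-well means on the same plate, making the vehicle group's
mean normalized translocation exactly 1 — an identity asserted in the
tests. Hit calling follows the classical two-step many-to-one
procedure: a one-way fixed-effects ANOVA on per-well values gates at
P < 0.05; when it passes, Dunnett's test compares every treatment to
vehicle using `T_i = (mean_i - mean_0) / (s_pooled sqrt(1/n_i + 1/n_0))`
with the pooled within-group variance from all groups on the plate,
and tiers hits at adjusted P < 0.05 and P < 0.01. Statistics run on
normalized values by default; because normalization is a
plate-constant rescale, the tiers are invariant to it (tested).
Dunnett is two-sided by default (suppression is biologically
possible), with hit *recovery* counted on the increase direction
only, since activity is defined as translocation above vehicle. Each
plate is its own family; no cross-plate correction is applied.

The critical value solves `P(max_i |T_i| <= d) = 1 - alpha` for the
equicorrelated multivariate t by a 2-D quadrature: Gauss-Hermite
(80 nodes) over the shared control variate and Gauss-Legendre
(96 nodes) over the scaled-chi density of the pooled standard
deviation, with Brent root finding (xtol 1e-8). Conditional on those
two variables the `T_i` are independent normals, and for balanced
designs the product over comparisons collapses to a power, which is
what makes 69-comparison plates cheap. Accuracy: the k = 1 case
reproduces the Student-t quantile to ~1e-12; k ∈ {2,4,8},
ν ∈ {6,12,30} agree with a 10^6-draw Monte-Carlo max-|T| oracle
within 3 MC standard errors; adjusted p-values match
`scipy.stats.dunnett` to its own QMC accuracy. Degenerate inputs are
handled explicitly: zero within-group variance yields an infinite F
(p = 0, flagged) and ±∞ t-statistics map to adjusted p of 0.

Dose-response summaries report per-dose normalized means ± SEM, the
Spearman rank correlation between dose and group mean, and the lowest
dose whose Dunnett-adjusted p is below alpha (the detection
threshold); unreplicated doses are excluded with a warning.

## qPCR

Quantification uses the standard-curve method: for each gene, a
least-squares line of Cq on log10 template quantity from a 10-fold
serial dilution series (≥ 3 points spanning ≥ 2 decades); efficiency
is `10^(-1/slope) - 1`, so perfect doubling gives slope −3.3219.
Quantities interpolated from the curve are normalized per replicate
to the reference gene (β-Actin/GAPDH style) and expressed as fold
change versus the mean vehicle value, reported as mean ± SEM across
replicates; Cq values outside the calibrated range are flagged as
extrapolated. A ΔΔCt mode exists for comparison but is not the
default. Significance of fold changes reuses the Dunnett machinery
with per-gene families. The simulator plants per-condition fold
changes (including rise-then-fall profiles, so nonmonotonic
dose-response shapes are representable) under
`Cq = Cq0 - log(q)/log(1 + E) + N(0, σ)`.

A calibration note: with σ = 0.15 cycles on every Cq measurement and
n = 4 replicates, a fold-change estimate carries a relative standard
error near 10% (target and reference noise combine to
`sqrt(2)·0.15 ≈ 0.21` cycles per replicate ratio, plus the vehicle
reference mean's own error), so recovery-within-10% checks at these
settings sit at roughly one standard error and individual runs can
land outside the band by ordinary sampling variation.

## Benchmark problem sizes

The acceptance benchmarks balance fidelity against a desk-scale
runtime (about five minutes total on one CPU): segmentation and ratio
recovery use full 512-px fields (10 fields × 50 cells; 3 fields × 40
cells per fraction); the familywise-error study runs 1000 plates of
69 null samples at the well-value level, where images add nothing to
a statistics-only question; the end-to-end hit-recovery study renders
20 complete 285-well plates at reduced scale (192-px single fields,
~7 cells each) through the full image pipeline; dose ladders use
192-px fields with 10 cells. Effect sizes for planted actives
(saturating dose: f from 0.25 to ~0.88) exceed five pooled standard
deviations by a wide margin, as the design intends.

## Known limitations

- The equal-field pooling policy (cells pooled across fields within a
  well before averaging) is one of two defensible orders; both are
  implemented and tested to agree for balanced fields.
- The collar parameters (2/2/4 px) are matched to the default blur
  scale; markedly different PSFs warrant re-deriving them.
- Watershed splitting can over-segment strongly non-convex nuclei;
  the split separation parameter is exposed.
- The simulator's uniform-compartment assumption makes the analytic
  N/C ratio exact; real cells have textured compartments, for which
  the mean-intensity ratio remains defined but the ground-truth
  comparison does not transfer.
- The familywise error study inherits the conservatism of the ANOVA
  gate; the measured rate on null plates is well below the nominal
  alpha.
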