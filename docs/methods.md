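# Methods

This note documents the models, numerical choices, and synthetic-study
design behind `leafchem`, in the spirit of a package's statistical methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Imaging and segmentation

A leaf acquisition is a rows × cols × bands reflectance cube on a strictly
ascending wavelength grid (nominally 400–1000 nm, ~300 channels, ~2 nm
spacing). Segmentation is a single NDVI threshold: the channels nearest
780 nm (NIR) and 660 nm (red) are selected — the grid rarely contains those
exact wavelengths, so nearest-channel lookup is used and a warning is
raised if a requested wavelength falls outside the grid — and pixels with
NDVI strictly greater than 0 are leaf. Pixels with zero NIR + red sum are
defined as NDVI 0 and hence background: fully dark pixels are never leaf.
No vein or discoloration removal is attempted; the mask is NDVI-only. The
per-sample observation is the unweighted mean spectrum over the mask; an
empty mask raises an error rather than producing a silent NaN spectrum.

ENVI I/O is implemented directly (text header + flat binary, BSQ/BIL/BIP,
the numeric ENVI data types, both byte orders). Wavelengths are written
with 17 significant digits so a float64 grid round-trips bit-exactly.
Negative reflectance encountered on ingest (sensor offsets) is clipped to
zero.

## Preprocessing

Savitzky–Golay smoothing (default window 11 channels, polynomial order 2)
runs per spectrum along the band axis with polynomial-interpolation edge
handling, so the band axis keeps its length and wavelength alignment —
a prerequisite for band selection downstream. The defaults suit the
~2 nm full-resolution grid; on coarser grids the window should be scaled
down accordingly (a window of 11 channels on a 10 nm grid spans ~100 nm
and will blur narrow spectral features into their neighbors). A
polynomial order of window − 1 would reproduce the input exactly, so the
configuration requires order ≤ window − 2.

Analyte concentrations span two orders of magnitude across the panel, so
each analyte is z-scored before regression using the **sample** SD
(ddof 1). The standardizer is always fitted on the training portion of a
split and inverted on test predictions, so all reported accuracy metrics
are in μmol/L. Reflectance is mean-centered inside the PLS fit but never
variance-scaled: bands share physical units, and scaling would inflate
quiet NIR channels.

## PLS regression and model order

PLS1 follows the classic NIPALS recursion: per component, the weight
vector is the normalized cross-covariance between the deflated predictors
and the response, scores and loadings follow, and X is deflated by the
rank-one score–loading product. The response needs no deflation for a
single response because deflated predictors are orthogonal to previous
scores. Coefficient vectors for all nested component counts are
accumulated via the standard R-recursion (equivalently W(PᵀW)⁻¹q), which
tests verify to 1e-10, along with the full-component equivalence to
ordinary least squares (1e-6 on well-conditioned fixtures) and the
monotone decrease of training RSS in the component count.

Model order minimizes leave-one-out PRESS. The implementation performs one
honest NIPALS refit per left-out sample (no virtual-leverage shortcut) and
reads the predictions for every candidate count off that fit's nested
coefficient path — arithmetically identical to refitting per count, and
asserted equal to an explicit fit/predict loop to 1e-10. Per fold the
count is capped at min(n − 2, bands). Ties in the PRESS profile break
toward the smallest count. The default search caps at A_max = 15,
generous for chemometric calibrations at these sample sizes while keeping
LOO affordable. If the cross-covariance or score norm vanishes (rank
exhausted) extraction stops early and later coefficient columns repeat the
last value.

## Two-stage sensitive-band screening

Stage 1 computes the per-band CV of reflectance across samples (sample SD;
bands with zero mean are flagged non-finite and excluded) and partitions
the axis at 717.08 nm: wavelengths ≤ boundary form the variable low range
where screening proceeds, the rest the quiet high range.

Stage 2, per repetition: draw a fresh training split (70% by default),
z-score the analyte on it, fit PLS on all candidate bands with
PRESS-selected order, sort bands by |coefficient| ascending **once**, and
remove them cumulatively in that fixed order down to a floor of 2 bands,
refitting (order re-selected) and recording the minimum LOO PRESS after
each removal. The surviving subset is the PRESS-minimum step; exact ties
break toward the larger subset. A re-ranking variant (the weakest
remaining band re-identified after every removal) is available as
`mode="dynamic"` but is not the default — the fixed sort is the simpler,
cheaper procedure and is what the frequency voting stabilizes anyway.
Over R = 100 repetitions (default), bands surviving in strictly more than
80 are the sensitive set; both R and the threshold are configurable, and
the strict inequality makes `threshold = R` yield an empty set by
construction.

## Evaluation harness

Each repetition draws a uniform random split with train size
round(0.7 n) — for the default 290-sample study exactly 203/87. An
experiment-stratified split is available behind a flag but is not the
default. Component count is re-selected inside every repetition; metrics
(R², RMSE, RE, RPD) are computed on test samples in original units, with
RE and RPD using the **test-set** mean and sample SD. RMSE = 0 reports
RPD as +inf rather than failing. Variant comparisons reuse one split
sequence across variants (paired design); winners maximize mean R² with
ties broken by mean RPD, then fewer bands, then variant order.

All randomness flows through `numpy.random.SeedSequence`: a master seed
spawns independent child streams per stage (generation, voting,
evaluation, scatter export), so changing one stage's repetition count
never perturbs another stage's draws, and identical configurations
reproduce byte-identical CSV outputs.

## Synthetic study design

The generator emulates a two-experiment nitrogen-response study (144 + 146
samples) with a 24-analyte panel and per-leaf mean spectra; experiment
membership is metadata only (one pooled distribution, as the modeling
pools samples).

**Concentrations.** Each analyte is log-normal, moment-matched to the
reference panel's mean and SD and truncated below at `min_clip`. Columns
are drawn as a midpoint quantile sample of that law (inverse CDF at the n
equal-probability stratum midpoints, independently shuffled per column).
Marginal shape and cross-column independence are those of log-normal
sampling, but sample moments track their targets far more tightly than
iid draws would: the panel's heaviest tails (CV ≈ 150–159%) make the iid
sample SD at n = 10,000 miss its target by more than 10% on a
non-negligible fraction of seeds, whereas the quantile sample's moment
error is small and deterministic (≈1.5% at n = 10,000, ≤9% at n = 290,
verified in the test suite). The cost is a mild, deterministic SD
compression at small n for the most skewed analytes.

**Optics.** A smooth leaf baseline (green peak at 550 nm, sigmoid red edge
at 720 nm, NIR plateau ≈ 0.40) is perturbed by eight Gaussian absorption
features at 512, 532, 552, 573, 603 nm (green–yellow window) and 664, 685,
705 nm (red/red-edge window), σ = 5 nm each. Feature depths are a bounded
monotone map of standardized concentrations through an analyte × feature
coupling matrix: d(u) = depth_scale · (expit(slope·u) − ½) with
depth_scale 0.09 and slope 0.4, so zero coupling reproduces the baseline
exactly, the response is near-linear over the bulk of the concentration
range while saturating smoothly in the tails (Beer–Lambert-like), and
reflectance never clips against the dark red baseline. Per-sample
multiplicative gain noise (SD 0.005) and additive band noise (SD 0.001)
complete the model; spectra are clipped to [0, 1] and a sample clipped at
every band raises a degenerate-optics error. The background spectrum of
image cubes decreases strictly with wavelength, making background NDVI
negative by construction — segmentation recovery is exact, not
threshold-marginal.

**Coupling design.** Eight analytes — five strong (BABA, Orn, Cit, Met,
His; strengths 2.0 down to 1.15) and three medium (Sar, Ala, Glu; 1.0 down
to 0.8) — occupy the eight mutually orthogonal Hadamard directions of
feature space, each therefore loading every feature with equal magnitude
and mixed signs. The remaining sixteen analytes get rows of a
column-orthonormalized random matrix (fixed seed; the coupling is a
package constant), so their aggregate interference is spread
near-isotropically over feature space, on a geometric strength ladder
from 0.60 down to 0.12. This layout is deliberate:

- Orthogonality makes each tiered analyte linearly identifiable, so
  estimation accuracy orders with coupling strength across the panel.
- Because the tiered analytes jointly span feature space, a model for any
  one of them must resolve signal at **every** feature to separate it from
  the others; no planted wavelength is redundant, which is what lets the
  backward-elimination/voting stage recover all planted centers rather
  than a minimal proxy subset. (With fewer than eight orthogonal
  directions, two to three feature bands are linearly redundant and a
  PRESS-minimizing selector correctly — and unhelpfully — drops them.)
- Features sit ≥ 20 nm apart with σ = 5 nm, so on a coarse 60-band test
  grid a neighboring band carries < 13% of a feature's response and the
  center band is decisively the strongest carrier; broader features make
  adjacent bands near-interchangeable and the selected representative
  drifts off-center.

**What the generator does not emulate.** No radiative-transfer realism
(no PROSPECT-class leaf optics), no genotype or treatment effects, no
temporal dynamics, no water or structural absorption features in the NIR,
and real pigment absorptions are far broader than the planted σ = 5 nm
features. Passing tests therefore demonstrate that the pipeline's
algorithms recover known structure under the stated noise model — not that
any particular accuracy is attainable on real leaves.

## Problem sizes used in tests and the acceptance script

Algorithms are identical at every scale; only the band count and
repetition counts are reduced to keep desk-scale runtimes:

- Test/acceptance studies use the full 290 samples on a 60-band grid
  (band selection cost grows with the band count: the cumulative
  elimination is O(bands) refits, each an O(n) LOO).
- Band voting runs R = 20 repetitions with a > 16 vote threshold
  (the 100/80 defaults scaled by the same 0.8 ratio).
- Holdout evaluations use R = 10 repetitions; the variability contrast
  (visible vs NIR CV) uses the full 300-band grid, where it costs nothing.

## Known limitations

- LOO PRESS by honest refits is O(n) fits per profile; at the full
  300-band, 100-repetition scale the elimination stage is hours of CPU,
  which is inherent to the procedure (the reference protocol) rather than
  to this implementation.
- The quantile concentration sampler slightly compresses extreme-tail SDs
  at small n (see above).
- R² can be negative on test sets for weakly coupled analytes; it is
  reported as computed, not floored at zero.
- The NDVI mask assumes a single leaf against a dark, spectrally
  decreasing background; multi-leaf scenes and specular highlights are out
  of scope.
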