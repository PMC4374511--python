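# Methods

`punctakit` quantifies the distribution of a fluorescent synaptic-vesicle
reporter (e.g. GFP-tagged RAB-3 or synaptobrevin) along a neuronal cord from
1D line-scan intensity profiles, and provides a synthetic-scene generator so
the entire analysis can be exercised and scored against ground truth.

## The quantification model

A *profile* is the fluorescence intensity sampled along a traced cord at
uniform arc-length steps, with an exclusion mask for cell bodies and
artifacts. Two per-animal statistics are computed:

- **Puncta number (PN)** — the count of called puncta whose peak lies in the
  analysis window.
- **Synaptic enrichment (SE)** — total punctal fluorescence (PF) divided by
  total inter-punctal fluorescence (IPF) within the window: the summed
  intensity inside punctum extents over the summed intensity between them.
  SE is high when the reporter concentrates at synapses and low when it is
  diffuse along the axon.

A candidate peak is called a **punctum** when its peak intensity divided by
the *average IPF* (the mean intensity of unmasked samples outside all
punctum extents) is at least the ratio threshold, **2, inclusive**. The
analysis window is **100 µm**, centered on the profile midpoint (a
configurable offset stands in for choosing the mid-cord region); profiles
shorter than the window are used whole and flagged.

### The fixed-point punctum-calling procedure

PF and IPF regions are mutually defining: the baseline is an average over
samples *outside* puncta, but which candidates qualify as puncta depends on
that baseline, and the punctum extents themselves depend on it too. The
procedure resolves this in two nested fixed points:

1. *Inner*: at fixed punctum membership, extents (half-max rule, below) and
   the average IPF are iterated to convergence (relative tolerance 1e-12).
   Starting from the global unmasked mean, the baseline sequence is
   monotonically decreasing and bounded below, so this converges.
2. *Outer*: starting from all candidates, any candidate whose peak/IPF
   ratio falls below threshold is dropped, and the inner fixed point is
   recomputed. Removals return bright extent samples to the inter-punctal
   pool and can only raise the baseline, so membership shrinks
   monotonically; the loop terminates in at most one sweep per candidate.

The converged set is the *maximal self-consistent set*: every member
satisfies the ratio rule against the baseline the set itself implies. The
test suite verifies this against exhaustive enumeration of all candidate
subsets on seeded multi-peak profiles. Note the inner convergence is what
makes borderline puncta handled correctly: a peak near the threshold can
qualify precisely because its own extent removes bright shoulder samples
from the baseline pool.

### Candidate detection

Candidates are unmasked local maxima (plateaus report their center sample;
masked stretches act as profile boundaries). Two filters precede the ratio
rule, both chosen to suppress only sampling artifacts and leave the ratio
rule primary:

- *minimum separation* (default 1 µm): of any pair of candidates closer
  than this, only the higher survives (ties keep the leftmost). The removal
  is pairwise — a candidate dominated by a neighbour is removed even if
  that neighbour is itself dominated — which suppresses chains of noise
  maxima on the shoulders of a tall punctum.
- *minimum prominence* (default 0, i.e. off).

No smoothing is applied by default; a moving-average window is exposed but
off. Camera-offset subtraction before ratio computation is likewise exposed
and off by default, so ratios are computed on raw intensities.

### Punctum extents

The extent of a punctum is the maximal contiguous run around its peak
strictly above the level midway between the baseline and the peak (a
half-max rule; for a Gaussian punctum the width is the FWHM, 2.355 σ).
Extension stops at masked samples. Boundary samples exactly at the half
level are excluded, which makes the degenerate peak-at-baseline case a
one-sample extent. Overlapping extents of neighbouring puncta are split at
the lowest sample between the two peaks (assigned to the right punctum), so
extents are always disjoint half-open index intervals. A consequence worth
noting: the profile minimum always sits below any half level, so the
inter-punctal pool can never be emptied by extents alone (only by masking).

### Degenerate cases

- Zero puncta → SE = 0 with a `no_puncta` flag (diffuse mutants yield a
  finite low SE rather than a missing value).
- Zero inter-punctal samples in the window (possible only through masking
  or extreme window placement) → SE undefined (NaN) with `zero_ipf`.
- Fully masked profile → `all_masked`, PN 0, SE NaN.
- PN and SE share one analysis window.

Both the ratio rule and SE are scale-free: multiplying all intensities by
any positive gain leaves PN and SE unchanged (asserted to 1e-9). Additive
offsets do *not* preserve them, which is why offset handling is explicit.

## Profile extraction from images

A cord trace is an ordered pixel-coordinate polyline (0-based, x = column,
pixel centers). The profile samples the trace at arc-length steps of one
pixel (native resolution, no resampling bias); at each sample the intensity
is the **maximum** over `2·half_width + 1` bilinear samples along the local
perpendicular — maximum rather than mean because it is robust to sub-pixel
tracing error on thin cords (mean is available). Perpendicular samples
leaving the image are ignored in the aggregate rather than zero-filled
(zero-filling would bias edges downward); samples with no in-bounds
contribution are flagged excluded, never dropped. Positions convert to µm
by the pixel size.

## The synthetic-scene generator

The generator emulates four qualitative phenotype classes of vesicle-marker
distribution: punctate wild type; diffuse mutants (punctum density 0,
elevated axonal baseline); enlarged/brighter puncta; and cell-body
retention (nearly all signal in soma blobs at the cord ends, dim cord).
Scenes carry exact ground-truth punctum tables.

Signal model: a flat axonal baseline (`diffuse_level`) plus one Gaussian
bump per punctum; punctum count is Poisson with mean density × length;
positions are uniform with a 2 µm hard minimum separation (sequential
rejection sampling), because the emulated puncta are visibly resolved
structures. The hard-core constraint leaves the mean count at the Poisson
value but under-disperses it (variance ≈ 20 at mean 30); only the mean is
calibrated. Amplitudes are Gaussian, clipped at zero. In 2D, the cord is a
Gaussian-cross-section ridge along the trace, puncta are isotropic 2D
Gaussians (an effective PSF blur), and soma blobs are wide Gaussians scaled
so a stated fraction of total above-offset signal lies in them.

Camera model: `out = Poisson(signal·gain)/gain + offset + N(0, read_sd)`,
clipped at zero; `gain = 0` selects the noiseless configuration. One seeded
generator per scene, with separate sub-streams for placement and noise so a
placement is reusable across noise realizations. Identical arguments give
bit-identical scenes.

### Default presets (arbitrary units; all configurable)

| preset | density /µm | amplitude | σ (µm) | diffuse | soma frac |
|---|---|---|---|---|---|
| wild_type | 0.30 | 120 ± 12 | 0.5 | 20 | 0 |
| diffuse_mutant | 0 | — | — | 60 | 0 |
| enlarged_puncta | 0.15 | 200 ± 25 | 0.8 | 20 | 0 |
| soma_retention | 0.05 | 30 ± 5 | 0.5 | 2 | 0.95 |

Shared camera defaults: offset 5, gain 4 photons/AU, read noise 1.

These magnitudes are simulation choices — no intensity scale or punctum
size range is prescribed by the imaging setup itself — and they define the
detector's *designed regime*: every wild-type punctum clears the ratio-2
rule with margin. Two choices deserve explanation. First, wild-type
amplitude 120 ± 12 over baseline 20: Gaussian tails below the half-max
extents remain in the IPF pool and raise the average IPF to ≈ 50, so the
effective calling threshold is ≈ 100, and the amplitude distribution is
placed so even its low tail clears it. Second, enlarged puncta are sparser
(0.15/µm) than wild type: at wild-type density their doubled width would
merge neighbours into a quasi-diffuse ridge, which is not the
resolved-oversized-puncta phenotype being emulated. The camera regime
(gain 4, read noise 1) is ordinary well-exposed imaging; in very dim
regimes at unit gain, discrete Poisson spikes can legitimately clear twice
a near-zero baseline, which is a property of the ratio rule itself, not of
the detector implementation.

What the generator does **not** emulate: optics-accurate PSFs, 3D stacks,
photobleaching, motion, autofluorescence gradients, multi-channel scenes,
or tracing error beyond what the perpendicular maximum absorbs. Passing
tests therefore show the analysis is correct and well-calibrated on scenes
matching its assumptions, not that those assumptions hold for any given
microscope.

## Group statistics

Groups are summarized as mean ± sample SD (n − 1). Pairwise comparisons use
the two-sided pooled-variance Student's t-test by default (Welch exposed);
labels are ** for p < 0.01, * for p < 0.05, NS otherwise. Two identical
zero-variance groups report t = 0, p = 1. No multiple-testing correction is
applied, matching conventional per-panel pairwise reporting; users running
many contrasts should correct externally. The test suite checks the t-test
against a permutation oracle and verifies the null rejection rate at
α = 0.05 on splits of an iid pool of simulated wild-type animals.

## Pipeline and reproducibility

`run_pipeline` executes simulate → (extract) → quantify → compare, writing
every intermediate artifact (profiles, truth tables, per-animal and
per-punctum CSVs, summaries, comparisons) plus a manifest with the config,
per-animal seeds and package version. Per-animal seeds derive from the run
seed through seed-sequence children, so a manifest-driven rerun is
byte-identical. CSVs are UTF-8 with "." decimals and floats at 10
significant digits. The default demo runs 4 presets × 20 animals of
110 µm cord at 0.1 µm/px in 1D-profile mode (quantification is defined on
line scans; 2D image mode renders TIFFs and extracts profiles first).
Problem sizes used by the verification script (20 animals per genotype,
50 recovery scenes, a 1000-animal null pool) are chosen as desk-scale
defaults that keep Monte-Carlo error well below the effect sizes involved.

## Known limitations

- The punctum-calling rule is threshold-based on a single ratio; it has no
  explicit shape prior, so in very low-SNR regimes isolated noise spikes
  can qualify (see camera regime above).
- "Average IPF" is read as the mean over inter-punctal *samples*; an
  alternative reading (mean over per-gap peak intensities) would weight
  gaps differently. The sample-mean reading matches IPF's definition as
  signal intensity in axons between synapses.
- The window is placed geometrically (profile midpoint); no anatomical
  registration is attempted.
- Extent splitting at the inter-peak minimum is one of several defensible
  conventions for overlapping puncta; it only affects PF/IPF attribution
  of samples between close peaks.
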