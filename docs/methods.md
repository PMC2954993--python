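# Methods

## Counting simulation

The model asks how many distinct objects an automated segmenter can report
when `N = round(density × area / 100)` square cell footprints (side 10 µm,
the approximate nuclear diameter) are placed uniformly at random in a
rectangular tissue region (default 100×100 µm). Densities are in cells per
100 µm². Three labeling schemes are compared: every cell one color
(`ONE_COLOR`); each cell one of three colors, uniform (`THREE_NOMIX`); each
cell a uniform draw from the 7 nonempty subsets of three colors
(`THREE_MIX` — equivalent to independent per-color inclusion conditioned on
non-emptiness, which is what co-delivering three constructs produces).

**Merge predicate.** The default segmenter merges two cells into one
object iff their footprints intersect with positive area *and* their color
subsets are identical; objects are connected components of this relation.
Rationale: a color-aware region grower cannot split touching same-colored
nuclei but does separate differently-colored overlaps. Footprints are
clipped at the region border (no wraparound); geometry is continuous, so
results are resolution-independent and deterministic given the seed. An
alternative `linked` mode (per-channel overlap components → centroid spots
→ transitive linking at 2 µm) is provided for sensitivity analysis; the
qualitative scheme ordering is the claim of record, not any particular
printed percentage, because the exact behavior of a segmentation package
depends on its kernel and rasterization.

Defaults follow the study conditions: density grid 0.1–2.4 (step 0.1) and
10,000 replicates per point. Tests and the acceptance script use 1,000
replicates — at that size the Monte-Carlo standard error of a mean
fraction is ≲ 0.005, an order of magnitude below every margin asserted —
with means and standard deviations reported alongside replicate counts so
standard errors are always recoverable.

## Synthetic movies

Image formation is linear: each nucleus is an isotropic Gaussian kernel
with FWHM equal to its diameter (default 10 µm), scaled by the cell's
nonnegative expression vector and mapped through the reference-spectra
matrix; a constant background, Poisson shot noise, and Gaussian read noise
are optional. Emission spectra are single Gaussians (σ = 15 nm; peaks CFP
476, GFP 507, YFP 527, RFP 584, mCherry 610 nm — conventional values, all
configurable) integrated over the channel bands and normalized to unit
column sum. Lambda layouts fill complete bins only
(`floor((λmax − λmin)/step)`), so 571–657 nm at 10.7 nm gives 8 channels
and 494–623 nm gives 12. Movies default to 2D fields (analysis operates on
maximum-intensity projections), 0.5 µm/px, 60 frames at 5 min (~5 h).

Scenario builders create the tracking hard cases with exact ground truth:
*crossing* sends all cells on straight lines through a common point at the
mid-frame (pairwise fingerprint L1 separation enforced, start/end
separation ≥ 2 diameters; for two cells this is the symmetric swap);
*division* splits a parent into two daughters that inherit its expression
vector, optionally with multiplicative partition noise. The random-walk
generator draws per-cell color subsets uniformly from the 7 possibilities
(`subset` mode, where equal within-subset fractions make rank order
degenerate by construction) or gives each cell a strict intensity
hierarchy — a permutation of fractions (0.6, 0.3, 0.1) (`hierarchical`
mode, emulating cells whose per-color intensity order is resolvable, the
regime in which rank-order stability is a meaningful identity signal).

What the generator does *not* emulate: z-dependent PSF blur, scattering,
chromatic aberration, spatially varying autofluorescence, or cell shape
beyond a Gaussian blob. Passing tests therefore demonstrate the logic of
the pipeline under a faithful noise model, not performance on real tissue.

## Unmixing and thresholding

Per-pixel abundances solve `min_{a≥0} ‖S·a − y‖²`. Nonnegativity is
physically required and standard. Implementation: vectorized unconstrained
least squares via the pseudo-inverse, with an active-set NNLS fallback for
the pixels whose unconstrained solution goes negative (the fast path is
then already optimal). Autofluorescence is an extra broad-Gaussian column
fitted and discarded afterwards. Rank-deficient or underdetermined spectra
trigger a warning, not an error.

Background thresholding uses the empirical per-channel rule: threshold =
1.25 × the maximum intensity inside a signal-free rectangle; the 25 %
headroom ensures comparable background pixels fall below it. Values at or
below the threshold are zeroed. The pipeline applies the rule after
unmixing (unmix → project → threshold), matching the processing order used
on real lambda stacks.

## Detection

Spots are integer-pixel local maxima of the image smoothed at
σ = diameter/2.355 (FWHM-matched), strictly above threshold, with minimum
peak separation diameter/2 (greedy suppression, brighter peak wins, exact
ties keep the smaller (row, column)). Label-specific parameters: expected
diameter 2 µm for particulate dye, 5 µm for nuclear labels, 10 µm for
membrane labels; linking distance 5 µm for particulate dye (one cell,
many specks) and 2 µm otherwise (strict `<`, single linkage with
transitive closure). All distances are physical (µm). Density estimation
tiles the field with 100 µm² windows and averages counts; the alternative
spacing estimate is mean nearest-neighbor center distance minus mean
nuclear diameter.

In the end-to-end pipeline the raw stack is pre-smoothed at the detection
scale *before* unmixing. Both operations are linear, so they commute in
expectation; smoothing first tames the shot noise before the pseudo-inverse
can amplify it into spurious abundance peaks near bright cells. The 125 %
rule is then measured per channel on the resulting abundance maps.

## Tracking

Both trackers share one engine: per frame pair, minimum-cost bipartite
assignment (Hungarian algorithm) gated at a maximum spatial displacement
(default 30 µm/frame = 3 diameters); unmatched detections open tracks,
unmatched tracks terminate; ties break deterministically toward the lower
track id. The blind baseline uses displacement only. The spectral tracker
adds `w ×` fingerprint L1 distance with `w = 10 µm` per unit L1, chosen so
a fully disjoint fingerprint pair (L1 = 2) costs as much as a two-diameter
displacement.

Conflict events are maximal intervals over which ≥ 2 tracks sit pairwise
within the conflict radius (default 10 µm, one nuclear diameter — the
scale at which positional identity is lost to optical resolution). After
each event the spectral tracker re-assigns the involved identities to
minimize total L1 distance between mean post-conflict and mean
pre-conflict fingerprints (windows of 5 frames), automating the
backward/forward spectral matching otherwise done by eye. If all
pre-conflict fingerprints are pairwise closer than the ambiguity tolerance
(0.1 L1), the cells are spectrally indistinguishable and the event is
flagged ambiguous instead of resolved — a declared default, since no
quantitative "same spectrum" criterion exists for the manual practice.

Fingerprints are per-channel intensity fractions (sum 1), invariant to
global intensity scaling and to equal photobleaching across channels; rank
ties are broken by channel order and flagged degenerate. Evaluation counts
identity switches as frame-to-frame truth-label changes within a reported
track, except where the new label is a truth daughter of the old one.

The tracking Monte-Carlos (crossing resolution, rank-order stability) run
on detections derived from generator ground truth — true position plus
0.3 µm isotropic localization jitter, per-channel intensities scaled by
independent `1 + 0.1·N(0,1)` factors — rather than re-rendering and
re-detecting hundreds of movies; the full render → unmix → detect → track
chain is exercised end-to-end in the pipeline tests. 0.3 µm is a typical
centroid localization error for a bright 10 µm nucleus at 0.5–1 µm/px.

## Numerical choices and limitations

* Seeds: every stochastic operation takes an explicit seed; sweeps derive
  per-density streams from `(seed, scheme, density index)` so curves are
  bit-reproducible and schemes are independent.
* Strict inequalities follow the stated rules ("less than 2 µm apart",
  intensity strictly above threshold); neighbor searches shrink KD-tree
  candidate sets with an exact distance check to honor strictness.
* Degenerate inputs: empty populations count as fraction 1 (nothing to
  miss); empty density lists, nonpositive sides/diameters, all-zero
  fingerprints, and malformed boxes raise parameter errors.
* The counting model's printed percentages depend on the (unpublished)
  segmentation kernel; this package asserts bounds and ordering, which are
  robust to that choice.
* 3D (z-stack) tracking, learning-based trackers, blind unmixing, and
  membrane-morphology segmentation are out of scope.
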