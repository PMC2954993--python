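# spectrack

A toolbox for **multicolor nuclear-label multispectral microscopy**: it
quantifies why single-color nuclear labeling breaks automated cell counting
in dense embryonic tissue, and how combinatorial multicolor labeling plus
spectral fingerprinting restores both counting and tracking.

Migratory embryonic cell populations such as the neural crest pack
nuclei (~10 µm diameter) at densities of 1–3 cells per 100 µm². At such
densities a segmentation algorithm cannot split touching same-colored
nuclei, so automated counts collapse; and when two cells cross trajectories
in a time-lapse, a position-only tracker faces k! possible reassignments
for k co-located cells. Labeling each cell with a random nonempty subset of
three nuclear fluorescent proteins yields 2³−1 = 7 distinguishable classes:
neighbors rarely share a class (counting survives higher density) and each
cell carries a persistent *spectral fingerprint* — its normalized
per-fluorophore intensity fractions and their rank order — that
re-identifies it after a crossing and is inherited through division.

The package provides:

* `counting_sim` — Monte-Carlo model of automated object counting vs cell
  density for 1-color, 3-color non-mixing, and 3-color mixing labeling:
  square footprints seeded uniformly in a tissue rectangle; overlapping
  cells with identical color subsets merge into one counted object.
* `spectral_render` — synthetic lambda-stack movie generator (Gaussian
  nuclei, linear image formation `I_c = Σ_k S[c,k]·A_k + bg`, Poisson/read
  noise) with full ground truth, including trajectory-crossing and
  cell-division scenarios.
* `unmixing` — per-pixel nonnegative least-squares unmixing
  `min_{a≥0} ‖S·a − y‖²` against Gaussian-emission reference spectra, an
  optional autofluorescence column, the 125 %-of-background-max threshold
  rule, and maximum-intensity projection.
* `detection` — scale-matched spot detection (Gaussian smoothing at
  FWHM/2.355, local maxima), transitive distance linking (spots < 2 µm
  apart merge; 5 µm for particulate dye labels), counting, and tissue
  density estimation.
* `tracking` — spectral-fingerprint computation, a spectrum-blind
  nearest-neighbor baseline, and fingerprint-aware tracking that resolves
  conflict events by matching post-conflict fingerprints to pre-conflict
  ones (flagging spectrally indistinguishable cells instead of guessing).
* `pipeline` / CLI — the end-to-end chain *generate → unmix → detect →
  track → evaluate* plus subcommands `simulate-counting`, `synth-movie`,
  `unmix`, `detect`, `track`, `run-pipeline`.

## Worked example

Counting accuracy for 1-color labeling at the densities where dense tissue
defeats segmentation:

```python
>>> import spectrack as st
>>> curve = st.run_density_sweep(st.ColorScheme.ONE_COLOR,
...                              densities=[0.6, 1.6], reps=1000, seed=1)
>>> [round(float(100 * f), 1) for f in curve.mean_fraction]
[29.7, 2.1]
```

At 0.6 cells/100 µm² only ~30 % of single-colored cells survive as distinct
objects (below 50 %), and at 1.6 cells/100 µm² only ~2 % (below 10 %) — the
rest merge with touching same-colored neighbors. The three-color mixing
scheme at the same seed stays far higher (≈86 % and ≈65 %).

Tracking through a symmetric two-cell crossing:

```python
>>> from spectrack import tracking as trk
>>> movie = st.make_crossing_scenario(n_cells=2, seed=3, render=False)
>>> dets = trk.detections_from_truth(movie, position_noise=0.3,
...                                  intensity_noise=0.10, seed=3)
>>> tracks, report = trk.spectral_track(dets)
>>> report.conflict_events, trk.evaluate_tracking(tracks).identity_switches
(1, 0)
```

The two cells meet within a nuclear diameter at mid-movie (one conflict
event); their distinct fingerprints let the spectral tracker keep both
identities (0 switches), while the spectrum-blind baseline flips a coin.

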