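"""Synthetic multispectral movie generator with full ground truth.

Emulates 4D (time x channel x y x x) confocal acquisitions of multicolor
nuclear-labeled cells: each cell carries a nonnegative expression vector
over a palette of histone-fusion fluorescent proteins, its nucleus renders
as an isotropic Gaussian blob (FWHM = nuclear diameter, ~10 µm), and the
per-channel signal follows a linear image-formation model

    I_c(x, y) = sum_k S[c, k] * A_k(x, y) + bg_c + noise,

where ``S`` is the fluorophore-by-channel reference-spectra matrix built
from Gaussian emission profiles integrated over the channel bands.  Lambda
mode mirrors spectral scanning in fixed-wavelength bins (e.g. 494-623 nm at
10.7 nm -> 12 channels); channel mode uses discrete bandpass windows.

Scenario builders produce trajectory-crossing and cell-division movies with
known lineage, the hard cases for positional tracking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

__all__ = [
    "Fluorophore",
    "ChannelLayout",
    "ReferenceSpectra",
    "SyntheticCell",
    "SyntheticMovie",
    "NoiseParams",
    "DEFAULT_FLUOROPHORES",
    "lambda_channels",
    "make_reference_spectra",
    "render_frame",
    "render_movie",
    "make_random_walk_movie",
    "make_crossing_scenario",
    "make_division_scenario",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # = 1/2.355


@dataclass(frozen=True)
class Fluorophore:
    """Single-Gaussian emission model of one fluorescent protein."""

    name: str
    emission_peak: float  # nm
    emission_sigma: float = 15.0  # nm
    brightness: float = 1.0

    def __post_init__(self):
        if not (400.0 <= self.emission_peak <= 700.0):
            raise ValueError("emission peak must lie in 400-700 nm")
        if self.emission_sigma <= 0:
            raise ValueError("emission sigma must be positive")
        if self.brightness < 0:
            raise ValueError("brightness must be nonnegative")


#: Conventional emission peaks for the H2B fusion palette.
DEFAULT_FLUOROPHORES = (
    Fluorophore("CFP", 476.0),
    Fluorophore("GFP", 507.0),
    Fluorophore("YFP", 527.0),
    Fluorophore("RFP", 584.0),
    Fluorophore("mCherry", 610.0),
)


def lambda_channels(lambda_min: float, lambda_max: float, step: float) -> int:
    """Number of spectral channels for a lambda scan over [min, max] nm.

    The detector fills complete bins only: ``floor((max - min) / step)``.
    571-657 nm at 10.7 nm gives 8 channels; 494-623 nm gives 12.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if lambda_max - lambda_min < step:
        raise ValueError("spectral range must cover at least one step")
    return int(math.floor((lambda_max - lambda_min) / step))


@dataclass(frozen=True)
class ChannelLayout:
    """Spectral binning of the detector.

    ``LAMBDA`` mode: contiguous bins of width ``step`` starting at
    ``lambda_min``.  ``CHANNEL`` mode: explicit bandpass windows
    ``bands`` = list of (lo, hi) nm.
    """

    mode: str = "LAMBDA"
    lambda_min: float = 494.0
    lambda_max: float = 623.0
    step: float = 10.7
    bands: tuple = ()

    def __post_init__(self):
        if self.mode not in ("LAMBDA", "CHANNEL"):
            raise ValueError("mode must be LAMBDA or CHANNEL")
        if self.mode == "LAMBDA":
            lambda_channels(self.lambda_min, self.lambda_max, self.step)  # validates
        elif not self.bands:
            raise ValueError("CHANNEL mode requires explicit bands")

    @property
    def n_channels(self) -> int:
        if self.mode == "LAMBDA":
            return lambda_channels(self.lambda_min, self.lambda_max, self.step)
        return len(self.bands)

    def band_edges(self) -> np.ndarray:
        """(C, 2) array of channel band edges in nm."""
        if self.mode == "LAMBDA":
            n = self.n_channels
            lo = self.lambda_min + self.step * np.arange(n)
            return np.column_stack([lo, lo + self.step])
        return np.asarray(self.bands, dtype=float)

    def channel_centers(self) -> np.ndarray:
        edges = self.band_edges()
        return edges.mean(axis=1)


@dataclass
class ReferenceSpectra:
    """Channel-by-fluorophore emission matrix with unit-sum columns.

    ``matrix`` has shape (C, K); an optional trailing autofluorescence
    column is included in K and flagged by ``has_autofluorescence``.
    """

    matrix: np.ndarray
    labels: list[str]
    channel_centers: np.ndarray
    has_autofluorescence: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.labels):
            raise ValueError("matrix must be C x K with one label per column")
        if np.any(self.matrix < 0):
            raise ValueError("spectra must be nonnegative")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_fluorophores(self) -> int:
        return self.matrix.shape[1]


def _gaussian_band_integral(peak: float, sigma: float, edges: np.ndarray) -> np.ndarray:
    """Integral of a unit-area Gaussian emission profile over each band."""
    a = (edges[:, 0] - peak) / (sigma * math.sqrt(2.0))
    b = (edges[:, 1] - peak) / (sigma * math.sqrt(2.0))
    return 0.5 * (erf(b) - erf(a))


def make_reference_spectra(
    fluorophores=DEFAULT_FLUOROPHORES,
    layout: ChannelLayout | None = None,
    include_autofluorescence: bool = False,
    autofluorescence_peak: float = 500.0,
    autofluorescence_sigma: float = 60.0,
) -> ReferenceSpectra:
    """Build the reference-spectra matrix for unmixing and rendering.

    Each column is the fluorophore's Gaussian emission profile integrated
    over the channel bands and normalized to unit sum, so abundances are on
    a total-detected-photon scale.  The optional autofluorescence column is
    a broad Gaussian standing in for tissue background, letting the unmixer
    subtract it out as an extra component.
    """
    fluorophores = list(fluorophores)
    if len(fluorophores) == 0:
        raise ValueError("at least one fluorophore required")
    names = [f.name for f in fluorophores]
    if len(set(names)) != len(names):
        raise ValueError("duplicate fluorophore names")
    layout = layout or ChannelLayout()
    edges = layout.band_edges()
    cols = []
    for f in fluorophores:
        col = _gaussian_band_integral(f.emission_peak, f.emission_sigma, edges)
        s = col.sum()
        if s <= 0:
            raise ValueError(f"{f.name}: emission does not overlap the channel range")
        cols.append(col / s)
    labels = list(names)
    if include_autofluorescence:
        af = _gaussian_band_integral(autofluorescence_peak, autofluorescence_sigma, edges)
        cols.append(af / af.sum())
        labels.append("autofluorescence")
    return ReferenceSpectra(
        matrix=np.column_stack(cols),
        labels=labels,
        channel_centers=layout.channel_centers(),
        has_autofluorescence=include_autofluorescence,
    )


# ---------------------------------------------------------------------------
# cells, movies, rendering
# ---------------------------------------------------------------------------

@dataclass
class NoiseParams:
    """Acquisition noise model.

    ``poisson`` applies shot noise to the (nonnegative) expected signal;
    ``read_sigma`` adds zero-mean Gaussian read noise (counts);
    ``background`` is a constant autofluorescence offset per channel.
    """

    poisson: bool = False
    read_sigma: float = 0.0
    background: float = 0.0


@dataclass
class SyntheticCell:
    """Ground-truth cell: trajectory, expression vector, lineage.

    ``path`` is a (T, 2) array of (x, y) in µm; frames before birth or after
    death are NaN.  ``expression`` is nonnegative over the fluorophore
    palette with at least one positive entry.
    """

    id: int
    path: np.ndarray
    expression: np.ndarray
    nuclear_diameter: float = 10.0
    parent: int | None = None

    def __post_init__(self):
        self.path = np.asarray(self.path, dtype=float)
        self.expression = np.asarray(self.expression, dtype=float)
        if np.any(self.expression < 0):
            raise ValueError("expression must be nonnegative")
        if not np.any(self.expression > 0):
            raise ValueError("expression must have at least one positive entry")
        if self.nuclear_diameter <= 0:
            raise ValueError("nuclear diameter must be positive")

    def alive_at(self, t: int) -> bool:
        return bool(np.all(np.isfinite(self.path[t])))


@dataclass
class SyntheticMovie:
    """Rendered movie plus the ground truth that produced it.

    ``frames``: (T, C, Y, X) nonnegative intensities. ``truth``: list of
    :class:`SyntheticCell`. ``pixel_size`` µm/px; ``frame_interval`` min.
    """

    frames: np.ndarray
    truth: list[SyntheticCell]
    spectra: ReferenceSpectra
    pixel_size: float = 0.5
    frame_interval: float = 5.0
    field_size: tuple[float, float] = (200.0, 200.0)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_channels(self) -> int:
        return self.frames.shape[1]


def render_frame(
    positions: np.ndarray,
    expressions: np.ndarray,
    spectra: ReferenceSpectra,
    field_size: tuple[float, float] = (200.0, 200.0),
    pixel_size: float = 0.5,
    nuclear_diameter: float | np.ndarray = 10.0,
    noise: NoiseParams | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one multichannel frame of Gaussian nuclei.

    ``positions``: (N, 2) µm; ``expressions``: (N, K) per-fluorophore
    amplitudes.  Each nucleus contributes an isotropic Gaussian kernel with
    FWHM equal to its diameter, scaled by expression and mapped through the
    spectra; superposition is exact, so noiseless rendering is linear in
    expression.  Pixel (i, j) samples the physical point at its center,
    ((j + 0.5) px, (i + 0.5) px) * pixel_size.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float)) if len(positions) else np.empty((0, 2))
    expressions = np.atleast_2d(np.asarray(expressions, dtype=float)) if len(expressions) else np.empty((0, spectra.n_fluorophores))
    if np.any(expressions < 0):
        raise ValueError("expression must be nonnegative")
    noise = noise or NoiseParams()
    w_um, h_um = field_size
    nx = int(round(w_um / pixel_size))
    ny = int(round(h_um / pixel_size))
    C = spectra.n_channels
    K = spectra.n_fluorophores
    if expressions.shape[0] and expressions.shape[1] != K:
        raise ValueError("expression dimension must match spectra fluorophore count")
    xs = (np.arange(nx) + 0.5) * pixel_size
    ys = (np.arange(ny) + 0.5) * pixel_size
    abundance = np.zeros((K, ny, nx))
    diam = np.broadcast_to(np.asarray(nuclear_diameter, dtype=float), (len(positions),))
    for p, e, d in zip(positions, expressions, diam):
        if not np.all(np.isfinite(p)):
            continue
        sig = d * FWHM_TO_SIGMA
        gx = np.exp(-0.5 * ((xs - p[0]) / sig) ** 2)
        gy = np.exp(-0.5 * ((ys - p[1]) / sig) ** 2)
        kern = np.outer(gy, gx)
        abundance += e[:, None, None] * kern[None, :, :]
    frame = np.tensordot(spectra.matrix, abundance, axes=(1, 0))  # (C, Y, X)
    frame += noise.background
    if noise.poisson or noise.read_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        if noise.poisson:
            frame = rng.poisson(np.clip(frame, 0, None)).astype(float)
        if noise.read_sigma > 0:
            frame = frame + rng.normal(0.0, noise.read_sigma, size=frame.shape)
        frame = np.clip(frame, 0.0, None)
    return frame


def render_movie(
    cells: list[SyntheticCell],
    spectra: ReferenceSpectra,
    n_frames: int,
    field_size: tuple[float, float] = (200.0, 200.0),
    pixel_size: float = 0.5,
    frame_interval: float = 5.0,
    noise: NoiseParams | None = None,
    seed: int = 0,
    bleach_rates: np.ndarray | None = None,
) -> SyntheticMovie:
    """Render a full movie from ground-truth cells.

    ``bleach_rates`` (per-fluorophore decay constants, per frame) apply
    exponential photobleaching ``exp(-rate * t)`` to expression; equal rates
    across fluorophores leave spectral fingerprints invariant.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for t in range(n_frames):
        alive = [c for c in cells if t < len(c.path) and c.alive_at(t)]
        pos = np.array([c.path[t] for c in alive]) if alive else np.empty((0, 2))
        expr = np.array([c.expression for c in alive]) if alive else np.empty((0, spectra.n_fluorophores))
        if bleach_rates is not None and len(expr):
            expr = expr * np.exp(-np.asarray(bleach_rates) * t)[None, :]
        diam = np.array([c.nuclear_diameter for c in alive]) if alive else 10.0
        frames.append(
            render_frame(pos, expr, spectra, field_size, pixel_size, diam, noise, rng)
        )
    return SyntheticMovie(
        frames=np.stack(frames),
        truth=cells,
        spectra=spectra,
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        field_size=field_size,
    )


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

#: Candidate fingerprints: the 7 nonempty subsets of 3 labels, normalized.
_SUBSET_FRACTIONS = np.array([
    [1, 0, 0], [0, 1, 0], [0, 0, 1],
    [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5],
    [1 / 3, 1 / 3, 1 / 3],
])


def _pick_separated_fingerprints(n: int, separation: float, rng: np.random.Generator) -> np.ndarray:
    """Choose n fingerprints from the 7 color-subset fractions with pairwise
    L1 distance >= separation; error if infeasible."""
    order = np.array([0, 1, 2, 5, 4, 3, 6])  # pure colors first, then pairs, then triple
    cands = _SUBSET_FRACTIONS[order]
    chosen: list[np.ndarray] = []
    for c in cands:
        if all(np.abs(c - p).sum() >= separation for p in chosen):
            chosen.append(c)
        if len(chosen) == n:
            return np.array(chosen)
    raise ValueError(
        f"cannot construct {n} fingerprints with pairwise L1 separation {separation}"
    )


def make_crossing_scenario(
    n_cells: int = 2,
    fingerprint_separation: float = 0.6,
    noise: NoiseParams | None = None,
    seed: int = 0,
    n_frames: int = 31,
    field_size: tuple[float, float] = (100.0, 100.0),
    pixel_size: float = 1.0,
    speed: float = 2.0,
    nuclear_diameter: float = 10.0,
    total_expression: float = 300.0,
    render: bool = True,
) -> SyntheticMovie:
    """Movie in which all cells pass within one nuclear diameter of a common
    point at the mid-frame -- an unavoidable positional conflict.

    Cells travel on straight lines through the field center at ``speed``
    µm/frame, entering along evenly spread directions, and carry distinct
    expression vectors with pairwise L1 fingerprint distance at least
    ``fingerprint_separation``.  For two cells this is the symmetric swap:
    each continues through the center and ends near the other's starting
    point.  Start/end positions are at least two diameters apart.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells to cross")
    rng = np.random.default_rng(seed)
    fp = _pick_separated_fingerprints(n_cells, fingerprint_separation, rng)
    center = np.array(field_size) / 2.0
    mid = n_frames // 2
    # small per-cell offset at the meeting point: within one diameter of center
    offsets = rng.uniform(-nuclear_diameter / 4, nuclear_diameter / 4, size=(n_cells, 2))
    angles = 2 * np.pi * np.arange(n_cells) / n_cells + rng.uniform(0, 2 * np.pi)
    cells = []
    t_axis = np.arange(n_frames) - mid
    for i in range(n_cells):
        direction = np.array([np.cos(angles[i]), np.sin(angles[i])])
        pos = center + offsets[i] + direction[None, :] * (speed * t_axis)[:, None]
        expr = fp[i] * total_expression
        cells.append(SyntheticCell(id=i, path=pos, expression=expr,
                                   nuclear_diameter=nuclear_diameter))
    spectra = make_reference_spectra(DEFAULT_FLUOROPHORES[1:4])  # GFP/YFP/RFP palette
    if render:
        return render_movie(cells, spectra, n_frames, field_size, pixel_size,
                            noise=noise, seed=seed)
    return SyntheticMovie(
        frames=np.zeros((n_frames, spectra.n_channels, 1, 1)),
        truth=cells, spectra=spectra, pixel_size=pixel_size,
        field_size=field_size,
    )


def make_division_scenario(
    parent_expression=(200.0, 100.0, 0.0),
    split_frame: int = 15,
    seed: int = 0,
    n_frames: int = 31,
    field_size: tuple[float, float] = (100.0, 100.0),
    pixel_size: float = 1.0,
    daughter_noise: float = 0.0,
    noise: NoiseParams | None = None,
    nuclear_diameter: float = 10.0,
    render: bool = True,
) -> SyntheticMovie:
    """Movie of one cell dividing into two daughters at ``split_frame``.

    Daughters inherit the parent expression vector, optionally perturbed by
    multiplicative lognormal-free noise ``(1 + daughter_noise * N(0,1))``
    clipped at zero, emulating unequal fluorophore partitioning.  The
    lineage table records the parent id on both daughters.
    """
    parent_expression = np.asarray(parent_expression, dtype=float)
    if not (0 < split_frame < n_frames):
        raise ValueError("split_frame must fall inside the movie")
    rng = np.random.default_rng(seed)
    center = np.array(field_size) / 2.0
    t = np.arange(n_frames, dtype=float)
    parent_path = np.full((n_frames, 2), np.nan)
    drift = np.array([0.5, 0.0])
    parent_path[:split_frame] = center + drift[None, :] * t[:split_frame, None]
    split_pos = center + drift * (split_frame - 1)
    cells = [SyntheticCell(id=0, path=parent_path, expression=parent_expression,
                           nuclear_diameter=nuclear_diameter)]
    sep_dir = np.array([0.0, 1.0])
    for d, sign in ((1, +1.0), (2, -1.0)):
        path = np.full((n_frames, 2), np.nan)
        tt = t[split_frame:] - split_frame + 1
        path[split_frame:] = split_pos[None, :] + sign * sep_dir[None, :] * (1.5 * tt)[:, None]
        expr = parent_expression.copy()
        if daughter_noise > 0:
            expr = np.clip(expr * (1 + daughter_noise * rng.standard_normal(expr.shape)), 0, None)
            if not np.any(expr > 0):
                expr = parent_expression.copy()
        cells.append(SyntheticCell(id=d, path=path, expression=expr,
                                   nuclear_diameter=nuclear_diameter, parent=0))
    spectra = make_reference_spectra(DEFAULT_FLUOROPHORES[1:4])
    if render:
        return render_movie(cells, spectra, n_frames, field_size, pixel_size,
                            noise=noise, seed=seed)
    return SyntheticMovie(
        frames=np.zeros((n_frames, spectra.n_channels, 1, 1)),
        truth=cells, spectra=spectra, pixel_size=pixel_size, field_size=field_size,
    )


def make_random_walk_movie(
    n_cells: int = 5,
    n_frames: int = 60,
    seed: int = 0,
    field_size: tuple[float, float] = (200.0, 200.0),
    pixel_size: float = 0.5,
    speed_mean: float = 1.0,
    persistence: float = 0.7,
    noise: NoiseParams | None = None,
    total_expression: float = 300.0,
    expression_mode: str = "subset",
    render: bool = True,
) -> SyntheticMovie:
    """Movie of cells on persistent random walks with random color subsets.

    Per-cell speed is drawn from an exponential around ``speed_mean``
    (µm/frame); direction follows an AR(1) heading with the given
    persistence.  Walks reflect at the field borders.  Defaults give a
    60-frame, 5-min-interval (~5 h) movie.

    ``expression_mode="subset"`` draws each cell's colors uniformly from
    the 7 nonempty label subsets (equal fractions within the subset, so
    rank order is degenerate by construction).  ``"hierarchical"`` gives
    each cell a strict intensity hierarchy -- a random permutation of
    fractions (0.6, 0.3, 0.1) -- emulating cells whose per-color intensity
    order is resolvable, e.g. red consistently higher than green.
    """
    rng = np.random.default_rng(seed)
    spectra = make_reference_spectra(DEFAULT_FLUOROPHORES[1:4])
    K = 3
    cells = []
    margin = 15.0
    for i in range(n_cells):
        pos = rng.uniform(margin, np.array(field_size) - margin)
        heading = rng.uniform(0, 2 * np.pi)
        speed = rng.exponential(speed_mean)
        path = np.empty((n_frames, 2))
        for t in range(n_frames):
            path[t] = pos
            heading = persistence * heading + (1 - persistence) * rng.uniform(0, 2 * np.pi) \
                + 0.2 * rng.standard_normal()
            step = speed * np.array([np.cos(heading), np.sin(heading)])
            pos = pos + step
            for ax in (0, 1):
                if pos[ax] < margin or pos[ax] > field_size[ax] - margin:
                    pos[ax] = np.clip(pos[ax], margin, field_size[ax] - margin)
        if expression_mode == "hierarchical":
            fracs = rng.permutation(np.array([0.6, 0.3, 0.1]))
        elif expression_mode == "subset":
            fracs = _SUBSET_FRACTIONS[rng.integers(0, 7)]
        else:
            raise ValueError(f"unknown expression mode: {expression_mode!r}")
        expr = fracs * total_expression * rng.uniform(0.7, 1.3)
        cells.append(SyntheticCell(id=i, path=path, expression=expr))
    if render:
        return render_movie(cells, spectra, n_frames, field_size, pixel_size,
                            noise=noise, seed=seed)
    return SyntheticMovie(
        frames=np.zeros((n_frames, spectra.n_channels, 1, 1)),
        truth=cells, spectra=spectra, pixel_size=pixel_size, field_size=field_size,
    )
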