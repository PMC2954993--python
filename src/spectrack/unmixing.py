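"""Linear unmixing of spectral stacks with background thresholding.

A lambda stack records a C-channel emission spectrum per pixel.  Linear
unmixing decomposes each pixel spectrum y into nonnegative abundances a of
K reference fluorophores, solving

    min_{a >= 0}  || S a - y ||^2

with S the channel-by-fluorophore reference matrix.  Nonnegativity is
physically required (negative dye amounts do not exist) and stabilizes the
solution when spectra overlap heavily.  An autofluorescence reference
column may participate in the fit and be discarded afterwards, subtracting
tissue background from the fluorophore maps.

Background thresholding follows the empirical per-channel rule used for
confocal data: take the maximum intensity inside a signal-free background
rectangle, add 25% headroom to make sure genuine background pixels fall
below it, and zero out everything at or below that threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .spectral_render import ReferenceSpectra

__all__ = [
    "AbundanceMap",
    "unmix_stack",
    "background_threshold",
    "apply_threshold",
    "max_intensity_projection",
]


@dataclass
class AbundanceMap:
    """Per-pixel fluorophore abundances and fit residuals.

    ``abundances``: (K, Y, X) nonnegative; ``residual``: (Y, X) Euclidean
    norm of S a - y per pixel; ``labels`` name the K planes.
    """

    abundances: np.ndarray
    residual: np.ndarray
    labels: list[str]

    def plane(self, label: str) -> np.ndarray:
        return self.abundances[self.labels.index(label)]

    def drop_autofluorescence(self) -> "AbundanceMap":
        """Discard the autofluorescence plane after solving, if present."""
        if "autofluorescence" not in self.labels:
            return self
        keep = [i for i, l in enumerate(self.labels) if l != "autofluorescence"]
        return AbundanceMap(self.abundances[keep], self.residual,
                            [self.labels[i] for i in keep])


def unmix_stack(stack: np.ndarray, spectra: ReferenceSpectra,
                tol: float = 1e-10) -> AbundanceMap:
    """Nonnegative least-squares unmixing of a (C, Y, X) stack.

    Pixels whose unconstrained least-squares solution is already
    nonnegative are solved in one vectorized step (that solution is then
    the NNLS optimum); the remainder fall back to an active-set NNLS solve
    per pixel.  Emits a warning when S is rank-deficient or has fewer
    channels than fluorophores (abundances not identifiable).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be C x Y x X")
    S = spectra.matrix
    C, K = S.shape
    if stack.shape[0] != C:
        raise ValueError(
            f"stack has {stack.shape[0]} channels but spectra expect {C}")
    if C < K or np.linalg.matrix_rank(S) < K:
        warnings.warn("reference spectra are rank-deficient or underdetermined; "
                      "abundances may not be identifiable", RuntimeWarning)
    _, Y, X = stack.shape
    pixels = stack.reshape(C, -1)  # (C, P)
    P = pixels.shape[1]
    # fast path: unconstrained solution via pseudo-inverse
    pinv = np.linalg.pinv(S)
    a = pinv @ pixels  # (K, P)
    bad = np.any(a < -tol, axis=0)
    a = np.clip(a, 0.0, None)
    if np.any(bad):
        for p in np.flatnonzero(bad):
            a[:, p], _ = nnls(S, pixels[:, p])
    resid = np.linalg.norm(S @ a - pixels, axis=0)
    return AbundanceMap(a.reshape(K, Y, X), resid.reshape(Y, X),
                        list(spectra.labels))


def background_threshold(channel_image: np.ndarray,
                         background_region: tuple[int, int, int, int],
                         headroom: float = 1.25) -> float:
    """Threshold = 125% of the maximum intensity in a background rectangle.

    ``background_region`` is (x0, y0, x1, y1) in pixel indices, half-open,
    drawn over an area with no fluorescent signal.  The 25% headroom
    guarantees that all pixels of comparable background level fall at or
    below the threshold.
    """
    img = np.asarray(channel_image)
    x0, y0, x1, y1 = background_region
    if not (0 <= x0 < x1 <= img.shape[1] and 0 <= y0 < y1 <= img.shape[0]):
        raise ValueError("background region empty or outside the image")
    return float(headroom * img[y0:y1, x0:x1].max())


def apply_threshold(stack: np.ndarray, thresholds) -> np.ndarray:
    """Zero out values at or below the per-channel threshold.

    ``stack`` is (C, Y, X) or (C, Z, Y, X); ``thresholds`` has one entry per
    channel.  Values strictly above the channel threshold pass unchanged.
    """
    stack = np.asarray(stack, dtype=float)
    thr = np.asarray(thresholds, dtype=float)
    if thr.ndim != 1 or len(thr) != stack.shape[0]:
        raise ValueError(
            f"need {stack.shape[0]} thresholds, got {thr.shape}")
    shape = (len(thr),) + (1,) * (stack.ndim - 1)
    out = stack.copy()
    out[stack <= thr.reshape(shape)] = 0.0
    return out


def max_intensity_projection(zstack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over the leading z axis of a (Z, Y, X) stack."""
    zstack = np.asarray(zstack)
    if zstack.ndim != 3 or zstack.shape[0] < 1:
        raise ValueError("zstack must be Z x Y x X with Z >= 1")
    return zstack.max(axis=0)
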