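"""Shared I/O, run configuration, and the end-to-end pipeline.

The pipeline chains the whole method on synthetic data: generate a movie
with ground truth, linearly unmix each frame against the reference spectra,
detect and link spots per channel, track cells with (or without) spectral
fingerprints, and evaluate against the ground truth.  Every run writes its
resolved configuration next to the outputs, and is deterministic for a
fixed seed.

Formats: multi-channel multi-frame TIFF with TCYX axes declared in the
metadata; CSV tables for ground truth, spectra, and tracks; JSON reports.
All physical units are µm / nm / minutes and are recorded in metadata.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage

from . import spectral_render as sr
from . import unmixing as um
from . import detection as det
from . import tracking as trk

__all__ = [
    "RunConfig",
    "run_pipeline",
    "write_movie_tiff",
    "read_movie_tiff",
    "write_truth_csv",
    "read_truth_csv",
    "write_spectra_csv",
    "read_spectra_csv",
    "write_tracks_csv",
]

logger = logging.getLogger("spectrack")


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def write_movie_tiff(path, frames: np.ndarray, pixel_size: float = 0.5,
                     frame_interval: float = 5.0):
    """Write a (T, C, Y, X) float stack as TIFF with declared axes."""
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim != 4:
        raise ValueError("frames must be T x C x Y x X")
    tifffile.imwrite(
        path, frames, imagej=False, photometric="minisblack",
        metadata={"axes": "TCYX", "pixel_size_um": pixel_size,
                  "frame_interval_min": frame_interval},
    )


def read_movie_tiff(path) -> tuple[np.ndarray, dict]:
    """Read a TIFF written by :func:`write_movie_tiff`; returns (TCYX, meta)."""
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    axes = meta.get("axes")
    if axes is not None and axes != "TCYX":
        raise ValueError(f"unsupported axis order {axes!r}; expected TCYX")
    if arr.ndim != 4:
        raise ValueError(f"expected a 4D TCYX stack, got shape {arr.shape}")
    return arr, dict(meta)


_TRUTH_COLUMNS = ["frame", "cell_id", "x_um", "y_um", "parent_id"]


def write_truth_csv(path, movie: sr.SyntheticMovie):
    """Ground truth as tidy CSV: one row per (frame, live cell)."""
    labels = [l for l in movie.spectra.labels if l != "autofluorescence"]
    rows = []
    for cell in movie.truth:
        for t in range(len(cell.path)):
            if not cell.alive_at(t):
                continue
            row = {"frame": t, "cell_id": cell.id,
                   "x_um": cell.path[t, 0], "y_um": cell.path[t, 1],
                   "parent_id": -1 if cell.parent is None else cell.parent}
            for k, name in enumerate(labels):
                row[f"expr_{name}"] = cell.expression[k]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_truth_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"truth CSV is missing required columns: {missing}")
    return df


def write_spectra_csv(path, spectra: sr.ReferenceSpectra):
    df = pd.DataFrame(spectra.matrix, columns=spectra.labels)
    df.insert(0, "channel_center_nm", spectra.channel_centers)
    df.to_csv(path, index=False)


def read_spectra_csv(path) -> sr.ReferenceSpectra:
    df = pd.read_csv(path)
    if "channel_center_nm" not in df.columns:
        raise ValueError("spectra CSV is missing the channel_center_nm column")
    labels = [c for c in df.columns if c != "channel_center_nm"]
    return sr.ReferenceSpectra(
        matrix=df[labels].to_numpy(),
        labels=labels,
        channel_centers=df["channel_center_nm"].to_numpy(),
        has_autofluorescence="autofluorescence" in labels,
    )


def write_tracks_csv(path, tracks: list[trk.Track]):
    rows = []
    for tr in tracks:
        for f, (x, y), fp in zip(tr.frames, tr.positions, tr.fingerprints):
            row = {"frame": f, "track_id": tr.id, "x_um": x, "y_um": y,
                   "parent_id": -1 if tr.parent is None else tr.parent}
            if fp is not None:
                for k, frac in enumerate(fp.fractions):
                    row[f"fraction_{k}"] = frac
                row["rank_order"] = ">".join(str(i) for i in fp.rank_order)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run; serializes losslessly."""

    seed: int = 0
    scenario: str = "crossing"  # walk | crossing | division
    n_cells: int = 2
    n_frames: int = 31
    field_size: tuple[float, float] = (100.0, 100.0)
    pixel_size: float = 1.0
    fingerprint_separation: float = 0.6
    noise_background: float = 2.0
    noise_poisson: bool = True
    noise_read_sigma: float = 1.0
    bg_box: tuple[int, int, int, int] = (0, 0, 10, 10)  # px, signal-free corner
    label_type: str = "h2b3"
    track_mode: str = "spectral"  # spectral | blind | none
    out_dir: str = "spectrack_run"

    def to_yaml(self, path):
        d = asdict(self)
        d["field_size"] = list(d["field_size"])
        d["bg_box"] = list(d["bg_box"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        for key in ("field_size", "bg_box"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


class StageError(RuntimeError):
    """Pipeline failure tagged with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _generate(cfg: RunConfig) -> sr.SyntheticMovie:
    noise = sr.NoiseParams(poisson=cfg.noise_poisson,
                           read_sigma=cfg.noise_read_sigma,
                           background=cfg.noise_background)
    if cfg.scenario == "crossing":
        return sr.make_crossing_scenario(
            n_cells=cfg.n_cells, fingerprint_separation=cfg.fingerprint_separation,
            noise=noise, seed=cfg.seed, n_frames=cfg.n_frames,
            field_size=cfg.field_size, pixel_size=cfg.pixel_size)
    if cfg.scenario == "division":
        return sr.make_division_scenario(
            seed=cfg.seed, n_frames=cfg.n_frames, field_size=cfg.field_size,
            pixel_size=cfg.pixel_size, noise=noise)
    if cfg.scenario == "walk":
        return sr.make_random_walk_movie(
            n_cells=cfg.n_cells, n_frames=cfg.n_frames, seed=cfg.seed,
            field_size=cfg.field_size, pixel_size=cfg.pixel_size, noise=noise)
    raise ValueError(f"unknown scenario: {cfg.scenario!r}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute generate -> unmix -> detect -> track -> evaluate.

    Writes movie TIFF, truth/spectra/tracks CSVs, and a JSON report into
    ``cfg.out_dir`` along with the resolved config; partial outputs are
    preserved if a later stage fails.  Returns the report dict.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    logger.info("pipeline run with resolved config: %s", asdict(cfg))

    try:
        movie = _generate(cfg)
        write_movie_tiff(out / "movie.tif", movie.frames, movie.pixel_size,
                         movie.frame_interval)
        write_truth_csv(out / "truth.csv", movie)
        write_spectra_csv(out / "spectra.csv", movie.spectra)
    except Exception as e:  # noqa: BLE001 - stage tagging
        raise StageError("generate", e) from e

    label = det.LabelType(cfg.label_type)
    diameter = det.LABEL_PARAMS[label][0]
    sigma_px = diameter / 2.355 / movie.pixel_size

    try:
        # pre-smooth at the object scale before unmixing: unmixing is
        # linear, so smoothing commutes with it in expectation but tames
        # the shot noise before the pseudo-inverse can amplify it
        abundance_frames = [
            um.unmix_stack(
                ndimage.gaussian_filter(frame, (0, sigma_px, sigma_px)),
                movie.spectra).abundances
            for frame in movie.frames
        ]
    except Exception as e:
        raise StageError("unmix", e) from e

    try:
        per_frame_objects = []
        for ab in abundance_frames:
            # 125%-of-background-max rule per channel
            thresholds = [um.background_threshold(p, cfg.bg_box) for p in ab]
            _, objects = det.count_cells(
                list(ab), label, threshold=thresholds,
                pixel_size=movie.pixel_size)
            per_frame_objects.append(objects)
    except Exception as e:
        raise StageError("detect", e) from e

    report = {
        "n_frames": movie.n_frames,
        "n_truth_cells": len(movie.truth),
        "mean_detections_per_frame": float(np.mean([len(o) for o in per_frame_objects])),
    }

    if cfg.track_mode != "none":
        try:
            detections = []
            for t, objects in enumerate(per_frame_objects):
                live = [c for c in movie.truth
                        if t < len(c.path) and c.alive_at(t)]
                dets = []
                for obj in objects:
                    cx, cy = obj.centroid
                    truth_id = None
                    if live:
                        dist, nearest = min(
                            (np.hypot(cx - c.path[t, 0], cy - c.path[t, 1]), c.id)
                            for c in live)
                        if dist <= 10.0:  # one nuclear diameter
                            truth_id = nearest
                    dets.append(trk.Detection(
                        cx, cy,
                        trk.compute_fingerprint(
                            obj.channel_intensities(len(abundance_frames[0]))),
                        truth_id=truth_id))
                detections.append(dets)
            if cfg.track_mode == "spectral":
                tracks, treport = trk.spectral_track(detections)
            else:
                tracks, treport = trk.nearest_neighbor_track(detections)
            write_tracks_csv(out / "tracks.csv", tracks)
            parent_map = {c.id: c.parent for c in movie.truth}
            evaluable = [tr for tr in tracks
                         if all(l is not None for l in tr.truth_ids)]
            switches = trk.evaluate_tracking(evaluable, parent_map).identity_switches
            report.update({
                "n_tracks": len(tracks),
                "conflict_events": treport.conflict_events,
                "resolved_by_spectrum": treport.resolved_by_spectrum,
                "ambiguous_conflicts": treport.ambiguous,
                "identity_switches": switches,
            })
        except Exception as e:
            raise StageError("track", e) from e

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
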