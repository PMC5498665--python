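"""Seeded synthetic-data generators with machine-readable ground truth.

Each generator is a pure function of ``(spec, seed)`` and returns both the
artefact (image, nested measurements, or assay table) and a
:class:`GroundTruth` record holding the exact quantities the analysis
pipeline is supposed to recover:

* dark-field scenes of cell somata with piecewise-linear neurites of known
  geometric length (optional Y-branching, longest-path truth);
* Western-blot films as Gaussian bands of known discrete integrated volume,
  rendered film-style (dark bands on a light, linearly ramped background);
* two-channel fluorescence pairs (marker + nucleus) with known
  suprathreshold cumulative sums;
* nested measurement hierarchies (experiment -> replicate -> picture ->
  measurement) with a known grand mean;
* assay tables with planted fold-change effects.

The noise model everywhere is additive Gaussian, clipped to the raster's
bit-depth range.  Geometry truth is the vertex polyline, never the raster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import line_aa
from skimage.morphology import disk as disk_footprint

from .micrograph import Micrograph, ScaleCalibration


class SceneOverflowError(ValueError):
    """Requested geometry cannot be placed without overlap within the retry budget."""


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NeuronSceneSpec:
    """Geometry and photometry of a synthetic neuron scene.

    Defaults emulate a 20x phase-contrast field after neurite enhancement:
    a handful of well-separated cells, two neurites per cell with lengths of
    a few soma diameters, faint additive noise.
    """

    image_height_px: int = 1024
    image_width_px: int = 1024
    n_cells: int = 5
    soma_radius_px: float = 8.0
    neurites_per_cell: int = 2
    neurite_length_px_range: tuple[float, float] = (60.0, 110.0)
    branch_probability: float = 0.0
    neurite_width_px: float = 3.0
    foreground_intensity: float = 40000.0
    background_intensity: float = 2000.0
    noise_sd: float = 300.0
    um_per_px: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.neurite_length_px_range
        if lo > hi or lo <= 0:
            raise ValueError("neurite_length_px_range must satisfy 0 < min <= max")
        if self.foreground_intensity <= self.background_intensity:
            raise ValueError("foreground_intensity must exceed background_intensity")
        if self.n_cells < 0 or self.neurites_per_cell < 0:
            raise ValueError("counts must be >= 0")
        if self.soma_radius_px <= 0 or self.neurite_width_px <= 0 or self.um_per_px <= 0:
            raise ValueError("radii, widths and calibration must be positive")
        if not 0.0 <= self.branch_probability <= 1.0:
            raise ValueError("branch_probability must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class BlotSpec:
    """Lane layout and band photometry for a synthetic blot film.

    ``lanes`` holds ``(target_band_amplitude, loading_band_amplitude)`` per
    lane.  Bands are isotropic Gaussian bumps subtracted from a light
    background (film polarity: signal is dark), so the densitometry stage's
    default film inversion applies directly.
    """

    lanes: tuple[tuple[float, float], ...] = (
        (8000.0, 10000.0),
        (12000.0, 10000.0),
        (16000.0, 10000.0),
    )
    band_sigma_px: float = 4.0
    lane_pitch_px: int = 48
    background_level: float = 50000.0
    background_gradient: float = 5.0
    noise_sd: float = 100.0

    def __post_init__(self) -> None:
        if len(self.lanes) == 0:
            raise ValueError("at least one lane required")
        for amp_t, amp_l in self.lanes:
            if amp_t < 0 or amp_l < 0:
                raise ValueError("band amplitudes must be >= 0")
        if self.band_sigma_px <= 0:
            raise ValueError("band_sigma_px must be > 0")
        if self.lane_pitch_px <= 4 * self.band_sigma_px:
            raise ValueError(
                f"lane_pitch_px ({self.lane_pitch_px}) must exceed 4*band_sigma_px "
                f"({4 * self.band_sigma_px}) so bands do not overlap"
            )
        max_amp = max(max(t, l) for t, l in self.lanes)
        if max_amp > self.background_level:
            raise ValueError("band amplitude exceeds background_level; dark bands would clip at 0")


@dataclass(frozen=True)
class FluorPairSpec:
    """Two-channel fluorescence scene: nucleus disks plus a positive marker fraction."""

    n_nuclei: int = 30
    nucleus_radius_px: float = 6.0
    marker_fraction_positive: float = 0.5
    marker_amplitude: float = 20000.0
    nucleus_amplitude: float = 20000.0
    threshold_truth: float = 5000.0
    noise_sd: float = 0.0
    image_shape: tuple[int, int] = (512, 512)

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if not 0.0 <= self.marker_fraction_positive <= 1.0:
            raise ValueError("marker_fraction_positive must lie in [0, 1]")
        if self.marker_amplitude <= self.threshold_truth:
            raise ValueError("marker_amplitude must exceed threshold_truth for positive objects")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class HierarchySpec:
    """Nested sampling design: experiment -> replicate -> picture -> measurement.

    Mirrors the measurement protocol for neurite lengths: independent
    experiments performed in duplicate, several pictures per replicate,
    15-30 neurites measured per picture.
    """

    n_experiments: int = 3
    replicates_per_experiment: int = 2
    pictures_per_replicate: int = 5
    measurements_per_picture_range: tuple[int, int] = (15, 30)
    grand_mean: float = 60.0
    sd_between_experiments: float = 4.0
    sd_between_pictures: float = 6.0
    sd_within_picture: float = 12.0

    def __post_init__(self) -> None:
        if min(self.n_experiments, self.replicates_per_experiment, self.pictures_per_replicate) < 1:
            raise ValueError("all counts must be >= 1")
        lo, hi = self.measurements_per_picture_range
        if lo > hi or lo < 1:
            raise ValueError("measurements_per_picture_range must satisfy 1 <= min <= max")
        for sd in (self.sd_between_experiments, self.sd_between_pictures, self.sd_within_picture):
            if sd < 0:
                raise ValueError("sd components must be >= 0")


@dataclass
class GroundTruth:
    """Exact generator-side record of what the analysis should recover."""

    kind: str  # neurites | blot | fluorescence | hierarchy | assay
    payload: dict[str, Any]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"kind": self.kind, "payload": self.payload}, fh, indent=1, default=_jsonable)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(kind=obj["kind"], payload=obj["payload"])


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# --------------------------------------------------------------------------
# Polyline helpers (shared truth arithmetic)
# --------------------------------------------------------------------------


def segment_sum(vertices: np.ndarray) -> float:
    """Euclidean length of a polyline: sum of consecutive-segment hypotenuses."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2:
        return 0.0
    return float(np.hypot(*np.diff(v, axis=0).T).sum())


def _walk(start: np.ndarray, heading: float, total_len: float, rng: np.random.Generator,
          n_segments: int, max_turn_deg: float = 18.0) -> np.ndarray:
    """Piecewise-linear walk of given total length with bounded heading jitter."""
    fracs = rng.dirichlet(np.full(n_segments, 4.0)) * total_len
    pts = [np.asarray(start, dtype=float)]
    h = heading
    for i, seg in enumerate(fracs):
        if i > 0:
            h += np.deg2rad(rng.uniform(-max_turn_deg, max_turn_deg))
        pts.append(pts[-1] + seg * np.array([np.sin(h), np.cos(h)]))
    return np.asarray(pts)


# --------------------------------------------------------------------------
# Neuron scenes
# --------------------------------------------------------------------------


def generate_neuron_scene(
    spec: NeuronSceneSpec, seed: int = 0
) -> tuple[Micrograph, GroundTruth]:
    """Render a dark-field scene of somata with neurites of known geometry.

    Somata are bright disks; neurites are anti-aliased polylines of width
    ``neurite_width_px`` starting at the soma boundary.  A branch replaces
    the distal part of a neurite with two arms; the recorded truth length
    follows the longest cumulative root-to-tip path.

    Cells are placed so that each cell's full territory (soma plus maximal
    neurite reach) is disjoint from every other cell's and from the image
    border, which guarantees neurites of different cells never touch.

    Returns the rendered image and a truth record with, per neurite, every
    root-to-tip path (vertex lists), the longest-path length in px and um,
    and the owning soma's centre.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.image_height_px, spec.image_width_px
    lmax = spec.neurite_length_px_range[1]
    territory = spec.soma_radius_px + lmax + spec.neurite_width_px + 2

    centers: list[np.ndarray] = []
    if spec.n_cells > 0:
        if min(h, w) <= 2 * territory:
            raise SceneOverflowError(
                "image too small for requested geometry: shrink neurite_length_px_range "
                "or soma_radius_px, or enlarge image_height_px/image_width_px"
            )
        budget = 400 * spec.n_cells
        while len(centers) < spec.n_cells and budget > 0:
            budget -= 1
            c = rng.uniform([territory, territory], [h - territory, w - territory])
            if all(np.hypot(*(c - o)) >= 2 * territory for o in centers):
                centers.append(c)
        if len(centers) < spec.n_cells:
            raise SceneOverflowError(
                "could not place all cells without overlap: reduce n_cells or "
                "neurite_length_px_range, or enlarge the image"
            )

    canvas = np.zeros((h, w), dtype=float)
    cells: list[dict[str, Any]] = []
    for ci, center in enumerate(centers):
        rr, cc = draw_disk(tuple(center), spec.soma_radius_px, shape=(h, w))
        canvas[rr, cc] = 1.0
        neurites = []
        base = rng.uniform(0, 2 * np.pi)
        for ni in range(spec.neurites_per_cell):
            # distinct angular sectors keep same-cell neurites apart
            theta = base + 2 * np.pi * ni / max(spec.neurites_per_cell, 1)
            theta += np.deg2rad(rng.uniform(-15, 15))
            total = rng.uniform(*spec.neurite_length_px_range)
            root = center + spec.soma_radius_px * np.array([np.sin(theta), np.cos(theta)])
            branched = rng.uniform() < spec.branch_probability
            if branched:
                stem_frac = rng.uniform(0.4, 0.65)
                stem = _walk(root, theta, stem_frac * total, rng, n_segments=2)
                # heading at the end of the stem
                dvec = stem[-1] - stem[-2]
                h_end = np.arctan2(dvec[0], dvec[1])
                spread = np.deg2rad(rng.uniform(18, 32))
                arm_a = _walk(stem[-1], h_end + spread, (1 - stem_frac) * total, rng, 2)
                arm_b = _walk(stem[-1], h_end - spread,
                              rng.uniform(0.5, 1.0) * (1 - stem_frac) * total, rng, 2)
                paths = [np.vstack([stem, arm_a[1:]]), np.vstack([stem, arm_b[1:]])]
            else:
                n_seg = int(rng.integers(2, 5))
                paths = [_walk(root, theta, total, rng, n_seg)]
            for p in paths:
                _rasterize_polyline(canvas, p)
            length_px = max(segment_sum(p) for p in paths)
            neurites.append(
                {
                    "paths": [p.tolist() for p in paths],
                    "branched": bool(branched),
                    "length_px": length_px,
                    "length_um": length_px * spec.um_per_px,
                }
            )
        cells.append({"center": center.tolist(), "radius": spec.soma_radius_px,
                      "neurites": neurites})

    radius = max(int(round((spec.neurite_width_px - 1) / 2)), 0)
    if radius > 0:
        canvas = ndimage.grey_dilation(canvas, footprint=disk_footprint(radius))
    img = spec.background_intensity + (spec.foreground_intensity - spec.background_intensity) * canvas
    if spec.noise_sd > 0:
        img = img + spec.noise_sd * rng.standard_normal(img.shape)
    pixels = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    truth = GroundTruth(
        kind="neurites",
        payload={"cells": cells, "um_per_px": spec.um_per_px,
                 "neurite_width_px": spec.neurite_width_px},
    )
    micro = Micrograph(pixels=pixels, bit_depth=16, channel="phase",
                       calibration=ScaleCalibration(spec.um_per_px))
    return micro, truth


def _rasterize_polyline(canvas: np.ndarray, vertices: np.ndarray) -> None:
    """Accumulate an anti-aliased polyline (max blend) onto a unit canvas."""
    h, w = canvas.shape
    v = np.rint(vertices).astype(int)
    for (r0, c0), (r1, c1) in zip(v[:-1], v[1:]):
        rr, cc, val = line_aa(r0, c0, r1, c1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        rr, cc, val = rr[keep], cc[keep], val[keep]
        np.maximum.at(canvas, (rr, cc), val)


def soma_mask_from_truth(truth: GroundTruth, shape: tuple[int, int]) -> np.ndarray:
    """Boolean soma mask reconstructed from a neuron-scene truth record."""
    mask = np.zeros(shape, dtype=bool)
    for cell in truth.payload["cells"]:
        rr, cc = draw_disk(tuple(cell["center"]), cell["radius"], shape=shape)
        mask[rr, cc] = True
    return mask


def neurite_mask_from_truth(truth: GroundTruth, shape: tuple[int, int]) -> np.ndarray:
    """Boolean neurite mask (rasterized truth polylines, at truth width)."""
    canvas = np.zeros(shape, dtype=float)
    for cell in truth.payload["cells"]:
        for neu in cell["neurites"]:
            for p in neu["paths"]:
                _rasterize_polyline(canvas, np.asarray(p))
    radius = max(int(round((truth.payload.get("neurite_width_px", 1) - 1) / 2)), 0)
    if radius > 0:
        canvas = ndimage.grey_dilation(canvas, footprint=disk_footprint(radius))
    return canvas > 0.05


# --------------------------------------------------------------------------
# Blot films
# --------------------------------------------------------------------------


def generate_blot_image(spec: BlotSpec, seed: int = 0) -> tuple[Micrograph, GroundTruth]:
    """Render a film-style blot: dark Gaussian bands over a light ramped background.

    Per lane, a target band row and a loading-control band row.  The truth
    integrated signal of each band is the *discrete* sum of its analytic
    bump over the raster, which is exactly what ROI densitometry (after film
    inversion and background subtraction) should recover.
    """
    n_lanes = len(spec.lanes)
    w = spec.lane_pitch_px * n_lanes
    h = max(int(np.ceil(24 * spec.band_sigma_px)), 64)
    target_row, loading_row = 0.3 * h, 0.7 * h
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]

    rng = np.random.default_rng(seed)
    background = spec.background_level + spec.background_gradient * rows.astype(float)
    background = np.broadcast_to(background, (h, w)).copy()

    signal = np.zeros((h, w), dtype=float)
    lanes_truth = []
    for i, (amp_t, amp_l) in enumerate(spec.lanes):
        col0 = (i + 0.5) * spec.lane_pitch_px
        bump_t = amp_t * np.exp(
            -((rows - target_row) ** 2 + (cols - col0) ** 2) / (2 * spec.band_sigma_px**2)
        )
        bump_l = amp_l * np.exp(
            -((rows - loading_row) ** 2 + (cols - col0) ** 2) / (2 * spec.band_sigma_px**2)
        )
        signal += bump_t + bump_l
        idv_t, idv_l = float(bump_t.sum()), float(bump_l.sum())
        lanes_truth.append(
            {
                "lane": i,
                "center_col": col0,
                "target_idv": idv_t,
                "loading_idv": idv_l,
                "ratio": idv_t / idv_l if idv_l > 0 else float("nan"),
            }
        )

    film = background - signal
    if spec.noise_sd > 0:
        film = film + spec.noise_sd * rng.standard_normal(film.shape)
    pixels = np.clip(np.rint(film), 0, 65535).astype(np.uint16)

    ratios = [lt["ratio"] for lt in lanes_truth]
    ref = ratios[0]
    truth = GroundTruth(
        kind="blot",
        payload={
            "lanes": lanes_truth,
            "fold_change_vs_lane0": [r / ref if np.isfinite(ref) and ref > 0 else float("nan")
                                     for r in ratios],
            "band_sigma_px": spec.band_sigma_px,
            "target_row": target_row,
            "loading_row": loading_row,
            "lane_pitch_px": spec.lane_pitch_px,
        },
    )
    return Micrograph(pixels=pixels, bit_depth=16, channel="blot"), truth


# --------------------------------------------------------------------------
# Fluorescence pairs
# --------------------------------------------------------------------------


def generate_fluorescence_pair(
    spec: FluorPairSpec, seed: int = 0
) -> tuple[Micrograph, Micrograph, GroundTruth]:
    """Render a marker/nucleus channel pair with known suprathreshold sums.

    The nucleus channel holds ``n_nuclei`` disks; the marker channel holds a
    slightly larger (cytoplasmic) disk over the positive fraction of
    objects.  Truth records the suprathreshold cumulative sum of each
    *noise-free* channel at ``threshold_truth`` (strict ``>``) and their
    ratio (the true RFI).
    """
    rng = np.random.default_rng(seed)
    h, w = spec.image_shape
    r_nuc = spec.nucleus_radius_px
    r_mark = 1.4 * r_nuc
    margin = r_mark + 2

    centers: list[np.ndarray] = []
    budget = 400 * max(spec.n_nuclei, 1)
    while len(centers) < spec.n_nuclei and budget > 0:
        budget -= 1
        c = rng.uniform([margin, margin], [h - margin, w - margin])
        if all(np.hypot(*(c - o)) >= 2 * r_mark + 2 for o in centers):
            centers.append(c)
    if len(centers) < spec.n_nuclei:
        raise SceneOverflowError("could not place all nuclei: reduce n_nuclei or radius")

    n_pos = int(round(spec.marker_fraction_positive * spec.n_nuclei))
    positive = rng.permutation(spec.n_nuclei)[:n_pos] if spec.n_nuclei else np.array([], dtype=int)

    nucleus = np.zeros((h, w), dtype=float)
    marker = np.zeros((h, w), dtype=float)
    for i, c in enumerate(centers):
        rr, cc = draw_disk(tuple(c), r_nuc, shape=(h, w))
        nucleus[rr, cc] = spec.nucleus_amplitude
        if i in positive:
            rr, cc = draw_disk(tuple(c), r_mark, shape=(h, w))
            marker[rr, cc] = spec.marker_amplitude

    thr = spec.threshold_truth
    marker_sum = float(marker[marker > thr].sum())
    nucleus_sum = float(nucleus[nucleus > thr].sum())
    rfi_truth = marker_sum / nucleus_sum if nucleus_sum > 0 else 0.0

    def _finish(chan: np.ndarray, tag: str) -> Micrograph:
        out = chan
        if spec.noise_sd > 0:
            out = out + spec.noise_sd * rng.standard_normal(out.shape)
        return Micrograph(np.clip(np.rint(out), 0, 65535).astype(np.uint16),
                          bit_depth=16, channel=tag)

    truth = GroundTruth(
        kind="fluorescence",
        payload={
            "threshold_truth": thr,
            "marker_suprathreshold_sum": marker_sum,
            "nucleus_suprathreshold_sum": nucleus_sum,
            "rfi": rfi_truth,
            "n_positive": int(n_pos),
            "centers": [c.tolist() for c in centers],
        },
    )
    return _finish(marker, "marker"), _finish(nucleus, "nucleus"), truth


# --------------------------------------------------------------------------
# Measurement hierarchies
# --------------------------------------------------------------------------


def generate_measurement_hierarchy(
    spec: HierarchySpec, seed: int = 0
) -> tuple[dict[str, dict[str, dict[str, list[float]]]], GroundTruth]:
    """Draw a nested experiment -> replicate -> picture -> measurement sample.

    Values are ``grand_mean + experiment offset + picture offset + within-
    picture noise``, each component normal with the spec's SD.  Replicates
    share their experiment's offset (they are repeated handling of the same
    biological preparation); pictures draw independent offsets.
    """
    rng = np.random.default_rng(seed)
    data: dict[str, dict[str, dict[str, list[float]]]] = {}
    offsets: dict[str, Any] = {"experiments": {}}
    lo, hi = spec.measurements_per_picture_range
    for e in range(spec.n_experiments):
        e_key = f"exp{e + 1}"
        e_off = float(spec.sd_between_experiments * rng.standard_normal())
        offsets["experiments"][e_key] = {"offset": e_off, "pictures": {}}
        data[e_key] = {}
        for r in range(spec.replicates_per_experiment):
            r_key = f"rep{r + 1}"
            data[e_key][r_key] = {}
            for p in range(spec.pictures_per_replicate):
                p_key = f"pic{p + 1}"
                p_off = float(spec.sd_between_pictures * rng.standard_normal())
                n = int(rng.integers(lo, hi + 1))
                vals = (spec.grand_mean + e_off + p_off
                        + spec.sd_within_picture * rng.standard_normal(n))
                data[e_key][r_key][p_key] = [float(v) for v in vals]
                offsets["experiments"][e_key]["pictures"][f"{r_key}/{p_key}"] = p_off
    truth = GroundTruth(
        kind="hierarchy",
        payload={"grand_mean": spec.grand_mean, "offsets": offsets,
                 "n_measurements": int(sum(len(v) for e in data.values()
                                           for r in e.values() for v in r.values()))},
    )
    return data, truth


def hierarchy_to_frame(data: dict[str, dict[str, dict[str, list[float]]]]) -> pd.DataFrame:
    """Flatten a nested hierarchy into the CSV layout
    ``experiment,replicate,picture_id,length_um``."""
    rows = [
        (e, r, p, v)
        for e, reps in data.items()
        for r, pics in reps.items()
        for p, vals in pics.items()
        for v in vals
    ]
    return pd.DataFrame(rows, columns=["experiment", "replicate", "picture_id", "length_um"])


def frame_to_hierarchy(df: pd.DataFrame) -> dict[str, dict[str, dict[str, list[float]]]]:
    """Inverse of :func:`hierarchy_to_frame`."""
    out: dict[str, dict[str, dict[str, list[float]]]] = {}
    for (e, r, p), grp in df.groupby(["experiment", "replicate", "picture_id"], sort=False):
        out.setdefault(str(e), {}).setdefault(str(r), {})[str(p)] = [
            float(v) for v in grp["length_um"]
        ]
    return out


# --------------------------------------------------------------------------
# Assay tables
# --------------------------------------------------------------------------


def generate_assay_table(
    conditions: list[str],
    fold_changes: list[float],
    n_per_condition: int = 6,
    noise_cv: float = 0.0,
    seed: int = 0,
    control: str | None = None,
    base_value: float = 1.0,
    protein_content_mean: float = 100.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Emit an assay table with planted protein-normalized fold changes.

    Rows are ``condition, replicate, raw_value, protein_content`` with
    ``raw = base * fold * protein * (1 + cv*z)``, so the protein-normalized
    value of each condition has expectation ``fold_change x`` the control's
    and the chain raw/protein -> /control recovers the planted folds exactly
    when ``noise_cv = 0``.
    """
    if control is None:
        raise ValueError("a control condition must be flagged (control=...)")
    if control not in conditions:
        raise ValueError(f"control condition {control!r} not among conditions")
    if len(fold_changes) != len(conditions):
        raise ValueError("fold_changes must align with conditions")
    ctl_fold = fold_changes[conditions.index(control)]
    if not np.isclose(ctl_fold, 1.0):
        raise ValueError(f"control fold change must be 1, got {ctl_fold}")
    if n_per_condition < 1:
        raise ValueError("n_per_condition must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")

    rng = np.random.default_rng(seed)
    rows = []
    for cond, fold in zip(conditions, fold_changes):
        protein = protein_content_mean * (1 + 0.05 * rng.standard_normal(n_per_condition))
        protein = np.clip(protein, 0.2 * protein_content_mean, None)
        raw = base_value * fold * protein * (1 + noise_cv * rng.standard_normal(n_per_condition))
        for k in range(n_per_condition):
            rows.append((cond, k + 1, float(raw[k]), float(protein[k])))
    df = pd.DataFrame(rows, columns=["condition", "replicate", "raw_value", "protein_content"])
    truth = GroundTruth(
        kind="assay",
        payload={"conditions": list(conditions), "fold_changes": [float(f) for f in fold_changes],
                 "control": control, "base_value": base_value},
    )
    return df, truth
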