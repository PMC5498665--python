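"""Neurite enhancement, tracing, and length morphometry.

The enhancement chain is fixed: Gaussian smoothing (noise removal) ->
Laplacian high-pass (edge/ridge response) -> median filter (despeckle) ->
binarization of the absolute response.  The binary map is superimposed in
blue on the original phase-contrast image for visual review.

Neurite length is the Euclidean distance in pixels, or a chained sum of
Euclidean distances, from the cell body to the tip.  When a neurite
branches, the longest root-to-tip path is always the reported length.
Pixel lengths are converted to micrometres through the scale-bar
calibration.

Two measurement modes exist:

* **annotation mode** (reference path): operator-supplied polylines are
  measured exactly — segment-sum of the annotated vertices;
* **automated mode** (convenience): the enhanced edge map is skeletonized,
  skeleton arcs are assembled into soma-anchored trees, and each arc is
  simplified back to a polyline before lengths are summed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import approximate_polygon, label as cc_label
from skimage.morphology import skeletonize, disk

from .micrograph import Micrograph, ScaleCalibration

_LAPLACE_4 = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)
_LAPLACE_8 = np.array([[1, 1, 1], [1, -8, 1], [1, 1, 1]], dtype=float)


@dataclass(frozen=True)
class FilterParams:
    """Parameters of the enhancement chain.

    Defaults are the smallest standard kernels that denoise and enhance
    thin bright processes: sigma-1 Gaussian, 4-connected Laplacian, 3x3
    median, Otsu cut on the absolute response.
    """

    gaussian_sigma_px: float = 1.0
    laplace_neighborhood: Literal["4-connected", "8-connected"] = "4-connected"
    median_window_px: int = 3
    edge_threshold: float | Literal["otsu"] = "otsu"

    def __post_init__(self) -> None:
        if self.gaussian_sigma_px <= 0:
            raise ValueError("gaussian_sigma_px must be > 0")
        if self.median_window_px < 3 or self.median_window_px % 2 == 0:
            raise ValueError("median_window_px must be an odd integer >= 3")
        if self.laplace_neighborhood not in ("4-connected", "8-connected"):
            raise ValueError("laplace_neighborhood must be '4-connected' or '8-connected'")


@dataclass(frozen=True)
class Polyline:
    """An ordered open chain of (row, col) vertices; consecutive vertices distinct."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 1:
            raise ValueError("polyline needs at least one vertex")
        arr = np.asarray(self.vertices, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("vertices must be (row, col) pairs")
        if len(arr) > 1 and np.any(np.all(np.diff(arr, axis=0) == 0, axis=1)):
            raise ValueError("consecutive vertices must be distinct")

    @classmethod
    def from_array(cls, arr: Sequence[Sequence[float]]) -> "Polyline":
        return cls(tuple((float(r), float(c)) for r, c in arr))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)


class NeuriteTree:
    """A soma-anchored neurite: a weighted tree rooted at the soma attachment.

    Nodes are (row, col) coordinates; each edge carries its Euclidean
    length.  The tree must be connected, acyclic, and contain the root.
    """

    def __init__(self, soma_anchor: tuple[float, float],
                 edges: Iterable[tuple[tuple[float, float], tuple[float, float]]]):
        self.soma_anchor = (float(soma_anchor[0]), float(soma_anchor[1]))
        g = nx.Graph()
        g.add_node(self.soma_anchor)
        for a, b in edges:
            a = (float(a[0]), float(a[1]))
            b = (float(b[0]), float(b[1]))
            g.add_edge(a, b, weight=float(np.hypot(a[0] - b[0], a[1] - b[1])))
        if g.number_of_nodes() > 1:
            if not nx.is_connected(g):
                raise ValueError("neurite tree must be connected")
            if g.number_of_edges() != g.number_of_nodes() - 1:
                raise ValueError("neurite tree must be acyclic")
        if self.soma_anchor not in g:
            raise ValueError("soma_anchor must be a node of the tree")
        self.graph = g

    @property
    def leaves(self) -> list[tuple[float, float]]:
        if self.graph.number_of_nodes() == 1:
            return [self.soma_anchor]
        return [n for n in self.graph if self.graph.degree(n) == 1 and n != self.soma_anchor]


# --------------------------------------------------------------------------
# Enhancement
# --------------------------------------------------------------------------


def enhance_neurites(image: Micrograph, params: FilterParams = FilterParams()) -> np.ndarray:
    """Gaussian -> Laplacian -> median -> binarize; returns a boolean edge map.

    The Laplacian responds on both flanks of a thin bright ridge, so after
    taking the absolute response the whole neurite band is marked; the
    median filter consolidates it and suppresses salt noise.  A constant
    image yields an all-false map (there is nothing to enhance).
    """
    pix = image.as_float()
    smoothed = ndimage.gaussian_filter(pix, sigma=params.gaussian_sigma_px)
    kernel = _LAPLACE_4 if params.laplace_neighborhood == "4-connected" else _LAPLACE_8
    highpass = ndimage.convolve(smoothed, kernel, mode="nearest")
    response = np.abs(ndimage.median_filter(highpass, size=params.median_window_px))
    if params.edge_threshold == "otsu":
        if np.ptp(response) == 0:
            return np.zeros_like(response, dtype=bool)
        thr = threshold_otsu(response)
    else:
        thr = float(params.edge_threshold)
    return response > thr


def overlay_edges(image: Micrograph, edges: np.ndarray) -> np.ndarray:
    """Superimpose the edge map in blue on the grayscale original (8-bit RGB)."""
    if edges.shape != image.shape:
        raise ValueError(f"edge map shape {edges.shape} != image shape {image.shape}")
    gray8 = np.clip(np.rint(image.as_float() / image.max_value * 255), 0, 255).astype(np.uint8)
    rgb = np.stack([gray8, gray8, gray8], axis=-1)
    rgb[edges] = (0, 0, 255)
    return rgb


# --------------------------------------------------------------------------
# Lengths
# --------------------------------------------------------------------------


def polyline_length_px(p: Polyline) -> float:
    """Chained Euclidean length of a polyline; 0 for a single vertex."""
    arr = p.as_array()
    if len(arr) < 2:
        return 0.0
    return float(np.hypot(*np.diff(arr, axis=0).T).sum())


def longest_path_length_px(t: NeuriteTree) -> float:
    """Maximum cumulative edge weight from the soma anchor to any leaf.

    This is the branch-selection rule: when a neurite has several branches
    the longest root-to-tip path is the neurite's length.
    """
    if t.graph.number_of_nodes() == 0:
        raise ValueError("empty tree")
    dist = nx.single_source_dijkstra_path_length(t.graph, t.soma_anchor, weight="weight")
    return float(max(dist.values()))


def calibrate_length(length_px: float, cal: ScaleCalibration | None) -> float:
    """Convert a pixel length to micrometres via the scale-bar calibration."""
    if cal is None:
        raise ValueError("missing spatial calibration (um_per_px)")
    if length_px < 0:
        raise ValueError("length_px must be >= 0")
    return length_px * cal.um_per_px


# --------------------------------------------------------------------------
# Automated tracing
# --------------------------------------------------------------------------

_STEP = {(-1, 0): 1.0, (1, 0): 1.0, (0, -1): 1.0, (0, 1): 1.0,
         (-1, -1): np.sqrt(2), (-1, 1): np.sqrt(2), (1, -1): np.sqrt(2), (1, 1): np.sqrt(2)}


def trace_neurites(
    edges: np.ndarray,
    soma_mask: np.ndarray,
    min_length_px: float = 10.0,
    simplify_tol_px: float = 2.0,
    soma_clear_px: int = 5,
    intensity: np.ndarray | None = None,
) -> list[NeuriteTree]:
    """Assemble soma-anchored neurite trees from an enhanced edge map.

    Steps: mask out the (slightly dilated) somata, skeletonize the
    remaining edge map, build an 8-connected pixel graph with unit/sqrt(2)
    step weights, and for every skeleton component attached to a soma grow
    a shortest-path tree from its attachment pixel.  Unary pixel runs are
    simplified (Douglas-Peucker) back to polylines so lengths are chained
    Euclidean distances rather than pixel-step counts, and the small gap
    between the attachment pixel and the soma boundary is restored as an
    initial edge.  Components not touching any soma, and trees whose
    longest path falls below ``min_length_px``, are discarded.

    When the original intensity raster is supplied, skeleton tips are
    refined against it: the edge response extends past the geometric tip by
    roughly the filter support, so leaf pixels whose underlying intensity
    falls below the image's foreground cut (Otsu) are walked back — the
    same judgement an operator applies when ending a trace.
    """
    if edges.shape != soma_mask.shape:
        raise ValueError("edge map and soma mask shapes differ")
    if not soma_mask.any():
        raise ValueError("no soma component in soma_mask; cannot anchor neurites")

    # the soma's own edge response forms a ring just outside the mask; clear
    # it so it cannot fuse distinct neurites into one skeleton component
    soma_zone = ndimage.binary_dilation(soma_mask, structure=disk(soma_clear_px))
    # the |Laplacian| of a ridge marks its centre and both flanks; close the
    # map so the band is solid and its skeleton is the centreline
    band = ndimage.binary_closing(edges, structure=disk(2)) & ~soma_zone
    skel = skeletonize(band)
    if not skel.any():
        return []

    # distance to the nearest soma pixel, and which pixel that is
    dist_to_soma, (ir, ic) = ndimage.distance_transform_edt(~soma_mask, return_indices=True)
    band_labels = cc_label(band, connectivity=2)

    foreground = None
    if intensity is not None:
        if intensity.shape != edges.shape:
            raise ValueError("intensity raster shape differs from edge map")
        inten = np.asarray(intensity, dtype=float)
        if np.ptp(inten) > 0:
            foreground = inten > threshold_otsu(inten)
            fg_halfwidth = ndimage.distance_transform_edt(foreground)

    labels = cc_label(skel, connectivity=2)
    trees: list[NeuriteTree] = []
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        coords = np.argwhere(comp)
        pix = {tuple(p) for p in map(tuple, coords)}
        # attachment is judged on the enclosing band component: the skeleton
        # retracts from the cut end of a wide band, the band itself does not
        owner = band_labels == band_labels[tuple(coords[0])]
        if dist_to_soma[owner].min() > soma_clear_px + 3.0:
            continue  # not attached to any soma
        d = dist_to_soma[comp]
        anchor = tuple(coords[int(np.argmin(d))])

        g = nx.Graph()
        for r, c in pix:
            g.add_node((r, c))
            for (dr, dc), wgt in _STEP.items():
                nb = (r + dr, c + dc)
                if nb in pix:
                    g.add_edge((r, c), nb, weight=wgt)
        preds, _ = nx.dijkstra_predecessor_and_distance(g, anchor, weight="weight")

        # skeleton pixels hugging the soma cut often form a short hook; trim
        # them and bridge straight from the soma boundary instead
        proximal = dist_to_soma < soma_clear_px + 4.0
        tree_edges, starts = _simplified_tree_edges(
            preds, anchor, simplify_tol_px, foreground,
            fg_halfwidth if foreground is not None else None,
            proximal_trim=proximal)
        root = (float(ir[anchor]), float(ic[anchor]))  # nearest soma pixel
        for start in starts:
            if root != start:
                tree_edges.append((root, start))
        if not tree_edges:
            continue
        tree = NeuriteTree(soma_anchor=root, edges=tree_edges)
        if longest_path_length_px(tree) >= min_length_px:
            trees.append(tree)
    return trees


def _simplified_tree_edges(
    preds: dict,
    anchor: tuple[int, int],
    tol: float,
    foreground: np.ndarray | None = None,
    fg_halfwidth: np.ndarray | None = None,
    proximal_trim: np.ndarray | None = None,
) -> tuple[list[tuple[tuple[float, float], tuple[float, float]]], list[tuple[float, float]]]:
    """Decompose a shortest-path predecessor tree into unary pixel runs and
    Douglas-Peucker-simplify each run; shared prefixes stay identical because
    runs are split at branch nodes.  Leaf runs are walked back while their
    pixels fall outside the foreground mask (tip refinement); runs leaving
    the anchor drop leading pixels flagged by ``proximal_trim``.  Returns the
    edge list plus the start node of every anchor run (for soma bridging)."""
    # ties in the pixel grid yield several equal-cost predecessors; keep one
    # so the traversal stays a tree
    children: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for node, ps in preds.items():
        if ps:
            children.setdefault(ps[0], []).append(node)

    edges: list[tuple[tuple[float, float], tuple[float, float]]] = []
    starts: list[tuple[float, float]] = []
    if not children.get(anchor):
        return edges, [(float(anchor[0]), float(anchor[1]))]
    stack = [anchor]
    while stack:
        key = stack.pop()
        for child in children.get(key, []):
            run = [key, child]
            while len(children.get(run[-1], [])) == 1:
                run.append(children[run[-1]][0])
            nxt = run[-1]  # branch node or endpoint: becomes a key node
            is_leaf = not children.get(nxt)
            if key == anchor and proximal_trim is not None:
                while len(run) > 2 and proximal_trim[run[0]]:
                    run.pop(0)
            if is_leaf and foreground is not None:
                while len(run) > 2 and not foreground[run[-1]]:
                    run.pop()
            simp = approximate_polygon(np.asarray(run, dtype=float), tolerance=tol)
            if is_leaf and foreground is not None and len(simp) >= 2:
                # thinning retracts from blunt band ends: push the tip out
                # along its final heading while the image stays foreground
                simp = _extend_tip(simp, foreground, fg_halfwidth)
            if key == anchor:
                starts.append(tuple(simp[0]))
            for a, b in zip(simp[:-1], simp[1:]):
                edges.append((tuple(a), tuple(b)))
            if not is_leaf:
                stack.append(nxt)
    return edges, starts


def _extend_tip(
    simp: np.ndarray,
    foreground: np.ndarray,
    fg_halfwidth: np.ndarray | None = None,
    max_steps: int = 50,
) -> np.ndarray:
    """Walk the last segment's direction from the tip while the underlying
    pixel is foreground, then retract by the stroke's local half-width (the
    raster cap extends that far past the geometric endpoint)."""
    tip, prev = simp[-1], simp[-2]
    d = tip - prev
    norm = np.hypot(*d)
    if norm == 0:
        return simp
    d = d / norm
    h, w = foreground.shape
    pos = tip.astype(float)
    steps = 0.0
    while steps < max_steps:
        cand = pos + d
        r, c = int(round(cand[0])), int(round(cand[1]))
        if not (0 <= r < h and 0 <= c < w) or not foreground[r, c]:
            break
        pos = cand
        steps += 1.0
    if steps > 0:
        if fg_halfwidth is not None:
            r, c = int(round(pos[0])), int(round(pos[1]))
            back = min(float(fg_halfwidth[r, c]), steps)
            pos = pos - back * d
        simp = simp.copy()
        simp[-1] = pos
    return simp


def detect_somata(image: Micrograph, min_area_px: int = 60) -> np.ndarray:
    """Segment bright cell bodies: Otsu threshold, morphological opening,
    removal of thin/small components.  A convenience for automated tracing
    when no operator-drawn soma mask is available."""
    pix = image.as_float()
    if np.ptp(pix) == 0:
        return np.zeros(image.shape, dtype=bool)
    mask = pix > threshold_otsu(pix)
    mask = ndimage.binary_opening(mask, structure=disk(2))
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_area_px) + 1
    return np.isin(labels, keep)


# --------------------------------------------------------------------------
# Picture-level measurement
# --------------------------------------------------------------------------


@dataclass
class PictureMeasurements:
    """Calibrated neurite lengths measured in one picture."""

    lengths_um: list[float]
    picture_id: str
    n: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.lengths_um) < 1:
            raise ValueError("a picture must carry at least one measurement")
        if not all(np.isfinite(v) and v >= 0 for v in self.lengths_um):
            raise ValueError("lengths must be finite and >= 0")
        self.n = len(self.lengths_um)


def measure_picture(
    items: Sequence[Polyline | NeuriteTree],
    cal: ScaleCalibration,
    picture_id: str = "",
) -> PictureMeasurements:
    """Measure every annotated polyline / traced tree in a picture.

    Polylines are measured by chained Euclidean distance; trees by the
    longest root-to-tip path.  Pixel lengths are calibrated to micrometres.
    """
    if len(items) == 0:
        raise ValueError(f"picture {picture_id!r}: no measurements supplied")
    lengths = []
    for item in items:
        if isinstance(item, Polyline):
            lpx = polyline_length_px(item)
        elif isinstance(item, NeuriteTree):
            lpx = longest_path_length_px(item)
        else:
            raise TypeError(f"cannot measure object of type {type(item)}")
        lengths.append(calibrate_length(lpx, cal))
    return PictureMeasurements(lengths_um=lengths, picture_id=picture_id)


# --------------------------------------------------------------------------
# Annotation I/O
# --------------------------------------------------------------------------


def load_annotations(path: str | Path) -> tuple[str, ScaleCalibration, list[Polyline]]:
    """Read an annotation file: ``{"picture_id", "um_per_px", "polylines"}``
    with polylines as arrays of [row, col] pairs."""
    with open(path) as fh:
        obj = json.load(fh)
    cal = ScaleCalibration(float(obj["um_per_px"]))
    polys = [Polyline.from_array(p) for p in obj["polylines"]]
    return str(obj.get("picture_id", Path(path).stem)), cal, polys
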