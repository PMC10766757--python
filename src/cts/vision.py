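"""Visual extraction of candidate action-options from the uncovered silhouette.

The uncovered region is rasterized to a binary mask, its morphological
boundary (dilation minus erosion) is taken as the edge image, and one edge
template per (tan kind, rotation in 45-degree steps, mirror flag) is slid
over it scoring window positions by the sum of squared differences (SSD).
Up to five local-minimum positions per template survive non-maximum
suppression; each is snapped to the nearest grid anchor, screened for
geometric legality and (optionally) for having support in the
phase-conditioned training frequencies, and becomes an
:class:`~cts.cognition.ActionOption` carrying a similarity in [0, 1].

Because both the scene and the templates are binarized with the same pixel
sampling and the same boundary operator, an uncovered hole exactly congruent
to a tan produces a zero-SSD match at that hole.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion
from scipy.signal import fftconvolve
from shapely import contains_xy
from shapely.geometry import Polygon

from .cognition import ActionOption
from .exact import to_floats
from .geometry import KINDS, ROTATIONS, Placement, PuzzleState, pose_vertices

DEFAULT_RESOLUTION = 16  # pixels per geometry unit
MAX_CANDIDATES = 5  # candidate placements kept per template


class InvalidScoreError(ValueError):
    """Raised for a negative SSD score."""


@dataclass
class EdgeImage:
    """Binary edge raster of the uncovered region.

    ``pixels[r, c]`` samples the geometry point
    ``origin + ((c + 0.5)/resolution, (r + 0.5)/resolution)`` (y up).
    """

    pixels: np.ndarray
    resolution: int
    origin: Tuple[float, float]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclass
class Template:
    kind: str
    rotation: int
    mirror: bool
    pixels: np.ndarray  # binary edge raster of the tan's bounding box


@dataclass
class Candidate:
    kind: str
    rotation: int
    mirror: bool
    pixel_location: Tuple[int, int]  # (row, col) of the window's lower-left
    location: Tuple[float, float]  # geometry coords of the window's lower-left
    grid_loc: int  # nearest grid anchor
    ssd: int
    similarity: float


TemplateBank = Dict[Tuple[str, int, bool], Template]


# ---------------------------------------------------------------------------
# Rasterization


def _raster_mask(poly: Polygon, origin: Tuple[float, float], shape: Tuple[int, int],
                 resolution: int) -> np.ndarray:
    h, w = shape
    xs = origin[0] + (np.arange(w) + 0.5) / resolution
    ys = origin[1] + (np.arange(h) + 0.5) / resolution
    xx, yy = np.meshgrid(xs, ys)
    if poly.is_empty:
        return np.zeros(shape, dtype=bool)
    return contains_xy(poly, xx, yy)


def _boundary(mask: np.ndarray) -> np.ndarray:
    if not mask.any():
        return np.zeros_like(mask)
    return binary_dilation(mask) & ~binary_erosion(mask, border_value=0)


def rasterize_uncovered(state: PuzzleState, resolution: int = DEFAULT_RESOLUTION) -> EdgeImage:
    """Binary edge raster of the boundary of the uncovered region (outer
    silhouette edges plus exposed edges of placed pieces)."""
    if resolution < 8:
        raise ValueError("resolution must be >= 8 px/unit")
    xmin, ymin, xmax, ymax = (float(v) for v in state.silhouette.exact_bbox)
    margin = 2  # px
    origin = (xmin - margin / resolution, ymin - margin / resolution)
    w = int(math.ceil((xmax - xmin) * resolution)) + 2 * margin + 1
    h = int(math.ceil((ymax - ymin) * resolution)) + 2 * margin + 1
    mask = _raster_mask(state.uncovered, origin, (h, w), resolution)
    return EdgeImage(_boundary(mask), resolution, origin)


def build_templates(resolution: int = DEFAULT_RESOLUTION,
                    mirror_allowed: bool = True) -> TemplateBank:
    """One edge template per (kind, rotation[, mirror]); deterministic.

    Symmetric duplicates (e.g. the square at rotations 0 and 90) are retained,
    not deduplicated.
    """
    bank: TemplateBank = {}
    for kind in KINDS:
        mirrors = (False, True) if (kind == "parallelogram" and mirror_allowed) else (False,)
        for mir in mirrors:
            for rot in ROTATIONS:
                verts = pose_vertices(kind, rot, mir)
                fl = to_floats(verts)
                wgeo = max(p[0] for p in fl)
                hgeo = max(p[1] for p in fl)
                tw = max(1, int(round(wgeo * resolution)))
                th = max(1, int(round(hgeo * resolution)))
                mask = _raster_mask(Polygon(fl), (0.0, 0.0), (th, tw), resolution)
                bank[(kind, rot, mir)] = Template(kind, rot, mir, _boundary(mask))
    return bank


# ---------------------------------------------------------------------------
# Matching


def similarity_from_ssd(ssd: float, ssd_max: float) -> float:
    """Map an SSD score to a similarity s in [0, 1], strictly decreasing in
    ssd on [0, ssd_max]: s = 1 - ssd/ssd_max, clipped."""
    if ssd < 0:
        raise InvalidScoreError(f"negative ssd {ssd}")
    if ssd_max <= 0:
        raise ValueError("ssd_max must be positive")
    return float(np.clip(1.0 - ssd / ssd_max, 0.0, 1.0))


def match_template(edges: EdgeImage, template: Template,
                   grid=None, max_candidates: int = MAX_CANDIDATES) -> List[Candidate]:
    """Up to ``max_candidates`` local-minimum SSD window positions, ascending
    by ssd, after non-maximum suppression within half the template's larger
    dimension.  Ties broken by (row, column) scan order."""
    E = edges.pixels.astype(np.float64)
    T = template.pixels.astype(np.float64)
    th, tw = T.shape
    H, W = E.shape
    if th > H or tw > W:
        return []
    sum_t = T.sum()
    corr = fftconvolve(E, T[::-1, ::-1], mode="valid")
    winsum = fftconvolve(E, np.ones((th, tw)), mode="valid")
    ssd = np.rint(sum_t + winsum - 2.0 * corr).astype(np.int64)
    np.maximum(ssd, 0, out=ssd)
    ssd_max = float(sum_t + np.rint(winsum.max()))
    if ssd_max <= 0:
        return []

    rows, cols = np.unravel_index(np.arange(ssd.size), ssd.shape)
    order = np.lexsort((cols, rows, ssd.ravel()))
    radius = max(th, tw) / 2.0
    kept: List[Tuple[int, int]] = []
    out: List[Candidate] = []
    for k in order:
        r, c = int(rows[k]), int(cols[k])
        if any((r - kr) ** 2 + (c - kc) ** 2 < radius ** 2 for kr, kc in kept):
            continue
        kept.append((r, c))
        loc = (edges.origin[0] + c / edges.resolution,
               edges.origin[1] + r / edges.resolution)
        gi = grid.nearest(*loc) if grid is not None else -1
        s = similarity_from_ssd(int(ssd[r, c]), ssd_max)
        out.append(Candidate(template.kind, template.rotation, template.mirror,
                             (r, c), loc, gi, int(ssd[r, c]), s))
        if len(out) >= max_candidates:
            break
    return out


# ---------------------------------------------------------------------------
# Filtering


def filter_candidates(cands: List[Candidate], state: PuzzleState, freqs,
                      phase: int, frequency_screen: bool = True) -> List[ActionOption]:
    """Plausibility screen: candidates snapping to the same placement are
    merged (keeping the lower ssd); survivors must be geometrically legal
    (no intersection with placed pieces, inside the target) and — when the
    frequency screen is on — have support in the training data at the
    current phase."""
    merged: Dict[Tuple[str, int, int, bool], Candidate] = {}
    for cand in cands:
        try:
            pl = Placement(cand.kind, cand.grid_loc, cand.rotation, cand.mirror)
        except ValueError:
            continue
        prev = merged.get(pl.key)
        if prev is None or cand.ssd < prev.ssd:
            merged[pl.key] = cand

    options: List[ActionOption] = []
    for key in sorted(merged, key=lambda k: (merged[k].ssd,) + _orderable(k)):
        cand = merged[key]
        pl = Placement(*key)
        if not state.is_legal(pl):
            continue
        f = float(freqs.get(pl.kind, pl.grid_loc, pl.rotation, phase)) if freqs is not None else 0.0
        if frequency_screen and f <= 0.0:
            continue
        options.append(ActionOption(pl.kind, pl.grid_loc, pl.rotation, pl.mirror,
                                    s_i=cand.similarity, f=f, phase=phase))
    return options


def _orderable(key) -> Tuple:
    kind, loc, rot, mir = key
    return (KINDS.index(kind), loc, rot, mir)


def extract_action_options(state: PuzzleState, bank: TemplateBank, freqs,
                           phase: int, resolution: int = DEFAULT_RESOLUTION,
                           frequency_screen: bool = True,
                           max_candidates: int = MAX_CANDIDATES) -> List[ActionOption]:
    """Full visual pipeline for one state: rasterize, match every template,
    filter.  Returns scored-for-similarity (not yet strength-ranked) options."""
    edges = rasterize_uncovered(state, resolution)
    grid = state.silhouette.grid
    free = set(state.free_kinds())
    cands: List[Candidate] = []
    for (kind, _rot, _mir), tpl in bank.items():
        if kind not in free:
            continue
        cands.extend(match_template(edges, tpl, grid=grid, max_candidates=max_candidates))
    return filter_candidates(cands, state, freqs, phase, frequency_screen)
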