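"""Vessel mapping: enhancement, binarization, skeleton, segments, diameter.

A multiscale Hessian ridge filter (Frangi-style, tuned for dark vessels
on a bright scleral background) produces a vesselness response that is
hysteresis-thresholded into a binary map.  The map is thinned to a
one-pixel skeleton, branch and end points are detected from skeleton
connectivity, and each node-to-node path becomes a
:class:`VesselSegment`.  The local vessel radius along a centreline is
read off the Euclidean distance transform (EDT) of the binary map: at a
centreline pixel the EDT equals the distance to the nearest wall, i.e.
the local radius.  The segment diameter is twice the mean centreline
EDT, converted to micrometres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.filters import apply_hysteresis_threshold
from skimage.measure import label
from skimage.morphology import skeletonize

from .video_io import CalibrationProfile

__all__ = [
    "VesselMask",
    "VesselSegment",
    "vesselness_filter",
    "binarize",
    "refine_mask_half_depth",
    "skeletonize_mask",
    "prune_spurs",
    "detect_nodes",
    "split_segments",
]

log = logging.getLogger(__name__)

DEFAULT_SCALES = (1.5, 3.0, 6.0, 9.0, 12.0)

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def _drop_small_components(binary: np.ndarray, min_size: int) -> np.ndarray:
    """Remove 8-connected components smaller than ``min_size`` pixels."""
    lab, n = label(binary, connectivity=2, return_num=True)
    if n == 0:
        return binary
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[lab]


@dataclass
class VesselMask:
    """Binary vessel map plus the vesselness response it came from."""

    binary: np.ndarray
    vesselness: np.ndarray

    def __post_init__(self) -> None:
        self.binary = np.asarray(self.binary, dtype=bool)
        self.vesselness = np.asarray(self.vesselness, dtype=np.float64)
        if self.binary.shape != self.vesselness.shape:
            raise ValueError("binary and vesselness shapes differ")


@dataclass
class VesselSegment:
    """A centreline polyline between two nodes with per-point radii.

    ``points`` are (row, col) pixel coordinates, consecutive points
    8-connected; ``radii_px`` are centreline EDT values (pixels, junction
    neighbourhoods excluded); ``diameter_um`` = 2 x mean(radii) x
    pixel scale.
    """

    segment_id: str
    points: np.ndarray
    radii_px: np.ndarray
    diameter_um: float
    length_um: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points)
        if len(self.points) < 2:
            raise ValueError("a segment needs at least 2 centreline points")
        if not self.diameter_um > 0:
            raise ValueError("diameter must be positive")


def vesselness_filter(frame: np.ndarray, scales: Sequence[float] = DEFAULT_SCALES) -> np.ndarray:
    """Multiscale Hessian tubularity response for dark ridges, in [0, 1].

    Per pixel, the maximum over ``scales`` (Gaussian sigmas in pixels) of
    a Frangi vesselness measure oriented for dark-on-bright tubes. The
    default scales cover vessel diameters of roughly 5-45 μm at typical
    slit-lamp calibrations.
    """
    scales = list(scales)
    if not scales or any(s <= 0 for s in scales):
        raise ValueError("scales must be a non-empty list of positive sigmas")
    frame = np.asarray(frame, dtype=np.float64)
    if np.ptp(frame) == 0:
        return np.zeros_like(frame)
    # scale-normalized (sigma^2) Hessian eigenvalues make responses of
    # equal-contrast vessels comparable across widths, so one global
    # structureness cutoff both balances thin against wide vessels and
    # suppresses low-contrast background texture
    eigs = []
    for s in scales:
        h = hessian_matrix(
            frame, sigma=s, mode="reflect", order="rc", use_gaussian_derivatives=True
        )
        ev = hessian_matrix_eigvals(h) * s**2
        eigs.append(ev)
    s_norm = [np.sqrt((ev**2).sum(axis=0)) for ev in eigs]
    gamma = 0.5 * max(sn.max() for sn in s_norm)
    if gamma <= 0:
        return np.zeros_like(frame)
    beta = 0.5
    resp = np.zeros_like(frame)
    for ev, sn in zip(eigs, s_norm):
        # order by |lambda|: lam2 is the cross-ridge curvature
        swap = np.abs(ev[0]) > np.abs(ev[1])
        lam1 = np.where(swap, ev[1], ev[0])
        lam2 = np.where(swap, ev[0], ev[1])
        with np.errstate(divide="ignore", invalid="ignore"):
            rb2 = (lam1 / lam2) ** 2
        rb2 = np.nan_to_num(rb2, nan=0.0, posinf=0.0)
        v = np.exp(-rb2 / (2 * beta**2)) * (1.0 - np.exp(-(sn**2) / (2 * gamma**2)))
        v[lam2 <= 0] = 0.0  # dark ridges only: positive cross-ridge curvature
        resp = np.maximum(resp, v)
    m = resp.max()
    return resp / m if m > 0 else resp


def binarize(
    response: np.ndarray,
    low: float = 0.05,
    high: float = 0.15,
    min_size: int = 64,
) -> VesselMask:
    """Hysteresis-threshold a vesselness response into a binary map.

    ``low`` and ``high`` are fractions of the response maximum: pixels
    above ``high`` seed regions that grow through pixels above ``low``.
    The permissive low threshold preserves thin vessels; connected
    components smaller than ``min_size`` pixels are removed as noise.
    """
    response = np.asarray(response, dtype=np.float64)
    m = response.max()
    if m <= 0:
        return VesselMask(np.zeros(response.shape, bool), response)
    binary = apply_hysteresis_threshold(response, low * m, high * m).astype(bool)
    binary = _drop_small_components(binary, min_size)
    return VesselMask(binary, response)


def refine_mask_half_depth(
    frame: np.ndarray,
    mask: VesselMask,
    background: Optional[np.ndarray] = None,
    dilation_px: int = 6,
    min_depth: float = 0.1,
    closing_px: int = 31,
) -> VesselMask:
    """Refine a vessel mask to the half-contrast-depth support.

    Blurred vessel cross-sections have soft edges, so the support of a
    threshold on the *response* depends on the filter scales. This
    refinement re-draws the mask at the full width at half maximum of the
    intensity deficit: with ``depth = background - frame``, a pixel is
    vessel if its depth exceeds half the depth of the nearest centreline
    pixel. For approximately Gaussian profiles this makes the binary
    width equal the profile FWHM, a scale-free convention.

    ``background`` defaults to a grey-closing of the frame with a
    ``closing_px`` structuring element, which must be larger than the
    widest vessel for the closing to bridge it.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if not mask.binary.any():
        return mask
    if background is None:
        background = ndimage.grey_closing(frame, size=(closing_px, closing_px))
    depth = np.clip(background - frame, 0.0, None)

    skel = skeletonize(mask.binary)
    if not skel.any():
        return mask
    # reference depth: the strongest centreline depth within a window
    # sized to the widest vessel present. Anchoring on the single
    # nearest skeleton pixel instead would underestimate the peak where
    # the skeleton shortcuts a high-curvature bend, inflating the mask.
    max_radius = float(ndimage.distance_transform_edt(mask.binary).max())
    win = 2 * int(np.ceil(max_radius)) + 3
    ridge_depth = ndimage.maximum_filter(np.where(skel, depth, 0.0), size=win)
    search = ndimage.binary_dilation(mask.binary, iterations=dilation_px)
    refined = search & (depth >= 0.5 * ridge_depth) & (ridge_depth >= min_depth)
    refined = _drop_small_components(refined, 16)
    return VesselMask(refined, mask.vesselness)


def skeletonize_mask(mask: VesselMask) -> np.ndarray:
    """Topology-preserving thinning to a 1-px-wide 8-connected skeleton."""
    return skeletonize(mask.binary)


def prune_spurs(skeleton: np.ndarray, min_branch_px: int = 12, iterations: int = 3) -> np.ndarray:
    """Remove short terminal side-branches from a skeleton.

    Boundary roughness of a wide vessel produces small spurs that would
    otherwise fragment one vessel into many short segments at spurious
    junctions. A terminal branch (one end free, the other at a junction)
    shorter than ``min_branch_px`` is deleted; repeated up to
    ``iterations`` times since removing a spur can expose another.
    """
    sk = np.asarray(skeleton, dtype=bool).copy()
    for _ in range(iterations):
        clusters, _ = detect_nodes(sk)
        if not clusters:
            break
        branch_px = set()
        for c in clusters:
            branch_px.update(map(tuple, c))
        body = sk.copy()
        for r, c in branch_px:
            body[r, c] = False
        lab, n = label(body, connectivity=2, return_num=True)
        counts = _neighbor_counts(sk)
        removed = False
        for i in range(1, n + 1):
            px = np.argwhere(lab == i)
            if len(px) >= min_branch_px:
                continue
            has_free_end = np.any(counts[px[:, 0], px[:, 1]] == 1) or len(px) == 1
            if has_free_end:
                sk[px[:, 0], px[:, 1]] = False
                removed = True
        if not removed:
            break
    return _remove_redundant_branch_pixels(sk)


def _remove_redundant_branch_pixels(sk: np.ndarray) -> np.ndarray:
    """Delete branch pixels whose neighbours remain mutually connected.

    Pruning a spur can leave its attachment pixel behind as a redundant
    corner: a pixel of degree >= 3 whose neighbours already form one
    8-connected chain without it. Removing such simple points restores a
    clean 1-px path through the former junction.
    """
    sk = sk.copy()
    changed = True
    while changed:
        changed = False
        counts = _neighbor_counts(sk)
        for r, c in np.argwhere(sk & (counts >= 3)):
            nbrs = [
                (r + dr, c + dc)
                for dr, dc in _OFFSETS
                if 0 <= r + dr < sk.shape[0] and 0 <= c + dc < sk.shape[1] and sk[r + dr, c + dc]
            ]
            # connectivity of the neighbour set without the centre pixel
            comp = {nbrs[0]}
            frontier = [nbrs[0]]
            rest = set(nbrs[1:])
            while frontier:
                p = frontier.pop()
                for q in list(rest):
                    if max(abs(p[0] - q[0]), abs(p[1] - q[1])) == 1:
                        rest.discard(q)
                        comp.add(q)
                        frontier.append(q)
            if not rest:
                sk[r, c] = False
                changed = True
    return sk


def _neighbor_counts(skeleton: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skeleton.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant")


def detect_nodes(skeleton: np.ndarray) -> Tuple[List[np.ndarray], List[Tuple[int, int]]]:
    """Branch clusters and end points of a 1-px skeleton.

    End points have exactly one 8-connected skeleton neighbour. Branch
    pixels have three or more; touching branch pixels are merged into one
    cluster (returned as an array of member pixels) so a junction is
    counted once.

    Returns
    -------
    (branch_clusters, end_points)
        ``branch_clusters``: list of (k, 2) arrays of (row, col) pixels;
        ``end_points``: list of (row, col) tuples.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    counts = _neighbor_counts(skeleton)
    ends = np.argwhere(skeleton & (counts == 1))
    branch_px = skeleton & (counts >= 3)
    lab, n = label(branch_px, connectivity=2, return_num=True)
    clusters = [np.argwhere(lab == i) for i in range(1, n + 1)]
    # deterministic order: by lowest row-major index of the cluster
    clusters.sort(key=lambda c: (c[:, 0].min(), c[c[:, 0] == c[:, 0].min(), 1].min()))
    return clusters, [tuple(e) for e in ends]


_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _trace_path(pixels: set) -> List[Tuple[int, int]]:
    """Order a connected set of 1-px-wide skeleton pixels into a path.

    Starts from a tip (single-neighbour pixel) when one exists, else from
    the lowest row-major pixel (loops).
    """
    neigh: Dict[Tuple[int, int], List[Tuple[int, int]]] = {}
    for p in pixels:
        neigh[p] = [q for dr, dc in _OFFSETS if (q := (p[0] + dr, p[1] + dc)) in pixels]
    tips = sorted(p for p, ns in neigh.items() if len(ns) <= 1)
    start = tips[0] if tips else min(pixels)
    path = [start]
    seen = {start}
    cur = start
    while True:
        nxt = [q for q in neigh[cur] if q not in seen]
        if not nxt:
            break
        # prefer 4-connected continuation for smoother paths
        nxt.sort(key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1]), q))
        cur = nxt[0]
        path.append(cur)
        seen.add(cur)
    return path


def _polyline_length(points: np.ndarray) -> float:
    d = np.diff(points.astype(float), axis=0)
    return float(np.sqrt((d**2).sum(axis=1)).sum())


def split_segments(
    skeleton: np.ndarray,
    nodes: Tuple[List[np.ndarray], List[Tuple[int, int]]],
    mask: VesselMask,
    calibration: CalibrationProfile,
    min_length_px: int = 15,
    branch_exclusion_px: int = 2,
) -> List[VesselSegment]:
    """Decompose a skeleton into node-to-node vessel segments.

    Branch-cluster pixels are removed; each remaining connected skeleton
    run becomes one segment, extended by the adjacent branch pixel at
    each junction end so segment endpoints coincide with detected nodes.
    Per-point radii are the EDT of the binary mask at centreline pixels;
    points within ``branch_exclusion_px`` of a branch pixel are excluded
    from the radius average because the EDT inflates at junctions, and
    points whose inscribed disc does not fit inside the frame (distance
    to the image border not exceeding the local EDT) are excluded
    because the radius is truncated where a vessel leaves the field of
    view.
    Segments shorter than ``min_length_px`` skeleton pixels are discarded
    (count logged).
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    if not skeleton.any():
        return []
    branch_clusters, _ = nodes
    branch_px = set()
    for c in branch_clusters:
        branch_px.update(map(tuple, c))

    edt = ndimage.distance_transform_edt(mask.binary)

    body = skeleton.copy()
    for r, c in branch_px:
        body[r, c] = False
    lab, n = label(body, connectivity=2, return_num=True)

    # distance to nearest branch pixel, for junction exclusion
    if branch_px:
        bmap = np.zeros_like(skeleton, dtype=bool)
        for r, c in branch_px:
            bmap[r, c] = True
        dist_to_branch = ndimage.distance_transform_edt(~bmap)
    else:
        dist_to_branch = np.full(skeleton.shape, np.inf)

    segments: List[VesselSegment] = []
    n_discarded = 0
    order = sorted(range(1, n + 1), key=lambda i: tuple(np.argwhere(lab == i).min(axis=0)))
    for seg_no, i in enumerate(order):
        px = set(map(tuple, np.argwhere(lab == i)))
        path = _trace_path(px)
        if len(path) < min_length_px:
            n_discarded += 1
            continue
        # re-attach the adjacent branch pixel at each open end
        for end_idx in (0, -1):
            r, c = path[0] if end_idx == 0 else path[-1]
            adj = sorted(
                (r + dr, c + dc) for dr, dc in _OFFSETS if (r + dr, c + dc) in branch_px
            )
            if adj:
                # tie-break: lowest row-major adjacent branch pixel
                path.insert(0, adj[0]) if end_idx == 0 else path.append(adj[0])
        pts = np.array(path)
        radii_all = edt[pts[:, 0], pts[:, 1]]
        H, W = skeleton.shape
        border = np.minimum.reduce(
            [pts[:, 0], pts[:, 1], H - 1 - pts[:, 0], W - 1 - pts[:, 1]]
        ).astype(float)
        keep = (dist_to_branch[pts[:, 0], pts[:, 1]] > branch_exclusion_px) & (
            border > radii_all
        )
        radii = radii_all[keep] if keep.any() else radii_all
        diameter_um = 2.0 * float(radii.mean()) * calibration.pixel_scale_um
        length_um = _polyline_length(pts) * calibration.pixel_scale_um
        segments.append(
            VesselSegment(
                segment_id=f"seg{seg_no:04d}",
                points=pts,
                radii_px=np.asarray(radii, dtype=float),
                diameter_um=diameter_um,
                length_um=length_um,
            )
        )
    if n_discarded:
        log.info("discarded %d segments shorter than %d px", n_discarded, min_length_px)
    return segments
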