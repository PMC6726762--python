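"""Nucleosome candidate detection, filament matching, arm splitting and
opening-angle measurement.

Nucleosomes appear as bright disks riding on filamentous DNA.  Candidates
are found with a circular Hough transform over edge pixels; the
``sensitivity`` parameter in (0, 1) maps to an accumulator threshold so
that *raising* sensitivity only ever adds candidates.  A candidate is
matched to a filament when its center lies within radius + max_gap of the
filament's pixels, and a filament carrying two or more candidates is
discarded entirely (multi-nucleosome arrays are out of scope, and an
ambiguous match would poison the arm statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.ndimage as ndi
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .afm_io import AFMImage
from .segment import LabeledObjects
from .trace import SkeletonGraph, end_shortening_correction, kulpa_length

#: Fraction of a complete circle's votes a peak must collect at
#: sensitivity s: threshold = _SENS_SCALE * (1 - s).  At the default
#: s = 0.93 a candidate needs ~35% of a full rim.
_SENS_SCALE = 5.0


@dataclass
class NucleosomeCandidate:
    center: tuple[int, int]  # (row, col)
    radius_nm: float
    score: float


@dataclass
class NucleosomeObject:
    candidate: NucleosomeCandidate
    filament_label: int
    arm_short_nm: float = np.nan
    arm_long_nm: float = np.nan
    theta_deg: float = np.nan
    entry_points: tuple | None = None
    qc_flags: tuple[str, ...] = field(default_factory=tuple)


def hough_circles(
    img: AFMImage,
    radius_nm: tuple[float, float],
    sensitivity: float,
    canny_sigma: float = 2.0,
    intensity_floor: float = 150.0,
) -> list[NucleosomeCandidate]:
    """Detect circular particles via the circular Hough transform.

    Edges come from a Canny detector on the (ideally denoised) image; the
    Hough accumulator is normalized per radius, so a perfect rim scores
    ~1.  Candidates are returned sorted by descending score, with no two
    centers closer than the minimum search radius.

    Curved filament segments also vote for small circles, so rim support
    alone is not enough; a candidate must additionally be *tall* — its
    median intensity within half a radius of the center must reach
    ``intensity_floor``, set between the filament ridge height (~120) and
    the nucleosome peak (~220) on the 8-bit scale.
    """
    lo_px = radius_nm[0] / img.nm_per_px
    hi_px = radius_nm[1] / img.nm_per_px
    if lo_px < 2:
        raise ValueError(
            f"minimum Hough radius {radius_nm[0]} nm is below 2 px at "
            f"{img.nm_per_px} nm/px"
        )
    radii = np.arange(int(np.floor(lo_px)), int(np.ceil(hi_px)) + 1)
    edges = canny(img.pixels / 255.0, sigma=canny_sigma)
    if not edges.any():
        return []
    accum = hough_circle(edges, radii, normalize=True)
    threshold = _SENS_SCALE * (1.0 - sensitivity)
    min_dist = max(int(np.floor(lo_px)), 1)
    scores, cx, cy, found_r = hough_circle_peaks(
        accum,
        radii,
        min_xdistance=min_dist,
        min_ydistance=min_dist,
        threshold=threshold,
    )
    cands = []
    h, w = img.pixels.shape
    for s, x, y, r in zip(scores, cx, cy, found_r):
        rr = np.arange(max(int(y - r / 2), 0), min(int(y + r / 2) + 1, h))
        cc = np.arange(max(int(x - r / 2), 0), min(int(x + r / 2) + 1, w))
        core = img.pixels[np.ix_(rr, cc)]
        if np.median(core) < intensity_floor:
            continue
        cands.append(
            NucleosomeCandidate((int(y), int(x)), float(r) * img.nm_per_px, float(s))
        )
    # hough_circle_peaks suppresses per x/y independently; enforce a true
    # Euclidean spacing of one minimum radius between surviving centers.
    kept: list[NucleosomeCandidate] = []
    for c in sorted(cands, key=lambda c: -c.score):
        if all(np.hypot(c.center[0] - k.center[0], c.center[1] - k.center[1]) >= min_dist
               for k in kept):
            kept.append(c)
    return kept


def match_candidates(
    cands: list[NucleosomeCandidate],
    objs: LabeledObjects,
    max_gap_px: int = 2,
) -> tuple[list[tuple[NucleosomeCandidate, int]], set[int]]:
    """Uniquely pair candidates with filaments by Euclidean vicinity.

    Returns (pairs, ambiguous_labels).  A candidate matches the filament
    whose pixels come within ``radius_px + max_gap_px`` of its center
    (nearest one if several); filaments attracting two or more candidates
    are excluded wholesale and reported as ambiguous.
    """
    matched: dict[int, list[NucleosomeCandidate]] = {}
    if objs.n_objects and cands:
        # distance from every pixel to the nearest object pixel, and which
        # object that is — one EDT serves all candidates
        dist, (ir, ic) = ndi.distance_transform_edt(
            objs.labels == 0, return_indices=True
        )
        for c in cands:
            r, col = c.center
            d = dist[r, col]
            radius_px = c.radius_nm / objs.nm_per_px
            if d <= radius_px + max_gap_px:
                lab = int(objs.labels[ir[r, col], ic[r, col]])
                if lab > 0:
                    matched.setdefault(lab, []).append(c)
    ambiguous = {lab for lab, cs in matched.items() if len(cs) > 1}
    pairs = [(cs[0], lab) for lab, cs in matched.items() if len(cs) == 1]
    pairs.sort(key=lambda p: p[1])
    return pairs, ambiguous


def split_arms(
    candidate: NucleosomeCandidate,
    skel: SkeletonGraph,
) -> tuple[list[list[tuple[int, int]]], list[tuple[int, int]], tuple[str, ...]]:
    """Cut the skeleton at the nucleosome disk and return the two arms.

    Skeleton pixels strictly inside the candidate circle are removed; the
    two largest remaining components incident to the circle become the
    arms, each ordered from its entry point (the pixel nearest the circle
    boundary) outward along the longest simple path.
    """
    flags: list[str] = []
    cr, cc = candidate.center
    radius_px = candidate.radius_nm / skel.nm_per_px

    def _dist(n):
        return float(np.hypot(n[0] - cr, n[1] - cc))

    outside = [n for n in skel.graph.nodes if _dist(n) >= radius_px]
    sub = skel.graph.subgraph(outside)
    # components incident to the circle: contain a pixel near the rim
    incident = []
    for comp in nx.connected_components(sub):
        rim_dist = min(_dist(n) for n in comp)
        if rim_dist <= radius_px + 2.0:
            incident.append(comp)
    if len(incident) < 2:
        flags.append("single_arm")
        return [], [], tuple(flags)
    incident.sort(key=len, reverse=True)
    if len(incident) > 2:
        flags.append("extra_components")
        incident = incident[:2]
    arms, entries = [], []
    for comp in incident:
        g = sub.subgraph(comp)
        entry = min(comp, key=_dist)
        # order the arm from its entry outward: geodesic to the farthest
        # skeleton pixel (robust to the spurious triangles of 8-adjacency)
        dist_map, paths = nx.single_source_dijkstra(g, entry, weight="weight")
        far = max(dist_map, key=dist_map.get)
        arms.append(paths[far])
        entries.append(entry)
    return arms, entries, tuple(flags)


def measure_arms(
    arms: list[list[tuple[int, int]]],
    mask: np.ndarray,
    nm_per_px: float,
) -> list[float]:
    """Arm contour lengths: Kulpa estimate + erosion correction at the free end."""
    lengths = []
    for arm in arms:
        raw = kulpa_length(arm, nm_per_px)
        if len(arm) > 1:
            raw += end_shortening_correction([arm[-1]], mask, nm_per_px)
        lengths.append(raw)
    return lengths


def opening_angle_vertex(
    arms: list[list[tuple[int, int]]],
    center: tuple[int, int],
    fit_px: int = 5,
) -> tuple[float, tuple[str, ...]]:
    """Opening angle with the vertex at the nucleosome center.

    Measures the angle subtended at the detected core center by the two
    arm windows (the mean position of up to ``2·fit_px`` arm pixels,
    skipping the ``fit_px // 2`` pixels nearest the cut, which sit in the
    tip-broadened merge zone).  This mirrors how the angle is measured
    manually with an angle tool anchored on the core, and is insensitive
    to the medial-axis distortion of the arm roots that biases a pure
    line fit at small opening angles.
    """
    flags: list[str] = []
    c = np.asarray(center, dtype=float)
    dirs = []
    for arm in arms:
        skip = fit_px // 2 if len(arm) > fit_px // 2 + 2 else 0
        pts = np.asarray(arm[skip:skip + 2 * fit_px], dtype=float)
        if len(pts) < 1:
            return np.nan, ("unmeasurable",)
        if len(pts) < fit_px:
            flags.append("short_fit")
        v = pts.mean(axis=0) - c
        norm = np.linalg.norm(v)
        if norm == 0:
            return np.nan, ("unmeasurable",)
        dirs.append(v / norm)
    cosang = float(np.clip(np.dot(dirs[0], dirs[1]), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang))), tuple(flags)


def _fit_direction(points: np.ndarray) -> np.ndarray:
    """Total-least-squares line direction of a point cloud (unit vector)."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def fit_opening_angle(
    arms: list[list[tuple[int, int]]],
    entry_points: list[tuple[int, int]],
    center: tuple[int, int],
    fit_px: int = 5,
    mask: np.ndarray | None = None,
    ridge_half_px: float | None = None,
) -> tuple[float, tuple[str, ...]]:
    """Opening angle between the outward arm directions at the DNA exit.

    A straight line is fitted (total least squares) to the first
    ``fit_px`` pixels of each arm, oriented to point away from the disk
    center; theta is the angle between the two directions, in [0°, 180°].

    Near the disk the object mask bulges (the tip-broadened particle
    merges with the arm roots) and the skeleton there is a medial-axis
    artifact, not DNA direction.  When the object ``mask`` is supplied,
    arm pixels whose distance to background exceeds ``ridge_half_px``
    (i.e. still inside the bulge) are skipped before the fit window.
    When ``ridge_half_px`` is None it is estimated per object as the
    median half-width over the outer halves of both arms, plus one
    pixel of slack.

    The returned flags include ``theta_inverted`` when the two fitted
    directions fall into the same half-plane along the entry-to-entry
    vector, the configuration in which the orientation assignment is
    untrustworthy and 180° − θ is the likelier truth.
    """
    flags: list[str] = []
    dirs = []
    edt = ndi.distance_transform_edt(mask) if mask is not None else None
    if edt is not None and ridge_half_px is None:
        widths = [edt[p] for arm in arms for p in arm[len(arm) // 2:]]
        ridge_half_px = float(np.median(widths)) + 1.0 if widths else np.inf
    for arm, entry in zip(arms, entry_points):
        start = 0
        if edt is not None:
            while start < len(arm) - fit_px and edt[arm[start]] > ridge_half_px:
                start += 1
        pts = np.asarray(arm[start:start + fit_px], dtype=float)
        if len(arm) - start < fit_px:
            flags.append("short_fit")
        if len(pts) < 2:
            return np.nan, tuple(flags) + ("unmeasurable",)
        d = _fit_direction(pts)
        outward = pts.mean(axis=0) - np.asarray(center, dtype=float)
        if np.dot(d, outward) < 0:
            d = -d
        dirs.append(d)
    cosang = float(np.clip(np.dot(dirs[0], dirs[1]), -1.0, 1.0))
    theta = float(np.degrees(np.arccos(cosang)))
    e = np.asarray(entry_points[1], float) - np.asarray(entry_points[0], float)
    if np.linalg.norm(e) > 0:
        s0, s1 = np.dot(dirs[0], e), np.dot(dirs[1], e)
        if s0 * s1 > 0:
            flags.append("theta_inverted")
    return theta, tuple(flags)
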