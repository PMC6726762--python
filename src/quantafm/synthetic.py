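"""Synthetic AFM scene generator with exact ground truth.

Emulates the appearance of surface-deposited DNA and mono-nucleosomes in
flattened AFM topographs:

* filaments — worm-like-chain curves (default persistence 50 nm, the
  canonical dsDNA value) rasterized as Gaussian ridges of ~3 px FWHM,
  the tip-broadened width of 2-nm DNA at ~2 nm/px;
* nucleosomes — Gaussian disks whose *apparent* radius is twice the
  crystallographic 5.5 nm, encoding the tip-convolution artifact; the
  wrapped DNA inside the disk is not rendered (it is unresolvable), so
  the two protruding arms start at the disk rim with a prescribed
  opening angle between their exit directions;
* nuisance structure — Gaussian background noise, per-row scan-line
  stripe offsets, and bright blob contaminations.

Every scene is reproducible bit-exactly from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .afm_io import DEFAULT_NM_PER_PX, AFMImage

RIDGE_PEAK = 120.0
RIDGE_FWHM_PX = 3.0
DISK_PEAK = 220.0
BACKGROUND = 30.0
APPARENT_RADIUS_FACTOR = 2.0  # tip broadening: apparent ≈ 2 × true radius


@dataclass
class NoiseParams:
    background_sigma: float = 6.0
    stripe_amplitude: float = 0.0
    stripe_period: int = 7          # rows between strong stripe offsets
    n_contaminations: int = 0
    contamination_radius_px: tuple[float, float] = (15.0, 40.0)


@dataclass
class GroundTruthObject:
    """True geometry of one rendered object.

    ``centerline`` is a list of polylines in nm (image coordinates,
    (row, col)): one polyline for free DNA, the two protruding arms for
    a nucleosome (each ordered from the disk rim outward).
    """

    kind: str  # "free_dna" | "nucleosome"
    centerline: list[np.ndarray]
    true_contour_nm: float
    nucleosome_center: tuple[float, float] | None = None  # nm coords
    true_radius_nm: float | None = None
    true_theta_deg: float | None = None
    true_arm_nm: tuple[float, float] | None = None


@dataclass
class SyntheticScene:
    image: AFMImage
    truth: list[GroundTruthObject]
    noise: NoiseParams
    rng_seed: int


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


def generate_filament(
    contour_nm: float,
    persistence_nm: float = 50.0,
    rng: np.random.Generator | None = None,
    step_nm: float = 2.0,
    max_attempts: int = 100,
) -> np.ndarray:
    """Discretized worm-like-chain polyline of exact total arc length.

    Steps are equal-length segments; the turning angle between successive
    segments is Gaussian with variance step/persistence (the 2-D WLC
    tangent-decorrelation rate).  Self-intersecting draws are rejected.
    Returns an (n+1, 2) array in nm, starting at the origin.
    """
    if contour_nm <= 0 or persistence_nm <= 0:
        raise ValueError("contour_nm and persistence_nm must be positive")
    rng = rng or np.random.default_rng()
    n = max(int(round(contour_nm / step_nm)), 1)
    step = contour_nm / n  # equal steps → arc length exact
    sigma = np.sqrt(step / persistence_nm)
    for _ in range(max_attempts):
        turns = rng.normal(0.0, sigma, size=n - 1) if n > 1 else np.empty(0)
        headings = rng.uniform(0, 2 * np.pi) + np.concatenate([[0.0], np.cumsum(turns)])
        deltas = step * np.column_stack([np.sin(headings), np.cos(headings)])
        pts = np.vstack([[0.0, 0.0], np.cumsum(deltas, axis=0)])
        if not _self_intersects(pts, clearance_nm=1.5):
            return pts
    raise RuntimeError("failed to draw a non-self-intersecting chain")


def _self_intersects(pts: np.ndarray, clearance_nm: float) -> bool:
    """True when non-neighboring vertices come closer than the clearance."""
    n = len(pts)
    if n < 5:
        return False
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    idx = np.arange(n)
    near = d2 < clearance_nm**2
    near &= np.abs(idx[:, None] - idx[None, :]) > 3
    return bool(near.any())


def generate_nucleosome(
    arm_nm: tuple[float, float],
    theta_deg: float,
    true_radius_nm: float = 5.5,
    persistence_nm: float = 50.0,
    rng: np.random.Generator | None = None,
    straight_exit_nm: float = 12.0,
    max_attempts: int = 100,
) -> GroundTruthObject:
    """A nucleosome with two protruding arms at a given opening angle.

    The arms leave the (apparent, tip-broadened) disk rim along exit
    directions separated by ``theta_deg``; each runs straight for
    ``straight_exit_nm`` (so the entry/exit geometry is well defined)
    and continues as a worm-like chain.  Arm draws that fold back into
    the disk or cross each other are rejected.
    """
    rng = rng or np.random.default_rng()
    r_app = APPARENT_RADIUS_FACTOR * true_radius_nm
    half = np.radians(theta_deg) / 2.0
    for _ in range(max_attempts):
        base = rng.uniform(0, 2 * np.pi)
        arms = []
        ok = True
        for sign, length in zip((+1, -1), arm_nm):
            ang = base + sign * half
            u = np.array([np.sin(ang), np.cos(ang)])
            start = r_app * u
            n_straight = max(int(straight_exit_nm / 2.0), 1)
            straight = start + np.outer(np.arange(n_straight + 1) * 2.0, u)
            rest_nm = length - n_straight * 2.0
            if rest_nm > 2.0:
                tail = generate_filament(rest_nm, persistence_nm, rng)
                tail = _orient(tail, u)
                tail = tail[1:] + straight[-1]
                arm = np.vstack([straight, tail])
            else:
                arm = straight
            # truncate/extend to exact length by construction of steps
            if np.min(np.hypot(arm[1:, 0], arm[1:, 1])) < r_app - 0.5:
                ok = False
                break
            arms.append(arm)
        if not ok:
            continue
        if _arms_cross(arms[0], arms[1]):
            continue
        total = sum(_polyline_length(a) for a in arms)
        return GroundTruthObject(
            kind="nucleosome",
            centerline=arms,
            true_contour_nm=total,
            nucleosome_center=(0.0, 0.0),
            true_radius_nm=true_radius_nm,
            true_theta_deg=float(theta_deg),
            true_arm_nm=(_polyline_length(arms[0]), _polyline_length(arms[1])),
        )
    raise RuntimeError("failed to draw nucleosome arms")


def _orient(pts: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Rotate a chain starting at the origin so its first step follows ``direction``."""
    first = pts[1] - pts[0]
    a0 = np.arctan2(first[0], first[1])
    a1 = np.arctan2(direction[0], direction[1])
    da = a1 - a0
    rot = np.array([[np.cos(da), np.sin(da)], [-np.sin(da), np.cos(da)]])
    return pts @ rot.T


def _arms_cross(a: np.ndarray, b: np.ndarray, clearance_nm: float = 2.5) -> bool:
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
    # entry points near the disk are legitimately close; skip the first
    # straight segment of each arm
    return bool((d2[3:, 3:] < clearance_nm**2).any())


def _bounding_radius(obj: GroundTruthObject) -> float:
    r = 0.0
    for line in obj.centerline:
        r = max(r, float(np.max(np.hypot(line[:, 0], line[:, 1]))))
    if obj.kind == "nucleosome":
        r = max(r, APPARENT_RADIUS_FACTOR * obj.true_radius_nm * 2)
    return r


def render_scene(
    objects: list[GroundTruthObject],
    nm_per_px: float = DEFAULT_NM_PER_PX,
    shape: tuple[int, int] = (1024, 1024),
    noise: NoiseParams | None = None,
    rng: np.random.Generator | None = None,
    rng_seed: int = 0,
    margin_px: float = 20.0,
    max_attempts: int = 200,
) -> SyntheticScene:
    """Place objects without overlap and render the scene.

    Objects are given in local coordinates (origin-centered); placement
    translates them randomly such that bounding disks keep ``margin_px``
    clearance from each other and from the border.  Raises a layout error
    when the field of view cannot accommodate them.
    """
    rng = rng or np.random.default_rng(rng_seed)
    noise = noise or NoiseParams()
    h, w = shape
    placed: list[GroundTruthObject] = []
    centers: list[tuple[float, float, float]] = []  # (row_nm, col_nm, radius_nm)
    for obj in objects:
        r_bound = _bounding_radius(obj)
        pad_nm = r_bound + margin_px * nm_per_px
        if 2 * pad_nm >= min(h, w) * nm_per_px:
            raise ValueError("object too large for the field of view")
        for _ in range(max_attempts):
            pos = rng.uniform([pad_nm, pad_nm],
                              [h * nm_per_px - pad_nm, w * nm_per_px - pad_nm])
            if all(np.hypot(pos[0] - cr, pos[1] - cc) >= r_bound + rr + margin_px * nm_per_px
                   for cr, cc, rr in centers):
                break
        else:
            raise ValueError("could not place all objects with the required margins")
        centers.append((pos[0], pos[1], r_bound))
        placed.append(_translate(obj, pos))

    canvas = _render_structures(placed, nm_per_px, shape)
    img = BACKGROUND + canvas
    img += rng.normal(0.0, noise.background_sigma, size=shape)
    if noise.stripe_amplitude > 0:
        offsets = np.zeros(h)
        stripe_rows = np.arange(0, h, max(noise.stripe_period, 1))
        offsets[stripe_rows] = rng.choice([-1.0, 1.0], size=len(stripe_rows)) \
            * noise.stripe_amplitude
        img += offsets[:, None]
    for _ in range(noise.n_contaminations):
        rad = rng.uniform(*noise.contamination_radius_px)
        cr = rng.uniform(rad, h - rad)
        cc = rng.uniform(rad, w - rad)
        rr, cc_grid = np.ogrid[:h, :w]
        d2 = (rr - cr) ** 2 + (cc_grid - cc) ** 2
        img = np.maximum(img, 240.0 * np.exp(-(d2 / rad**2) ** 2))
    image = AFMImage(np.clip(img, 0, 255), nm_per_px, source_id=f"synthetic_{rng_seed}")
    return SyntheticScene(image, placed, noise, rng_seed)


def _translate(obj: GroundTruthObject, pos_nm: np.ndarray) -> GroundTruthObject:
    lines = [line + pos_nm for line in obj.centerline]
    center = None
    if obj.nucleosome_center is not None:
        center = (obj.nucleosome_center[0] + pos_nm[0],
                  obj.nucleosome_center[1] + pos_nm[1])
    return GroundTruthObject(obj.kind, lines, obj.true_contour_nm, center,
                             obj.true_radius_nm, obj.true_theta_deg, obj.true_arm_nm)


def _render_structures(
    objects: list[GroundTruthObject],
    nm_per_px: float,
    shape: tuple[int, int],
) -> np.ndarray:
    """Gaussian-profile ridges for filaments, Gaussian disks for nucleosomes."""
    h, w = shape
    marks = np.ones(shape, dtype=bool)
    for obj in objects:
        for line in obj.centerline:
            pts_px = line / nm_per_px
            dense = _densify(pts_px, max_step=0.4)
            rr = np.clip(np.round(dense[:, 0]).astype(int), 0, h - 1)
            cc = np.clip(np.round(dense[:, 1]).astype(int), 0, w - 1)
            marks[rr, cc] = False
    sigma_ridge = RIDGE_FWHM_PX / 2.355
    if marks.all():
        ridge = np.zeros(shape)
    else:
        d = ndi.distance_transform_edt(marks)
        ridge = RIDGE_PEAK * np.exp(-(d**2) / (2 * sigma_ridge**2))
    canvas = ridge
    for obj in objects:
        if obj.kind != "nucleosome":
            continue
        r_app_nm = APPARENT_RADIUS_FACTOR * obj.true_radius_nm
        sigma_disk = (r_app_nm / nm_per_px) / np.sqrt(2 * np.log(2))  # half-max at r_app
        cr, cc = (obj.nucleosome_center[0] / nm_per_px,
                  obj.nucleosome_center[1] / nm_per_px)
        rr, cg = np.ogrid[:h, :w]
        d2 = (rr - cr) ** 2 + (cg - cc) ** 2
        canvas = np.maximum(canvas, DISK_PEAK * np.exp(-d2 / (2 * sigma_disk**2)))
    return canvas


def _densify(pts: np.ndarray, max_step: float) -> np.ndarray:
    """Resample a polyline so consecutive points are ≤ max_step apart."""
    out = [pts[:1]]
    for a, b in zip(pts[:-1], pts[1:]):
        seg = np.hypot(*(b - a))
        n = max(int(np.ceil(seg / max_step)), 1)
        t = np.linspace(0, 1, n + 1)[1:, None]
        out.append(a + t * (b - a))
    return np.vstack(out)


def generate_scene(
    n_filaments: int = 5,
    n_nucleosomes: int = 3,
    contour_nm: float = 157.8,
    arm_nm: tuple[float, float] = (50.0, 58.0),
    theta_deg: float | list[float] = 90.0,
    shape: tuple[int, int] = (1024, 1024),
    nm_per_px: float = DEFAULT_NM_PER_PX,
    noise: NoiseParams | None = None,
    seed: int = 0,
) -> SyntheticScene:
    """Convenience builder: a full scene from scalar knobs and one seed."""
    rng = np.random.default_rng(seed)
    thetas = np.atleast_1d(np.asarray(theta_deg, dtype=float))
    objects = [
        GroundTruthObject("free_dna", [generate_filament(contour_nm, rng=rng)],
                          contour_nm)
        for _ in range(n_filaments)
    ]
    for i in range(n_nucleosomes):
        objects.append(
            generate_nucleosome(arm_nm, float(thetas[i % len(thetas)]), rng=rng)
        )
    return render_scene(objects, nm_per_px, shape, noise, rng, rng_seed=seed)
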