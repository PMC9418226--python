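"""Synthetic fundus-autofluorescence-like scene generator.

Clinical FAF datasets for atrophic macular disease are not publicly
available, so every stage of the pipeline is exercised on generated
scenes that emulate the image features the method actually depends on:

* a dark branching vessel tree (whose junctions are the registration
  landmarks),
* hypo-fluorescent lesions -- a single well-demarcated focus (AMD-like
  geographic atrophy) or several poorly demarcated foci (Stargardt-like),
* a dark optic-nerve-head disc near the image edge as a false-positive
  confounder,
* speckle noise, an optional black border at the image bottom, and
* monotone lesion growth between baseline and the 12-month visit, plus a
  known rigid acquisition perturbation of the follow-up image.

Scenes are deterministic functions of ``SceneSpec.seed``.  Images are
floats in [0, 1]; masks are strict {0, 1} uint8 arrays.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .registration import RigidTransform, image_center, warp_image, warp_mask

__all__ = [
    "LesionSpec",
    "SceneSpec",
    "SceneBundle",
    "generate_scene",
    "grow_lesion",
    "simulate_followup_acquisition",
    "save_scene",
    "generate_dataset",
]


@dataclass
class LesionSpec:
    """Axes of lesion variation: focality, demarcation, depth, growth.

    ``n_foci=1`` with small ``edge_sharpness`` gives an AMD-GA-like
    well-demarcated single lesion; several foci with larger blur give a
    Stargardt-like multi-focal pattern.  ``hypo_level`` is the lesion
    intensity as a fraction of the local background (hypo-fluorescent,
    so < 1).  ``growth_fraction`` is the fractional area increase over
    one follow-up interval.
    """

    n_foci: int = 3
    focus_centers: list | None = None      # (row, col) pixels; None -> random
    focus_radii: list | float | None = None  # pixels; None -> random per focus
    edge_sharpness: float = 1.0            # Gaussian edge blur sigma (px); 0 = crisp
    hypo_level: float = 0.35
    growth_fraction: float = 0.3

    def validate(self) -> None:
        if self.n_foci < 1:
            raise ValueError("LesionSpec.n_foci must be >= 1")
        if self.edge_sharpness < 0:
            raise ValueError("LesionSpec.edge_sharpness must be >= 0")
        if not 0 <= self.hypo_level < 1:
            raise ValueError("LesionSpec.hypo_level must lie in [0, 1)")
        if self.growth_fraction < 0:
            raise ValueError("LesionSpec.growth_fraction must be >= 0")
        if self.focus_radii is not None:
            radii = np.atleast_1d(self.focus_radii).astype(float)
            if (radii <= 0).any():
                raise ValueError("LesionSpec.focus_radii must be > 0")


@dataclass
class SceneSpec:
    """Full description of one synthetic scene."""

    canvas_size: tuple[int, int] = (192, 192)
    vessel_depth: int = 4
    vessel_contrast: float = 0.45
    include_onh: bool = True
    n_distractors: int = 6       # scattered shallow hypo-fluorescent spots
    distractor_level: float = 0.72  # their intensity fraction of background
    noise_sigma: float = 0.02
    border_rows: int = 0
    lesion: LesionSpec = field(default_factory=LesionSpec)
    seed: int = 0

    def validate(self) -> None:
        h, w = self.canvas_size
        if h < 64 or w < 64:
            raise ValueError("SceneSpec.canvas_size must be at least 64x64")
        if self.border_rows < 0 or self.border_rows >= h:
            raise ValueError("SceneSpec.border_rows must be in [0, height)")
        if not 0 <= self.vessel_contrast <= 1:
            raise ValueError("SceneSpec.vessel_contrast must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("SceneSpec.noise_sigma must be >= 0")
        if self.n_distractors < 0:
            raise ValueError("SceneSpec.n_distractors must be >= 0")
        if not 0 < self.distractor_level <= 1:
            raise ValueError("SceneSpec.distractor_level must lie in (0, 1]")
        self.lesion.validate()


@dataclass
class SceneBundle:
    """A generated scene with ground truth for every pipeline stage."""

    image_t0: np.ndarray
    mask_t0: np.ndarray
    image_t12: np.ndarray        # follow-up rendered in the baseline frame
    mask_t12: np.ndarray         # follow-up label in the baseline frame
    image_t12_moved: np.ndarray  # follow-up after the true acquisition perturbation
    mask_t12_moved: np.ndarray
    true_transform: RigidTransform
    spec: SceneSpec | None = None


# ----------------------------------------------------------------- vessels

def _stamp_line(canvas: np.ndarray, p0, p1, width: float) -> None:
    """Draw a thick line segment by stamping discs along it."""
    h, w = canvas.shape
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    length = np.linalg.norm(p1 - p0)
    n = max(2, int(length * 2))
    r = max(width / 2.0, 0.6)
    ri = int(np.ceil(r))
    for s in np.linspace(0.0, 1.0, n):
        cr, cc = p0 * (1 - s) + p1 * s
        r0, r1 = int(max(0, np.floor(cr - r))), int(min(h - 1, np.ceil(cr + r)))
        c0, c1 = int(max(0, np.floor(cc - r))), int(min(w - 1, np.ceil(cc + r)))
        if r0 > r1 or c0 > c1:
            continue
        yy, xx = np.mgrid[r0:r1 + 1, c0:c1 + 1]
        d2 = (yy - cr) ** 2 + (xx - cc) ** 2
        patch = canvas[r0:r1 + 1, c0:c1 + 1]
        np.maximum(patch, (d2 <= r * r).astype(canvas.dtype), out=patch)


def _vessel_tree(shape, depth: int, rng: np.random.Generator, origin) -> np.ndarray:
    """Rasterize a recursive branching vessel tree (1 inside vessels)."""
    canvas = np.zeros(shape, dtype=np.float32)
    h, w = shape
    scale = min(h, w)

    def grow(p, angle, level, width):
        if level >= depth:
            return
        length = scale * 0.28 * (0.78 ** level) * rng.uniform(0.8, 1.2)
        # draw the segment as a short polyline with direction jitter
        pos = np.asarray(p, float)
        ang = angle
        n_sub = 3
        for _ in range(n_sub):
            ang += rng.uniform(-0.25, 0.25)
            nxt = pos + (length / n_sub) * np.array([np.sin(ang), np.cos(ang)])
            _stamp_line(canvas, pos, nxt, width)
            pos = nxt
        # branch into two children at the segment tip
        spread = rng.uniform(0.35, 0.75)
        grow(pos, ang + spread, level + 1, max(width * 0.75, 1.0))
        grow(pos, ang - spread, level + 1, max(width * 0.75, 1.0))

    # two or three trunks fanning out from the origin
    n_trunks = int(rng.integers(2, 4))
    base_angle = np.arctan2(h / 2 - origin[0], w / 2 - origin[1])
    for k in range(n_trunks):
        a = base_angle + (k - (n_trunks - 1) / 2) * rng.uniform(0.5, 0.9)
        grow(origin, a, 0, width=max(scale / 64.0, 1.8))
    return canvas


# ------------------------------------------------------------------ lesion

def grow_lesion(mask: np.ndarray, growth_fraction: float, seed: int) -> np.ndarray:
    """Grow a lesion mask by stochastic boundary accretion.

    Random boundary pixels (weighted by how many lesion neighbours they
    touch) are accreted until the area reaches
    ``round(area * (1 + growth_fraction))``, emulating the scattered,
    irregular border progression of atrophic lesions rather than a
    uniform morphological dilation.  The output is always a pixelwise
    superset of the input and the result is deterministic for a fixed
    seed.
    """
    mask = np.asarray(mask)
    if not np.isin(np.unique(mask), (0, 1)).all():
        raise ValueError("grow_lesion expects a binary {0,1} mask")
    area = int(mask.sum())
    if area == 0:
        raise ValueError("grow_lesion: mask is empty, nothing to grow")
    if growth_fraction < 0:
        raise ValueError("growth_fraction must be >= 0")
    out = mask.astype(bool).copy()
    target = int(round(area * (1.0 + growth_fraction)))
    rng = np.random.default_rng(seed)
    cross = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.uint8)
    while out.sum() < target:
        nb = ndimage.convolve(out.astype(np.uint8), cross, mode="constant")
        cand = (~out) & (nb > 0)
        rr, cc = np.nonzero(cand)
        if rr.size == 0:  # canvas saturated
            break
        p = 0.6 * nb[rr, cc] / 4.0
        accept = rng.random(rr.size) < p
        idx = np.nonzero(accept)[0]
        need = target - int(out.sum())
        if idx.size > need:
            idx = rng.choice(idx, size=need, replace=False)
        out[rr[idx], cc[idx]] = True
    return out.astype(np.uint8)


def _irregular_blob(shape, center, radius: float, rng: np.random.Generator) -> np.ndarray:
    """A disc roughened by one round of stochastic boundary accretion."""
    h, w = shape
    yy, xx = np.ogrid[:h, :w]
    disc = ((yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2).astype(np.uint8)
    if disc.sum() == 0:
        disc[int(round(center[0])) % h, int(round(center[1])) % w] = 1
    return grow_lesion(disc, 0.25, seed=int(rng.integers(2**31)))


def _place_lesion(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.canvas_size
    usable_h = h - spec.border_rows
    scale = min(usable_h, w)
    les = spec.lesion

    if les.focus_radii is None:
        radii = rng.uniform(0.055, 0.11, size=les.n_foci) * scale
    else:
        radii = np.resize(np.atleast_1d(les.focus_radii).astype(float), les.n_foci)
    if 2 * radii.max() > scale * 0.8:
        raise ValueError(
            "focus_radii too large for canvas_size: "
            f"radius {radii.max():.1f}px does not fit in a {h}x{w} canvas"
        )

    if les.focus_centers is not None:
        centers = np.asarray(les.focus_centers, float).reshape(-1, 2)
        if len(centers) != les.n_foci:
            raise ValueError("focus_centers must provide one centre per focus (n_foci)")
    else:
        # central region, clear of the ONH corner and the border rows
        lo_r, hi_r = 0.18 * usable_h, 0.72 * usable_h
        lo_c, hi_c = 0.15 * w, 0.68 * w
        centers = np.column_stack(
            [rng.uniform(lo_r, hi_r, les.n_foci), rng.uniform(lo_c, hi_c, les.n_foci)]
        )
    for (r, c), rad in zip(centers, radii):
        if r - rad < -1 or r + rad > usable_h + 1 or c - rad < -1 or c + rad > w + 1:
            raise ValueError(
                f"focus_centers: focus at ({r:.0f},{c:.0f}) with radius {rad:.0f} "
                "does not fit on the canvas"
            )

    mask = np.zeros((h, w), dtype=np.uint8)
    for (r, c), rad in zip(centers, radii):
        mask |= _irregular_blob((h, w), (r, c), rad, rng)
    mask[usable_h:, :] = 0
    return mask


# ----------------------------------------------------------------- render

def _onh_geometry(spec: SceneSpec):
    h, w = spec.canvas_size
    return (0.45 * h, 0.9 * w), 0.075 * min(h, w)


def _distractor_field(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Scattered shallow hypo-fluorescent spots, excluded from the label.

    These emulate the scattered autofluorescence reductions seen around
    and away from frank atrophy (incomplete RPE loss): dark-ish blobs
    that are *not* part of the delineated lesion and therefore act as
    false-positive hazards for the segmentation models.
    """
    h, w = spec.canvas_size
    usable_h = h - spec.border_rows
    field = np.zeros((h, w), dtype=np.float32)
    scale = min(usable_h, w)
    for _ in range(spec.n_distractors):
        r = rng.uniform(0.10 * usable_h, 0.92 * usable_h)
        c = rng.uniform(0.06 * w, 0.94 * w)
        rad = rng.uniform(0.015, 0.045) * scale
        yy, xx = np.ogrid[:h, :w]
        field = np.maximum(
            field, ((yy - r) ** 2 + (xx - c) ** 2 <= rad**2).astype(np.float32)
        )
    if field.any():
        field = ndimage.gaussian_filter(field, 1.5)
        peak = field.max()
        if peak > 0:
            field /= peak
    return field


def _render(
    background: np.ndarray,
    vessels: np.ndarray,
    mask: np.ndarray,
    spec: SceneSpec,
    noise_rng: np.random.Generator | None,
    distractors: np.ndarray | None = None,
) -> np.ndarray:
    """Compose background, lesion, distractors, vessels, ONH, noise, border."""
    img = background.copy()
    les = spec.lesion
    soft = mask.astype(np.float32)
    if les.edge_sharpness > 0:
        soft = ndimage.gaussian_filter(soft, les.edge_sharpness)
    img = img * (1.0 - (1.0 - les.hypo_level) * soft)
    if distractors is not None:
        img = img * (1.0 - (1.0 - spec.distractor_level) * distractors)
    img = img * (1.0 - spec.vessel_contrast * vessels)
    if spec.include_onh:
        (orow, ocol), orad = _onh_geometry(spec)
        yy, xx = np.ogrid[: img.shape[0], : img.shape[1]]
        onh = ((yy - orow) ** 2 + (xx - ocol) ** 2 <= orad**2).astype(np.float32)
        onh = ndimage.gaussian_filter(onh, 1.0)
        img = img * (1.0 - 0.62 * onh)
    if noise_rng is not None and spec.noise_sigma > 0:
        img = img + noise_rng.normal(0.0, spec.noise_sigma, img.shape)
    if spec.border_rows > 0:
        img[-spec.border_rows:, :] = 0.0
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def generate_scene(spec: SceneSpec, render_noise: bool = True) -> SceneBundle:
    """Generate a complete scene bundle from a spec (deterministic per seed).

    The follow-up image is rendered in the baseline frame from the grown
    lesion mask (same vessels and illumination), then perturbed by a
    known random rigid transform plus fresh noise to produce the
    misaligned acquisition that the registration stage must undo.
    """
    spec.validate()
    h, w = spec.canvas_size
    ss = np.random.SeedSequence(spec.seed)
    (rng_bg, rng_vessel, rng_lesion, rng_noise0,
     rng_noise12, rng_tf, rng_noise_mv, rng_distract) = [
        np.random.default_rng(s) for s in ss.spawn(8)]

    base = 0.62 + 0.04 * _smooth_field((h, w), min(h, w) / 4.0, rng_bg)
    (orow, ocol), _ = _onh_geometry(spec)
    origin = (orow, min(w - 2.0, ocol)) if spec.include_onh else (h * 0.5, w - 2.0)
    vessels = _vessel_tree((h, w), spec.vessel_depth, rng_vessel, origin)

    mask_t0 = _place_lesion(spec, rng_lesion)
    g = spec.lesion.growth_fraction
    if g > 0:
        mask_t12 = grow_lesion(mask_t0, g, seed=int(rng_lesion.integers(2**31)))
    else:
        mask_t12 = mask_t0.copy()

    distractors = (_distractor_field(spec, rng_distract)
                   if spec.n_distractors > 0 else None)
    image_t0 = _render(base, vessels, mask_t0, spec,
                       rng_noise0 if render_noise else None, distractors)
    image_t12 = _render(base, vessels, mask_t12, spec,
                        rng_noise12 if render_noise else None, distractors)

    t_max = min(10.0, min(h, w) / 16.0)   # keep the lesion on small canvases
    bundle = SceneBundle(
        image_t0=image_t0,
        mask_t0=mask_t0,
        image_t12=image_t12,
        mask_t12=mask_t12,
        image_t12_moved=image_t12,       # placeholder, replaced below
        mask_t12_moved=mask_t12,
        true_transform=RigidTransform.identity((h, w)),
        spec=spec,
    )
    noise_seed = int(rng_noise_mv.integers(2**31))
    for attempt in range(20):            # redraw if the lesion leaves the canvas
        shrink = 0.8**attempt
        theta = float(rng_tf.uniform(-6.0, 6.0)) * shrink
        t = tuple(rng_tf.uniform(-t_max, t_max, size=2) * shrink)
        true_tf = RigidTransform(theta_deg=theta, t=t, center=image_center((h, w)))
        try:
            img_mv, mask_mv = simulate_followup_acquisition(
                bundle, true_tf,
                noise_sigma=spec.noise_sigma if render_noise else 0.0,
                seed=noise_seed,
            )
            break
        except ValueError:
            continue
    else:
        raise ValueError("could not draw an acquisition perturbation keeping the lesion on-canvas")
    bundle.image_t12_moved = img_mv
    bundle.mask_t12_moved = mask_mv
    return bundle


def _smooth_field(shape, sigma, rng) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    peak = np.abs(f).max()
    return (f / peak if peak > 0 else f).astype(np.float32)


def simulate_followup_acquisition(
    bundle: SceneBundle,
    transform: RigidTransform,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a known rigid acquisition perturbation to the follow-up pair.

    Warps ``image_t12`` (bilinear) and ``mask_t12`` (nearest-neighbour)
    by ``transform``, adds fresh speckle noise, and records the
    transform on the bundle as ground truth.  Raises if the perturbation
    pushes more than 20% of the lesion off-canvas.
    """
    mask_mv = warp_mask(bundle.mask_t12, transform)
    area0 = int(bundle.mask_t12.sum())
    if area0 > 0 and mask_mv.sum() < 0.8 * area0:
        raise ValueError(
            "transform pushes the lesion off-canvas: "
            f"{mask_mv.sum()} of {area0} lesion pixels remain (< 80%)"
        )
    img_mv = warp_image(bundle.image_t12, transform)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img_mv = img_mv + rng.normal(0.0, noise_sigma, img_mv.shape)
    img_mv = np.clip(img_mv, 0.0, 1.0).astype(np.float32)
    bundle.true_transform = transform
    return img_mv, mask_mv.astype(np.uint8)


# ---------------------------------------------------------------- dataset

def generate_dataset(n_scenes: int, spec: SceneSpec | None = None, seed: int = 0):
    """Generate ``n_scenes`` bundles with per-scene seeds derived from ``seed``."""
    base = spec if spec is not None else SceneSpec()
    bundles = []
    for k in range(n_scenes):
        s = dataclasses.replace(base, seed=int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % 2**31))
        bundles.append(generate_scene(s))
    return bundles


def save_scene(bundle: SceneBundle, out_dir, stem: str) -> dict:
    """Write a bundle as 8-bit PNGs plus a JSON sidecar; returns the file map."""
    from . import io as fio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name in ("image_t0", "image_t12", "image_t12_moved"):
        path = out_dir / f"{stem}_{name}.png"
        fio.write_image(path, getattr(bundle, name))
        files[name] = str(path)
    for name in ("mask_t0", "mask_t12", "mask_t12_moved"):
        path = out_dir / f"{stem}_{name}.png"
        fio.write_mask(path, getattr(bundle, name))
        files[name] = str(path)
    spec = bundle.spec
    sidecar = {
        "true_transform": bundle.true_transform.to_json(),
        "seed": spec.seed if spec else None,
        "spec": _spec_to_json(spec) if spec else None,
        "files": files,
    }
    with open(out_dir / f"{stem}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return files


def _spec_to_json(spec: SceneSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["canvas_size"] = list(d["canvas_size"])
    return d
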