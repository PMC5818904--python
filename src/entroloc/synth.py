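"""Seeded synthetic fundus images with ground truth.

The generator emulates the statistical structure the entropy localizer
exploits, not photographic realism: a near-black surround outside a
circular camera aperture, a reddish smoothly shaded retina, a handful of
dark curvilinear vessels radiating from the optic disc toward the
periphery, and a bright disc whose interior carries high-variance texture
(noise plus the vessel roots crossing it).  The disc region is therefore
the only patch whose brightness histogram spreads over many levels, which
is exactly the contrast the two-stage search needs.

Everything is a pure function of ``(seed, params)``: the same call yields
a pixel-identical image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import image_io

__all__ = ["FundusParams", "SyntheticFundus", "generate_fundus", "generate_suite"]


@dataclass(frozen=True)
class FundusParams:
    """Generation knobs; defaults produce a 256 x 256 frame.

    ``od_radius`` defaults to 1/8 of the short side (32 px at 256), the
    relative disc size of a narrow-field (~30 degree) fundus camera, so one
    3 x 3 patch comfortably contains most of the disc.  ``aperture_frac``
    > 0.5 means the field-of-view circle is cropped by the frame, leaving
    only small dark corners, as in typical clinical photographs.
    ``texture_noise_sigma`` controls how widely the disc interior spreads
    across brightness levels; ``background_gradient`` is the peak-to-peak
    shading amplitude of the retinal background (kept small so background
    patches stay low-entropy).
    """

    height: int = 256
    width: int = 256
    od_radius: int = 32
    aperture_frac: float = 0.62  # aperture radius / short image side
    n_vessels: tuple[int, int] = (5, 15)  # inclusive range
    vessel_contrast: float = 40.0  # green-channel darkening under a vessel
    disc_brightness: float = 160.0  # green-channel disc base level
    texture_noise_sigma: float = 60.0
    background_gradient: float = 12.0
    background_noise_sigma: float = 1.5
    center_margin: int = 8  # extra clearance between disc rim and aperture rim

    def __post_init__(self) -> None:
        if min(self.height, self.width) < 96:
            raise ValueError("image must be at least 96 x 96")
        if self.od_radius > min(self.height, self.width) // 8:
            raise ValueError("od_radius must be <= min(H, W) / 8")
        if self.od_radius < 1:
            raise ValueError("od_radius must be positive")


@dataclass
class SyntheticFundus:
    image: np.ndarray  # H x W x 3 uint8
    od_center: tuple[int, int]  # (row, col)
    od_radius: int
    params: FundusParams = field(repr=False)
    seed: int


def _aperture_geometry(params: FundusParams) -> tuple[float, float, float]:
    cy = (params.height - 1) / 2.0
    cx = (params.width - 1) / 2.0
    return cy, cx, params.aperture_frac * min(params.height, params.width)


def _sample_od_center(rng: np.random.Generator, params: FundusParams) -> tuple[int, int]:
    """Uniform over the retina interior, keeping the disc clear of the rim.

    The disc must stay inside both the camera aperture and the image frame
    (the aperture circle may be cropped by the frame, as in real fundus
    photographs).
    """
    cy, cx, ap_r = _aperture_geometry(params)
    clearance = params.od_radius + params.center_margin
    max_off = min(ap_r, params.height / 2, params.width / 2) - clearance
    if max_off <= 0:
        raise ValueError("disc too large for the aperture")
    radius = max_off * math.sqrt(rng.uniform())
    angle = rng.uniform(0.0, 2.0 * math.pi)
    return (int(round(cy + radius * math.sin(angle))), int(round(cx + radius * math.cos(angle))))


def _vessel_mask(
    rng: np.random.Generator,
    params: FundusParams,
    od_center: tuple[int, int],
) -> np.ndarray:
    """Quadratic Bezier strokes (1-3 px wide) from the disc to the periphery."""
    h, w = params.height, params.width
    cy, cx, ap_r = _aperture_geometry(params)
    oy, ox = od_center
    n = int(rng.integers(params.n_vessels[0], params.n_vessels[1] + 1))
    mask_by_width = {1: np.zeros((h, w), bool), 2: np.zeros((h, w), bool), 3: np.zeros((h, w), bool)}
    d0 = np.array([oy - cy, ox - cx])
    for _ in range(n):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        u = np.array([math.sin(theta), math.cos(theta)])
        # start just inside the disc so the stroke crosses its rim
        r0 = rng.uniform(0.1, 0.6) * params.od_radius
        p0 = np.array([oy, ox]) + r0 * u
        # radiate outward from the disc; the rim distance along this
        # direction solves |d0 + t u| = ap_r, so strokes stay in-aperture
        proj = float(d0 @ u)
        t_rim = -proj + math.sqrt(max(proj**2 + ap_r**2 - float(d0 @ d0), 0.0))
        reach = rng.uniform(0.45, 0.95) * t_rim
        p2 = np.array([oy, ox]) + reach * u
        chord = p2 - p0
        normal = np.array([-chord[1], chord[0]])
        nrm = np.linalg.norm(normal)
        normal = normal / nrm if nrm > 0 else normal
        p1 = (p0 + p2) / 2 + normal * rng.uniform(-0.15, 0.15) * np.linalg.norm(chord)
        length = np.linalg.norm(p1 - p0) + np.linalg.norm(p2 - p1)
        t = np.linspace(0.0, 1.0, max(int(2 * length), 8))[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2
        rr = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
        cc = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
        width = int(rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1]))
        mask_by_width[width][rr, cc] = True
    mask = mask_by_width[1]
    if mask_by_width[2].any():
        cross = ndimage.generate_binary_structure(2, 1)
        mask = mask | ndimage.binary_dilation(mask_by_width[2], cross)
    if mask_by_width[3].any():
        mask = mask | ndimage.binary_dilation(mask_by_width[3], np.ones((3, 3), bool))
    return mask


def generate_fundus(
    seed: int,
    params: FundusParams | None = None,
    od_center: tuple[int, int] | None = None,
) -> SyntheticFundus:
    """Render one synthetic fundus image with known disc centre and radius.

    If ``od_center`` is not given it is sampled (from ``seed``) uniformly
    over the retina interior with the disc kept clear of the aperture rim;
    an explicit centre that puts the disc outside the aperture is rejected.
    """
    params = params or FundusParams()
    rng = np.random.default_rng(seed)
    h, w = params.height, params.width
    cy, cx, ap_r = _aperture_geometry(params)

    if od_center is None:
        od_center = _sample_od_center(rng, params)
    oy, ox = od_center
    if math.hypot(oy - cy, ox - cx) + params.od_radius > ap_r:
        raise ValueError(f"disc at {od_center} (r={params.od_radius}) outside aperture")
    r = params.od_radius
    if not (oy - r >= 0 and oy + r < h and ox - r >= 0 and ox + r < w):
        raise ValueError(f"disc at {od_center} (r={r}) crosses the image frame")

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= ap_r**2
    disc = (yy - oy) ** 2 + (xx - ox) ** 2 <= params.od_radius**2

    # smooth linear shading in a random direction, peak-to-peak = background_gradient
    phi = rng.uniform(0.0, 2.0 * math.pi)
    ramp = (yy * math.sin(phi) + xx * math.cos(phi)) / math.hypot(h, w)
    ramp = (ramp - ramp.min()) * params.background_gradient

    red = np.full((h, w), 150.0) + ramp
    green = np.full((h, w), 60.0) + ramp
    blue = np.full((h, w), 30.0) + 0.4 * ramp
    if params.background_noise_sigma > 0:
        green += rng.normal(0.0, params.background_noise_sigma, (h, w))

    # bright, strongly textured disc; green carries the largest contrast
    red[disc] = params.disc_brightness + 20.0
    green[disc] = params.disc_brightness
    blue[disc] = 70.0
    if params.texture_noise_sigma > 0:
        texture = rng.normal(0.0, params.texture_noise_sigma, (h, w))
        red[disc] += 0.8 * texture[disc]
        green[disc] += texture[disc]
        blue[disc] += 0.5 * texture[disc]

    vessels = _vessel_mask(rng, params, od_center) & inside
    red[vessels] -= 55.0
    green[vessels] -= params.vessel_contrast
    blue[vessels] -= 12.0

    img = np.stack([red, green, blue], axis=-1)
    img[~inside] = [4.0, 2.0, 2.0]  # near-black surround outside the aperture
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return SyntheticFundus(img, od_center, params.od_radius, params, seed)


def generate_suite(
    n: int,
    base_seed: int,
    params: FundusParams | None = None,
    outdir: str | Path | None = None,
) -> tuple[list[SyntheticFundus], pd.DataFrame]:
    """Generate ``n`` images (seeds ``base_seed .. base_seed+n-1``) + ground truth.

    The ground-truth table has columns ``filename, center_row, center_col,
    radius``.  When ``outdir`` is given, each image is written as
    ``fundus_<seed>.png`` and the table as ``ground_truth.csv``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or FundusParams()
    images = [generate_fundus(base_seed + i, params) for i in range(n)]
    truth = pd.DataFrame(
        {
            "filename": [f"fundus_{f.seed:05d}.png" for f in images],
            "center_row": [f.od_center[0] for f in images],
            "center_col": [f.od_center[1] for f in images],
            "radius": [f.od_radius for f in images],
        }
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for fundus, name in zip(images, truth["filename"]):
            image_io.write_image(outdir / name, fundus.image)
        truth.to_csv(outdir / "ground_truth.csv", index=False)
    return images, truth
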