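"""Synthetic angiogram phantoms with exact ground-truth vessel masks.

Real X-ray coronary angiograms show dark, smoothly curving tubular vessels
on a bright, nonuniformly illuminated, noisy background.  The generator
emulates those features deterministically:

* background: a base gray level plus a random low-order 2-D polynomial
  shading field (nonuniform illumination);
* vessels: smooth curvature-limited random-walk centerlines, optionally
  spawning one branch each, carved into the background as a Gaussian
  cross-sectional intensity dip (vessels darker than background, as in
  angiography) whose full width at half maximum is ``vessel_fwhm``;
* additive Gaussian noise, then clipping to [0, 1].

The ground-truth mask is exact by construction: a pixel is vessel iff its
distance to the nearest centerline pixel is at most ``vessel_fwhm / 2``.
The FWHM parameterization makes the phantom width directly commensurable
with the Gabor bank's thickness parameter tau.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
from scipy import ndimage

from .gabor import FWHM_FACTOR

__all__ = ["PhantomConfig", "Phantom", "generate_phantom", "generate_dataset", "save_dataset"]


@dataclasses.dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for one synthetic angiogram.

    Defaults give a nontrivial but solvable detection task: three vessels of
    7 px width at 35% contrast on a shaded background with mild noise.
    """

    width: int = 300
    height: int = 300
    n_vessels: int = 3
    vessel_fwhm: float = 7.0
    contrast: float = 0.35
    background_level: float = 0.7
    illumination_amplitude: float = 0.15
    noise_sigma: float = 0.03
    branch_probability: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if min(self.width, self.height) < 64:
            raise ValueError("width and height must be >= 64")
        if self.vessel_fwhm < 1:
            raise ValueError("vessel_fwhm must be >= 1")
        if self.vessel_fwhm >= min(self.width, self.height) / 2:
            raise ValueError(
                f"vessel_fwhm={self.vessel_fwhm} too large for a "
                f"{self.width}x{self.height} image"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0 <= self.contrast <= 1):
            raise ValueError("contrast must be in [0, 1]")
        if not (0 <= self.branch_probability <= 1):
            raise ValueError("branch_probability must be in [0, 1]")


@dataclasses.dataclass
class Phantom:
    """A synthetic angiogram with its exact ground truth."""

    image: np.ndarray
    mask: np.ndarray
    centerlines: list[np.ndarray]
    config: PhantomConfig


def _illumination(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Random low-order polynomial shading field scaled to +-illumination_amplitude."""
    ys = np.linspace(-1.0, 1.0, config.height)[:, None]
    xs = np.linspace(-1.0, 1.0, config.width)[None, :]
    c = rng.uniform(-1.0, 1.0, size=5)
    field = c[0] * xs + c[1] * ys + c[2] * xs * ys + c[3] * xs**2 + c[4] * ys**2
    peak = np.abs(field).max()
    if peak > 0:
        field = field / peak
    return config.illumination_amplitude * field


def _walk(
    start: np.ndarray,
    heading: float,
    shape: tuple[int, int],
    rng: np.random.Generator,
    max_steps: int,
    turn_sigma: float = 0.04,
) -> np.ndarray:
    """Curvature-limited unit-step random walk; stops on leaving the image."""
    h, w = shape
    pts = [start.copy()]
    p = start.copy()
    for _ in range(max_steps):
        heading += rng.normal(0.0, turn_sigma)
        p = p + np.array([math.cos(heading), math.sin(heading)])
        if not (0 <= p[0] < w and 0 <= p[1] < h):
            break
        pts.append(p.copy())
    return np.array(pts)


def _centerlines(config: PhantomConfig, rng: np.random.Generator) -> list[np.ndarray]:
    h, w = config.height, config.width
    diag = int(2 * math.hypot(h, w))
    lines: list[np.ndarray] = []
    for _ in range(config.n_vessels):
        # start near a random border, heading inward
        side = rng.integers(4)
        u = rng.uniform(0.1, 0.9)
        if side == 0:  # left
            start, heading = np.array([0.0, u * h]), rng.uniform(-math.pi / 3, math.pi / 3)
        elif side == 1:  # right
            start, heading = np.array([w - 1.0, u * h]), math.pi + rng.uniform(
                -math.pi / 3, math.pi / 3
            )
        elif side == 2:  # top
            start, heading = np.array([u * w, 0.0]), math.pi / 2 + rng.uniform(
                -math.pi / 3, math.pi / 3
            )
        else:  # bottom
            start, heading = np.array([u * w, h - 1.0]), -math.pi / 2 + rng.uniform(
                -math.pi / 3, math.pi / 3
            )
        line = _walk(start, heading, (h, w), rng, diag)
        lines.append(line)
        if len(line) > 20 and rng.uniform() < config.branch_probability:
            idx = rng.integers(len(line) // 4, 3 * len(line) // 4)
            d = line[min(idx + 1, len(line) - 1)] - line[idx]
            parent_heading = math.atan2(d[1], d[0])
            sign = 1 if rng.uniform() < 0.5 else -1
            branch_heading = parent_heading + sign * rng.uniform(math.pi / 6, math.pi / 3)
            lines.append(_walk(line[idx].copy(), branch_heading, (h, w), rng, diag))
    return lines


def generate_phantom(config: PhantomConfig, rng: np.random.Generator | None = None) -> Phantom:
    """Generate one phantom; the same config (seed included) is byte-identical."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    background = config.background_level + _illumination(config, rng)

    lines = _centerlines(config, rng)
    on_centerline = np.zeros((h, w), dtype=bool)
    for line in lines:
        if len(line) == 0:
            continue
        cols = np.clip(np.rint(line[:, 0]).astype(int), 0, w - 1)
        rows = np.clip(np.rint(line[:, 1]).astype(int), 0, h - 1)
        on_centerline[rows, cols] = True

    if on_centerline.any():
        dist = ndimage.distance_transform_edt(~on_centerline)
    else:
        dist = np.full((h, w), np.inf)

    sigma_v = config.vessel_fwhm / FWHM_FACTOR
    with np.errstate(over="ignore", under="ignore"):
        dip = np.where(
            np.isfinite(dist), np.exp(-(dist**2) / (2.0 * sigma_v**2)), 0.0
        )
    image = background - config.contrast * background * dip
    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, size=(h, w))
    image = np.clip(image, 0.0, 1.0)

    mask = dist <= config.vessel_fwhm / 2.0
    return Phantom(image=image, mask=mask, centerlines=lines, config=config)


def generate_dataset(
    config: PhantomConfig, n_images: int, rng: np.random.Generator | None = None
) -> list[Phantom]:
    """Generate ``n_images`` phantoms with per-image seeds derived from the config seed.

    The derived seeds are deterministic, so the same master config always
    reproduces the same dataset; datasets from different master seeds are
    independent (e.g. disjoint train/test splits).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    child_seeds = np.random.SeedSequence(config.seed).generate_state(n_images)
    phantoms = []
    for s in child_seeds:
        sub = dataclasses.replace(config, seed=int(s))
        phantoms.append(generate_phantom(sub))
    return phantoms


def save_dataset(phantoms: list[Phantom], directory) -> Path:
    """Write phantoms as paired 8-bit PNGs (img_NNN.png / mask_NNN.png) + manifest.

    The manifest (manifest.yaml) records the shared generation parameters and
    the per-image seed, so the files can be regenerated bit-exactly.
    """
    import imageio.v3 as iio
    import yaml

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, ph in enumerate(phantoms):
        img_name, mask_name = f"img_{i:03d}.png", f"mask_{i:03d}.png"
        iio.imwrite(
            directory / img_name,
            np.floor(ph.image * 255.0 + 0.5).astype(np.uint8),
        )
        iio.imwrite(directory / mask_name, ph.mask.astype(np.uint8) * 255)
        entries.append({"image": img_name, "mask": mask_name, "seed": ph.config.seed})
    manifest = {
        "config": dataclasses.asdict(dataclasses.replace(phantoms[0].config, seed=0)),
        "images": entries,
    }
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return directory
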