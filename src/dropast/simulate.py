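"""Synthetic droplet experiments with known ground truth.

Two generators stand in for the wet-lab side of a droplet single-cell AST
experiment:

* ``simulate_counts`` — per-concentration droplet count tables.  Droplet
  occupancy is Poisson (stochastic confinement: lambda = CFU/mL x droplet
  volume, ~0.1 so that ~90% of droplets stay empty and ~9% carry exactly
  one cell), each cell carries an individual MIC drawn from a
  Weibull(scale=true_p1, shape=true_p2) distribution — the distribution
  whose survival function is the Gompertz curve the analysis fits — and a
  droplet is growth-positive at concentration c when its cell tolerates c.

* ``generate_droplet_images`` — bright-field-like micrographs of circular
  droplets with a per-droplet ground-truth manifest.  Empty droplets have a
  smooth interior plus camera noise; droplets carrying a microcolony get a
  granular high-spatial-frequency texture, which is what the GLCM classifier
  keys on.  Rendering is schematic (no optics model): discs with a dark rim
  on a uniform background, value noise only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import CountTable

__all__ = [
    "SimulationConfig",
    "ImageConfig",
    "GroundTruthManifest",
    "poisson_occupancy",
    "simulate_counts",
    "generate_droplet_images",
    "DEFAULT_CONC_GRID",
]

# fine linear ladder bracketing the scale of the default truth (p1 ~ 9.8),
# plus a c = 0 control — mirrors a concentration series stepped tightly
# around the expected MIC
DEFAULT_CONC_GRID = (0.0, 2.0, 4.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0, 14.0, 16.0, 20.0)


def poisson_occupancy(cfu_per_ml: float, droplet_volume_nl: float) -> dict[str, float]:
    """Poisson occupancy masses {P(0), P(1), P(>=2)} for droplet loading.

    lambda = cfu_per_ml x droplet volume in mL (1 nL = 1e-6 mL).  At the
    standard loading of 1e5 CFU/mL into 1 nL droplets, lambda = 0.1: about
    90% of droplets are empty and 9% hold a single cell, which is what makes
    droplet growth readout a single-cell measurement.
    """
    if cfu_per_ml <= 0:
        raise ValueError(f"cfu_per_ml must be > 0, got {cfu_per_ml}")
    if droplet_volume_nl <= 0:
        raise ValueError(f"droplet_volume_nl must be > 0, got {droplet_volume_nl}")
    lam = cfu_per_ml * droplet_volume_nl * 1e-6
    p0 = math.exp(-lam)
    p1 = lam * p0
    return {"P0": p0, "P1": p1, "P2plus": 1.0 - p0 - p1, "lambda": lam}


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and sampling design for a synthetic count experiment."""

    true_p1: float = 9.8           # iMIC scale, concentration units
    true_p2: float = 4.4           # iMIC shape, dimensionless
    conc_grid: tuple[float, ...] = DEFAULT_CONC_GRID
    n_droplets_per_conc: int = 5000
    cfu_per_ml: float = 1e5
    droplet_volume_nl: float = 1.0
    n_replicates: int = 3
    multi_occupancy_rule: str = "single_only"  # or "max_of_k"
    seed: int = 0
    unit: str = "ng/mL"

    def __post_init__(self):
        if self.true_p1 <= 0 or self.true_p2 <= 0:
            raise ValueError("true_p1 and true_p2 must be > 0")
        grid = tuple(float(c) for c in self.conc_grid)
        if len(grid) < 2 or grid[0] != 0.0 or any(
            b <= a for a, b in zip(grid, grid[1:])
        ):
            raise ValueError("conc_grid must be sorted ascending and start at 0")
        if self.n_droplets_per_conc < 1:
            raise ValueError("n_droplets_per_conc must be >= 1")
        if self.cfu_per_ml <= 0 or self.droplet_volume_nl <= 0:
            raise ValueError("cfu_per_ml and droplet_volume_nl must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.multi_occupancy_rule not in ("single_only", "max_of_k"):
            raise ValueError("multi_occupancy_rule must be 'single_only' or 'max_of_k'")
        object.__setattr__(self, "conc_grid", grid)

    @property
    def occupancy_lambda(self) -> float:
        return self.cfu_per_ml * self.droplet_volume_nl * 1e-6


def _weibull_imic(rng: np.random.Generator, p1: float, p2: float, size: int) -> np.ndarray:
    return p1 * rng.weibull(p2, size=size)


def _max_of_k_imic(
    rng: np.random.Generator, p1: float, p2: float, k: np.ndarray
) -> np.ndarray:
    # max of k iid Weibulls by inverse transform: CDF of the max is F(c)^k,
    # so c = F^{-1}(u^{1/k}) with u ~ U(0,1)
    u = rng.random(k.shape)
    return p1 * (-np.log1p(-(u ** (1.0 / k)))) ** (1.0 / p2)


def simulate_counts(config: SimulationConfig) -> list[CountTable]:
    """Simulate replicate droplet count tables under the iMIC model.

    For every replicate and concentration c, ``n_droplets_per_conc`` fresh
    droplets are loaded with Poisson(lambda) cells.  Under the default
    ``single_only`` rule every occupied droplet behaves as a single cell
    (the regime Poisson loading is designed for), so the expected positive
    fraction among occupied droplets is exactly the Weibull survival
    exp{-(c/p1)^p2}.  The ``max_of_k`` rule instead lets a droplet grow if
    the most tolerant of its k cells survives, probing the small upward bias
    multi-occupancy would cause.

    Deterministic for a fixed config (seeded generator).
    """
    rng = np.random.default_rng(config.seed)
    lam = config.occupancy_lambda
    n = config.n_droplets_per_conc
    tables = []
    for rep in range(config.n_replicates):
        rows = []
        for c in config.conc_grid:
            k = rng.poisson(lam, size=n)
            occupied = k > 0
            n_occ = int(occupied.sum())
            if n_occ == 0:
                rows.append((c, n, 0))
                continue
            if config.multi_occupancy_rule == "single_only":
                imic = _weibull_imic(rng, config.true_p1, config.true_p2, n_occ)
            else:
                imic = _max_of_k_imic(
                    rng, config.true_p1, config.true_p2, k[occupied].astype(float)
                )
            n_pos = int(np.count_nonzero(imic > c))
            rows.append((c, n, n_pos))
        tables.append(
            CountTable(
                replicate_id=f"rep{rep + 1}",
                data=pd.DataFrame(
                    rows, columns=["concentration", "n_total", "n_positive"]
                ),
                unit=config.unit,
            )
        )
    return tables


# ---------------------------------------------------------------------------
# image generation


@dataclass(frozen=True)
class ImageConfig:
    """Rendering parameters for synthetic bright-field droplet images.

    Grey amplitudes (``texture_contrast``, ``background_noise_sd``) are in
    8-bit grey levels (0-255) regardless of the output bit depth; images are
    rendered in floating point and scaled on write.
    """

    image_size_px: tuple[int, int] = (640, 640)  # (H, W)
    droplet_radius_px: tuple[float, float] = (24.0, 2.0)  # (mean, SD)
    n_droplets_per_image: int = 50
    n_images: int = 1
    occupancy_prob: float = 0.091
    texture_contrast: float = 20.0
    background_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size_px
        if h < 16 or w < 16:
            raise ValueError("image too small")
        mu, sd = self.droplet_radius_px
        if mu <= 0 or sd < 0:
            raise ValueError("droplet radius mean must be > 0 and SD >= 0")
        if self.n_droplets_per_image < 1 or self.n_images < 1:
            raise ValueError("need at least one droplet and one image")
        if not 0.0 <= self.occupancy_prob <= 1.0:
            raise ValueError("occupancy_prob must be in [0, 1]")
        if self.texture_contrast < 0 or self.background_noise_sd < 0:
            raise ValueError("texture_contrast and background_noise_sd must be >= 0")


@dataclass
class GroundTruthManifest:
    """One row per rendered droplet: geometry and occupancy ground truth."""

    data: pd.DataFrame  # image, droplet_id, cx, cy, r, occupied, n_cells

    def __post_init__(self):
        required = {"image", "droplet_id", "cx", "cy", "r", "occupied", "n_cells"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        occ = self.data["occupied"].astype(bool)
        if ((self.data["n_cells"] > 0) != occ).any():
            raise ValueError("n_cells inconsistent with occupied flag")


def _place_droplets(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    radius_mean: float,
    radius_sd: float,
    max_tries: int = 20000,
) -> list[tuple[float, float, float]]:
    """Rejection-sample n non-overlapping circles fully inside the frame."""
    h, w = shape
    placed: list[tuple[float, float, float]] = []
    tries = 0
    margin_gap = 2.0  # rim clearance between droplets, px
    while len(placed) < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n} droplets of radius ~{radius_mean} in a "
                f"{h}x{w} image after {max_tries} tries; reduce droplet count "
                f"or radius"
            )
        tries += 1
        r = max(4.0, rng.normal(radius_mean, radius_sd))
        cx = rng.uniform(r + 2, w - r - 2)
        cy = rng.uniform(r + 2, h - r - 2)
        ok = all(
            math.hypot(cx - x, cy - y) >= r + rr + margin_gap
            for x, y, rr in placed
        )
        if ok:
            placed.append((cx, cy, r))
    return placed


def _render_image(
    rng: np.random.Generator,
    config: ImageConfig,
    circles: list[tuple[float, float, float]],
    occupied: np.ndarray,
) -> np.ndarray:
    """Render one frame in float grey levels (0-255 scale)."""
    h, w = config.image_size_px
    img = np.full((h, w), 110.0)  # background
    yy, xx = np.mgrid[0:h, 0:w]
    for (cx, cy, r), occ in zip(circles, occupied):
        d = np.hypot(xx - cx, yy - cy)
        interior = d <= r - 1.5
        rim = (d > r - 1.5) & (d <= r + 0.5)
        img[interior] = 150.0
        img[rim] = 40.0  # dark droplet boundary (oil/water interface)
        if occ and config.texture_contrast > 0:
            # granular microcolony texture: pixel-scale grain of SD
            # texture_contrast, confined well inside the rim
            core = d <= max(2.0, r - 3.0)
            img[core] += rng.normal(
                0.0, config.texture_contrast, size=int(core.sum())
            )
    if config.background_noise_sd > 0:
        img += rng.normal(0.0, config.background_noise_sd, size=(h, w))
    return np.clip(img, 0.0, 255.0)


def generate_droplet_images(
    config: ImageConfig,
) -> tuple[list[np.ndarray], GroundTruthManifest]:
    """Render synthetic droplet micrographs plus their ground-truth manifest.

    Returns a list of float images in 0-255 grey levels (convert with
    ``dropast.io.save_images``) and a manifest with one row per droplet.
    Occupancy is Bernoulli(``occupancy_prob``) per droplet; occupied droplets
    carry a Poisson(1)+1 cell count (at least one cell, manifest bookkeeping
    only — rendering depends just on the occupancy flag).  Deterministic per
    seed.
    """
    rng = np.random.default_rng(config.seed)
    images: list[np.ndarray] = []
    rows = []
    for i in range(config.n_images):
        circles = _place_droplets(
            rng,
            config.image_size_px,
            config.n_droplets_per_image,
            config.droplet_radius_px[0],
            config.droplet_radius_px[1],
        )
        occupied = rng.random(len(circles)) < config.occupancy_prob
        n_cells = np.where(occupied, rng.poisson(1.0, len(circles)) + 1, 0)
        images.append(_render_image(rng, config, circles, occupied))
        for j, ((cx, cy, r), occ, k) in enumerate(zip(circles, occupied, n_cells)):
            rows.append((f"image_{i:03d}", j, cx, cy, r, bool(occ), int(k)))
    manifest = GroundTruthManifest(
        data=pd.DataFrame(
            rows,
            columns=["image", "droplet_id", "cx", "cy", "r", "occupied", "n_cells"],
        )
    )
    return images, manifest
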