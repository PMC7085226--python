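"""Seeded phantom generators for TPAF/SHG image pairs with ground truth.

No public image archive accompanies the kind of label-free multiphoton
study this package quantifies, so every pipeline stage is exercised on
phantoms that emulate the two channels' salient structure:

* TPAF: bright cytoplasm/stroma (endogenous NAD(H)/FAD fluorescence) with
  dark signal-void nuclei, plus occasional very bright blobs mimicking
  necrosis or lipid-laden foam cells.
* SHG: bright curvilinear collagen fibers on a dark background, drawn until
  the ground-truth area fraction reaches a requested target.

Cohort generation draws per-sample metric targets (mean nuclear area,
collagen fraction) from truncated normal distributions parameterized by
group mean +/- SD, then renders one phantom pair per sample with a child
seed derived deterministically from the master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from .errors import GenerationError, PlacementError
from .image_io import BinaryMask, ChannelRole, MpmImage

__all__ = [
    "TpafPhantomParams",
    "ShgPhantomParams",
    "GroupParams",
    "CohortSpec",
    "CohortSample",
    "generate_tpaf",
    "generate_shg",
    "generate_cohort",
    "draw_cohort_targets",
    "child_seed",
]

#: Published pre-treatment group row used as generator defaults:
#: nuclear area 596.56 +/- 208.69 px^2, collagen 22.81 +/- 10.23 %, n=30.
PRE_TREATMENT_DEFAULTS = dict(
    n_samples=30,
    nuclear_area_mean=596.56,
    nuclear_area_sd=208.69,
    collagen_mean_pct=22.81,
    collagen_sd_pct=10.23,
)
#: Published post-treatment row: 856.22 +/- 255.74 px^2, 36.10 +/- 12.42 %.
POST_TREATMENT_DEFAULTS = dict(
    n_samples=30,
    nuclear_area_mean=856.22,
    nuclear_area_sd=255.74,
    collagen_mean_pct=36.10,
    collagen_sd_pct=12.42,
)

#: Minimum area (px^2) an individual rendered nucleus is truncated to;
#: keeps ellipses rasterizable. Per-sample *target means* are truncated only
#: to positive values so group-mean recovery stays unbiased.
MIN_RENDERED_NUCLEUS_AREA_PX2 = 50.0


@dataclass
class TpafPhantomParams:
    """Parameters of a TPAF phantom: dark elliptical nuclei on bright cytoplasm."""

    image_shape: tuple[int, int] = (256, 256)
    n_nuclei: int = 12
    nucleus_area_mean_px2: float = 596.56
    nucleus_area_sd_px2: float = 90.0
    nucleus_eccentricity_range: tuple[float, float] = (0.0, 0.6)
    cytoplasm_level: float = 190.0
    nucleus_level: float = 25.0
    n_bright_blobs: int = 2
    noise_sd: float = 4.0
    seed: int = 0
    bit_depth: int = 8
    min_separation_px: int = 4

    def __post_init__(self) -> None:
        if self.nucleus_level >= self.cytoplasm_level:
            raise ValueError(
                "nucleus_level must be below cytoplasm_level (nuclei are signal voids)"
            )
        if self.n_nuclei < 0 or self.n_bright_blobs < 0:
            raise ValueError("object counts must be non-negative")
        if self.noise_sd < 0 or self.nucleus_area_sd_px2 < 0:
            raise ValueError("standard deviations must be non-negative")
        lo, hi = self.nucleus_eccentricity_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("eccentricity range must lie in [0, 1)")


@dataclass
class ShgPhantomParams:
    """Parameters of an SHG phantom: curvilinear fibers at a target area fraction."""

    image_shape: tuple[int, int] = (256, 256)
    target_collagen_fraction_pct: float = 22.81
    fiber_width_px: int = 3
    fiber_level_range: tuple[float, float] = (100.0, 220.0)
    background_level: float = 8.0
    noise_sd: float = 4.0
    seed: int = 0
    bit_depth: int = 8

    #: Achieved ground-truth fraction must land within this band of target.
    tolerance_pct: float = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.target_collagen_fraction_pct <= 100:
            raise ValueError("target fraction must lie in [0, 100] %")
        if self.fiber_width_px < 1:
            raise ValueError("fiber_width_px must be >= 1")
        if self.fiber_level_range[0] <= self.background_level:
            raise ValueError("fiber levels must exceed the background level")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class GroupParams:
    """Group-level cohort parameters (per-sample targets ~ truncated normal)."""

    n_samples: int
    nuclear_area_mean: float
    nuclear_area_sd: float
    collagen_mean_pct: float
    collagen_sd_pct: float

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.nuclear_area_mean <= 0:
            raise ValueError("nuclear_area_mean must be positive")
        if min(self.nuclear_area_sd, self.collagen_sd_pct) < 0:
            raise ValueError("SDs must be non-negative")
        if not 0 <= self.collagen_mean_pct <= 100:
            raise ValueError("collagen_mean_pct must lie in [0, 100]")


@dataclass
class CohortSpec:
    """A two-group (pre/post therapy) synthetic cohort specification."""

    pre: GroupParams = field(
        default_factory=lambda: GroupParams(**PRE_TREATMENT_DEFAULTS)
    )
    post: GroupParams = field(
        default_factory=lambda: GroupParams(**POST_TREATMENT_DEFAULTS)
    )
    master_seed: int = 0
    image_shape: tuple[int, int] = (256, 256)
    n_nuclei: int = 10
    within_sample_area_cv: float = 0.10

    @property
    def groups(self) -> dict[str, GroupParams]:
        return {"pre": self.pre, "post": self.post}


@dataclass
class CohortSample:
    """One rendered cohort sample with its ground truth."""

    sample_id: str
    group: str
    seed: int
    tpaf: MpmImage
    nucleus_labels: np.ndarray
    shg: MpmImage
    collagen_mask: BinaryMask
    target_nuclear_area_px2: float
    target_collagen_pct: float
    achieved_collagen_pct: float


def _ellipse_semiaxes(area: float, eccentricity: float) -> tuple[float, float]:
    """Semi-axes (a >= b) of an ellipse with given area and eccentricity."""
    ratio = math.sqrt(1.0 - eccentricity**2)  # b/a
    a = math.sqrt(area / (math.pi * ratio))
    return a, a * ratio


def _rasterize_ellipse(
    shape: tuple[int, int], center: tuple[float, float], a: float, b: float,
    theta: float,
) -> np.ndarray:
    """Boolean mask of pixel centers inside a rotated ellipse."""
    r0, c0 = center
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr, dc = rr - r0, cc - c0
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float = np.inf
) -> float:
    """Draw N(mean, sd) by rejection until the value lands in [lo, hi]."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise GenerationError(
        f"truncated normal ({mean}, {sd}) never hit [{lo}, {hi}]"
    )


def generate_tpaf(params: TpafPhantomParams) -> tuple[MpmImage, np.ndarray]:
    """Render a TPAF phantom and its ground-truth nucleus label mask.

    Returns
    -------
    image, labels
        ``labels`` is an integer mask where label ``k > 0`` marks nucleus
        ``k``; nuclei are pairwise disjoint (separated by
        ``min_separation_px``). Same seed, same params => bit-identical
        output.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    maxv = 2**params.bit_depth - 1
    img = np.full((h, w), float(params.cytoplasm_level))
    labels = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)  # nuclei + separation margin

    sep = params.min_separation_px
    placed = 0
    attempts = 0
    max_attempts = 600 * max(params.n_nuclei, 1)
    while placed < params.n_nuclei:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed only {placed}/{params.n_nuclei} nuclei "
                f"after {max_attempts} attempts"
            )
        attempts += 1
        area = _truncated_normal(
            rng,
            params.nucleus_area_mean_px2,
            params.nucleus_area_sd_px2,
            lo=MIN_RENDERED_NUCLEUS_AREA_PX2,
        )
        ecc = rng.uniform(*params.nucleus_eccentricity_range)
        theta = rng.uniform(0, math.pi)
        a, b = _ellipse_semiaxes(area, ecc)
        # bounding half-extents of the rotated ellipse, plus separation
        half_r = math.sqrt((a * math.sin(theta)) ** 2 + (b * math.cos(theta)) ** 2)
        half_c = math.sqrt((a * math.cos(theta)) ** 2 + (b * math.sin(theta)) ** 2)
        margin_r = half_r + sep + 1
        margin_c = half_c + sep + 1
        if 2 * margin_r >= h or 2 * margin_c >= w:
            continue  # ellipse cannot fit; resample
        r0 = rng.uniform(margin_r, h - margin_r)
        c0 = rng.uniform(margin_c, w - margin_c)
        mask = _rasterize_ellipse((h, w), (r0, c0), a, b, theta)
        halo = _rasterize_ellipse((h, w), (r0, c0), a + sep, b + sep, theta)
        if (halo & occupied).any():
            continue
        placed += 1
        labels[mask] = placed
        occupied |= halo
        img[mask] = params.nucleus_level

    # bright necrosis / foam-cell mimics, kept off nuclei
    blob_level = (params.cytoplasm_level + maxv) / 2.0
    for _ in range(params.n_bright_blobs):
        for _try in range(200):
            radius = rng.uniform(4, 10)
            r0 = rng.uniform(radius + 1, h - radius - 1)
            c0 = rng.uniform(radius + 1, w - radius - 1)
            rr, cc = draw_disk((r0, c0), radius, shape=(h, w))
            if not occupied[rr, cc].any():
                img[rr, cc] = blob_level
                break

    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, maxv)
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    mpm = MpmImage(
        img.astype(dtype),
        ChannelRole.TPAF,
        bit_depth=params.bit_depth,
        provenance=f"tpaf-phantom(seed={params.seed})",
    )
    return mpm, labels


def _draw_fiber(
    rng: np.random.Generator, shape: tuple[int, int], width: int, n_steps: int
) -> np.ndarray:
    """Boolean stroke of one smoothed random-walk fiber."""
    h, w = shape
    stroke = np.zeros(shape, dtype=bool)
    r = rng.uniform(0, h)
    c = rng.uniform(0, w)
    angle = rng.uniform(0, 2 * math.pi)
    radius = max(width / 2.0, 0.8)
    step = 2.0
    for _ in range(n_steps):
        rr, cc = draw_disk((r, c), radius, shape=shape)
        stroke[rr, cc] = True
        angle += rng.normal(0.0, 0.25)
        r += step * math.sin(angle)
        c += step * math.cos(angle)
        if not (-width <= r < h + width and -width <= c < w + width):
            break
    return stroke


def generate_shg(params: ShgPhantomParams) -> tuple[MpmImage, BinaryMask]:
    """Render an SHG phantom whose ground-truth fiber fraction hits the target.

    Fibers (smoothed random walks of fixed stroke width, each at its own
    intensity drawn from ``fiber_level_range``) are added until the mask
    fraction lies within ``tolerance_pct`` of the target; a fiber that would
    overshoot the band is re-proposed shorter. Raises
    :class:`~mpmquant.errors.GenerationError` if the band cannot be reached
    within a bounded number of iterations.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    maxv = 2**params.bit_depth - 1
    total = h * w
    target = params.target_collagen_fraction_pct
    tol = params.tolerance_pct

    img = np.full((h, w), float(params.background_level))
    gt = np.zeros((h, w), dtype=bool)

    n_steps = max(10, int(0.5 * min(h, w)))
    iterations = 0
    while 100.0 * gt.sum() / total < target:
        iterations += 1
        if iterations > 3000:
            raise GenerationError(
                f"could not reach {target:.1f}% +/- {tol}% fiber fraction "
                f"(stuck at {100.0 * gt.sum() / total:.2f}%)"
            )
        stroke = _draw_fiber(rng, (h, w), params.fiber_width_px, n_steps)
        new_frac = 100.0 * (gt | stroke).sum() / total
        if new_frac > target + tol:
            # overshoot: retry with a shorter fiber
            n_steps = max(3, n_steps // 2)
            continue
        level = rng.uniform(*params.fiber_level_range)
        img[stroke] = level
        gt |= stroke

    achieved = 100.0 * gt.sum() / total
    if abs(achieved - target) > tol:
        raise GenerationError(
            f"achieved fraction {achieved:.2f}% outside {target:.2f}% +/- {tol}%"
        )

    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, maxv)
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    mpm = MpmImage(
        img.astype(dtype),
        ChannelRole.SHG,
        bit_depth=params.bit_depth,
        provenance=f"shg-phantom(seed={params.seed})",
    )
    return mpm, BinaryMask(np.where(gt, 255, 0).astype(np.uint8))


def child_seed(master_seed: int, group_index: int, sample_index: int) -> int:
    """Deterministic child seed: SeedSequence(master, spawn_key=(g, i)) < 2**31."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(group_index, sample_index))
    return int(ss.generate_state(1)[0] % 2**31)


def draw_cohort_targets(spec: CohortSpec) -> pd.DataFrame:
    """Draw per-sample metric targets for a cohort, without rendering images.

    One row per sample: group, sample id, child seed, target mean nuclear
    area (truncated normal on positive values) and target collagen fraction
    (truncated normal on [0, 100] %). This is the sampling
    stage of :func:`generate_cohort` and is what replicate-level power and
    type-I-error simulations operate on.
    """
    rows = []
    for gi, (group, gp) in enumerate(spec.groups.items()):
        for i in range(gp.n_samples):
            seed = child_seed(spec.master_seed, gi, i)
            rng = np.random.default_rng(seed)
            area = _truncated_normal(
                rng, gp.nuclear_area_mean, gp.nuclear_area_sd, lo=1.0
            )
            collagen = _truncated_normal(
                rng, gp.collagen_mean_pct, gp.collagen_sd_pct, lo=0.0, hi=100.0
            )
            rows.append(
                dict(
                    sample_id=f"{group}-{i:03d}",
                    group=group,
                    seed=seed,
                    target_nuclear_area_px2=area,
                    target_collagen_pct=collagen,
                )
            )
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec) -> list[CohortSample]:
    """Render a full two-group cohort of TPAF/SHG phantom pairs.

    Per-sample targets come from :func:`draw_cohort_targets`; each sample's
    phantoms are generated with further child seeds so samples are
    independent and the whole cohort is reproducible from ``master_seed``.
    """
    targets = draw_cohort_targets(spec)
    samples: list[CohortSample] = []
    for _, row in targets.iterrows():
        try:
            tpaf_params = TpafPhantomParams(
                image_shape=spec.image_shape,
                n_nuclei=spec.n_nuclei,
                nucleus_area_mean_px2=row.target_nuclear_area_px2,
                nucleus_area_sd_px2=spec.within_sample_area_cv
                * row.target_nuclear_area_px2,
                seed=int(row.seed) ^ 0x55555,
            )
            tpaf, labels = generate_tpaf(tpaf_params)
            shg_params = ShgPhantomParams(
                image_shape=spec.image_shape,
                target_collagen_fraction_pct=row.target_collagen_pct,
                seed=int(row.seed) ^ 0x2AAAA,
            )
            shg, gt_mask = generate_shg(shg_params)
        except (GenerationError, PlacementError) as exc:
            raise GenerationError(f"sample {row.sample_id}: {exc}") from exc
        samples.append(
            CohortSample(
                sample_id=row.sample_id,
                group=row.group,
                seed=int(row.seed),
                tpaf=tpaf,
                nucleus_labels=labels,
                shg=shg,
                collagen_mask=gt_mask,
                target_nuclear_area_px2=float(row.target_nuclear_area_px2),
                target_collagen_pct=float(row.target_collagen_pct),
                achieved_collagen_pct=gt_mask.foreground_fraction_pct,
            )
        )
    return samples
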