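"""Ground-truthed synthetic droplet scenes.

Renders what the in-box camera sees: bright circular spots (droplet
stains turned transparent) on a dark carrier whose background level
follows the Beer-Lambert transmittance of the dry ink.  The spot versus
background contrast is therefore a monotone function of both the
ambient illumination and the ink thickness, which is exactly the
coupling the contrast-adaptation agent is trained against.

Geometry is sampled once per seed: droplet radii are lognormal, a
configurable fraction of droplets is placed as overlapping ("adhesive")
pairs at centre distance (r1 + r2) * U(0.6, 0.95), and the rest are kept
disjoint.  Disks are rendered with 4x supersampling so that circularity
statistics are stable even at small radii, then Gaussian pixel noise is
added.  Every scene carries its full ground truth (centres, radii,
adhesion pairs, analytic coverage) so each pipeline stage can be scored
without hardware.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .optics import DEFAULT_TAU_MEAN, transmitted_intensity
from .segment import CarrierImage

__all__ = ["SceneSpec", "SyntheticScene", "generate_scene", "generate_illumination_series"]

_SUPERSAMPLE = 4


@dataclass
class SceneSpec:
    """Parameters of a synthetic deposition scene.

    Defaults emulate a moderate-flow pass on a 2.56 cm square window:
    200 droplets with lognormal radii around 5 px (~0.025 cm), 15% of
    droplets fused into adhesive pairs, ambient illumination in the
    3.5-3.6 kLx band and a 0.01 cm ink layer, with mild sensor noise.
    """

    width_px: int = 512
    height_px: int = 512
    scale_cm_per_px: float = 0.005
    n_droplets: int = 200
    radius_median_px: float = 5.0
    radius_sigma: float = 0.25  # lognormal sigma in log-space
    min_radius_px: float = 2.0
    adhesion_fraction: float = 0.15
    illumination_lx: float = 3550.0
    ink_thickness_cm: float = 0.01
    tau_mean: float = DEFAULT_TAU_MEAN
    camera_full_scale_lx: float = 4000.0
    noise_sd: float = 0.02
    seed: int = 0
    max_place_tries: int = 5000

    def __post_init__(self) -> None:
        if not 0.0 <= self.adhesion_fraction <= 1.0:
            raise ValueError("adhesion_fraction must be in [0, 1]")
        if self.min_radius_px < 1.0:
            raise ValueError("radii below 1 px are not resolvable")
        if self.n_droplets < 0:
            raise ValueError("n_droplets must be >= 0")


@dataclass
class SyntheticScene:
    """A rendered carrier image together with its generating truth."""

    image: CarrierImage
    truth_centers: np.ndarray  # (N, 2) row, col
    truth_radii: np.ndarray  # (N,)
    truth_adhesion_pairs: List[Tuple[int, int]] = field(default_factory=list)
    truth_n: int = 0
    truth_coverage_pct: float = 0.0
    truth_mask: Optional[np.ndarray] = None


def _sample_radius(spec: SceneSpec, rng: np.random.Generator) -> float:
    r = float(
        np.exp(rng.normal(math.log(spec.radius_median_px), spec.radius_sigma))
    )
    return max(r, spec.min_radius_px)


def _overlaps(
    y: float, x: float, r: float,
    centers: List[Tuple[float, float]], radii: List[float],
    skip: Optional[int] = None, buffer_px: float = 2.0,
) -> bool:
    for k, ((cy, cx), cr) in enumerate(zip(centers, radii)):
        if k == skip:
            continue
        if math.hypot(cy - y, cx - x) < r + cr + buffer_px:
            return True
    return False


def _sample_geometry(spec: SceneSpec, rng: np.random.Generator):
    """Place adhesive pairs then disjoint singles, with bounded retries."""
    n_pairs = round(spec.n_droplets * spec.adhesion_fraction / 2.0)
    n_singles = spec.n_droplets - 2 * n_pairs
    centers: List[Tuple[float, float]] = []
    radii: List[float] = []
    pairs: List[Tuple[int, int]] = []

    def _place(r: float, partner_of: Optional[int] = None) -> Tuple[float, float]:
        for _ in range(spec.max_place_tries):
            if partner_of is None:
                y = rng.uniform(r + 2, spec.height_px - r - 2)
                x = rng.uniform(r + 2, spec.width_px - r - 2)
            else:
                ay, ax = centers[partner_of]
                ar = radii[partner_of]
                dist = (r + ar) * rng.uniform(0.6, 0.95)
                ang = rng.uniform(0.0, 2.0 * math.pi)
                y = ay + dist * math.sin(ang)
                x = ax + dist * math.cos(ang)
                if not (r + 2 <= y <= spec.height_px - r - 2):
                    continue
                if not (r + 2 <= x <= spec.width_px - r - 2):
                    continue
            if not _overlaps(y, x, r, centers, radii, skip=partner_of):
                return y, x
        raise RuntimeError(
            f"could not place droplet after {spec.max_place_tries} tries: "
            "packing infeasible for this spec"
        )

    for _ in range(n_pairs):
        r1 = _sample_radius(spec, rng)
        y1, x1 = _place(r1)
        centers.append((y1, x1))
        radii.append(r1)
        i1 = len(centers) - 1
        r2 = _sample_radius(spec, rng)
        y2, x2 = _place(r2, partner_of=i1)
        centers.append((y2, x2))
        radii.append(r2)
        pairs.append((i1, len(centers) - 1))
    for _ in range(n_singles):
        r = _sample_radius(spec, rng)
        y, x = _place(r)
        centers.append((y, x))
        radii.append(r)
    return (
        np.asarray(centers, dtype=float).reshape(-1, 2),
        np.asarray(radii, dtype=float),
        pairs,
    )


def _render_mask_supersampled(
    centers: np.ndarray, radii: np.ndarray, spec: SceneSpec
) -> np.ndarray:
    """Boolean union of all disks on the 4x supersampled grid."""
    s = _SUPERSAMPLE
    H, W = spec.height_px * s, spec.width_px * s
    mask = np.zeros((H, W), dtype=bool)
    for (cy, cx), r in zip(centers, radii):
        # supersampled coordinates: pixel centres at (i + 0.5) / s
        cy_s, cx_s = cy * s, cx * s
        r_s = r * s
        y0 = max(int(cy_s - r_s) - 1, 0)
        y1 = min(int(cy_s + r_s) + 2, H)
        x0 = max(int(cx_s - r_s) - 1, 0)
        x1 = min(int(cx_s + r_s) + 2, W)
        yy = np.arange(y0, y1) + 0.5
        xx = np.arange(x0, x1) + 0.5
        d2 = (yy[:, None] - cy_s) ** 2 + (xx[None, :] - cx_s) ** 2
        mask[y0:y1, x0:x1] |= d2 <= r_s**2
    return mask


def _render(
    centers: np.ndarray,
    radii: np.ndarray,
    spec: SceneSpec,
    illumination_lx: float,
    noise_rng: np.random.Generator,
):
    """Rasterise the scene at a given ambient illumination."""
    s = _SUPERSAMPLE
    mask_ss = _render_mask_supersampled(centers, radii, spec)
    alpha = mask_ss.reshape(
        spec.height_px, s, spec.width_px, s
    ).mean(axis=(1, 3))
    cam = spec.camera_full_scale_lx
    bg = transmitted_intensity(illumination_lx, spec.ink_thickness_cm, spec.tau_mean) / cam
    sp = illumination_lx / cam
    bg, sp = min(bg, 1.0), min(sp, 1.0)
    img = bg + alpha * (sp - bg)
    if spec.noise_sd > 0:
        img = img + noise_rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    coverage_pct = 100.0 * float(mask_ss.mean())
    truth_mask = alpha >= 0.5
    return img, coverage_pct, truth_mask


def _noise_rng(seed: int, illumination_lx: float) -> np.random.Generator:
    """Noise stream derived from (seed, illumination) so that a
    one-element illumination series reproduces ``generate_scene``."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, int(round(illumination_lx * 1000))])
    )


def generate_scene(spec: SceneSpec | None = None) -> SyntheticScene:
    """Generate one reproducible scene with full ground truth."""
    spec = spec or SceneSpec()
    rng = np.random.default_rng(spec.seed)
    centers, radii, pairs = _sample_geometry(spec, rng)
    img, cov, tmask = _render(
        centers, radii, spec, spec.illumination_lx,
        _noise_rng(spec.seed, spec.illumination_lx),
    )
    image = CarrierImage(
        pixels=img,
        scale_cm_per_px=spec.scale_cm_per_px,
        illumination_lx=spec.illumination_lx,
        polarity="bright",
    )
    return SyntheticScene(
        image=image,
        truth_centers=centers,
        truth_radii=radii,
        truth_adhesion_pairs=pairs,
        truth_n=len(radii),
        truth_coverage_pct=cov,
        truth_mask=tmask,
    )


def generate_illumination_series(
    spec: SceneSpec | None = None,
    illum_values: Sequence[float] = (),
) -> List[SyntheticScene]:
    """Render one droplet layout under several ambient illuminations.

    Geometry (and hence all truth fields) is identical across the
    series; only the spot/background contrast and the noise realisation
    differ.  This is the training corpus for the contrast-adaptation
    agent.
    """
    spec = spec or SceneSpec()
    rng = np.random.default_rng(spec.seed)
    centers, radii, pairs = _sample_geometry(spec, rng)
    scenes = []
    for io in illum_values:
        img, cov, tmask = _render(
            centers, radii, spec, float(io), _noise_rng(spec.seed, float(io))
        )
        image = CarrierImage(
            pixels=img,
            scale_cm_per_px=spec.scale_cm_per_px,
            illumination_lx=float(io),
            polarity="bright",
        )
        scenes.append(
            SyntheticScene(
                image=image,
                truth_centers=centers,
                truth_radii=radii,
                truth_adhesion_pairs=pairs,
                truth_n=len(radii),
                truth_coverage_pct=cov,
                truth_mask=tmask,
            )
        )
    return scenes
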