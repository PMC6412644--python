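"""Deposition parameters computed from a segmentation result.

Spray quality is summarised by three numbers on the test window:
the droplet count N, the coverage C (% of the window area stained) and
the coverage density K = N / S in droplets per cm**2, where S is the
window area.  N counts regions after adhesive splitting and removal of
small protrusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np

from .segment import CarrierImage, RegionFeatures, SegmentationResult

__all__ = [
    "DepositionReport",
    "coverage",
    "coverage_density",
    "image_area_cm2",
    "build_report",
    "evaluate_against_truth",
]


@dataclass
class DepositionReport:
    """Deposition summary: count, coverage %, density, per-region table."""

    n_droplets: int
    coverage_pct: float
    coverage_density: float  # droplets per cm**2
    image_area_cm2: float
    per_region: List[RegionFeatures] = field(default_factory=list)


def coverage(binary: np.ndarray) -> float:
    """Stained fraction of the window, in percent."""
    binary = np.asarray(binary, dtype=bool)
    if binary.size == 0:
        raise ValueError("empty mask")
    return 100.0 * float(binary.mean())


def coverage_density(n: int, image_area_cm2: float) -> float:
    """Droplet count per cm**2 of test window."""
    if image_area_cm2 <= 0:
        raise ValueError(f"image area must be > 0, got {image_area_cm2}")
    return n / image_area_cm2


def image_area_cm2(shape: tuple, scale_cm_per_px: float) -> float:
    """Physical window area from pixel geometry and the cm/px scale."""
    if scale_cm_per_px <= 0:
        raise ValueError("scale must be > 0")
    h, w = shape[:2]
    return h * w * scale_cm_per_px**2


def build_report(
    result: SegmentationResult, image: CarrierImage
) -> DepositionReport:
    """Assemble the deposition report for a segmented carrier image."""
    area = image.area_cm2
    n = result.n_droplets
    return DepositionReport(
        n_droplets=n,
        coverage_pct=coverage(result.labels > 0),
        coverage_density=coverage_density(n, area),
        image_area_cm2=area,
        per_region=result.regions,
    )


def evaluate_against_truth(result: SegmentationResult, truth) -> dict:
    """Score a segmentation against generator ground truth.

    Detected regions are matched one-to-one to truth droplets: a region
    may match a droplet whose disk contains the region centroid, and
    candidate matches are assigned greedily by centroid-to-centre
    distance.  Returns percentages: count error, false positives
    (unmatched detections / detections), false negatives (missed truth
    droplets / truth count) and the absolute coverage error in points.
    """
    if result.labels.shape != truth.image.pixels.shape[:2]:
        raise ValueError("segmentation and truth geometry differ")
    centers = np.asarray(truth.truth_centers, dtype=float).reshape(-1, 2)
    radii = np.asarray(truth.truth_radii, dtype=float)
    n_true = len(radii)
    n_det = result.n_droplets

    pairs = []  # (distance, det_index, truth_index)
    for i, reg in enumerate(result.regions):
        cy, cx = reg.centroid
        if n_true:
            dists = np.hypot(centers[:, 0] - cy, centers[:, 1] - cx)
            for j in np.nonzero(dists <= radii)[0]:
                pairs.append((dists[j], i, int(j)))
    pairs.sort(key=lambda t: t[0])
    det_used: set = set()
    true_used: set = set()
    for _, i, j in pairs:
        if i in det_used or j in true_used:
            continue
        det_used.add(i)
        true_used.add(j)

    fp = 100.0 * (n_det - len(det_used)) / n_det if n_det else 0.0
    fn = 100.0 * (n_true - len(true_used)) / n_true if n_true else 0.0
    count_err = 100.0 * abs(n_det - n_true) / n_true if n_true else float(n_det > 0) * 100.0
    cov_err = abs(coverage(result.labels > 0) - truth.truth_coverage_pct)
    return {
        "n_detected": n_det,
        "n_true": n_true,
        "count_error_pct": count_err,
        "false_positive_pct": fp,
        "false_negative_pct": fn,
        "coverage_error_pct_points": cov_err,
    }
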