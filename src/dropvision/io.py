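"""Raster and report I/O.

Images are exchanged as PNG/TIFF/JPEG and normalised to float in [0, 1]
on read.  Physical metadata (cm/px scale, illumination, polarity) lives
in a JSON sidecar next to the image (``<image>.meta.json``) rather than
in EXIF tags, which keeps it format-agnostic and human-editable; CLI
flags override the sidecar.  Reports are written as versioned JSON plus
a per-region CSV.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .metrics import DepositionReport
from .segment import CarrierImage, RegionFeatures, SegmentationResult

__all__ = [
    "read_image",
    "write_image",
    "sidecar_path",
    "write_sidecar",
    "write_report",
    "read_report",
    "write_region_csv",
    "write_label_png",
    "write_overlay_png",
]

REPORT_SCHEMA_VERSION = 1


def sidecar_path(image_path: str | Path) -> Path:
    return Path(str(image_path) + ".meta.json")


def write_sidecar(
    image_path: str | Path,
    scale_cm_per_px: float,
    illumination_lx: Optional[float] = None,
    polarity: str = "dark",
) -> Path:
    p = sidecar_path(image_path)
    p.write_text(
        json.dumps(
            {
                "scale_cm_per_px": scale_cm_per_px,
                "illumination_lx": illumination_lx,
                "polarity": polarity,
            },
            indent=2,
        )
    )
    return p


def _normalize(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError(f"float image {path} not in [0, 1]")
        return arr.astype(float)
    raise ValueError(f"unsupported bit depth {arr.dtype} in {path}")


def read_image(
    path: str | Path,
    scale_cm_per_px: Optional[float] = None,
    illumination_lx: Optional[float] = None,
    polarity: Optional[str] = None,
) -> CarrierImage:
    """Load a carrier raster; metadata from flags, then sidecar, then defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise ValueError(f"could not read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]  # drop alpha
    px = _normalize(arr, path)

    meta = {}
    sp = sidecar_path(path)
    if sp.exists():
        meta = json.loads(sp.read_text())
    scale = scale_cm_per_px or meta.get("scale_cm_per_px")
    if scale is None:
        warnings.warn(
            f"no scale for {path}; assuming 1 cm/px", stacklevel=2
        )
        scale = 1.0
    return CarrierImage(
        pixels=px,
        scale_cm_per_px=float(scale),
        illumination_lx=(
            illumination_lx
            if illumination_lx is not None
            else meta.get("illumination_lx")
        ),
        polarity=polarity or meta.get("polarity", "dark"),
    )


def write_image(image: CarrierImage, path: str | Path, bits: int = 16) -> None:
    """Write the raster as 8- or 16-bit PNG/TIFF."""
    if bits == 16:
        arr = np.round(image.pixels * 65535.0).astype(np.uint16)
    elif bits == 8:
        arr = np.round(image.pixels * 255.0).astype(np.uint8)
    else:
        raise ValueError("bits must be 8 or 16")
    iio.imwrite(Path(path), arr)


def write_label_png(result: SegmentationResult, path: str | Path) -> None:
    """Write the label raster as a 16-bit PNG (label 0 = background)."""
    labels = result.labels
    if labels.max() > 65535:
        raise ValueError("more than 65535 regions; cannot encode as 16-bit PNG")
    iio.imwrite(Path(path), labels.astype(np.uint16))


def write_overlay_png(
    result: SegmentationResult, image: CarrierImage, path: str | Path
) -> None:
    """Label-to-colour overlay of the segmentation on the grayscale image."""
    from skimage.color import label2rgb

    px = image.pixels
    gray = px if px.ndim == 2 else px @ np.array([0.299, 0.587, 0.114])
    rgb = label2rgb(result.labels, image=gray, bg_label=0)
    iio.imwrite(Path(path), np.round(rgb * 255.0).astype(np.uint8))


def _region_frame(regions: list[RegionFeatures]) -> pd.DataFrame:
    cols = ["label", "area_px", "perimeter_px", "shape_degree", "is_adhesive",
            "centroid_row", "centroid_col"]
    rows = [
        {
            "label": r.label,
            "area_px": r.area_px,
            "perimeter_px": r.perimeter_px,
            "shape_degree": r.shape_degree,
            "is_adhesive": r.is_adhesive,
            "centroid_row": r.centroid[0],
            "centroid_col": r.centroid[1],
        }
        for r in regions
    ]
    return pd.DataFrame(rows, columns=cols)


def write_region_csv(regions: list[RegionFeatures], path: str | Path) -> None:
    _region_frame(regions).to_csv(path, index=False)


def write_report(report: DepositionReport, path: str | Path) -> None:
    """Serialise a deposition report to JSON (plus a per-region CSV).

    ``path`` is the JSON file; the CSV is written next to it with a
    ``.regions.csv`` suffix.
    """
    path = Path(path)
    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "n_droplets": report.n_droplets,
        "coverage_pct": report.coverage_pct,
        "coverage_density_per_cm2": report.coverage_density,
        "image_area_cm2": report.image_area_cm2,
    }
    path.write_text(json.dumps(payload, indent=2))
    write_region_csv(report.per_region, path.with_suffix(".regions.csv"))


def read_report(path: str | Path) -> DepositionReport:
    """Read back a JSON report (per-region table from the sibling CSV)."""
    path = Path(path)
    d = json.loads(path.read_text())
    if d.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValueError(f"unsupported report schema: {d.get('schema_version')}")
    regions = []
    csv_path = path.with_suffix(".regions.csv")
    if csv_path.exists():
        df = pd.read_csv(csv_path)
        regions = [
            RegionFeatures(
                label=int(row.label),
                area_px=int(row.area_px),
                perimeter_px=float(row.perimeter_px),
                shape_degree=float(row.shape_degree),
                is_adhesive=bool(row.is_adhesive),
                centroid=(float(row.centroid_row), float(row.centroid_col)),
            )
            for row in df.itertuples()
        ]
    return DepositionReport(
        n_droplets=int(d["n_droplets"]),
        coverage_pct=float(d["coverage_pct"]),
        coverage_density=float(d["coverage_density_per_cm2"]),
        image_area_cm2=float(d["image_area_cm2"]),
        per_region=regions,
    )
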