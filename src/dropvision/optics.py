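"""Beer-Lambert optics of the achromatic-ink deposition carrier.

The deposition carrier is a silicone-oil paper screen-printed with an
achromatic ink that turns transparent on contact with water.  Inside the
(otherwise dark) detection box the dry ink layer attenuates ambient light
according to the Beer-Lambert law,

    A = log10(Io / It) = tau * L,

where ``Io`` is the ambient illumination (Lx) outside the carrier, ``It``
the illumination transmitted into the box, ``L`` the ink thickness (cm)
and ``tau`` the absorbance per centimetre of the dry ink (the product of
its absorption coefficient and concentration, constant once dry).

Droplet separation is insensitive to ambient light once the transmitted
level falls below ~50 Lx, so the carrier thickness is chosen per
deployment by inverting the law at that target:

    L = (1 / tau) * log10(Io / 50).

``tau`` is a property of the ink batch; the default ``DEFAULT_TAU_MEAN``
is a bench calibration averaged over several illumination levels and is
overridable through :class:`InkModel` or the pipeline configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "DEFAULT_TAU_MEAN",
    "DEFAULT_IT_THRESHOLD_LX",
    "InkModel",
    "LightReading",
    "absorbance",
    "transmitted_intensity",
    "required_thickness",
    "fit_tau_mean",
]

#: Calibrated mean absorbance per cm of the dry achromatic ink.
DEFAULT_TAU_MEAN = 257.11

#: Transmitted-light target (Lx) below which segmentation is
#: illumination-independent.
DEFAULT_IT_THRESHOLD_LX = 50.0


@dataclass(frozen=True)
class InkModel:
    """Dry-ink absorbance model.

    Parameters
    ----------
    tau_mean:
        Absorbance per centimetre of ink (dimensionless / cm), > 0.
    it_threshold:
        Transmitted-light target in Lx, > 0.
    """

    tau_mean: float = DEFAULT_TAU_MEAN
    it_threshold: float = DEFAULT_IT_THRESHOLD_LX

    def __post_init__(self) -> None:
        if not self.tau_mean > 0:
            raise ValueError(f"tau_mean must be > 0, got {self.tau_mean}")
        if not self.it_threshold > 0:
            raise ValueError(
                f"it_threshold must be > 0, got {self.it_threshold}"
            )


@dataclass(frozen=True)
class LightReading:
    """One calibration measurement.

    ``io`` is the ambient illumination (Lx); ``li`` is the ink thickness
    (cm) at which the light transmitted into the box equals the target
    threshold.
    """

    io: float
    li: float


def absorbance(io: float, it: float) -> float:
    """Decadic absorbance ``log10(io / it)`` of the ink layer.

    Zero when the layer transmits all light (``io == it``).
    """
    if io <= 0 or it <= 0:
        raise ValueError(f"intensities must be positive, got io={io}, it={it}")
    return math.log10(io / it)


def transmitted_intensity(io: float, thickness: float, tau: float) -> float:
    """Light level (Lx) behind an ink layer of the given thickness (cm).

    Inverse of the absorbance relation: ``io * 10**(-tau * thickness)``.
    Equals ``io`` at zero thickness and decreases monotonically with
    thickness.
    """
    if io < 0:
        raise ValueError(f"io must be >= 0, got {io}")
    if thickness < 0:
        raise ValueError(f"thickness must be >= 0, got {thickness}")
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    return io * 10.0 ** (-tau * thickness)


def required_thickness(io: float, model: InkModel | None = None) -> float:
    """Minimum ink thickness (cm) that darkens the box to the target level.

    Solves the Beer-Lambert law for thickness at transmitted light equal
    to ``model.it_threshold``.  Strictly increasing in ``io``.

    Raises
    ------
    ValueError
        If ``io`` does not exceed the transmitted-light threshold; the
        inversion is undefined there (no ink is needed), and clamping
        would mask a faulty illumination sensor.
    """
    model = model or InkModel()
    if io <= model.it_threshold:
        raise ValueError(
            f"io={io} Lx must exceed the transmitted-light threshold "
            f"({model.it_threshold} Lx)"
        )
    return absorbance(io, model.it_threshold) / model.tau_mean


def fit_tau_mean(
    readings: Sequence[LightReading] | Iterable[LightReading],
    it_threshold: float = DEFAULT_IT_THRESHOLD_LX,
) -> float:
    """Calibrate the mean ink absorbance from bench measurements.

    Each reading pairs an ambient level ``io`` with the thickness ``li``
    at which the transmitted light hits ``it_threshold``; the per-reading
    absorbance coefficients ``log10(io / it_threshold) / li`` are
    averaged arithmetically.
    """
    readings = list(readings)
    if not readings:
        raise ValueError("at least one calibration reading is required")
    taus = []
    for rd in readings:
        if rd.li <= 0:
            raise ValueError(f"ink thickness must be > 0, got {rd.li}")
        if rd.io <= it_threshold:
            raise ValueError(
                f"reading io={rd.io} Lx does not exceed the threshold "
                f"{it_threshold} Lx"
            )
        taus.append(absorbance(rd.io, it_threshold) / rd.li)
    return sum(taus) / len(taus)
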