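"""Five-band reflectance primitives.

The sensor model is a five-band multispectral camera with nominal central
wavelengths 475 (blue), 560 (green), 668 (red), 717 (red edge) and 842 nm
(near infrared).  Many published vegetation indices are defined on narrowband
reflectance (e.g. 705 or 750 nm); :func:`resolve_band` maps such literature
wavelengths onto the nearest sensor band through a fixed, explicit table so
that every index formula in the registry is stated unambiguously in terms of
the five bands actually measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["BandSet", "BAND_NAMES", "NOMINAL_WAVELENGTHS_NM", "resolve_band"]

BAND_NAMES = ("blue", "green", "red", "rededge", "nir")

NOMINAL_WAVELENGTHS_NM = {
    "blue": 475,
    "green": 560,
    "red": 668,
    "rededge": 717,
    "nir": 842,
}

#: Narrowband literature wavelength -> sensor band.  Fixed by design; an
#: unmapped wavelength is a configuration error, never a silent nearest-match.
WAVELENGTH_TABLE = {
    445: "blue",
    475: "blue",
    531: "green",
    550: "green",
    560: "green",
    668: "red",
    670: "red",
    700: "rededge",
    705: "rededge",
    710: "rededge",
    717: "rededge",
    750: "nir",
    800: "nir",
    842: "nir",
    850: "nir",
}

_SENSOR_RANGE_NM = (400, 900)


class BandValidationError(ValueError):
    """A reflectance value is non-finite or outside [0, 1]."""


class WavelengthError(KeyError):
    """A requested wavelength has no configured sensor-band mapping."""


@dataclass(frozen=True)
class BandSet:
    """One five-band reflectance vector (pixel or plot mean).

    All values are unitless reflectance fractions in [0, 1]; construction
    validates this so downstream index arithmetic never sees raw digital
    numbers or NaNs.
    """

    blue: float
    green: float
    red: float
    rededge: float
    nir: float

    def __post_init__(self) -> None:
        for name in BAND_NAMES:
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise BandValidationError(
                    f"band {name!r} must be a finite number, got {value!r}"
                )
            if not 0.0 <= value <= 1.0:
                raise BandValidationError(
                    f"band {name!r} reflectance {value} outside [0, 1]; "
                    "calibrate digital numbers before building a BandSet"
                )

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.blue, self.green, self.red, self.rededge, self.nir)


def resolve_band(requested_wavelength_nm: float) -> str:
    """Map a narrowband literature wavelength (nm) onto a sensor band name.

    Raises :class:`WavelengthError` for wavelengths outside the sensor's
    400-900 nm range, and for in-range wavelengths absent from the fixed
    mapping table (the error names the offending wavelength).
    """
    lo, hi = _SENSOR_RANGE_NM
    if not lo <= requested_wavelength_nm <= hi:
        raise WavelengthError(
            f"wavelength outside sensor range: {requested_wavelength_nm} nm "
            f"(sensor covers {lo}-{hi} nm)"
        )
    try:
        return WAVELENGTH_TABLE[int(requested_wavelength_nm)]
    except KeyError:
        raise WavelengthError(
            f"no sensor-band mapping configured for {requested_wavelength_nm} nm"
        ) from None
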