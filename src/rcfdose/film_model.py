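"""Optical response of radiochromic film.

The dose-dependent signal of a radiochromic film is the net optical
density

    netOD = OD_after - OD_before = -log10(I / I0),

where ``I0`` and ``I`` are the light intensities transmitted through the
unexposed and the irradiated film.  This module provides

* the netOD arithmetic and the %OD-dispersion statistic used to
  quantify field inhomogeneity,
* a forward dose -> netOD response (saturating rational plus linear
  term) used by the synthetic irradiators, and
* fifth-order polynomial calibration fitting and its numerical
  inversion, the standard workflow for converting netOD into absolute
  dose.

The forward response and the calibration machinery are deliberately
independent: a calibration is always *learned* from (dose, netOD)
samples, never copied from the generator's parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.polynomial import polynomial as npol
from scipy.optimize import brentq

from .exceptions import CalibrationError, DomainError, OutOfRangeError

__all__ = [
    "ODMap",
    "FilmResponse",
    "CalibrationCurve",
    "SCANNER_RED",
    "LED_GREEN",
    "net_od",
    "od_dispersion",
    "dose_to_netod",
    "fit_calibration",
    "invert_calibration",
]

#: polynomial degree of the dose calibration, fixed by protocol
CALIBRATION_DEGREE = 5


@dataclass
class ODMap:
    """A 2-D map of net optical density on film coordinates.

    Parameters
    ----------
    values
        2-D array of netOD (dimensionless).  Small negative values from
        read noise are legal; clamping happens only at reporting time.
    pixel_pitch
        Pixel size in mm (square pixels).
    origin
        Film-frame (x, y) position in mm of the centre of pixel
        ``values[0, 0]``.
    """

    values: np.ndarray
    pixel_pitch: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise DomainError("ODMap values must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("ODMap values must be finite everywhere")
        if np.any(self.values < -0.05):
            raise DomainError("ODMap contains values below -0.05; not noise")
        if not self.pixel_pitch > 0:
            raise DomainError("pixel_pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def extent_mm(self) -> tuple[float, float]:
        """(width, height) of the map in mm."""
        ny, nx = self.values.shape
        return nx * self.pixel_pitch, ny * self.pixel_pitch

    def mean(self) -> float:
        return float(self.values.mean())


@dataclass(frozen=True)
class FilmResponse:
    """Forward film response netOD(D) = a*D/(1 + b*D) + c*D.

    ``scale_a`` [netOD/Gy] sets the initial slope, ``saturation_b``
    [1/Gy] the curvature towards saturation and ``linear_c`` [netOD/Gy]
    a residual linear term keeping the response strictly increasing at
    high dose.  ``readout_tag`` names the colour channel the response
    refers to (the red scanner channel and the green LED channel of the
    photodetector array see different effective netOD).
    """

    scale_a: float = 0.115
    saturation_b: float = 0.08
    linear_c: float = 0.004
    readout_tag: str = "scanner_red"

    def __post_init__(self) -> None:
        if not self.scale_a > 0:
            raise DomainError("scale_a must be positive")
        if self.saturation_b < 0:
            raise DomainError("saturation_b must be non-negative")
        if self.linear_c < 0:
            raise DomainError("linear_c must be non-negative")


#: default response seen through the red channel of a flatbed scanner
SCANNER_RED = FilmResponse()
#: default response seen through the green LED / photoresistor channel
LED_GREEN = FilmResponse(scale_a=0.090, saturation_b=0.06, linear_c=0.003,
                         readout_tag="led_green")


def net_od(intensity_exposed, intensity_unexposed):
    """Net optical density, ``-log10(I / I0)``.

    Accepts scalars or equal-shaped arrays; arrays are processed
    elementwise.  Raises :class:`DomainError` naming the first offending
    index if any intensity is non-positive.
    """
    i = np.asarray(intensity_exposed, dtype=float)
    i0 = np.asarray(intensity_unexposed, dtype=float)
    if i.shape != i0.shape:
        try:
            i, i0 = np.broadcast_arrays(i, i0)
        except ValueError as exc:
            raise DomainError(
                f"intensity shapes {i.shape} and {i0.shape} do not match"
            ) from exc
    for name, arr in (("exposed", i), ("unexposed", i0)):
        bad = ~(arr > 0)
        if np.any(bad):
            idx = np.unravel_index(int(np.argmax(bad)), arr.shape)
            raise DomainError(
                f"non-positive {name} intensity at index {tuple(int(k) for k in idx)}"
            )
    out = -np.log10(i / i0)
    if out.ndim == 0:
        return float(out)
    return out


def od_dispersion(od_map, reference: float):
    """Percentage OD dispersion about a reference netOD.

    Each element is ``100 * |netOD - reference| / reference``; the
    second return value is the maximum over the map.  The reference is
    typically the film-mean netOD.
    """
    if not reference > 0:
        raise DomainError("reference netOD must be positive")
    vals = od_map.values if isinstance(od_map, ODMap) else np.asarray(od_map, float)
    disp = 100.0 * np.abs(vals - reference) / reference
    return disp, float(disp.max())


def dose_to_netod(dose, response: FilmResponse = SCANNER_RED):
    """Forward film response: netOD = a*D/(1 + b*D) + c*D, D in Gy."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise DomainError("dose must be non-negative")
    out = response.scale_a * d / (1.0 + response.saturation_b * d) + response.linear_c * d
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class CalibrationCurve:
    """A fifth-order polynomial relation value(dose) with validity range.

    ``coefficients`` are in ascending order (constant term first).  The
    curve is guaranteed strictly monotone over ``dose_range`` by
    :func:`fit_calibration`; ``increasing`` records the direction
    (netOD curves rise with dose, photodetector count curves fall).
    """

    coefficients: np.ndarray
    dose_range: tuple[float, float]
    residual_rms: float
    n_points: int
    increasing: bool = True

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        lo, hi = self.dose_range
        if not hi > lo:
            raise CalibrationError("dose_range must be a non-degenerate interval")
        self.dose_range = (float(lo), float(hi))

    def __call__(self, dose):
        out = npol.polyval(np.asarray(dose, dtype=float), self.coefficients)
        if np.ndim(out) == 0:
            return float(out)
        return out

    def value_bounds(self) -> tuple[float, float]:
        """(min, max) of the curve value over the dose range."""
        lo, hi = self.dose_range
        a, b = self(lo), self(hi)
        return (a, b) if a <= b else (b, a)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "coefficients": [float(c) for c in self.coefficients],
            "dose_range": list(self.dose_range),
            "residual_rms": float(self.residual_rms),
            "n_points": int(self.n_points),
            "increasing": bool(self.increasing),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            coefficients=np.asarray(d["coefficients"], float),
            dose_range=tuple(d["dose_range"]),
            residual_rms=float(d["residual_rms"]),
            n_points=int(d["n_points"]),
            increasing=bool(d.get("increasing", True)),
        )

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        return cls.from_dict(json.loads(Path(path).read_text()))


#: largest tolerated counter-directional excursion of a fit, as a
#: fraction of its full span; guards inversion against wrong-branch
#: errors while not rejecting immaterial noise wiggles at the range ends
MONOTONE_EXCURSION_TOL = 0.005


def _monotone_direction(coeffs: np.ndarray, lo: float, hi: float,
                        n_check: int = 2048) -> int:
    """+1 / -1 for an (effectively) monotone polynomial over [lo, hi], else 0.

    A degree-5 least-squares fit through noisy readings can carry a tiny
    counter-directional ripple near the range ends; such a ripple is
    harmless for bracketed inversion (the dose ambiguity is bounded by
    the ripple's width), so the fit is only rejected when the summed
    excursion against the dominant direction exceeds
    ``MONOTONE_EXCURSION_TOL`` of the fitted span.
    """
    grid = np.linspace(lo, hi, n_check)
    vals = npol.polyval(grid, coeffs)
    inc = np.diff(vals)
    up = float(inc[inc > 0].sum())
    down = float(-inc[inc < 0].sum())
    span = max(up, down)
    if span == 0:
        return 0
    if min(up, down) > MONOTONE_EXCURSION_TOL * span:
        return 0
    return 1 if up >= down else -1


def fit_calibration(doses, values, dose_range: tuple[float, float] | None = None
                    ) -> CalibrationCurve:
    """Least-squares fifth-order polynomial fit value(dose).

    Requires at least 7 distinct dose points (degree + 2).  The fit is
    rejected with a :class:`CalibrationError` if it is not strictly
    monotone over the dose range, because a non-monotone curve cannot be
    inverted on a single branch; the fix is denser dose sampling.
    """
    d = np.asarray(doses, dtype=float)
    v = np.asarray(values, dtype=float)
    if d.ndim != 1 or d.shape != v.shape:
        raise CalibrationError("doses and values must be equal-length 1-D sequences")
    if not (np.all(np.isfinite(d)) and np.all(np.isfinite(v))):
        raise CalibrationError("calibration data must be finite")
    if np.unique(d).size < CALIBRATION_DEGREE + 2:
        raise CalibrationError(
            f"need at least {CALIBRATION_DEGREE + 2} distinct dose points, "
            f"got {np.unique(d).size}"
        )
    coeffs = npol.polyfit(d, v, CALIBRATION_DEGREE)
    resid = npol.polyval(d, coeffs) - v
    rms = float(np.sqrt(np.mean(resid ** 2)))
    if dose_range is None:
        dose_range = (float(d.min()), float(d.max()))
    direction = _monotone_direction(coeffs, *dose_range)
    if direction == 0:
        raise CalibrationError(
            "fifth-order fit is not monotone over the dose range; "
            "sample the dose range more densely or narrow it"
        )
    return CalibrationCurve(
        coefficients=coeffs,
        dose_range=dose_range,
        residual_rms=rms,
        n_points=int(d.size),
        increasing=direction > 0,
    )


def invert_calibration(curve: CalibrationCurve, value: float) -> float:
    """Unique dose with curve(dose) == value, by bracketed root finding.

    Monotonicity over the dose range is guaranteed by
    :func:`fit_calibration`, so the bracket [Gy_min, Gy_max] contains
    exactly one root.  Tolerance 1e-9 Gy.  Values outside the curve's
    range raise :class:`OutOfRangeError` reporting the valid interval.
    """
    lo, hi = curve.dose_range
    vlo, vhi = curve(lo), curve(hi)
    vmin, vmax = (vlo, vhi) if vlo <= vhi else (vhi, vlo)
    value = float(value)
    # tolerate pure round-off at the interval edges
    eps = 1e-12 * max(1.0, abs(vmin), abs(vmax))
    if value < vmin - eps or value > vmax + eps:
        raise OutOfRangeError(
            f"value {value:.6g} outside calibrated interval "
            f"[{vmin:.6g}, {vmax:.6g}]"
        )
    value = min(max(value, vmin), vmax)
    if value == vlo:
        return lo
    if value == vhi:
        return hi
    return float(brentq(lambda x: curve(x) - value, lo, hi, xtol=1e-9))
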