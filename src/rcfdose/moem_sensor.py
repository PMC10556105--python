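"""Forward simulator of the opto-electronic film-reading device.

The device sandwiches an irradiated film between a 3x3 grid of green
LEDs and a 5x10 matrix of light-dependent resistors (LDRs, 5 mm
diameter).  Light transmitted through the film lowers each LDR's
resistance (``R = R0 * light**(-gamma)``); a divider plus a gain/offset
amplifier converts the resistance to a voltage that a multiplexed
12-bit ADC digitizes several times per LDR, storing the average to tame
glitch noise.  The film sees the array as its specular (left-right
mirrored) image.

Per-LDR manufacturing spread is modelled as a multiplicative voltage
gain factor; two array positions (#19 and #20 by default) carry
inflated read noise, emulating channels with anomalous error.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError, DomainError, GeometryError
from .film_model import FilmResponse, LED_GREEN, ODMap, dose_to_netod

__all__ = [
    "LDRParams",
    "SensorArray",
    "ADCFrame",
    "dosimoems_v1",
    "led_voltage",
    "film_transmission_over_ldr",
    "ldr_resistance",
    "ldr_voltage",
    "adc_quantize",
    "mirror_index",
    "ldr_film_position",
    "calibrate_gain",
    "scan_film",
]

_LIGHT_FLOOR = 1e-6


@dataclass(frozen=True)
class LDRParams:
    """Response parameters of one photoresistor.

    ``r0_ohm`` is the resistance at unit relative light, ``gamma`` the
    response exponent (R proportional to light**-gamma; gamma = 1 is
    exact inverse proportionality), ``gain_spread`` a multiplicative
    manufacturing factor on the output voltage.
    """

    r0_ohm: float = 10_000.0
    gamma: float = 0.8
    gain_spread: float = 1.0

    def __post_init__(self) -> None:
        if not self.r0_ohm > 0:
            raise ConfigurationError("r0_ohm must be positive")
        if not 0 < self.gamma <= 2:
            raise ConfigurationError("gamma must lie in (0, 2]")
        if not self.gain_spread > 0:
            raise ConfigurationError("gain_spread must be positive")


@dataclass(frozen=True)
class SensorArray:
    """Geometry and response configuration of the 5x10 LDR array.

    LDR indices are 1-based and row-major on the device: index 1 is row
    0 / column 0, index 10 ends row 0, index 50 ends row 4.  Device
    column ``c`` faces film-frame column ``n_cols - 1 - c`` (specular
    mapping).  The amplifier applies ``gain * (v_divider - offset)``,
    a fixed strictly monotone map whose two parameters are set by
    :func:`calibrate_gain` so irradiated films spanning 0-10 Gy cover
    the ADC range.
    """

    n_rows: int = 5
    n_cols: int = 10
    ldr_diameter: float = 5.0
    pitch: float = 6.0
    ldr_params: tuple[LDRParams, ...] = ()
    reference_ldr: int = 1
    led_levels: tuple[int, ...] = (255,) * 9
    amplifier_gain: float = 1.0
    amplifier_offset_v: float = 0.0
    vref: float = 3.3
    adc_bits: int = 12
    reads_per_ldr: int = 16
    glitch_sigma: float = 0.01
    bad_ldrs: frozenset = frozenset({19, 20})
    bad_noise_factor: float = 5.0
    source_voltage: float = 3.3
    divider_r_ohm: float = 10_000.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigurationError("array must have at least one row and column")
        if not (self.ldr_diameter > 0 and self.pitch > 0):
            raise ConfigurationError("diameter and pitch must be positive")
        if not self.ldr_params:
            object.__setattr__(
                self, "ldr_params", tuple(LDRParams() for _ in range(self.n_ldrs))
            )
        if len(self.ldr_params) != self.n_ldrs:
            raise ConfigurationError(
                f"need {self.n_ldrs} LDR parameter sets, got {len(self.ldr_params)}"
            )
        if len(self.led_levels) != 9:
            raise ConfigurationError("led_levels is the 3x3 LED drive grid (9 values)")
        for lv in self.led_levels:
            if not (isinstance(lv, (int, np.integer)) and 0 <= lv <= 255):
                raise ConfigurationError("LED drive levels are integers in [0, 255]")
        if not 1 <= self.reference_ldr <= self.n_ldrs:
            raise ConfigurationError("reference_ldr outside the array")
        if self.reads_per_ldr < 1:
            raise ConfigurationError("reads_per_ldr must be >= 1")

    @property
    def n_ldrs(self) -> int:
        return self.n_rows * self.n_cols

    def row_col(self, index: int) -> tuple[int, int]:
        self._check_index(index)
        return (index - 1) // self.n_cols, (index - 1) % self.n_cols

    def _check_index(self, index: int) -> None:
        if not 1 <= index <= self.n_ldrs:
            raise ConfigurationError(
                f"LDR index {index} outside 1..{self.n_ldrs}"
            )

    def params(self, index: int) -> LDRParams:
        self._check_index(index)
        return self.ldr_params[index - 1]

    @property
    def top_rows_indices(self) -> tuple[int, ...]:
        """Indices of the top two rows - the LDRs used in film experiments."""
        return tuple(range(1, 2 * self.n_cols + 1))

    @property
    def led_drive(self) -> float:
        """Array-mean relative LED illumination (mean drive level / 255)."""
        return float(np.mean(self.led_levels)) / 255.0

    def led_drive_at(self, index: int) -> float:
        """Relative illumination over one LDR.

        The 3x3 LED grid spans the array; the local drive is the
        bilinear interpolation of the drive levels at the LDR's
        fractional position.  Equal levels give a uniform field.
        """
        levels = np.asarray(self.led_levels, float).reshape(3, 3) / 255.0
        if np.all(levels == levels[0, 0]):
            return float(levels[0, 0])
        row, col = self.row_col(index)
        u = col / (self.n_cols - 1) if self.n_cols > 1 else 0.5
        v = row / (self.n_rows - 1) if self.n_rows > 1 else 0.5
        grid = np.array([0.0, 0.5, 1.0])
        cols = np.array([np.interp(u, grid, levels[r]) for r in range(3)])
        return float(np.interp(v, grid, cols))


def led_voltage(level: int) -> float:
    """LED drive voltage: 0-3 V in 256 integer steps (level * 3 / 255)."""
    if not (isinstance(level, (int, np.integer)) and 0 <= level <= 255):
        raise ConfigurationError(f"LED level must be an integer in [0, 255], got {level!r}")
    return level * 3.0 / 255.0


def mirror_index(index: int, array: SensorArray) -> int:
    """Device index facing the same film spot: column mirrored, row kept.

    The film sees the array as its specular image, so device column c
    maps to film column ``n_cols - 1 - c``.  Applying the map twice is
    the identity.
    """
    row, col = array.row_col(index)
    return row * array.n_cols + (array.n_cols - 1 - col) + 1


def ldr_film_position(index: int, array: SensorArray) -> tuple[float, float]:
    """Film-frame (x, y) centre [mm] of an LDR's footprint (mirrored)."""
    row, col = array.row_col(index)
    x = (array.n_cols - 1 - col) * array.pitch + array.pitch / 2.0
    y = row * array.pitch + array.pitch / 2.0
    return x, y


#: subsampling factor for the circle/pixel coverage weights
_APERTURE_SUBSAMPLE = 5


def film_transmission_over_ldr(od_map: ODMap, center_mm: tuple[float, float],
                               diameter: float) -> tuple[float, bool]:
    """Mean transmission 10**(-netOD) over a circular footprint.

    Pixels partially covered by the circle are weighted by their covered
    area fraction (estimated on a 5x5 subgrid), so the average converges
    to the true aperture integral independently of the map's pixel
    pitch.  Returns (mean transmission, boundary flag); the flag is set
    when the footprint is clipped at the film edge (an LDR straddling
    the boundary integrates a partial aperture).  A footprint wholly
    outside the film raises :class:`GeometryError`.
    """
    if diameter <= 0:
        raise GeometryError("footprint diameter must be positive")
    cx, cy = center_mm
    r = diameter / 2.0
    ny, nx = od_map.shape
    pitch = od_map.pixel_pitch
    ox, oy = od_map.origin
    # bounding box of the footprint in pixel indices
    c0 = max(int(np.floor((cx - r - ox) / pitch)), 0)
    c1 = min(int(np.ceil((cx + r - ox) / pitch)), nx)
    r0 = max(int(np.floor((cy - r - oy) / pitch)), 0)
    r1 = min(int(np.ceil((cy + r - oy) / pitch)), ny)
    if c1 <= c0 or r1 <= r0:
        raise GeometryError(
            f"LDR footprint at ({cx:.1f}, {cy:.1f}) mm lies outside the film"
        )
    m = _APERTURE_SUBSAMPLE
    sub = (np.arange(m) + 0.5) / m
    xs = ox + (c0 + np.add.outer(np.arange(c1 - c0), sub).ravel()) * pitch
    ys = oy + (r0 + np.add.outer(np.arange(r1 - r0), sub).ravel()) * pitch
    inside = ((xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2) <= r ** 2
    # covered-area fraction per pixel
    weights = inside.reshape(r1 - r0, m, c1 - c0, m).mean(axis=(1, 3))
    wsum = weights.sum()
    if wsum == 0:
        raise GeometryError(
            f"LDR footprint at ({cx:.1f}, {cy:.1f}) mm lies outside the film"
        )
    xmin, xmax = ox, ox + nx * pitch
    ymin, ymax = oy, oy + ny * pitch
    boundary = (cx - r < xmin or cx + r > xmax or cy - r < ymin or cy + r > ymax)
    block = 10.0 ** (-od_map.values[r0:r1, c0:c1])
    mean_t = float((weights * block).sum() / wsum)
    return mean_t, boundary


def ldr_resistance(light: float, params: LDRParams) -> float:
    """Photoresistor resistance R0 * light**(-gamma), floored in darkness."""
    if light < 0:
        raise DomainError("light must be >= 0")
    return params.r0_ohm * max(light, _LIGHT_FLOOR) ** (-params.gamma)


def _divider_voltage(resistance: float, array: SensorArray) -> float:
    """Voltage across the fixed divider resistor (rises as R falls)."""
    return array.source_voltage * array.divider_r_ohm / (array.divider_r_ohm + resistance)


def ldr_voltage(light: float, params: LDRParams, array: SensorArray) -> float:
    """Output voltage of one LDR channel, strictly increasing in light.

    Chain: resistance R = R0*light**-gamma, divider
    ``Vs * Rf / (Rf + R)``, then the amplifier's fixed monotone map
    ``gain * (v - offset)`` and the per-LDR manufacturing gain factor.
    Clamped at 0 V (the ADC cannot see negative voltages).
    """
    v_div = _divider_voltage(ldr_resistance(light, params), array)
    v = array.amplifier_gain * (v_div - array.amplifier_offset_v) * params.gain_spread
    return max(v, 0.0)


def adc_quantize(voltage: float, vref: float, bits: int = 12) -> int:
    """12-bit quantization: floor(2**bits * v / vref), clamped to the range."""
    if not vref > 0:
        raise DomainError("vref must be positive")
    n_codes = 2 ** bits
    code = math.floor(n_codes * voltage / vref)
    return int(min(max(code, 0), n_codes - 1))


def calibrate_gain(array: SensorArray, response: FilmResponse = LED_GREEN,
                   dose_span: tuple[float, float] = (0.0, 10.0),
                   code_span: tuple[float, float] = (0.06, 0.88)) -> SensorArray:
    """Set amplifier gain and offset so films spanning ``dose_span`` cover
    the ADC range.

    Mimics the device's gain-setting procedure: the ADC input for a
    nominal (spread-free) LDR reading an unirradiated film is placed at
    ``code_span[1]`` of full scale and for a film at the top dose at
    ``code_span[0]``.  The upper point leaves ~12 % headroom so channels
    with a +10 % manufacturing gain factor do not clip against the ADC
    ceiling (a clipped channel's calibration curve flattens and becomes
    uninvertible).  Returns a new array; the input is unchanged.
    """
    nominal = LDRParams()
    v_hi = _divider_voltage(
        ldr_resistance(array.led_drive * 10 ** (-dose_to_netod(dose_span[0], response)),
                       nominal), array)
    v_lo = _divider_voltage(
        ldr_resistance(array.led_drive * 10 ** (-dose_to_netod(dose_span[1], response)),
                       nominal), array)
    if not v_hi > v_lo:
        raise ConfigurationError("degenerate dose span: no voltage swing to calibrate")
    lo_t, hi_t = code_span
    gain = (hi_t - lo_t) * array.vref / (v_hi - v_lo)
    offset = v_lo - lo_t * array.vref / gain
    return replace(array, amplifier_gain=float(gain), amplifier_offset_v=float(offset))


def dosimoems_v1(seed: int = 20210301, spread: float = 0.10,
                 response: FilmResponse = LED_GREEN) -> SensorArray:
    """The default 5x10 device preset.

    Per-LDR manufacturing gain factors are drawn uniformly in
    ``1 +/- spread`` from ``seed`` (the reference LDR keeps factor 1 so
    normalized calibrations have an exact anchor), and the amplifier is
    span-calibrated for 0-10 Gy films through ``response``.
    """
    rng = np.random.default_rng(seed)
    base = SensorArray()
    factors = rng.uniform(1.0 - spread, 1.0 + spread, size=base.n_ldrs)
    factors[base.reference_ldr - 1] = 1.0
    params = tuple(LDRParams(gain_spread=float(f)) for f in factors)
    array = replace(base, ldr_params=params)
    return calibrate_gain(array, response=response)


# ---------------------------------------------------------------------------
# readout
# ---------------------------------------------------------------------------

@dataclass
class ADCFrame:
    """One multiplexed, averaged readout of the array.

    ``counts`` maps LDR index to the average of ``n_reads`` quantized
    ADC codes (a float in [0, 4095]).  ``boundary`` collects LDRs whose
    footprint was clipped at the film edge; ``bad`` the configured
    anomalous LDRs present in the frame.
    """

    counts: dict
    n_reads: int
    seed: int
    timestamp_tag: str = ""
    boundary: frozenset = frozenset()
    bad: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ConfigurationError("n_reads must be >= 1")
        for idx, c in self.counts.items():
            if not 0 <= c <= 4095:
                raise ConfigurationError(f"count {c} of LDR {idx} outside ADC range")

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(sorted(self.counts))

    def to_csv(self, path, array: SensorArray) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["ldr_index", "row", "col", "count", "n_reads"])
            for idx in self.indices:
                row, col = array.row_col(idx)
                w.writerow([idx, row, col, repr(self.counts[idx]), self.n_reads])

    @classmethod
    def from_csv(cls, path, seed: int = -1) -> "ADCFrame":
        counts = {}
        n_reads = 1
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                counts[int(rec["ldr_index"])] = float(rec["count"])
                n_reads = int(rec["n_reads"])
        return cls(counts=counts, n_reads=n_reads, seed=seed)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "counts": {str(k): v for k, v in self.counts.items()},
            "n_reads": self.n_reads,
            "seed": self.seed,
            "timestamp_tag": self.timestamp_tag,
            "boundary": sorted(self.boundary),
            "bad": sorted(self.bad),
        }, indent=1))


def scan_film(od_map: ODMap, array: SensorArray, seed: int = 0,
              film_origin: tuple[float, float] = (0.0, 0.0),
              ldr_indices=None, timestamp_tag: str = "") -> ADCFrame:
    """Digitize a film: one averaged multiplexed readout.

    The film's ODMap origin is placed at ``film_origin`` in the device's
    (mirrored) film frame.  By default every LDR whose footprint
    intersects the film is read; passing explicit ``ldr_indices``
    instead raises :class:`GeometryError` if any footprint misses the
    film entirely.  Each LDR is read ``reads_per_ldr`` times with seeded
    multiplicative glitch noise on the channel voltage (inflated by
    ``bad_noise_factor`` for the configured bad LDRs) and the quantized
    codes are averaged.  Reproducible from ``seed``.
    """
    shifted = ODMap(od_map.values, od_map.pixel_pitch,
                    origin=(od_map.origin[0] + film_origin[0],
                            od_map.origin[1] + film_origin[1]))
    explicit = ldr_indices is not None
    if not explicit:
        ldr_indices = range(1, array.n_ldrs + 1)
    rng = np.random.default_rng(seed)
    counts: dict[int, float] = {}
    boundary = set()
    for idx in sorted(ldr_indices):
        center = ldr_film_position(idx, array)
        try:
            mean_t, clipped = film_transmission_over_ldr(
                shifted, center, array.ldr_diameter)
        except GeometryError:
            if explicit:
                raise
            continue
        if clipped:
            boundary.add(idx)
        params = array.params(idx)
        light = array.led_drive_at(idx) * mean_t
        v = ldr_voltage(light, params, array)
        sigma = array.glitch_sigma * (
            array.bad_noise_factor if idx in array.bad_ldrs else 1.0)
        noise = rng.normal(0.0, sigma, size=array.reads_per_ldr) if sigma > 0 else \
            np.zeros(array.reads_per_ldr)
        codes = [adc_quantize(v * (1.0 + e), array.vref, array.adc_bits)
                 for e in noise]
        counts[idx] = float(np.mean(codes))
    if not counts:
        raise GeometryError("no LDR footprint intersects the film")
    return ADCFrame(counts=counts, n_reads=array.reads_per_ldr, seed=seed,
                    timestamp_tag=timestamp_tag, boundary=frozenset(boundary),
                    bad=frozenset(array.bad_ldrs & set(counts)))
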