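"""Synthetic irradiation: sources, spectra, phantoms and dose fields.

Two source models are provided:

* a kilovoltage X-ray tube whose machine calibration follows the
  inverse-square-like law ``Dose(mGy) = A * (SSD - D')**(-p)`` per unit
  calibration time, with a filtered bremsstrahlung spectrum and a
  markedly inhomogeneous field (up to ~20 % OD dispersion), and
* a Cs-137 irradiator with a homogeneous field (< 4 % dispersion) and a
  constant dose rate.

Staircase phantoms (PMMA and aluminium step wedges) attenuate the beam
under each step; the attenuation is modelled as spectrum-weighted
Beer-Lambert transmission using a bundled table of mass attenuation
coefficients, a deliberately simple stand-in for full Monte Carlo
photon transport.  :func:`irradiate_film` composes source law, field
inhomogeneity, staircase attenuation and the film response into a dose
field and the corresponding netOD map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import (
    ConfigurationError,
    DomainError,
    EstimationError,
    GeometryError,
)
from .film_model import FilmResponse, ODMap, SCANNER_RED, dose_to_netod

__all__ = [
    "BeamModel",
    "Spectrum",
    "StaircasePhantom",
    "DoseField",
    "mass_attenuation",
    "linear_attenuation_per_mm",
    "film_dose_response",
    "beam_spectrum",
    "step_dose_ratio",
    "dose_at_ssd",
    "estimate_offset",
    "xray_spectrum",
    "transmission_ratio",
    "inhomogeneity_field",
    "irradiate_film",
    "xray_60kv_paper",
    "cs137_paper",
    "pmma_stairs_paper",
    "al_stairs_paper",
]

# ---------------------------------------------------------------------------
# bundled attenuation data
# ---------------------------------------------------------------------------
# Mass attenuation coefficients mu/rho [cm^2/g] on a 5-100 keV grid
# (NIST standard-reference values, photoelectric + scatter, with
# coherent), log-log interpolated between grid points.
_ENERGY_GRID_KEV = np.array(
    [5.0, 6.0, 8.0, 10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0]
)

_MU_RHO = {
    "Al": np.array(
        [193.4, 115.3, 50.33, 26.23, 7.955, 3.441,
         1.128, 0.5685, 0.3681, 0.2778, 0.2018, 0.1704]
    ),
    "PMMA": np.array(
        [26.07, 15.31, 6.494, 3.357, 1.101, 0.5714,
         0.3032, 0.2350, 0.2074, 0.1924, 0.1751, 0.1641]
    ),
}

#: densities in g/cm^3
_DENSITY = {"Al": 2.699, "PMMA": 1.190}

# Mass energy-absorption coefficients mu_en/rho [cm^2/g] for water on the
# same grid; radiochromic film is close to water-equivalent, so dose at a
# point behind an absorber weights the photon fluence by E * mu_en/rho.
_WATER_MUEN = np.array(
    [41.2, 23.1, 9.41, 4.944, 1.374, 0.5503,
     0.1557, 0.06947, 0.04223, 0.03190, 0.02597, 0.02546]
)


def mass_attenuation(material: str, energy_kev) -> np.ndarray:
    """mu/rho [cm^2/g] for a bundled material, log-log interpolated."""
    if material not in _MU_RHO:
        raise ConfigurationError(
            f"unknown material {material!r}; bundled materials: "
            f"{sorted(_MU_RHO)}"
        )
    e = np.asarray(energy_kev, dtype=float)
    if np.any(e < _ENERGY_GRID_KEV[0]) or np.any(e > _ENERGY_GRID_KEV[-1]):
        raise DomainError(
            f"energy outside bundled 5-100 keV table: {e.min()}-{e.max()} keV"
        )
    out = np.exp(
        np.interp(np.log(e), np.log(_ENERGY_GRID_KEV), np.log(_MU_RHO[material]))
    )
    return out


def linear_attenuation_per_mm(material: str, energy_kev) -> np.ndarray:
    """Linear attenuation coefficient mu [1/mm]."""
    return mass_attenuation(material, energy_kev) * _DENSITY[material] / 10.0


def film_dose_response(energy_kev) -> np.ndarray:
    """Dose-response weight of a water-equivalent detector, E * mu_en/rho.

    Dose at a point is the energy fluence times the mass energy-absorption
    coefficient of the medium; use this as ``response_weighting`` in
    :func:`transmission_ratio` when the compared quantity is a dose ratio
    rather than a photon-fluence ratio.
    """
    e = np.asarray(energy_kev, dtype=float)
    muen = np.exp(
        np.interp(np.log(e), np.log(_ENERGY_GRID_KEV), np.log(_WATER_MUEN))
    )
    return e * muen


# ---------------------------------------------------------------------------
# source model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeamModel:
    """Source model parameters.

    ``amplitude_A`` [mGy*mm^p] and ``exponent_p`` define the X-ray tube
    output law ``A * (SSD - D')**(-p)`` per unit calibration time, with
    ``offset_Dprime`` [mm] the effective-origin offset.  ``kvp`` and
    ``filtration_mmAl`` parametrize the tube spectrum.
    ``inherent_filtration_mmAl`` is the Al-equivalent of the anode
    self-absorption and exit window that the bare Kramers form neglects;
    it adds to the external filtration when the spectrum is built.
    ``field_dispersion_target`` is the maximum %OD dispersion of the
    irradiation field about its mean.  The Cs-137 source instead has a
    constant ``cs_dose_rate`` [Gy/min] and a nearly flat field.
    """

    amplitude_A: float = 138251.0
    exponent_p: float = 2.003
    offset_Dprime: float = 0.0
    kvp: float = 60.0
    filtration_mmAl: float = 1.3
    inherent_filtration_mmAl: float = 1.2
    field_dispersion_target: float = 20.0
    source_type: str = "xray_tube"
    cs_dose_rate: float = 4.05
    #: fractional (x, y) offset of the field maximum from film centre
    field_peak_offset: tuple[float, float] = (0.15, 0.10)

    def __post_init__(self) -> None:
        if not self.amplitude_A > 0:
            raise ConfigurationError("amplitude_A must be positive")
        if not 1.5 <= self.exponent_p <= 2.5:
            raise ConfigurationError("exponent_p must lie in [1.5, 2.5]")
        if self.field_dispersion_target < 0:
            raise ConfigurationError("field_dispersion_target must be >= 0")
        if not self.cs_dose_rate > 0:
            raise ConfigurationError("cs_dose_rate must be positive")
        if self.source_type not in ("xray_tube", "cs137"):
            raise ConfigurationError(
                f"source_type must be 'xray_tube' or 'cs137', got {self.source_type!r}"
            )


def xray_60kv_paper() -> BeamModel:
    """60 kVp tube preset: 1.3 mm Al filtration, ~20 % field dispersion."""
    return BeamModel()


def cs137_paper() -> BeamModel:
    """Cs-137 irradiator preset: homogeneous field (< 4 % dispersion)."""
    return BeamModel(
        source_type="cs137",
        field_dispersion_target=4.0,
        field_peak_offset=(0.0, 0.0),
    )


def dose_at_ssd(ssd: float, beam: BeamModel, time: float = 1.0) -> float:
    """Tube output ``A * (SSD - D')**(-p)`` [mGy], scaled by exposure time.

    ``time`` is in units of the machine-calibration time base (dose rate
    is constant, so scaling is linear).
    """
    if not ssd > beam.offset_Dprime:
        raise DomainError(
            f"SSD ({ssd} mm) must exceed the offset D' ({beam.offset_Dprime} mm)"
        )
    return beam.amplitude_A * (ssd - beam.offset_Dprime) ** (-beam.exponent_p) * time


def estimate_offset(meas1: tuple[float, float], meas2: tuple[float, float],
                    exponent_p: float = 2.003) -> float:
    """Solve for the source-position offset D' from two (SSD, dose-rate) pairs.

    Under the power law the rates satisfy
    ``(SSD1 - D')/(SSD2 - D') = (rate2/rate1)**(1/p)``, which is linear
    in D'.  The solution must lie below both SSDs to be physical.
    """
    (s1, r1), (s2, r2) = meas1, meas2
    if s1 == s2:
        raise EstimationError("the two SSDs must be distinct")
    if not (r1 > 0 and r2 > 0):
        raise EstimationError("dose rates must be positive")
    k = (r2 / r1) ** (1.0 / exponent_p)
    if math.isclose(k, 1.0, rel_tol=0.0, abs_tol=1e-12):
        raise EstimationError(
            "equal dose rates at distinct SSDs are inconsistent with a "
            "decaying power law"
        )
    dprime = (s1 - k * s2) / (1.0 - k)
    if dprime >= min(s1, s2):
        raise EstimationError(
            f"no admissible offset: D'={dprime:.3f} mm is not below both SSDs"
        )
    return float(dprime)


# ---------------------------------------------------------------------------
# spectrum and attenuation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Spectrum:
    """A relative photon-fluence spectrum on a keV grid."""

    energies: np.ndarray
    weights: np.ndarray
    kvp: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "energies", np.asarray(self.energies, float))
        object.__setattr__(self, "weights", np.asarray(self.weights, float))
        if self.energies.ndim != 1 or self.energies.shape != self.weights.shape:
            raise ConfigurationError("energies and weights must be matching 1-D arrays")
        if self.energies.size > 1 and not np.all(np.diff(self.energies) > 0):
            raise ConfigurationError("energies must be strictly increasing")
        if np.any(self.weights < 0) or not np.any(self.weights > 0):
            raise ConfigurationError("weights must be >= 0 with at least one > 0")
        if self.energies.max() > self.kvp:
            raise ConfigurationError("no photon can exceed the tube potential")

    @property
    def mean_energy(self) -> float:
        return float(np.sum(self.energies * self.weights) / np.sum(self.weights))


#: tube potential range of the modelled microfocus source
_TUBE_KVP_RANGE = (20.0, 90.0)


def xray_spectrum(kvp: float = 60.0, filtration_mmAl: float = 1.3,
                  e_min: float = 5.0) -> Spectrum:
    """Filtered Kramers bremsstrahlung spectrum on a 1 keV grid.

    Unfiltered weights follow the Kramers form ``(kVp - E)/E`` from
    ``e_min`` up to the tube potential (weight 0 at the endpoint), then
    are attenuated by ``exp(-mu_Al(E) * t)`` for the aluminium
    filtration and normalized to unit sum.  Characteristic tungsten
    lines are neglected (the K-lines sit at ~59-67 keV and carry no
    weight at 60 kVp).
    """
    if not _TUBE_KVP_RANGE[0] <= kvp <= _TUBE_KVP_RANGE[1]:
        raise ConfigurationError(
            f"kvp {kvp} outside tube range {_TUBE_KVP_RANGE}"
        )
    if filtration_mmAl < 0:
        raise ConfigurationError("filtration must be >= 0")
    energies = np.arange(e_min, kvp + 0.5, 1.0)
    if energies[-1] > kvp:
        energies = energies[:-1]
    if energies[-1] < kvp:
        energies = np.append(energies, kvp)
    weights = (kvp - energies) / energies
    if filtration_mmAl > 0:
        weights = weights * np.exp(
            -linear_attenuation_per_mm("Al", energies) * filtration_mmAl
        )
    total = weights.sum()
    return Spectrum(energies=energies, weights=weights / total, kvp=kvp)


def transmission_ratio(spectrum: Spectrum, material: str, thickness_mm: float,
                       response_weighting=None) -> float:
    """Unattenuated over attenuated detector-weighted fluence (>= 1).

    ``ratio = sum(w*r) / sum(w*r*exp(-mu*t))`` with ``r(E)`` an optional
    energy-response weight (flat when None).  This spectrum-weighted
    Beer-Lambert model is the package's stand-in for Monte Carlo dose
    ratios under a step of the given material and thickness.
    """
    if thickness_mm < 0:
        raise DomainError("thickness must be >= 0")
    w = spectrum.weights
    if response_weighting is not None:
        r = (response_weighting(spectrum.energies)
             if callable(response_weighting)
             else np.asarray(response_weighting, float))
        w = w * r
    if thickness_mm == 0:
        return 1.0
    mu = linear_attenuation_per_mm(material, spectrum.energies)
    return float(w.sum() / np.sum(w * np.exp(-mu * thickness_mm)))


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StaircasePhantom:
    """A step-wedge phantom: consecutive steps of increasing height.

    Steps are listed as (width, height) in mm and advance along
    ``orientation`` ('x' or 'y') starting at ``origin`` [mm] in the film
    frame; the film region before/after the phantom is unattenuated and
    acts as the open-field reference zone.
    """

    material: str
    steps: tuple[tuple[float, float], ...]
    pitch: float
    orientation: str = "x"
    origin: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple((float(w), float(h)) for w, h in self.steps))
        if self.material not in _MU_RHO:
            raise ConfigurationError(
                f"unknown material {self.material!r}; bundled: {sorted(_MU_RHO)}"
            )
        if not self.steps:
            raise ConfigurationError("phantom needs at least one step")
        for w, h in self.steps:
            if not (w > 0 and h > 0):
                raise ConfigurationError("step widths and heights must be positive")
        if not self.pitch > 0:
            raise ConfigurationError("pitch must be positive")
        for w, _ in self.steps:
            if w > self.pitch:
                raise ConfigurationError("steps overlap: width exceeds pitch")
        if self.orientation not in ("x", "y"):
            raise ConfigurationError("orientation must be 'x' or 'y'")

    @property
    def extent_mm(self) -> float:
        """Length of the phantom along its orientation axis."""
        n = len(self.steps)
        return (n - 1) * self.pitch + self.steps[-1][0]

    def height_at(self, coord) -> np.ndarray:
        """Step height [mm] at film coordinate(s) along the orientation axis.

        0 outside every step footprint (open field).
        """
        c = np.asarray(coord, dtype=float) - self.origin
        heights = np.zeros_like(c)
        for k, (w, h) in enumerate(self.steps):
            lo = k * self.pitch
            inside = (c >= lo) & (c < lo + w)
            heights[inside] = h
        return heights


def pmma_stairs_paper() -> StaircasePhantom:
    """PMMA step wedge: six 5 mm-wide steps at 5 mm pitch, heights
    1, 2, 3, 4, 5 and 10 mm."""
    heights = (1.0, 2.0, 3.0, 4.0, 5.0, 10.0)
    return StaircasePhantom(
        material="PMMA",
        steps=tuple((5.0, h) for h in heights),
        pitch=5.0,
    )


def al_stairs_paper() -> StaircasePhantom:
    """Aluminium step wedge: 12 mm-wide steps at 3 and 6 mm height."""
    return StaircasePhantom(
        material="Al",
        steps=((12.0, 3.0), (12.0, 6.0)),
        pitch=12.0,
    )


# ---------------------------------------------------------------------------
# dose fields
# ---------------------------------------------------------------------------

@dataclass
class DoseField:
    """A 2-D absolute dose map [Gy] produced by a synthetic irradiation."""

    values: np.ndarray
    pixel_pitch: float
    nominal_dose: float
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise DomainError("dose values must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def mean(self) -> float:
        return float(self.values.mean())


def inhomogeneity_field(shape: tuple[int, int], pixel_pitch: float,
                        dispersion_target: float, source_type: str = "xray_tube",
                        seed: int = 0,
                        peak_offset: tuple[float, float] = (0.15, 0.10),
                        noise_fraction: float = 0.05) -> np.ndarray:
    """Relative 2-D irradiation field with mean exactly 1.

    A smooth quadratic surface peaking at a configurable fractional
    offset from the film centre (emulating an off-axis beam-intensity
    displacement) plus seeded Gaussian texture, affinely rescaled so the
    maximum %dispersion about the mean equals ``dispersion_target``.
    ``noise_fraction`` is the noise amplitude relative to the smooth
    surface's amplitude.  A zero target returns the flat field.
    """
    if dispersion_target < 0:
        raise DomainError("dispersion_target must be >= 0")
    ny, nx = shape
    if dispersion_target == 0:
        return np.ones((ny, nx))
    rng = np.random.default_rng(seed)
    y, x = np.mgrid[0:ny, 0:nx]
    # normalized coordinates in [-0.5, 0.5]
    u = (x + 0.5) / nx - 0.5
    v = (y + 0.5) / ny - 0.5
    cx, cy = peak_offset
    surface = -((u - cx) ** 2 + (v - cy) ** 2)
    amp = surface.max() - surface.min()
    if amp == 0:
        amp = 1.0
    z = surface + rng.normal(0.0, noise_fraction * amp, size=(ny, nx))
    z -= z.mean()
    zmax = np.abs(z).max()
    alpha = (dispersion_target / 100.0) / zmax
    return 1.0 + alpha * z


def beam_spectrum(beam: BeamModel) -> Spectrum:
    """The tube spectrum of a beam, external plus inherent filtration."""
    if beam.source_type != "xray_tube":
        raise ConfigurationError("only the X-ray tube has a bremsstrahlung spectrum")
    return xray_spectrum(
        beam.kvp, beam.filtration_mmAl + beam.inherent_filtration_mmAl
    )


def step_dose_ratio(beam: BeamModel, material: str, height_mm: float) -> float:
    """Dose-reduction ratio under one step: spectrum-weighted, dose-response
    weighted Beer-Lambert transmission (the Monte Carlo stand-in)."""
    return transmission_ratio(
        beam_spectrum(beam), material, height_mm,
        response_weighting=film_dose_response,
    )


def _step_ratio_map(phantom: StaircasePhantom, beam: BeamModel,
                    shape: tuple[int, int], pixel_pitch: float) -> np.ndarray:
    """Per-pixel dose-reduction ratio (>= 1) under a staircase phantom."""
    ny, nx = shape
    if phantom.orientation == "x":
        coords = (np.arange(nx) + 0.5) * pixel_pitch
    else:
        coords = (np.arange(ny) + 0.5) * pixel_pitch
    heights = phantom.height_at(coords)
    ratios = np.ones_like(heights)
    for h in np.unique(heights):
        if h > 0:
            ratios[heights == h] = step_dose_ratio(beam, phantom.material, h)
    if phantom.orientation == "x":
        return np.broadcast_to(ratios[None, :], (ny, nx)).copy()
    return np.broadcast_to(ratios[:, None], (ny, nx)).copy()


def irradiate_film(nominal_dose: float, beam: BeamModel,
                   phantom: StaircasePhantom | None = None,
                   film_size_mm: tuple[float, float] = (50.0, 50.0),
                   response: FilmResponse = SCANNER_RED,
                   seed: int = 0, pixel_pitch: float = 0.2,
                   od_noise_sigma: float = 0.003) -> tuple[DoseField, ODMap]:
    """Simulate one film irradiation.

    Composes ``dose = nominal * field / step_ratio`` with the source's
    inhomogeneity field (mean exactly 1) and the per-step attenuation
    ratios, then maps dose to netOD through the film response and adds
    seeded Gaussian read noise in OD space.  Deterministic given
    ``seed``; the same seed yields identical films.
    """
    if nominal_dose < 0:
        raise DomainError("nominal_dose must be >= 0")
    width, height = film_size_mm
    nx = max(1, int(round(width / pixel_pitch)))
    ny = max(1, int(round(height / pixel_pitch)))
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    seed_field, seed_noise = ss.spawn(2)
    field_rel = inhomogeneity_field(
        (ny, nx), pixel_pitch, beam.field_dispersion_target,
        source_type=beam.source_type,
        seed=seed_field, peak_offset=beam.field_peak_offset,
    )
    ratio = np.ones((ny, nx))
    if phantom is not None:
        film_extent = width if phantom.orientation == "x" else height
        if phantom.origin + phantom.extent_mm > film_extent + 1e-9:
            raise GeometryError(
                f"phantom extent {phantom.origin + phantom.extent_mm:.1f} mm "
                f"exceeds film ({film_extent:.1f} mm along {phantom.orientation})"
            )
        if beam.source_type != "xray_tube":
            raise ConfigurationError(
                "staircase attenuation is modelled for the X-ray tube spectrum only"
            )
        ratio = _step_ratio_map(phantom, beam, (ny, nx), pixel_pitch)
    dose = nominal_dose * field_rel / ratio
    od = dose_to_netod(dose, response)
    if od_noise_sigma > 0:
        rng = np.random.default_rng(seed_noise)
        od = od + rng.normal(0.0, od_noise_sigma, size=od.shape)
        od = np.maximum(od, -0.049)
    seed_tag = seed if isinstance(seed, int) else -1
    dose_field = DoseField(values=dose, pixel_pitch=pixel_pitch,
                           nominal_dose=nominal_dose, seed=seed_tag)
    od_map = ODMap(values=od, pixel_pitch=pixel_pitch)
    return dose_field, od_map
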