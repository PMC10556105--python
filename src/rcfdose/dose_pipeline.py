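"""Inverse analyses: from raw readings to absolute dose.

Two branches convert readings into dose through a fifth-order
calibration:

* the scanner branch maps per-pixel netOD (from an exposed/unexposed
  transmission-scan pair) to a dose map and ROI statistics;
* the photodetector-array branch fits one count(dose) curve per LDR,
  collapses them onto a reference LDR with scalar conversion factors,
  and inverts the reference curve to read dose in situ.

On top sit the staircase analyses: background subtraction (dividing out
the open-field irradiation field), three-zone step statistics, dose
ratio tables and film-orientation detection, plus the end-to-end
synthetic experiments used to validate both branches at nominal doses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    CalibrationError,
    ConfigurationError,
    DomainError,
    GeometryError,
)
from . import beam_phantom as bp
from . import moem_sensor as ms
from .film_model import (
    CalibrationCurve,
    FilmResponse,
    LED_GREEN,
    ODMap,
    SCANNER_RED,
    fit_calibration,
    invert_calibration,
    net_od,
)

__all__ = [
    "DoseMap",
    "ROIStats",
    "LDRCalibration",
    "OrientationResult",
    "scanner_dose_map",
    "calibrate_ldrs",
    "adc_to_dose",
    "step_analysis",
    "make_step_table",
    "dose_ratio_table",
    "detect_orientation",
    "scanner_branch_experiment",
    "moem_branch_experiment",
    "cross_method_comparison",
]

STEP_TABLE_COLUMNS = ["step_id", "step_height_mm", "zone", "mean_dose_gy",
                      "sd_gy", "n"]

_INVERT_GRID = 4096


@dataclass
class DoseMap:
    """A reconstructed 2-D dose map [Gy] with an invalid-pixel mask."""

    values: np.ndarray
    pixel_pitch: float
    origin: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray | None = None
    n_masked: int = 0
    n_out_of_range: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class ROIStats:
    """Mean +/- sd dose over a region of interest."""

    mean: float
    sd: float
    n: int
    n_masked: int = 0
    n_out_of_range: int = 0
    roi_clipped: bool = False


def _invert_netod_map(netod: np.ndarray, curve: CalibrationCurve
                      ) -> tuple[np.ndarray, int]:
    """Vectorized curve inversion on a dense grid (monotone guaranteed).

    Values outside the calibrated netOD interval are clamped to the
    nearest end and counted.
    """
    grid = np.linspace(*curve.dose_range, _INVERT_GRID)
    cv = curve(grid)
    if not curve.increasing:
        grid, cv = grid[::-1], cv[::-1]
    n_oor = int(np.sum((netod < cv[0]) | (netod > cv[-1])))
    return np.interp(netod, cv, grid), n_oor


def _as_odmap(exposed, unexposed, channel: str, saturation) -> tuple[ODMap, int]:
    """Build the netOD map from the supported input kinds.

    Returns (od map, number of masked pixels).  Saturated or
    non-positive intensities are masked by substituting the unexposed
    intensity (netOD 0) and counted.
    """
    if isinstance(exposed, ODMap) and unexposed is None:
        return exposed, 0
    # FilmScan duck-typing: anything with .pixels and .pixel_pitch
    def grab(obj):
        if hasattr(obj, "pixels"):
            return np.asarray(obj.pixels, float), obj.pixel_pitch
        if isinstance(obj, ODMap):
            raise ConfigurationError(
                "mixing an ODMap with an intensity image is ambiguous"
            )
        raise ConfigurationError(
            "expected an ODMap (alone) or two film scans / intensity images"
        )
    if unexposed is None:
        raise ConfigurationError("an unexposed (control) scan is required")
    i, pitch = grab(exposed)
    i0, pitch0 = grab(unexposed)
    if i.shape != i0.shape:
        raise GeometryError(
            f"exposed {i.shape} and unexposed {i0.shape} scans are not congruent"
        )
    if saturation is None:
        saturation = np.inf
    bad = (i <= 0) | (i0 <= 0) | (i >= saturation) | (i0 >= saturation)
    n_masked = int(bad.sum())
    i = np.where(bad, 1.0, i)
    i0 = np.where(bad, 1.0, i0)
    od = net_od(i, i0)
    od = np.maximum(od, -0.049)
    return ODMap(od, pitch), n_masked


def scanner_dose_map(exposed, unexposed=None, *, curve: CalibrationCurve,
                     roi_mm: tuple[float, float, float, float] | None = None,
                     saturation: float | None = None
                     ) -> tuple[DoseMap, ROIStats]:
    """Scanner-branch reconstruction: netOD map -> dose map + ROI stats.

    ``exposed``/``unexposed`` are either a single ODMap (already in
    netOD) or an exposed/unexposed scan pair (objects with ``pixels``
    and ``pixel_pitch``).  ``roi_mm = (x0, y0, width, height)`` selects
    the region for the statistics (whole map when None); a ROI reaching
    past the film is clipped and flagged.
    """
    od_map, n_masked = _as_odmap(exposed, unexposed, "red", saturation)
    dose, n_oor = _invert_netod_map(od_map.values, curve)
    ny, nx = dose.shape
    pitch = od_map.pixel_pitch
    clipped = False
    if roi_mm is None:
        sl = (slice(0, ny), slice(0, nx))
    else:
        x0, y0, w, h = roi_mm
        c0, c1 = int(np.floor(x0 / pitch)), int(np.ceil((x0 + w) / pitch))
        r0, r1 = int(np.floor(y0 / pitch)), int(np.ceil((y0 + h) / pitch))
        if c0 < 0 or r0 < 0 or c1 > nx or r1 > ny:
            clipped = True
        c0, r0 = max(c0, 0), max(r0, 0)
        c1, r1 = min(c1, nx), min(r1, ny)
        if c1 <= c0 or r1 <= r0:
            raise GeometryError("ROI does not intersect the film")
        sl = (slice(r0, r1), slice(c0, c1))
    roi_vals = dose[sl]
    stats = ROIStats(
        mean=float(roi_vals.mean()),
        sd=float(roi_vals.std(ddof=1)) if roi_vals.size > 1 else 0.0,
        n=int(roi_vals.size),
        n_masked=n_masked,
        n_out_of_range=n_oor,
        roi_clipped=clipped,
    )
    dose_map = DoseMap(values=dose, pixel_pitch=pitch, origin=od_map.origin,
                       n_masked=n_masked, n_out_of_range=n_oor)
    return dose_map, stats


# ---------------------------------------------------------------------------
# photodetector-array branch
# ---------------------------------------------------------------------------

@dataclass
class LDRCalibration:
    """Per-LDR count(dose) curves plus scalar conversion factors.

    Multiplying an LDR's counts by its factor lands them on the
    reference LDR's curve; the reference factor is exactly 1.
    """

    per_ldr_curves: dict
    conversion_factors: dict
    reference_ldr: int

    def __post_init__(self) -> None:
        if self.reference_ldr not in self.per_ldr_curves:
            raise CalibrationError("reference LDR has no calibration curve")
        if self.conversion_factors[self.reference_ldr] != 1.0:
            raise CalibrationError("reference conversion factor must be exactly 1")
        if any(f <= 0 for f in self.conversion_factors.values()):
            raise CalibrationError("conversion factors must be positive")

    @property
    def reference_curve(self) -> CalibrationCurve:
        return self.per_ldr_curves[self.reference_ldr]

    @property
    def dose_range(self) -> tuple[float, float]:
        return self.reference_curve.dose_range


def calibrate_ldrs(exposures, reference_ldr: int = 1) -> LDRCalibration:
    """Fit a fifth-order count(dose) curve per LDR and normalize.

    ``exposures`` is a sequence of (dose [Gy], ADCFrame) pairs covering
    at least 7 dose levels; every LDR participating must be present in
    every frame.  Curves are fitted first, then collapsed onto the
    reference LDR's curve with one least-squares scalar per LDR over a
    common dose grid.
    """
    exposures = sorted(exposures, key=lambda p: p[0])
    doses = np.array([d for d, _ in exposures], dtype=float)
    if np.unique(doses).size < 7:
        raise CalibrationError(
            f"need at least 7 distinct calibration dose levels, got "
            f"{np.unique(doses).size}"
        )
    common = set.intersection(*(set(f.counts) for _, f in exposures))
    union = set.union(*(set(f.counts) for _, f in exposures))
    missing = union - common
    if missing:
        raise CalibrationError(
            f"LDR(s) {sorted(missing)} missing from some calibration frames"
        )
    if reference_ldr not in common:
        raise CalibrationError(f"reference LDR {reference_ldr} not in the frames")
    curves = {}
    for idx in sorted(common):
        counts = np.array([f.counts[idx] for _, f in exposures])
        try:
            curve = fit_calibration(doses, counts)
        except CalibrationError as exc:
            raise CalibrationError(f"LDR {idx}: {exc}") from exc
        if curve.increasing:
            raise CalibrationError(
                f"LDR {idx}: counts increase with dose; expected a darkening film"
            )
        curves[idx] = curve
    grid = np.linspace(doses.min(), doses.max(), 256)
    ref_vals = curves[reference_ldr](grid)
    factors = {}
    for idx, curve in curves.items():
        vals = curve(grid)
        factors[idx] = float(np.dot(vals, ref_vals) / np.dot(vals, vals))
    factors[reference_ldr] = 1.0
    return LDRCalibration(per_ldr_curves=curves, conversion_factors=factors,
                          reference_ldr=reference_ldr)


def adc_to_dose(frame: ms.ADCFrame, cal: LDRCalibration) -> pd.DataFrame:
    """Convert one averaged readout to per-LDR doses.

    Counts are multiplied by the LDR's conversion factor and the
    reference curve is inverted.  Counts outside the calibrated count
    interval yield NaN dose with the ``out_of_range`` flag set; bad and
    boundary LDRs are flagged, never dropped.  ``good`` marks rows with
    no flag at all.
    """
    missing = set(frame.counts) - set(cal.conversion_factors)
    if missing:
        raise CalibrationError(
            f"frame contains uncalibrated LDR(s) {sorted(missing)}"
        )
    ref = cal.reference_curve
    vmin, vmax = ref.value_bounds()
    # pure round-off at the interval ends must not flag a level
    tol = 1e-6 * (vmax - vmin)
    rows = []
    for idx in frame.indices:
        norm = frame.counts[idx] * cal.conversion_factors[idx]
        oor = not (vmin - tol <= norm <= vmax + tol)
        dose = (np.nan if oor
                else invert_calibration(ref, min(max(norm, vmin), vmax)))
        rows.append({
            "ldr": idx,
            "count": frame.counts[idx],
            "normalized_count": norm,
            "dose_gy": dose,
            "out_of_range": oor,
            "bad": idx in frame.bad,
            "boundary": idx in frame.boundary,
        })
    df = pd.DataFrame(rows).set_index("ldr")
    df["good"] = ~(df.out_of_range | df.bad | df.boundary)
    return df


# ---------------------------------------------------------------------------
# staircase analyses
# ---------------------------------------------------------------------------

_ZONE_NAMES = {1: ("all",), 3: ("top", "middle", "bottom")}
#: fraction of each step's width used for the per-step averages
CENTRAL_BAND = 0.6


def _zone_of(y: float, height_mm: float, zones: int) -> str:
    names = _ZONE_NAMES[zones]
    k = min(int(zones * y / height_mm), zones - 1)
    return names[k]


def _step_regions(phantom: bp.StaircasePhantom, extent_mm: float):
    """Yield (step_id, height, lo, hi) intervals along the phantom axis.

    Step 0 is the open field (everything outside the steps); steps use
    only the central fraction of their width to stay off the penumbra.
    """
    regions = []
    open_lo = 0.0
    for k, (w, h) in enumerate(phantom.steps):
        lo = phantom.origin + k * phantom.pitch
        hi = lo + w
        margin = (1.0 - CENTRAL_BAND) / 2.0 * w
        regions.append((k + 1, h, lo + margin, hi - margin))
    # open-field region: before the phantom and after it
    spans = []
    if phantom.origin > 0:
        spans.append((0.0, phantom.origin))
    tail = phantom.origin + phantom.extent_mm
    if tail < extent_mm:
        spans.append((tail, extent_mm))
    return regions, spans


def step_analysis(measured, phantom: bp.StaircasePhantom, background,
                  zones: int = 3, *, curve: CalibrationCurve | None = None,
                  array: ms.SensorArray | None = None) -> pd.DataFrame:
    """Per-step, per-zone dose statistics with background subtraction.

    ``measured``/``background`` are congruent pairs of either

    * ODMaps with ``curve`` given - the background's OD variation about
      its mean is subtracted in OD space before converting to dose, or
    * dose maps (DoseField/DoseMap) - the background's relative field is
      divided out, or
    * per-LDR dose tables from :func:`adc_to_dose` with ``array``
      given - per-LDR relative background division.

    Zones split the film into equal horizontal bands (1 or 3); per-step
    averages use the central 60 % of each step's width.
    """
    if zones not in _ZONE_NAMES:
        raise ConfigurationError("zones must be 1 or 3")
    if isinstance(measured, pd.DataFrame):
        return _step_analysis_ldr(measured, phantom, background, zones, array)
    if isinstance(measured, ODMap):
        if curve is None:
            raise ConfigurationError("OD-map analysis requires the calibration curve")
        if measured.shape != background.shape:
            raise GeometryError("measured and background maps are not congruent")
        od_corr = measured.values - (background.values - background.values.mean())
        dose, _ = _invert_netod_map(od_corr, curve)
        pitch = measured.pixel_pitch
    else:
        if measured.values.shape != background.values.shape:
            raise GeometryError("measured and background maps are not congruent")
        rel = background.values / background.values.mean()
        dose = measured.values / rel
        pitch = measured.pixel_pitch
    ny, nx = dose.shape
    if phantom.orientation == "x":
        axis_coord = (np.arange(nx) + 0.5) * pitch
        band_coord = (np.arange(ny) + 0.5) * pitch
        extent, band_extent = nx * pitch, ny * pitch
    else:
        axis_coord = (np.arange(ny) + 0.5) * pitch
        band_coord = (np.arange(nx) + 0.5) * pitch
        extent, band_extent = ny * pitch, nx * pitch
    if phantom.origin + phantom.extent_mm > extent + 1e-9:
        raise GeometryError("phantom is not registered within the film frame")
    regions, open_spans = _step_regions(phantom, extent)
    zone_edges = np.linspace(0.0, band_extent, zones + 1)
    names = _ZONE_NAMES[zones]
    rows = []

    def collect(step_id, height, axis_mask):
        for z, zname in enumerate(names):
            zmask = (band_coord >= zone_edges[z]) & (band_coord < zone_edges[z + 1])
            if phantom.orientation == "x":
                block = dose[np.ix_(zmask, axis_mask)]
            else:
                block = dose[np.ix_(axis_mask, zmask)]
            if block.size == 0:
                continue
            rows.append({
                "step_id": step_id, "step_height_mm": height, "zone": zname,
                "mean_dose_gy": float(block.mean()),
                "sd_gy": float(block.std(ddof=1)) if block.size > 1 else 0.0,
                "n": int(block.size),
            })

    open_mask = np.zeros_like(axis_coord, dtype=bool)
    for lo, hi in open_spans:
        open_mask |= (axis_coord >= lo) & (axis_coord < hi)
    if open_mask.any():
        collect(0, 0.0, open_mask)
    for step_id, h, lo, hi in regions:
        collect(step_id, h, (axis_coord >= lo) & (axis_coord < hi))
    return pd.DataFrame(rows, columns=STEP_TABLE_COLUMNS)


def _step_analysis_ldr(measured: pd.DataFrame, phantom, background,
                       zones: int, array) -> pd.DataFrame:
    if array is None:
        raise ConfigurationError("per-LDR analysis requires the sensor array")
    if not isinstance(background, pd.DataFrame):
        raise ConfigurationError("background must also be a per-LDR dose table")
    common = measured.index.intersection(background.index)
    good = measured.loc[common, "good"] & background.loc[common, "good"]
    idxs = common[good]
    if len(idxs) == 0:
        raise GeometryError("no usable LDR is present in both tables")
    bg = background.loc[idxs, "dose_gy"]
    corrected = measured.loc[idxs, "dose_gy"] * (bg.mean() / bg)
    pos = {i: ms.ldr_film_position(i, array) for i in idxs}
    ys = np.array([pos[i][1] for i in idxs])
    y_lo, y_hi = ys.min() - array.pitch / 2, ys.max() + array.pitch / 2
    zone_edges = np.linspace(y_lo, y_hi, zones + 1)
    names = _ZONE_NAMES[zones]
    rows = []
    axis = 0 if phantom.orientation == "x" else 1
    for i in idxs:
        c = pos[i][axis]
        h = float(phantom.height_at(c))
        # step id from the phantom interval the LDR centre falls in
        rel = c - phantom.origin
        k = int(rel // phantom.pitch)
        in_step = (0 <= k < len(phantom.steps)
                   and rel - k * phantom.pitch < phantom.steps[k][0])
        step_id = k + 1 if in_step else 0
        z = min(int(np.searchsorted(zone_edges, pos[i][1], side="right")) - 1,
                zones - 1)
        rows.append({"step_id": step_id, "height": h, "zone": names[max(z, 0)],
                     "dose": corrected.loc[i]})
    raw = pd.DataFrame(rows)
    out = []
    for (sid, zname), grp in raw.groupby(["step_id", "zone"], sort=True):
        out.append({
            "step_id": sid, "step_height_mm": float(grp.height.iloc[0]),
            "zone": zname, "mean_dose_gy": float(grp.dose.mean()),
            "sd_gy": float(grp.dose.std(ddof=1)) if len(grp) > 1 else 0.0,
            "n": int(len(grp)),
        })
    return pd.DataFrame(out, columns=STEP_TABLE_COLUMNS)


def make_step_table(doses, step_heights_mm=None, zone: str = "middle",
                    sds=None) -> pd.DataFrame:
    """Build a step-dose table from plain per-step doses.

    ``doses`` maps step_id -> mean dose [Gy] (step 0 = open field).
    Convenient for entering published step doses into
    :func:`dose_ratio_table`.
    """
    rows = []
    for sid, dose in doses.items():
        rows.append({
            "step_id": sid,
            "step_height_mm": 0.0 if step_heights_mm is None
            else float(step_heights_mm.get(sid, 0.0)),
            "zone": zone,
            "mean_dose_gy": float(dose),
            "sd_gy": 0.0 if sds is None else float(sds.get(sid, 0.0)),
            "n": 1,
        })
    return pd.DataFrame(rows, columns=STEP_TABLE_COLUMNS)


def dose_ratio_table(table: pd.DataFrame, reference_step: int = 0,
                     zone: str | None = None, decimals: int = 2) -> pd.DataFrame:
    """Per-step dose ratios, reference dose over step dose.

    The reference is typically the open-field measurement (step 0).
    Ratios are rounded to ``decimals`` (2 by default, the usual printed
    precision); the unrounded value is kept in ``ratio_full``.
    """
    t = table
    if zone is not None:
        t = t[t.zone == zone]
    elif "middle" in set(t.zone):
        t = t[t.zone == "middle"]
    ref_rows = t[t.step_id == reference_step]
    if ref_rows.empty:
        raise ConfigurationError(f"reference step {reference_step} not in table")
    ref = float(ref_rows.mean_dose_gy.iloc[0])
    if ref <= 0:
        raise DomainError("reference dose must be positive")
    out = t.copy()
    out["ratio_full"] = ref / out.mean_dose_gy
    out["ratio"] = out.ratio_full.round(decimals)
    return out[["step_id", "step_height_mm", "zone", "mean_dose_gy",
                "ratio", "ratio_full"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# orientation detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrientationResult:
    orientation: str
    scores: dict
    report: pd.DataFrame


def detect_orientation(frame: ms.ADCFrame, cal: LDRCalibration,
                       phantom: bp.StaircasePhantom | None,
                       array: ms.SensorArray, nominal_dose: float,
                       beam: bp.BeamModel | None = None,
                       candidates: tuple[str, ...] = ("R", "R+90")
                       ) -> OrientationResult:
    """Identify the film orientation from the staircase signature.

    For each candidate the expected per-LDR dose is predicted from the
    phantom geometry (steps advance along x for ``R`` and along y for
    ``R+90``) and the spectrum-weighted step ratios; the orientation
    minimizing the summed absolute dose mismatch over usable LDRs wins.
    A symmetric/absent phantom, or a near tie, returns "undetermined".
    Frame LDRs without a calibration are ignored (the film may cover
    more of the array than the calibrated subset).
    """
    covered = set(frame.counts) & set(cal.conversion_factors)
    if not covered:
        raise CalibrationError("no calibrated LDR present in the frame")
    sub = ms.ADCFrame(
        counts={i: frame.counts[i] for i in covered},
        n_reads=frame.n_reads, seed=frame.seed,
        boundary=frame.boundary & covered, bad=frame.bad & covered)
    observed = adc_to_dose(sub, cal)
    usable = observed[observed.good]
    if phantom is None or usable.empty:
        return OrientationResult("undetermined", {},
                                 pd.DataFrame({"observed": observed.dose_gy}))
    beam = beam or bp.xray_60kv_paper()
    ratio_cache = {0.0: 1.0}
    for _, h in phantom.steps:
        ratio_cache.setdefault(
            h, bp.step_dose_ratio(beam, phantom.material, h))
    report = pd.DataFrame({"observed": usable.dose_gy})
    scores = {}
    for cand in candidates:
        exp = []
        for idx in usable.index:
            x, y = ms.ldr_film_position(idx, array)
            coord = x if cand == "R" else y
            h = float(phantom.height_at(coord))
            exp.append(nominal_dose / ratio_cache[h])
        report[f"expected_{cand}"] = exp
        scores[cand] = float(np.abs(report[f"expected_{cand}"]
                                    - report.observed).sum())
    ordered = sorted(scores.items(), key=lambda kv: kv[1])
    best, runner = ordered[0], ordered[1] if len(ordered) > 1 else (None, np.inf)
    if runner[1] - best[1] < 0.05 * max(best[1], runner[1], 1e-9):
        return OrientationResult("undetermined", scores, report)
    return OrientationResult(best[0], scores, report)


# ---------------------------------------------------------------------------
# end-to-end synthetic experiments
# ---------------------------------------------------------------------------

#: scanner-branch calibration dose levels for the X-ray experiments [Gy]
XRAY_CAL_DOSES = (0.2, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0)
#: per-LDR calibration dose levels for the Cs-137 experiments [Gy]
#: (denser than the scanner grid: 20 independent quintic fits on noisy
#: averaged counts need more support than one fit on ROI-mean netOD)
CS137_CAL_DOSES = (0.2, 0.4, 0.8, 1.2, 1.6, 2.0, 2.4, 2.8, 3.2, 3.6, 4.0)
#: wide-range per-LDR calibration grid for cross-method comparisons [Gy]
WIDE_CAL_DOSES = (0.2, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)


def scanner_branch_experiment(seed: int, nominal_dose: float = 0.60,
                              cal_doses=XRAY_CAL_DOSES,
                              beam: bp.BeamModel | None = None,
                              response: FilmResponse = SCANNER_RED,
                              film_size_mm=(50.0, 50.0),
                              roi_mm=(5.0, 5.0, 40.0, 40.0),
                              pixel_pitch: float = 0.2) -> dict:
    """Full scanner branch: calibrate on synthetic films, then recover a
    validation film's dose.

    One film per calibration dose is irradiated (each with its own
    sub-seed), the ROI-mean netOD fitted against dose with the
    fifth-order polynomial, and a separate validation film at
    ``nominal_dose`` is reconstructed.  Returns the fitted curve and the
    ROI statistics of the recovered dose map.
    """
    beam = beam or bp.xray_60kv_paper()
    seeds = np.random.SeedSequence(seed).spawn(len(cal_doses) + 1)
    netods = []
    for d, s in zip(cal_doses, seeds):
        _, od = bp.irradiate_film(d, beam, film_size_mm=film_size_mm,
                                  response=response, seed=s,
                                  pixel_pitch=pixel_pitch)
        _, roi_od = _roi_mean_od(od, roi_mm)
        netods.append(roi_od)
    curve = fit_calibration(np.asarray(cal_doses), np.asarray(netods))
    _, od_val = bp.irradiate_film(nominal_dose, beam, film_size_mm=film_size_mm,
                                  response=response, seed=seeds[-1],
                                  pixel_pitch=pixel_pitch)
    dose_map, stats = scanner_dose_map(od_val, curve=curve, roi_mm=roi_mm)
    return {"curve": curve, "dose_map": dose_map, "stats": stats,
            "recovered_dose_gy": stats.mean, "nominal_dose_gy": nominal_dose}


def _roi_mean_od(od_map: ODMap, roi_mm) -> tuple[ODMap, float]:
    x0, y0, w, h = roi_mm
    pitch = od_map.pixel_pitch
    c0, c1 = int(np.floor(x0 / pitch)), int(np.ceil((x0 + w) / pitch))
    r0, r1 = int(np.floor(y0 / pitch)), int(np.ceil((y0 + h) / pitch))
    block = od_map.values[max(r0, 0):r1, max(c0, 0):c1]
    return od_map, float(block.mean())


def moem_branch_experiment(seed: int, nominal_dose: float = 0.6,
                           cal_doses=CS137_CAL_DOSES,
                           beam: bp.BeamModel | None = None,
                           response: FilmResponse = LED_GREEN,
                           array: ms.SensorArray | None = None,
                           film_size_mm=(60.0, 12.0),
                           pixel_pitch: float = 0.2) -> dict:
    """Full photodetector-array branch on a homogeneous-field source.

    One film and one averaged readout per calibration dose, per-LDR
    fifth-order calibration with conversion-factor normalization, then
    a validation film at ``nominal_dose`` converted ADC -> dose; the
    recovered dose is the mean over good (unflagged) LDRs.
    """
    beam = beam or bp.cs137_paper()
    array = array or ms.dosimoems_v1()
    seeds = np.random.SeedSequence(seed).spawn(2 * len(cal_doses) + 2)
    exposures = []
    for k, d in enumerate(cal_doses):
        _, od = bp.irradiate_film(d, beam, film_size_mm=film_size_mm,
                                  response=response, seed=seeds[2 * k],
                                  pixel_pitch=pixel_pitch)
        frame = ms.scan_film(od, array, seed=_small_seed(seeds[2 * k + 1]))
        exposures.append((d, frame))
    cal = calibrate_ldrs(exposures, reference_ldr=array.reference_ldr)
    _, od_val = bp.irradiate_film(nominal_dose, beam, film_size_mm=film_size_mm,
                                  response=response, seed=seeds[-2],
                                  pixel_pitch=pixel_pitch)
    frame_val = ms.scan_film(od_val, array, seed=_small_seed(seeds[-1]))
    doses = adc_to_dose(frame_val, cal)
    good = doses[doses.good].dose_gy
    return {"calibration": cal, "doses": doses,
            "recovered_dose_gy": float(good.mean()),
            "recovered_sd_gy": float(good.std(ddof=1)),
            "nominal_dose_gy": nominal_dose}


def _small_seed(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1)[0] % (2 ** 31))


def cross_method_comparison(seed: int, doses=(0.5, 1.0, 2.0, 3.0, 5.0, 8.0),
                            cal_doses=WIDE_CAL_DOSES,
                            array: ms.SensorArray | None = None,
                            film_size_mm=(60.0, 12.0),
                            pixel_pitch: float = 0.2) -> pd.DataFrame:
    """Scanner vs array branch on the same synthetic films.

    Both branches are independently calibrated under the homogeneous
    source, then each test film (one dose field, rendered through the
    red scanner channel and the green LED channel) is reconstructed by
    both; returns a table of mean doses and their difference.
    """
    beam = bp.cs137_paper()
    array = array or ms.dosimoems_v1()
    roi = (5.0, 1.0, film_size_mm[0] - 10.0, film_size_mm[1] - 2.0)
    ss = np.random.SeedSequence(seed)
    s_cal, s_test = ss.spawn(2)
    cal_seeds = s_cal.spawn(2 * len(cal_doses))
    netods, exposures = [], []
    for k, d in enumerate(cal_doses):
        film_seed = cal_seeds[2 * k]
        _, od_red = bp.irradiate_film(d, beam, film_size_mm=film_size_mm,
                                      response=SCANNER_RED, seed=film_seed,
                                      pixel_pitch=pixel_pitch)
        _, od_green = bp.irradiate_film(d, beam, film_size_mm=film_size_mm,
                                        response=LED_GREEN, seed=film_seed,
                                        pixel_pitch=pixel_pitch)
        _, roi_od = _roi_mean_od(od_red, roi)
        netods.append(roi_od)
        exposures.append((d, ms.scan_film(od_green, array,
                                          seed=_small_seed(cal_seeds[2 * k + 1]))))
    curve = fit_calibration(np.asarray(cal_doses), np.asarray(netods))
    cal = calibrate_ldrs(exposures, reference_ldr=array.reference_ldr)
    rows = []
    test_seeds = s_test.spawn(2 * len(doses))
    for k, d in enumerate(doses):
        film_seed = test_seeds[2 * k]
        _, od_red = bp.irradiate_film(d, beam, film_size_mm=film_size_mm,
                                      response=SCANNER_RED, seed=film_seed,
                                      pixel_pitch=pixel_pitch)
        _, od_green = bp.irradiate_film(d, beam, film_size_mm=film_size_mm,
                                        response=LED_GREEN, seed=film_seed,
                                        pixel_pitch=pixel_pitch)
        _, stats = scanner_dose_map(od_red, curve=curve, roi_mm=roi)
        frame = ms.scan_film(od_green, array,
                             seed=_small_seed(test_seeds[2 * k + 1]))
        per_ldr = adc_to_dose(frame, cal)
        moem = float(per_ldr[per_ldr.good].dose_gy.mean())
        rows.append({"dose_gy": d, "scanner_gy": stats.mean, "moem_gy": moem,
                     "difference_gy": stats.mean - moem})
    return pd.DataFrame(rows)
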