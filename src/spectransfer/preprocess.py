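"""Raw hyperspectral cubes -> per-leaf mean reflectance spectra.

Pipeline: black/white calibration, NIR-threshold plant segmentation
(792 nm, reflectance > 0.1), manual stem-rectangle removal, 8-connected
leaf labelling, band trimming to 450-902 nm, and rule-based outlier
rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

#: nearest-band lookup tolerance: requested nm must be within this of a band
BAND_TOLERANCE_NM = 5.0


@dataclass
class SpectralCube:
    """rows x cols x bands array with a strictly increasing wavelength axis."""

    values: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"  # {"raw", "reflectance"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("cube must be rows x cols x bands")
        if self.wavelengths.ndim != 1 or self.wavelengths.size != self.values.shape[2]:
            raise ValueError("wavelength axis must match band count")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"unknown cube kind {self.kind!r}")

    def band_index(self, wavelength: float, tolerance: float = BAND_TOLERANCE_NM) -> int:
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        if abs(self.wavelengths[idx] - wavelength) > tolerance:
            raise ValueError(
                f"no band within {tolerance} nm of {wavelength} nm "
                f"(nearest: {self.wavelengths[idx]} nm)"
            )
        return idx


@dataclass
class LeafSpectrum:
    """One leaf's per-band mean reflectance plus its experimental labels."""

    reflectance: np.ndarray
    wavelengths: np.ndarray
    labels: dict = field(default_factory=dict)
    n_pixels: int = 0

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.reflectance.shape != self.wavelengths.shape:
            raise ValueError("reflectance/wavelength length mismatch")


def calibrate(raw: SpectralCube, dark: SpectralCube, white: SpectralCube) -> SpectralCube:
    """reflectance = (raw - dark) / (white - dark), per pixel and band.

    No clipping: out-of-[0, 1] reflectance is an outlier signal handled
    downstream, not silently fixed here.
    """
    for other, name in ((dark, "dark"), (white, "white")):
        if other.values.shape != raw.values.shape:
            raise ValueError(f"{name} frame shape {other.values.shape} != raw {raw.values.shape}")
        if not np.array_equal(other.wavelengths, raw.wavelengths):
            raise ValueError(f"{name} frame wavelength grid differs from raw")
    denom = white.values - dark.values
    if np.any(denom <= 0):
        raise ValueError("white - dark must be positive for every pixel/band")
    refl = (raw.values - dark.values) / denom
    return SpectralCube(refl, raw.wavelengths, kind="reflectance")


def segment_plant(
    cube: SpectralCube, wavelength: float = 792.0, threshold: float = 0.1
) -> np.ndarray:
    """Plant mask: reflectance at the band nearest ``wavelength`` > threshold."""
    if cube.kind != "reflectance":
        raise ValueError("segment_plant requires a reflectance cube")
    band = cube.band_index(wavelength)
    return cube.values[:, :, band] > threshold


def remove_stems(mask: np.ndarray, rectangles: list[dict]) -> np.ndarray:
    """Zero out pixels inside any half-open [x, x+w) x [y, y+h) rectangle."""
    mask = np.asarray(mask, dtype=bool)
    out = mask.copy()
    h, w = mask.shape
    for rect in rectangles:
        x, y = int(rect["x"]), int(rect["y"])
        rw, rh = int(rect["width"]), int(rect["height"])
        if x < 0 or y < 0 or rw < 0 or rh < 0 or x + rw > w or y + rh > h:
            raise ValueError(f"rectangle {rect} out of image bounds {h}x{w}")
        out[y : y + rh, x : x + rw] = False
    return out


_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


def extract_leaves(mask: np.ndarray, min_area: int = 50) -> np.ndarray:
    """8-connected components with area >= min_area, labelled 1..k.

    Labels follow raster order of each component's first pixel so the output
    is a pure function of the mask.
    """
    labelled, _ = ndimage.label(np.asarray(mask, dtype=bool), structure=_STRUCTURE_8)
    out = np.zeros_like(labelled)
    next_label = 0
    seen: dict[int, int] = {}
    flat = labelled.ravel()
    areas = np.bincount(flat)
    for lab in flat:
        if lab == 0 or lab in seen:
            continue
        if areas[lab] >= min_area:
            next_label += 1
            seen[lab] = next_label
        else:
            seen[lab] = 0
    for old, new in seen.items():
        out[labelled == old] = new
    return out


def mean_spectrum(
    cube: SpectralCube, component: np.ndarray, labels: dict | None = None
) -> LeafSpectrum:
    """Per-band arithmetic mean over a boolean pixel set."""
    component = np.asarray(component, dtype=bool)
    n = int(component.sum())
    if n == 0:
        raise ValueError("empty component")
    mean = cube.values[component, :].mean(axis=0)
    return LeafSpectrum(mean, cube.wavelengths, labels=dict(labels or {}), n_pixels=n)


def trim_bands(spectrum: LeafSpectrum, low: float = 450.0, high: float = 902.0) -> LeafSpectrum:
    """Keep bands with low <= wavelength <= high (inclusive both ends)."""
    if low > high:
        raise ValueError("low must be <= high")
    keep = (spectrum.wavelengths >= low) & (spectrum.wavelengths <= high)
    if not keep.any():
        raise ValueError(f"no bands within [{low}, {high}] nm")
    return replace(
        spectrum,
        reflectance=spectrum.reflectance[keep],
        wavelengths=spectrum.wavelengths[keep],
    )


def extract_cube_spectra(
    raw: SpectralCube,
    dark: SpectralCube,
    white: SpectralCube,
    stem_rectangles: list[dict],
    labels: dict | None = None,
    *,
    min_area: int = 50,
    low: float = 450.0,
    high: float = 902.0,
) -> list[LeafSpectrum]:
    """Full cube pipeline: calibrate -> segment -> de-stem -> label -> mean -> trim."""
    refl = calibrate(raw, dark, white)
    mask = segment_plant(refl)
    mask = remove_stems(mask, stem_rectangles)
    components = extract_leaves(mask, min_area=min_area)
    spectra = []
    for leaf_id in range(1, components.max() + 1):
        labs = dict(labels or {})
        labs["leaf_id"] = leaf_id
        spec = mean_spectrum(refl, components == leaf_id, labs)
        spectra.append(trim_bands(spec, low, high))
    return spectra


# ---------------------------------------------------------------------------
# Outlier rejection on the wide spectra table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutlierRules:
    """Concrete rendering of a shape-and-reflectance sanity screen.

    A spectrum is rejected if any band is negative or above ``band_max``, if
    its mean NIR (``nir_low``-``nir_high`` nm) reflectance is below
    ``nir_floor`` (background/soil, not leaf), or if its Euclidean distance
    to its (experiment, group, DAT) mean exceeds ``distance_factor`` x the
    stratum's median such distance.  The distance rule is applied once, not
    iterated, for determinism.
    """

    band_min: float = 0.0
    band_max: float = 1.2
    nir_low: float = 780.0
    nir_high: float = 900.0
    nir_floor: float = 0.15
    distance_factor: float = 4.0


def reject_outliers(
    table: pd.DataFrame, rules: OutlierRules = OutlierRules()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a wide spectra table into (retained, rejected-with-reason).

    ``table`` uses the generator's schema: label columns then ``wl_<nm>``
    columns.  Returns the retained rows and a frame of rejected rows with a
    ``reason`` column naming the triggering rule.
    """
    wl_cols = [c for c in table.columns if c.startswith("wl_")]
    if not wl_cols:
        raise ValueError("table has no wl_<nm> columns")
    wl = np.array([float(c[3:]) for c in wl_cols])
    values = table[wl_cols].to_numpy(dtype=float)

    reasons = pd.Series("", index=table.index, dtype=object)

    bad_band = (values < rules.band_min).any(axis=1) | (values > rules.band_max).any(axis=1)
    reasons[bad_band] = f"band outside [{rules.band_min}, {rules.band_max}]"

    nir = (wl >= rules.nir_low) & (wl <= rules.nir_high)
    if nir.any():
        low_nir = values[:, nir].mean(axis=1) < rules.nir_floor
        low_nir &= reasons == ""
        reasons[low_nir] = f"mean NIR reflectance < {rules.nir_floor}"

    strata = [c for c in ("experiment", "cultivar", "treatment", "dat") if c in table.columns]
    if strata:
        for _, idx in table.groupby(strata, sort=False).groups.items():
            sub = values[table.index.get_indexer(idx)]
            centre = sub.mean(axis=0)
            dist = np.linalg.norm(sub - centre, axis=1)
            med = np.median(dist)
            if med > 0:
                far = dist > rules.distance_factor * med
                for row, is_far in zip(idx, far):
                    if is_far and reasons[row] == "":
                        reasons[row] = (
                            f"distance to group mean > {rules.distance_factor}x median"
                        )

    rejected = table[reasons != ""].copy()
    rejected["reason"] = reasons[reasons != ""]
    return table[reasons == ""].copy(), rejected


def spectra_to_table(spectra: list[LeafSpectrum]) -> pd.DataFrame:
    """Stack LeafSpectrum objects into the wide CSV schema."""
    if not spectra:
        raise ValueError("no spectra")
    wl = spectra[0].wavelengths
    for s in spectra:
        if not np.array_equal(s.wavelengths, wl):
            raise ValueError("spectra are on different wavelength grids")
    labels = pd.DataFrame([s.labels for s in spectra])
    labels["n_pixels"] = [s.n_pixels for s in spectra]
    values = pd.DataFrame(
        np.vstack([s.reflectance for s in spectra]),
        columns=[f"wl_{w:g}" for w in wl],
    )
    return pd.concat([labels, values], axis=1)
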