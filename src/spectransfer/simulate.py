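"""Seeded synthetic leaf spectra with class, time-course and domain-shift structure.

The generator emulates a glyphosate-screening trial on maize seedlings:
four groups (RT/RW/ST/SW: resistant/sensitive x treated/water), sampled at
2, 4, 6 and 8 days after treatment (DAT), across several independent
"experiments" that differ by an instrument/condition domain shift.  Only the
sensitive-treated (ST) group senesces; RT, RW and SW share one healthy
reflectance curve at every DAT.

The healthy leaf curve is a logistic red-edge step from a visible baseline
to a NIR plateau, minus Gaussian pigment absorption dips centred at 670 nm
(chlorophyll) and 500 nm (carotenoid).  Senescence in ST is a linear ramp in
(DAT - onset): the chlorophyll dip shallows, the red edge shifts blue and
the NIR plateau declines.  Each experiment applies an affine
(gain/offset) distortion, a wavelength-registration shift and per-band
Gaussian noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("RT", "RW", "ST", "SW")

#: nm centres / widths of the two pigment absorption features
CHLOROPHYLL_NM = 670.0
CHLOROPHYLL_SIGMA = 25.0
CAROTENOID_NM = 500.0
CAROTENOID_SIGMA = 20.0


def default_wavelengths() -> np.ndarray:
    """Analysis grid: 450-902 nm, 2 nm step (227 bands)."""
    return np.arange(450.0, 904.0, 2.0)


def acquisition_wavelengths() -> np.ndarray:
    """Full sensor grid before trimming: 380-1030 nm, 2 nm step."""
    return np.arange(380.0, 1032.0, 2.0)


@dataclass(frozen=True)
class BaseCurve:
    """Healthy-leaf reflectance curve parameters (unitless reflectance, nm)."""

    visible_level: float = 0.08
    nir_plateau: float = 0.55
    red_edge_nm: float = 715.0
    red_edge_width: float = 10.0
    chlorophyll_dip: float = 0.05
    carotenoid_dip: float = 0.03


@dataclass(frozen=True)
class SenescenceModel:
    """Linear per-day drift of ST away from the healthy curve after onset.

    Divergence is zero for DAT <= ``onset_dat`` and grows linearly in
    (DAT - onset) afterwards.
    """

    chlorophyll_dip_decay: float = 0.010   # dip depth lost per day
    red_edge_shift: float = 5.0            # nm blue-shift per day
    nir_decline: float = 0.030             # plateau reflectance lost per day
    onset_dat: float = 4.0

    def ramp(self, dat: float) -> float:
        return max(0.0, float(dat) - self.onset_dat)


@dataclass(frozen=True)
class DomainShift:
    """Per-experiment measurement distortion.

    ``gain``/``offset`` form an affine reflectance error, ``wavelength_shift``
    a registration error in nm, ``noise_sd`` per-band Gaussian noise.
    """

    gain: float = 1.0
    offset: float = 0.0
    wavelength_shift: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError(f"gain must be > 0, got {self.gain}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")


IDENTITY_DOMAIN = DomainShift()

#: Three-experiment defaults: large enough to break a naive cross-experiment
#: SVM, small enough for TCA / source updating to recover.
DEFAULT_DOMAINS: dict[str, DomainShift] = {
    "Exp1": DomainShift(gain=1.00, offset=0.000, wavelength_shift=0.0, noise_sd=0.006),
    "Exp2": DomainShift(gain=0.92, offset=0.020, wavelength_shift=2.0, noise_sd=0.010),
    "Exp3": DomainShift(gain=1.08, offset=-0.015, wavelength_shift=-2.0, noise_sd=0.008),
}


@dataclass(frozen=True)
class GeneratorConfig:
    wavelengths: np.ndarray = field(default_factory=default_wavelengths)
    n_plants_per_group: int = 40
    leaves_per_plant: int = 3
    dats: tuple[int, ...] = (2, 4, 6, 8)
    groups: tuple[str, ...] = GROUPS
    seed: int = 0
    base: BaseCurve = field(default_factory=BaseCurve)
    senescence: SenescenceModel = field(default_factory=SenescenceModel)
    domains: dict[str, DomainShift] = field(default_factory=lambda: dict(DEFAULT_DOMAINS))
    plant_effect_sd: float = 0.10   # sd of multiplicative plant effect on dip/plateau
    leaf_effect_sd: float = 0.05    # sd of additional per-leaf effect

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be 1-D and strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        if self.n_plants_per_group < 1 or self.leaves_per_plant < 1:
            raise ValueError("counts must be >= 1")
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("duplicate group labels")
        if len(self.dats) == 0:
            raise ValueError("at least one DAT required")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


def _gauss(wl: np.ndarray, centre: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - centre) / sigma) ** 2)


def base_reflectance(
    wl: np.ndarray,
    base: BaseCurve,
    *,
    chlorophyll_dip: float | None = None,
    nir_plateau: float | None = None,
    red_edge_nm: float | None = None,
) -> np.ndarray:
    """Closed-form healthy/senescing curve with optional parameter overrides."""
    dip = base.chlorophyll_dip if chlorophyll_dip is None else chlorophyll_dip
    plateau = base.nir_plateau if nir_plateau is None else nir_plateau
    edge = base.red_edge_nm if red_edge_nm is None else red_edge_nm
    step = 1.0 / (1.0 + np.exp(-(wl - edge) / base.red_edge_width))
    curve = base.visible_level + (plateau - base.visible_level) * step
    curve = curve - dip * _gauss(wl, CHLOROPHYLL_NM, CHLOROPHYLL_SIGMA)
    curve = curve - base.carotenoid_dip * _gauss(wl, CAROTENOID_NM, CAROTENOID_SIGMA)
    return curve


def _group_curve_params(
    group: str, dat: float, base: BaseCurve, sen: SenescenceModel,
    dip_effect: float = 0.0, plateau_effect: float = 0.0,
) -> dict[str, float]:
    dip = base.chlorophyll_dip * (1.0 + dip_effect)
    plateau = base.nir_plateau * (1.0 + plateau_effect)
    edge = base.red_edge_nm
    if group == "ST":
        r = sen.ramp(dat)
        dip = max(dip - sen.chlorophyll_dip_decay * r, 0.0)
        plateau = plateau - sen.nir_decline * r
        edge = edge - sen.red_edge_shift * r
    return {"chlorophyll_dip": dip, "nir_plateau": plateau, "red_edge_nm": edge}


def simulate_spectrum(
    group: str,
    dat: float,
    domain: DomainShift = IDENTITY_DOMAIN,
    plant_effect: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
    config: GeneratorConfig | None = None,
) -> np.ndarray:
    """One leaf's reflectance on the configured grid.

    ``plant_effect`` is a (dip, plateau) pair of relative perturbations;
    (0, 0) yields the deterministic group curve.  The domain's wavelength
    shift is applied by evaluating the analytic curve at ``wl + shift``, so
    between-domain differences of noiseless spectra are exactly the composed
    affine + registration transform.
    """
    config = config or GeneratorConfig()
    if group not in config.groups:
        raise ValueError(f"unknown group {group!r}; configured: {config.groups}")
    if dat not in config.dats:
        raise ValueError(f"dat {dat} not in configured set {config.dats}")
    wl = config.wavelengths
    if abs(domain.wavelength_shift) >= (wl[-1] - wl[0]) / 2:
        raise ValueError("wavelength_shift larger than half the spectral range")
    params = _group_curve_params(
        group, dat, config.base, config.senescence,
        dip_effect=plant_effect[0], plateau_effect=plant_effect[1],
    )
    curve = base_reflectance(wl + domain.wavelength_shift, config.base, **params)
    refl = domain.gain * curve + domain.offset
    if domain.noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        refl = refl + rng.normal(0.0, domain.noise_sd, size=wl.shape)
    return np.clip(refl, 0.001, 0.999)


def wavelength_columns(wl: np.ndarray) -> list[str]:
    return [f"wl_{w:g}" for w in wl]


def simulate_experiment(config: GeneratorConfig, experiment_id: str) -> pd.DataFrame:
    """All leaves of one experiment as a wide table.

    Columns: experiment, plant_id, leaf_id, cultivar, treatment, dat, then
    one ``wl_<nm>`` column per band.  One row per
    (group x plant x leaf x DAT); plant effects persist across DATs and
    leaves, leaf effects across DATs.
    """
    if experiment_id not in config.domains:
        raise KeyError(f"unknown experiment {experiment_id!r}; configured: {list(config.domains)}")
    domain = config.domains[experiment_id]
    exp_index = list(config.domains).index(experiment_id)
    rng = np.random.default_rng([config.seed, exp_index])

    rows = []
    spectra = []
    for group in config.groups:
        cultivar, treatment = group[0], group[1]
        for plant in range(config.n_plants_per_group):
            p_dip, p_plat = rng.normal(0.0, config.plant_effect_sd, size=2)
            for leaf in range(config.leaves_per_plant):
                l_dip, l_plat = rng.normal(0.0, config.leaf_effect_sd, size=2)
                effect = (p_dip + l_dip, p_plat + l_plat)
                for dat in config.dats:
                    spectra.append(
                        simulate_spectrum(group, dat, domain, effect, rng, config)
                    )
                    rows.append(
                        (experiment_id, f"{group}_{plant:03d}", leaf, cultivar, treatment, dat)
                    )
    labels = pd.DataFrame(
        rows, columns=["experiment", "plant_id", "leaf_id", "cultivar", "treatment", "dat"]
    )
    values = pd.DataFrame(np.asarray(spectra), columns=wavelength_columns(config.wavelengths))
    return pd.concat([labels, values], axis=1)


def simulate_all(config: GeneratorConfig) -> pd.DataFrame:
    """Concatenate :func:`simulate_experiment` over every configured domain."""
    return pd.concat(
        [simulate_experiment(config, e) for e in config.domains], ignore_index=True
    )


# ---------------------------------------------------------------------------
# Scene rendering: full cubes with dark/white references and stem rectangles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneSpec:
    """Tray layout for :func:`render_cube`.

    Leaves are ellipses on a grid of cells with a stem rectangle attached
    below each; background reflectance is flat and below the 792 nm / 0.1
    segmentation threshold by construction.
    """

    n_rows: int = 2
    n_cols: int = 4
    cell_px: int = 40
    leaf_semi_axes: tuple[int, int] = (9, 14)   # (row, col) semi-axes
    stem_size: tuple[int, int] = (4, 8)          # (height, width) in px
    background_reflectance: float = 0.05
    dark_level: float = 100.0
    white_level: float = 4000.0
    pixel_noise_sd: float = 0.005


@dataclass
class RenderedScene:
    raw: "np.ndarray"            # counts, rows x cols x bands
    dark: "np.ndarray"
    white: "np.ndarray"
    wavelengths: np.ndarray
    stem_rectangles: list[dict]  # {x, y, width, height} pixel coords
    leaf_labels: np.ndarray      # ground-truth leaf id per pixel (0 = none)
    spectra: np.ndarray          # input spectra, one row per leaf


def render_cube(
    spectra: np.ndarray,
    wavelengths: np.ndarray,
    scene: SceneSpec = SceneSpec(),
    rng: np.random.Generator | None = None,
) -> RenderedScene:
    """Render leaf spectra into a raw-count cube with references.

    raw = dark + reflectance * (white - dark), plus pixel noise on leaf
    reflectance.  Leaves never overlap (grid placement); stems carry their
    leaf's spectrum and are annotated as rectangles for later removal.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    wavelengths = np.asarray(wavelengths, dtype=float)
    n_leaves, n_bands = spectra.shape
    if n_bands != wavelengths.size:
        raise ValueError("spectra band count does not match wavelength grid")
    if n_leaves > scene.n_rows * scene.n_cols:
        raise ValueError(
            f"cannot place {n_leaves} leaves in a {scene.n_rows}x{scene.n_cols} grid without overlap"
        )
    rng = rng or np.random.default_rng(0)

    h = scene.n_rows * scene.cell_px
    w = scene.n_cols * scene.cell_px
    refl = np.full((h, w, n_bands), scene.background_reflectance, dtype=float)
    labels = np.zeros((h, w), dtype=int)
    rects: list[dict] = []

    a, b = scene.leaf_semi_axes
    rr, cc = np.mgrid[0:h, 0:w]
    for k in range(n_leaves):
        cell_r, cell_c = divmod(k, scene.n_cols)
        cy = cell_r * scene.cell_px + scene.cell_px // 2 - scene.stem_size[0] // 2
        cx = cell_c * scene.cell_px + scene.cell_px // 2
        inside = ((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1.0
        labels[inside] = k + 1
        refl[inside, :] = spectra[k]
        sh, sw = scene.stem_size
        sy, sx = cy + a, cx - sw // 2
        refl[sy : sy + sh, sx : sx + sw, :] = spectra[k]
        rects.append({"x": int(sx), "y": int(sy), "width": int(sw), "height": int(sh)})

    leafish = labels > 0
    for r in rects:
        leafish[r["y"] : r["y"] + r["height"], r["x"] : r["x"] + r["width"]] = True
    noise = rng.normal(0.0, scene.pixel_noise_sd, size=refl.shape)
    refl = np.where(leafish[:, :, None], refl + noise, refl)

    dark = np.full((h, w, n_bands), scene.dark_level, dtype=float)
    white = np.full((h, w, n_bands), scene.white_level, dtype=float)
    raw = dark + refl * (white - dark)
    return RenderedScene(
        raw=raw, dark=dark, white=white, wavelengths=wavelengths,
        stem_rectangles=rects, leaf_labels=labels, spectra=spectra,
    )
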