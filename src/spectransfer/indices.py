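"""Declarative registry of 16 vegetation spectral indices.

Each index is an arithmetic expression over reflectances at named
wavelengths (``R670`` = reflectance at the band nearest 670 nm).  A missing
band (outside the grid by more than the lookup tolerance) is an *error*; a
zero denominator is a legitimately *undefined* value, returned as NaN and
flagged — never silently coerced to 0.

The default registry holds canonical literature formulas for health,
pigment-composition and photosynthesis indices (NDVI, GNDVI, RDVI, EVI,
NRI, TVI, PRI, ARI, PSRI, SIPI, TCARI, OSAVI, TCARI/OSAVI, MCARI, ZM,
CRI550).  It is data-driven: an alternative 16-index set can be loaded from
a JSON file without code changes.  The blue bands of EVI/SIPI are mapped to
450 nm, the floor of the trimmed 450-902 nm analysis range.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import BAND_TOLERANCE_NM, LeafSpectrum

LABEL_COLUMNS = ("experiment", "plant_id", "leaf_id", "cultivar", "treatment", "dat")


@dataclass(frozen=True)
class IndexDefinition:
    name: str
    wavelengths: tuple[float, ...]
    expression: str

    def __post_init__(self) -> None:
        used = {float(m) for m in re.findall(r"R(\d+)", self.expression)}
        listed = {float(w) for w in self.wavelengths}
        if not used <= listed:
            raise ValueError(
                f"{self.name}: expression uses bands {sorted(used - listed)} "
                "not listed in wavelengths"
            )


def _d(name, wavelengths, expression):
    return IndexDefinition(name, tuple(wavelengths), expression)


DEFAULT_REGISTRY: tuple[IndexDefinition, ...] = (
    _d("NDVI", (800, 670), "(R800 - R670) / (R800 + R670)"),
    _d("GNDVI", (800, 550), "(R800 - R550) / (R800 + R550)"),
    _d("RDVI", (800, 670), "(R800 - R670) / sqrt(R800 + R670)"),
    _d("EVI", (800, 670, 450), "2.5 * (R800 - R670) / (R800 + 6*R670 - 7.5*R450 + 1)"),
    _d("NRI", (570, 670), "(R570 - R670) / (R570 + R670)"),
    _d("TVI", (750, 670, 550), "0.5 * (120*(R750 - R550) - 200*(R670 - R550))"),
    _d("PRI", (531, 570), "(R531 - R570) / (R531 + R570)"),
    _d("ARI", (550, 700), "1/R550 - 1/R700"),
    _d("PSRI", (680, 500, 750), "(R680 - R500) / R750"),
    _d("SIPI", (800, 450, 680), "(R800 - R450) / (R800 - R680)"),
    _d("TCARI", (700, 670, 550), "3 * ((R700 - R670) - 0.2*(R700 - R550)*(R700/R670))"),
    _d("OSAVI", (800, 670), "1.16 * (R800 - R670) / (R800 + R670 + 0.16)"),
    _d(
        "TCARI_OSAVI",
        (700, 670, 550, 800),
        "(3 * ((R700 - R670) - 0.2*(R700 - R550)*(R700/R670)))"
        " / (1.16 * (R800 - R670) / (R800 + R670 + 0.16))",
    ),
    _d("MCARI", (700, 670, 550), "((R700 - R670) - 0.2*(R700 - R550)) * (R700/R670)"),
    _d("ZM", (750, 710), "R750 / R710"),
    _d("CRI550", (510, 550), "1/R510 - 1/R550"),
)

INDEX_NAMES: tuple[str, ...] = tuple(d.name for d in DEFAULT_REGISTRY)


def band_at(
    wavelengths: np.ndarray,
    reflectance: np.ndarray,
    wavelength: float,
    tolerance: float = BAND_TOLERANCE_NM,
) -> float:
    """Reflectance at the nearest grid band; tie goes to the lower band."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    idx = int(np.argmin(np.abs(wavelengths - wavelength)))
    if abs(wavelengths[idx] - wavelength) > tolerance:
        raise ValueError(
            f"no band within {tolerance} nm of {wavelength} nm "
            f"(nearest: {wavelengths[idx]} nm)"
        )
    return float(np.asarray(reflectance, dtype=float)[idx])


_EVAL_GLOBALS = {"__builtins__": {}, "sqrt": math.sqrt}


def compute_index(spectrum: LeafSpectrum, definition: IndexDefinition) -> float:
    """Evaluate one index; NaN marks a degenerate (zero-denominator) value."""
    bands = {
        f"R{int(w)}": band_at(spectrum.wavelengths, spectrum.reflectance, w)
        for w in definition.wavelengths
    }
    try:
        with np.errstate(divide="ignore", invalid="ignore"):
            value = float(eval(definition.expression, _EVAL_GLOBALS, bands))
    except ZeroDivisionError:
        return math.nan
    return value if math.isfinite(value) else math.nan


def index_table(
    spectra: list[LeafSpectrum] | pd.DataFrame,
    registry: tuple[IndexDefinition, ...] = DEFAULT_REGISTRY,
) -> pd.DataFrame:
    """Samples x indices table with labels carried through.

    Accepts either LeafSpectrum objects or a wide ``wl_<nm>`` table.  Adds a
    boolean ``flagged`` column marking rows with any undefined index; such
    rows are excluded from modelling by default downstream.
    """
    if isinstance(spectra, pd.DataFrame):
        spectra = _frame_to_spectra(spectra)
    if len(spectra) == 0:
        raise ValueError("no spectra")
    labels = pd.DataFrame([s.labels for s in spectra])
    values = pd.DataFrame(
        [[compute_index(s, d) for d in registry] for s in spectra],
        columns=[d.name for d in registry],
    )
    out = pd.concat([labels.reset_index(drop=True), values], axis=1)
    out["flagged"] = values.isna().any(axis=1)
    return out


def _frame_to_spectra(table: pd.DataFrame) -> list[LeafSpectrum]:
    wl_cols = [c for c in table.columns if c.startswith("wl_")]
    if not wl_cols:
        raise ValueError("table has no wl_<nm> columns")
    wl = np.array([float(c[3:]) for c in wl_cols])
    label_cols = [c for c in table.columns if not c.startswith("wl_")]
    values = table[wl_cols].to_numpy(dtype=float)
    return [
        LeafSpectrum(values[i], wl, labels=dict(zip(label_cols, row)))
        for i, row in enumerate(table[label_cols].itertuples(index=False, name=None))
    ]


def save_registry(registry: tuple[IndexDefinition, ...], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            [
                {"name": d.name, "wavelengths": list(d.wavelengths), "expression": d.expression}
                for d in registry
            ],
            indent=2,
        )
    )


def load_registry(path: str | Path) -> tuple[IndexDefinition, ...]:
    entries = json.loads(Path(path).read_text())
    registry = tuple(
        IndexDefinition(e["name"], tuple(e["wavelengths"]), e["expression"]) for e in entries
    )
    names = [d.name for d in registry]
    if len(set(names)) != len(names):
        raise ValueError("duplicate index names in registry")
    return registry


class SpectralIndexTransformer(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer: wide spectra table -> index matrix.

    ``transform`` returns the numeric index columns only (registry order),
    so the step drops straight into an sklearn pipeline ahead of a
    classifier; use :func:`index_table` when labels must be carried.
    """

    def __init__(self, registry: tuple[IndexDefinition, ...] = DEFAULT_REGISTRY):
        self.registry = registry

    def fit(self, X, y=None):
        self.n_features_in_ = len(self.registry)
        return self

    def transform(self, X) -> np.ndarray:
        table = index_table(X, self.registry)
        return table[[d.name for d in self.registry]].to_numpy(dtype=float)

    def get_feature_names_out(self, input_features=None):
        return np.array([d.name for d in self.registry], dtype=object)
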