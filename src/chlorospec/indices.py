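"""Vegetation and water spectral indices.

Fourteen closed-form indices over raw reflectance at named wavelengths:
ten chlorophyll-sensitive vegetation indices and four water-sensitive
indices.  Normalized-difference forms lie in [-1, 1] for positive
reflectance; ratio forms are scale invariant.

TVI is registered with two parenthesizations because its printed form is
ambiguous: the default ``literal`` reading 60(R750-R500) - 100(R670-R500)
follows the band list as printed; ``canonical`` switches to the commonly
cited 0.5[120(R750-R550) - 200(R670-R550)].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import IndexComputationError, RegistryError, SpectraValidationError
from .spectra import RAW_TAG, SpectraSet


@dataclass(frozen=True)
class IndexDefinition:
    name: str
    required_bands: tuple
    formula: str  # human-readable form


def _ratio(num, den, name):
    den = np.asarray(den, float)
    if np.any(den == 0):
        raise IndexComputationError(
            f"{name}: zero denominator for leaf row(s) "
            f"{np.flatnonzero(den == 0).tolist()}"
        )
    return np.asarray(num, float) / den


def _nd(b_hi, b_lo, name):
    return _ratio(b_hi - b_lo, b_hi + b_lo, name)


def _tvi(b, form):
    if form == "literal":
        return 60.0 * (b(750) - b(500)) - 100.0 * (b(670) - b(500))
    if form == "canonical":
        return 0.5 * (120.0 * (b(750) - b(550)) - 200.0 * (b(670) - b(550)))
    raise RegistryError(f"unknown TVI form {form!r}")


_FORMULAS = {
    "GNDVI": lambda b, f: _nd(b(750), b(550), "GNDVI"),
    "CIgreen": lambda b, f: _ratio(b(800), b(550), "CIgreen") - 1.0,
    "RVI": lambda b, f: _ratio(b(810), b(570), "RVI"),
    "CIred edge": lambda b, f: _ratio(b(800), b(720), "CIred edge") - 1.0,
    "VOG3": lambda b, f: _ratio(b(734) - b(747), b(715) + b(720), "VOG3"),
    "RNDVI": lambda b, f: _nd(b(750), b(705), "RNDVI"),
    "NDVI": lambda b, f: _nd(b(800), b(670), "NDVI"),
    "PRI": lambda b, f: _nd(b(531), b(570), "PRI"),
    "NPCI": lambda b, f: _nd(b(680), b(430), "NPCI"),
    "TVI": _tvi,
    "WI": lambda b, f: _ratio(b(900), b(970), "WI"),
    "WBI": lambda b, f: _ratio(b(950), b(900), "WBI"),
    "NDWI": lambda b, f: _nd(b(860), b(1240), "NDWI"),
    "MSI": lambda b, f: _ratio(b(1600), b(820), "MSI"),
}

_BANDS = {
    "GNDVI": (750, 550), "CIgreen": (800, 550), "RVI": (810, 570),
    "CIred edge": (800, 720), "VOG3": (734, 747, 715, 720),
    "RNDVI": (750, 705), "NDVI": (800, 670), "PRI": (531, 570),
    "NPCI": (680, 430), "TVI": (750, 670, 500, 550),
    "WI": (900, 970), "WBI": (950, 900), "NDWI": (860, 1240),
    "MSI": (1600, 820),
}

_TEXT = {
    "GNDVI": "(R750-R550)/(R750+R550)", "CIgreen": "R800/R550 - 1",
    "RVI": "R810/R570", "CIred edge": "R800/R720 - 1",
    "VOG3": "(R734-R747)/(R715+R720)", "RNDVI": "(R750-R705)/(R750+R705)",
    "NDVI": "(R800-R670)/(R800+R670)", "PRI": "(R531-R570)/(R531+R570)",
    "NPCI": "(R680-R430)/(R680+R430)",
    "TVI": "60(R750-R500) - 100(R670-R500)  [literal form]",
    "WI": "R900/R970", "WBI": "R950/R900",
    "NDWI": "(R860-R1240)/(R860+R1240)", "MSI": "R1600/R820",
}

INDEX_REGISTRY = {
    name: IndexDefinition(name, _BANDS[name], _TEXT[name]) for name in _FORMULAS
}

ALL_INDICES = tuple(INDEX_REGISTRY)  # 14 entries, chlorophyll set first
#: the ten chlorophyll-sensitive vegetation indices
CHLOROPHYLL_INDICES = ALL_INDICES[:10]
#: the six vegetation indices most correlated with chlorophyll
VI6 = ("GNDVI", "CIgreen", "RVI", "CIred edge", "VOG3", "RNDVI")
#: the four water-sensitive indices
WATER_INDICES = ("WI", "WBI", "NDWI", "MSI")

_ALIASES = {"CIrededge": "CIred edge", "CI_red_edge": "CIred edge",
            "CI red edge": "CIred edge"}


def _canonical(name: str) -> str:
    key = _ALIASES.get(name, name)
    if key not in INDEX_REGISTRY:
        raise RegistryError(f"unknown spectral index {name!r}")
    return key


def compute_index(name: str, s: SpectraSet, tvi_form: str = "literal") -> np.ndarray:
    """Per-leaf values of one index, computed from raw reflectance."""
    if s.transform_tag != RAW_TAG:
        raise SpectraValidationError(
            f"indices are defined on raw reflectance, got tag {s.transform_tag!r}"
        )
    key = _canonical(name)
    return np.asarray(_FORMULAS[key](s.band, tvi_form), dtype=float)


def compute_index_table(s: SpectraSet, names=ALL_INDICES,
                        tvi_form: str = "literal") -> pd.DataFrame:
    """Leaves x indices predictor table, columns in the requested order."""
    data = {(_canonical(n)): compute_index(n, s, tvi_form) for n in names}
    return pd.DataFrame(data)
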