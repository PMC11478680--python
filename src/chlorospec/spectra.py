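"""Leaf spectra data model, delimited-text I/O and group-mean curves.

A :class:`SpectraSet` couples an ``n_leaves x n_wavelengths`` reflectance
matrix on a shared :class:`WavelengthGrid` with per-leaf metadata
(seedling id, drought treatment T1-T4, leaf-pair position, leaf side) and
the measured chlorophyll content in mg/g.  Wavelengths are always
addressed by their physical nm label, never by column index.

The on-disk format is a wide CSV: one comment line carrying the transform
tag, then a header with the metadata columns followed by one column per
wavelength.  Raw reflectance ("R") must lie in (0, 1]; transformed sets
may take any real values.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import GridError, SchemaError, SpectraValidationError

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("seedling_id", "treatment", "pair_position", "leaf_side", "chlorophyll")
TREATMENTS = ("T1", "T2", "T3", "T4")

#: tag of an untransformed reflectance set
RAW_TAG = "R"

_TAG_PREFIX = "# transform_tag:"


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing, uniformly spaced wavelength axis in nm.

    The default instrument grid is 350-2500 nm resampled at 1 nm, i.e.
    exactly 2151 points; band 550 nm then sits at column 200.
    """

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 2:
            raise GridError("wavelength grid needs at least two points")
        diffs = np.diff(vals)
        if np.any(diffs <= 0):
            raise GridError("wavelength grid must be strictly increasing")
        if not np.allclose(diffs, diffs[0], rtol=0, atol=1e-6):
            raise GridError("wavelength grid must be uniformly spaced")

    @classmethod
    def default(cls) -> "WavelengthGrid":
        return cls(np.arange(350.0, 2501.0, 1.0))

    @classmethod
    def regular(cls, start: float, stop: float, step: float) -> "WavelengthGrid":
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))

    @property
    def start_nm(self) -> float:
        return float(self.values[0])

    @property
    def stop_nm(self) -> float:
        return float(self.values[-1])

    @property
    def step_nm(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return self.values.size

    def index_of(self, wavelength_nm: float) -> int:
        """Column index of a physical wavelength; exact match required."""
        idx = int(round((wavelength_nm - self.start_nm) / self.step_nm))
        if idx < 0 or idx >= len(self) or abs(self.values[idx] - wavelength_nm) > 1e-6:
            raise GridError(f"wavelength {wavelength_nm} nm not on grid")
        return idx

    def window_mask(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Boolean mask of grid points inside the inclusive window."""
        return (self.values >= lo_nm) & (self.values <= hi_nm)


@dataclass(frozen=True)
class LeafRecord:
    """Metadata for one leaf.

    pair_position counts leaf pairs from the shoot apex: 1 is the first
    pair of top leaves.  Treatment Tk carries positions 1..k only.
    """

    seedling_id: str
    treatment: str
    pair_position: int
    leaf_side: int
    chlorophyll: float

    def __post_init__(self):
        if self.treatment not in TREATMENTS:
            raise SchemaError(f"unknown treatment {self.treatment!r}")
        k = int(self.treatment[1])
        if not 1 <= self.pair_position <= k:
            raise SchemaError(
                f"treatment {self.treatment} admits pair_position 1..{k}, "
                f"got {self.pair_position}"
            )
        if self.leaf_side not in (1, 2):
            raise SchemaError(f"leaf_side must be 1 or 2, got {self.leaf_side}")
        if not self.chlorophyll > 0:
            raise SchemaError("chlorophyll must be positive")


@dataclass
class SpectraSet:
    """Reflectance matrix plus aligned leaf metadata.

    ``records`` is a DataFrame with the METADATA_COLUMNS; its row order
    matches the rows of ``reflectance``.
    """

    grid: WavelengthGrid
    reflectance: np.ndarray
    records: pd.DataFrame
    transform_tag: str = RAW_TAG

    def __post_init__(self):
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.ndim != 2:
            self.reflectance = self.reflectance.reshape(-1, len(self.grid))
        self.records = self.records.reset_index(drop=True)
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        n, p = self.reflectance.shape
        if p != len(self.grid):
            raise GridError(f"reflectance has {p} bands, grid has {len(self.grid)}")
        if len(self.records) != n:
            raise SchemaError(f"{n} spectra but {len(self.records)} metadata rows")
        missing = [c for c in METADATA_COLUMNS if c not in self.records.columns]
        if missing:
            raise SchemaError(f"missing metadata column(s): {', '.join(missing)}")
        if n and not np.isfinite(self.reflectance).all():
            bad = np.argwhere(~np.isfinite(self.reflectance))[:5]
            raise SpectraValidationError(f"non-finite reflectance at (row, band) {bad.tolist()}")
        if self.transform_tag == RAW_TAG and n:
            out = (self.reflectance <= 0) | (self.reflectance > 1)
            if out.any():
                cells = [
                    (int(i), float(self.grid.values[j]), float(self.reflectance[i, j]))
                    for i, j in np.argwhere(out)[:10]
                ]
                raise SpectraValidationError(
                    "raw reflectance outside (0, 1] at (row, wavelength, value): "
                    f"{cells}"
                )

    # -- accessors ---------------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return self.reflectance.shape[0]

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.values

    @property
    def chlorophyll(self) -> np.ndarray:
        return self.records["chlorophyll"].to_numpy(dtype=float)

    def band(self, wavelength_nm: float) -> np.ndarray:
        """Per-leaf values at one wavelength, addressed by nm label."""
        return self.reflectance[:, self.grid.index_of(wavelength_nm)]

    def with_values(self, values: np.ndarray, tag: str) -> "SpectraSet":
        """Same leaves/grid, new matrix and transform tag."""
        return SpectraSet(self.grid, np.asarray(values, float), self.records.copy(), tag)

    def subset(self, row_index) -> "SpectraSet":
        idx = np.asarray(row_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SpectraSet(
            self.grid,
            self.reflectance[idx],
            self.records.iloc[idx].reset_index(drop=True),
            self.transform_tag,
        )

    def trim(self, lo_nm: float, hi_nm: float) -> "SpectraSet":
        """Restrict to an inclusive wavelength window (edge-band trimming)."""
        mask = self.grid.window_mask(lo_nm, hi_nm)
        if mask.sum() < 2:
            raise GridError("trim window keeps fewer than two bands")
        return SpectraSet(
            WavelengthGrid(self.grid.values[mask]),
            self.reflectance[:, mask],
            self.records.copy(),
            self.transform_tag,
        )

    def to_frame(self) -> pd.DataFrame:
        spec = pd.DataFrame(
            self.reflectance,
            columns=[_format_wavelength(w) for w in self.grid.values],
        )
        return pd.concat([self.records.reset_index(drop=True), spec], axis=1)


def _format_wavelength(w: float) -> str:
    return f"{w:g}"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_spectra(s: SpectraSet, path) -> str:
    """Write a SpectraSet as wide CSV; round-trips through read_spectra."""
    frame = s.to_frame()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{_TAG_PREFIX} {s.transform_tag}\n")
        frame.to_csv(fh, index=False, float_format="%.10g")
    return str(path)


def read_spectra(path, dialect: dict | None = None) -> SpectraSet:
    """Read a wide-CSV spectra file into a validated SpectraSet.

    ``dialect`` may carry ``{"sep": ...}`` for other delimiters.
    """
    sep = (dialect or {}).get("sep", ",")
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        tag = RAW_TAG
        if first.startswith(_TAG_PREFIX):
            tag = first[len(_TAG_PREFIX):].strip()
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(io.StringIO(body), sep=sep)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing metadata column(s): {', '.join(missing)}")
    band_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    try:
        wavelengths = np.array([float(c) for c in band_cols])
    except ValueError as exc:
        raise GridError(f"non-numeric wavelength column: {exc}") from exc
    grid = WavelengthGrid(wavelengths)  # raises GridError on duplicates/non-uniform
    reflectance = df[band_cols].to_numpy(dtype=float)
    records = df[list(METADATA_COLUMNS)].copy()
    records["pair_position"] = records["pair_position"].astype(int)
    records["leaf_side"] = records["leaf_side"].astype(int)
    return SpectraSet(grid, reflectance, records, tag)


# ---------------------------------------------------------------------------
# Group means
# ---------------------------------------------------------------------------

def mean_spectrum_by_group(s: SpectraSet, group_keys=("treatment", "pair_position")) -> pd.DataFrame:
    """Arithmetic mean spectrum per metadata group.

    With empty ``group_keys`` a single global mean row is returned.  Groups
    are ordered by treatment then pair position.  The per-group mean is a
    convex combination of the member spectra, so it lies between the
    per-wavelength min and max of the group.
    """
    keys = list(group_keys)
    bad = [k for k in keys if k not in ("treatment", "pair_position")]
    if bad:
        raise SchemaError(f"unsupported group key(s): {bad}")
    band_cols = [_format_wavelength(w) for w in s.grid.values]
    frame = s.to_frame()
    if not keys:
        mean = frame[band_cols].mean(axis=0).to_frame().T
        mean.insert(0, "group", "all")
        return mean
    grouped = frame.groupby(keys, sort=True, observed=True)[band_cols].mean()
    if grouped.empty:
        logger.warning("no non-empty groups for keys %s", keys)
    return grouped.reset_index()
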