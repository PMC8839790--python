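"""NIR spectra data model and CSV I/O.

Spectra live in a :class:`SpectraSet`: an absorbance matrix on a strictly
increasing wavelength grid plus one metadata record per spectrum describing
the experimental cell it came from (honey type, heat-treatment temperature
and duration, replicate bottle, cuvette fill, consecutive scan).

The on-disk format is a wide CSV: six metadata columns followed by one
column per wavelength, headers being the wavelength in nm as a plain
decimal. Untreated control rows carry ``temperature_C="CONTROL"`` and
``time_min=0``. Periodic reference water scans are accepted under
``honey_type="WATER_REF"`` but are excluded from all modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import RangeError, SchemaError, SpectraValidationError

__all__ = [
    "CONTROL",
    "HONEY_TYPES",
    "META_COLUMNS",
    "TEMPERATURES",
    "TIMES",
    "WATER_REF",
    "WavelengthGrid",
    "SpectraSet",
    "read_spectra_csv",
    "write_spectra_csv",
    "cut_range",
]

HONEY_TYPES = ("sunflower", "bastard_indigo", "acacia")
WATER_REF = "WATER_REF"
CONTROL = "CONTROL"
TEMPERATURES = (40, 60, 80, 100)
TIMES = (60, 120, 180, 240)
REPLICATES = ("R1", "R2", "R3")
META_COLUMNS = ("honey_type", "temperature_C", "time_min", "replicate", "fill", "scan")

#: legal (temperature, time) design cells: 4 x 4 factorial plus the control
LEGAL_CELLS = frozenset({(CONTROL, 0)} | {(t, m) for t in TEMPERATURES for m in TIMES})

#: raw transflectance absorbance should stay below two absorbance units
MAX_RAW_ABSORBANCE = 2.0


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing, uniformly spaced wavelength axis in nm."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if wl.ndim != 1 or wl.size < 2:
            raise SpectraValidationError("grid needs at least two wavelengths")
        d = np.diff(wl)
        if np.any(d <= 0):
            raise SpectraValidationError("wavelengths must be strictly increasing")
        if np.ptp(d) > 1e-9:
            raise SpectraValidationError("wavelength spacing must be uniform")
        if wl[0] < 900.0 - 1e-9 or wl[-1] > 1700.0 + 1e-9:
            raise SpectraValidationError(
                f"wavelengths must lie in [900, 1700] nm, got [{wl[0]}, {wl[-1]}]"
            )

    @property
    def step_nm(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    @property
    def n_wavelengths(self) -> int:
        return int(self.wavelengths.size)

    def index_of_nearest(self, nm: float) -> int:
        return int(np.argmin(np.abs(self.wavelengths - nm)))

    def __len__(self) -> int:
        return self.n_wavelengths

    def __eq__(self, other) -> bool:
        return isinstance(other, WavelengthGrid) and np.array_equal(
            self.wavelengths, other.wavelengths
        )


def _validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise SchemaError(f"missing metadata column(s): {', '.join(missing)}")
    meta = meta.loc[:, list(META_COLUMNS)].copy()
    meta["honey_type"] = meta["honey_type"].astype(str)
    meta["time_min"] = meta["time_min"].astype(int)
    meta["replicate"] = meta["replicate"].astype(str)
    meta["fill"] = meta["fill"].astype(int)
    meta["scan"] = meta["scan"].astype(int)

    def _norm_temp(v):
        s = str(v).strip()
        if s.upper() == CONTROL:
            return CONTROL
        return int(float(s))

    meta["temperature_C"] = meta["temperature_C"].map(_norm_temp).astype(object)

    is_sample = meta["honey_type"] != WATER_REF
    cells = list(zip(meta.loc[is_sample, "temperature_C"], meta.loc[is_sample, "time_min"]))
    bad = [c for c in cells if c not in LEGAL_CELLS]
    if bad:
        t, m = bad[0]
        raise SpectraValidationError(
            f"illegal (temperature, time) design cell: ({t!r}, {m}); "
            f"control must pair with time_min=0 and heat levels with 60/120/180/240 min"
        )
    return meta.reset_index(drop=True)


class SpectraSet:
    """Absorbance matrix with aligned per-spectrum metadata.

    Parameters
    ----------
    grid
        Wavelength axis shared by all spectra.
    absorbance
        ``(n_spectra, n_wavelengths)`` array in absorbance units (AU).
    meta
        DataFrame with one row per spectrum and the columns
        ``honey_type, temperature_C, time_min, replicate, fill, scan``.
    """

    def __init__(self, grid: WavelengthGrid, absorbance: np.ndarray, meta: pd.DataFrame):
        absorbance = np.asarray(absorbance, dtype=float)
        if absorbance.ndim != 2:
            raise SpectraValidationError("absorbance must be a 2-D matrix")
        if absorbance.shape[1] != grid.n_wavelengths:
            raise SpectraValidationError(
                f"absorbance has {absorbance.shape[1]} columns but grid has "
                f"{grid.n_wavelengths} wavelengths"
            )
        meta = _validate_meta(meta)
        if len(meta) != absorbance.shape[0]:
            raise SpectraValidationError(
                f"{absorbance.shape[0]} spectra but {len(meta)} metadata rows"
            )
        if not np.all(np.isfinite(absorbance)):
            raise SpectraValidationError("absorbance contains NaN or Inf")
        self.grid = grid
        self.absorbance = absorbance
        self.meta = meta

    # ------------------------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def sample_ids(self) -> pd.Series:
        """One id per physical sample (bottle x treatment cell)."""
        m = self.meta
        return (
            m["honey_type"].astype(str)
            + "|" + m["temperature_C"].astype(str)
            + "|" + m["time_min"].astype(str)
            + "|" + m["replicate"].astype(str)
        )

    def select(self, mask) -> "SpectraSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpectraSet(self.grid, self.absorbance[idx], self.meta.iloc[idx])

    def exclude_water_refs(self) -> "SpectraSet":
        return self.select((self.meta["honey_type"] != WATER_REF).to_numpy())

    def subset(self, **conditions) -> "SpectraSet":
        """Row subset by metadata equality, e.g. ``subset(honey_type="acacia")``.

        A condition value may be a list/tuple/set for membership tests.
        """
        mask = np.ones(self.n_spectra, dtype=bool)
        for col, val in conditions.items():
            if col not in self.meta.columns:
                raise SchemaError(f"unknown metadata column: {col}")
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= self.meta[col].isin(list(val)).to_numpy()
            else:
                mask &= (self.meta[col] == val).to_numpy()
        return self.select(mask)

    def __len__(self) -> int:
        return self.n_spectra

    def __repr__(self) -> str:
        wl = self.grid.wavelengths
        return (
            f"<SpectraSet {self.n_spectra} spectra x {self.grid.n_wavelengths} "
            f"wavelengths [{wl[0]:g}-{wl[-1]:g} nm]>"
        )


# ----------------------------------------------------------------------
# CSV I/O


def read_spectra_csv(path) -> SpectraSet:
    """Read a wide-format spectra CSV into a validated :class:`SpectraSet`.

    Wavelength columns are sorted ascending regardless of file order, so a
    column-shuffled file round-trips to the same object.
    """
    df = pd.read_csv(path, low_memory=False)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing metadata column(s): {', '.join(missing)}")
    wl_cols = []
    for c in df.columns:
        if c in META_COLUMNS:
            continue
        try:
            wl_cols.append((float(c), c))
        except ValueError as exc:
            raise SchemaError(f"column {c!r} is neither metadata nor a wavelength") from exc
    if len(wl_cols) < 2:
        raise SchemaError("need at least two numeric wavelength columns")
    wl_cols.sort(key=lambda t: t[0])
    wl = np.array([v for v, _ in wl_cols])
    cols = [c for _, c in wl_cols]
    try:
        absorbance = df[cols].to_numpy(dtype=float)
    except (TypeError, ValueError):
        for c in cols:
            bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaError(
                    f"non-numeric absorbance value at row {row}, column {c!r}"
                ) from None
        raise
    if np.isnan(absorbance).any():
        i, j = map(int, np.argwhere(np.isnan(absorbance))[0])
        raise SchemaError(f"non-numeric absorbance value at row {i}, column {cols[j]!r}")
    s = SpectraSet(WavelengthGrid(wl), absorbance, df[list(META_COLUMNS)])
    if np.nanmax(absorbance) > MAX_RAW_ABSORBANCE:
        warnings.warn(
            f"absorbance exceeds {MAX_RAW_ABSORBANCE} AU; raw transflectance data "
            "is expected to stay below two absorbance units",
            stacklevel=2,
        )
    return s


def write_spectra_csv(s: SpectraSet, path) -> None:
    """Write a :class:`SpectraSet` in the wide CSV dialect."""
    wl_headers = [f"{w:g}" for w in s.grid.wavelengths]
    df = pd.concat(
        [
            s.meta.reset_index(drop=True),
            pd.DataFrame(s.absorbance, columns=wl_headers),
        ],
        axis=1,
    )
    df.to_csv(path, index=False, float_format="%.10g")


def cut_range(s: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Keep wavelengths in ``[lo, hi]``, inclusive, snapping the bounds to
    the nearest grid points."""
    if lo >= hi:
        raise RangeError(f"lo must be < hi, got ({lo}, {hi})")
    wl = s.grid.wavelengths
    if lo > wl[-1] or hi < wl[0]:
        raise RangeError(
            f"[{lo}, {hi}] nm does not overlap the grid [{wl[0]:g}, {wl[-1]:g}] nm"
        )
    lo_snap = wl[s.grid.index_of_nearest(lo)]
    hi_snap = wl[s.grid.index_of_nearest(hi)]
    keep = (wl >= lo_snap - 1e-9) & (wl <= hi_snap + 1e-9)
    if not keep.any():
        raise RangeError(f"cut [{lo}, {hi}] nm leaves no wavelengths")
    return SpectraSet(WavelengthGrid(wl[keep]), s.absorbance[:, keep], s.meta)
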