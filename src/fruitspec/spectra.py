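"""Reflectance spectra containers, calibration and wavelength-grid handling.

The measurement convention emulated here is a handheld VIS/NIR spectrometer
covering 302-1148 nm at a 2 nm interval (424 bands).  Raw instrument counts
are converted to reflectance factors against a white reference panel, and the
spectrum of one fruit is the pooled average of repeated scans taken at three
spots on the fruit surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_WAVELENGTHS",
    "STAGES",
    "WavelengthGrid",
    "SpectraSet",
    "TraitTable",
    "RawScanGroup",
    "SpectraFormatError",
    "CalibrationError",
    "canonical_grid",
    "calibrate",
    "average_scans",
    "resample_to_grid",
    "reflectance_at",
    "read_spectra",
    "write_spectra",
    "read_traits",
    "write_traits",
]

#: Canonical acquisition grid: 302, 304, ..., 1148 nm (424 bands).
CANONICAL_WAVELENGTHS = np.arange(302.0, 1149.0, 2.0)

#: Ripening stages in temporal order.
STAGES = ("unripe", "ripe", "overripe")

#: Reflectance factors above this are physically suspect (specular glints);
#: they trigger a warning rather than an error.
REFLECTANCE_WARN_LIMIT = 1.5


class SpectraFormatError(ValueError):
    """A spectra or trait file violates the expected layout."""


class CalibrationError(ValueError):
    """White-reference calibration cannot be applied."""


@dataclass(frozen=True)
class WavelengthGrid:
    """A strictly increasing set of wavelengths in nanometres."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise SpectraFormatError("wavelength grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(wl)):
            raise SpectraFormatError("wavelength grid contains non-finite values")
        if np.any(np.diff(wl) <= 0):
            raise SpectraFormatError("wavelengths not increasing")
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return np.array_equal(self.wavelengths, other.wavelengths)

    def __contains__(self, nm: float) -> bool:
        return bool(np.any(np.isclose(self.wavelengths, nm)))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def index_of(self, nm: float) -> int:
        """Exact index of a wavelength; raises if ``nm`` is off-grid."""
        hits = np.flatnonzero(np.isclose(self.wavelengths, nm))
        if hits.size == 0:
            raise KeyError(f"wavelength {nm} nm not on grid")
        return int(hits[0])


def canonical_grid() -> WavelengthGrid:
    """The 302-1148 nm, 2 nm-interval acquisition grid (424 bands)."""
    return WavelengthGrid(CANONICAL_WAVELENGTHS.copy())


@dataclass
class SpectraSet:
    """Calibrated reflectance spectra for a set of fruit samples.

    Parameters
    ----------
    grid
        Wavelength grid shared by every row of ``reflectance``.
    reflectance
        ``(n_samples, n_bands)`` array of unitless reflectance factors.
    sample_ids
        Unique sample identifiers, one per row.
    fruit_type
        Optional ``"mango"`` or ``"strawberry"`` tag.
    """

    grid: WavelengthGrid
    reflectance: np.ndarray
    sample_ids: list[str]
    fruit_type: str | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.reflectance, dtype=float)
        if r.ndim != 2:
            raise SpectraFormatError("reflectance must be a 2-D matrix")
        if r.shape[1] != len(self.grid):
            raise SpectraFormatError(
                f"reflectance has {r.shape[1]} bands but grid has {len(self.grid)}"
            )
        ids = [str(s) for s in self.sample_ids]
        if len(ids) != r.shape[0]:
            raise SpectraFormatError("sample_ids length does not match row count")
        seen: set[str] = set()
        for sid in ids:
            if sid in seen:
                raise SpectraFormatError(f"duplicated sample id: {sid!r}")
            seen.add(sid)
        if not np.all(np.isfinite(r)):
            raise SpectraFormatError("reflectance contains non-finite values")
        if np.any(r < 0):
            raise SpectraFormatError("reflectance contains negative values")
        if np.any(r > REFLECTANCE_WARN_LIMIT):
            warnings.warn(
                f"reflectance exceeds {REFLECTANCE_WARN_LIMIT} (possible specular glint)",
                stacklevel=2,
            )
        self.reflectance = r
        self.sample_ids = ids
        if self.fruit_type is not None and self.fruit_type not in ("mango", "strawberry"):
            raise SpectraFormatError(f"unknown fruit_type {self.fruit_type!r}")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.reflectance, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.wavelengths,
        )


@dataclass
class TraitTable:
    """Per-sample fruit quality traits and ripening-stage labels.

    Traits are stored as a mapping from trait name (``SPAD``, ``TSS``,
    ``firmness``, ``L``, ``b``) to a numeric vector aligned with
    ``sample_ids``.  Units: SPAD unitless, TSS in °Brix, firmness in N,
    L* on the 0-100 CIELAB lightness axis, b* on the CIELAB blue-yellow axis.
    """

    sample_ids: list[str]
    stage: list[str]
    traits: dict[str, np.ndarray]
    fruit_type: str | None = None

    def __post_init__(self) -> None:
        ids = [str(s) for s in self.sample_ids]
        if len(set(ids)) != len(ids):
            raise SpectraFormatError("duplicated sample id in trait table")
        stages = [str(s) for s in self.stage]
        if len(stages) != len(ids):
            raise SpectraFormatError("stage labels do not align with sample ids")
        for s in stages:
            if s not in STAGES:
                raise SpectraFormatError(f"unknown ripening stage {s!r}")
        traits: dict[str, np.ndarray] = {}
        for name, vec in self.traits.items():
            v = np.asarray(vec, dtype=float)
            if v.shape != (len(ids),):
                raise SpectraFormatError(f"trait {name!r} does not align with sample ids")
            if not np.all(np.isfinite(v)):
                raise SpectraFormatError(f"trait {name!r} contains non-finite values")
            traits[str(name)] = v
        self.sample_ids = ids
        self.stage = stages
        self.traits = traits

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits)

    def values(self, trait: str) -> np.ndarray:
        if trait not in self.traits:
            raise KeyError(f"unknown trait {trait!r}; available: {self.trait_names}")
        return self.traits[trait]

    def stage_array(self) -> np.ndarray:
        return np.asarray(self.stage, dtype=object)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.sample_ids, "stage": self.stage})
        if self.fruit_type is not None:
            df.insert(1, "fruit_type", self.fruit_type)
        for name, vec in self.traits.items():
            df[name] = vec
        return df

    def aligned_with(self, spectra: SpectraSet) -> bool:
        return self.sample_ids == spectra.sample_ids


@dataclass
class RawScanGroup:
    """Repeated raw scans of one fruit, grouped by measurement spot."""

    sample_id: str
    scans: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        scans = [np.asarray(s, dtype=float) for s in self.scans]
        if scans:
            n = scans[0].size
            for s in scans:
                if s.ndim != 1 or s.size != n:
                    raise SpectraFormatError("scans do not share a common grid")
        self.scans = scans


def average_scans(group: RawScanGroup) -> np.ndarray:
    """Pooled arithmetic mean of all scans of all spots, per band.

    With the standard 3-spot x 10-scan protocol this equals the mean of the
    three per-spot means; with unequal scan counts the pooled mean weights
    spots by their scan count.
    """
    if not group.scans:
        raise SpectraFormatError(f"no scans for sample {group.sample_id!r}")
    return np.mean(np.vstack(group.scans), axis=0)


def calibrate(
    sample_counts: np.ndarray,
    white_counts: np.ndarray,
    panel_factor: float | np.ndarray = 1.0,
    *,
    grid: WavelengthGrid,
    sample_ids: Sequence[str],
    fruit_type: str | None = None,
) -> SpectraSet:
    """White-reference calibration of raw counts to reflectance factors.

    ``reflectance = (sample_counts / white_counts) * panel_factor`` per band,
    where ``panel_factor`` is the certified reflectance of the white panel
    (scalar or per-band vector).
    """
    counts = np.atleast_2d(np.asarray(sample_counts, dtype=float))
    white = np.asarray(white_counts, dtype=float)
    if white.ndim != 1 or white.size != counts.shape[1]:
        raise CalibrationError("white_counts must be one value per band")
    if np.any(~np.isfinite(white)) or np.any(white <= 0):
        raise CalibrationError("white reference counts must be strictly positive")
    factor = np.asarray(panel_factor, dtype=float)
    refl = counts / white[np.newaxis, :] * factor
    return SpectraSet(grid=grid, reflectance=refl, sample_ids=list(sample_ids),
                      fruit_type=fruit_type)


def resample_to_grid(s: SpectraSet, target: WavelengthGrid) -> SpectraSet:
    """Piecewise-linear resampling of every spectrum onto ``target``.

    Exact pass-through on shared grid points; extrapolation outside the
    source span is refused.
    """
    lo, hi = s.grid.span
    tw = target.wavelengths
    if tw[0] < lo or tw[-1] > hi:
        raise ValueError(
            f"target grid [{tw[0]}, {tw[-1]}] nm extends beyond source span [{lo}, {hi}] nm"
        )
    if target == s.grid:
        return SpectraSet(grid=target, reflectance=s.reflectance.copy(),
                          sample_ids=list(s.sample_ids), fruit_type=s.fruit_type)
    out = np.empty((s.n_samples, len(target)))
    for i in range(s.n_samples):
        out[i] = np.interp(tw, s.wavelengths, s.reflectance[i])
    return SpectraSet(grid=target, reflectance=out, sample_ids=list(s.sample_ids),
                      fruit_type=s.fruit_type)


def reflectance_at(s: SpectraSet, nm: float) -> np.ndarray:
    """Per-sample reflectance at one wavelength, linearly interpolated if
    ``nm`` falls between grid points (Table-style indices use odd wavelengths
    such as 677 nm that are absent from the even 2 nm grid)."""
    lo, hi = s.grid.span
    if nm < lo or nm > hi:
        raise ValueError(f"wavelength {nm} nm outside grid span [{lo}, {hi}]")
    try:
        return s.reflectance[:, s.grid.index_of(nm)]
    except KeyError:
        return np.array([np.interp(nm, s.wavelengths, row) for row in s.reflectance])


# ---------------------------------------------------------------------------
# File I/O: wide delimited text, first column `sample_id`, numeric nm headers.
# ---------------------------------------------------------------------------

def read_spectra(path, delimiter: str = ",", fruit_type: str | None = None) -> SpectraSet:
    """Read a wide spectra table (rows = samples, columns = wavelengths)."""
    df = pd.read_csv(path, delimiter=delimiter, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise SpectraFormatError("spectra file needs a sample_id column plus bands")
    ids = df.iloc[:, 0].astype(str).tolist()
    try:
        wl = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavelength header: {exc}") from exc
    if np.any(np.diff(wl) <= 0):
        raise SpectraFormatError("wavelengths not increasing")
    values = np.empty((len(ids), wl.size))
    for j, col in enumerate(df.columns[1:]):
        try:
            values[:, j] = df[col].astype(float).to_numpy()
        except ValueError:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise SpectraFormatError(
                f"non-numeric reflectance at row {bad + 1}, column {col!r}"
            ) from None
    return SpectraSet(grid=WavelengthGrid(wl), reflectance=values, sample_ids=ids,
                      fruit_type=fruit_type)


def write_spectra(s: SpectraSet, path, delimiter: str = ",",
                  header_comment: str | None = None) -> None:
    """Write a SpectraSet as wide delimited text (full float precision)."""
    df = s.to_frame()
    df.columns = [_format_nm(w) for w in s.wavelengths]
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep=delimiter, float_format="%.17g")


def _format_nm(w: float) -> str:
    return f"{w:g}"


_TRAIT_COLUMNS = ("SPAD", "TSS", "firmness", "L", "b")


def read_traits(path, delimiter: str = ",") -> TraitTable:
    """Read a trait table: sample_id, fruit_type, stage, then trait columns."""
    df = pd.read_csv(path, delimiter=delimiter, comment="#")
    for required in ("sample_id", "stage"):
        if required not in df.columns:
            raise SpectraFormatError(f"trait table missing column {required!r}")
    fruit = None
    if "fruit_type" in df.columns:
        kinds = df["fruit_type"].unique()
        if len(kinds) == 1:
            fruit = str(kinds[0])
    traits = {
        c: df[c].astype(float).to_numpy()
        for c in df.columns
        if c not in ("sample_id", "fruit_type", "stage")
    }
    return TraitTable(
        sample_ids=df["sample_id"].astype(str).tolist(),
        stage=df["stage"].astype(str).tolist(),
        traits=traits,
        fruit_type=fruit,
    )


def write_traits(t: TraitTable, path, delimiter: str = ",",
                 header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        t.to_frame().to_csv(fh, sep=delimiter, index=False, float_format="%.17g")
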