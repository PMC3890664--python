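"""Core domain types for the integrative delimitation pipeline.

The pipeline compares candidate taxa along three lines of evidence —
discrete character diagnosability, gaps in continuous characters, and
climatic niche identity — anchored on candidate discovery from a rooted
gene tree.  The types here are thin, validated containers shared by all
stages; statistics live in :mod:`intdelim.tolerance` and
:mod:`intdelim.niche`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

MISSING_TOKENS = {"", "na", "nan", "none"}

#: applicability classes a character may carry (who it can be scored on)
APPLICABILITY = ("all", "adults-only", "adult-males-only")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass(frozen=True)
class ToleranceConfig:
    """Content proportion and confidence level governing tolerance computations.

    Parameters
    ----------
    content
        Population proportion P the interval must cover (default 0.95).
    confidence
        Confidence level 1 - alpha with which coverage is achieved
        (default 0.95).
    side
        ``"two-sided"`` for normal tolerance intervals, ``"one-sided"``
        for binomial tolerance bounds.
    """

    content: float = 0.95
    confidence: float = 0.95
    side: str = "two-sided"

    def __post_init__(self) -> None:
        if not 0.0 < self.content < 1.0:
            raise ValidationError(f"content must be in (0,1), got {self.content}")
        if not 0.0 < self.confidence < 1.0:
            raise ValidationError(f"confidence must be in (0,1), got {self.confidence}")
        if self.side not in ("one-sided", "two-sided"):
            raise ValidationError(f"side must be one-sided or two-sided, got {self.side!r}")

    @property
    def alpha(self) -> float:
        return 1.0 - self.confidence


@dataclass(frozen=True)
class Individual:
    id: str
    taxon: str
    sex: str = "unknown"  # male | female | unknown
    age_class: str = "adult"  # adult | juvenile | unknown


@dataclass
class CharacterMatrix:
    """Individuals x binary characters with taxon/sex/age metadata.

    ``data`` holds one row per individual with columns ``id, taxon, sex,
    age_class`` followed by one float column per character (0.0, 1.0 or
    NaN for missing).  ``applicability`` maps character name to one of
    :data:`APPLICABILITY`; non-applicable individuals are masked to
    missing by :meth:`apply_applicability` so downstream statistics never
    re-implement the filtering.
    """

    data: pd.DataFrame
    applicability: dict = field(default_factory=dict)

    META_COLUMNS = ("id", "taxon", "sex", "age_class")

    def __post_init__(self) -> None:
        for col in self.META_COLUMNS:
            if col not in self.data.columns:
                raise ValidationError(f"character matrix lacks metadata column {col!r}")
        if self.data.empty:
            raise ValidationError("character matrix has no individuals")
        dup = self.data["id"].duplicated()
        if dup.any():
            raise ValidationError(
                f"duplicate individual id(s): {sorted(self.data.loc[dup, 'id'])}"
            )
        bad = [
            c for c in self.characters
            if not self.data[c].dropna().isin([0.0, 1.0]).all()
        ]
        if bad:
            raise ValidationError(f"non-binary states in character(s) {bad}")
        for ch, flag in self.applicability.items():
            if flag not in APPLICABILITY:
                raise ValidationError(f"unknown applicability {flag!r} for {ch!r}")

    @property
    def characters(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.META_COLUMNS]

    @property
    def taxa(self) -> list[str]:
        return sorted(self.data["taxon"].unique())

    def apply_applicability(self) -> "CharacterMatrix":
        """Mask states of non-applicable individuals to missing.

        Characters flagged ``adults-only`` keep states for adults;
        ``adult-males-only`` keep states for adult males.  Individuals of
        unknown sex/age are conservatively masked.
        """
        df = self.data.copy()
        adult = df["age_class"] == "adult"
        male = df["sex"] == "male"
        for ch in self.characters:
            flag = self.applicability.get(ch, "all")
            if flag == "adults-only":
                df.loc[~adult, ch] = np.nan
            elif flag == "adult-males-only":
                df.loc[~(adult & male), ch] = np.nan
        return CharacterMatrix(df, dict(self.applicability))

    def states(self, taxon: str, character: str) -> np.ndarray:
        """Observed (non-missing) states of one taxon for one character."""
        if character not in self.characters:
            raise KeyError(character)
        sub = self.data.loc[self.data["taxon"] == taxon, character].dropna()
        return sub.to_numpy(dtype=float)


@dataclass(frozen=True)
class ContinuousSummary:
    """Per taxon x character sample summary: mean, SD and sample size.

    ``n`` is always taken from an explicit column of the source table,
    never inferred, because published summary and tolerance tables may
    disagree on n for the same sample.
    """

    taxon: str
    character: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError(f"sd must be >= 0, got {self.sd} ({self.taxon}/{self.character})")
        if self.n < 2:
            raise ValidationError(f"n must be >= 2, got {self.n} ({self.taxon}/{self.character})")


@dataclass
class OccurrenceSet:
    """Georeferenced presence records of one taxon (WGS84 decimal degrees)."""

    taxon: str
    records: np.ndarray  # shape (n, 2): lon, lat

    def __post_init__(self) -> None:
        self.records = np.asarray(self.records, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ClimateStack:
    """Aligned gridded climate layers (ESRI ASCII grid convention).

    Values are cell-center registered; row 0 is the northernmost row,
    column 0 the westernmost.  All layers share extent, cell size and
    nodata mask.
    """

    names: list[str]
    values: np.ndarray  # (n_layers, nrows, ncols)
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != len(self.names):
            raise ValidationError("values must be (n_layers, nrows, ncols) matching names")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    @property
    def n_layers(self) -> int:
        return self.values.shape[0]

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid, True where every layer has data."""
        return ~np.any(self.values == self.nodata, axis=0) & ~np.any(
            np.isnan(self.values), axis=0
        )

    @property
    def extent(self) -> tuple[float, float, float, float]:
        nrows, ncols = self.shape
        return (
            self.xllcorner,
            self.yllcorner,
            self.xllcorner + ncols * self.cellsize,
            self.yllcorner + nrows * self.cellsize,
        )

    def cell_of(self, lon: float, lat: float) -> Optional[tuple[int, int]]:
        """Row/col of the cell containing (lon, lat), or None if outside."""
        west, south, east, north = self.extent
        if not (west <= lon < east and south <= lat < north):
            return None
        col = int((lon - self.xllcorner) / self.cellsize)
        row = int((north - lat) / self.cellsize)
        nrows, ncols = self.shape
        if 0 <= row < nrows and 0 <= col < ncols:
            return row, col
        return None

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        west, _, _, north = self.extent
        return (
            west + (col + 0.5) * self.cellsize,
            north - (row + 0.5) * self.cellsize,
        )


@dataclass
class SuitabilitySurface:
    """Habitat-suitability values on a ClimateStack lattice.

    After :func:`intdelim.niche.normalize`, values over valid cells sum
    to 1 and the surface is a probability distribution over cells — the
    operand of Schoener's D.
    """

    values: np.ndarray  # (nrows, ncols), >= 0
    mask: np.ndarray  # True = valid cell

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValidationError("surface values and mask shapes differ")
        if np.any(self.values[self.mask] < 0):
            raise ValidationError("suitability values must be >= 0")

    @property
    def is_normalized(self) -> bool:
        return bool(abs(self.values[self.mask].sum() - 1.0) <= 1e-9)


@dataclass
class TaxonTree:
    """A rooted tree plus a tip-label -> taxon assignment map."""

    tree: "object"  # dendropy.Tree; kept loose to avoid import at type time
    assignments: dict

    def __post_init__(self) -> None:
        tips = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        missing = tips - set(self.assignments)
        if missing:
            raise ValidationError(f"tip(s) lacking a taxon assignment: {sorted(missing)}")
        if len(set(self.assignments.values())) < 2:
            raise ValidationError("a taxon tree needs at least 2 taxa")

    @property
    def taxa(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def tips_of(self, taxon: str) -> list[str]:
        return sorted(t for t, tx in self.assignments.items() if tx == taxon)
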