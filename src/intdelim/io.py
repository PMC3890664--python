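"""Readers and writers for the pipeline's plain-text formats.

Formats
-------
character matrix CSV
    columns ``id, taxon, sex, age_class`` then one 0/1/NA column per
    character; applicability flags come from a companion YAML mapping.
continuous summary CSV
    columns ``taxon, character, mean, sd, n``.
raw measurements CSV
    columns ``id, taxon, sex`` then one numeric column per character;
    :func:`summaries_from_raw` derives per-taxon summaries.
occurrences CSV
    columns ``taxon, longitude, latitude``.
climate layers
    one ESRI ASCII grid (.asc) per layer; all layers of a stack must
    share their header.
tree
    newick with named tips; assignments as a two-column CSV (tip, taxon).

All readers validate and raise :class:`~intdelim.datatypes.ValidationError`
rather than silently coercing out-of-range values.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    MISSING_TOKENS,
    CharacterMatrix,
    ClimateStack,
    ContinuousSummary,
    OccurrenceSet,
    TaxonTree,
    ToleranceConfig,
    ValidationError,
)

logger = logging.getLogger("intdelim")

_META = list(CharacterMatrix.META_COLUMNS)


def _parse_state(raw, row_label, col: str) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return np.nan
    text = str(raw).strip()
    if text.lower() in MISSING_TOKENS:
        return np.nan
    if text in ("0", "0.0"):
        return 0.0
    if text in ("1", "1.0"):
        return 1.0
    raise ValidationError(
        f"malformed state {raw!r} at row {row_label!r}, column {col!r} "
        "(expected 0, 1 or NA)"
    )


def read_character_matrix(path, applicability: Optional[dict | str | Path] = None) -> CharacterMatrix:
    """Read a character matrix CSV and apply applicability masking.

    ``applicability`` may be a dict (character -> flag) or the path of a
    YAML file containing such a mapping.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _META:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    if df.empty:
        raise ValidationError(f"{path}: no data rows")
    chars = [c for c in df.columns if c not in _META]
    out = df[_META].copy()
    for ch in chars:
        out[ch] = [
            _parse_state(v, rid, ch) for v, rid in zip(df[ch], df["id"])
        ]
    if isinstance(applicability, (str, Path)):
        with open(applicability) as fh:
            applicability = yaml.safe_load(fh) or {}
    matrix = CharacterMatrix(out, dict(applicability or {}))
    return matrix.apply_applicability()


def write_character_matrix(matrix: CharacterMatrix, path, applicability_path=None) -> None:
    df = matrix.data.copy()
    for ch in matrix.characters:
        df[ch] = df[ch].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    df.to_csv(path, index=False)
    if applicability_path is not None:
        with open(applicability_path, "w") as fh:
            yaml.safe_dump(matrix.applicability, fh)


def read_continuous_summary(path) -> list[ContinuousSummary]:
    df = pd.read_csv(path)
    required = {"taxon", "character", "mean", "sd", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        ContinuousSummary(
            taxon=str(r.taxon),
            character=str(r.character),
            mean=float(r.mean),
            sd=float(r.sd),
            n=int(r.n),
        )
        for r in df.itertuples()
    ]


def write_continuous_summary(summaries: Iterable[ContinuousSummary], path) -> None:
    pd.DataFrame(
        [
            {"taxon": s.taxon, "character": s.character, "mean": s.mean, "sd": s.sd, "n": s.n}
            for s in summaries
        ]
    ).to_csv(path, index=False)


def summaries_from_raw(raw: pd.DataFrame) -> list[ContinuousSummary]:
    """Derive per-taxon summaries from individual measurements.

    ``raw`` has columns ``id, taxon, sex`` plus numeric character columns;
    missing cells are excluded from n.  Taxa with fewer than 2 measured
    individuals for a character are skipped (no tolerance interval is
    estimable from one observation).
    """
    chars = [c for c in raw.columns if c not in ("id", "taxon", "sex", "age_class")]
    out: list[ContinuousSummary] = []
    for taxon, sub in raw.groupby("taxon", sort=True):
        for ch in chars:
            vals = pd.to_numeric(sub[ch], errors="coerce").dropna()
            if len(vals) < 2:
                continue
            out.append(
                ContinuousSummary(
                    taxon=str(taxon),
                    character=ch,
                    mean=float(vals.mean()),
                    sd=float(vals.std(ddof=1)),
                    n=int(len(vals)),
                )
            )
    return out


# ---------------------------------------------------------------------------
# ESRI ASCII grids

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path) -> tuple[str, np.ndarray, dict]:
    """Read one ESRI ASCII grid; returns (layer name, array, header dict)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh, dtype=float, ndmin=2)
    for key in _HEADER_KEYS:
        if key not in header:
            raise ValidationError(f"{path}: ESRI ASCII header lacks {key}")
    header.setdefault("nodata_value", -9999.0)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise ValidationError(
            f"{path}: grid body {data.shape} does not match header ({nrows}, {ncols})"
        )
    return path.stem, data, header


def write_ascii_grid(path, values: np.ndarray, xllcorner: float, yllcorner: float,
                     cellsize: float, nodata: float = -9999.0) -> None:
    values = np.asarray(values, dtype=float)
    nrows, ncols = values.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n")
        fh.write(f"xllcorner {xllcorner!r}\nyllcorner {yllcorner!r}\n")
        fh.write(f"cellsize {cellsize!r}\nNODATA_value {nodata!r}\n")
        np.savetxt(fh, values, fmt="%.10g")


def read_climate_stack(paths: Sequence) -> ClimateStack:
    """Read >= 1 ASCII grids and align them on a shared lattice."""
    if not paths:
        raise ValidationError("a climate stack needs at least one layer")
    names, arrays, headers = [], [], []
    for p in sorted(Path(p) for p in paths):
        name, arr, hdr = read_ascii_grid(p)
        names.append(name)
        arrays.append(arr)
        headers.append(hdr)
    ref = headers[0]
    for name, hdr in zip(names[1:], headers[1:]):
        if any(not math.isclose(hdr[k], ref[k], rel_tol=0, abs_tol=1e-9) for k in _HEADER_KEYS):
            raise ValidationError(f"layer {name!r} header mismatches the first layer")
    nodata = ref["nodata_value"]
    values = np.stack(arrays)
    # unify nodata across layers so the mask is shared
    values[np.isclose(values, nodata)] = nodata
    return ClimateStack(
        names=names,
        values=values,
        xllcorner=ref["xllcorner"],
        yllcorner=ref["yllcorner"],
        cellsize=ref["cellsize"],
        nodata=nodata,
    )


def write_climate_stack(stack: ClimateStack, directory) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for name, layer in zip(stack.names, stack.values):
        p = directory / f"{name}.asc"
        write_ascii_grid(p, layer, stack.xllcorner, stack.yllcorner, stack.cellsize, stack.nodata)
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# Occurrences

def read_occurrences(path) -> list[OccurrenceSet]:
    df = pd.read_csv(path)
    missing = {"taxon", "longitude", "latitude"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    lon = pd.to_numeric(df["longitude"], errors="coerce")
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    bad = lon.isna() | lat.isna() | (lon.abs() > 180) | (lat.abs() > 90)
    if bad.any():
        raise ValidationError(f"{path}: malformed coordinates at row(s) {list(df.index[bad])}")
    return [
        OccurrenceSet(taxon=str(t), records=np.column_stack([lon[df["taxon"] == t], lat[df["taxon"] == t]]))
        for t in sorted(df["taxon"].unique())
    ]


def write_occurrences(sets: Iterable[OccurrenceSet], path) -> None:
    rows = []
    for s in sets:
        for lon, lat in s.records:
            rows.append({"taxon": s.taxon, "longitude": lon, "latitude": lat})
    pd.DataFrame(rows, columns=["taxon", "longitude", "latitude"]).to_csv(path, index=False)


def deduplicate(occ: OccurrenceSet, stack: ClimateStack) -> OccurrenceSet:
    """Keep at most one record per raster cell, dropping off-grid and
    nodata records (with a logged warning).  Idempotent."""
    mask = stack.mask
    seen: set[tuple[int, int]] = set()
    kept = []
    for lon, lat in occ.records:
        cell = stack.cell_of(lon, lat)
        if cell is None:
            logger.warning("%s: record (%.5f, %.5f) outside extent, dropped", occ.taxon, lon, lat)
            continue
        if not mask[cell]:
            logger.warning("%s: record (%.5f, %.5f) on a nodata cell, dropped", occ.taxon, lon, lat)
            continue
        if cell in seen:
            continue
        seen.add(cell)
        kept.append((lon, lat))
    return OccurrenceSet(taxon=occ.taxon, records=np.array(kept, dtype=float).reshape(-1, 2))


# ---------------------------------------------------------------------------
# Trees

def read_tree(path, assignments) -> TaxonTree:
    """Read a rooted newick tree plus tip -> taxon assignments.

    ``assignments`` is a dict or the path of a two-column CSV
    (``tip, taxon``).  The tree is used as rooted — no unrooted
    bipartition fallback.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick", rooting="default-rooted",
                             preserve_underscores=True)
    if isinstance(assignments, (str, Path)):
        df = pd.read_csv(assignments)
        missing = {"tip", "taxon"} - set(df.columns)
        if missing:
            raise ValidationError(f"{assignments}: missing column(s) {sorted(missing)}")
        assignments = dict(zip(df["tip"].astype(str), df["taxon"].astype(str)))
    return TaxonTree(tree=tree, assignments=dict(assignments))


# ---------------------------------------------------------------------------
# Config

def read_config(path) -> dict:
    """Read the nested key-value run configuration (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return cfg


def tolerance_config_from(cfg: dict) -> ToleranceConfig:
    sub = cfg.get("tolerance", {})
    return ToleranceConfig(
        content=float(sub.get("content", 0.95)),
        confidence=float(sub.get("confidence", 0.95)),
        side=str(sub.get("side", "two-sided")),
    )
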