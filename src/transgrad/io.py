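"""Readers/writers for the delimited tables every stage exchanges.

Conventions: tab-delimited on write (reads sniff tab vs comma from the
header line), ``region_id`` first column, fixed decimal formatting so two
writes of the same object are byte-identical.  Missing values must be
explicit in the file (empty cell -> masked); nothing is silently imputed.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .containers import (
    AlignmentError,
    ConnectivityMatrix,
    EffectMatrix,
    FeaturePanel,
    ParcellationMeta,
    ParcelMap,
    ProfileSet,
)

__all__ = [
    "read_parcel_table",
    "write_parcel_table",
    "read_meta",
    "write_meta",
    "read_matrix",
    "write_matrix",
    "align_sources",
]

_FLOAT_FMT = "%.17g"  # shortest-exact is not stable across writers; 17 digits round-trips

Alignable = Union[ParcelMap, EffectMatrix, FeaturePanel, ProfileSet, ConnectivityMatrix]


def _sniff_sep(path: str) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_frame(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected a region_id column plus data columns")
    return df


def _numeric_columns(df: pd.DataFrame, path: str) -> np.ndarray:
    cols = []
    for col in df.columns[1:]:
        raw = df[col].str.strip()
        vals = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
        bad = raw.ne("") & vals.isna()
        if bad.any():
            row = int(np.where(bad)[0][0])
            raise ValueError(
                f"{path}: non-numeric value {raw.iloc[row]!r} in column {col!r}, "
                f"row {row + 2} (region {df.iloc[row, 0]!r})"
            )
        cols.append(vals.to_numpy(dtype=float))
    return np.column_stack(cols)


def read_parcel_table(
    path: str,
    meta: ParcellationMeta,
    kind: str = "auto",
    missing: str = "error",
):
    """Read a region-keyed table and align rows to ``meta``'s region order.

    Parameters
    ----------
    path : str
        Delimited text file; header row; first column region_id.
    meta : ParcellationMeta
        Target region order.
    kind : {'auto', 'map', 'effects', 'features'}
        Container to return.  'auto' picks the narrowest fit: one value
        column -> ParcelMap, several -> EffectMatrix.
    missing : {'error', 'mask'}
        What to do when the file lacks regions present in ``meta``:
        raise (default) or return them masked / as NaN rows.
    """
    df = _read_frame(path)
    ids = df.iloc[:, 0].str.strip().tolist()
    dupes = sorted({r for r in ids if ids.count(r) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicate region rows: {dupes}")
    unknown = sorted(set(ids) - set(meta.region_id))
    if unknown:
        raise ValueError(f"{path}: unknown regions (not in parcellation): {unknown}")
    absent = [r for r in meta.region_id if r not in set(ids)]
    if absent and missing == "error":
        raise ValueError(f"{path}: missing regions: {absent}")

    data = _numeric_columns(df, path)
    n, p = meta.n_regions, data.shape[1]
    full = np.full((n, p), np.nan)
    pos = {r: i for i, r in enumerate(meta.region_id)}
    for row, r in enumerate(ids):
        full[pos[r]] = data[row]

    names = [str(c) for c in df.columns[1:]]
    if kind == "auto":
        kind = "map" if p == 1 else "effects"
    if kind == "map":
        if p != 1:
            raise ValueError(f"{path}: expected a single value column, found {p}")
        return ParcelMap(full[:, 0], meta, name=names[0])
    if kind == "effects":
        return EffectMatrix(full, names, meta)
    if kind == "features":
        return FeaturePanel(full, names, meta)
    raise ValueError(f"unknown kind: {kind!r}")


def _format_cell(v: float) -> str:
    return "" if not np.isfinite(v) else _FLOAT_FMT % v


def write_parcel_table(obj, path: str) -> None:
    """Write a ParcelMap / EffectMatrix / FeaturePanel / ProfileSet as TSV."""
    if isinstance(obj, ParcelMap):
        names: Sequence[str] = [obj.name]
        values = np.where(obj.mask, np.nan, obj.values)[:, None]
    elif isinstance(obj, EffectMatrix):
        names = obj.conditions
        values = obj.values
    elif isinstance(obj, FeaturePanel):
        names = obj.feature_names
        values = obj.values
    elif isinstance(obj, ProfileSet):
        names = [_FLOAT_FMT % d for d in obj.depth_fractions]
        values = obj.intensities
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    meta = obj.meta
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("region_id\t" + "\t".join(names) + "\n")
        for i, r in enumerate(meta.region_id):
            fh.write(r + "\t" + "\t".join(_format_cell(v) for v in values[i]) + "\n")


def read_meta(path: str) -> ParcellationMeta:
    """Read a parcellation table (region_id, hemisphere, x, y, z, community, hierarchy)."""
    df = pd.read_csv(path, sep=_sniff_sep(path))
    required = ["region_id", "hemisphere", "x", "y", "z", "community", "hierarchy"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return ParcellationMeta(
        df["region_id"].astype(str).tolist(),
        df["hemisphere"].astype(str).tolist(),
        df[["x", "y", "z"]].to_numpy(dtype=float),
        df["community"].astype(str).tolist(),
        df["hierarchy"].astype(str).tolist(),
    )


def write_meta(meta: ParcellationMeta, path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("region_id\themisphere\tx\ty\tz\tcommunity\thierarchy\n")
        for i, r in enumerate(meta.region_id):
            x, y, z = meta.centroid[i]
            fh.write(
                f"{r}\t{meta.hemisphere[i]}\t{_FLOAT_FMT % x}\t{_FLOAT_FMT % y}\t"
                f"{_FLOAT_FMT % z}\t{meta.community[i]}\t{meta.hierarchy[i]}\n"
            )


def read_matrix(path: str, meta: ParcellationMeta, kind: str = "connectivity") -> ConnectivityMatrix:
    """Read a square region x region matrix (region_id column + one column per region)."""
    df = _read_frame(path)
    ids = df.iloc[:, 0].str.strip().tolist()
    cols = [str(c) for c in df.columns[1:]]
    if ids != list(meta.region_id) or cols != list(meta.region_id):
        raise ValueError(
            f"{path}: matrix rows/columns must match the parcellation region order"
        )
    return ConnectivityMatrix(_numeric_columns(df, path), meta, kind=kind)


def write_matrix(mat: ConnectivityMatrix, path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("region_id\t" + "\t".join(mat.meta.region_id) + "\n")
        for i, r in enumerate(mat.meta.region_id):
            fh.write(r + "\t" + "\t".join(_FLOAT_FMT % v for v in mat.values[i]) + "\n")


def _available(obj: Alignable) -> set[str]:
    if isinstance(obj, ParcelMap):
        return set(obj.available_regions())
    if isinstance(obj, (EffectMatrix, FeaturePanel)):
        ok = np.isfinite(obj.values).all(axis=1)
    elif isinstance(obj, ProfileSet):
        ok = np.isfinite(obj.intensities).all(axis=1)
    elif isinstance(obj, ConnectivityMatrix):
        ok = np.isfinite(obj.values).all(axis=1)
    else:
        raise TypeError(f"cannot align object of type {type(obj).__name__}")
    return {r for r, m in zip(obj.meta.region_id, ok) if m}


def align_sources(*objects: Alignable) -> list[Alignable]:
    """Restrict all inputs to their common (complete) region subset.

    Region order follows the first object's parcellation.  Objects whose
    region sets already coincide with the intersection are returned
    restricted to a shared meta so downstream alignment checks pass.
    Raises AlignmentError on an empty intersection.
    """
    if not objects:
        raise ValueError("align_sources needs at least one object")
    common = _available(objects[0])
    for obj in objects[1:]:
        common &= _available(obj)
    if not common:
        raise AlignmentError("no regions shared by all inputs")
    base = objects[0].meta
    target = base.subset([r for r in base.region_id if r in common])
    aligned = [obj.restrict(target) for obj in objects]
    return aligned
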