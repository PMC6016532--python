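"""Readers and writers for landmark datasets and topology side-tables.

Three landmark dialects are supported:

``csv_long``
    Columns ``specimen, point_name, x, y, z``; one row per point.
``csv_wide``
    One row per specimen: ``specimen, x1, y1, z1, x2, ...``.
``tps``
    LM3 blocks: an ``LM3=p`` header, ``p`` whitespace-separated coordinate
    rows, then an ``ID=label`` line.

Slider and bilateral-pair tables are headered CSV with 1-based point indices
(the convention of published landmark tables); they are converted to 0-based
indices on read and back on write.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    BilateralMap,
    LandmarkDataset,
    SlidingDefinition,
    StructuralError,
)

DIALECTS = ("csv_long", "csv_wide", "tps")


class ParseError(ValueError):
    """A file could not be parsed under the requested dialect."""


# ---------------------------------------------------------------------------
# landmark datasets


def read_landmarks(
    path: str | Path,
    dialect: str = "csv_long",
    factors: pd.DataFrame | None = None,
    point_roles: np.ndarray | None = None,
) -> LandmarkDataset:
    """Read a landmark dataset from ``path`` in the given dialect.

    Point order is file order.  ``factors`` and ``point_roles`` may be
    attached afterwards with :func:`attach_factors`; roles default to
    ``fixed`` when not supplied.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    if dialect == "csv_long":
        ds = _read_csv_long(path)
    elif dialect == "csv_wide":
        ds = _read_csv_wide(path)
    else:
        ds = _read_tps(path)
    if point_roles is not None:
        ds.point_roles = np.asarray(point_roles, dtype=object)
    if factors is not None:
        ds = attach_factors(ds, factors)
    problems = ds.validation_errors()
    if problems:
        raise StructuralError("; ".join(problems))
    return ds


def write_landmarks(dataset: LandmarkDataset, path: str | Path,
                    dialect: str = "csv_long") -> None:
    """Write ``dataset`` to ``path`` at full float precision."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    if dialect == "csv_long":
        _write_csv_long(dataset, path)
    elif dialect == "csv_wide":
        _write_csv_wide(dataset, path)
    else:
        _write_tps(dataset, path)


def _read_csv_long(path: Path) -> LandmarkDataset:
    df = pd.read_csv(path, dtype={"specimen": str, "point_name": str},
                     float_precision="round_trip")
    required = {"specimen", "point_name", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: csv_long missing columns {sorted(missing)}")
    for col in ("x", "y", "z"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ParseError(
                f"{path}: non-numeric {col!r} value at data row {row}"
            )
        df[col] = pd.to_numeric(df[col])
    specimen_ids = list(dict.fromkeys(df["specimen"]))
    blocks, names_ref = [], None
    for spec in specimen_ids:
        sub = df[df["specimen"] == spec]
        names = list(sub["point_name"])
        if names_ref is None:
            names_ref = names
        elif len(names) != len(names_ref):
            raise StructuralError(
                f"specimen {spec} has {len(names)} points where others "
                f"have {len(names_ref)}"
            )
        elif names != names_ref:
            raise StructuralError(
                f"specimen {spec} point names differ from first specimen"
            )
        blocks.append(sub[["x", "y", "z"]].to_numpy(dtype=float))
    coords = np.stack(blocks)
    return LandmarkDataset(
        coords=coords,
        specimen_ids=specimen_ids,
        point_names=list(names_ref),
        point_roles=np.array(["fixed"] * coords.shape[1], dtype=object),
    )


def _write_csv_long(ds: LandmarkDataset, path: Path) -> None:
    rows = []
    for i, spec in enumerate(ds.specimen_ids):
        for j, name in enumerate(ds.point_names):
            x, y, z = (float(v) for v in ds.coords[i, j])
            rows.append((spec, name, repr(x), repr(y), repr(z)))
    out = pd.DataFrame(rows, columns=["specimen", "point_name", "x", "y", "z"])
    out.to_csv(path, index=False)


def _read_csv_wide(path: Path) -> LandmarkDataset:
    df = pd.read_csv(path, dtype={"specimen": str},
                     float_precision="round_trip")
    if "specimen" not in df.columns:
        raise ParseError(f"{path}: csv_wide requires a 'specimen' column")
    coord_cols = [c for c in df.columns if c != "specimen"]
    if len(coord_cols) % 3:
        raise ParseError(f"{path}: coordinate column count not a multiple of 3")
    p = len(coord_cols) // 3
    expected = [f"{ax}{k}" for k in range(1, p + 1) for ax in "xyz"]
    if coord_cols != expected:
        raise ParseError(f"{path}: csv_wide columns must be x1,y1,z1,...,z{p}")
    vals = df[coord_cols].apply(pd.to_numeric, errors="coerce")
    if vals.isna().to_numpy().any():
        row = int(np.argwhere(vals.isna().to_numpy())[0][0])
        raise ParseError(f"{path}: non-numeric coordinate at data row {row}")
    coords = vals.to_numpy(dtype=float).reshape(len(df), p, 3)
    return LandmarkDataset(
        coords=coords,
        specimen_ids=list(df["specimen"]),
        point_names=[f"p{k}" for k in range(1, p + 1)],
        point_roles=np.array(["fixed"] * p, dtype=object),
    )


def _write_csv_wide(ds: LandmarkDataset, path: Path) -> None:
    p = ds.n_points
    cols = [f"{ax}{k}" for k in range(1, p + 1) for ax in "xyz"]
    buf = _io.StringIO()
    buf.write("specimen," + ",".join(cols) + "\n")
    for i, spec in enumerate(ds.specimen_ids):
        flat = ds.coords[i].reshape(-1)
        buf.write(spec + "," + ",".join(repr(float(v)) for v in flat) + "\n")
    Path(path).write_text(buf.getvalue())


def _read_tps(path: Path) -> LandmarkDataset:
    blocks: list[np.ndarray] = []
    ids: list[str] = []
    cur: list[list[float]] = []
    expect = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3="):
                if expect is not None:
                    raise ParseError(f"{path}:{lineno}: LM3 block without ID=")
                expect = int(line.split("=", 1)[1])
                cur = []
            elif upper.startswith("ID="):
                if expect is None:
                    raise ParseError(f"{path}:{lineno}: ID= before LM3=")
                if len(cur) != expect:
                    raise ParseError(
                        f"{path}:{lineno}: specimen {line.split('=', 1)[1]} "
                        f"has {len(cur)} coordinate rows where {expect} were "
                        "declared"
                    )
                ids.append(line.split("=", 1)[1])
                blocks.append(np.array(cur, dtype=float))
                expect, cur = None, []
            else:
                parts = line.split()
                if len(parts) != 3:
                    raise ParseError(f"{path}:{lineno}: expected 3 coordinates")
                try:
                    cur.append([float(v) for v in parts])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from None
    if expect is not None:
        raise ParseError(f"{path}: file ends inside an LM3 block")
    if not blocks:
        raise ParseError(f"{path}: no LM3 blocks found")
    p = blocks[0].shape[0]
    for spec, b in zip(ids, blocks):
        if b.shape[0] != p:
            raise StructuralError(
                f"specimen {spec} has {b.shape[0]} points where others have {p}"
            )
    return LandmarkDataset(
        coords=np.stack(blocks),
        specimen_ids=ids,
        point_names=[f"p{k}" for k in range(1, p + 1)],
        point_roles=np.array(["fixed"] * p, dtype=object),
    )


def _write_tps(ds: LandmarkDataset, path: Path) -> None:
    buf = _io.StringIO()
    for i, spec in enumerate(ds.specimen_ids):
        buf.write(f"LM3={ds.n_points}\n")
        for x, y, z in ds.coords[i]:
            buf.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")
        buf.write(f"ID={spec}\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# factor tables


def attach_factors(ds: LandmarkDataset, factors: pd.DataFrame) -> LandmarkDataset:
    """Join a specimen-keyed factor table onto the dataset (order-aligned)."""
    factors = factors.copy()
    if "specimen" in factors.columns:
        factors = factors.set_index("specimen")
    missing = [s for s in ds.specimen_ids if s not in factors.index]
    if missing:
        raise StructuralError(f"factor table missing specimens {missing}")
    ds.factors = factors.loc[ds.specimen_ids].reset_index(drop=True)
    return ds


def read_factors(path: str | Path) -> pd.DataFrame:
    """Read a factor table CSV keyed by a ``specimen`` column."""
    df = pd.read_csv(path, dtype=str)
    if "specimen" not in df.columns:
        raise ParseError(f"{path}: factor table requires a 'specimen' column")
    return df


# ---------------------------------------------------------------------------
# topology side-tables (1-based in files, 0-based in memory)


def read_sliders(path: str | Path, n_points: int | None = None,
                 patch_path: str | Path | None = None) -> SlidingDefinition:
    """Read a curve-slider table (columns ``before, slide, after``, 1-based).

    ``patch_path`` optionally names a patch-neighbour CSV with columns
    ``point`` and ``neighbors`` (semicolon-separated 1-based indices).
    """
    df = pd.read_csv(path)
    required = {"before", "slide", "after"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: slider table needs columns {sorted(required)}")
    sliders = []
    for row, rec in enumerate(df.itertuples(index=False)):
        triple = (int(rec.before) - 1, int(rec.slide) - 1, int(rec.after) - 1)
        if n_points is not None:
            for i in triple:
                if not (0 <= i < n_points):
                    raise StructuralError(
                        f"{path}: row {row} references point {i + 1} outside "
                        f"a {n_points}-point dataset"
                    )
        sliders.append(triple)
    patches: dict[int, list[int]] = {}
    if patch_path is not None:
        pdf = pd.read_csv(patch_path, dtype={"neighbors": str})
        if not {"point", "neighbors"} <= set(pdf.columns):
            raise ParseError(f"{patch_path}: needs columns point, neighbors")
        for row, rec in enumerate(pdf.itertuples(index=False)):
            pt = int(rec.point) - 1
            nbrs = [int(v) - 1 for v in str(rec.neighbors).split(";")]
            if n_points is not None:
                for i in [pt] + nbrs:
                    if not (0 <= i < n_points):
                        raise StructuralError(
                            f"{patch_path}: row {row} references point {i + 1} "
                            f"outside a {n_points}-point dataset"
                        )
            patches[pt] = nbrs
    return SlidingDefinition(curve_sliders=sliders, patch_points=patches)


def write_sliders(sliders: SlidingDefinition, path: str | Path,
                  patch_path: str | Path | None = None) -> None:
    rows = [(b + 1, s + 1, a + 1) for b, s, a in sliders.curve_sliders]
    pd.DataFrame(rows, columns=["before", "slide", "after"]).to_csv(
        path, index=False)
    if patch_path is not None:
        prows = [
            (pt + 1, ";".join(str(i + 1) for i in nbrs))
            for pt, nbrs in sorted(sliders.patch_points.items())
        ]
        pd.DataFrame(prows, columns=["point", "neighbors"]).to_csv(
            patch_path, index=False)


def read_bilateral(path: str | Path, n_points: int) -> BilateralMap:
    """Read a bilateral-pair table (columns ``right, left``, 1-based).

    Midline points are the complement of all paired points, matching the
    convention of landmark tables that list only symmetric pairs.
    """
    df = pd.read_csv(path)
    if not {"right", "left"} <= set(df.columns):
        raise ParseError(f"{path}: bilateral table needs columns right, left")
    pairs = []
    for row, rec in enumerate(df.itertuples(index=False)):
        r, l = int(rec.right) - 1, int(rec.left) - 1
        for i in (r, l):
            if not (0 <= i < n_points):
                raise StructuralError(
                    f"{path}: row {row} references point {i + 1} outside "
                    f"a {n_points}-point dataset"
                )
        pairs.append((r, l))
    paired = {i for pr in pairs for i in pr}
    midline = [i for i in range(n_points) if i not in paired]
    return BilateralMap(pairs=pairs, midline=midline)


def write_bilateral(bilateral: BilateralMap, path: str | Path) -> None:
    rows = [(r + 1, l + 1) for r, l in bilateral.pairs]
    pd.DataFrame(rows, columns=["right", "left"]).to_csv(path, index=False)
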