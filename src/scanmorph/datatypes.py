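"""Core containers for landmark datasets and their topology side-tables.

A landmark dataset is a stack of specimen configurations, each a ``p x 3``
matrix of Cartesian coordinates, together with per-point metadata (names and
roles) and a per-specimen factor table (individual, device, replicate,
optionally sex).  All point indices are 0-based internally; file formats use
1-based indices and are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

POINT_ROLES = ("fixed", "semilandmark", "patch")


class StructuralError(ValueError):
    """A dataset or side-table violates a structural invariant."""


@dataclass
class LandmarkDataset:
    """Stacked 3D landmark configurations with specimen-level factors.

    Parameters
    ----------
    coords
        Array of shape ``(n_specimens, p, 3)``.
    specimen_ids
        Unique label per specimen, length ``n_specimens``.
    point_names
        Label per point, length ``p``.
    point_roles
        One of ``fixed``, ``semilandmark``, ``patch`` per point.
    factors
        DataFrame with one row per specimen (aligned with ``specimen_ids``)
        and columns ``individual``, ``device``, ``replicate`` and optionally
        ``sex``.
    """

    coords: np.ndarray
    specimen_ids: list[str]
    point_names: list[str]
    point_roles: np.ndarray
    factors: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructuralError(
                f"coords must have shape (n, p, 3), got {self.coords.shape}"
            )
        self.point_roles = np.asarray(self.point_roles, dtype=object)
        self.specimen_ids = [str(s) for s in self.specimen_ids]

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_points(self) -> int:
        return self.coords.shape[1]

    def role_indices(self, *roles: str) -> np.ndarray:
        """Indices of points whose role is in ``roles``."""
        mask = np.isin(self.point_roles, roles)
        return np.nonzero(mask)[0]

    def subset_points(self, indices: np.ndarray) -> "LandmarkDataset":
        """New dataset restricted to the given point indices (order kept)."""
        indices = np.asarray(indices, dtype=int)
        return LandmarkDataset(
            coords=self.coords[:, indices, :].copy(),
            specimen_ids=list(self.specimen_ids),
            point_names=[self.point_names[i] for i in indices],
            point_roles=self.point_roles[indices].copy(),
            factors=self.factors.copy(),
        )

    def subset_specimens(self, mask: np.ndarray) -> "LandmarkDataset":
        """New dataset restricted to specimens selected by boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        ids = [s for s, m in zip(self.specimen_ids, mask) if m]
        return LandmarkDataset(
            coords=self.coords[mask].copy(),
            specimen_ids=ids,
            point_names=list(self.point_names),
            point_roles=self.point_roles.copy(),
            factors=self.factors.loc[mask].reset_index(drop=True),
        )

    def validation_errors(self) -> list[str]:
        """All invariant violations, empty if the dataset is consistent."""
        problems: list[str] = []
        if len(self.specimen_ids) != self.n_specimens:
            problems.append(
                f"{len(self.specimen_ids)} specimen ids for "
                f"{self.n_specimens} coordinate blocks"
            )
        if len(set(self.specimen_ids)) != len(self.specimen_ids):
            problems.append("specimen ids are not unique")
        if len(self.point_names) != self.n_points:
            problems.append(
                f"{len(self.point_names)} point names for {self.n_points} points"
            )
        if len(self.point_roles) != self.n_points:
            problems.append("point_roles length does not match point count")
        bad_roles = set(self.point_roles) - set(POINT_ROLES)
        if bad_roles:
            problems.append(f"unknown point roles: {sorted(bad_roles)}")
        if not np.all(np.isfinite(self.coords)):
            idx = np.argwhere(~np.isfinite(self.coords))
            spec = self.specimen_ids[idx[0][0]] if len(self.specimen_ids) else "?"
            problems.append(f"non-finite coordinate in specimen {spec}")
        if not self.factors.empty:
            required = {"individual", "device", "replicate"}
            missing = required - set(self.factors.columns)
            if missing:
                problems.append(f"factor table missing columns {sorted(missing)}")
            elif len(self.factors) != self.n_specimens:
                problems.append("factor table row count does not match specimens")
            else:
                key = self.factors[["individual", "device", "replicate"]]
                dup = key.duplicated()
                if dup.any():
                    row = key[dup].iloc[0]
                    problems.append(
                        "duplicated (individual, device, replicate) triple "
                        f"({row['individual']}, {row['device']}, {row['replicate']})"
                    )
        return problems


@dataclass
class SlidingDefinition:
    """Which points slide, and along what neighbours.

    ``curve_sliders`` holds ``(before, slider, after)`` index triples: the
    slider moves along the chord through its two neighbours.  ``patch_points``
    maps a patch-point index to the neighbour set (>= 3 indices) whose local
    principal plane defines its two sliding directions.  All indices 0-based.
    """

    curve_sliders: list[tuple[int, int, int]] = field(default_factory=list)
    patch_points: dict[int, list[int]] = field(default_factory=dict)

    @property
    def slider_indices(self) -> np.ndarray:
        return np.array([s[1] for s in self.curve_sliders], dtype=int)

    @property
    def sliding_indices(self) -> np.ndarray:
        """All point indices that move during sliding."""
        idx = [s[1] for s in self.curve_sliders] + list(self.patch_points)
        return np.array(sorted(idx), dtype=int)

    def validation_errors(self, n_points: int) -> list[str]:
        problems: list[str] = []
        seen: set[int] = set()
        for row, (b, s, a) in enumerate(self.curve_sliders):
            for i in (b, s, a):
                if not (0 <= i < n_points):
                    problems.append(
                        f"curve slider row {row}: index {i} out of range "
                        f"for {n_points} points"
                    )
            if len({b, s, a}) != 3:
                problems.append(f"curve slider row {row}: indices not distinct")
            if s in seen:
                problems.append(f"point {s} appears as slider more than once")
            seen.add(s)
        for pt, nbrs in self.patch_points.items():
            if not (0 <= pt < n_points):
                problems.append(f"patch point {pt} out of range")
            if pt in seen:
                problems.append(f"point {pt} is both curve slider and patch point")
            if len(nbrs) < 3:
                problems.append(f"patch point {pt} has fewer than 3 neighbours")
            for i in nbrs:
                if not (0 <= i < n_points):
                    problems.append(f"patch point {pt}: neighbour {i} out of range")
        return problems


@dataclass
class BilateralMap:
    """Bilateral-pair structure of an object-symmetric configuration.

    ``pairs`` lists ``(right, left)`` point-index pairs; ``midline`` lists the
    unpaired points on the sagittal plane.  Together they must partition all
    point indices.
    """

    pairs: list[tuple[int, int]] = field(default_factory=list)
    midline: list[int] = field(default_factory=list)

    def validation_errors(self, n_points: int) -> list[str]:
        problems: list[str] = []
        used: list[int] = []
        for r, l in self.pairs:
            used.extend((r, l))
        used.extend(self.midline)
        for i in used:
            if not (0 <= i < n_points):
                problems.append(f"bilateral index {i} out of range")
        counts = np.bincount([i for i in used if 0 <= i < n_points],
                             minlength=n_points)
        for i in np.nonzero(counts > 1)[0]:
            problems.append(f"point {i} appears more than once in bilateral map")
        for i in np.nonzero(counts == 0)[0]:
            problems.append(f"point {i} missing from bilateral map")
        return problems


def validate(
    dataset: LandmarkDataset,
    sliders: SlidingDefinition | None = None,
    bilateral: BilateralMap | None = None,
) -> list[str]:
    """Collect every invariant violation across a dataset and its side-tables.

    Returns an empty list iff everything is structurally consistent.
    """
    report = dataset.validation_errors()
    if sliders is not None:
        report += sliders.validation_errors(dataset.n_points)
        fixed = set(dataset.role_indices("fixed"))
        moving = set(int(i) for i in sliders.sliding_indices)
        for i in sorted(moving & fixed):
            report.append(f"fixed landmark {i} is listed as a sliding point")
    if bilateral is not None:
        report += bilateral.validation_errors(dataset.n_points)
    return report
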