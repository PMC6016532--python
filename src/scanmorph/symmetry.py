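"""Object-symmetry handling: mirror-and-relabel and the symmetric /
asymmetric decomposition of shape.

A bilaterally symmetric structure (object symmetry) is analyzed by jointly
superimposing every configuration with its mirrored, relabeled copy.  The
per-specimen average of the two aligned copies is the symmetric component;
the remainder is the asymmetric component.  The mean asymmetric component
across specimens is directional asymmetry; its individual variation is
fluctuating asymmetry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import BilateralMap, LandmarkDataset
from .procrustes import ProcrustesResult, gpa

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class SymmetryDecomposition:
    """Symmetric and asymmetric shape components for every specimen.

    ``aligned_original + 0 == symmetric + asymmetric`` holds coordinate-wise;
    ``reflected_aligned`` are the aligned mirrored-relabeled copies.
    """

    symmetric: np.ndarray          # (n, p, 3)
    asymmetric: np.ndarray         # (n, p, 3)
    aligned_original: np.ndarray   # (n, p, 3)
    reflected_aligned: np.ndarray  # (n, p, 3)
    consensus: np.ndarray          # (p, 3) of the joint fit
    gpa_result: ProcrustesResult
    mirror_normal: np.ndarray | None = None  # unit normal of the symmetry
    # plane in the aligned frame (alignment may reorient the axes)


def mirror_relabel(config: np.ndarray, bilateral: BilateralMap,
                   axis: str = "x") -> np.ndarray:
    """Mirror a configuration across the plane normal to ``axis`` and swap
    the rows of each bilateral pair (midline rows keep their labels)."""
    config = np.asarray(config, dtype=float)
    problems = bilateral.validation_errors(config.shape[0])
    if problems:
        raise ValueError("incomplete bilateral map: " + "; ".join(problems))
    out = config.copy()
    out[:, _AXES[axis]] *= -1.0
    for r, l in bilateral.pairs:
        out[[r, l]] = out[[l, r]]
    return out


def autodetect_axis(config: np.ndarray, bilateral: BilateralMap) -> str:
    """Axis whose mirrored-relabeled copy is closest to the original —
    i.e. the axis minimizing the spread of pair midpoints off the plane."""
    best, best_axis = np.inf, "x"
    for axis in _AXES:
        mirrored = mirror_relabel(config, bilateral, axis)
        score = float(((config - mirrored) ** 2).sum())
        if score < best:
            best, best_axis = score, axis
    return best_axis


def decompose(
    dataset: LandmarkDataset | np.ndarray,
    bilateral: BilateralMap,
    axis: str = "x",
    tol: float = 1e-10,
    max_iter: int = 100,
) -> SymmetryDecomposition:
    """Symmetric/asymmetric decomposition via a joint GPA of originals and
    mirrored-relabeled copies.

    Originals are aligned with proper rotations only; mirrored copies are
    allowed reflections.  The symmetric component of a specimen is the mean
    of its two aligned copies, the asymmetric component the difference of
    the aligned original from that mean.
    """
    coords = dataset.coords if isinstance(dataset, LandmarkDataset) else dataset
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    mirrored = np.stack(
        [mirror_relabel(coords[i], bilateral, axis) for i in range(n)]
    )
    doubled = np.concatenate([coords, mirrored], axis=0)
    refl = np.zeros(2 * n, dtype=bool)
    refl[n:] = True
    result = gpa(doubled, tol=tol, max_iter=max_iter, allow_reflection=refl)
    aligned_orig = result.aligned[:n]
    aligned_mirr = result.aligned[n:]
    symmetric = 0.5 * (aligned_orig + aligned_mirr)
    asymmetric = aligned_orig - symmetric
    normal = None
    if bilateral.pairs:
        diffs = np.stack([result.consensus[r] - result.consensus[l]
                          for r, l in bilateral.pairs])
        _, _, vt = np.linalg.svd(diffs, full_matrices=False)
        normal = vt[0]
    return SymmetryDecomposition(
        symmetric=symmetric,
        asymmetric=asymmetric,
        aligned_original=aligned_orig,
        reflected_aligned=aligned_mirr,
        consensus=result.consensus,
        gpa_result=result,
        mirror_normal=normal,
    )


def symmetric_dataset(dataset: LandmarkDataset,
                      decomposition: SymmetryDecomposition) -> LandmarkDataset:
    """Package the symmetric component as a dataset for downstream ANOVA."""
    return LandmarkDataset(
        coords=decomposition.symmetric.copy(),
        specimen_ids=list(dataset.specimen_ids),
        point_names=list(dataset.point_names),
        point_roles=dataset.point_roles.copy(),
        factors=dataset.factors.copy(),
    )


def directional_asymmetry(decomposition: SymmetryDecomposition) -> np.ndarray:
    """Mean asymmetric component across specimens, shape ``(p, 3)``."""
    return decomposition.asymmetric.mean(axis=0)
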