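"""Ordinary and generalized Procrustes superimposition.

Superimposition removes position (centering), size (scaling every
configuration to unit centroid size) and orientation (least-squares
rotation), leaving shape.  The generalized fit iterates ordinary fits
against a consensus that is re-estimated each round; shape variables for
multivariate statistics are obtained by orthogonal projection of the aligned
configurations onto the tangent plane of shape space at the consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import LandmarkDataset

log = logging.getLogger(__name__)


@dataclass
class ProcrustesResult:
    """Output of a generalized Procrustes fit.

    ``aligned`` holds the superimposed ``(n, p, 3)`` configurations, each
    centered at the origin with unit centroid size.  ``tangent_coords`` are
    the ``(n, 3p)`` shape variables after tangent projection: deviations from
    the consensus, orthogonal to the consensus direction.
    """

    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    tangent_coords: np.ndarray
    iterations: int
    converged: bool
    objective_history: list[float] = field(default_factory=list)


def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared deviations of points from their centroid.

    Raises ``ValueError`` for a degenerate configuration (all points
    coincident).
    """
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or config.shape[1] != 3 or config.shape[0] < 3:
        raise ValueError(f"expected a (p>=3, 3) configuration, got {config.shape}")
    if not np.all(np.isfinite(config)):
        raise ValueError("non-finite coordinates")
    centered = config - config.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs == 0.0:
        raise ValueError("degenerate configuration: zero centroid size")
    return cs


def _center_scale(config: np.ndarray) -> tuple[np.ndarray, float]:
    centered = config - config.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs == 0.0:
        raise ValueError("degenerate configuration: zero centroid size")
    return centered / cs, cs


def optimal_rotation(moving: np.ndarray, reference: np.ndarray,
                     allow_reflection: bool = False) -> np.ndarray:
    """Orthogonal matrix R minimizing ``||moving @ R - reference||_F``.

    With ``allow_reflection=False`` the smallest singular direction is
    sign-corrected so that det(R) = +1.
    """
    h = moving.T @ reference
    u, _, vt = np.linalg.svd(h)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return r


def opa(moving: np.ndarray, reference: np.ndarray,
        allow_reflection: bool = False) -> tuple[np.ndarray, float]:
    """Ordinary Procrustes fit of ``moving`` onto ``reference``.

    Both configurations are centered and scaled to unit centroid size; the
    moving one is then rotated to minimize the summed squared distance to the
    reference.  Returns the transformed configuration and the residual
    Procrustes distance.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: moving {moving.shape} vs reference {reference.shape}"
        )
    x, _ = _center_scale(moving)
    y, _ = _center_scale(reference)
    r = optimal_rotation(x, y, allow_reflection=allow_reflection)
    fitted = x @ r
    return fitted, float(np.linalg.norm(fitted - y))


def gpa(
    dataset: LandmarkDataset | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
    allow_reflection: bool | np.ndarray = False,
) -> ProcrustesResult:
    """Generalized Procrustes analysis of a stack of configurations.

    Iterates align-to-consensus / update-consensus until the consensus moves
    by less than ``tol`` (root-sum-square) or ``max_iter`` is reached.
    ``allow_reflection`` may be a per-specimen boolean vector (used by the
    object-symmetry machinery for mirrored copies).
    """
    coords = dataset.coords if isinstance(dataset, LandmarkDataset) else dataset
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("GPA requires at least 2 specimens")
    refl = np.broadcast_to(np.asarray(allow_reflection, dtype=bool), (n,))

    sizes = np.empty(n)
    aligned = np.empty_like(coords)
    for i in range(n):
        aligned[i], sizes[i] = _center_scale(coords[i])

    consensus = aligned[0].copy()
    iterations = 0
    converged = False
    history: list[float] = []
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            r = optimal_rotation(aligned[i], consensus,
                                 allow_reflection=bool(refl[i]))
            aligned[i] = aligned[i] @ r
        new_consensus, _ = _center_scale(aligned.mean(axis=0))
        history.append(float(((aligned - new_consensus) ** 2).sum()))
        delta = float(np.linalg.norm(new_consensus - consensus))
        consensus = new_consensus
        if delta < tol:
            converged = True
            break
    if not converged:
        log.warning("GPA did not converge within %d iterations", max_iter)

    # canonical orientation: consensus on its principal axes, so the fit
    # depends only on shape, not on the input frame
    rot = _principal_axes(consensus)
    consensus = consensus @ rot
    aligned = aligned @ rot

    result = ProcrustesResult(
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=sizes,
        tangent_coords=np.empty((n, 0)),
        iterations=iterations,
        converged=converged,
        objective_history=history,
    )
    result.tangent_coords = tangent_project(result)
    return result


def _principal_axes(config: np.ndarray) -> np.ndarray:
    """Proper rotation taking ``config`` onto its principal axes, with a
    sign convention that depends only on the shape itself."""
    vals, vecs = np.linalg.eigh(config.T @ config)
    vecs = vecs[:, np.argsort(vals)[::-1]]
    proj = config @ vecs
    for j in range(3):
        if proj[np.argmax(np.abs(proj[:, j])), j] < 0:
            vecs[:, j] *= -1.0
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] *= -1.0
    return vecs


def tangent_project(result: ProcrustesResult) -> np.ndarray:
    """Orthogonal tangent-space projection of aligned configurations.

    Each aligned configuration is flattened, its deviation from the consensus
    taken, and the component along the unit consensus direction removed:
    the consensus itself maps to the zero vector.
    """
    n, p, _ = result.aligned.shape
    flat = result.aligned.reshape(n, 3 * p)
    c = result.consensus.reshape(-1)
    c_hat = c / np.linalg.norm(c)
    dev = flat - c
    return dev - np.outer(dev @ c_hat, c_hat)


def total_procrustes_variance(result: ProcrustesResult) -> float:
    """Summed squared deviation of aligned specimens from the consensus,
    divided by the number of specimens."""
    dev = result.aligned - result.consensus
    return float((dev**2).sum() / result.aligned.shape[0])
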