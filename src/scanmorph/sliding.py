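"""Sliding semilandmarks under the Procrustes-distance criterion.

Curve semilandmarks carry one degree of freedom (along the chord through
their two neighbours); patch points carry two (within the local principal
plane of their neighbour set).  Sliding moves each such point by projecting
its deviation from the consensus onto those allowed directions, which by
construction cannot increase the Procrustes distance to the consensus.
Sliding alternates with re-superimposition for a few cycles.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import LandmarkDataset, SlidingDefinition
from .procrustes import ProcrustesResult, gpa

log = logging.getLogger(__name__)


def estimate_tangents(
    coords: np.ndarray, sliders: SlidingDefinition
) -> dict[int, np.ndarray]:
    """Per sliding point, an orthonormal basis (columns) of its directions.

    Curve sliders get the unit chord from before- to after-neighbour (one
    column); patch points get the top-2 principal directions of their
    neighbour set centered on the point (two columns).
    """
    coords = np.asarray(coords, dtype=float)
    frames: dict[int, np.ndarray] = {}
    for b, s, a in sliders.curve_sliders:
        chord = coords[a] - coords[b]
        norm = np.linalg.norm(chord)
        if norm == 0.0:
            raise ValueError(
                f"slider {s}: coincident neighbours {b} and {a} (zero chord)"
            )
        frames[s] = (chord / norm)[:, None]
    for pt, nbrs in sliders.patch_points.items():
        local = coords[np.asarray(nbrs, dtype=int)] - coords[pt]
        # top-2 right singular vectors span the local least-squares plane
        _, _, vt = np.linalg.svd(local, full_matrices=False)
        frames[pt] = vt[:2].T
    return frames


def slide_once(
    aligned: np.ndarray,
    consensus: np.ndarray,
    frames: dict[int, np.ndarray],
) -> np.ndarray:
    """Move each sliding point by the tangent-projected deviation toward the
    consensus; all other points are untouched."""
    out = aligned.copy()
    for pt, basis in frames.items():
        dev = consensus[pt] - aligned[:, pt, :]       # (n, 3)
        out[:, pt, :] = aligned[:, pt, :] + (dev @ basis) @ basis.T
    return out


def slide_gpa(
    dataset: LandmarkDataset | np.ndarray,
    sliders: SlidingDefinition | None,
    n_cycles: int = 3,
    tol: float = 1e-10,
    max_iter: int = 100,
    per_specimen_tangents: bool = False,
) -> ProcrustesResult:
    """GPA with interleaved semilandmark sliding.

    Alternates superimposition, tangent-frame estimation on the current
    consensus (or per specimen when ``per_specimen_tangents``), and sliding,
    for ``n_cycles`` or until the consensus change drops below ``tol``.
    With no sliders this reduces exactly to plain :func:`gpa`.
    """
    result = gpa(dataset, tol=tol, max_iter=max_iter)
    if sliders is None or (
        not sliders.curve_sliders and not sliders.patch_points
    ):
        return result
    history = list(result.objective_history)
    for _ in range(n_cycles):
        prev_consensus = result.consensus
        if per_specimen_tangents:
            slid = result.aligned.copy()
            for i in range(slid.shape[0]):
                frames = estimate_tangents(result.aligned[i], sliders)
                slid[i] = slide_once(result.aligned[i][None], result.consensus,
                                     frames)[0]
        else:
            frames = estimate_tangents(result.consensus, sliders)
            slid = slide_once(result.aligned, result.consensus, frames)
        result = gpa(slid, tol=tol, max_iter=max_iter)
        history.extend(result.objective_history)
        if float(np.linalg.norm(result.consensus - prev_consensus)) < tol:
            break
    else:
        log.debug("sliding stopped at the n_cycles limit")
    result.objective_history = history
    return result
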