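"""Digitization-error metrics: repeatability and per-group Procrustes
variance.

Repeatability is the intraclass-correlation analogue computed from the mean
squares of a one-factor (individual) Procrustes ANOVA on repeated
digitizations: with ``r`` replicates per individual,

    s2_among = (MS_among - MS_within) / r
    R        = s2_among / (s2_among + MS_within)

Values near 1 mean among-individual variation dwarfs digitization error.

Procrustes variance of a set of observations is the mean squared deviation
from the set mean — the trace of the set's covariance matrix with
denominator ``n``.  Computed per individual/device cell of replicates, it
isolates pure digitization variation; device-level values are compared with
a permutation test that shuffles device labels within individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anova import procrustes_anova
from .datatypes import LandmarkDataset
from .symmetry import BilateralMap, decompose

log = logging.getLogger(__name__)

LANDMARK_SUBSETS = {
    "all": ("fixed", "semilandmark", "patch"),
    "fixed+curves": ("fixed", "semilandmark"),
    "fixed_only": ("fixed",),
}


@dataclass
class RepeatabilityResult:
    r_value: float
    ms_among: float
    ms_within: float
    replicates_per_group: int
    s2_among: float
    warning: str | None = None
    anova: pd.DataFrame | None = None


@dataclass
class DisparityResult:
    """Per-cell and per-group Procrustes variances for two device groups."""

    cell_variances: pd.DataFrame     # columns: individual, device, variance
    group_variances: dict[str, float]
    observed_difference: float
    p_value: float | None = None
    permuted_differences: np.ndarray = field(
        default_factory=lambda: np.empty(0))


def repeatability_from_ms(ms_among: float, ms_within: float,
                          r: int) -> RepeatabilityResult:
    """Repeatability from ANOVA mean squares with ``r`` replicates/group."""
    if r < 2:
        raise ValueError(f"need r >= 2 replicates per group, got {r}")
    if ms_among < 0 or ms_within < 0:
        raise ValueError("mean squares must be non-negative")
    s2_among = (ms_among - ms_within) / r
    denom = s2_among + ms_within
    if denom == 0:
        raise ValueError("both mean squares are zero")
    r_value = s2_among / denom
    warning = None
    if ms_among <= ms_within:
        warning = (
            "among-group mean square does not exceed within-group mean "
            "square; repeatability is not positive"
        )
        log.warning(warning)
    return RepeatabilityResult(
        r_value=float(r_value),
        ms_among=float(ms_among),
        ms_within=float(ms_within),
        replicates_per_group=int(r),
        s2_among=float(s2_among),
        warning=warning,
    )


def repeatability(
    dataset: LandmarkDataset,
    device: str | None = None,
    landmark_subset: str = "all",
    bilateral: BilateralMap | None = None,
    symmetric: bool = False,
    sliders=None,
    n_cycles: int = 3,
) -> RepeatabilityResult:
    """Repeatability of digitization for one device's replicate design.

    Re-runs superimposition from raw coordinates on the requested landmark
    subset (and, when ``symmetric`` and a bilateral map restricted to the
    subset are available, symmetric-component extraction), fits a one-factor
    individual Procrustes ANOVA, and applies the mean-squares formula.
    Requires a balanced design: the same replicate count for every
    individual within the device.
    """
    from .sliding import slide_gpa

    if landmark_subset not in LANDMARK_SUBSETS:
        raise ValueError(
            f"unknown landmark_subset {landmark_subset!r}; expected one of "
            f"{sorted(LANDMARK_SUBSETS)}"
        )
    ds = dataset
    if device is not None:
        mask = (ds.factors["device"].astype(str) == str(device)).to_numpy()
        if not mask.any():
            raise ValueError(f"no specimens for device {device!r}")
        ds = ds.subset_specimens(mask)
    counts = ds.factors.groupby("individual", sort=False).size()
    if counts.nunique() != 1:
        raise ValueError(
            "unbalanced replicate counts per individual: "
            f"{dict(counts)} — the ICC formula assumes balance"
        )
    r = int(counts.iloc[0])
    if r < 2:
        raise ValueError(f"need >= 2 replicates per individual, got {r}")

    keep = ds.role_indices(*LANDMARK_SUBSETS[landmark_subset])
    sub = ds.subset_points(keep)
    sub_sliders = _restrict_sliders(sliders, keep) if sliders is not None else None
    if symmetric:
        if bilateral is None:
            raise ValueError("symmetric extraction requires a bilateral map")
        sub_bilateral = _restrict_bilateral(bilateral, keep)
        fit = slide_gpa(sub, sub_sliders, n_cycles=n_cycles)
        decomp = decompose(fit.aligned, sub_bilateral)
        coords = decomp.gpa_result.tangent_coords[: sub.n_specimens]
    else:
        fit = slide_gpa(sub, sub_sliders, n_cycles=n_cycles)
        coords = fit.tangent_coords

    table = procrustes_anova(coords, sub.factors, ["individual"], n_perm=0)
    out = repeatability_from_ms(
        table.loc["individual", "MS"], table.loc["Residuals", "MS"], r
    )
    out.anova = table
    return out


def _restrict_sliders(sliders, keep: np.ndarray):
    """Sliders whose slider point and neighbours all survive the subset."""
    from .datatypes import SlidingDefinition

    pos = {int(old): new for new, old in enumerate(keep)}
    curve = [
        (pos[b], pos[s], pos[a])
        for b, s, a in sliders.curve_sliders
        if b in pos and s in pos and a in pos
    ]
    patches = {
        pos[pt]: [pos[i] for i in nbrs if i in pos]
        for pt, nbrs in sliders.patch_points.items()
        if pt in pos
    }
    patches = {pt: nbrs for pt, nbrs in patches.items() if len(nbrs) >= 3}
    return SlidingDefinition(curve_sliders=curve, patch_points=patches)


def _restrict_bilateral(bilateral: BilateralMap, keep: np.ndarray) -> BilateralMap:
    """Bilateral map re-indexed to a point subset (pairs must survive whole)."""
    pos = {int(old): new for new, old in enumerate(keep)}
    pairs = [(pos[r], pos[l]) for r, l in bilateral.pairs
             if r in pos and l in pos]
    midline = [pos[i] for i in bilateral.midline if i in pos]
    return BilateralMap(pairs=pairs, midline=midline)


def procrustes_variance_by_group(
    tangent_coords: np.ndarray,
    factors: pd.DataFrame,
    denominator: str = "n",
) -> DisparityResult:
    """Procrustes variance for every individual/device cell of replicates.

    The cell variance is the mean squared deviation of the cell's replicates
    from the cell mean (denominator ``n``, i.e. the trace of the cell
    covariance divided by the number of observations; ``denominator='n-1'``
    selects the unbiased variant).  The device-level value is the unweighted
    mean over that device's cells.
    """
    y = np.asarray(tangent_coords, dtype=float)
    if denominator not in ("n", "n-1"):
        raise ValueError("denominator must be 'n' or 'n-1'")
    factors = factors.reset_index(drop=True)
    rows = []
    for (ind, dev), idx in factors.groupby(
            ["individual", "device"], sort=False).groups.items():
        block = y[np.asarray(idx)]
        m = block.shape[0]
        if m < 2:
            raise ValueError(
                f"cell (individual={ind}, device={dev}) has a single "
                "replicate; Procrustes variance undefined"
            )
        dev_sq = ((block - block.mean(axis=0)) ** 2).sum()
        denom = m if denominator == "n" else m - 1
        rows.append((ind, dev, float(dev_sq / denom)))
    cells = pd.DataFrame(rows, columns=["individual", "device", "variance"])
    groups = cells.groupby("device", sort=False)["variance"].mean().to_dict()
    if len(groups) == 2:
        a, b = groups.values()
        observed = abs(float(a) - float(b))
    else:
        observed = float("nan")
    return DisparityResult(
        cell_variances=cells,
        group_variances={str(k): float(v) for k, v in groups.items()},
        observed_difference=observed,
    )


def compare_group_variance(
    disparity: DisparityResult,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Permutation p-value for the absolute device-variance difference.

    Device labels are permuted within each individual (cell variances are
    exchangeable under the null of equal digitization noise); the p-value is
    ``(b + 1) / (n_perm + 1)``.
    """
    cells = disparity.cell_variances
    devices = list(dict.fromkeys(cells["device"]))
    if len(devices) != 2:
        raise ValueError(f"exactly 2 device groups required, got {devices}")
    if n_perm < 99:
        log.warning("n_perm=%d is low for a permutation test", n_perm)
    wide = cells.pivot(index="individual", columns="device", values="variance")
    vals = wide[devices].to_numpy()           # (n_ind, 2)
    observed = abs(vals[:, 0].mean() - vals[:, 1].mean())
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_perm)
    for b in range(n_perm):
        flip = rng.random(vals.shape[0]) < 0.5
        v = vals.copy()
        v[flip] = v[flip][:, ::-1]
        diffs[b] = abs(v[:, 0].mean() - v[:, 1].mean())
    tol = 1e-9 * (1.0 + observed)
    p = (int(np.sum(diffs >= observed - tol)) + 1) / (n_perm + 1)
    disparity.observed_difference = float(observed)
    disparity.p_value = float(p)
    disparity.permuted_differences = diffs
    return float(p)
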