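"""Synthetic replicate landmark data with known variance components.

The generator emulates a repeated-digitization study design: each of
``n_individuals`` is digitized ``replicates`` times from each of two
capture devices.  Shape variation is built from additive components on a
bilaterally symmetric template (points on a hemiellipsoid — a smooth
cranium-like surface with exact mirror pairs about the ``x = 0`` plane):

* a symmetric individual effect (shared by all of an individual's
  digitizations),
* directional asymmetry — one antisymmetric field shared by every
  individual,
* fluctuating asymmetry — an antisymmetric field per individual,
* a systematic device field — one smooth symmetric low-order polynomial
  displacement applied to every configuration from the second device
  (a coherent shape shift, detectable in ordinations, not white noise),
* digitization noise — independent Gaussian per replicate, with a
  per-device standard deviation,
* and nuisance rotation/translation/scale, which superimposition must
  remove.

The exact effect draws are recorded in a :class:`SyntheticTruth` so that
parameter-recovery tests can compare estimates against ground truth.
Defaults mirror a two-device study of 19 individuals with 3 replicate
digitizations per device and 289 points (58 fixed, 145 curve
semilandmarks, 86 patch points).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import BilateralMap, LandmarkDataset, SlidingDefinition


@dataclass
class SyntheticParams:
    """Generator settings; standard deviations are in template length units
    (the template spans roughly 20 units along its long axis)."""

    n_individuals: int = 19
    devices: int = 2
    replicates: int = 3
    n_pairs: int = 116
    n_midline: int = 57
    sigma_individual: float = 0.15
    da_magnitude: float = 0.08
    sigma_fa: float = 0.03
    device_offset_scale: float = 0.1
    sigma_digitization: tuple[float, ...] | float = (0.04, 0.02)
    sliding_noise_factor: float = 0.6
    sex_effect_scale: float = 0.02
    rotation_nuisance: bool = True
    translation_range: float | None = None   # None -> one template diameter
    scale_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def digitization_sds(self) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(self.sigma_digitization, dtype=float))
        if arr.size == 1:
            sds = np.full(self.devices, arr[0])
        elif arr.size >= self.devices:
            sds = arr[: self.devices].copy()
        else:
            raise ValueError(
                f"{arr.size} digitization sds for {self.devices} devices"
            )
        if (sds < 0).any():
            raise ValueError("digitization sds must be >= 0")
        return sds

    def __post_init__(self) -> None:
        if min(self.n_individuals, self.devices, self.replicates) < 1:
            raise ValueError("design counts must be >= 1")
        if min(self.n_pairs, self.n_midline) < 1:
            raise ValueError("template point counts must be >= 1")
        for name in ("sigma_individual", "da_magnitude", "sigma_fa",
                     "device_offset_scale", "sex_effect_scale",
                     "sliding_noise_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.digitization_sds()


@dataclass
class SyntheticTruth:
    """Ground-truth draws and expected summaries for a simulated dataset."""

    template: np.ndarray
    bilateral: BilateralMap
    sliders: SlidingDefinition
    mirror_index: np.ndarray
    individual_effects: np.ndarray    # (I, p, 3), symmetric
    da_field: np.ndarray              # (p, 3), antisymmetric
    fa_effects: np.ndarray            # (I, p, 3), antisymmetric
    device_field: np.ndarray          # (p, 3), symmetric, applied to device 2
    sex_field: np.ndarray             # (p, 3), symmetric, applied to males
    sexes: list[str | None]
    params: SyntheticParams
    expected_repeatability_per_device: dict[str, float] = field(
        default_factory=dict)
    expected_variance_ordering: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# template construction


def _ellipsoid_point(theta: float, phi: float,
                     axes: tuple[float, float, float]) -> np.ndarray:
    a, b, c = axes
    return np.array([
        a * np.sin(theta) * np.cos(phi),
        b * np.cos(theta),
        c * np.sin(theta) * np.sin(phi),
    ])


def _allocate_roles(n_pairs: int, n_midline: int
                    ) -> tuple[int, int, int, int, int]:
    """Split counts into (fixed_mid, curve_mid, fixed_pair, curve_pair,
    patch_pair), proportioned like a cranial template (58/145/86)."""
    fixed_mid = min(max(2, round(n_midline * 12 / 57)), n_midline)
    curve_mid = n_midline - fixed_mid
    fixed_pair = min(max(2, round(n_pairs * 23 / 116)), n_pairs)
    patch_pair = max(0, min(round(n_pairs * 43 / 116),
                            n_pairs - fixed_pair))
    curve_pair = n_pairs - fixed_pair - patch_pair
    return fixed_mid, curve_mid, fixed_pair, curve_pair, patch_pair


def make_template(
    n_pairs: int = 116,
    n_midline: int = 57,
    seed: int = 0,
    axes: tuple[float, float, float] = (5.0, 10.0, 4.0),
) -> tuple[np.ndarray, BilateralMap, SlidingDefinition, np.ndarray]:
    """Symmetric mean configuration with bilateral and sliding topology.

    Points lie on the upper half of an ellipsoid, exactly mirror-paired
    about ``x = 0``.  Midline and right-side points are organized into
    ordered chains bracketed by fixed landmarks; interior chain points are
    curve semilandmarks whose slider neighbours are their chain neighbours.
    Patch points are scattered on the surface; their tangent-plane
    neighbour sets are the 6 nearest non-fixed points on the template.

    Returns ``(coords, bilateral, sliders, roles)``; point layout is
    midline block, right block, left block.
    """
    rng = np.random.default_rng(seed)
    fixed_mid, curve_mid, fixed_pair, curve_pair, patch_pair = \
        _allocate_roles(n_pairs, n_midline)

    points: list[np.ndarray] = []
    roles: list[str] = []
    sliders: list[tuple[int, int, int]] = []

    def build_chain(thetas: np.ndarray, phi: float, n_fixed: int) -> None:
        """Append an ordered chain; evenly spaced ranks are fixed."""
        m = len(thetas)
        if n_fixed >= m:
            fixed_ranks = set(range(m))
        else:
            fixed_ranks = set(
                np.round(np.linspace(0, m - 1, max(n_fixed, 2))).astype(int))
        start = len(points)
        for rank, th in enumerate(thetas):
            points.append(_ellipsoid_point(th, phi, axes))
            roles.append("fixed" if rank in fixed_ranks else "semilandmark")
        for rank in range(m):
            if rank in fixed_ranks:
                continue
            b = start + rank - 1 if rank > 0 else start + rank + 1
            a = start + rank + 1 if rank < m - 1 else start + rank - 1
            if rank == 0:
                b, a = start + 1, start + 2
            elif rank == m - 1:
                b, a = start + rank - 2, start + rank - 1
            sliders.append((b, start + rank, a))

    def chain_thetas(m: int) -> np.ndarray:
        base = np.linspace(0.12 * np.pi, 0.88 * np.pi, m)
        if m > 1:
            jitter = rng.uniform(-0.15, 0.15, m) * (base[1] - base[0])
            base = np.sort(base + jitter)
        return base

    # midline chain at phi = pi/2 (x = 0)
    build_chain(chain_thetas(fixed_mid + curve_mid), 0.5 * np.pi, fixed_mid)
    n_mid = len(points)

    # right-side chains at interior phi values
    n_line_pts = fixed_pair + curve_pair
    n_lines = max(1, round(n_line_pts / 18))
    phis = np.linspace(0.12 * np.pi, 0.42 * np.pi, n_lines)
    sizes = np.full(n_lines, n_line_pts // n_lines)
    sizes[: n_line_pts % n_lines] += 1
    fixed_left = fixed_pair
    right_start = len(points)
    for k, (phi, size) in enumerate(zip(phis, sizes)):
        remaining_lines = n_lines - k
        n_fix = max(2, round(fixed_left / remaining_lines)) if size >= 2 else size
        n_fix = min(n_fix, size, fixed_left)
        fixed_left -= n_fix
        build_chain(chain_thetas(int(size)), float(phi), n_fix)

    # right-side patch points scattered between the chains
    patch_start = len(points)
    for _ in range(patch_pair):
        th = rng.uniform(0.2 * np.pi, 0.8 * np.pi)
        ph = rng.uniform(0.08 * np.pi, 0.46 * np.pi)
        points.append(_ellipsoid_point(th, ph, axes))
        roles.append("patch")

    coords_half = np.asarray(points)
    n_right = len(points) - n_mid

    # mirror the right block to create the left block
    left = coords_half[n_mid:].copy()
    left[:, 0] *= -1.0
    coords = np.vstack([coords_half, left])
    roles_all = np.array(roles + roles[n_mid:], dtype=object)

    mirror_index = np.arange(coords.shape[0])
    right_idx = np.arange(n_mid, n_mid + n_right)
    left_idx = right_idx + n_right
    mirror_index[right_idx] = left_idx
    mirror_index[left_idx] = right_idx

    # left-side sliders mirror the right-side ones (midline maps to itself)
    left_sliders = [
        (int(mirror_index[b]), int(mirror_index[s]), int(mirror_index[a]))
        for b, s, a in sliders if s >= n_mid
    ]
    all_sliders = sliders + left_sliders

    # patch tangent-plane neighbours: 6 nearest non-fixed template points
    nonfixed = np.nonzero(roles_all != "fixed")[0]
    patch_points: dict[int, list[int]] = {}
    patch_idx = [i for i in range(coords.shape[0])
                 if roles_all[i] == "patch"]
    for pt in patch_idx:
        d = np.linalg.norm(coords[nonfixed] - coords[pt], axis=1)
        order = nonfixed[np.argsort(d)]
        patch_points[pt] = [int(i) for i in order if i != pt][:6]

    bilateral = BilateralMap(
        pairs=[(int(r), int(l)) for r, l in zip(right_idx, left_idx)],
        midline=list(range(n_mid)),
    )
    sliding = SlidingDefinition(curve_sliders=all_sliders,
                                patch_points=patch_points)
    return coords, bilateral, sliding, roles_all


# ---------------------------------------------------------------------------
# effect fields


def _make_symmetric(raw: np.ndarray, mirror_index: np.ndarray,
                    midline: np.ndarray) -> np.ndarray:
    """Symmetric field built from the raw values on midline + right points:
    the left block is the exact mirror of the right block."""
    out = raw.copy()
    out[midline, 0] = 0.0
    right = np.nonzero(mirror_index > np.arange(len(mirror_index)))[0]
    left = mirror_index[right]
    out[left] = out[right]
    out[left, 0] *= -1.0
    return out


def _make_antisymmetric(raw: np.ndarray, mirror_index: np.ndarray,
                        midline: np.ndarray) -> np.ndarray:
    """Antisymmetric field (its mirror equals its negation): midline keeps
    only the x component; the left block is minus the mirror of the right."""
    out = raw.copy()
    out[midline, 1:] = 0.0
    right = np.nonzero(mirror_index > np.arange(len(mirror_index)))[0]
    left = mirror_index[right]
    out[left] = -out[right]
    out[left, 0] *= -1.0
    return out


def _smooth_field(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-order polynomial displacement field over the template."""
    x = coords / np.abs(coords).max()
    basis = np.column_stack([
        np.ones(len(x)), x[:, 0], x[:, 1], x[:, 2],
        x[:, 0] * x[:, 1], x[:, 1] * x[:, 2], x[:, 0] * x[:, 2],
        x[:, 0] ** 2, x[:, 1] ** 2, x[:, 2] ** 2,
    ])
    coef = rng.normal(size=(basis.shape[1], 3))
    return basis @ coef


def _remove_similarity_component(field: np.ndarray,
                                 template: np.ndarray) -> np.ndarray:
    """Project out the displacement directions a Procrustes fit absorbs:
    translations, infinitesimal rotations of the template, and scaling.
    Without this a smooth field's effective (post-superimposition) size
    would vary wildly with its random coefficients."""
    centered = template - template.mean(axis=0)
    p = len(template)
    basis = []
    for k in range(3):  # translations
        t = np.zeros((p, 3))
        t[:, k] = 1.0
        basis.append(t)
    gens = [np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0.0]]),
            np.array([[0, 0, 1], [0, 0, 0], [-1, 0, 0.0]]),
            np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0.0]])]
    for g in gens:  # infinitesimal rotations
        basis.append(centered @ g.T)
    basis.append(centered)  # scaling
    b = np.stack([v.reshape(-1) for v in basis], axis=1)
    q, _ = np.linalg.qr(b)
    flat = field.reshape(-1)
    return (flat - q @ (q.T @ flat)).reshape(p, 3)


def _scale_rms(f: np.ndarray, target: float) -> np.ndarray:
    rms = float(np.sqrt((f**2).mean()))
    return f * (target / rms) if rms > 0 else f


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


# ---------------------------------------------------------------------------
# dataset generation


def simulate_dataset(params: SyntheticParams
                     ) -> tuple[LandmarkDataset, SyntheticTruth]:
    """Simulate a replicate landmark study with recorded ground truth.

    For each individual a symmetric individual effect is drawn once and
    shared across devices/replicates; directional asymmetry is one field
    shared by all individuals; each individual adds its own fluctuating
    asymmetry; the second device adds the systematic device field; each
    replicate adds its device's digitization noise; finally every
    configuration is hit with nuisance rotation/translation/scale.
    """
    rng = np.random.default_rng(params.seed)
    template, bilateral, sliders, roles = make_template(
        params.n_pairs, params.n_midline,
        seed=int(rng.integers(2**31)),
    )
    p = template.shape[0]
    mirror_index = np.arange(p)
    for r_, l_ in bilateral.pairs:
        mirror_index[r_], mirror_index[l_] = l_, r_
    midline = np.asarray(bilateral.midline, dtype=int)

    ind_effects = np.stack([
        _make_symmetric(rng.normal(0.0, params.sigma_individual, (p, 3)),
                        mirror_index, midline)
        for _ in range(params.n_individuals)
    ])
    def shaped_field(make, target):
        field = make(_smooth_field(template, rng), mirror_index, midline)
        field = _remove_similarity_component(field, template)
        return _scale_rms(make(field, mirror_index, midline), target)

    da_field = shaped_field(_make_antisymmetric, params.da_magnitude)
    fa_effects = np.stack([
        _make_antisymmetric(rng.normal(0.0, params.sigma_fa, (p, 3)),
                            mirror_index, midline)
        for _ in range(params.n_individuals)
    ])
    device_field = shaped_field(_make_symmetric, params.device_offset_scale)
    sex_field = shaped_field(_make_symmetric, params.sex_effect_scale)

    # a sexed subset in roughly the 7f:4m proportion of 11 of 19
    # individuals; the remainder have unknown sex
    n_sexed = min(params.n_individuals,
                  max(2, round(params.n_individuals * 11 / 19)))
    n_f = max(1, round(n_sexed * 7 / 11))
    n_f = min(n_f, n_sexed - 1)
    sexes: list[str | None] = []
    for i in range(params.n_individuals):
        if i < n_f:
            sexes.append("f")
        elif i < n_sexed:
            sexes.append("m")
        else:
            sexes.append(None)

    sds = params.digitization_sds()
    # semilandmark/patch placement is (semi-)automated in digitization
    # software, so those points carry scaled-down noise relative to
    # manually placed fixed landmarks
    point_scale = np.where(roles == "fixed", 1.0,
                           params.sliding_noise_factor)[:, None]
    diameter = float(np.linalg.norm(
        template.max(axis=0) - template.min(axis=0)))
    trans_range = (params.translation_range if params.translation_range
                   is not None else diameter)

    blocks, ids, rows = [], [], []
    for i in range(params.n_individuals):
        base = template + ind_effects[i] + da_field + fa_effects[i]
        if sexes[i] == "m":
            base = base + sex_field
        for d in range(params.devices):
            shape = base + (device_field if d == 1 else 0.0)
            for r_ in range(params.replicates):
                config = shape + rng.normal(0.0, 1.0, (p, 3)) \
                    * (sds[d] * point_scale)
                if params.rotation_nuisance:
                    config = config @ _random_rotation(rng)
                config = config * rng.uniform(*params.scale_range)
                config = config + rng.uniform(-trans_range, trans_range, 3)
                blocks.append(config)
                spec = f"ind{i + 1:02d}_dev{d + 1}_rep{r_ + 1}"
                ids.append(spec)
                rows.append({
                    "individual": f"ind{i + 1:02d}",
                    "device": f"dev{d + 1}",
                    "replicate": str(r_ + 1),
                    "sex": sexes[i],
                })

    dataset = LandmarkDataset(
        coords=np.stack(blocks),
        specimen_ids=ids,
        point_names=[f"p{k + 1}" for k in range(p)],
        point_roles=roles,
        factors=pd.DataFrame(rows),
    )
    truth = SyntheticTruth(
        template=template,
        bilateral=bilateral,
        sliders=sliders,
        mirror_index=mirror_index,
        individual_effects=ind_effects,
        da_field=da_field,
        fa_effects=fa_effects,
        device_field=device_field,
        sex_field=sex_field,
        sexes=sexes,
        params=params,
        expected_repeatability_per_device={
            f"dev{d + 1}": expected_repeatability(params, device=d)
            for d in range(params.devices)
            if sds[d] > 0 or params.sigma_individual > 0
        },
        expected_variance_ordering=_expected_ordering(params),
    )
    return dataset, truth


def _expected_ordering(params: SyntheticParams) -> list[str]:
    sds = params.digitization_sds()
    contributions = {
        "Individual": params.sigma_individual**2,
        "Side": params.da_magnitude**2,
        "Ind * Side": params.sigma_fa**2,
        "Device": params.device_offset_scale**2 / 4.0,
        "Residuals": float(np.mean(sds**2)),
    }
    return sorted(contributions, key=contributions.get, reverse=True)


def expected_repeatability(params: SyntheticParams, device: int = 0,
                           midline_correction: bool = False) -> float:
    """Expected intraclass correlation for one device's replicate design.

    The simple per-coordinate prediction is
    ``sigma_ind^2 / (sigma_ind^2 + sigma_dig^2)``, valid for small nuisance
    and noise.  ``midline_correction`` accounts for the generator's midline
    points carrying no individual variance in their ``x`` coordinate
    (symmetry pins them to the sagittal plane), which deflates the
    among-individual variance by the fraction of constrained coordinates.
    """
    s_ind2 = params.sigma_individual**2
    s_dig2 = float(params.digitization_sds()[device] ** 2)
    if s_ind2 == 0 and s_dig2 == 0:
        raise ValueError("both sigma_individual and sigma_digitization are 0")
    if midline_correction:
        p = 2 * params.n_pairs + params.n_midline
        s_ind2 *= (3 * p - params.n_midline) / (3 * p)
    return s_ind2 / (s_ind2 + s_dig2)
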