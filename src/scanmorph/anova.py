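"""Procrustes ANOVA: sequential variance partitioning of shape.

Shape variation (summed over all ``3p`` tangent coordinates) is decomposed
over an ordered list of design factors by sequential (Type I) sums of
squares.  Significance comes from residual randomization: for each term the
residuals of the reduced model (all prior terms) are permuted across
observations, the term's SS and F recomputed, and the p-value taken as
``(b + 1) / (n_perm + 1)`` where ``b`` counts permuted F statistics at least
as large as the observed one.  The effect size Z is the standardized
position of ``log F`` in the permutation distribution of ``log F``.

Degrees of freedom follow the standard linear model on specimen counts
(a term's df is the rank it adds to the design matrix); the %Var / R-squared
column — each term's SS over the total SS — does not depend on df.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANOVA_COLUMNS = ["Df", "SS", "MS", "Rsq", "F", "Z", "Pr(>F)"]


class DesignError(ValueError):
    """The requested design cannot be fitted on the given factors."""


@dataclass
class DesignSpec:
    """Ordered factor terms; ``a:b`` denotes the crossed/nested term."""

    terms: list[str] = field(default_factory=list)

    def columns(self) -> set[str]:
        return {c for t in self.terms for c in t.split(":")}


def _term_dummies(factors: pd.DataFrame, term: str) -> np.ndarray:
    combo = factors[term.split(":")[0]].astype(str)
    for col in term.split(":")[1:]:
        combo = combo + "\x1f" + factors[col].astype(str)
    if combo.nunique() < 2:
        raise DesignError(f"term {term!r} has fewer than 2 levels")
    return pd.get_dummies(combo, dtype=float).to_numpy()


def _orthonormal_complement(block: np.ndarray, q_prev: np.ndarray,
                            rtol: float = 1e-9) -> np.ndarray:
    """Orthonormal basis of the part of ``block`` outside span(q_prev)."""
    resid = block - q_prev @ (q_prev.T @ block)
    u, s, _ = np.linalg.svd(resid, full_matrices=False)
    keep = s > rtol * max(1.0, s[0] if s.size else 1.0)
    return u[:, keep]


def procrustes_anova(
    tangent_coords: np.ndarray,
    factors: pd.DataFrame,
    design: DesignSpec | list[str],
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sequential Procrustes ANOVA of shape variables over design factors.

    Parameters
    ----------
    tangent_coords
        ``(n, q)`` shape variables (rows are observations).
    factors
        Per-observation factor table holding every column the design names.
    design
        Ordered terms, e.g. ``["individual", "individual:device"]``.
    n_perm
        Residual-randomization permutations (>= 99 for inferential use;
        0 skips the permutation test).
    seed
        Seed or generator controlling the permutations.

    Returns
    -------
    DataFrame indexed by term names plus ``Residuals`` and ``Total`` with
    columns ``Df, SS, MS, Rsq, F, Z, Pr(>F)``.
    """
    if isinstance(design, DesignSpec):
        terms = list(design.terms)
    else:
        terms = list(design)
    if not terms:
        raise DesignError("design has no terms")
    y = np.asarray(tangent_coords, dtype=float)
    if y.ndim != 2:
        raise DesignError(f"tangent_coords must be 2-D, got shape {y.shape}")
    n = y.shape[0]
    if len(factors) != n:
        raise DesignError("factor table does not match observation count")
    missing = {c for t in terms for c in t.split(":")} - set(factors.columns)
    if missing:
        raise DesignError(f"factor table missing columns {sorted(missing)}")
    if 0 < n_perm < 99:
        raise DesignError("n_perm must be >= 99 (or 0 to skip permutations)")
    factors = factors.reset_index(drop=True)

    # cumulative orthonormal basis; first column = intercept
    q = np.full((n, 1), 1.0 / np.sqrt(n))
    slices: list[slice] = []
    for term in terms:
        block = _term_dummies(factors, term)
        q_delta = _orthonormal_complement(block, q)
        if q_delta.shape[1] == 0:
            raise DesignError(
                f"term {term!r} is confounded with prior terms "
                f"({terms[:terms.index(term)] or 'intercept'})"
            )
        slices.append(slice(q.shape[1], q.shape[1] + q_delta.shape[1]))
        q = np.hstack([q, q_delta])
    rank_full = q.shape[1]
    df_res = n - rank_full
    if df_res <= 0:
        raise DesignError(
            "zero residual degrees of freedom: the design saturates the data "
            "(e.g. a single replicate everywhere)"
        )

    v0 = q.T @ y
    ss_total = float((y**2).sum() - (v0[0] ** 2).sum())
    ss_terms = np.array([float((v0[sl] ** 2).sum()) for sl in slices])
    ss_res = float((y**2).sum() - (v0**2).sum())
    ss_res = max(ss_res, 0.0)
    df_terms = np.array([sl.stop - sl.start for sl in slices])
    ms_terms = ss_terms / df_terms
    ms_res = ss_res / df_res
    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = ms_terms / ms_res if ms_res > 0 else np.full(len(terms), np.inf)

    p_vals = np.full(len(terms), np.nan)
    z_vals = np.full(len(terms), np.nan)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        for k, (term, sl) in enumerate(zip(terms, slices)):
            q_red = q[:, : sl.start]
            r_red = y - q_red @ (q_red.T @ y)
            r_norm2 = float((r_red**2).sum())
            f_perm = np.empty(n_perm)
            for b in range(n_perm):
                perm = rng.permutation(n)
                v = q.T @ r_red[perm]
                ss_k = float((v[sl] ** 2).sum())
                sse = max(r_norm2 - float((v**2).sum()), 0.0)
                ms_k = ss_k / df_terms[k]
                f_perm[b] = ms_k / (sse / df_res) if sse > 0 else np.inf
            # tolerance so permutations tying the observed statistic count
            tol = 1e-9 * (1.0 + abs(f_obs[k])) if np.isfinite(f_obs[k]) else 0
            count = int(np.sum(f_perm >= f_obs[k] - tol))
            p_vals[k] = (count + 1) / (n_perm + 1)
            with np.errstate(divide="ignore"):
                log_f = np.log(f_perm[np.isfinite(f_perm) & (f_perm > 0)])
            sd = log_f.std(ddof=1) if log_f.size > 1 else 0.0
            if sd > 0 and np.isfinite(f_obs[k]) and f_obs[k] > 0:
                z_vals[k] = (np.log(f_obs[k]) - log_f.mean()) / sd

    rows = []
    for k, term in enumerate(terms):
        rows.append(
            (term, df_terms[k], ss_terms[k], ms_terms[k],
             ss_terms[k] / ss_total, f_obs[k], z_vals[k], p_vals[k])
        )
    rows.append(("Residuals", df_res, ss_res, ms_res,
                 ss_res / ss_total, np.nan, np.nan, np.nan))
    rows.append(("Total", n - 1, ss_total, np.nan, 1.0, np.nan, np.nan, np.nan))
    table = pd.DataFrame(
        rows, columns=["factor"] + ANOVA_COLUMNS
    ).set_index("factor")
    table.index.name = None
    return table


def symmetry_anova(
    decomposition,
    factors: pd.DataFrame,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Object-symmetry Procrustes ANOVA over individual, side, device.

    Works on the doubled data (aligned originals and mirrored copies from
    the symmetry decomposition): ``Individual`` captures variation of
    individual mean (symmetric) shapes, ``Side`` the mean asymmetric
    component (directional asymmetry), ``Ind * Side`` its individual
    variation (fluctuating asymmetry), ``Device`` device means within
    individuals, and the residual the replicate digitization error.
    """
    from .procrustes import tangent_project

    required = {"individual", "device", "replicate"}
    missing = required - set(factors.columns)
    if missing:
        raise DesignError(f"factor table missing columns {sorted(missing)}")
    cell_sizes = factors.groupby(["individual", "device"], sort=False).size()
    if (cell_sizes < 2).any():
        bad = cell_sizes[cell_sizes < 2].index[0]
        raise DesignError(
            f"individual/device cell {bad} has a single replicate; the "
            "residual (digitization) term is undefined"
        )
    y = tangent_project(decomposition.gpa_result)
    doubled = pd.concat([factors, factors], ignore_index=True)
    doubled["side"] = ["orig"] * len(factors) + ["mirror"] * len(factors)
    table = procrustes_anova(
        y,
        doubled,
        ["individual", "side", "individual:side", "individual:device"],
        n_perm=n_perm,
        seed=seed,
    )
    table = table.rename(
        index={
            "individual": "Individual",
            "side": "Side",
            "individual:side": "Ind * Side",
            "individual:device": "Device",
        }
    )
    table["%Var"] = 100.0 * table["Rsq"]
    return table


def percent_variance(table: pd.DataFrame | np.ndarray) -> pd.Series:
    """Per-factor percentage of total variation: 100 * SS / sum(SS).

    Accepts an AnovaTable (the ``Total`` row, if present, is excluded from
    the denominator sum) or a bare sequence of sums of squares.
    """
    if isinstance(table, pd.DataFrame):
        if "SS" not in table.columns:
            raise ValueError("table has no SS column")
        ss = table["SS"].drop(index="Total", errors="ignore")
    elif isinstance(table, pd.Series):
        ss = table.astype(float)
    else:
        ss = pd.Series(np.asarray(table, dtype=float))
    if len(ss) < 1:
        raise ValueError("need at least one factor row")
    total = float(ss.sum())
    if total <= 0:
        raise ValueError("zero total sum of squares")
    return 100.0 * ss / total
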