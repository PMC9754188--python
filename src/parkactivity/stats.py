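"""Statistical layer: interaction OLS and (partial) constrained
correspondence analysis with permutation testing.

The correspondence machinery is implemented directly on the chi-square
standardized table: with ``P = Y / grand_total``, row masses ``r`` and
column masses ``c``,

    Q_ij = (P_ij - r_i c_j) / sqrt(r_i c_j)

has total inertia ``sum(Q**2)``.  Constraints are weighted-centred,
scaled by ``sqrt(r)`` and (optionally) residualized on the conditioning
matrix; the constrained axes are the SVD of the projection of Q onto the
resulting column space.  A conditioning matrix Z removes its own
weighted projection from both Q and X first, so

    conditioned + constrained + residual inertia == total inertia

holds to machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

_TOL = 1e-9


# ---------------------------------------------------------------------------
# OLS with an interaction, sequential ANOVA
# ---------------------------------------------------------------------------


@dataclass
class LinearModelResult:
    params: pd.Series
    bse: pd.Series
    anova: pd.DataFrame  # sequential (type-I) table with a Residuals row
    r_squared: float
    df_resid: int
    nobs: int


_TERMS = ("intercept", "covariate", "group", "covariate:group")


def _binary_codes(group) -> np.ndarray:
    g = np.asarray(group)
    if g.dtype == bool:
        return g.astype(float)
    levels = pd.unique(pd.Series(g))
    if len(levels) > 2:
        raise ValueError(f"group must be binary, got levels {list(levels)}")
    levels = sorted(levels, key=str)
    return np.asarray([float(levels.index(v)) if len(levels) == 2 else 0.0 for v in g])


def fit_lm_interaction(response, covariate, group) -> LinearModelResult:
    """OLS of ``response`` on covariate, group and their interaction.

    The ANOVA table is sequential (type I) with single-df terms in the
    order covariate, group, interaction — matching how the model is
    reported downstream.  Coefficients come from the exact least-squares
    solution of the full design.
    """
    y = np.asarray(response, dtype=float).ravel()
    x = np.asarray(covariate, dtype=float).ravel()
    g = _binary_codes(group).ravel()
    n = y.size
    if x.size != n or g.size != n:
        raise ValueError("response, covariate and group must have equal length")
    if n < 5:
        raise ValueError(f"need at least 5 observations, got {n}")
    if np.isnan(y).any() or np.isnan(x).any() or np.isnan(g).any():
        raise ValueError("missing values are not allowed")

    columns = [np.ones(n), x, g, x * g]
    design = np.empty((n, 0))
    for name, col in zip(_TERMS, columns):
        grown = np.column_stack([design, col])
        if np.linalg.matrix_rank(grown) <= np.linalg.matrix_rank(design):
            raise ValueError(
                f"design is rank deficient: term '{name}' is collinear "
                f"with preceding terms"
            )
        design = grown

    # RSS of each nested model (intercept-only first => rss[0] is the TSS)
    rss = []
    for k in range(1, 5):
        beta_k = np.linalg.lstsq(design[:, :k], y, rcond=None)[0]
        resid = y - design[:, :k] @ beta_k
        rss.append(float(resid @ resid))

    beta = np.linalg.lstsq(design, y, rcond=None)[0]
    df_resid = n - 4
    mse = rss[-1] / df_resid
    cov_beta = mse * np.linalg.inv(design.T @ design)
    bse = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))

    rows = []
    for i, name in enumerate(_TERMS[1:], start=1):
        ss = rss[i - 1] - rss[i]
        f = ss / mse if mse > 0 else np.inf
        rows.append((name, 1, ss, f, float(_sps.f.sf(f, 1, df_resid))))
    rows.append(("Residuals", df_resid, rss[-1], np.nan, np.nan))
    anova = pd.DataFrame(rows, columns=["term", "df", "sum_sq", "F", "p"])

    return LinearModelResult(
        params=pd.Series(beta, index=list(_TERMS)),
        bse=pd.Series(bse, index=list(_TERMS)),
        anova=anova,
        r_squared=1.0 - rss[-1] / rss[0] if rss[0] > 0 else np.nan,
        df_resid=df_resid,
        nobs=n,
    )


# ---------------------------------------------------------------------------
# (partial) constrained correspondence analysis
# ---------------------------------------------------------------------------


@dataclass
class CcaResult:
    total_inertia: float
    conditioned_inertia: float
    constrained_inertia: float
    residual_inertia: float
    eigenvalues: np.ndarray  # constrained axes
    residual_eigenvalues: np.ndarray
    rank_constraints: int
    rank_conditions: int
    pseudo_f: float
    df_num: int
    df_den: int
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    # Variance-explained fractions, all reported explicitly because
    # "variation explained" is ambiguous between these denominators.
    prop_explained_total: float
    prop_explained_unconditioned: float
    adj_r_squared: float


@dataclass
class PermutationTestResult:
    p_value: float
    f_observed: float
    f_permuted: np.ndarray
    n_perm: int
    seed: int


def _clean_table(Y, X, Z):
    """Coerce inputs, dropping all-zero rows/columns consistently."""
    if isinstance(Y, pd.DataFrame):
        values = Y.to_numpy(dtype=float)
        row_labels = list(map(str, Y.index))
        col_labels = list(map(str, Y.columns))
    else:
        values = np.asarray(Y, dtype=float)
        row_labels = [f"site{i}" for i in range(values.shape[0])]
        col_labels = [f"sp{j}" for j in range(values.shape[1])]
    if values.ndim != 2:
        raise ValueError("response table must be 2-D")
    if (values < 0).any():
        raise ValueError("response table must be nonnegative")

    Xa = np.atleast_2d(np.asarray(X, dtype=float))
    if Xa.shape[0] == 1 and values.shape[0] != 1:
        Xa = Xa.T
    Za = None
    if Z is not None:
        Za = np.atleast_2d(np.asarray(Z, dtype=float))
        if Za.shape[0] == 1 and values.shape[0] != 1:
            Za = Za.T
    if Xa.shape[0] != values.shape[0]:
        raise ValueError("constraint matrix rows must align with response rows")
    if Za is not None and Za.shape[0] != values.shape[0]:
        raise ValueError("condition matrix rows must align with response rows")

    row_keep = values.sum(axis=1) > 0
    col_keep = values.sum(axis=0) > 0
    if not row_keep.all():
        warnings.warn(
            f"dropping {int((~row_keep).sum())} all-zero row(s) before ordination",
            stacklevel=3,
        )
    if not col_keep.all():
        warnings.warn(
            f"dropping {int((~col_keep).sum())} all-zero column(s) before ordination",
            stacklevel=3,
        )
    values = values[np.ix_(row_keep, col_keep)]
    Xa = Xa[row_keep]
    Za = Za[row_keep] if Za is not None else None
    row_labels = [l for l, k in zip(row_labels, row_keep) if k]
    col_labels = [l for l, k in zip(col_labels, col_keep) if k]
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("ordination needs at least 2 sites and 2 species")
    return values, Xa, Za, row_labels, col_labels


def _chi_square_standardize(values: np.ndarray):
    total = values.sum()
    P = values / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    Q = (P - E) / np.sqrt(E)
    return Q, r, c


def _scale_constraints(M: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Weighted-centre columns by row mass, then scale rows by sqrt(r)."""
    centered = M - r @ M
    return centered * np.sqrt(r)[:, None]


def _orthobasis(M: np.ndarray, ref_scale: float = 0.0) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing SVD).

    ``ref_scale`` anchors the rank tolerance to the matrix's scale
    *before* any residualization, so constraints fully absorbed by the
    condition are recognized as rank 0 rather than numerical dust.
    """
    if M.size == 0:
        return M.reshape(M.shape[0], 0)
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    if s.size == 0 or s[0] <= 0:
        return M[:, :0]
    tol = max(s[0], ref_scale) * 1e-10
    return U[:, s > tol]


def _fit_inertia(
    Qc: np.ndarray, Xs: np.ndarray, ref_scale: float = 0.0
) -> tuple[np.ndarray, int]:
    basis = _orthobasis(Xs, ref_scale)
    fitted = basis @ (basis.T @ Qc)
    return fitted, basis.shape[1]


def cca(Y, X, Z=None) -> CcaResult:
    """(Partial) constrained correspondence analysis.

    Y is a nonnegative site × species table (DataFrame or array); X the
    constraint matrix; Z an optional conditioning matrix whose weighted
    projection is removed from both Y's standardized table and X before
    the constrained step.  X columns are used as given — standardize
    heterogeneous predictors before calling.
    """
    values, Xa, Za, row_labels, col_labels = _clean_table(Y, X, Z)
    n = values.shape[0]
    Q, r, c = _chi_square_standardize(values)
    total_inertia = float(np.sum(Q * Q))
    sqrt_r = np.sqrt(r)

    pz = 0
    conditioned = 0.0
    Qc = Q
    z_basis = None
    if Za is not None:
        Zs = _scale_constraints(Za, r)
        z_basis = _orthobasis(Zs)
        pz = z_basis.shape[1]
        Qz = z_basis @ (z_basis.T @ Q)
        conditioned = float(np.sum(Qz * Qz))
        Qc = Q - Qz

    Xs = _scale_constraints(Xa, r)
    raw_rank = _orthobasis(Xs).shape[1]
    x_scale = float(np.linalg.norm(Xs, 2)) if Xs.size else 0.0
    if z_basis is not None:
        Xs = Xs - z_basis @ (z_basis.T @ Xs)

    fitted, q = _fit_inertia(Qc, Xs, x_scale)
    if q == 0 and raw_rank > 0 and Za is not None:
        # Everything the constraints could explain is already in the
        # condition; constrained inertia is exactly 0.
        warnings.warn("constraints aliased with condition", stacklevel=2)
    constrained = float(np.sum(fitted * fitted))
    residual_q = Qc - fitted
    residual = float(np.sum(residual_q * residual_q))

    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    keep = s > (s[0] * _TOL if s.size and s[0] > 0 else np.inf)
    U, s, V = U[:, keep], s[keep], Vt[keep].T

    # Sign convention: each axis correlates nonnegatively with the first
    # constraint column (eigenvectors are sign-ambiguous otherwise).
    if Xs.shape[1] > 0 and np.linalg.norm(Xs[:, 0]) > 0:
        ref = Xs[:, 0]
        for k in range(U.shape[1]):
            dot = ref @ U[:, k]
            if dot < 0:
                U[:, k] *= -1
                V[:, k] *= -1

    _, s_res, _ = np.linalg.svd(residual_q, full_matrices=False)
    res_keep = s_res > (s_res[0] * _TOL if s_res.size and s_res[0] > 0 else np.inf)

    axes = [f"CCA{k + 1}" for k in range(U.shape[1])]
    site_scores = pd.DataFrame(
        (U * s) / sqrt_r[:, None], index=row_labels, columns=axes
    )
    species_scores = pd.DataFrame(
        V / np.sqrt(c)[:, None], index=col_labels, columns=axes
    )
    bip = np.zeros((Xs.shape[1], U.shape[1]))
    for j in range(Xs.shape[1]):
        norm = np.linalg.norm(Xs[:, j])
        if norm > 0:
            bip[j] = (Xs[:, j] / norm) @ U
    biplot_scores = pd.DataFrame(
        bip, index=[f"x{j}" for j in range(Xs.shape[1])], columns=axes
    )

    df_den = n - pz - q - 1
    if q > 0 and df_den > 0 and residual > 0:
        pseudo_f = (constrained / q) / (residual / df_den)
    else:
        pseudo_f = np.nan

    prop_total = constrained / total_inertia if total_inertia > 0 else np.nan
    uncond = total_inertia - conditioned
    prop_uncond = constrained / uncond if uncond > 0 else np.nan
    if n - pz - q - 1 > 0 and np.isfinite(prop_total):
        adj = 1.0 - (1.0 - prop_total) * (n - 1 - pz) / (n - pz - q - 1)
    else:
        adj = np.nan

    return CcaResult(
        total_inertia=total_inertia,
        conditioned_inertia=conditioned,
        constrained_inertia=constrained,
        residual_inertia=residual,
        eigenvalues=s**2,
        residual_eigenvalues=s_res[res_keep] ** 2,
        rank_constraints=q,
        rank_conditions=pz,
        pseudo_f=pseudo_f,
        df_num=q,
        df_den=df_den,
        site_scores=site_scores,
        species_scores=species_scores,
        biplot_scores=biplot_scores,
        prop_explained_total=prop_total,
        prop_explained_unconditioned=prop_uncond,
        adj_r_squared=adj,
    )


def permutation_test_cca(
    Y, X, Z=None, n_perm: int = 999, seed: int = 0
) -> PermutationTestResult:
    """Permutation test of the pCCA pseudo-F.

    Rows of X are freely permuted while Z stays fixed; the conditioning
    residualization is recomputed for every permutation.  The p-value is
    ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    if n_perm < 99:
        raise ValueError(f"n_perm must be >= 99, got {n_perm}")
    values, Xa, Za, _, _ = _clean_table(Y, X, Z)
    n = values.shape[0]
    if n < 3:
        raise ValueError("too few rows for an exchangeable permutation test")

    Q, r, _ = _chi_square_standardize(values)
    z_basis = None
    pz = 0
    Qc = Q
    if Za is not None:
        z_basis = _orthobasis(_scale_constraints(Za, r))
        pz = z_basis.shape[1]
        Qc = Q - z_basis @ (z_basis.T @ Q)

    def statistic(Xmat: np.ndarray) -> float:
        Xs = _scale_constraints(Xmat, r)
        x_scale = float(np.linalg.norm(Xs, 2)) if Xs.size else 0.0
        if z_basis is not None:
            Xs = Xs - z_basis @ (z_basis.T @ Xs)
        fitted, q = _fit_inertia(Qc, Xs, x_scale)
        if q == 0:
            return np.nan
        constrained = float(np.sum(fitted * fitted))
        resid = float(np.sum(Qc * Qc)) - constrained
        df_den = n - pz - q - 1
        if df_den <= 0 or resid <= 0:
            return np.inf
        return (constrained / q) / (resid / df_den)

    f_obs = statistic(Xa)
    rng = np.random.default_rng(seed)
    f_perm = np.empty(n_perm)
    for i in range(n_perm):
        f_perm[i] = statistic(Xa[rng.permutation(n)])
    n_ge = int(np.sum(f_perm >= f_obs))
    return PermutationTestResult(
        p_value=(1 + n_ge) / (1 + n_perm),
        f_observed=f_obs,
        f_permuted=f_perm,
        n_perm=n_perm,
        seed=seed,
    )


def cca_year_check(
    Y: pd.DataFrame, years=None, n_perm: int = 999, seed: int = 0
) -> tuple[CcaResult, PermutationTestResult]:
    """Single-predictor CCA with survey year as the constraint.

    Convenience wrapper used to verify that composition is stable across
    survey years before conditioning on year in the main model.  ``Y``
    may carry years in a MultiIndex level named ``year``; otherwise pass
    them explicitly.
    """
    if years is None:
        if isinstance(Y.index, pd.MultiIndex) and "year" in (Y.index.names or []):
            years = Y.index.get_level_values("year").to_numpy()
        else:
            raise ValueError("years not given and not found in the table index")
    years = np.asarray(years, dtype=float)
    if np.unique(years).size < 2:
        raise ValueError("year check needs at least 2 distinct survey years")
    X = years.reshape(-1, 1)
    return cca(Y, X), permutation_test_cca(Y, X, n_perm=n_perm, seed=seed)
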