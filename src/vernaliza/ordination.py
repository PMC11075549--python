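"""Constrained ordination: redundancy analysis (RDA), Ezekiel-adjusted R²,
permutation tests, and double-stopping forward selection, plus PCA and
Kendall rank-correlation utilities.

Forward selection follows the adjusted-R² stepwise scheme: at each step the
candidate that maximizes cumulative adjusted R² is evaluated; it enters only
if its permutation p-value is at or below ``pin`` and (when the scope rule
is on) the cumulative adjusted R² does not exceed the full model's.
Selection stops the first time the best candidate is inadmissible.

Factor variables are handled as blocks: the whole one-hot coding (first
level dropped) enters or leaves as a unit, and the adjusted-R² penalty
counts every fitted coding column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RdaModel",
    "SelectionTrace",
    "rda_fit",
    "adjusted_r2",
    "permutation_test",
    "forward_select",
    "pca",
    "kendall_tau",
]


def _as_matrix(a) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def encode_design(X: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, dict[str, list[int]]]:
    """Expand a mixed numeric/factor table to a numeric design matrix.

    Object/categorical/boolean columns become one-hot blocks with the first
    level dropped.  Returns the matrix and a map variable -> column indices.
    """
    if not isinstance(X, pd.DataFrame):
        mat = _as_matrix(X)
        return mat, {f"x{i + 1}": [i] for i in range(mat.shape[1])}
    cols, blocks = [], {}
    for name in X.columns:
        col = X[name]
        if col.dtype.kind in "OUb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True, dtype=float)
            start = sum(c.shape[1] for c, _ in cols)
            cols.append((dummies.to_numpy(), name))
            blocks[name] = list(range(start, start + dummies.shape[1]))
        else:
            start = sum(c.shape[1] for c, _ in cols)
            cols.append((col.to_numpy(dtype=float)[:, None], name))
            blocks[name] = [start]
    mat = np.concatenate([c for c, _ in cols], axis=1) if cols else np.empty((len(X), 0))
    return mat, blocks


@dataclass
class RdaModel:
    """Least-squares fit of a (centered) response matrix on a design matrix."""

    R2: float
    R2adj: float
    F_stat: float
    n: int
    m: int
    coefficients: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    axes: np.ndarray           # constrained axes: PCs of fitted values
    axis_eigvals: np.ndarray
    Yc: np.ndarray = field(repr=False, default=None)
    Xc: np.ndarray = field(repr=False, default=None)


def _fit_core(Yc: np.ndarray, Xc: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Least squares of centered Y on centered X; returns (fitted, coef, rank)."""
    if Xc.shape[1] == 0:
        return np.zeros_like(Yc), np.empty((0, Yc.shape[1])), 0
    coef, _, rank, _ = np.linalg.lstsq(Xc, Yc, rcond=None)
    return Xc @ coef, coef, int(rank)


def rda_fit(Y, X) -> RdaModel:
    """Redundancy analysis: regress Y on X, then ordinate the fitted values.

    With a single response column this is multiple regression: R² equals the
    squared multiple correlation.  Aliased (rank-deficient) columns are kept
    in the fit via the minimum-norm solution but only the design rank counts
    toward the adjusted-R² penalty; a warning is emitted.
    """
    Ymat = _as_matrix(Y)
    Xmat, _ = encode_design(X) if isinstance(X, pd.DataFrame) else (_as_matrix(X), None)
    n = Ymat.shape[0]
    if Xmat.shape[0] != n:
        raise ValueError("Y and X row counts differ")
    Yc = Ymat - Ymat.mean(axis=0)
    Xc = Xmat - Xmat.mean(axis=0)
    fitted, coef, rank = _fit_core(Yc, Xc)
    if rank < Xc.shape[1]:
        warnings.warn("rank-deficient design: aliased columns do not add parameters",
                      stacklevel=2)
    m = rank
    if n <= m + 1:
        raise ValueError(f"need n > m + 1 (n={n}, m={m})")
    tot = float((Yc ** 2).sum())
    if tot == 0:
        raise ValueError("response has zero variance")
    expl = float((fitted ** 2).sum())
    R2 = expl / tot
    F = (R2 / m) / ((1 - R2) / (n - m - 1)) if m > 0 else 0.0
    # constrained axes = principal components of the fitted values
    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    return RdaModel(
        R2=R2,
        R2adj=adjusted_r2(R2, n, m),
        F_stat=F,
        n=n,
        m=m,
        coefficients=coef,
        fitted=fitted,
        residuals=Yc - fitted,
        axes=u * s,
        axis_eigvals=s ** 2 / max(n - 1, 1),
        Yc=Yc,
        Xc=Xc,
    )


def adjusted_r2(R2: float, n: int, m: int) -> float:
    """Ezekiel adjustment: 1 - (1 - R2) (n - 1)/(n - m - 1).  May be negative."""
    if n <= m + 1:
        raise ValueError(f"adjusted R2 undefined for n={n}, m={m}")
    return 1.0 - (1.0 - R2) * (n - 1) / (n - m - 1)


def _rss_after_projection(Ymat: np.ndarray, H: np.ndarray | None) -> np.ndarray:
    """Residual sum of squares of each column of Ymat after projecting on H."""
    if H is None:
        return (Ymat ** 2).sum(axis=0)
    resid = Ymat - H @ Ymat
    return (resid ** 2).sum(axis=0)


def _hat(Xc: np.ndarray) -> np.ndarray | None:
    if Xc.shape[1] == 0:
        return None
    return Xc @ np.linalg.pinv(Xc)


def permutation_test(
    model: RdaModel | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    *,
    Y=None,
    X=None,
    X_reduced=None,
) -> float:
    """Permutation p-value for an RDA fit (add-one convention).

    Without conditioning variables the rows of Y are freely permuted.  When
    ``X_reduced`` is given, the test is for the columns added on top of the
    reduced design: residuals of the reduced model are permuted and added
    back to its fitted values (residual permutation under the reduced model).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    if model is not None:
        Yc, Xc = model.Yc, model.Xc
    else:
        Ymat, Xmat = _as_matrix(Y), _as_matrix(X)
        Yc = Ymat - Ymat.mean(axis=0)
        Xc = Xmat - Xmat.mean(axis=0)
    n, q = Yc.shape
    H_full = _hat(Xc)
    if X_reduced is None:
        m_full = np.linalg.matrix_rank(Xc) if Xc.shape[1] else 0
        df1, df2 = m_full, n - m_full - 1
        tot = (Yc ** 2).sum()
        rss_obs = _rss_after_projection(Yc, H_full).sum()
        F_obs = ((tot - rss_obs) / df1) / (rss_obs / df2)
        if q == 1:
            perm_cols = np.empty((n, n_perm))
            for b in range(n_perm):
                perm_cols[:, b] = Yc[rng.permutation(n), 0]
            rss = _rss_after_projection(perm_cols, H_full)
            tot_p = (perm_cols ** 2).sum(axis=0)
            F_perm = ((tot_p - rss) / df1) / (rss / df2)
            count = int(np.sum(F_perm >= F_obs - 1e-12))
        else:
            count = 0
            for _ in range(n_perm):
                Yp = Yc[rng.permutation(n)]
                rss = _rss_after_projection(Yp, H_full).sum()
                F = ((tot - rss) / df1) / (rss / df2)
                if F >= F_obs - 1e-12:
                    count += 1
        return (1 + count) / (1 + n_perm)
    # partial test: residual permutation under the reduced model
    Xr = _as_matrix(X_reduced)
    Xr = Xr - Xr.mean(axis=0)
    H_red = _hat(Xr)
    m_red = np.linalg.matrix_rank(Xr) if Xr.shape[1] else 0
    m_full = np.linalg.matrix_rank(Xc)
    df1 = m_full - m_red
    df2 = n - m_full - 1
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degenerate degrees of freedom in partial test")

    def partial_F(Ymat):
        rss_red = _rss_after_projection(Ymat, H_red).sum(axis=0) \
            if Ymat.ndim == 2 else _rss_after_projection(Ymat[:, None], H_red).sum()
        rss_full = _rss_after_projection(Ymat, H_full).sum(axis=0) \
            if Ymat.ndim == 2 else _rss_after_projection(Ymat[:, None], H_full).sum()
        return ((rss_red - rss_full) / df1) / (rss_full / df2)

    F_obs = float(np.sum(partial_F(Yc)))
    fitted_red = np.zeros_like(Yc) if H_red is None else H_red @ Yc
    resid_red = Yc - fitted_red
    count = 0
    if q == 1:
        # vectorized over permutations
        perm_cols = np.empty((n, n_perm))
        for b in range(n_perm):
            perm_cols[:, b] = resid_red[rng.permutation(n), 0]
        Ystar = fitted_red + perm_cols
        rss_red = _rss_after_projection(Ystar, H_red)
        rss_full = _rss_after_projection(Ystar, H_full)
        F_perm = ((rss_red - rss_full) / df1) / (rss_full / df2)
        count = int(np.sum(F_perm >= F_obs - 1e-12))
    else:
        for _ in range(n_perm):
            Ystar = fitted_red + resid_red[rng.permutation(n)]
            if float(np.sum(partial_F(Ystar))) >= F_obs - 1e-12:
                count += 1
    return (1 + count) / (1 + n_perm)


@dataclass
class SelectionTrace:
    """Ordered record of admitted variables plus the stopping context."""

    steps: list[dict]
    scope_r2adj: float | None
    stopping_reason: str

    @property
    def selected(self) -> list[str]:
        return [s["variable"] for s in self.steps]

    def to_frame(self) -> pd.DataFrame:
        cols = ["variable", "cumulative_r2adj", "aic", "F", "p"]
        return pd.DataFrame(self.steps, columns=cols)


def _aic_like(rss: float, n: int, k: int) -> float:
    # k = fitted parameters incl. intercept; reporting parity only
    return n * np.log(max(rss, 1e-300) / n) + 2 * (k + 1)


def forward_select(
    Y,
    candidates: dict[str, object] | pd.DataFrame,
    pin: float = 0.01,
    n_perm: int = 999,
    r2scope: bool = True,
    seed: int | None = None,
) -> SelectionTrace:
    """Double-stopping forward selection on cumulative adjusted R².

    ``candidates`` maps variable names to columns (a factor maps to its
    whole coding block).  At each step the candidate maximizing cumulative
    adjusted R² is permutation-tested (marginal at step one, residual
    permutation under the current model afterwards); admission additionally
    requires staying at or below the all-candidate model's adjusted R²
    when ``r2scope`` is set.
    """
    rng = np.random.default_rng(seed)
    if isinstance(candidates, pd.DataFrame):
        mat, blocks = encode_design(candidates)
        cand = {name: mat[:, idx] for name, idx in blocks.items()}
    else:
        cand = {}
        for name, v in candidates.items():
            if isinstance(v, pd.DataFrame):
                enc, _ = encode_design(v)
                cand[name] = enc
            elif isinstance(v, pd.Series) and (
                v.dtype.kind in "OUb" or isinstance(v.dtype, pd.CategoricalDtype)
            ):
                cand[name] = pd.get_dummies(v, drop_first=True, dtype=float).to_numpy()
            else:
                cand[name] = _as_matrix(v)
    if not cand:
        raise ValueError("candidates must be non-empty")
    Ymat = _as_matrix(Y)
    n = Ymat.shape[0]
    Yc = Ymat - Ymat.mean(axis=0)

    scope = None
    if r2scope:
        full_X = np.concatenate(list(cand.values()), axis=1)
        scope = rda_fit(Yc, full_X).R2adj

    selected: list[str] = []
    X_sel = np.empty((n, 0))
    steps: list[dict] = []
    reason = "no admissible candidate"
    while True:
        remaining = [name for name in cand if name not in selected]
        if not remaining:
            reason = "all candidates admitted"
            break
        best_name, best_r2adj, best_model = None, -np.inf, None
        for name in remaining:
            X_try = np.concatenate([X_sel, cand[name]], axis=1)
            try:
                model = rda_fit(Yc, X_try)
            except ValueError:
                continue  # not enough df for this block
            if model.R2adj > best_r2adj:
                best_name, best_r2adj, best_model = name, model.R2adj, model
        if best_name is None:
            reason = "no candidate fittable"
            break
        if r2scope and best_r2adj > scope + 1e-12:
            reason = "R2scope exceeded"
            break
        p = permutation_test(
            n_perm=n_perm,
            seed=int(rng.integers(2 ** 31)),
            Y=Yc,
            X=np.concatenate([X_sel, cand[best_name]], axis=1),
            X_reduced=X_sel if selected else None,
        )
        if p > pin:
            reason = "Pin exceeded"
            break
        rss = float((best_model.residuals ** 2).sum())
        steps.append({
            "variable": best_name,
            "cumulative_r2adj": best_r2adj,
            "aic": _aic_like(rss, n, best_model.m),
            "F": best_model.F_stat,
            "p": p,
        })
        selected.append(best_name)
        X_sel = np.concatenate([X_sel, cand[best_name]], axis=1)
    return SelectionTrace(steps=steps, scope_r2adj=scope, stopping_reason=reason)


def pca(X: pd.DataFrame | np.ndarray):
    """PCA on the correlation matrix (columns standardized first).

    Returns (scores, loadings, variance_fractions).  Constant columns are
    dropped with a warning.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        mat = X.to_numpy(dtype=float)
    else:
        mat = _as_matrix(X)
        names = [f"x{i + 1}" for i in range(mat.shape[1])]
    n = mat.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    sd = mat.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [names[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"dropping constant columns: {dropped}", stacklevel=2)
    Z = (mat[:, keep] - mat[:, keep].mean(axis=0)) / sd[keep]
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = s ** 2 / (n - 1)
    fractions = eigvals / eigvals.sum()
    return u * s, vt.T, fractions


def kendall_tau(x, y) -> tuple[float, float]:
    """Tie-corrected Kendall tau-b with normal-approximation two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need paired vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau undefined for an all-tied vector")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
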