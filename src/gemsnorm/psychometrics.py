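"""Classical-test-theory and factor-structure validation of a score matrix.

Internal consistency uses the *standardised* Cronbach's alpha, computed from
the mean pairwise inter-item correlation r_bar of the k = 11 weighted task
scores:

    alpha = k r_bar / (1 + (k - 1) r_bar).

Exploratory factor analysis uses maximum-likelihood extraction on the
correlation matrix (profile likelihood over the uniquenesses, the classical
Lawley-Maxwell formulation), with the Bartlett-corrected likelihood-ratio
goodness-of-fit statistic

    chi2 = (n - 1 - (2p + 5)/6 - 2m/3) * F_min,
    df   = ((p - m)^2 - (p + m)) / 2,

evaluated on the unrotated solution; chi-square and df are invariant to the
orthogonal rotation applied for interpretation (varimax by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import ComputationError, ValidationError
from .session_io import NormativeTable, TASK_COLUMNS

__all__ = [
    "EFAResult",
    "standardized_alpha",
    "item_total_correlations",
    "ml_efa",
    "efa_degrees_of_freedom",
    "varimax",
    "descriptive_table",
    "score_matrix",
]


def score_matrix(table) -> pd.DataFrame:
    """Extract the n x 11 weighted-score matrix from a normative table."""
    df = table.valid() if isinstance(table, NormativeTable) else table
    return df.loc[:, list(TASK_COLUMNS)].astype(float)


def _as_matrix(matrix) -> pd.DataFrame:
    if isinstance(matrix, NormativeTable):
        return score_matrix(matrix)
    m = pd.DataFrame(matrix)
    return m.astype(float)


def standardized_alpha(matrix) -> float:
    """Standardised Cronbach's alpha from the mean inter-item correlation."""
    m = _as_matrix(matrix)
    k = m.shape[1]
    if k < 2:
        raise ComputationError("alpha needs at least 2 columns")
    sds = m.std(ddof=1)
    constant = list(sds.index[sds == 0])
    if constant:
        raise ComputationError(f"constant column(s): {constant}")
    corr = m.corr().to_numpy()
    iu = np.triu_indices(k, 1)
    r_bar = float(corr[iu].mean())
    return k * r_bar / (1 + (k - 1) * r_bar)


def item_total_correlations(
    matrix, totals=None, corrected: bool = False
) -> pd.Series:
    """Pearson r of each task with the global score.

    By default the item is *included* in the total (the instrument's
    convention); ``corrected=True`` removes the item's own weighted score
    from the total before correlating.
    """
    m = _as_matrix(matrix)
    if totals is None:
        totals = m.sum(axis=1) * 100.0 / 99.0
    totals = np.asarray(totals, dtype=float)
    if len(totals) != len(m):
        raise ValidationError("totals length differs from matrix rows")
    out = {}
    flagged = []
    for col in m.columns:
        x = m[col].to_numpy()
        y = totals - x * 100.0 / 99.0 if corrected else totals
        if np.std(x) == 0 or np.std(y) == 0:
            out[col] = np.nan
            flagged.append(col)
        else:
            out[col] = float(stats.pearsonr(x, y).statistic)
    s = pd.Series(out, name="item_total_r")
    if flagged:
        s.attrs["zero_variance"] = flagged
        warnings.warn(f"zero-variance column(s) flagged: {flagged}")
    return s


def efa_degrees_of_freedom(p: int, m: int) -> int:
    """Degrees of freedom of the m-factor likelihood-ratio test on p items."""
    df = ((p - m) ** 2 - (p + m)) / 2
    return int(df)


@dataclass
class EFAResult:
    loadings: pd.DataFrame       # p x m, rotated per `rotation`
    uniquenesses: pd.Series
    n_factors: int
    chi_square: float
    df: int
    p_value: float
    rotation: str
    converged: bool
    heywood: bool

    @property
    def communalities(self) -> pd.Series:
        return (self.loadings ** 2).sum(axis=1)

    def display(self, min_loading: float = 0.1) -> pd.DataFrame:
        """Loadings table with sub-threshold values shown as dashes."""
        out = self.loadings.round(3).astype(object)
        out[self.loadings.abs() < min_loading] = "-"
        return out


def _ml_objective(log_psi, corr, m):
    psi = np.exp(log_psi)
    scale = 1.0 / np.sqrt(psi)
    sstar = corr * np.outer(scale, scale)
    eig = np.linalg.eigvalsh(sstar)[::-1]
    tail = eig[m:]
    tail = np.clip(tail, 1e-12, None)
    return float(np.sum(tail - np.log(tail)) - len(tail))


def _ml_loadings(psi, corr, m):
    scale = 1.0 / np.sqrt(psi)
    sstar = corr * np.outer(scale, scale)
    vals, vecs = np.linalg.eigh(sstar)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order[:m]], vecs[:, order[:m]]
    load = vecs * np.sqrt(np.clip(vals - 1.0, 0.0, None))
    return load * np.sqrt(psi)[:, None]


def varimax(loadings: np.ndarray, normalize: bool = True,
            tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """Kaiser varimax rotation (orthogonal); preserves communalities."""
    L = np.asarray(loadings, dtype=float).copy()
    p, m = L.shape
    if m < 2:
        return L
    if normalize:
        h = np.sqrt((L ** 2).sum(axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]
    R = np.eye(m)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr ** 3 - Lr @ np.diag((Lr ** 2).sum(axis=0)) / p)
        )
        R = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol:
            break
        var_old = var_new
    L = L @ R
    if normalize:
        L = L * h[:, None]
    # orient: make each factor's largest-magnitude loading positive, order by
    # explained variance for a deterministic layout
    order = np.argsort(-(L ** 2).sum(axis=0), kind="stable")
    L = L[:, order]
    for j in range(m):
        if L[np.argmax(np.abs(L[:, j])), j] < 0:
            L[:, j] = -L[:, j]
    return L


def ml_efa(
    data,
    n_factors: int,
    rotation: str = "varimax",
    n_obs: int | None = None,
    psi_lower: float = 0.005,
) -> EFAResult:
    """Maximum-likelihood exploratory factor analysis on the correlations.

    ``data`` is either a raw score matrix (rows = examinees) or a correlation
    matrix (square, unit diagonal; ``n_obs`` then required).  Uniquenesses are
    bounded below at ``psi_lower``; a solution on the bound is a Heywood case
    and is flagged (with a warning) rather than returned unconstrained.
    """
    if rotation not in ("none", "varimax"):
        raise ValidationError(f"unsupported rotation {rotation!r}")
    m = int(n_factors)
    if isinstance(data, NormativeTable):
        data = score_matrix(data)
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 2 and arr.shape[0] == arr.shape[1] and np.allclose(
        np.diag(arr), 1.0
    ) and np.allclose(arr, arr.T):
        corr = arr
        names = list(getattr(data, "columns", range(arr.shape[0])))
        if n_obs is None:
            raise ValidationError("n_obs required with a correlation matrix")
        n = int(n_obs)
    else:
        dfm = _as_matrix(data)
        names = list(dfm.columns)
        corr = dfm.corr().to_numpy()
        n = len(dfm)
    p = corr.shape[0]
    df = efa_degrees_of_freedom(p, m)
    if m < 1:
        raise ValidationError("need at least one factor")
    if df < 0:
        raise ValidationError(f"{m} factors on {p} items gives df {df} < 0")
    if n <= p:
        raise ComputationError(f"need more observations ({n}) than items ({p})")

    # factanal-style start: psi proportional to 1/diag(R^-1)
    inv_diag = np.diag(np.linalg.pinv(corr))
    start = np.clip((1 - 0.5 * m / p) / np.clip(inv_diag, 1e-8, None),
                    psi_lower, 1.0)
    res = optimize.minimize(
        _ml_objective,
        np.log(start),
        args=(corr, m),
        method="L-BFGS-B",
        bounds=[(np.log(psi_lower), 0.0)] * p,
        options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-9},
    )
    psi = np.exp(res.x)
    heywood = bool(np.any(psi <= psi_lower * (1 + 1e-6)))
    if heywood:
        warnings.warn(
            "Heywood case: uniqueness(es) at the lower bound; solution kept "
            "at the bounded optimum"
        )
    fmin = _ml_objective(res.x, corr, m)
    chi2 = max((n - 1 - (2 * p + 5) / 6 - 2 * m / 3) * fmin, 0.0)
    pval = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    load = _ml_loadings(psi, corr, m)
    if rotation == "varimax":
        load = varimax(load)
    cols = [f"factor_{j + 1}" for j in range(m)]
    return EFAResult(
        loadings=pd.DataFrame(load, index=names, columns=cols),
        uniquenesses=pd.Series(psi, index=names, name="uniqueness"),
        n_factors=m,
        chi_square=float(chi2),
        df=df,
        p_value=pval,
        rotation=rotation,
        converged=bool(res.success),
        heywood=heywood,
    )


_DESC_COLUMNS = ("mean", "sd", "median", "min", "max", "kurtosis",
                 "skewness", "q1", "q3")


def descriptive_table(table, columns=None) -> pd.DataFrame:
    """Per-variable summary in the normative-table layout.

    Columns: mean, SD, median, min, max, Fisher excess kurtosis (bias
    corrected), sample skewness (bias corrected, "type 2"), linearly
    interpolated quartiles.  Constant columns report 0 skewness/kurtosis and
    are flagged in ``attrs['degenerate']``.
    """
    if isinstance(table, NormativeTable):
        df = table.valid()
        columns = columns or ["age", "education", "cr", *TASK_COLUMNS, "total"]
    else:
        df = pd.DataFrame(table)
        columns = columns or [
            c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])
        ]
    if len(df) < 4:
        raise ComputationError("need at least 4 rows for descriptives")
    rows = {}
    degenerate = []
    for col in columns:
        x = pd.to_numeric(df[col], errors="coerce").dropna().to_numpy()
        const = np.std(x) == 0
        if const:
            degenerate.append(col)
        rows[col] = {
            "mean": np.mean(x),
            "sd": np.std(x, ddof=1),
            "median": np.median(x),
            "min": np.min(x),
            "max": np.max(x),
            "kurtosis": 0.0 if const else float(
                stats.kurtosis(x, fisher=True, bias=False)
            ),
            "skewness": 0.0 if const else float(stats.skew(x, bias=False)),
            "q1": np.quantile(x, 0.25),   # linear interpolation (type 7)
            "q3": np.quantile(x, 0.75),
        }
    out = pd.DataFrame(rows).T.loc[columns, list(_DESC_COLUMNS)]
    out.attrs["degenerate"] = degenerate
    return out
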