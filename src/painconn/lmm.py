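"""Random-intercept linear mixed models for edge-wise behaviour coupling.

The three models relate single-trial pain ratings to single-trial edge
connectivity (Fisher-Z, standardized per edge):

* M1  ``rating ~ z + (1 | subject)``
* M2  ``rating ~ z * condition + (1 | subject:condition)``
* M3  ``rating ~ z : struc + (1 | subject)``

All are Gaussian random-intercept models, so the covariance has a single
free ratio ``lambda = sigma_group^2 / sigma_resid^2``.  Estimation is by
restricted maximum likelihood with the fixed effects and the residual
variance profiled out, leaving a 1-D criterion in ``lambda``:

    crit(lambda) = (n - p) log RSS(lambda) + log|M| + log|X' M^-1 X|,

with ``M = I + lambda Z Z'`` block diagonal over groups, minimized on a log
grid followed by golden-section refinement (the zero-variance boundary is
always compared, where the fit reduces exactly to OLS).  Because
``M^-1 = I - diag_g(c_g J)`` with ``c_g = lambda / (1 + lambda n_g)``, every
quantity reduces to group sums, which lets the mass (per-edge) fitter run
fully vectorized across edges and across permutation replicates at once.

t statistics are beta / se with GLS standard errors at the REML optimum;
downstream inference is permutation-based, so the reference distribution of
t never enters the family-wise correction (nominal residual df are reported
for information only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import EdgeTensor

LAMBDA_GRID = np.concatenate([[0.0], np.logspace(-6.0, 4.0, 41)])
GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0
REFINE_ITER = 40
LAMBDA_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# fit container
# ---------------------------------------------------------------------------


@dataclass
class LmeFit:
    """Result of a single random-intercept REML fit."""

    params: pd.Series          # fixed-effect estimates
    se: pd.Series
    tstat: pd.Series
    sigma2_resid: float
    sigma2_group: float
    lambda_ratio: float
    n_obs: int
    n_groups: int
    df_resid: int              # nominal n - p, informational only
    converged: bool
    extras: dict = field(default_factory=dict)

    def pvalues(self) -> pd.Series:
        """Two-sided normal-reference p-values (uncorrected)."""
        from scipy import stats

        return pd.Series(
            2.0 * stats.norm.sf(np.abs(self.tstat.to_numpy())),
            index=self.tstat.index,
        )


def _fit_to_lme(res: dict, names: list[str], extras: dict | None = None) -> LmeFit:
    return LmeFit(
        params=pd.Series(res["beta"], index=names),
        se=pd.Series(res["se"], index=names),
        tstat=pd.Series(res["tstat"], index=names),
        sigma2_resid=res["sigma2_resid"],
        sigma2_group=res["sigma2_group"],
        lambda_ratio=res["lambda"],
        n_obs=res["n_obs"],
        n_groups=res["n_groups"],
        df_resid=res["df_resid"],
        converged=res["converged"],
        extras=extras or {},
    )


# ---------------------------------------------------------------------------
# scalar fitter (general fixed-effect design)
# ---------------------------------------------------------------------------


def _group_codes(groups) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(groups), sort=False)
    if (codes < 0).any():
        raise ValueError("missing values in grouping factor")
    return codes.astype(np.intp), len(uniques)


def _scalar_crit(lam, pre):
    """REML criterion and GLS pieces for one lambda (general design)."""
    ng, Sx, Sy, XtX, Xty, yy, n, p = pre
    c = lam / (1.0 + lam * ng)
    A = XtX - Sx.T @ (c[:, None] * Sx)
    b = Xty - Sx.T @ (c * Sy)
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.inf, None
    yMy = yy - c @ (Sy * Sy)
    rss = yMy - beta @ b
    sign, logdetA = np.linalg.slogdet(A)
    if rss <= 0 or sign <= 0:
        return np.inf, None
    logdetM = np.log1p(lam * ng).sum()
    crit = (n - p) * np.log(rss) + logdetM + logdetA
    return crit, (beta, A, rss)


def _fit_scalar(
    y: np.ndarray,
    X: np.ndarray,
    groups,
    refine_iter: int = REFINE_ITER,
) -> dict:
    """Profiled-REML fit of ``y = X beta + (1|group) + eps``."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    codes, G = _group_codes(groups)
    n, p = X.shape
    if G < 2:
        raise ValueError("need at least 2 groups")
    if n / G < 3:
        raise ValueError("need at least 3 observations per group on average")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design is rank deficient (constant predictor?)")

    ind = np.zeros((n, G))
    ind[np.arange(n), codes] = 1.0
    ng = ind.sum(axis=0)
    Sx = ind.T @ X
    Sy = ind.T @ y
    pre = (ng, Sx, Sy, X.T @ X, X.T @ y, y @ y, n, p)

    crits = np.array([_scalar_crit(lam, pre)[0] for lam in LAMBDA_GRID])
    i = int(np.argmin(crits))
    if i == 0:
        lo, hi = np.log10(LAMBDA_FLOOR), np.log10(LAMBDA_GRID[2])
    else:
        lo = np.log10(max(LAMBDA_GRID[max(i - 1, 1)], LAMBDA_FLOOR))
        hi = np.log10(LAMBDA_GRID[min(i + 1, len(LAMBDA_GRID) - 1)])
    x1 = hi - GOLDEN * (hi - lo)
    x2 = lo + GOLDEN * (hi - lo)
    f1 = _scalar_crit(10.0 ** x1, pre)[0]
    f2 = _scalar_crit(10.0 ** x2, pre)[0]
    for _ in range(refine_iter):
        if f1 < f2:
            hi, x2, f2 = x2, x1, f1
            x1 = hi - GOLDEN * (hi - lo)
            f1 = _scalar_crit(10.0 ** x1, pre)[0]
        else:
            lo, x1, f1 = x1, x2, f2
            x2 = lo + GOLDEN * (hi - lo)
            f2 = _scalar_crit(10.0 ** x2, pre)[0]
    lam = 10.0 ** ((lo + hi) / 2.0)
    crit_ref, stats_ref = _scalar_crit(lam, pre)
    crit0, stats0 = _scalar_crit(0.0, pre)
    if crit0 <= crit_ref:
        lam, stats_ref = 0.0, stats0
    beta, A, rss = stats_ref
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    converged = not np.isclose(lam, LAMBDA_GRID[-1])
    return {
        "beta": beta,
        "se": se,
        "tstat": beta / se,
        "sigma2_resid": sigma2,
        "sigma2_group": lam * sigma2,
        "lambda": lam,
        "n_obs": n,
        "n_groups": G,
        "df_resid": n - p,
        "converged": converged,
    }


# ---------------------------------------------------------------------------
# batched slope fitter: X_e = [1, x_e], many edges x many outcomes
# ---------------------------------------------------------------------------


class MassSlopeEngine:
    """Vectorized REML slope fits for designs ``[1, x_e]`` over one grouping.

    Precomputes predictor-side group sums once; :meth:`fit` then evaluates
    all edges and all outcome columns (e.g. permutation replicates)
    simultaneously.  Balanced groupings (equal group sizes — the rule for
    the designs handled here) use a fast path in which the shrinkage weight
    ``c = lambda / (1 + lambda m)`` is a scalar per (edge, outcome) cell;
    unbalanced groupings fall back to explicit per-group reductions.
    """

    def __init__(self, x: np.ndarray, groups, refine_iter: int = REFINE_ITER):
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        self.n, self.E = x.shape
        self.codes, self.G = _group_codes(groups)
        if self.G < 2:
            raise ValueError("need at least 2 groups")
        self.refine_iter = refine_iter
        ind = np.zeros((self.n, self.G))
        ind[np.arange(self.n), self.codes] = 1.0
        self._ind = ind
        self.ng = ind.sum(axis=0)
        self.balanced = bool(np.all(self.ng == self.ng[0]))
        self.m = float(self.ng[0]) if self.balanced else None
        self.x = x
        self.Sx = ind.T @ x                      # (G, E)
        self.sum_x = x.sum(axis=0)               # (E,)
        self.sum_x2 = (x * x).sum(axis=0)        # (E,)
        self.Sx2sum = (self.Sx ** 2).sum(axis=0)

    # -- criterion evaluations ------------------------------------------------

    def _pieces_scalar_lam(self, lam, Ydata):
        """All GLS pieces for a single scalar lambda; broadcasts to (E, P)."""
        Sy, sum_y, sum_y2, xty = Ydata
        c = lam / (1.0 + lam * self.ng)          # (G,)
        a11 = self.n - c @ (self.ng ** 2)
        a12 = self.sum_x - (c * self.ng) @ self.Sx
        a22 = self.sum_x2 - c @ (self.Sx ** 2)
        b1 = sum_y - (c * self.ng) @ Sy
        b2 = xty - self.Sx.T @ (c[:, None] * Sy)
        q = sum_y2 - c @ (Sy ** 2)
        logdetM = float(np.log1p(lam * self.ng).sum())
        return a11, a12[:, None], a22[:, None], b1[None, :], b2, q[None, :], logdetM

    def _pieces_cell_lam(self, lam_ep, Ydata):
        """GLS pieces for per-(edge, outcome) lambda array of shape (E, P)."""
        Sy, sum_y, sum_y2, xty = Ydata
        if self.balanced:
            m = self.m
            c = lam_ep / (1.0 + lam_ep * m)      # (E, P)
            a11 = self.n - c * (self.G * m * m)
            a12 = self.sum_x[:, None] - c * (m * self.Sx.sum(axis=0))[:, None]
            a22 = self.sum_x2[:, None] - c * self.Sx2sum[:, None]
            b1 = sum_y[None, :] - c * (m * Sy.sum(axis=0))[None, :]
            b2 = xty - c * (self.Sx.T @ Sy)
            q = sum_y2[None, :] - c * (Sy ** 2).sum(axis=0)[None, :]
            logdetM = self.G * np.log1p(lam_ep * m)
        else:
            c = lam_ep[None, :, :] / (
                1.0 + lam_ep[None, :, :] * self.ng[:, None, None]
            )
            a11 = self.n - np.einsum("gep,g->ep", c, self.ng ** 2)
            a12 = self.sum_x[:, None] - np.einsum(
                "gep,ge->ep", c, self.ng[:, None] * self.Sx
            )
            a22 = self.sum_x2[:, None] - np.einsum("gep,ge->ep", c, self.Sx ** 2)
            b1 = sum_y[None, :] - np.einsum("gep,g,gp->ep", c, self.ng, Sy)
            b2 = xty - np.einsum("gep,ge,gp->ep", c, self.Sx, Sy)
            q = sum_y2[None, :] - np.einsum("gep,gp->ep", c, Sy ** 2)
            logdetM = np.log1p(
                lam_ep[None, :, :] * self.ng[:, None, None]
            ).sum(axis=0)
        return a11, a12, a22, b1, b2, q, logdetM

    @staticmethod
    def _crit_from_pieces(pieces, n):
        a11, a12, a22, b1, b2, q, logdetM = pieces
        det = a11 * a22 - a12 ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            beta1 = (a11 * b2 - a12 * b1) / det
            beta0 = (a22 * b1 - a12 * b2) / det
            rss = q - beta0 * b1 - beta1 * b2
            crit = (n - 2) * np.log(rss) + logdetM + np.log(det)
        return np.where(np.isfinite(crit), crit, np.inf)

    # -- fitting --------------------------------------------------------------

    def fit(self, Y: np.ndarray) -> dict:
        """Fit all edges against all outcome columns.

        Parameters
        ----------
        Y: (n,) or (n, P) outcome matrix.

        Returns
        -------
        dict of (E, P) arrays: ``beta`` (slope), ``intercept``, ``se``,
        ``tstat``, ``lambda``, ``sigma2_resid``, ``sigma2_group``.
        """
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        Ydata = (
            self._ind.T @ Y,            # Sy (G, P)
            Y.sum(axis=0),              # sum_y (P,)
            (Y * Y).sum(axis=0),        # sum_y2 (P,)
            self.x.T @ Y,               # xty (E, P)
        )
        n = self.n

        best = np.full((self.E, Y.shape[1]), np.inf)
        best_idx = np.zeros((self.E, Y.shape[1]), dtype=np.intp)
        for k, lam in enumerate(LAMBDA_GRID):
            crit = self._crit_from_pieces(self._pieces_scalar_lam(lam, Ydata), n)
            better = crit < best
            best = np.where(better, crit, best)
            best_idx = np.where(better, k, best_idx)
        crit0 = self._crit_from_pieces(self._pieces_scalar_lam(0.0, Ydata), n)

        kmax = len(LAMBDA_GRID) - 1
        lo_idx = np.maximum(best_idx - 1, 1)
        hi_idx = np.minimum(best_idx + 1, kmax)
        lo = np.where(
            best_idx == 0,
            np.log10(LAMBDA_FLOOR),
            np.log10(LAMBDA_GRID[lo_idx]),
        )
        hi = np.where(
            best_idx == 0,
            np.log10(LAMBDA_GRID[2]),
            np.log10(LAMBDA_GRID[hi_idx]),
        )
        x1 = hi - GOLDEN * (hi - lo)
        x2 = lo + GOLDEN * (hi - lo)
        f1 = self._crit_from_pieces(self._pieces_cell_lam(10.0 ** x1, Ydata), n)
        f2 = self._crit_from_pieces(self._pieces_cell_lam(10.0 ** x2, Ydata), n)
        for _ in range(self.refine_iter):
            take1 = f1 < f2
            hi = np.where(take1, x2, hi)
            lo = np.where(take1, lo, x1)
            span = hi - lo
            cand = np.where(take1, hi - GOLDEN * span, lo + GOLDEN * span)
            fcand = self._crit_from_pieces(
                self._pieces_cell_lam(10.0 ** cand, Ydata), n
            )
            x1_old, f1_old, x2_old, f2_old = x1, f1, x2, f2
            x1 = np.where(take1, cand, x2_old)
            f1 = np.where(take1, fcand, f2_old)
            x2 = np.where(take1, x1_old, cand)
            f2 = np.where(take1, f1_old, fcand)

        lam = 10.0 ** ((lo + hi) / 2.0)
        crit_ref = self._crit_from_pieces(self._pieces_cell_lam(lam, Ydata), n)
        lam = np.where(crit0 <= crit_ref, 0.0, lam)
        a11, a12, a22, b1, b2, q, _ = self._pieces_cell_lam(lam, Ydata)
        det = a11 * a22 - a12 ** 2
        beta1 = (a11 * b2 - a12 * b1) / det
        beta0 = (a22 * b1 - a12 * b2) / det
        rss = q - beta0 * b1 - beta1 * b2
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 * a11 / det)
        return {
            "beta": beta1,
            "intercept": beta0 + np.zeros_like(beta1),
            "se": se,
            "tstat": beta1 / se,
            "lambda": lam + np.zeros_like(beta1),
            "sigma2_resid": sigma2,
            "sigma2_group": lam * sigma2,
        }


# ---------------------------------------------------------------------------
# public single-fit operations
# ---------------------------------------------------------------------------


def _standardize(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu = float(np.mean(x))
    sd = float(np.std(x))
    if sd == 0:
        raise ValueError("constant predictor")
    return (x - mu) / sd, mu, sd


def fit_random_intercept(
    data: pd.DataFrame,
    outcome: str = "rating",
    predictor: str = "z",
    group: str = "subject",
    standardize: bool = True,
) -> LmeFit:
    """M1: ``outcome ~ predictor + (1 | group)``.

    The predictor is standardized (z-scored) before fitting by default, so
    the slope is in outcome units per predictor SD; the raw-scale slope is
    reported in ``extras['beta_raw']``.
    """
    y = data[outcome].to_numpy(dtype=float)
    x = data[predictor].to_numpy(dtype=float)
    sd = 1.0
    if standardize:
        x, _, sd = _standardize(x)
    elif np.std(x) == 0:
        raise ValueError("constant predictor")
    X = np.column_stack([np.ones_like(x), x])
    res = _fit_scalar(y, X, data[group].to_numpy())
    fit = _fit_to_lme(res, ["intercept", predictor])
    fit.extras["beta_raw"] = fit.params[predictor] / sd
    return fit


def fit_condition_interaction(
    data: pd.DataFrame,
    outcome: str = "rating",
    predictor: str = "z",
    condition_col: str = "condition",
    subject_col: str = "subject",
    conditions: list | None = None,
    standardize: bool = True,
) -> LmeFit:
    """M2: ``outcome ~ predictor * condition + (1 | subject:condition)``.

    Fixed effects: intercept, predictor, condition indicators and
    predictor x condition interactions, with the first condition as
    reference.  The interaction t statistics carry the condition contrasts.
    """
    if conditions is None:
        conditions = list(pd.unique(data[condition_col]))
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    for cond in conditions:
        n_subj = data.loc[data[condition_col] == cond, subject_col].nunique()
        if n_subj < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 subjects")
    y = data[outcome].to_numpy(dtype=float)
    x = data[predictor].to_numpy(dtype=float)
    if standardize:
        x, _, _ = _standardize(x)
    cols = [np.ones_like(x), x]
    names = ["intercept", predictor]
    cond_values = data[condition_col].to_numpy()
    for cond in conditions[1:]:
        d = (cond_values == cond).astype(float)
        cols.append(d)
        names.append(f"cond[{cond}]")
    for cond in conditions[1:]:
        d = (cond_values == cond).astype(float)
        cols.append(x * d)
        names.append(f"{predictor}:cond[{cond}]")
    X = np.column_stack(cols)
    cells = (
        data[subject_col].astype(str) + ":" + data[condition_col].astype(str)
    ).to_numpy()
    res = _fit_scalar(y, X, cells)
    return _fit_to_lme(res, names, {"conditions": list(conditions)})


def fit_structural_mediation(
    data: pd.DataFrame,
    outcome: str = "rating",
    predictor: str = "z",
    structural_col: str = "struc",
    group: str = "subject",
    standardize: bool = True,
) -> LmeFit:
    """M3: ``outcome ~ predictor : struc + (1 | group)``.

    The structural weight is constant within subject (log(1 + streamline
    count), standardized across subjects before the product); the single
    fixed effect beyond the intercept is the product term.
    """
    subj_w = data.groupby(group)[structural_col].first()
    if subj_w.nunique() < 2 or subj_w.std(ddof=0) == 0:
        raise ValueError("structural weights constant across subjects")
    w_std = (subj_w - subj_w.mean()) / subj_w.std(ddof=0)
    w_rows = data[group].map(w_std).to_numpy(dtype=float)
    x = data[predictor].to_numpy(dtype=float)
    if standardize:
        x, _, _ = _standardize(x)
    product = x * w_rows
    if np.std(product) == 0:
        raise ValueError("degenerate product term")
    y = data[outcome].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(product), product])
    res = _fit_scalar(y, X, data[group].to_numpy())
    return _fit_to_lme(res, ["intercept", f"{predictor}:struc"])


# ---------------------------------------------------------------------------
# mass (edge-wise) fitting
# ---------------------------------------------------------------------------


def structural_weights(
    structural: dict[str, np.ndarray],
    subjects: list[str],
    edge_index,
) -> np.ndarray:
    """Per-(subject, edge) structural weights from streamline-count matrices.

    Counts are mapped through ``log(1 + count)`` and standardized across
    subjects per edge.  Edges whose counts are identical across subjects get
    NaN weights (degenerate for the product model).
    """
    i, j = edge_index.pair_arrays()
    w = np.empty((len(subjects), edge_index.n_edges))
    for s, subject in enumerate(subjects):
        mat = np.asarray(structural[subject], dtype=float)
        w[s] = np.log1p(mat[i, j])
    sd = w.std(axis=0)
    mean = w.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (w - mean) / sd
    w[:, sd == 0] = np.nan
    return w


def select_condition_rows(
    trials: pd.DataFrame, condition: str, unmodulated: str
) -> np.ndarray:
    """Row mask for one condition's analysis: its trials plus unmodulated."""
    cond = trials["condition"].to_numpy()
    if not np.any(cond == condition):
        raise ValueError(f"condition {condition!r} not present")
    if not np.any(cond == unmodulated):
        raise ValueError(f"no unmodulated trials ({unmodulated!r}) present")
    return (cond == condition) | (cond == unmodulated)


@dataclass
class SlopeMassProblem:
    """Assembled edge-wise slope-model problem (M1 or M3).

    Holds the observed outcome, the per-edge predictors, and pre-built REML
    engines: one batched engine over all complete edges plus per-edge
    engines for edges with tolerable missingness.  Used identically by the
    observed mass fit and by every permutation refit, which keeps the two
    passes symmetric by construction.
    """

    model: str
    condition: str
    unmodulated: str
    rows: np.ndarray                   # trial-table row indices used
    y: np.ndarray                      # ratings for those rows
    subjects: np.ndarray               # subject label per row
    n_edges: int
    complete_idx: np.ndarray
    engine: MassSlopeEngine | None
    partial: list                      # (edge, local row indices, engine)
    col_sd: np.ndarray                 # per-edge z SD (raw scale)
    missing_frac: np.ndarray
    standardize: bool

    @property
    def fitted_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_edges, dtype=bool)
        mask[self.complete_idx] = True
        for e, _, _ in self.partial:
            mask[e] = True
        return mask

    def fit_outcomes(self, Y: np.ndarray) -> dict:
        """Fit every fitted edge against outcome column(s) Y (n rows)."""
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        P = Y.shape[1]
        out = {
            k: np.full((self.n_edges, P), np.nan)
            for k in ("beta", "se", "tstat")
        }
        if self.engine is not None:
            res = self.engine.fit(Y)
            for k in out:
                out[k][self.complete_idx] = res[k]
        for e, ok, eng in self.partial:
            res = eng.fit(Y[ok])
            for k in out:
                out[k][e] = res[k][0]
        return out


def prepare_slope_mass(
    tensor: EdgeTensor,
    model: str = "M1",
    condition: str | None = None,
    unmodulated: str | None = None,
    structural: dict[str, np.ndarray] | None = None,
    max_missing: float = 0.2,
    standardize: bool = True,
    refine_iter: int = REFINE_ITER,
) -> SlopeMassProblem:
    """Assemble the per-edge slope problem for M1 or M3."""
    if model not in ("M1", "M3"):
        raise ValueError(f"prepare_slope_mass handles M1/M3, not {model!r}")
    trials = tensor.trials
    if unmodulated is None:
        unmodulated = trials["condition"].iloc[0]
    if condition is None:
        raise ValueError("condition must be specified")
    mask = select_condition_rows(trials, condition, unmodulated)
    rows = np.flatnonzero(mask)
    sub = trials.iloc[rows]
    y = sub["rating"].to_numpy(dtype=float)
    subjects_rows = sub["subject"].to_numpy()
    Z = tensor.z[rows]
    n, E = Z.shape
    missing_frac = np.isnan(Z).mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_sd = np.nanstd(Z, axis=0)
    fit_mask = (missing_frac <= max_missing) & (col_sd > 0)

    W_rows = None
    if model == "M3":
        if structural is None:
            raise ValueError("model M3 requires structural matrices")
        subj_order = list(pd.unique(trials["subject"]))
        w_subj = structural_weights(structural, subj_order, tensor.edge_index)
        pos = {s: i for i, s in enumerate(subj_order)}
        subj_pos = np.array([pos[s] for s in subjects_rows])
        W_rows = w_subj[subj_pos]
        fit_mask &= np.isfinite(W_rows).all(axis=0)

    def predictor(cols: np.ndarray, row_sel: np.ndarray) -> np.ndarray:
        z = Z[np.ix_(row_sel, cols)]
        if standardize:
            z = (z - z.mean(axis=0)) / z.std(axis=0)
        if model == "M3":
            z = z * W_rows[np.ix_(row_sel, cols)]
        return z

    complete = np.flatnonzero(fit_mask & (missing_frac == 0))
    engine = None
    if complete.size:
        Xc = predictor(complete, np.arange(n))
        ok_var = Xc.std(axis=0) > 0
        complete = complete[ok_var]
        if complete.size:
            engine = MassSlopeEngine(
                Xc[:, ok_var], subjects_rows, refine_iter=refine_iter
            )
    partial = []
    for e in np.flatnonzero(fit_mask & (missing_frac > 0)):
        ok = np.flatnonzero(np.isfinite(Z[:, e]))
        x = predictor(np.array([e]), ok)
        if x.std() == 0:
            continue
        try:
            eng = MassSlopeEngine(x, subjects_rows[ok], refine_iter=refine_iter)
        except ValueError:
            continue
        partial.append((int(e), ok, eng))

    return SlopeMassProblem(
        model=model,
        condition=condition,
        unmodulated=unmodulated,
        rows=rows,
        y=y,
        subjects=subjects_rows,
        n_edges=E,
        complete_idx=complete,
        engine=engine,
        partial=partial,
        col_sd=col_sd,
        missing_frac=missing_frac,
        standardize=standardize,
    )


def mass_fit(
    tensor: EdgeTensor,
    model: str = "M1",
    condition: str | None = None,
    unmodulated: str | None = None,
    structural: dict[str, np.ndarray] | None = None,
    max_missing: float = 0.2,
    standardize: bool = True,
    refine_iter: int = REFINE_ITER,
) -> pd.DataFrame:
    """Fit the requested model for every edge; returns the EdgeStats table.

    Each condition's dataset is that condition's trials plus the unmodulated
    trials (for M2: all trials, with a binary target-vs-rest condition
    contrast and a random intercept per original subject:condition cell).
    Edges missing in more than ``max_missing`` of the rows are skipped (NaN
    statistics, ``skipped=True``); edges with fewer missing rows are fitted
    on their complete rows.

    Columns: region_a, region_b, model, condition, beta (slope per
    predictor SD), beta_raw, se, t, n_obs, missing_frac, skipped,
    attenuation_encoding (negative slope: higher connectivity in better
    attenuation trials).
    """
    trials = tensor.trials
    if unmodulated is None:
        unmodulated = trials["condition"].iloc[0]
    if condition is None:
        raise ValueError("condition must be specified")

    E = tensor.edge_index.n_edges
    out = tensor.edge_index.to_frame()
    out["model"] = model
    out["condition"] = condition
    beta = np.full(E, np.nan)
    beta_raw = np.full(E, np.nan)
    se = np.full(E, np.nan)
    t = np.full(E, np.nan)
    n_obs = np.zeros(E, dtype=int)

    if model == "M2":
        select_condition_rows(trials, condition, unmodulated)  # validation
        y = trials["rating"].to_numpy(dtype=float)
        Z = tensor.z
        missing_frac = np.isnan(Z).mean(axis=0)
        is_target = (trials["condition"] == condition).to_numpy().astype(float)
        cells = (
            trials["subject"].astype(str) + ":" + trials["condition"].astype(str)
        ).to_numpy()
        for e in range(E):
            col = Z[:, e]
            ok = np.isfinite(col)
            if 1.0 - ok.mean() > max_missing:
                continue
            x = col[ok]
            sd = np.std(x)
            if sd == 0:
                continue
            if standardize:
                x = (x - x.mean()) / sd
            d = is_target[ok]
            X = np.column_stack([np.ones_like(x), x, d, x * d])
            try:
                res = _fit_scalar(y[ok], X, cells[ok], refine_iter=refine_iter)
            except ValueError:
                continue
            beta[e] = res["beta"][3]
            se[e] = res["se"][3]
            t[e] = res["tstat"][3]
            beta_raw[e] = res["beta"][3] / (sd if standardize else 1.0)
            n_obs[e] = int(ok.sum())
    elif model in ("M1", "M3"):
        problem = prepare_slope_mass(
            tensor,
            model=model,
            condition=condition,
            unmodulated=unmodulated,
            structural=structural,
            max_missing=max_missing,
            standardize=standardize,
            refine_iter=refine_iter,
        )
        missing_frac = problem.missing_frac
        res = problem.fit_outcomes(problem.y)
        beta = res["beta"][:, 0]
        se = res["se"][:, 0]
        t = res["tstat"][:, 0]
        with np.errstate(invalid="ignore", divide="ignore"):
            beta_raw = beta / np.where(
                problem.col_sd > 0, problem.col_sd, np.nan
            ) if standardize else beta.copy()
        n_obs[problem.complete_idx] = len(problem.rows)
        for e, ok, _ in problem.partial:
            n_obs[e] = len(ok)
    else:
        raise ValueError(f"unknown model {model!r}")

    out["beta"] = beta
    out["beta_raw"] = beta_raw
    out["se"] = se
    out["t"] = t
    out["n_obs"] = n_obs
    out["missing_frac"] = missing_frac
    out["skipped"] = ~np.isfinite(t)
    out["attenuation_encoding"] = beta < 0
    out.attrs["model"] = model
    out.attrs["condition"] = condition
    out.attrs["unmodulated"] = unmodulated
    return out


def prefilter_for_mediation(stats: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """Edges whose M1 |t| exceeds ``threshold`` (default 2), for M3 fitting."""
    keep = stats["t"].abs() > threshold
    return stats.loc[keep.fillna(False)].copy()
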