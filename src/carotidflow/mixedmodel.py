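"""Random-intercept linear mixed model with Type-III F tests.

The model is ``y = X b + z_group + e`` with a single random intercept per
group, fitted by REML.  The variance ratio is profiled out, so each
evaluation of the criterion is a closed-form generalized least squares
solve (Woodbury identity per group).  Fixed-effect terms are tested with
Type-III Wald F statistics; denominator degrees of freedom use the
Satterthwaite approximation (numeric gradients of the contrast variance with
respect to the two variance components), with a containment-style fallback.

Factors are sum-to-zero (effects) coded, which makes the Type-III tests
match the conventional ANOVA decomposition in the presence of interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["TermTest", "MixedModelResult", "ConvergenceError", "fit_mixed_model"]

_LAMBDA_MAX = 1e6


class ConvergenceError(RuntimeError):
    """Raised when the REML fit is degenerate or fails to converge."""


@dataclass(frozen=True)
class TermTest:
    term: str
    f_stat: float
    df_num: float
    df_den: float
    p_value: float


@dataclass(frozen=True)
class MixedModelResult:
    terms: dict[str, TermTest]
    random_intercept_var: float
    residual_var: float
    coefficients: pd.Series
    n_obs: int
    n_groups: int
    df_method: str

    def anova_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": t.term,
                    "F": t.f_stat,
                    "df_num": t.df_num,
                    "df_den": t.df_den,
                    "p": t.p_value,
                }
                for t in self.terms.values()
            ]
        )


def _effects_columns(values: pd.Series, levels: list[str], name: str):
    """Sum-to-zero coding: one column per non-reference level."""
    k = len(levels)
    idx = values.map({lev: i for i, lev in enumerate(levels)})
    if idx.isna().any():
        raise ValueError(f"factor {name} contains unmapped levels")
    idx = idx.to_numpy()
    cols = np.zeros((len(values), k - 1))
    for j in range(k - 1):
        cols[idx == j, j] = 1.0
    cols[idx == k - 1, :] = -1.0
    names = [f"{name}[{levels[j]}]" for j in range(k - 1)]
    return cols, names


def _build_design(
    data: pd.DataFrame,
    factors: tuple[str, ...],
    interactions: tuple[tuple[str, str], ...],
):
    """Design matrix with intercept, effects-coded main terms, interactions."""
    levels = {}
    for f in factors:
        levs = sorted(data[f].astype(str).unique())
        if len(levs) < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels, found {levs}")
        levels[f] = levs

    blocks = {"Intercept": (np.ones((len(data), 1)), ["Intercept"])}
    for f in factors:
        blocks[f] = _effects_columns(data[f].astype(str), levels[f], f)
    for a, b in interactions:
        xa, na = blocks[a]
        xb, nb = blocks[b]
        cols = np.einsum("ij,ik->ijk", xa, xb).reshape(len(data), -1)
        names = [f"{i}:{j}" for i in na for j in nb]
        blocks[f"{a}:{b}"] = (cols, names)

    term_slices = {}
    mats, names = [], []
    start = 0
    for term, (cols, colnames) in blocks.items():
        mats.append(cols)
        names.extend(colnames)
        term_slices[term] = slice(start, start + cols.shape[1])
        start += cols.shape[1]
    return np.hstack(mats), names, term_slices


class _RandomInterceptREML:
    """Profiled REML machinery over the variance ratio lambda = s2_b / s2_e."""

    def __init__(self, x: np.ndarray, y: np.ndarray, group_idx: np.ndarray):
        self.n, self.p = x.shape
        self.groups = []
        for g in np.unique(group_idx):
            mask = group_idx == g
            xi, yi = x[mask], y[mask]
            self.groups.append(
                {
                    "n": int(mask.sum()),
                    "xtx": xi.T @ xi,
                    "xty": xi.T @ yi,
                    "yty": float(yi @ yi),
                    "sx": xi.sum(axis=0),
                    "sy": float(yi.sum()),
                }
            )
        self.m = len(self.groups)

    def _gls(self, lam: float):
        """Return (xtwx, xtwy, ywy) for W_i = (I + lam J)^-1."""
        p = self.p
        xtwx = np.zeros((p, p))
        xtwy = np.zeros(p)
        ywy = 0.0
        for g in self.groups:
            c = lam / (1.0 + lam * g["n"])
            xtwx += g["xtx"] - c * np.outer(g["sx"], g["sx"])
            xtwy += g["xty"] - c * g["sx"] * g["sy"]
            ywy += g["yty"] - c * g["sy"] ** 2
        return xtwx, xtwy, ywy

    def profile_criterion(self, lam: float) -> float:
        xtwx, xtwy, ywy = self._gls(lam)
        sign, logdet = np.linalg.slogdet(xtwx)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(xtwx, xtwy)
        rss = ywy - beta @ xtwy
        if rss <= 0:
            return np.inf
        s2e = rss / (self.n - self.p)
        crit = (self.n - self.p) * np.log(s2e) + logdet
        crit += sum(np.log1p(lam * g["n"]) for g in self.groups)
        return crit

    def fit(self):
        obj = lambda u: self.profile_criterion(np.exp(u))
        res = optimize.minimize_scalar(
            obj, bounds=(np.log(1e-10), np.log(_LAMBDA_MAX)), method="bounded",
            options={"xatol": 1e-10},
        )
        if not res.success:
            raise ConvergenceError("REML profile optimization failed")
        lam = float(np.exp(res.x))
        if self.profile_criterion(0.0) < res.fun:
            lam = 0.0
        xtwx, xtwy, ywy = self._gls(lam)
        if np.linalg.cond(xtwx) > 1e10:
            raise ConvergenceError("fixed-effects design is singular or near-singular")
        beta = np.linalg.solve(xtwx, xtwy)
        rss = ywy - beta @ xtwy
        s2e = rss / (self.n - self.p)
        return lam, beta, s2e

    # -- quantities as functions of theta = (s2_b, s2_e), for Satterthwaite --

    def beta_cov(self, theta: np.ndarray) -> np.ndarray:
        s2b, s2e = theta
        xtwx, _, _ = self._gls(s2b / s2e)
        return s2e * np.linalg.inv(xtwx)

    def minus2_reml(self, theta: np.ndarray) -> float:
        s2b, s2e = theta
        if s2e <= 0 or s2b < 0:
            return np.inf
        lam = s2b / s2e
        xtwx, xtwy, ywy = self._gls(lam)
        sign, logdet = np.linalg.slogdet(xtwx / s2e)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(xtwx, xtwy)
        rss = ywy - beta @ xtwy
        out = rss / s2e + logdet
        for g in self.groups:
            out += (g["n"] - 1) * np.log(s2e) + np.log(s2e + g["n"] * s2b)
        return out

    def theta_cov(self, theta: np.ndarray) -> np.ndarray:
        """Asymptotic covariance of the REML variance estimates."""
        h = np.zeros((2, 2))
        steps = np.maximum(1e-4 * theta, 1e-12)
        for i in range(2):
            for j in range(i + 1):
                ei = np.eye(2)[i] * steps[i]
                ej = np.eye(2)[j] * steps[j]
                fpp = self.minus2_reml(theta + ei + ej)
                fpm = self.minus2_reml(theta + ei - ej)
                fmp = self.minus2_reml(theta - ei + ej)
                fmm = self.minus2_reml(theta - ei - ej)
                h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
        try:
            return 2.0 * np.linalg.inv(h)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("variance-component information is singular") from exc


def _satterthwaite_df(
    engine: _RandomInterceptREML, theta: np.ndarray, a_cov: np.ndarray, ell: np.ndarray
) -> float:
    """Denominator df for a single contrast via the Satterthwaite recipe."""
    steps = np.maximum(1e-4 * theta, 1e-12)
    grad = np.zeros(2)
    for i in range(2):
        e = np.eye(2)[i] * steps[i]
        gp = ell @ engine.beta_cov(theta + e) @ ell
        gm = ell @ engine.beta_cov(theta - e) @ ell
        grad[i] = (gp - gm) / (2 * steps[i])
    g_hat = float(ell @ engine.beta_cov(theta) @ ell)
    denom = float(grad @ a_cov @ grad)
    if denom <= 0:
        return np.inf
    return 2.0 * g_hat**2 / denom


def fit_mixed_model(
    data: pd.DataFrame,
    response: str = "ess_mean_dyn_cm2",
    group: str = "participant_id",
    factors: tuple[str, ...] = ("modality", "intensity", "sex"),
    interactions: tuple[tuple[str, str], ...] = (("modality", "intensity"),),
    df_method: str = "satterthwaite",
) -> MixedModelResult:
    """REML fit of ``response ~ factors + interactions + (1 | group)``.

    Returns Type-III F tests per fixed-effect term (excluding the intercept)
    plus the two variance components.  ``df_method`` is ``"satterthwaite"``
    (default) or ``"containment"``.
    """
    if df_method not in ("satterthwaite", "containment"):
        raise ValueError(f"unknown df_method {df_method!r}")
    data = data.reset_index(drop=True)
    if data[response].isna().any():
        raise ValueError("response contains missing values")
    group_codes, _ = pd.factorize(data[group])
    if len(np.unique(group_codes)) < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    counts = np.bincount(group_codes)
    if counts.min() < 2:
        raise ValueError("every group must contribute at least 2 observations")

    x, names, term_slices = _build_design(data, factors, interactions)
    y = data[response].to_numpy(dtype=float)
    engine = _RandomInterceptREML(x, y, group_codes)
    if engine.p >= engine.n:
        raise ConvergenceError("more fixed-effect parameters than observations")
    lam, beta, s2e = engine.fit()
    s2b = lam * s2e
    theta = np.array([s2b, s2e])

    cov = engine.beta_cov(theta)
    # at the boundary (vanishing intercept variance) the variance-component
    # Hessian is not interior; fall back to containment df there
    use_satterthwaite = df_method == "satterthwaite" and s2b > 1e-8 * s2e
    a_cov = engine.theta_cov(theta) if use_satterthwaite else None

    terms: dict[str, TermTest] = {}
    for term, sl in term_slices.items():
        if term == "Intercept":
            continue
        q = sl.stop - sl.start
        lmat = np.zeros((q, engine.p))
        lmat[np.arange(q), np.arange(sl.start, sl.stop)] = 1.0
        est = lmat @ beta
        vmat = lmat @ cov @ lmat.T
        f_stat = float(est @ np.linalg.solve(vmat, est) / q)
        if use_satterthwaite:
            # per-eigenvector 1-df contrasts, then the multi-df combination
            evals, evecs = np.linalg.eigh(vmat)
            nus = []
            for j in range(q):
                ell = lmat.T @ evecs[:, j]
                nus.append(_satterthwaite_df(engine, theta, a_cov, ell))
            finite = [nu for nu in nus if nu > 2 and np.isfinite(nu)]
            e_sum = sum(nu / (nu - 2.0) for nu in finite)
            if len(finite) == q and e_sum > q:
                df_den = 2.0 * e_sum / (e_sum - q)
            else:
                df_den = _containment_df(x, lmat, group_codes, engine)
        else:
            df_den = _containment_df(x, lmat, group_codes, engine)
        p_value = float(stats.f.sf(f_stat, q, df_den)) if df_den > 0 else np.nan
        terms[term] = TermTest(term, f_stat, float(q), float(df_den), p_value)

    return MixedModelResult(
        terms=terms,
        random_intercept_var=float(s2b),
        residual_var=float(s2e),
        coefficients=pd.Series(beta, index=names),
        n_obs=engine.n,
        n_groups=engine.m,
        df_method=df_method,
    )


def _containment_df(x, lmat, group_codes, engine) -> float:
    """Containment-style denominator df.

    Terms constant within groups are tested against between-group df; terms
    varying within groups against the within-group residual df.
    """
    cols = np.abs(lmat).sum(axis=0) > 0
    xt = x[:, cols]
    between = all(
        np.allclose(xt[group_codes == g], xt[group_codes == g][0])
        for g in np.unique(group_codes)
    )
    n_between = 1  # intercept
    for j in range(x.shape[1]):
        col_between = all(
            np.allclose(x[group_codes == g, j], x[group_codes == g][0, j])
            for g in np.unique(group_codes)
        )
        if j > 0 and col_between:
            n_between += 1
    if between:
        return float(engine.m - n_between)
    return float(engine.n - engine.p - (engine.m - 1))
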