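"""Mixed-model analysis of recombination-rate residuals.

The model is

    Y = alpha + T1 + T2 + A + A^2 + B + B^2 + g + eps,
    g ~ N(0, sigma_g^2 G),   eps ~ N(0, sigma_e^2 I),

with Y the residual-adjusted genome-wide crossover count of one maternal
meiosis, T1/T2 three-level temperature categories during fetal development of
the offspring and of the dam, A maternal age in months, B the dam's calendar
birth year, and G a genomic relationship matrix over the dams.  Multiple
meioses of one dam share her genetic effect through an incidence mapping.

Estimation is exact REML.  Writing V = sigma_e^2 (I + gamma * Z G Z') with
gamma = sigma_g^2 / sigma_e^2, a single eigendecomposition of the (dams x
dams) matrix L' Z' Z L (G = L L') turns every restricted-likelihood
evaluation into O(n) work, and sigma_e^2 profiles out analytically; the
remaining one-dimensional criterion in h^2 = gamma / (1 + gamma) is minimized
on [0, 1) by bounded scalar search, which cannot miss the optimum of a
two-component model the way gradient-based updates can.  Fixed effects are
GLS at the REML variance estimates with Wald z-tests; SE(h^2) comes from the
delta method on the numerically evaluated information of (sigma_g^2,
sigma_e^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import make_smoothing_spline

from .grm import GRM

__all__ = [
    "RecombinationMixedModel", "MixedModelResults", "VarianceComponents",
    "build_design", "estimate_heritability", "fit_age_spline",
    "group_summary", "temp_group_summary", "SplineFit",
]

_LOG2PI = np.log(2.0 * np.pi)

TEMP_LEVELS = ("cold", "hot")  # "normal" is the reference level


def build_design(table: pd.DataFrame, include_temperature: bool = True,
                 center: bool = False) -> pd.DataFrame:
    """Fixed-effect design for the full model (intercept, T1/T2 dummies, A, A2, B, B2).

    Temperature dummies are relative to the "normal" level.  ``center``
    subtracts the mean of A and B before forming the quadratics (a
    conditioning option; coefficients then refer to centered scales).
    """
    X = pd.DataFrame(index=table.index)
    X["Intercept"] = 1.0
    if include_temperature:
        for col in ("T1", "T2"):
            present = set(table[col].dropna().unique())
            for lev in TEMP_LEVELS:
                if lev not in present:
                    warnings.warn(f"temperature level {lev!r} absent from {col}; "
                                  "column omitted from the design")
                    continue
                X[f"{col}[{lev}]"] = (table[col] == lev).astype(float)
    a = table["A"].to_numpy(dtype=float)
    b = table["B"].to_numpy(dtype=float)
    if center:
        a = a - a.mean()
        b = b - b.mean()
    X["age"] = a
    X["age_sq"] = a ** 2
    X["birth_year"] = b
    X["birth_year_sq"] = b ** 2
    return X


@dataclass
class VarianceComponents:
    """REML variance components of the adjusted phenotype and their covariance."""

    sigma_g2: float
    sigma_e2: float
    cov: np.ndarray  # 2x2 asymptotic covariance of (sigma_g2, sigma_e2)

    @property
    def h2(self) -> float:
        return estimate_heritability(self.sigma_g2, self.sigma_e2)[0]


def estimate_heritability(sigma_g2: float, sigma_e2: float,
                          cov: np.ndarray | None = None) -> tuple[float, float]:
    """h2 = sigma_g2/(sigma_g2+sigma_e2) with a delta-method standard error."""
    total = sigma_g2 + sigma_e2
    if total <= 0:
        raise ValueError("both variance components are zero; h2 undefined")
    h2 = sigma_g2 / total
    if cov is None:
        return h2, float("nan")
    grad = np.array([sigma_e2, -sigma_g2]) / total ** 2
    var = float(grad @ np.asarray(cov) @ grad)
    return h2, np.sqrt(max(var, 0.0))


class RecombinationMixedModel:
    """GRM mixed model for adjusted crossover counts (statsmodels-style).

    Parameters
    ----------
    endog : response vector (adjusted counts Y), length n meioses.
    exog : fixed-effect design matrix (n x p) or DataFrame.
    grm : :class:`~pedrec.grm.GRM` over the dams.
    groups : dam id per meiosis; maps rows onto GRM entries.
    """

    def __init__(self, endog, exog, grm: GRM, groups, exog_names=None):
        y = np.asarray(endog, dtype=float)
        if isinstance(exog, pd.DataFrame):
            exog_names = list(exog.columns)
            X = exog.to_numpy(dtype=float)
        else:
            X = np.asarray(exog, dtype=float)
            if exog_names is None:
                exog_names = [f"x{j}" for j in range(X.shape[1])]
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("exog must be (n, p) matching endog")
        n, p = X.shape
        if n < p + 2:
            raise ValueError("too few rows to fit the model")
        # rank check, naming the aliased column
        q, r = np.linalg.qr(X / np.maximum(np.sqrt((X ** 2).mean(axis=0)), 1e-300))
        diag = np.abs(np.diag(r))
        if np.any(diag < 1e-8 * diag.max()):
            j = int(np.argmin(diag / diag.max()))
            raise ValueError(f"fixed-effect design is rank deficient; column "
                             f"{exog_names[j]!r} is aliased")

        groups = list(groups)
        gindex = {a: i for i, a in enumerate(grm.ids)}
        missing = [a for a in set(groups) if a not in gindex]
        if missing:
            raise ValueError(f"GRM does not cover parents: {sorted(missing)[:5]}")
        gidx = np.array([gindex[a] for a in groups])

        self.endog, self.exog, self.exog_names = y, X, exog_names
        self.grm, self.groups = grm, groups
        self.nobs, self.k_fixed = n, p

        # column equilibration: uncentered age/year quadratics make X badly
        # scaled, so solve in the scaled basis and transform back
        self._scale = np.sqrt((X ** 2).mean(axis=0))
        self._scale[self._scale == 0] = 1.0
        Xs = X / self._scale

        # one-time reduction: G = L L', W = L[group rows], eigen of W'W
        gv, gq = np.linalg.eigh(grm.matrix)
        gv = np.clip(gv, 0.0, None)
        L = gq * np.sqrt(gv)
        W = L[gidx]
        d, Q = np.linalg.eigh(W.T @ W)
        keep = d > max(d.max(), 1.0) * 1e-12
        self._d = d[keep]
        U1 = W @ (Q[:, keep] / np.sqrt(self._d))
        self._y1 = U1.T @ y
        self._X1 = U1.T @ Xs
        self._yy = float(y @ y)
        self._Xy = Xs.T @ y
        self._XX = Xs.T @ Xs
        self._logscale = float(np.sum(np.log(self._scale)))

    # -- restricted likelihood ------------------------------------------------

    def _parts(self, gamma: float):
        """Sufficient pieces at variance ratio gamma = sigma_g2/sigma_e2."""
        w = gamma * self._d / (1.0 + gamma * self._d)
        XVX = self._XX - (self._X1.T * w) @ self._X1
        XVy = self._Xy - self._X1.T @ (w * self._y1)
        yVy = self._yy - float(self._y1 @ (w * self._y1))
        beta_s = np.linalg.solve(XVX, XVy)
        quad = yVy - float(XVy @ beta_s)
        logdetV = float(np.sum(np.log1p(gamma * self._d)))
        sign, logdetXVX = np.linalg.slogdet(XVX)
        logdetXVX -= 2.0 * self._logscale  # undo column scaling
        return beta_s, XVX, quad, logdetV, logdetXVX

    def reml_loglike(self, sigma_g2: float, sigma_e2: float) -> float:
        """Exact restricted log-likelihood at the given variance components."""
        if sigma_e2 <= 0 or sigma_g2 < 0:
            return -np.inf
        gamma = sigma_g2 / sigma_e2
        _, _, quad, logdetV, logdetXVX = self._parts(gamma)
        n, p = self.nobs, self.k_fixed
        neg2 = ((n - p) * (_LOG2PI + np.log(sigma_e2)) + logdetV + logdetXVX
                + quad / sigma_e2)
        return -0.5 * neg2

    def _profile_neg2(self, h2: float) -> float:
        gamma = h2 / (1.0 - h2)
        _, _, quad, logdetV, logdetXVX = self._parts(gamma)
        n, p = self.nobs, self.k_fixed
        s2 = quad / (n - p)
        return (n - p) * (_LOG2PI + np.log(s2) + 1.0) + logdetV + logdetXVX

    # -- fitting ---------------------------------------------------------------

    def fit(self, h2_bounds: tuple[float, float] = (0.0, 1.0 - 1e-6)) -> "MixedModelResults":
        lo = max(h2_bounds[0], 0.0)
        hi = min(h2_bounds[1], 1.0 - 1e-9)
        res = optimize.minimize_scalar(self._profile_neg2, bounds=(max(lo, 1e-10), hi),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        h2_hat, crit = float(res.x), float(res.fun)
        converged = bool(res.success)
        # the boundary sigma_g2 = 0 is a legal REML solution
        crit0 = self._profile_neg2(0.0)
        boundary = crit0 <= crit + 1e-9
        if boundary:
            h2_hat, crit = 0.0, crit0

        n, p = self.nobs, self.k_fixed
        gamma = h2_hat / (1.0 - h2_hat)
        beta_s, XVX, quad, _, _ = self._parts(gamma)
        sigma_e2 = quad / (n - p)
        sigma_g2 = gamma * sigma_e2
        params = beta_s / self._scale
        cov_beta = sigma_e2 * np.linalg.inv(XVX)
        cov_beta = cov_beta / np.outer(self._scale, self._scale)
        bse = np.sqrt(np.diag(cov_beta))
        z = params / bse
        pvalues = 2.0 * stats.norm.sf(np.abs(z))
        llf = self.reml_loglike(sigma_g2, sigma_e2)

        cov_vc = self._vc_covariance(sigma_g2, sigma_e2, boundary)
        vc = VarianceComponents(sigma_g2=float(sigma_g2), sigma_e2=float(sigma_e2),
                                cov=cov_vc)
        return MixedModelResults(model=self, params=params, bse=bse,
                                 pvalues=pvalues, cov_params=cov_beta,
                                 vc=vc, llf=float(llf), converged=converged,
                                 at_boundary=boundary)

    def _vc_covariance(self, sigma_g2: float, sigma_e2: float,
                       boundary: bool) -> np.ndarray:
        """Asymptotic covariance of the variance components via the observed
        information (central finite differences of the restricted likelihood)."""
        theta = np.array([sigma_g2, sigma_e2])
        # steps must stay well above the round-off floor of the likelihood:
        # the criterion is O(n * 100), so differences below ~1e-10 are noise
        step = np.maximum(1e-2 * np.maximum(theta, sigma_e2), 1e-6)
        if boundary:
            # one-sided in sigma_g2 to stay in the parameter space
            theta = theta + np.array([2 * step[0], 0.0])
        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(i, 2):
                ei = np.eye(2)[i] * step[i]
                ej = np.eye(2)[j] * step[j]
                f = self.reml_loglike
                H[i, j] = H[j, i] = (
                    f(*(theta + ei + ej)) - f(*(theta + ei - ej))
                    - f(*(theta - ei + ej)) + f(*(theta - ei - ej))
                ) / (4 * step[i] * step[j])
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            cov = np.full((2, 2), np.nan)
        if not np.all(np.isfinite(cov)) or cov[0, 0] < 0 or cov[1, 1] < 0:
            cov = np.linalg.pinv(-H) if np.all(np.isfinite(H)) else np.full((2, 2), np.nan)
        return cov

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, grm: GRM,
                       response: str = "Y", group_col: str = "parent_id",
                       include_temperature: bool = True,
                       center: bool = False) -> "RecombinationMixedModel":
        """Build the full model from an analysis-ready table."""
        X = build_design(table, include_temperature=include_temperature, center=center)
        return cls(table[response], X, grm, table[group_col])


@dataclass
class MixedModelResults:
    """REML fit: fixed effects, variance components, heritability."""

    model: RecombinationMixedModel
    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    cov_params: np.ndarray
    vc: VarianceComponents
    llf: float
    converged: bool
    at_boundary: bool

    @property
    def exog_names(self) -> list[str]:
        return self.model.exog_names

    @property
    def sigma_g2(self) -> float:
        return self.vc.sigma_g2

    @property
    def sigma_e2(self) -> float:
        return self.vc.sigma_e2

    @property
    def h2(self) -> float:
        return estimate_heritability(self.sigma_g2, self.sigma_e2)[0]

    @property
    def h2_se(self) -> float:
        return estimate_heritability(self.sigma_g2, self.sigma_e2, self.vc.cov)[1]

    def fixed_effects(self) -> pd.DataFrame:
        return pd.DataFrame({"beta": self.params, "se": self.bse,
                             "p_value": self.pvalues}, index=self.exog_names)

    def summary(self) -> str:
        lines = ["Recombination-rate mixed model (REML)",
                 f"  n meioses: {self.model.nobs}   n parents: {len(set(self.model.groups))}",
                 f"  restricted log-likelihood: {self.llf:.3f}"
                 + ("" if self.converged else "   [NOT CONVERGED]"),
                 f"  sigma_g^2 = {self.sigma_g2:.4f}   sigma_e^2 = {self.sigma_e2:.4f}",
                 f"  h^2 = {self.h2:.3f} (SE {self.h2_se:.3f})"
                 + ("  [boundary]" if self.at_boundary else ""),
                 "", f"  {'factor':<18}{'beta':>12}{'SE':>11}{'P-value':>12}"]
        for name, b, s, p in zip(self.exog_names, self.params, self.bse, self.pvalues):
            lines.append(f"  {name:<18}{b:>12.4g}{s:>11.3g}{p:>12.3g}")
        return "\n".join(lines)

    def age_spline(self, table: pd.DataFrame, response: str = "Y") -> "SplineFit":
        """Smoothing-spline trend of the response against maternal age."""
        return fit_age_spline(table["A"], table[response])


# ---------------------------------------------------------------------------
# descriptive summaries (Figure-style outputs)
# ---------------------------------------------------------------------------

@dataclass
class SplineFit:
    """Cubic smoothing spline of Y on age, with the age minimizing the curve."""

    grid: np.ndarray
    fitted: np.ndarray
    argmin_age: float
    spline: object

    def __call__(self, x):
        return self.spline(x)


def fit_age_spline(ages, y, n_grid: int = 201) -> SplineFit:
    """Cubic smoothing spline (GCV-chosen penalty) of Y against age.

    Replicate ages are averaged and weighted by their counts before the
    spline is fitted, which leaves the penalized criterion unchanged.
    """
    a = np.asarray(ages, dtype=float)
    yv = np.asarray(y, dtype=float)
    ua, inv, counts = np.unique(a, return_inverse=True, return_counts=True)
    if ua.size < 10:
        raise ValueError("need >= 10 distinct ages to fit the age spline")
    ym = np.bincount(inv, weights=yv) / counts
    spl = make_smoothing_spline(ua, ym, w=counts.astype(float), lam=None)
    grid = np.linspace(ua.min(), ua.max(), n_grid)
    fitted = spl(grid)
    return SplineFit(grid=grid, fitted=fitted,
                     argmin_age=float(grid[np.argmin(fitted)]), spline=spl)


def group_summary(y, groups) -> pd.DataFrame:
    """Per-group n, mean, and standard error (sd/sqrt(n))."""
    df = pd.DataFrame({"y": np.asarray(y, dtype=float), "group": groups})
    df = df[pd.notna(df["group"])]
    out = df.groupby("group")["y"].agg(n="count", mean="mean",
                                       sd=lambda s: s.std(ddof=1))
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd").reset_index()


def temp_group_summary(y, categories,
                       levels: tuple[str, ...] = ("cold", "normal", "hot")) -> pd.DataFrame:
    """Boxplot statistics of Y per temperature category.

    Whiskers follow the 1.5 x IQR rule (most extreme points inside the
    fences).  Absent categories are omitted with a warning.
    """
    yv = np.asarray(y, dtype=float)
    cats = np.asarray(categories, dtype=object)
    rows = []
    for lev in levels:
        vals = yv[cats == lev]
        if vals.size == 0:
            warnings.warn(f"temperature category {lev!r} has no records; omitted")
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        rows.append(dict(category=lev, n=int(vals.size), mean=float(vals.mean()),
                         median=float(med), q1=float(q1), q3=float(q3),
                         whisker_lo=float(inside.min()), whisker_hi=float(inside.max())))
    return pd.DataFrame(rows)
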