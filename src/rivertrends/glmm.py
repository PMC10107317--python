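"""Hierarchical overdispersed Poisson trend models.

The abundance model for per-sample aggregate counts y_i is

    y_i ~ Poisson(lambda_i),
    log lambda_i = x_i' beta + u0_s(i) + u1_s(i) * t_i + v_t(i) + e_i,

with correlated site random intercepts/slopes (u0, u1), year random
intercepts v_t absorbing good/bad years, and an observation-level random
intercept e_i (OLRE) absorbing extra-Poisson dispersion.  The fixed part
is either year alone (national model) or year x river-typology
(interaction model), with year coded as an integer t = calendar year -
2002.

Estimation maximizes the Laplace approximation to the marginal likelihood.
The inner step jointly optimizes (beta, u) by Newton iterations on the
penalized Poisson log-likelihood; the linear algebra exploits the model's
structure exactly — the OLRE block is diagonal, site blocks are 2x2, and
only a dense (years + fixed effects) core remains — so each iteration is
linear in the number of observations.  The outer step optimizes the
variance parameters (log SDs, atanh-scaled correlation) by quasi-Newton
search with finite-difference gradients.  Everything is deterministic
given the data and options.

Derived quantities: population-level yearly predictions (random effects at
zero), total percentage change Psi = (y_last - y_first)/y_first * 100, and
annual growth rate AGR = Psi / divisor (divisor 18 by convention of the
reference analysis; see docs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special, stats

from .errors import DesignError, FitError, UsageError

YEAR0_DEFAULT = 2002

# ---------------------------------------------------------------------------
# Model data / design construction
# ---------------------------------------------------------------------------


@dataclass
class ModelData:
    """Response vector, fixed-effect design and random-effect indices."""

    y: np.ndarray
    X: np.ndarray
    fixed_names: list[str]
    site_idx: np.ndarray
    n_sites: int
    site_ids: list
    year_idx: np.ndarray
    n_years: int
    years: np.ndarray
    t: np.ndarray
    offset: np.ndarray
    reference_class: str | None = None
    typology_classes: list[str] = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return len(self.y)


def build_design(
    agg: pd.DataFrame,
    *,
    typology_map: pd.Series | dict | None = None,
    interaction: bool = False,
    year0: int = YEAR0_DEFAULT,
) -> ModelData:
    """Build model matrices from per-sample aggregate totals of one unit.

    ``agg`` needs columns site_id, year, count.  With ``interaction`` the
    fixed part gains reference-coded typology main effects and year x
    typology interactions; ``typology_map`` (site_id -> class) must then
    cover every site, and unclassified sites raise :class:`DesignError`
    listing the offenders.  The reference class is the alphabetically first
    class present.
    """
    required = {"site_id", "year", "count"}
    missing = required - set(agg.columns)
    if missing:
        raise DesignError(f"aggregate table missing columns: {sorted(missing)}")
    if agg.empty:
        raise DesignError("aggregate table is empty")

    y = agg["count"].to_numpy(dtype=float)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise DesignError("counts must be non-negative integers")

    years_col = agg["year"].to_numpy(dtype=int)
    t = (years_col - year0).astype(float)
    if t.min() < 0:
        raise DesignError(f"years before {year0} present in data")

    site_ids, site_idx = np.unique(agg["site_id"].to_numpy(), return_inverse=True)
    years, year_idx = np.unique(years_col, return_inverse=True)

    cols = [np.ones(len(agg)), t]
    names = ["(Intercept)", "year"]
    reference = None
    classes: list[str] = []
    if interaction:
        if typology_map is None:
            raise DesignError("interaction model requires a typology map")
        tmap = (
            typology_map
            if isinstance(typology_map, dict)
            else typology_map.to_dict()
        )
        site_class = []
        offenders = []
        for sid in agg["site_id"]:
            cls = tmap.get(sid)
            if cls is None or cls == "excluded":
                offenders.append(sid)
                site_class.append(None)
            else:
                site_class.append(cls)
        if offenders:
            raise DesignError(
                f"unclassified sites present: {sorted(set(offenders))[:10]}"
            )
        classes = sorted(set(site_class))
        reference = classes[0]
        cls_arr = np.asarray(site_class)
        for cls in classes[1:]:
            dummy = (cls_arr == cls).astype(float)
            cols.append(dummy)
            names.append(f"typology[{cls}]")
        for cls in classes[1:]:
            dummy = (cls_arr == cls).astype(float)
            cols.append(dummy * t)
            names.append(f"year:typology[{cls}]")

    X = np.column_stack(cols)
    return ModelData(
        y=y,
        X=X,
        fixed_names=names,
        site_idx=site_idx,
        n_sites=len(site_ids),
        site_ids=list(site_ids),
        year_idx=year_idx,
        n_years=len(years),
        years=years,
        t=t,
        offset=np.zeros(len(agg)),
        reference_class=reference,
        typology_classes=classes,
    )


# ---------------------------------------------------------------------------
# Random-effect structure and variance components
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RandomStructure:
    """Which random terms enter the model (toggles exist for testing)."""

    site_intercept: bool = True
    site_slope: bool = True
    site_correlation: bool = True
    year: bool = True
    olre: bool = True

    def __post_init__(self):
        if self.site_slope and not self.site_intercept:
            raise UsageError("site_slope requires site_intercept")


@dataclass
class VarianceComponents:
    """Random-effect SDs (and site intercept-slope correlation)."""

    sd_site_intercept: float = 0.0
    sd_site_slope: float = 0.0
    corr_site: float = 0.0
    sd_year: float = 0.0
    sd_olre: float = 0.0

    def as_dict(self) -> dict:
        return {
            "sd_site_intercept": self.sd_site_intercept,
            "sd_site_slope": self.sd_site_slope,
            "corr_site": self.corr_site,
            "sd_year": self.sd_year,
            "sd_olre": self.sd_olre,
        }


@dataclass
class FitOptions:
    """Optimizer controls.  The fit is deterministic; ``optimizer_seed`` is
    accepted for interface compatibility and ignored."""

    max_iter: int = 500
    tol: float = 1e-4
    optimizer_seed: int | None = None


@dataclass
class FitResult:
    """Estimated fixed effects, variance components and fit diagnostics."""

    beta: pd.Series
    se: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    vc: VarianceComponents
    loglik: float
    n_obs: int
    n_params: int
    aic: float
    bic: float
    converged: bool
    grad_norm: float
    n_outer_evals: int
    cov_beta: np.ndarray
    structure: RandomStructure
    reference_class: str | None = None
    typology_classes: list[str] = field(default_factory=list)
    year0: int = YEAR0_DEFAULT
    years: np.ndarray | None = None

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.beta,
                "se": self.se,
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )


# ---------------------------------------------------------------------------
# Laplace machinery
# ---------------------------------------------------------------------------

_LOG2PI = np.log(2.0 * np.pi)


class _LaplaceModel:
    """Laplace-approximated marginal likelihood with structured elimination.

    Joint Newton over (beta, site effects, year effects, OLRE) eliminates,
    in order, the diagonal OLRE block, the 2x2 site blocks, and finally a
    dense core of size (n_years + n_fixed).
    """

    def __init__(
        self,
        data: ModelData,
        structure: RandomStructure,
        *,
        beta_fixed: np.ndarray | None = None,
    ):
        self.data = data
        self.structure = structure
        self.y = data.y
        self.n = data.n_obs
        self.s = data.site_idx
        self.yi = data.year_idx
        self.t = data.t
        self.S = data.n_sites if structure.site_intercept else 0
        self.Y = data.n_years if structure.year else 0
        self.ds = (2 if structure.site_slope else 1) if structure.site_intercept else 0
        self.has_olre = structure.olre
        self.offset = data.offset.copy()
        if beta_fixed is not None:
            self.offset = self.offset + data.X @ np.asarray(beta_fixed, float)
            self.X = np.zeros((self.n, 0))
        else:
            self.X = data.X
        self.p = self.X.shape[1]
        self.K = self.Y + self.p
        self.loggamma_y = special.gammaln(self.y + 1.0).sum()
        # Warm-start state
        self.beta = np.zeros(self.p)
        if self.p:
            self.beta[0] = np.log(self.y.mean() + 0.5)
        self.a = np.zeros((self.S, max(self.ds, 1)))
        self.v = np.zeros(self.Y)
        self.e = np.zeros(self.n)

        names = []
        if self.S:
            names.append("log_sd_site_intercept")
            if self.ds == 2:
                names.append("log_sd_site_slope")
                if structure.site_correlation:
                    names.append("z_corr_site")
        if self.Y:
            names.append("log_sd_year")
        if self.has_olre:
            names.append("log_sd_olre")
        self.theta_names = names

    # -- variance-parameter transforms ------------------------------------

    def theta0(self) -> np.ndarray:
        return np.array(
            [0.0 if n == "z_corr_site" else np.log(0.5) for n in self.theta_names]
        )

    def bounds(self):
        return [
            (-4.0, 4.0) if n == "z_corr_site" else (-8.0, 3.0)
            for n in self.theta_names
        ]

    def unpack(self, theta: np.ndarray) -> VarianceComponents:
        vals = dict(zip(self.theta_names, theta))
        vc = VarianceComponents()
        if "log_sd_site_intercept" in vals:
            vc.sd_site_intercept = float(np.exp(vals["log_sd_site_intercept"]))
        if "log_sd_site_slope" in vals:
            vc.sd_site_slope = float(np.exp(vals["log_sd_site_slope"]))
        if "z_corr_site" in vals:
            vc.corr_site = float(np.tanh(vals["z_corr_site"]))
        if "log_sd_year" in vals:
            vc.sd_year = float(np.exp(vals["log_sd_year"]))
        if "log_sd_olre" in vals:
            vc.sd_olre = float(np.exp(vals["log_sd_olre"]))
        return vc

    def pack(self, vc: VarianceComponents) -> np.ndarray:
        out = []
        for n in self.theta_names:
            if n == "log_sd_site_intercept":
                out.append(np.log(max(vc.sd_site_intercept, 1e-8)))
            elif n == "log_sd_site_slope":
                out.append(np.log(max(vc.sd_site_slope, 1e-8)))
            elif n == "z_corr_site":
                out.append(np.arctanh(np.clip(vc.corr_site, -0.999, 0.999)))
            elif n == "log_sd_year":
                out.append(np.log(max(vc.sd_year, 1e-8)))
            elif n == "log_sd_olre":
                out.append(np.log(max(vc.sd_olre, 1e-8)))
        return np.array(out)

    def _site_precision(self, vc: VarianceComponents) -> tuple[np.ndarray, float]:
        """(ds x ds) precision of the site effects and logdet of their cov."""
        if self.ds == 1:
            var = vc.sd_site_intercept**2
            return np.array([[1.0 / var]]), float(np.log(var))
        s0, s1, rho = vc.sd_site_intercept, vc.sd_site_slope, vc.corr_site
        cov = np.array([[s0**2, rho * s0 * s1], [rho * s0 * s1, s1**2]])
        det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
        prec = np.array([[cov[1, 1], -cov[0, 1]], [-cov[0, 1], cov[0, 0]]]) / det
        return prec, float(np.log(det))

    # -- inner penalized Newton --------------------------------------------

    def _eta(self) -> np.ndarray:
        eta = self.offset + self.e
        if self.p:
            eta = eta + self.X @ self.beta
        if self.S:
            eta = eta + self.a[self.s, 0]
            if self.ds == 2:
                eta = eta + self.a[self.s, 1] * self.t
        if self.Y:
            eta = eta + self.v[self.yi]
        return eta

    def _objective(self, vc, P_site, eta) -> float:
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        f = float(mu.sum() - self.y @ eta)
        if self.S:
            f += 0.5 * float(np.einsum("si,ij,sj->", self.a[:, : self.ds], P_site, self.a[:, : self.ds]))
        if self.Y:
            f += 0.5 * float(self.v @ self.v) / vc.sd_year**2
        if self.has_olre:
            f += 0.5 * float(self.e @ self.e) / vc.sd_olre**2
        return f

    def _inner(self, vc: VarianceComponents, max_iter: int = 100):
        """Newton-optimize (beta, u) at fixed variance components.

        Returns (f, assembled) where ``assembled`` carries the pieces needed
        for the Laplace log-determinant and the fixed-effect covariance.
        """
        P_site, logdet_cov_site = self._site_precision(vc) if self.S else (None, 0.0)
        n, s, yi, t, X, Y, p, K = (
            self.n,
            self.s,
            self.yi,
            self.t,
            self.X,
            self.Y,
            self.p,
            self.K,
        )
        prec_year = 1.0 / vc.sd_year**2 if Y else 0.0
        prec_olre = 1.0 / vc.sd_olre**2 if self.has_olre else 0.0

        eta = self._eta()
        f = self._objective(vc, P_site, eta)
        if not np.isfinite(f):  # stale warm start from another theta region
            self.beta = np.zeros(p)
            if p:
                self.beta[0] = np.log(self.y.mean() + 0.5)
            self.a[:] = 0.0
            self.v[:] = 0.0
            self.e[:] = 0.0
            eta = self._eta()
            f = self._objective(vc, P_site, eta)

        assembled = None
        for _ in range(max_iter):
            mu = np.exp(np.clip(eta, -30.0, 30.0))
            r = mu - self.y

            gnorm = 0.0
            if self.has_olre:
                g_e = r + prec_olre * self.e
                gnorm = max(gnorm, np.abs(g_e).max(initial=0.0))
            if self.S:
                g_a = np.column_stack(
                    [np.bincount(s, r, minlength=self.S)]
                    + ([np.bincount(s, r * t, minlength=self.S)] if self.ds == 2 else [])
                ) + self.a[:, : self.ds] @ P_site
                gnorm = max(gnorm, np.abs(g_a).max(initial=0.0))
            if Y:
                g_v = np.bincount(yi, r, minlength=Y) + prec_year * self.v
                gnorm = max(gnorm, np.abs(g_v).max(initial=0.0))
            if p:
                g_b = X.T @ r
                gnorm = max(gnorm, np.abs(g_b).max(initial=0.0))

            # Elimination of the diagonal OLRE block.
            if self.has_olre:
                D = mu + prec_olre
                w = mu - mu**2 / D
                q = r - mu * g_e / D
            else:
                D = None
                w = mu
                q = r

            # Site 2x2 (or 1x1) blocks after OLRE elimination.
            if self.S:
                A = np.empty((self.S, self.ds, self.ds))
                A[:, 0, 0] = np.bincount(s, w, minlength=self.S) + P_site[0, 0]
                if self.ds == 2:
                    wt = w * t
                    A[:, 0, 1] = A[:, 1, 0] = (
                        np.bincount(s, wt, minlength=self.S) + P_site[0, 1]
                    )
                    A[:, 1, 1] = np.bincount(s, wt * t, minlength=self.S) + P_site[1, 1]
                G = np.zeros((self.S, self.ds, K))
                if Y:
                    flat = s * Y + yi
                    G[:, 0, :Y] = np.bincount(flat, w, minlength=self.S * Y).reshape(
                        self.S, Y
                    )
                    if self.ds == 2:
                        G[:, 1, :Y] = np.bincount(
                            flat, w * t, minlength=self.S * Y
                        ).reshape(self.S, Y)
                for j in range(p):
                    G[:, 0, Y + j] = np.bincount(s, w * X[:, j], minlength=self.S)
                    if self.ds == 2:
                        G[:, 1, Y + j] = np.bincount(
                            s, w * t * X[:, j], minlength=self.S
                        )
                rhs_a = -(
                    np.column_stack(
                        [np.bincount(s, q, minlength=self.S)]
                        + (
                            [np.bincount(s, q * t, minlength=self.S)]
                            if self.ds == 2
                            else []
                        )
                    )
                    + self.a[:, : self.ds] @ P_site
                )
            # Dense core: year effects then fixed effects.
            M = np.zeros((K, K))
            rhs_K = np.zeros(K)
            if Y:
                M[np.arange(Y), np.arange(Y)] = (
                    np.bincount(yi, w, minlength=Y) + prec_year
                )
                for j in range(p):
                    col = np.bincount(yi, w * X[:, j], minlength=Y)
                    M[:Y, Y + j] = col
                    M[Y + j, :Y] = col
                rhs_K[:Y] = -(np.bincount(yi, q, minlength=Y) + prec_year * self.v)
            if p:
                M[Y:, Y:] = X.T @ (w[:, None] * X)
                rhs_K[Y:] = -(X.T @ q)

            if self.S:
                if self.ds == 1:
                    Ainv = 1.0 / A
                else:
                    det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] ** 2
                    if np.any(det <= 0):
                        return np.inf, None
                    Ainv = np.empty_like(A)
                    Ainv[:, 0, 0] = A[:, 1, 1] / det
                    Ainv[:, 1, 1] = A[:, 0, 0] / det
                    Ainv[:, 0, 1] = Ainv[:, 1, 0] = -A[:, 0, 1] / det
                T = np.einsum("sij,sjk->sik", Ainv, G)
                M = M - np.einsum("sik,sil->kl", G, T)
                u_a = np.einsum("sij,sj->si", Ainv, rhs_a)
                rhs_K = rhs_K - np.einsum("sik,si->k", G, u_a)

            if K:
                try:
                    cho = linalg.cho_factor(M, lower=True)
                except linalg.LinAlgError:
                    return np.inf, None
                d_K = linalg.cho_solve(cho, rhs_K)
            else:
                cho = None
                d_K = np.zeros(0)

            d_beta = d_K[Y:] if p else np.zeros(0)
            d_v = d_K[:Y] if Y else np.zeros(0)
            if self.S:
                d_a = u_a - np.einsum("sij,sjk,k->si", Ainv, G, d_K)
            deta = np.zeros(n)
            if p:
                deta += X @ d_beta
            if self.S:
                deta += d_a[s, 0]
                if self.ds == 2:
                    deta += d_a[s, 1] * t
            if Y:
                deta += d_v[yi]
            if self.has_olre:
                d_e = -(g_e + mu * deta) / D

            converged = gnorm <= 1e-9 * (1.0 + abs(f))
            if converged:
                assembled = {
                    "cho": cho,
                    "M": M,
                    "D": D,
                    "A": A if self.S else None,
                    "P_site": P_site,
                    "logdet_cov_site": logdet_cov_site,
                    "f": f,
                    "vc": vc,
                }
                break

            # Damped update.
            step = 1.0
            old = (self.beta.copy(), self.a.copy(), self.v.copy(), self.e.copy())
            while True:
                if p:
                    self.beta = old[0] + step * d_beta
                if self.S:
                    self.a = old[1].copy()
                    self.a[:, : self.ds] = old[1][:, : self.ds] + step * d_a
                if Y:
                    self.v = old[2] + step * d_v
                if self.has_olre:
                    self.e = old[3] + step * d_e
                eta = self._eta()
                f_new = self._objective(vc, P_site, eta)
                if np.isfinite(f_new) and f_new <= f + 1e-9 * (1.0 + abs(f)):
                    break
                step *= 0.5
                if step < 1e-10:
                    (self.beta, self.a, self.v, self.e) = old
                    eta = self._eta()
                    f_new = f
                    break
            if f_new >= f - 1e-12 * (1.0 + abs(f)) and step < 1.0:
                # No further progress possible; accept the current point.
                mu = np.exp(np.clip(eta, -30.0, 30.0))
                assembled = {
                    "cho": cho,
                    "M": M,
                    "D": D,
                    "A": A if self.S else None,
                    "P_site": P_site,
                    "logdet_cov_site": logdet_cov_site,
                    "f": f_new,
                    "vc": vc,
                }
                f = f_new
                break
            f = f_new
        else:
            mu = np.exp(np.clip(eta, -30.0, 30.0))
            assembled = {
                "cho": cho,
                "M": M,
                "D": D,
                "A": A if self.S else None,
                "P_site": P_site,
                "logdet_cov_site": logdet_cov_site,
                "f": f,
                "vc": vc,
            }
        return f, assembled

    # -- Laplace log-likelihood --------------------------------------------

    def loglik(self, theta: np.ndarray) -> tuple[float, dict | None]:
        vc = self.unpack(np.asarray(theta, float))
        f, assembled = self._inner(vc)
        if assembled is None or not np.isfinite(f):
            return -1e10, None
        # Log-determinant of the joint Hessian restricted to the random
        # effects (fixed effects are profiled, not integrated).
        logdet = 0.0
        q_dim = 0
        norm_const = 0.0
        if self.has_olre:
            logdet += float(np.log(assembled["D"]).sum())
            q_dim += self.n
            norm_const += self.n * (np.log(vc.sd_olre**2) + _LOG2PI)
        if self.S:
            A = assembled["A"]
            if self.ds == 1:
                logdet += float(np.log(A[:, 0, 0]).sum())
            else:
                det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] ** 2
                logdet += float(np.log(det).sum())
            q_dim += self.S * self.ds
            norm_const += self.S * (
                assembled["logdet_cov_site"] + self.ds * _LOG2PI
            )
        if self.Y:
            Mvv = assembled["M"][: self.Y, : self.Y]
            sign, ld = np.linalg.slogdet(Mvv)
            if sign <= 0:
                return -1e10, None
            logdet += float(ld)
            q_dim += self.Y
            norm_const += self.Y * (np.log(vc.sd_year**2) + _LOG2PI)

        ll = (
            -assembled["f"]
            - self.loggamma_y
            - 0.5 * norm_const
            + 0.5 * q_dim * _LOG2PI
            - 0.5 * logdet
        )
        return float(ll), assembled

    def cov_beta(self, assembled: dict) -> np.ndarray:
        """Covariance of the fixed effects given the variance components."""
        if self.p == 0:
            return np.zeros((0, 0))
        M = assembled["M"]
        Y = self.Y
        if Y:
            C = M[Y:, Y:] - M[Y:, :Y] @ np.linalg.solve(M[:Y, :Y], M[:Y, Y:])
        else:
            C = M
        return np.linalg.inv(C)


def laplace_loglik(
    data: ModelData,
    structure: RandomStructure,
    vc: VarianceComponents,
    beta: np.ndarray,
) -> float:
    """Laplace marginal log-likelihood at fixed (beta, variance components).

    Used to validate the approximation against independent numerical
    integration on small instances; the fixed effects enter as an offset so
    only the random effects are optimized and integrated.
    """
    model = _LaplaceModel(data, structure, beta_fixed=beta)
    ll, assembled = model.loglik(model.pack(vc))
    if assembled is None:
        raise FitError("inner optimization failed at the supplied parameters")
    return ll


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _start_beta(data: ModelData) -> np.ndarray:
    """Poisson GLM (no random effects) start values for the fixed effects."""
    import statsmodels.api as sm

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(
                data.y, data.X, family=sm.families.Poisson(), offset=data.offset
            ).fit(maxiter=100)
        beta = np.asarray(res.params, float)
        if np.all(np.isfinite(beta)):
            return beta
    except Exception:
        pass
    beta = np.zeros(data.X.shape[1])
    beta[0] = np.log(data.y.mean() + 0.5)
    return beta


def fit_poisson_glmm(
    data: ModelData,
    structure: RandomStructure | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit the hierarchical Poisson model by maximizing the Laplace likelihood.

    Returns a :class:`FitResult` with Wald z-tests for the fixed effects and
    AIC/BIC computed from the maximized marginal log-likelihood.  A fit that
    stops without meeting the gradient tolerance is returned with
    ``converged=False`` and diagnostics rather than raised.
    """
    structure = structure or RandomStructure()
    options = options or FitOptions()

    if np.all(data.y == 0):
        raise FitError("all counts are zero; the trend model is degenerate")
    if structure.site_intercept and data.n_sites < 2:
        raise FitError("need >= 2 sites to estimate site effects")
    if data.n_years < 2:
        raise FitError("need >= 2 distinct years to estimate a trend")

    model = _LaplaceModel(data, structure)
    model.beta = _start_beta(data)

    evals = {"n": 0}

    def objective(theta):
        evals["n"] += 1
        ll, _ = model.loglik(theta)
        return -ll

    theta0 = model.theta0()
    if len(theta0):
        res = optimize.minimize(
            objective,
            theta0,
            method="L-BFGS-B",
            bounds=model.bounds(),
            options={
                "maxiter": options.max_iter,
                "ftol": 1e-12,
                "gtol": min(options.tol, 1e-5),
            },
        )
        theta_hat = res.x
        grad_norm = float(np.abs(np.atleast_1d(res.jac)).max()) if res.jac is not None else np.nan
        converged = bool(grad_norm <= options.tol or res.success)
    else:  # no random terms: plain GLM limit
        theta_hat = theta0
        grad_norm = 0.0
        converged = True

    ll, assembled = model.loglik(theta_hat)
    if assembled is None:
        raise FitError("likelihood evaluation failed at the optimum")
    vc = model.unpack(theta_hat)
    cov = model.cov_beta(assembled)
    se = np.sqrt(np.diag(cov)) if cov.size else np.zeros(0)
    beta = model.beta.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    n_params = model.p + len(model.theta_names)
    idx = data.fixed_names
    return FitResult(
        beta=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        zvalues=pd.Series(z, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        vc=vc,
        loglik=ll,
        n_obs=data.n_obs,
        n_params=n_params,
        aic=-2.0 * ll + 2.0 * n_params,
        bic=-2.0 * ll + n_params * np.log(data.n_obs),
        converged=converged,
        grad_norm=grad_norm,
        n_outer_evals=evals["n"],
        cov_beta=cov,
        structure=structure,
        reference_class=data.reference_class,
        typology_classes=list(data.typology_classes),
        year0=YEAR0_DEFAULT,
        years=data.years,
    )


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------


def predict_year_means(
    fit: FitResult,
    t_range: np.ndarray | None = None,
    *,
    typology: str | None = None,
    bias_correct: bool = False,
) -> np.ndarray:
    """Population-level predicted mean abundance per year.

    All random effects are set to zero:  yhat_t = exp(b0 + b1 t), plus the
    typology main effect and interaction when ``typology`` names a
    non-reference class of an interaction fit.  ``bias_correct`` adds the
    lognormal marginalization term exp(sum(sd^2)/2); default off, matching
    the conditional-prediction workflow.
    """
    if not fit.converged:
        warnings.warn(
            "predicting from a fit that did not meet the convergence tolerance",
            UserWarning,
            stacklevel=2,
        )
    if t_range is None:
        t_range = np.arange(0, 18)
    t_range = np.asarray(t_range, float)
    b0 = fit.beta["(Intercept)"]
    b1 = fit.beta["year"]
    if typology is not None and typology != fit.reference_class:
        main = f"typology[{typology}]"
        inter = f"year:typology[{typology}]"
        if main not in fit.beta.index:
            raise UsageError(f"unknown typology class {typology!r}")
        b0 = b0 + fit.beta[main]
        b1 = b1 + fit.beta[inter]
    eta = b0 + b1 * t_range
    if bias_correct:
        vc = fit.vc
        eta = eta + 0.5 * (
            vc.sd_site_intercept**2 + vc.sd_year**2 + vc.sd_olre**2
        )
    return np.exp(eta)


def total_change(yhat: np.ndarray) -> float:
    """Total percentage change Psi between the first and last predicted year."""
    yhat = np.asarray(yhat, float)
    if len(yhat) < 2:
        raise UsageError("need at least two predicted years")
    if yhat[0] <= 0:
        raise UsageError("first-year prediction must be positive")
    return float((yhat[-1] - yhat[0]) / yhat[0] * 100.0)


def annual_growth_rate(psi: float, divisor: int = 18) -> float:
    """Annual growth rate: total percentage change divided by the year count.

    The 18-year series uses divisor 18 by the convention of the reference
    national analysis (17, the number of yearly steps, is the alternative
    reading; both are reported in pipeline metadata).
    """
    if divisor < 1:
        raise UsageError("divisor must be >= 1")
    return float(psi) / float(divisor)


@dataclass
class ModelComparison:
    lrt: float
    df: int
    pvalue: float
    delta_aic: float
    delta_bic: float


def compare_models(fit_full: FitResult, fit_reduced: FitResult) -> ModelComparison:
    """Likelihood-ratio test plus AIC/BIC deltas for nested fits."""
    if fit_full.n_obs != fit_reduced.n_obs:
        raise UsageError("models were fitted to different numbers of rows")
    if fit_full.n_params < fit_reduced.n_params or not set(
        fit_reduced.beta.index
    ).issubset(fit_full.beta.index):
        raise UsageError("models are not nested (reduced must be within full)")
    lrt = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    if lrt < -1e-6 * (1 + abs(fit_full.loglik)):
        warnings.warn(
            f"LRT statistic {lrt:.3g} < 0 beyond tolerance; clipping to 0",
            UserWarning,
            stacklevel=2,
        )
    lrt = max(lrt, 0.0)
    df = fit_full.n_params - fit_reduced.n_params
    p = float(stats.chi2.sf(lrt, df)) if df > 0 else float("nan")
    return ModelComparison(
        lrt=float(lrt),
        df=df,
        pvalue=p,
        delta_aic=fit_full.aic - fit_reduced.aic,
        delta_bic=fit_full.bic - fit_reduced.bic,
    )


def typology_slopes(fit: FitResult) -> pd.DataFrame:
    """Per-typology-class year slopes from an interaction fit.

    The reference class slope is the ``year`` coefficient; every other class
    adds its interaction coefficient, with the standard error from the delta
    method, var(a+b) = var(a) + var(b) + 2 cov(a, b).
    """
    if fit.cov_beta is None or fit.cov_beta.size == 0:
        raise UsageError("fit carries no coefficient covariance")
    if not fit.typology_classes:
        raise UsageError("fit is not a typology-interaction model")
    names = list(fit.beta.index)
    i_year = names.index("year")
    rows = []
    for cls in fit.typology_classes:
        if cls == fit.reference_class:
            slope = fit.beta["year"]
            var = fit.cov_beta[i_year, i_year]
        else:
            term = f"year:typology[{cls}]"
            i_int = names.index(term)
            slope = fit.beta["year"] + fit.beta[term]
            var = (
                fit.cov_beta[i_year, i_year]
                + fit.cov_beta[i_int, i_int]
                + 2.0 * fit.cov_beta[i_year, i_int]
            )
        se = float(np.sqrt(var))
        z = slope / se if se > 0 else np.nan
        rows.append(
            {
                "typology": cls,
                "slope": float(slope),
                "se": se,
                "p": float(2.0 * stats.norm.sf(abs(z))),
            }
        )
    return pd.DataFrame(rows)
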