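"""Normal-theory maximum-likelihood confirmatory factor analysis.

Fits a covariance-structure model Sigma(theta) = Lambda Phi Lambda' + Theta to
a sample covariance matrix S by minimizing the ML discrepancy

    F_ML(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p ,

with chi2 = n_effective * F_min.  Follows the statsmodels model/results
idiom: :class:`CFAModel` holds data (as :class:`SampleMoments`) and a
:class:`~newsy.model_spec.MeasurementModelSpec`; :meth:`CFAModel.fit` returns
a :class:`CFAResults` carrying estimates, standard errors (inverse observed
information), fit indices (CFI, RMSEA with 95 % CI, SRMR), the standardized
solution, Wald z tests and residual diagnostics.

For clustered samples the model can be fitted to the pooled within-cluster
covariance matrix (deviations about cluster means, divisor N - G), which
estimates individual-level item relationships net of area effects; the
effective sample size is then N - G.

Identification follows the spec's scaling rule: unit latent variances with
all loadings free (default; free inter-factor covariances are then
correlations), or marker scaling (first loading per factor fixed at 1, latent
variances free).  Both give identical fit and standardized solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model_spec import MeasurementModelSpec

logger = logging.getLogger(__name__)

_CORR_BOUND = 0.995
_VAR_FLOOR = 1e-6  # soft lower bound for error variances (Heywood handling)


class CFAError(ValueError):
    pass


@dataclass
class SampleMoments:
    """Sample covariance matrix with its effective sample size.

    ``n_effective`` is N - 1 for raw data and N - G for pooled within-cluster
    covariance matrices (G clusters).
    """

    S: np.ndarray
    n_effective: int
    items: list[str]
    n_dropped_singletons: int = 0

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        p = len(self.items)
        if self.S.shape != (p, p):
            raise CFAError(f"S must be {p}x{p} to match the item list")
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise CFAError("S must be symmetric")
        self.S = (self.S + self.S.T) / 2.0

    @property
    def p(self) -> int:
        return len(self.items)

    @classmethod
    def from_data(cls, data: pd.DataFrame, items: list[str] | None = None
                  ) -> "SampleMoments":
        """Ordinary sample covariance (divisor N - 1) from raw respondent data."""
        items = list(items if items is not None else data.columns)
        X = data[items].to_numpy(dtype=float)
        if np.isnan(X).any():
            X = X[~np.isnan(X).any(axis=1)]
        n = X.shape[0]
        if n < 2:
            raise CFAError("need at least two complete rows")
        return cls(np.cov(X, rowvar=False, ddof=1), n - 1, items)


def pooled_within_covariance(data: pd.DataFrame, cluster_ids,
                             items: list[str] | None = None) -> SampleMoments:
    """Pooled within-cluster covariance matrix.

    S_PW = sum_g sum_i (y_ig - ybar_g)(y_ig - ybar_g)' / (N - G), computed
    over clusters with at least two members; singleton clusters are dropped
    (count recorded on the result and logged).
    """
    items = list(items if items is not None else data.columns)
    X = data[items].to_numpy(dtype=float)
    cluster_ids = np.asarray(cluster_ids)
    if len(cluster_ids) != len(X):
        raise CFAError("cluster_ids length must match data rows")
    labels, counts = np.unique(cluster_ids, return_counts=True)
    keep = set(labels[counts >= 2])
    n_singletons = int((counts == 1).sum())
    if not keep:
        raise CFAError("all clusters are singletons; no within-cluster information")
    if n_singletons:
        logger.info("pooled_within_covariance: dropped %d singleton clusters",
                    n_singletons)
    mask = np.array([c in keep for c in cluster_ids])
    X, cluster_ids = X[mask], cluster_ids[mask]
    N, G = X.shape[0], len(keep)
    acc = np.zeros((len(items), len(items)))
    for g in keep:
        Y = X[cluster_ids == g]
        D = Y - Y.mean(axis=0)
        acc += D.T @ D
    return SampleMoments(acc / (N - G), N - G, items, n_dropped_singletons=n_singletons)


def baseline_chi_square(moments: SampleMoments) -> tuple[float, int]:
    """Chi-square and df of the independence (diagonal-covariance) model.

    The ML solution of the independence model is sigma_ii = s_ii, so
    F_b = sum ln s_ii - ln|S| in closed form; df_b = p(p-1)/2.
    """
    S = moments.S
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        raise CFAError("S is not positive definite")
    F_b = float(np.sum(np.log(np.diag(S))) - logdet)
    p = moments.p
    return moments.n_effective * max(F_b, 0.0), p * (p - 1) // 2


def _to_corr_scale(M: np.ndarray) -> np.ndarray:
    d = 1.0 / np.sqrt(np.diag(M))
    return M * np.outer(d, d)


def srmr(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Standardized root mean squared residual over all p(p+1)/2 unique
    elements, diagonal included, each matrix standardized by its own item
    standard deviations."""
    R = _to_corr_scale_pair_resid(S, Sigma)
    p = S.shape[0]
    iu = np.triu_indices(p)
    return float(np.sqrt(np.mean(R[iu] ** 2)))


def residual_diagnostics(S: np.ndarray, Sigma: np.ndarray, items=None,
                         top: int = 10):
    """Standardized residual matrix s_ij/sqrt(s_ii s_jj) - sig_ij/sqrt(sig_ii sig_jj)
    and the ``top`` largest-|residual| cells for reporting."""
    R = _to_corr_scale_pair_resid(S, Sigma)
    p = S.shape[0]
    names = list(items) if items is not None else [f"x{i}" for i in range(p)]
    iu = np.triu_indices(p)
    order = np.argsort(-np.abs(R[iu]))
    largest = [(names[iu[0][k]], names[iu[1][k]], float(R[iu][k]))
               for k in order[:top]]
    return R, largest


def _to_corr_scale_pair_resid(S: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    S, Sigma = np.asarray(S, float), np.asarray(Sigma, float)
    if S.shape != Sigma.shape:
        raise CFAError("S and Sigma dimensions differ")
    return _to_corr_scale(S) - _to_corr_scale(Sigma)


def _rmsea_point(chi2: float, df: int, n_eff: int) -> float:
    if df == 0:
        return 0.0
    return float(np.sqrt(max(chi2 - df, 0.0) / (df * n_eff)))


def _ncp_bound(chi2: float, df: int, prob: float) -> float:
    """Noncentrality lambda with ncx2.cdf(chi2, df, lambda) = prob (bisection)."""
    if stats.chi2.cdf(chi2, df) < prob:  # even lambda=0 gives cdf below prob
        return 0.0
    f = lambda lam: stats.ncx2.cdf(chi2, df, lam) - prob
    hi = max(chi2, 1.0)
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e8:
            break
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-8))


def fit_indices(chi2: float, df: int, chi2_b: float, df_b: int, n_effective: int,
                S: np.ndarray | None = None, Sigma: np.ndarray | None = None):
    """CFI, RMSEA with 95 % CI (noncentral chi-square inversion), and SRMR.

    CFI = 1 - max(chi2-df, 0)/max(chi2_b-df_b, chi2-df, 0); RMSEA and its CI
    use lambda/(df * n_effective) with lambda the noncentrality parameter.
    With df = 0 the RMSEA is undefined and reported as 0.
    """
    if df < 0 or df_b < df:
        raise CFAError("need 0 <= df <= df_b")
    d = max(chi2 - df, 0.0)
    d_b = max(chi2_b - df_b, d, 0.0)
    cfi = 1.0 if d_b == 0 else 1.0 - d / d_b
    cfi = float(min(max(cfi, 0.0), 1.0))
    if df == 0:
        rmsea, ci = 0.0, (0.0, 0.0)
    else:
        rmsea = _rmsea_point(chi2, df, n_effective)
        lo = _ncp_bound(chi2, df, 0.95)
        hi = _ncp_bound(chi2, df, 0.05)
        ci = (float(np.sqrt(lo / (df * n_effective))),
              float(np.sqrt(hi / (df * n_effective))))
    s = srmr(S, Sigma) if S is not None and Sigma is not None else np.nan
    return cfi, rmsea, ci, s


class _Parameterization:
    """Maps the free-parameter vector to (Lambda, Phi, Theta) and back.

    Layout: free loadings, factor variances (marker scaling only, log scale),
    free factor covariances, error variances (log scale), error covariances.
    """

    def __init__(self, spec: MeasurementModelSpec, items: list[str]):
        if list(spec.items) != list(items):
            raise CFAError("moment item order must match the model spec")
        self.spec = spec
        self.p, self.m = spec.n_items, spec.n_factors
        self.item_idx = {it: i for i, it in enumerate(spec.items)}
        self.fac_idx = {f: j for j, f in enumerate(spec.factors)}
        self.marker = spec.scaling == "marker"
        self.load_cells = []      # (row, col, free?) in item order
        self.free_load = []
        markers = set()
        for f in spec.factors:
            first = spec.factor_items(f)[0]
            markers.add((self.item_idx[first], self.fac_idx[f]))
        for it in spec.items:
            cell = (self.item_idx[it], self.fac_idx[spec.loadings[it]])
            fixed = self.marker and cell in markers
            self.load_cells.append((*cell, not fixed))
            if not fixed:
                self.free_load.append(cell)
        self.cov_pairs = [(self.fac_idx[a], self.fac_idx[b])
                          for a, b in spec.free_cov_pairs()]
        self.res_pairs = [(self.item_idx[a], self.item_idx[b])
                          for a, b in spec.residual_pairs]
        self.n_free = (len(self.free_load) + (self.m if self.marker else 0)
                       + len(self.cov_pairs) + self.p + len(self.res_pairs))
        self.slices = {}
        k = 0
        for name, size in [("load", len(self.free_load)),
                           ("fvar", self.m if self.marker else 0),
                           ("fcov", len(self.cov_pairs)),
                           ("evar", self.p),
                           ("ecov", len(self.res_pairs))]:
            self.slices[name] = slice(k, k + size)
            k += size

    def start_values(self, S: np.ndarray) -> np.ndarray:
        sd = np.sqrt(np.diag(S))
        theta = np.zeros(self.n_free)
        lam0 = np.empty(self.p)
        for it in self.spec.items:
            i = self.item_idx[it]
            sign = -1.0 if self.spec.reference_loadings.get(it, 0.7) < 0 else 1.0
            lam0[i] = 0.7 * sign * sd[i]
        if not self.marker:
            theta[self.slices["load"]] = [lam0[i] for i, _ in self.free_load]
            theta[self.slices["fcov"]] = 0.2
        else:
            # rescale to the marker metric so factor orientation follows the
            # fixed (=1) marker loading
            a = np.empty(self.m)
            for f in self.spec.factors:
                j = self.fac_idx[f]
                a[j] = lam0[self.item_idx[self.spec.factor_items(f)[0]]]
            theta[self.slices["load"]] = [lam0[i] / a[j] for i, j in self.free_load]
            theta[self.slices["fvar"]] = np.log(a ** 2)
            theta[self.slices["fcov"]] = [0.2 * a[f] * a[g]
                                          for f, g in self.cov_pairs]
        theta[self.slices["evar"]] = np.log(0.51 * np.diag(S))
        theta[self.slices["ecov"]] = 0.0
        return theta

    def bounds(self):
        b = [(None, None)] * self.n_free
        if not self.marker:
            for k in range(*self.slices["fcov"].indices(self.n_free)):
                b[k] = (-_CORR_BOUND, _CORR_BOUND)
        for k in range(*self.slices["evar"].indices(self.n_free)):
            b[k] = (np.log(_VAR_FLOOR), None)
        return b

    def matrices(self, theta: np.ndarray, natural_evar: bool = False):
        Lam = np.zeros((self.p, self.m))
        it = iter(theta[self.slices["load"]])
        for i, j, free in self.load_cells:
            Lam[i, j] = next(it) if free else 1.0
        Phi = np.eye(self.m)
        if self.marker:
            np.fill_diagonal(Phi, np.exp(theta[self.slices["fvar"]]))
        for (f, g), v in zip(self.cov_pairs, theta[self.slices["fcov"]]):
            if self.marker:
                Phi[f, g] = Phi[g, f] = v
            else:
                Phi[f, g] = Phi[g, f] = v
        for pair in self.spec.fixed_zero_pairs():
            f, g = self.fac_idx[pair[0]], self.fac_idx[pair[1]]
            Phi[f, g] = Phi[g, f] = 0.0
        ev = theta[self.slices["evar"]]
        Theta = np.diag(ev if natural_evar else np.exp(ev))
        for (i, j), v in zip(self.res_pairs, theta[self.slices["ecov"]]):
            Theta[i, j] = Theta[j, i] = v
        return Lam, Phi, Theta

    def to_natural(self, theta: np.ndarray) -> np.ndarray:
        out = theta.copy()
        out[self.slices["evar"]] = np.exp(theta[self.slices["evar"]])
        if self.marker:
            out[self.slices["fvar"]] = np.exp(theta[self.slices["fvar"]])
        return out

    def labels(self) -> list[tuple[str, str]]:
        names = []
        for i, j, free in self.load_cells:
            if free:
                names.append(("loading", f"{self.spec.items[i]}~{self.spec.factors[j]}"))
        if self.marker:
            names += [("factor_variance", f) for f in self.spec.factors]
        names += [("factor_covariance", f"{a}~~{b}") for a, b in self.spec.free_cov_pairs()]
        names += [("error_variance", it) for it in self.spec.items]
        names += [("error_covariance", f"{a}~~{b}") for a, b in self.spec.residual_pairs]
        return names


def _discrepancy(S, logdet_S, Lam, Phi, Theta):
    Sigma = Lam @ Phi @ Lam.T + Theta
    try:
        c = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return None, None, None
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    Sinv = np.linalg.inv(Sigma)
    F = logdet + np.trace(S @ Sinv) - logdet_S - S.shape[0]
    return float(F), Sigma, Sinv


class CFAModel:
    """Confirmatory factor model to be fitted by maximum likelihood.

    Parameters
    ----------
    moments : SampleMoments
        Sample covariance matrix and effective n (use
        :func:`pooled_within_covariance` for clustered data).
    spec : MeasurementModelSpec
        Factor structure to fit.
    """

    def __init__(self, moments: SampleMoments, spec: MeasurementModelSpec):
        if spec.degrees_of_freedom() < 0:
            raise CFAError("model not identified (negative df)")
        self.moments = moments
        self.spec = spec
        self.param = _Parameterization(spec, moments.items)
        sign, logdet = np.linalg.slogdet(moments.S)
        self._ridge_used = False
        if sign <= 0 or not np.isfinite(logdet):
            # ridge fallback: tiny diagonal inflation to restore invertibility
            logger.warning("sample covariance singular; adding ridge 1e-8 * mean var")
            self._ridge_used = True
            self.moments = SampleMoments(
                moments.S + 1e-8 * np.mean(np.diag(moments.S)) * np.eye(moments.p),
                moments.n_effective, moments.items, moments.n_dropped_singletons)
            sign, logdet = np.linalg.slogdet(self.moments.S)
        self._logdet_S = float(logdet)

    @classmethod
    def from_data(cls, data: pd.DataFrame, spec: MeasurementModelSpec,
                  cluster_ids=None) -> "CFAModel":
        """Build from raw respondent data; pools within clusters if given."""
        if cluster_ids is not None:
            moments = pooled_within_covariance(data, cluster_ids, spec.items)
        else:
            moments = SampleMoments.from_data(data, spec.items)
        return cls(moments, spec)

    # objective and analytic gradient ------------------------------------

    def _objective(self, theta: np.ndarray):
        S = self.moments.S
        Lam, Phi, Theta = self.param.matrices(theta)
        F, Sigma, Sinv = _discrepancy(S, self._logdet_S, Lam, Phi, Theta)
        if F is None:
            return 1e10, np.zeros_like(theta)
        A = Sinv - Sinv @ S @ Sinv  # dF = tr(A dSigma)
        g = np.zeros_like(theta)
        ALP = A @ Lam @ Phi
        g[self.param.slices["load"]] = [2.0 * ALP[i, j] for i, j in self.param.free_load]
        LAL = Lam.T @ A @ Lam
        if self.param.marker:
            fv = np.exp(theta[self.param.slices["fvar"]])
            g[self.param.slices["fvar"]] = np.diag(LAL) * fv
        g[self.param.slices["fcov"]] = [2.0 * LAL[f, gg] for f, gg in self.param.cov_pairs]
        ev = np.exp(theta[self.param.slices["evar"]])
        g[self.param.slices["evar"]] = np.diag(A) * ev
        g[self.param.slices["ecov"]] = [2.0 * A[i, j] for i, j in self.param.res_pairs]
        return F, g

    def _objective_natural(self, theta_nat: np.ndarray) -> float:
        """F_ML in the natural (untransformed-variance) parameterization;
        used for the observed-information standard errors."""
        Lam, Phi, Theta = self.param.matrices(theta_nat, natural_evar=True)
        if self.param.marker:
            fv = theta_nat[self.param.slices["fvar"]]
            np.fill_diagonal(Phi, fv)
        F, _, _ = _discrepancy(self.moments.S, self._logdet_S, Lam, Phi, Theta)
        return 1e10 if F is None else F

    def fit(self, start: np.ndarray | None = None, maxiter: int = 1000,
            gtol: float = 1e-8) -> "CFAResults":
        """Minimize F_ML by L-BFGS-B with analytic gradient."""
        theta0 = self.param.start_values(self.moments.S) if start is None else start
        res = optimize.minimize(
            self._objective, theta0, jac=True, method="L-BFGS-B",
            bounds=self.param.bounds(),
            options={"maxiter": maxiter, "ftol": 1e-14, "gtol": gtol},
        )
        # polish: a second pass from the solution helps on flat regions
        res2 = optimize.minimize(
            self._objective, res.x, jac=True, method="L-BFGS-B",
            bounds=self.param.bounds(),
            options={"maxiter": maxiter, "ftol": 1e-15, "gtol": gtol / 10},
        )
        if res2.fun <= res.fun:
            res = res2
        return CFAResults(self, res)


@dataclass
class CFAResults:
    """Fitted CFA solution with fit indices and diagnostics."""

    model: CFAModel
    opt: "optimize.OptimizeResult"
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        par = self.model.param
        self.theta = np.asarray(self.opt.x, dtype=float)
        self.converged = bool(self.opt.success) and np.isfinite(self.opt.fun)
        self.iterations = int(self.opt.get("nit", -1))
        self.F_min = float(max(self.opt.fun, 0.0))
        Lam, Phi, Theta = par.matrices(self.theta)
        self.Lambda, self.Phi, self.Theta = Lam, Phi, Theta
        self.Sigma = Lam @ Phi @ Lam.T + Theta
        self.heywood = bool(np.any(np.diag(Theta) <= _VAR_FLOOR * 1.0001))
        if self.heywood:
            logger.warning("Heywood case: error variance at lower bound")
        n_eff = self.model.moments.n_effective
        self.df = self.model.spec.degrees_of_freedom()
        self.chi2 = float(n_eff * self.F_min)
        self.chi2_baseline, self.df_baseline = baseline_chi_square(self.model.moments)
        self.cfi, self.rmsea, self.rmsea_ci95, self.srmr = fit_indices(
            self.chi2, self.df, self.chi2_baseline, self.df_baseline, n_eff,
            self.model.moments.S, self.Sigma)

    # -- uncertainties ----------------------------------------------------

    @property
    def params_natural(self) -> np.ndarray:
        return self.model.param.to_natural(self.theta)

    def _hessian_natural(self) -> np.ndarray:
        from statsmodels.tools.numdiff import approx_hess2
        return approx_hess2(self.params_natural, self.model._objective_natural)

    def standard_errors(self) -> np.ndarray:
        """SEs from the inverse observed information (n_eff/2 * Hessian of F)."""
        if "se" not in self._cache:
            H = self._hessian_natural() * (self.model.moments.n_effective / 2.0)
            try:
                cov = np.linalg.inv(H)
                se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            except np.linalg.LinAlgError:
                se = np.full(self.model.param.n_free, np.nan)
            self._cache["se"] = se
        return self._cache["se"]

    def parameter_table(self) -> pd.DataFrame:
        """Estimates (natural scale), SEs, Wald z and two-sided p per free parameter."""
        labels = self.model.param.labels()
        est = self.params_natural
        se = self.standard_errors()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = est / se
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({
            "kind": [k for k, _ in labels],
            "param": [n for _, n in labels],
            "estimate": est, "se": se, "z": z, "p": pvals,
        })

    def wald_tests(self) -> pd.DataFrame:
        """Per-parameter Wald z statistics; entries with SE <= 0 are flagged NaN."""
        tab = self.parameter_table().copy()
        bad = ~(tab["se"] > 0)
        tab.loc[bad, ["z", "p"]] = np.nan
        tab["valid_se"] = ~bad
        return tab

    # -- standardized solution --------------------------------------------

    def standardized_solution(self):
        """Loadings rescaled to unit item and factor variances, and factor
        correlations; invariant to the identification rule."""
        Lam, Phi, Sigma = self.Lambda, self.Phi, self.Sigma
        item_sd = np.sqrt(np.diag(Sigma))
        fac_sd = np.sqrt(np.diag(Phi))
        if np.any(~np.isfinite(item_sd)) or np.any(item_sd <= 0):
            logger.warning("non-positive implied item variance in standardization")
        std_load = Lam * fac_sd[None, :] / item_sd[:, None]
        fac_corr = Phi / np.outer(fac_sd, fac_sd)
        spec = self.model.spec
        loads = pd.Series(
            {it: std_load[i, self.model.param.fac_idx[spec.loadings[it]]]
             for i, it in enumerate(spec.items)})
        return loads, pd.DataFrame(fac_corr, index=spec.factors, columns=spec.factors)

    @property
    def standardized_loadings(self) -> pd.Series:
        return self.standardized_solution()[0]

    def residuals(self, top: int = 10):
        return residual_diagnostics(self.model.moments.S, self.Sigma,
                                    self.model.spec.items, top=top)

    def modification_indices(self) -> pd.DataFrame:
        """Univariate score (Lagrange-multiplier) tests for fixed-to-zero
        factor covariances and error covariances: expected chi-square drop if
        the parameter were freed.  Reporting only; no automated respecification."""
        rows = []
        par = self.model.param
        n_eff = self.model.moments.n_effective
        S, logdet_S = self.model.moments.S, self.model._logdet_S
        Lam, Phi, Theta = self.Lambda, self.Phi, self.Theta

        def score_test(perturb):
            eps = 1e-5
            f0 = self.F_min
            fp = perturb(eps)
            fm = perturb(-eps)
            g = (fp - fm) / (2 * eps)
            h = (fp - 2 * f0 + fm) / eps ** 2
            if h <= 0:
                return np.nan
            return (n_eff / 2.0) * g * g / h

        for a, b in self.model.spec.fixed_zero_pairs():
            f, g_ = par.fac_idx[a], par.fac_idx[b]

            def pert(eps, f=f, g_=g_):
                P = Phi.copy(); P[f, g_] = P[g_, f] = eps
                F, _, _ = _discrepancy(S, logdet_S, Lam, P, Theta)
                return 1e10 if F is None else F
            rows.append(("factor_covariance", f"{a}~~{b}", score_test(pert)))
        existing = set(self.model.spec.residual_pairs)
        items = self.model.spec.items
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                if (min(items[i], items[j]), max(items[i], items[j])) in existing:
                    continue

                def pert(eps, i=i, j=j):
                    T = Theta.copy(); T[i, j] = T[j, i] = eps
                    F, _, _ = _discrepancy(S, logdet_S, Lam, Phi, T)
                    return 1e10 if F is None else F
                rows.append(("error_covariance", f"{items[i]}~~{items[j]}",
                             score_test(pert)))
        return (pd.DataFrame(rows, columns=["kind", "param", "mod_index"])
                .sort_values("mod_index", ascending=False, ignore_index=True))

    # -- reporting ---------------------------------------------------------

    def fit_summary(self) -> dict:
        return {
            "n_effective": self.model.moments.n_effective,
            "converged": self.converged, "iterations": self.iterations,
            "F_min": self.F_min, "chi2": self.chi2, "df": self.df,
            "chi2_baseline": self.chi2_baseline, "df_baseline": self.df_baseline,
            "cfi": self.cfi, "rmsea": self.rmsea,
            "rmsea_ci95": list(self.rmsea_ci95), "srmr": self.srmr,
            "heywood": self.heywood,
        }

    def summary(self) -> str:
        fs = self.fit_summary()
        lines = [
            "Confirmatory factor analysis (ML)",
            f"  model: {self.model.spec.name or '<unnamed>'}   "
            f"items: {self.model.spec.n_items}   factors: {self.model.spec.n_factors}",
            f"  n_effective: {fs['n_effective']}   converged: {fs['converged']}"
            + ("   [Heywood]" if fs["heywood"] else ""),
            f"  chi2({fs['df']}) = {fs['chi2']:.2f}   CFI = {fs['cfi']:.3f}   "
            f"RMSEA = {fs['rmsea']:.3f} ({fs['rmsea_ci95'][0]:.3f}, "
            f"{fs['rmsea_ci95'][1]:.3f})   SRMR = {fs['srmr']:.3f}",
            "",
            "Standardized loadings:",
        ]
        loads, corr = self.standardized_solution()
        spec = self.model.spec
        for it in spec.items:
            lines.append(f"    {it:>5s} ~ {spec.loadings[it]:<4s} {loads[it]: .3f}")
        lines.append("")
        lines.append("Factor correlations:")
        lines.append(corr.round(3).to_string())
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = self.fit_summary()
        loads, corr = self.standardized_solution()
        d["standardized_loadings"] = {k: float(v) for k, v in loads.items()}
        d["factor_correlations"] = corr.to_dict()
        tab = self.parameter_table()
        d["parameters"] = tab.to_dict(orient="records")
        return d
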