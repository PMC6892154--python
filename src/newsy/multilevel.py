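"""Between-country variance decomposition via empty multilevel models.

An "empty" (intercept-only) linear mixed model with a random intercept for
country — and optionally for administrative unit nested in country —
partitions a subscale's total variance into level-specific components.  The
quantity of interest is the percentage of total variance attributable to
between-country differences,

    pct_between_country = 100 * s2_country / (s2_country + s2_unit + s2_resid).

Estimation is REML (default) or ML through statsmodels' ``MixedLM``.  REML is
the default because with only ~15 countries the ML divisor noticeably shrinks
the country-level component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .reference import SUBSCALES


class MultilevelError(ValueError):
    pass


def _fit_with_fallback(md, reml: bool):
    """Fit a MixedLM, retrying with alternative optimizers when the default
    stalls (typically at a zero-variance boundary)."""
    import warnings as _warnings
    res = None
    # note: lbfgs can report convergence with untouched fixed effects on
    # boundary problems, so it is deliberately absent from this chain
    for opt_method in (None, "powell", "cg"):
        kwargs = {} if opt_method is None else {"method": opt_method}
        try:
            with np.errstate(all="ignore"), _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                cand = md.fit(reml=reml, **kwargs)
        except (np.linalg.LinAlgError, ValueError):
            continue
        if res is None or cand.converged:
            res = cand
        if cand.converged:
            break
    if res is None:
        raise MultilevelError("mixed-model fit failed under every optimizer")
    return res


@dataclass
class VarianceComponents:
    """REML/ML variance components of an empty multilevel model."""

    sigma2_country: float
    sigma2_unit: float | None
    sigma2_residual: float
    converged: bool
    method: str = "reml"

    @property
    def total(self) -> float:
        return self.sigma2_country + (self.sigma2_unit or 0.0) + self.sigma2_residual

    @property
    def pct_between_country(self) -> float:
        return 100.0 * self.sigma2_country / self.total

    @property
    def pct_unit(self) -> float | None:
        if self.sigma2_unit is None:
            return None
        return 100.0 * self.sigma2_unit / self.total

    @property
    def pct_residual(self) -> float:
        return 100.0 * self.sigma2_residual / self.total

    def to_dict(self) -> dict:
        return {
            "sigma2_country": self.sigma2_country,
            "sigma2_unit": self.sigma2_unit,
            "sigma2_residual": self.sigma2_residual,
            "pct_between_country": self.pct_between_country,
            "converged": self.converged, "method": self.method,
        }


class VarianceComponentsModel:
    """Empty multilevel model of one outcome on country (and unit) intercepts."""

    def __init__(self, y, country_ids, unit_ids=None):
        y = np.asarray(y, dtype=float)
        country_ids = np.asarray(country_ids)
        if len(y) != len(country_ids):
            raise MultilevelError("y and country_ids length mismatch")
        if len(np.unique(country_ids)) < 2:
            raise MultilevelError("need >= 2 countries to decompose variance")
        self.df = pd.DataFrame({"y": y, "country": country_ids})
        if unit_ids is not None:
            unit_ids = np.asarray(unit_ids)
            if len(unit_ids) != len(y):
                raise MultilevelError("unit_ids length mismatch")
            # units must be nested in countries
            tab = pd.DataFrame({"c": country_ids, "u": unit_ids})
            if (tab.groupby("u")["c"].nunique() > 1).any():
                raise MultilevelError("unit_ids must be nested within countries")
            self.df["unit"] = unit_ids
        self.three_level = unit_ids is not None

    def fit(self, method: str = "reml") -> VarianceComponents:
        reml = method.lower() == "reml"
        if self.three_level:
            md = sm.MixedLM.from_formula(
                "y ~ 1", groups="country", re_formula="1",
                vc_formula={"unit": "0 + C(unit)"}, data=self.df)
        else:
            md = sm.MixedLM.from_formula("y ~ 1", groups="country", data=self.df)
        res = _fit_with_fallback(md, reml)
        s2_country = float(np.clip(res.cov_re.iloc[0, 0], 0.0, None))
        s2_unit = (float(np.clip(res.vcomp[0], 0.0, None))
                   if self.three_level else None)
        return VarianceComponents(
            sigma2_country=s2_country, sigma2_unit=s2_unit,
            sigma2_residual=float(res.scale),
            converged=bool(res.converged), method="reml" if reml else "ml")


def fit_empty_multilevel(y, country_ids, unit_ids=None,
                         method: str = "reml") -> VarianceComponents:
    """Convenience wrapper: build and fit a :class:`VarianceComponentsModel`."""
    return VarianceComponentsModel(y, country_ids, unit_ids).fit(method=method)


def variance_share_table(scores: pd.DataFrame, subscales: list[str] | None = None,
                         unit_level: bool = False,
                         method: str = "reml") -> pd.DataFrame:
    """Between-country variance share per subscale on a scored cohort.

    Expects ``<subscale>_score`` columns plus ``country`` (and ``unit_id``
    when ``unit_level``).  Returns one row per subscale.
    """
    if "country" not in scores.columns:
        raise MultilevelError("scored cohort must carry a 'country' column")
    subscales = subscales or [s for s in SUBSCALES
                              if f"{s}_score" in scores.columns]
    rows = []
    for s in subscales:
        col = f"{s}_score"
        if col not in scores.columns:
            continue
        mask = scores[col].notna()
        vc = fit_empty_multilevel(
            scores.loc[mask, col], scores.loc[mask, "country"],
            scores.loc[mask, "unit_id"] if unit_level else None, method=method)
        rows.append({"subscale": s, **vc.to_dict()})
    return pd.DataFrame(rows)
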