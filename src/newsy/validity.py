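"""Construct validity: mixed models of subscale scores on area-level exposures.

For each subscale a linear mixed model regresses the score on binary
area-level SES and walkability, adjusted for adolescent age, sex and country
(fixed dummies), with random intercepts for the clustering factors
(administrative unit, optionally school nested within unit).  "Generalized"
mixed models with continuous scores reduce to the identity link, which is
what is implemented; fixed-effect inference is Wald (normal approximation):
CI = b +- 1.96 se.

Construct validity holds when scores associate with walkability/SES exactly
where hypothesized: :func:`hypothesis_evaluation` flags each hypothesized
association as confirmed/unconfirmed/contradicted and reports significant
associations that were not hypothesized as "unexpected".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .reference import VALIDITY_HYPOTHESES

Z95 = 1.959963984540054


class ValidityModelError(ValueError):
    pass


@dataclass
class FixedEffectEstimate:
    term: str
    b: float
    se: float
    p: float

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.b - Z95 * self.se, self.b + Z95 * self.se)

    def to_dict(self) -> dict:
        lo, hi = self.ci95
        return {"term": self.term, "b": self.b, "se": self.se,
                "ci95": [lo, hi], "p": self.p}


@dataclass
class ValidityHypothesis:
    subscale: str
    positive_with: frozenset  # subset of {"ses", "walk"}


def default_hypotheses() -> list[ValidityHypothesis]:
    return [ValidityHypothesis(s, frozenset(v))
            for s, v in VALIDITY_HYPOTHESES.items()]


_EXPOSURE_COLS = {"ses": "ses_high", "walk": "walk_high"}


class ValidityModel:
    """Random-intercept linear mixed model for one subscale score.

    Parameters
    ----------
    data : DataFrame
        Scored cohort with exposure, covariate and cluster columns.
    outcome : str
        Score column (e.g. ``"aesthetics_score"``).
    exposures, covariates : sequences of column names
        Fixed-effect terms; ``country`` enters as fixed dummies.
    clusters : sequence of column names
        Random-intercept factors; the first is the grouping level, any
        second is a nested variance component.
    """

    def __init__(self, data: pd.DataFrame, outcome: str,
                 exposures=("ses_high", "walk_high"),
                 covariates=("age", "sex_male", "country"),
                 clusters=("unit_id",),
                 exclude_countries=()):
        cols = [outcome, *exposures, *covariates, *clusters]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValidityModelError(f"missing columns: {missing}")
        df = data.dropna(subset=cols).copy()
        if exclude_countries:
            df = df[~df["country"].isin(exclude_countries)]
        for e in exposures:
            vals = set(pd.unique(df[e]))
            if not vals <= {0, 1}:
                raise ValidityModelError(f"exposure {e} must be binary 0/1")
        if not clusters:
            raise ValidityModelError("at least one cluster factor required")
        if df[clusters[0]].nunique() < 2:
            raise ValidityModelError("need >= 2 clusters")
        self.data = df
        self.outcome = outcome
        self.exposures = list(exposures)
        self.covariates = list(covariates)
        self.clusters = list(clusters)
        terms = [*self.exposures,
                 *[f"C({c})" if df[c].dtype == object else c
                   for c in self.covariates]]
        self.formula = f"{outcome} ~ " + " + ".join(terms)
        self._check_rank(df, terms)

    def _check_rank(self, df: pd.DataFrame, terms) -> None:
        import patsy
        X = patsy.dmatrix(" + ".join(terms), df, return_type="dataframe")
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            # name the offending columns for the error message
            _, R = np.linalg.qr(X.to_numpy())
            bad = [X.columns[i] for i in range(X.shape[1])
                   if abs(R[i, i]) < 1e-8]
            raise ValidityModelError(f"rank-deficient fixed design; "
                                     f"collinear columns: {bad}")

    def fit(self, reml: bool = True) -> "ValidityResults":
        from .multilevel import _fit_with_fallback
        vc = ({self.clusters[1]: f"0 + C({self.clusters[1]})"}
              if len(self.clusters) > 1 else None)
        md = sm.MixedLM.from_formula(
            self.formula, groups=self.clusters[0],
            re_formula="1" if vc else None, vc_formula=vc, data=self.data)
        res = _fit_with_fallback(md, reml)
        return ValidityResults(self, res)


class ValidityResults:
    """Fixed effects with Wald CIs for one fitted validity model."""

    def __init__(self, model: ValidityModel, res):
        self.model = model
        self._res = res
        self.converged = bool(res.converged)

    def fixed_effects(self, terms=None) -> list[FixedEffectEstimate]:
        terms = terms if terms is not None else self.model.exposures
        out = []
        fe = self._res.fe_params
        se = self._res.bse_fe
        for t in terms:
            if t not in fe.index:
                continue
            b, s = float(fe[t]), float(se[t])
            p = 2.0 * stats.norm.sf(abs(b / s)) if s > 0 else np.nan
            out.append(FixedEffectEstimate(t, b, s, p))
        return out

    def all_fixed_effects(self) -> list[FixedEffectEstimate]:
        return self.fixed_effects(terms=list(self._res.fe_params.index))

    def summary(self) -> str:
        lines = [f"Validity mixed model: {self.model.formula}",
                 f"  clusters: {self.model.clusters}  converged: {self.converged}"]
        for est in self.all_fixed_effects():
            lo, hi = est.ci95
            lines.append(f"  {est.term:<28s} b = {est.b: .3f} "
                         f"({lo: .3f}, {hi: .3f})  p = {est.p:.3g}")
        return "\n".join(lines)


def fit_validity_lmm(data: pd.DataFrame, outcome: str, **kwargs) -> ValidityResults:
    """Build and fit a :class:`ValidityModel` in one call."""
    return ValidityModel(data, outcome, **kwargs).fit()


def hypothesis_evaluation(estimates: dict[str, dict[str, FixedEffectEstimate]],
                          hypotheses: list[ValidityHypothesis] | None = None,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Confront estimated exposure effects with the a priori hypotheses.

    ``estimates`` maps subscale -> {"ses": estimate, "walk": estimate}.
    Flags per (subscale, exposure):

    * ``confirmed`` — hypothesized positive, estimated significantly positive;
    * ``not_confirmed`` — hypothesized but not significant;
    * ``contradicted`` — hypothesized positive, significantly negative;
    * ``unexpected`` — significant though not hypothesized;
    * ``null_upheld`` — not hypothesized and not significant;
    * ``untested`` — hypothesized but no estimate supplied.
    """
    hypotheses = hypotheses or default_hypotheses()
    rows = []
    for hyp in hypotheses:
        for exp in ("ses", "walk"):
            expected = exp in hyp.positive_with
            est = estimates.get(hyp.subscale, {}).get(exp)
            if est is None:
                status = "untested" if expected else "no_estimate"
                rows.append({"subscale": hyp.subscale, "exposure": exp,
                             "hypothesized": expected, "b": np.nan,
                             "ci_lo": np.nan, "ci_hi": np.nan, "p": np.nan,
                             "status": status})
                continue
            sig = est.p < alpha
            if expected:
                status = ("confirmed" if sig and est.b > 0
                          else "contradicted" if sig and est.b < 0
                          else "not_confirmed")
            else:
                status = "unexpected" if sig else "null_upheld"
            lo, hi = est.ci95
            rows.append({"subscale": hyp.subscale, "exposure": exp,
                         "hypothesized": expected, "b": est.b,
                         "ci_lo": lo, "ci_hi": hi, "p": est.p,
                         "status": status})
    return pd.DataFrame(rows)
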