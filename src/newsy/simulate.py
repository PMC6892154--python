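"""Synthetic multi-country survey cohorts with the study's printed structure.

The raw survey microdata are not deposited, so analyses are exercised on
synthetic cohorts that emulate the published marginal structure:

* country-specific sample sizes and demographics (published sample table);
* subscale means/SDs per country, with two-level clustering (administrative
  unit within country) controlled by a unit-level intraclass correlation;
* item-level responses generated from the final five-factor measurement
  models with the published standardized loadings (continuous, or
  discretized to the 1-4 Likert scale at equal-probability normal cut
  points);
* binary area-level SES and walkability labels assigned at the
  administrative-unit level following the stratified (2 x 2 balanced)
  recruitment design, with configurable fixed effects on subscale scores
  whose defaults carry the published association signs and magnitudes.

Everything is a pure function of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference as ref
from .model_spec import MeasurementModelSpec
from .registry import load_builtin_model


class SimulationConfigError(ValueError):
    pass


#: administrative units per country when not configured; four per stratum of
#: the 2x2 SES-by-walkability recruitment design
DEFAULT_N_UNITS = 16

#: default share of within-country variance at the administrative-unit level
DEFAULT_UNIT_ICC = 0.05


@dataclass
class CountryProfile:
    """Generator parameters for one country."""

    country_id: str
    n: int
    subscale_means: dict[str, float]
    subscale_sds: dict[str, float]
    n_units: int = DEFAULT_N_UNITS
    n_schools: int = 8
    unit_icc: float = DEFAULT_UNIT_ICC
    age_range: tuple[float, float] = (11.0, 19.0)
    pct_male: float = 46.7
    pct_ses_high: float = 50.0
    pct_walk_high: float = 50.0
    measurement_model: MeasurementModelSpec | None = None
    factor_correlation: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SimulationConfigError(f"{self.country_id}: n must be >= 1")
        if not (0 <= self.unit_icc < 1):
            raise SimulationConfigError(f"{self.country_id}: unit_icc must be in [0, 1)")
        if any(s < 0 for s in self.subscale_sds.values()):
            raise SimulationConfigError(f"{self.country_id}: SDs must be >= 0")


@dataclass
class ExposureEffectConfig:
    """Fixed effects of binary exposures (and covariates) on subscale scores."""

    ses_effects: dict[str, float] = field(default_factory=dict)
    walk_effects: dict[str, float] = field(default_factory=dict)
    age_effects: dict[str, float] = field(default_factory=dict)
    sex_effects: dict[str, float] = field(default_factory=dict)

    @classmethod
    def null(cls) -> "ExposureEffectConfig":
        return cls()

    @classmethod
    def published(cls) -> "ExposureEffectConfig":
        """Published pooled association point estimates as generator truth."""
        return cls(
            ses_effects={s: v["ses"][0] for s, v in ref.VALIDITY_EFFECTS.items()},
            walk_effects={s: v["walk"][0] for s, v in ref.VALIDITY_EFFECTS.items()},
        )


def default_profiles(countries: list[str] | None = None,
                     unit_icc: float = DEFAULT_UNIT_ICC) -> list[CountryProfile]:
    """Country profiles reproducing the published sample sizes, demographics
    and subscale descriptive statistics."""
    out = []
    for c in countries or ref.COUNTRIES:
        cs = ref.COUNTRY_STATS[c]
        stats_ = ref.SUBSCALE_STATS[c]
        model = (load_builtin_model(f"final_{c}") if c in ref.CFA_COUNTRIES else None)
        out.append(CountryProfile(
            country_id=c, n=cs["n"],
            subscale_means={s: m for s, (m, _) in zip(ref.SUBSCALES, stats_)},
            subscale_sds={s: sd for s, (_, sd) in zip(ref.SUBSCALES, stats_)},
            unit_icc=unit_icc,
            pct_male=cs["pct_male"], pct_ses_high=cs["pct_ses_high"],
            pct_walk_high=cs["pct_walk_high"],
            measurement_model=model,
            factor_correlation=ref.AVG_ABS_FACTOR_CORRELATION.get(c),
        ))
    return out


# -- generator configuration I/O ------------------------------------------

def save_generator_config(path, profiles: list[CountryProfile],
                          effects: ExposureEffectConfig | None = None,
                          seed: int = 0, mode: str = "continuous") -> None:
    """Serialize a full generator configuration to JSON or YAML."""
    import json
    from pathlib import Path

    import yaml

    d = {
        "seed": seed, "mode": mode,
        "profiles": [
            {
                "country_id": p.country_id, "n": p.n,
                "subscale_means": dict(p.subscale_means),
                "subscale_sds": dict(p.subscale_sds),
                "n_units": p.n_units, "n_schools": p.n_schools,
                "unit_icc": p.unit_icc, "age_range": list(p.age_range),
                "pct_male": p.pct_male, "pct_ses_high": p.pct_ses_high,
                "pct_walk_high": p.pct_walk_high,
                "measurement_model": (p.measurement_model.to_dict()
                                      if p.measurement_model else None),
                "factor_correlation": p.factor_correlation,
            } for p in profiles],
        "effects": {
            "ses_effects": dict((effects or ExposureEffectConfig()).ses_effects),
            "walk_effects": dict((effects or ExposureEffectConfig()).walk_effects),
            "age_effects": dict((effects or ExposureEffectConfig()).age_effects),
            "sex_effects": dict((effects or ExposureEffectConfig()).sex_effects),
        },
    }
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_generator_config(path):
    """Load (profiles, effects, seed, mode) from a JSON/YAML config."""
    import json
    from pathlib import Path

    import yaml

    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    profiles = []
    for pd_ in d["profiles"]:
        mm = pd_.get("measurement_model")
        profiles.append(CountryProfile(
            country_id=pd_["country_id"], n=pd_["n"],
            subscale_means=dict(pd_["subscale_means"]),
            subscale_sds=dict(pd_["subscale_sds"]),
            n_units=pd_.get("n_units", DEFAULT_N_UNITS),
            n_schools=pd_.get("n_schools", 8),
            unit_icc=pd_.get("unit_icc", DEFAULT_UNIT_ICC),
            age_range=tuple(pd_.get("age_range", (11.0, 19.0))),
            pct_male=pd_.get("pct_male", 46.7),
            pct_ses_high=pd_.get("pct_ses_high", 50.0),
            pct_walk_high=pd_.get("pct_walk_high", 50.0),
            measurement_model=(MeasurementModelSpec.from_dict(mm) if mm else None),
            factor_correlation=pd_.get("factor_correlation"),
        ))
    eff = d.get("effects", {})
    effects = ExposureEffectConfig(
        ses_effects=dict(eff.get("ses_effects", {})),
        walk_effects=dict(eff.get("walk_effects", {})),
        age_effects=dict(eff.get("age_effects", {})),
        sex_effects=dict(eff.get("sex_effects", {})),
    )
    return profiles, effects, d.get("seed", 0), d.get("mode", "continuous")


# -- item-level generation ------------------------------------------------

def _factor_corr_matrix(spec: MeasurementModelSpec, r: float) -> np.ndarray:
    """Uniform correlation ``r`` on free factor pairs, zero on fixed pairs."""
    m = spec.n_factors
    Phi = np.eye(m)
    idx = {f: j for j, f in enumerate(spec.factors)}
    for a, b in spec.free_cov_pairs():
        Phi[idx[a], idx[b]] = Phi[idx[b], idx[a]] = r
    w, _ = np.linalg.eigh(Phi)
    if w.min() <= 1e-10:
        raise SimulationConfigError(f"factor correlation {r} makes Phi non-PD")
    return Phi


def implied_item_covariance(spec: MeasurementModelSpec,
                            factor_correlation: float = 0.2,
                            residual_corr: float = 0.0) -> np.ndarray:
    """Model-implied item covariance Lambda Phi Lambda' + Theta on the
    standardized-item scale, from the spec's reference loadings."""
    if not spec.reference_loadings:
        raise SimulationConfigError("spec carries no reference loadings")
    lam = np.array([spec.reference_loadings[i] for i in spec.items])
    if np.any(np.abs(lam) > 1):
        raise SimulationConfigError("|loading| must be <= 1 for standardized generation")
    p, m = spec.n_items, spec.n_factors
    idx = {f: j for j, f in enumerate(spec.factors)}
    Lam = np.zeros((p, m))
    for i, it in enumerate(spec.items):
        Lam[i, idx[spec.loadings[it]]] = lam[i]
    Phi = _factor_corr_matrix(spec, factor_correlation)
    Theta = np.diag(1.0 - lam ** 2)
    iidx = {it: i for i, it in enumerate(spec.items)}
    for a, b in spec.residual_pairs:
        i, j = iidx[a], iidx[b]
        cov = residual_corr * np.sqrt(Theta[i, i] * Theta[j, j])
        Theta[i, j] = Theta[j, i] = cov
    w = np.linalg.eigvalsh(Theta)
    if w.min() < -1e-12:
        raise SimulationConfigError("residual covariances make Theta non-PSD")
    return Lam @ Phi @ Lam.T + Theta


def generate_factor_items(spec: MeasurementModelSpec, n: int, seed,
                          mode: str = "continuous",
                          factor_correlation: float = 0.2,
                          residual_corr: float = 0.0) -> pd.DataFrame:
    """Draw ``n`` item-response vectors from a measurement model.

    Latent factors are multivariate normal (zero mean, unit variance,
    uniform inter-factor correlation on the free pairs); each item is
    lambda * factor + residual with residual variance 1 - lambda^2 (plus any
    configured correlated-residual covariance).  ``likert`` mode discretizes
    each marginal into 1..4 at equal-probability normal cut points.
    """
    if mode not in ("continuous", "likert"):
        raise SimulationConfigError(f"unknown mode {mode!r}")
    Sigma = implied_item_covariance(spec, factor_correlation, residual_corr)
    rng = np.random.default_rng(seed)
    try:
        X = rng.multivariate_normal(np.zeros(spec.n_items), Sigma, size=n,
                                    method="cholesky")
    except np.linalg.LinAlgError:
        # singular implied covariance (e.g. zero residual variances)
        X = rng.multivariate_normal(np.zeros(spec.n_items), Sigma, size=n,
                                    method="eigh")
    if mode == "likert":
        from scipy import stats as sps
        cuts = sps.norm.ppf([0.25, 0.5, 0.75])
        X = 1.0 + np.searchsorted(cuts, X).reshape(X.shape)
    return pd.DataFrame(X, columns=spec.items)


# -- subscale-level generation --------------------------------------------

def generate_subscale_cohort(profiles: list[CountryProfile], seed) -> pd.DataFrame:
    """Respondent-level subscale scores with country means and two-level
    clustering: value = country mean + unit intercept (variance
    unit_icc * SD^2) + residual (variance (1 - unit_icc) * SD^2)."""
    if not profiles:
        raise SimulationConfigError("profiles must be nonempty")
    rng = np.random.default_rng(seed)
    frames = []
    for prof in profiles:
        unit_ids = np.arange(prof.n) % prof.n_units
        df = pd.DataFrame({
            "country": prof.country_id,
            "unit_id": [f"{prof.country_id}_u{u:02d}" for u in unit_ids],
        })
        for s, mu in prof.subscale_means.items():
            sd = prof.subscale_sds[s]
            u_sd = np.sqrt(prof.unit_icc) * sd
            e_sd = np.sqrt(1.0 - prof.unit_icc) * sd
            unit_eff = rng.normal(0.0, u_sd, prof.n_units)
            df[f"{s}_score"] = mu + unit_eff[unit_ids] + rng.normal(0.0, e_sd, prof.n)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _assign_units(prof: CountryProfile, rng: np.random.Generator,
                  balanced: bool = True) -> pd.DataFrame:
    """Unit table with stratified SES/walkability labels.

    Balanced mode cycles units through the four design strata (~50/50 on
    each label); otherwise labels are Bernoulli draws at the profile's
    published percentages.
    """
    strata = [(1, 1), (1, 0), (0, 1), (0, 0)]  # (ses_high, walk_high)
    rows = []
    for u in range(prof.n_units):
        if balanced:
            ses, walk = strata[u % 4]
        else:
            ses = int(rng.random() < prof.pct_ses_high / 100.0)
            walk = int(rng.random() < prof.pct_walk_high / 100.0)
        rows.append({"unit": u, "ses_high": ses, "walk_high": walk})
    return pd.DataFrame(rows)


def generate_full_cohort(profiles: list[CountryProfile],
                         effects: ExposureEffectConfig | None = None,
                         seed=0, mode: str = "continuous",
                         items: bool = True, balanced: bool = True) -> pd.DataFrame:
    """Full cohort: covariates, unit-level exposures, subscale scores with
    exposure effects added, and (optionally) item responses for the
    factor-analyzable subscales.

    Item responses are generated from each country's measurement model (on
    the standardized scale) independently of the subscale-score columns;
    exposure effects are applied to the score columns.
    """
    effects = effects or ExposureEffectConfig.null()
    rng = np.random.default_rng(seed)
    scores = generate_subscale_cohort(profiles, rng.integers(2 ** 31))
    frames = []
    offset = 0
    for prof in profiles:
        block = scores.iloc[offset:offset + prof.n].reset_index(drop=True)
        offset += prof.n
        units = _assign_units(prof, rng, balanced=balanced)
        unit_nums = np.arange(prof.n) % prof.n_units
        block["school_id"] = [f"{prof.country_id}_s{u % prof.n_schools:02d}"
                              for u in unit_nums]
        block["ses_high"] = units["ses_high"].to_numpy()[unit_nums]
        block["walk_high"] = units["walk_high"].to_numpy()[unit_nums]
        lo, hi = prof.age_range
        block["age"] = rng.uniform(lo, hi, prof.n)
        block["sex_male"] = (rng.random(prof.n) < prof.pct_male / 100.0).astype(int)
        for s in prof.subscale_means:
            col = f"{s}_score"
            block[col] = (block[col]
                          + effects.ses_effects.get(s, 0.0) * block["ses_high"]
                          + effects.walk_effects.get(s, 0.0) * block["walk_high"]
                          + effects.age_effects.get(s, 0.0) * block["age"]
                          + effects.sex_effects.get(s, 0.0) * block["sex_male"])
        if items and prof.measurement_model is not None:
            r = (prof.factor_correlation
                 if prof.factor_correlation is not None else 0.2)
            item_df = generate_factor_items(
                prof.measurement_model, prof.n, rng.integers(2 ** 31),
                mode=mode, factor_correlation=r)
            block = pd.concat([block, item_df], axis=1)
        frames.append(block)
    return pd.concat(frames, ignore_index=True)
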