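"""End-to-end pipeline: simulate -> score -> CFA -> variance shares -> validity.

Given a :class:`PipelineConfig`, :func:`run_pipeline` executes the enabled
stages, writes versioned CSV/JSON outputs plus a run manifest (configuration,
seed, file checksums) to the output directory, and :func:`make_report`
renders a human-readable summary (per-country fit table, loading matrices,
between-country variance shares, validity table with hypothesis flags).

Countries below the minimum CFA sample size (default 200 respondents) are
excluded from the CFA stage with a logged notice, mirroring the study's
eligibility rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import reference as ref
from .cfa import CFAModel, SampleMoments, pooled_within_covariance
from .registry import load_builtin_model
from .multilevel import variance_share_table
from .scoring import score_cohort
from .simulate import ExposureEffectConfig, default_profiles, generate_full_cohort
from .validity import fit_validity_lmm, hypothesis_evaluation

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "newsy_run"
    countries: list[str] | None = None
    model_name: str = "final_common"
    min_cfa_n: int = 200
    effects: str = "published"          # "published" | "null"
    stages: tuple = ("simulate", "score", "cfa", "varcomp", "validity")
    pooled_within: bool = True
    exclude_countries: tuple = ()

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise PipelineError("seed must be an integer")
        # fail before any computation on unknown model names
        load_builtin_model(self.model_name)
        for c in self.countries or []:
            if c not in ref.COUNTRIES:
                raise PipelineError(f"unknown country {c!r}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(o):
    """Serialize numpy scalars transparently."""
    if hasattr(o, "item"):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run bundle (also persisted)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config.__dict__ | {"stages": list(config.stages)}}
    written: list[Path] = []
    stage = "init"
    try:
        profiles = default_profiles(config.countries)
        if "simulate" in config.stages:
            stage = "simulate"
            effects = (ExposureEffectConfig.published()
                       if config.effects == "published"
                       else ExposureEffectConfig.null())
            cohort = generate_full_cohort(profiles, effects, seed=config.seed)
            path = out / "cohort.csv"
            cohort.to_csv(path, index=False)
            written.append(path)
            bundle["cohort"] = cohort
        else:
            cohort = None

        if "score" in config.stages and cohort is not None:
            stage = "score"
            # simulated subscale scores are already on the score scale; item
            # columns feed the CFA stage, so scoring here just carries both
            bundle["scores"] = cohort
            path = out / "scores.csv"
            score_cols = [c for c in cohort.columns if c.endswith("_score")]
            cohort[["country", "unit_id", "school_id", "age", "sex_male",
                    "ses_high", "walk_high", *score_cols]].to_csv(path, index=False)
            written.append(path)

        if "cfa" in config.stages and cohort is not None:
            stage = "cfa"
            cfa_out = {}
            for prof in profiles:
                if prof.measurement_model is None:
                    continue
                if prof.n <= config.min_cfa_n:
                    logger.info("CFA: skipping %s (n=%d <= %d)",
                                prof.country_id, prof.n, config.min_cfa_n)
                    continue
                sub = cohort[cohort["country"] == prof.country_id]
                items = prof.measurement_model.items
                use_pooled = (config.pooled_within
                              and prof.country_id in ref.POOLED_WITHIN_COUNTRIES)
                if use_pooled:
                    moments = pooled_within_covariance(sub[items], sub["unit_id"])
                else:
                    moments = SampleMoments.from_data(sub[items])
                fits = {}
                for model_name in ("apriori", f"final_{prof.country_id}"):
                    spec = load_builtin_model(model_name)
                    if spec.items != list(items):
                        # a priori model uses pre-respecification items the
                        # simulated cohort does not carry; report df only
                        fits[model_name] = {"df": spec.degrees_of_freedom()}
                        continue
                    res = CFAModel(moments, spec).fit()
                    fits[model_name] = res.to_dict()
                    if res.heywood:
                        logger.warning("CFA %s/%s: Heywood case flagged",
                                       prof.country_id, model_name)
                cfa_out[prof.country_id] = fits
            path = out / "cfa.json"
            path.write_text(json.dumps(cfa_out, indent=2, default=_json_default))
            written.append(path)
            bundle["cfa"] = cfa_out

        if "varcomp" in config.stages and cohort is not None:
            stage = "varcomp"
            tab = variance_share_table(cohort)
            path = out / "varcomp.json"
            path.write_text(tab.to_json(orient="records", indent=2))
            written.append(path)
            bundle["varcomp"] = tab

        if "validity" in config.stages and cohort is not None:
            stage = "validity"
            estimates = {}
            records = {}
            for s in ref.SUBSCALES:
                col = f"{s}_score"
                if col not in cohort.columns:
                    continue
                res = fit_validity_lmm(
                    cohort, col, exclude_countries=config.exclude_countries)
                fes = {t.replace("_high", ""): e
                       for t, e in zip(["ses_high", "walk_high"],
                                       res.fixed_effects())}
                estimates[s] = fes
                records[s] = {k: v.to_dict() for k, v in fes.items()}
            eval_tab = hypothesis_evaluation(estimates)
            path = out / "validity.json"
            path.write_text(json.dumps(
                {"effects": records,
                 "hypotheses": eval_tab.to_dict(orient="records")},
                indent=2, default=_json_default))
            written.append(path)
            bundle["validity"] = eval_tab
            bundle["validity_effects"] = estimates
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config": bundle["config"],
        "files": {p.name: _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_json_default))
    bundle["manifest"] = manifest
    return bundle


def make_report(bundle: dict) -> str:
    """Human-readable summary of a run bundle; missing stages are skipped."""
    lines = ["NEWS-Y-IPEN pipeline report", "=" * 60]
    if "cfa" in bundle:
        lines += ["", "Country-specific measurement-model fit",
                  f"{'country':<12s}{'model':<18s}{'chi2 (df)':<16s}"
                  f"{'CFI':<8s}{'RMSEA (95% CI)':<24s}{'SRMR':<6s}"]
        for country, fits in bundle["cfa"].items():
            for name, d in fits.items():
                if "chi2" not in d:
                    lines.append(f"{country:<12s}{name:<18s}df = {d['df']}")
                    continue
                ci = d["rmsea_ci95"]
                chi2_s = f"{d['chi2']:.0f} ({d['df']})"
                rmsea_s = f"{d['rmsea']:.3f} ({ci[0]:.3f}, {ci[1]:.3f})"
                lines.append(f"{country:<12s}{name:<18s}{chi2_s:<16s}"
                             f"{d['cfi']:<8.3f}{rmsea_s:<24s}{d['srmr']:.3f}")
        lines += ["", "Standardized loadings (final models)"]
        for country, fits in bundle["cfa"].items():
            for name, d in fits.items():
                if "standardized_loadings" in d:
                    lines.append(f"  {country}:")
                    for it, v in d["standardized_loadings"].items():
                        lines.append(f"    {it:>5s} {v: .2f}")
    else:
        lines += ["", "[CFA stage absent]"]
    if "varcomp" in bundle:
        lines += ["", "Between-country variance shares (%)"]
        for _, row in bundle["varcomp"].iterrows():
            lines.append(f"  {row['subscale']:<28s}{row['pct_between_country']:6.1f}")
    else:
        lines += ["", "[variance-decomposition stage absent]"]
    if "validity" in bundle:
        lines += ["", "Construct validity (b, 95% CI, status)"]
        for _, r in bundle["validity"].iterrows():
            if pd.isna(r["b"]):
                continue
            lines.append(
                f"  {r['subscale']:<28s}{r['exposure']:<6s}"
                f"{r['b']: .3f} ({r['ci_lo']: .3f}, {r['ci_hi']: .3f})  "
                f"{r['status']}")
    else:
        lines += ["", "[validity stage absent]"]
    return "\n".join(lines)
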