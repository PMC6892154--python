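"""NEWS-Y-IPEN subscale scoring.

Eight subscale scores per respondent:

* **Residential density** — weighted sum of six housing-type frequency items
  (each rated 0 = none .. 4 = all).  Weights reflect the approximate number of
  dwelling units per building type: 1, 11, 25, 50, 75, 100.  The Denmark
  variant omits the sixth item (no >20-story buildings at that site), weights
  1, 11, 25, 50, 75.
* **Land use mix – diversity** — mean of 13 walking-proximity items
  (1 = >30 min .. 5 = 1-5 min walk).
* **Recreational facilities** — mean of 9 proximity items on the same scale;
  the Nigeria variant uses 6 (parks and public school facilities absent at
  that site; the dropped slots are configurable since the exact supplementary
  listing is not reproduced here).
* Five factor-analyzable subscales (Accessibility & walking facilities,
  Traffic safety, Pedestrian infrastructure & safety, Safety from crime,
  Aesthetics) — means of 4-point Likert items, reverse-scoring items worded
  against walkability/safety (AW1; TS1, TS3; CR1-CR4) so that higher scores
  always mean a more walkable / safer environment.

Missing handling is listwise per subscale by default: any missing item yields
a missing score, no imputation.  A "mean of >= 80 % answered" mode is
available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import pandas as pd

from .registry import FINAL_ITEM_DEFINITIONS

DENSITY_WEIGHTS = (1, 11, 25, 50, 75, 100)
DENSITY_ITEMS = [f"RD{i}" for i in range(1, 7)]
DIVERSITY_ITEMS = [f"LU{i}" for i in range(1, 14)]
RECREATION_ITEMS = [f"RF{i}" for i in range(1, 10)]

LIKERT_REVERSE = {d.item_id for d in FINAL_ITEM_DEFINITIONS if d.reverse_coded}

LIKERT_SUBSCALE_ITEMS = {
    "accessibility_walking": ["AW1", "AW2", "AW3", "AW4", "AW5"],
    "traffic_safety": ["TS1", "TS2", "TS3"],
    "pedestrian_infrastructure": ["PI1", "PI2", "PI3"],
    "safety_from_crime": ["CR1", "CR2", "CR3", "CR4"],
    "aesthetics": ["AE1", "AE2", "AE3"],
}


class ScoringError(ValueError):
    pass


def _check_range(values, lo, hi, what):
    arr = np.asarray(values, dtype=float)
    finite = arr[~np.isnan(arr)]
    if ((finite < lo) | (finite > hi)).any():
        raise ScoringError(f"{what}: responses must lie in [{lo}, {hi}]")


def score_residential_density(responses, variant: str = "standard") -> float:
    """Weighted sum of housing-type frequency ratings.

    Parameters
    ----------
    responses : sequence of int
        Six ordinal ratings in 0..4 (five for the ``no_item6`` variant).
    variant : {"standard", "no_item6"}
        ``no_item6`` drops the >20-story item (Denmark).

    Returns NaN if any response is missing (listwise rule).
    """
    weights = DENSITY_WEIGHTS if variant == "standard" else DENSITY_WEIGHTS[:5]
    if variant not in ("standard", "no_item6"):
        raise ScoringError(f"unknown residential-density variant {variant!r}")
    r = np.asarray(responses, dtype=float)
    if r.shape != (len(weights),):
        raise ScoringError(
            f"expected {len(weights)} density responses, got {r.shape}"
        )
    _check_range(r, 0, 4, "residential density")
    if np.isnan(r).any():
        return math.nan
    return float(np.dot(weights, r))


def score_destination_mix(responses, expected_k: int) -> float:
    """Mean of walking-proximity ratings (1..5) across ``expected_k`` destinations."""
    r = np.asarray(responses, dtype=float)
    if r.shape != (expected_k,):
        raise ScoringError(f"expected {expected_k} proximity responses, got {r.shape}")
    _check_range(r, 1, 5, "destination proximity")
    if np.isnan(r).any():
        return math.nan
    return float(r.mean())


def reverse_code(x, scale_min: int = 1, scale_max: int = 4):
    """Reflect a response about its scale: returns (scale_min + scale_max) - x.

    A strictly decreasing involution of the scale; used to orient items so
    that higher values mean higher walkability/safety.
    """
    arr = np.asarray(x, dtype=float)
    _check_range(arr, scale_min, scale_max, "reverse_code")
    out = (scale_min + scale_max) - arr
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def score_likert_subscale(responses: dict, items: list[str], reverse_set=frozenset(),
                          scale_min: int = 1, scale_max: int = 4) -> float:
    """Mean of Likert responses after reverse-coding ``reverse_set`` items."""
    vals = []
    for it in items:
        v = responses.get(it, math.nan)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return math.nan
        _check_range([v], scale_min, scale_max, it)
        vals.append(reverse_code(v, scale_min, scale_max) if it in reverse_set else float(v))
    return float(np.mean(vals))


@dataclass
class ScoringProtocol:
    """Subscale -> item-set configuration, with per-country variants.

    ``density_variant``: "standard" | "no_item6"; ``recreation_variant``:
    "standard" (9 items) | "six_item" (Nigeria); ``recreation_drop``: the
    three RF slots omitted in the six-item variant.
    """

    density_variant: str = "standard"
    recreation_variant: str = "standard"
    recreation_drop: tuple[str, str, str] = ("RF7", "RF8", "RF9")
    likert_reverse: frozenset = frozenset(LIKERT_REVERSE)
    min_answered_fraction: float | None = None  # None = listwise

    @classmethod
    def for_country(cls, country: str) -> "ScoringProtocol":
        if country == "denmark":
            return cls(density_variant="no_item6")
        if country == "nigeria":
            return cls(recreation_variant="six_item")
        return cls()

    @property
    def recreation_items(self) -> list[str]:
        if self.recreation_variant == "standard":
            return list(RECREATION_ITEMS)
        if self.recreation_variant == "six_item":
            return [i for i in RECREATION_ITEMS if i not in self.recreation_drop]
        raise ScoringError(f"unknown recreation variant {self.recreation_variant!r}")

    @property
    def density_items(self) -> list[str]:
        if self.density_variant == "standard":
            return list(DENSITY_ITEMS)
        if self.density_variant == "no_item6":
            return DENSITY_ITEMS[:5]
        raise ScoringError(f"unknown density variant {self.density_variant!r}")


_CARRY_COLUMNS = [
    "country", "unit_id", "school_id", "age", "sex_male", "ses_high", "walk_high",
]


def _row_mean(block: pd.DataFrame, min_frac: float | None) -> pd.Series:
    if min_frac is None:
        return block.mean(axis=1).where(block.notna().all(axis=1))
    answered = block.notna().mean(axis=1)
    return block.mean(axis=1).where(answered >= min_frac)


def score_cohort(table: pd.DataFrame, protocol: ScoringProtocol | None = None,
                 per_country_variants: bool = True) -> pd.DataFrame:
    """Score every respondent row of an item-level cohort table.

    Applies country-specific protocol variants (Denmark density, Nigeria
    recreation) when ``per_country_variants`` and a ``country`` column are
    present.  Returns one row per input row with ``<subscale>_score`` columns;
    identifier/covariate columns are carried through.
    """
    base = protocol or ScoringProtocol()
    out = pd.DataFrame(index=table.index)
    for col in _CARRY_COLUMNS:
        if col in table.columns:
            out[col] = table[col]

    if per_country_variants and "country" in table.columns:
        groups = [(c, table.index[table["country"] == c]) for c in table["country"].unique()]
    else:
        groups = [(None, table.index)]

    score_cols = {}
    for country, idx in groups:
        proto = (ScoringProtocol.for_country(country)
                 if country is not None and per_country_variants else base)
        if base.min_answered_fraction is not None:
            proto.min_answered_fraction = base.min_answered_fraction
        sub = table.loc[idx]

        if set(proto.density_items) <= set(table.columns):
            block = sub[proto.density_items].astype(float)
            _check_range(block.to_numpy(), 0, 4, "residential density")
            w = np.array(DENSITY_WEIGHTS[:len(proto.density_items)], dtype=float)
            dens = (block * w).sum(axis=1).where(block.notna().all(axis=1))
            score_cols.setdefault("residential_density_score", {}).update(dens.to_dict())

        for name, items, lo, hi in [
            ("land_use_mix_diversity", DIVERSITY_ITEMS, 1, 5),
            ("recreational_facilities", proto.recreation_items, 1, 5),
        ]:
            if set(items) <= set(table.columns):
                block = sub[items].astype(float)
                _check_range(block.to_numpy(), lo, hi, name)
                score_cols.setdefault(f"{name}_score", {}).update(
                    _row_mean(block, proto.min_answered_fraction).to_dict()
                )

        for name, items in LIKERT_SUBSCALE_ITEMS.items():
            if set(items) <= set(table.columns):
                block = sub[items].astype(float)
                _check_range(block.to_numpy(), 1, 4, name)
                rev = [i for i in items if i in proto.likert_reverse]
                block = block.copy()
                block[rev] = 5.0 - block[rev]
                score_cols.setdefault(f"{name}_score", {}).update(
                    _row_mean(block, proto.min_answered_fraction).to_dict()
                )

    for col, values in score_cols.items():
        out[col] = pd.Series(values)
    return out
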