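"""Built-in NEWS-Y-IPEN measurement-model catalog.

Provides the a priori six-factor, 22-item model, the common final five-factor,
18-item model, and the ten country-specific final models.  Country models
carry the published standardized loadings as reference values.

The publication reports only *counts* of freed inter-factor covariances and
correlated-error pairs per country, not their identities (except the largest
inter-factor correlation, whose factor pair is printed).  The built-ins
therefore use a documented canonical assignment: the printed maximum-
correlation pair is freed first, remaining pairs follow a fixed order, and
correlated-error pairs are drawn from a fixed within-factor list.  These
assignments reproduce the published model degrees of freedom exactly but are
not authoritative as to which specific covariances were freed; both are
overridable when constructing a spec by hand.
"""

from __future__ import annotations

from . import reference as ref
from .model_spec import ItemDefinition, MeasurementModelSpec


#: final-model item definitions; reverse-coded items are those published with
#: negative loadings (worded against walkability/safety)
FINAL_ITEM_DEFINITIONS = [
    ItemDefinition("AW1", "Hilly streets make it difficult to walk in the neighborhood", 1, 4, True),
    ItemDefinition("AW2", "Less cul-de-sacs in the neighborhood", 1, 4),
    ItemDefinition("AW3", "Many different routes for getting from place to place", 1, 4),
    ItemDefinition("AW4", "Presence of sidewalks on most of the streets", 1, 4),
    ItemDefinition("AW5", "Sidewalks separated from the road/traffic by parked cars", 1, 4),
    ItemDefinition("TS1", "Difficult/unpleasant to walk due to traffic", 1, 4, True),
    ItemDefinition("TS2", "Speed of traffic usually slow (30 mph)", 1, 4),
    ItemDefinition("TS3", "Drivers drive faster than speed limit", 1, 4, True),
    ItemDefinition("PI1", "Good lighting at night", 1, 4),
    ItemDefinition("PI2", "Easy view of walkers/bikers from houses", 1, 4),
    ItemDefinition("PI3", "Crosswalks and signals to cross busy streets", 1, 4),
    ItemDefinition("CR1", "Fear of child being hurt by a stranger when alone outside around the home", 1, 4, True),
    ItemDefinition("CR2", "Fear of child being hurt by a stranger when with a friend outside around the home", 1, 4, True),
    ItemDefinition("CR3", "Fear of child being hurt by a stranger when walking in local streets", 1, 4, True),
    ItemDefinition("CR4", "Fear of child being hurt by a stranger in local park", 1, 4, True),
    ItemDefinition("AE1", "Interesting things to look at", 1, 4),
    ItemDefinition("AE2", "Beautiful natural things to look at", 1, 4),
    ItemDefinition("AE3", "Buildings/homes nice to look at", 1, 4),
]

FINAL_FACTORS = ["AW", "TS", "PI", "CR", "AE"]

_FINAL_LOADING_MAP = {d.item_id: d.item_id[:2] for d in FINAL_ITEM_DEFINITIONS}

#: canonical ordering of final-model factor pairs used when freeing a subset
_FINAL_PAIR_ORDER = [
    ("AW", "TS"), ("AW", "PI"), ("AW", "CR"), ("AW", "AE"), ("PI", "TS"),
    ("CR", "TS"), ("AE", "TS"), ("CR", "PI"), ("AE", "PI"), ("AE", "CR"),
]

#: canonical within-factor correlated-error pair pool (arbitrary, documented)
_DEFAULT_RESIDUAL_PAIRS = [
    ("CR1", "CR2"), ("CR3", "CR4"), ("AW4", "AW5"), ("TS2", "TS3"),
]

# a priori six-factor structure: item counts 2+6+5+4+3+2 = 22; item codes for
# the pre-respecification model are placeholders (full wordings come from the
# instrument's supplementary adaptation tables, which are not reproduced here)
_APRIORI_FACTOR_ITEMS = {
    "LA": ["LA1", "LA2"],                                  # land use mix - access
    "PS": ["PS1", "PS2", "PS3", "PS4", "PS5", "PS6"],      # pedestrian & automobile traffic safety
    "CR": ["CR1", "CR2", "CR3", "CR4", "CR5"],             # safety from crime
    "AE": ["AE1", "AE2", "AE3", "AE4"],                    # aesthetics
    "WF": ["WF1", "WF2", "WF3"],                           # walking/cycling facilities
    "SC": ["SC1", "SC2"],                                  # street connectivity
}


def _apriori_spec() -> MeasurementModelSpec:
    items: list[str] = []
    loadings: dict[str, str] = {}
    for fac, its in _APRIORI_FACTOR_ITEMS.items():
        items.extend(its)
        loadings.update({i: fac for i in its})
    return MeasurementModelSpec(
        items=items,
        factors=list(_APRIORI_FACTOR_ITEMS),
        loadings=loadings,
        free_factor_cov=None,
        name="apriori",
    )


def _final_common_spec() -> MeasurementModelSpec:
    return MeasurementModelSpec(
        items=list(ref.FINAL_MODEL_ITEMS),
        factors=list(FINAL_FACTORS),
        loadings=dict(_FINAL_LOADING_MAP),
        free_factor_cov=None,
        name="final_common",
    )


def _country_free_cov(country: str) -> set[tuple[str, str]]:
    k = ref.FREE_FACTOR_COV_COUNTS[country]
    _, max_pair = ref.MAX_FACTOR_CORRELATION[country]
    max_pair = tuple(sorted(max_pair))
    order = [max_pair] + [tuple(sorted(p)) for p in _FINAL_PAIR_ORDER
                          if tuple(sorted(p)) != max_pair]
    return set(order[:k])


def _final_country_spec(country: str) -> MeasurementModelSpec:
    n_res = ref.RESIDUAL_PAIR_COUNTS[country]
    return MeasurementModelSpec(
        items=list(ref.FINAL_MODEL_ITEMS),
        factors=list(FINAL_FACTORS),
        loadings=dict(_FINAL_LOADING_MAP),
        free_factor_cov=_country_free_cov(country),
        residual_pairs=set(_DEFAULT_RESIDUAL_PAIRS[:n_res]),
        reference_loadings=dict(
            zip(ref.FINAL_MODEL_ITEMS, ref.FINAL_MODEL_LOADINGS[country])
        ),
        name=f"final_{country}",
    )


def catalog_keys() -> list[str]:
    """Names of all built-in measurement models."""
    return ["apriori", "final_common"] + [f"final_{c}" for c in ref.CFA_COUNTRIES]


def load_builtin_model(name: str) -> MeasurementModelSpec:
    """Return a fully specified, identified built-in model by catalog name.

    Raises
    ------
    KeyError
        If ``name`` is not in the catalog; the message lists available keys.
    """
    if name == "apriori":
        return _apriori_spec()
    if name == "final_common":
        return _final_common_spec()
    if name.startswith("final_") and name[6:] in ref.CFA_COUNTRIES:
        return _final_country_spec(name[6:])
    raise KeyError(
        f"unknown built-in model {name!r}; available: {', '.join(catalog_keys())}"
    )
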