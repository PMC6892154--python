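"""Declarative confirmatory-factor-analysis model specifications.

A :class:`MeasurementModelSpec` describes the factor structure to be fitted:
which item loads on which latent factor (each item on exactly one), which
inter-factor covariances are free versus fixed to zero, which error (residual)
covariances are freed, and the identification rule.  Two identification rules
are supported:

``unit_variance``
    latent variances fixed at 1, all loadings free (loadings come out on the
    standardized-factor scale directly);
``marker``
    first loading per factor fixed at 1, latent variances free.

Both yield the same degrees of freedom and the same standardized solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import yaml


@dataclass(frozen=True)
class ItemDefinition:
    """A single questionnaire item and its response scale."""

    item_id: str
    label: str = ""
    scale_min: int = 1
    scale_max: int = 4
    reverse_coded: bool = False

    def __post_init__(self) -> None:
        if self.scale_min >= self.scale_max:
            raise ValueError(
                f"{self.item_id}: scale_min ({self.scale_min}) must be < "
                f"scale_max ({self.scale_max})"
            )


class ModelSpecError(ValueError):
    """Raised for malformed or unidentified model specifications."""


def _norm_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class MeasurementModelSpec:
    """Factor structure: items, factors, loading pattern and covariance pattern.

    Parameters
    ----------
    items : list of str
        Ordered observed-variable names (p items).
    factors : list of str
        Ordered latent-factor names (m factors).
    loadings : dict
        Map ``item -> factor``; every item loads on exactly one factor.
    free_factor_cov : set of pairs, optional
        Factor pairs whose covariance is freely estimated.  ``None`` means
        all m(m-1)/2 pairs free.  Pairs not listed are fixed to zero.
    residual_pairs : set of pairs, optional
        Item pairs with a freely estimated error covariance.
    scaling : {"unit_variance", "marker"}
        Identification rule.
    reference_loadings : dict, optional
        Published standardized loadings (signed), carried for simulation and
        reporting; not used in fitting.
    name : str
        Catalog name, if any.
    """

    items: list[str]
    factors: list[str]
    loadings: dict[str, str]
    free_factor_cov: set[tuple[str, str]] | None = None
    residual_pairs: set[tuple[str, str]] = field(default_factory=set)
    scaling: str = "unit_variance"
    reference_loadings: dict[str, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            raise ModelSpecError("duplicate item ids")
        if self.scaling not in ("unit_variance", "marker"):
            raise ModelSpecError(f"unknown scaling rule {self.scaling!r}")
        missing = [i for i in self.items if i not in self.loadings]
        if missing:
            raise ModelSpecError(f"items without a factor assignment: {missing}")
        bad = [i for i, f in self.loadings.items() if f not in self.factors]
        if bad:
            raise ModelSpecError(f"items loading on unknown factors: {bad}")
        if self.free_factor_cov is not None:
            self.free_factor_cov = {_norm_pair(*p) for p in self.free_factor_cov}
            for a, b in self.free_factor_cov:
                if a == b or a not in self.factors or b not in self.factors:
                    raise ModelSpecError(f"invalid factor covariance pair ({a}, {b})")
        norm_res = {_norm_pair(*p) for p in self.residual_pairs}
        if len(norm_res) != len(self.residual_pairs):
            raise ModelSpecError("duplicate residual covariance pairs")
        for a, b in norm_res:
            if a == b or a not in self.items or b not in self.items:
                raise ModelSpecError(f"invalid residual pair ({a}, {b})")
        self.residual_pairs = norm_res
        if self.degrees_of_freedom() < 0:
            raise ModelSpecError(
                "model not identified: negative degrees of freedom "
                f"({self.degrees_of_freedom()})"
            )

    # -- structure queries ------------------------------------------------

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def factor_items(self, factor: str) -> list[str]:
        return [i for i in self.items if self.loadings[i] == factor]

    def all_factor_pairs(self) -> list[tuple[str, str]]:
        m = self.factors
        return [_norm_pair(m[i], m[j]) for i in range(len(m)) for j in range(i + 1, len(m))]

    def free_cov_pairs(self) -> list[tuple[str, str]]:
        """Factor pairs with a free covariance, in canonical order."""
        if self.free_factor_cov is None:
            return self.all_factor_pairs()
        return [p for p in self.all_factor_pairs() if p in self.free_factor_cov]

    def fixed_zero_pairs(self) -> list[tuple[str, str]]:
        free = set(self.free_cov_pairs())
        return [p for p in self.all_factor_pairs() if p not in free]

    # -- parameter accounting ---------------------------------------------

    def count_free_parameters(self) -> dict[str, int]:
        """Tally of free parameters under the spec's identification rule.

        Unit-variance scaling frees all p loadings and fixes the m latent
        variances at 1; marker scaling fixes one loading per factor and frees
        the m latent variances.  Either way the total is identical.
        """
        p, m = self.n_items, self.n_factors
        n_cov = len(self.free_cov_pairs())
        if self.scaling == "unit_variance":
            tally = {
                "loadings": p,
                "factor_variances": 0,
                "factor_covariances": n_cov,
                "error_variances": p,
                "error_covariances": len(self.residual_pairs),
            }
        else:
            tally = {
                "loadings": p - m,
                "factor_variances": m,
                "factor_covariances": n_cov,
                "error_variances": p,
                "error_covariances": len(self.residual_pairs),
            }
        tally["total"] = sum(v for k, v in tally.items() if k != "total")
        return tally

    def degrees_of_freedom(self) -> int:
        """Model df = p(p+1)/2 minus the number of free parameters."""
        p = self.n_items
        return p * (p + 1) // 2 - self.count_free_parameters()["total"]

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "items": list(self.items),
            "factors": list(self.factors),
            "loadings": dict(self.loadings),
            "free_factor_cov": (
                None if self.free_factor_cov is None
                else sorted([list(p) for p in self.free_factor_cov])
            ),
            "fixed_zero_cov": sorted([list(p) for p in self.fixed_zero_pairs()]),
            "residual_pairs": sorted([list(p) for p in self.residual_pairs]),
            "scaling": self.scaling,
            "reference_loadings": dict(self.reference_loadings),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MeasurementModelSpec":
        ffc = d.get("free_factor_cov")
        return cls(
            items=list(d["items"]),
            factors=list(d["factors"]),
            loadings=dict(d["loadings"]),
            free_factor_cov=None if ffc is None else {tuple(p) for p in ffc},
            residual_pairs={tuple(p) for p in d.get("residual_pairs", [])},
            scaling=d.get("scaling", "unit_variance"),
            reference_loadings=dict(d.get("reference_loadings", {})),
            name=d.get("name", ""),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(d, sort_keys=False))
        else:
            path.write_text(json.dumps(d, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "MeasurementModelSpec":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(d)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MeasurementModelSpec):
            return NotImplemented
        return self.to_dict() == other.to_dict()
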