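"""Allostatic-load computable phenotype.

Ten physiological measurements across three body systems are discretized at
clinical thresholds into binary "unhealthy" indicators.  The index is the
proportion of *non-missing* indicators equal to one, so missing components
are excluded from both the numerator and the denominator rather than being
treated as healthy.  Missing components that carry auxiliary-information
anchors (related diagnoses) can later be recovered as unhealthy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ComponentSpec",
    "AliValue",
    "UndefinedAliError",
    "MISSING",
    "load_component_specs",
    "component_names",
    "discretize_component",
    "compute_ali",
    "apply_roadmap_recovery",
    "discretize_cohort",
]

#: Sentinel for a missing indicator (kept as float NaN so arrays stay numeric).
MISSING = float("nan")

_DIRECTIONS = frozenset({"greater", "greater_equal", "less"})
_SYSTEMS = frozenset({"cardiovascular", "metabolic", "inflammation"})
N_COMPONENTS = 10


class UndefinedAliError(ValueError):
    """All ten components missing: the index has an empty denominator."""


@dataclass(frozen=True)
class ComponentSpec:
    """One component of the index: threshold rule plus audit anchors."""

    name: str
    system: str
    threshold: float | None
    direction: str
    sex_specific_thresholds: Mapping[str, float] | None = None
    auxiliary_anchors: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.system not in _SYSTEMS:
            raise ValueError(f"unknown system {self.system!r}")
        if self.threshold is None and not self.sex_specific_thresholds:
            raise ValueError(f"component {self.name!r} has no threshold")

    @property
    def recoverable(self) -> bool:
        """Whether a missing value can be recovered from chart anchors."""
        return len(self.auxiliary_anchors) > 0

    def cutoff_for(self, sex: str | None) -> float:
        if self.sex_specific_thresholds:
            if sex is None:
                raise ValueError(
                    f"component {self.name!r} has sex-specific thresholds; "
                    "sex is required"
                )
            try:
                return self.sex_specific_thresholds[sex]
            except KeyError:
                raise ValueError(
                    f"no threshold for sex {sex!r} in component {self.name!r}"
                ) from None
        assert self.threshold is not None
        return self.threshold


@dataclass(frozen=True)
class AliValue:
    """Index value: proportion of non-missing components at unhealthy levels."""

    value: float
    n_nonmissing: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("index value must lie in [0, 1]")
        if not 0 < self.n_nonmissing <= N_COMPONENTS:
            raise ValueError("n_nonmissing must be in 1..10")


def _parse_anchors(raw: object) -> tuple[str, ...]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return ()
    text = str(raw).strip()
    if not text:
        return ()
    return tuple(a.strip() for a in text.split("|") if a.strip())


def load_component_specs(
    path: str | None = None,
    overrides: Mapping[str, Mapping[str, object]] | None = None,
) -> dict[str, ComponentSpec]:
    """Load the canonical ten-component table (or a user-supplied one).

    Parameters
    ----------
    path:
        Optional CSV with the same columns as the packaged table.
    overrides:
        Per-component field overrides, e.g.
        ``{"serum_albumin": {"direction": "less"}}`` for sites that treat
        low albumin as unhealthy instead of the printed rule.
    """
    if path is None:
        ref = resources.files("alivalid.data").joinpath("components.csv")
        with ref.open("r") as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)

    specs: dict[str, ComponentSpec] = {}
    for row in table.itertuples(index=False):
        fields: dict[str, object] = {
            "name": row.name,
            "system": row.system,
            "threshold": None if pd.isna(row.threshold) else float(row.threshold),
            "direction": row.direction,
            "auxiliary_anchors": _parse_anchors(row.anchors),
        }
        if not pd.isna(row.threshold_male) or not pd.isna(row.threshold_female):
            fields["sex_specific_thresholds"] = {
                "male": float(row.threshold_male),
                "female": float(row.threshold_female),
            }
        if overrides and row.name in overrides:
            fields.update(overrides[row.name])
        specs[str(row.name)] = ComponentSpec(**fields)  # type: ignore[arg-type]

    if path is None and len(specs) != N_COMPONENTS:
        raise RuntimeError("packaged component table must have ten rows")
    return specs


def component_names(specs: Mapping[str, ComponentSpec] | None = None) -> list[str]:
    """Canonical component ordering (table order)."""
    if specs is None:
        specs = load_component_specs()
    return list(specs)


def _is_missing(x: object) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def discretize_component(
    measurement: float | Iterable[float] | None,
    spec: ComponentSpec,
    sex: str | None = None,
) -> float:
    """Binary unhealthy indicator for one measurement (NaN when missing).

    An iterable of encounter-level measurements is reduced to the mean of its
    non-missing values before thresholding.
    """
    if not _is_missing(measurement) and not isinstance(measurement, (int, float)):
        vals = [float(v) for v in measurement if not _is_missing(v)]  # type: ignore[union-attr]
        if not vals:
            return MISSING
        measurement = float(np.mean(vals))
    if _is_missing(measurement):
        return MISSING
    cutoff = spec.cutoff_for(sex)
    x = float(measurement)  # type: ignore[arg-type]
    if spec.direction == "greater":
        return float(x > cutoff)
    if spec.direction == "greater_equal":
        return float(x >= cutoff)
    return float(x < cutoff)


def compute_ali(indicators: Sequence[float]) -> AliValue:
    """Proportion of non-missing indicators equal to one.

    Raises
    ------
    UndefinedAliError
        When every indicator is missing (empty denominator); the index is
        never silently reported as zero in that case.
    ValueError
        When the input does not have exactly ten entries or contains values
        outside {0, 1, missing}.
    """
    arr = np.asarray(list(indicators), dtype=float)
    if arr.shape != (N_COMPONENTS,):
        raise ValueError(f"expected exactly {N_COMPONENTS} indicators")
    observed = arr[~np.isnan(arr)]
    if not np.all(np.isin(observed, (0.0, 1.0))):
        raise ValueError("indicators must be 0, 1, or missing")
    n = observed.size
    if n == 0:
        raise UndefinedAliError("all ten components missing; index undefined")
    return AliValue(value=float(observed.sum() / n), n_nonmissing=int(n))


def apply_roadmap_recovery(
    indicators: Mapping[str, float],
    auxiliary_found: Mapping[str, bool],
    specs: Mapping[str, ComponentSpec] | None = None,
) -> dict[str, float]:
    """Recover missing components for which chart anchors were located.

    A missing component whose auxiliary information was found becomes a
    non-missing indicator equal to one (the anchors exist only for values
    presumed unhealthy); everything else is returned unchanged.

    Raises
    ------
    ValueError
        If ``auxiliary_found`` marks a non-missing component, or one with no
        anchors (serum albumin can never be recovered).
    """
    if specs is None:
        specs = load_component_specs()
    out = dict(indicators)
    for name, found in auxiliary_found.items():
        if name not in out:
            raise ValueError(f"unknown component {name!r}")
        if not found:
            continue
        if not _is_missing(out[name]):
            raise ValueError(
                f"auxiliary information marked for non-missing component {name!r}"
            )
        if not specs[name].recoverable:
            raise ValueError(f"component {name!r} has no auxiliary anchors")
        out[name] = 1.0
    return out


def discretize_cohort(
    table: pd.DataFrame,
    specs: Mapping[str, ComponentSpec] | None = None,
    sex_col: str = "sex",
) -> pd.DataFrame:
    """Discretize a raw-measurement cohort table into indicator columns.

    ``table`` has one row per patient and one column per component (named as
    in the component table) holding the (mean) measurement, plus a sex
    column where sex-specific thresholds apply.  Returns a copy with
    ``ind_<name>`` indicator columns and ``ali``/``ali_n`` columns computed
    over the non-missing indicators.
    """
    if specs is None:
        specs = load_component_specs()
    out = table.copy()
    indicators = {}
    for name, spec in specs.items():
        if name not in table.columns:
            raise ValueError(f"missing measurement column {name!r}")
        sexes = (table[sex_col] if spec.sex_specific_thresholds
                 else [None] * len(table))
        indicators[f"ind_{name}"] = [
            discretize_component(m if not pd.isna(m) else None, spec, s)
            for m, s in zip(table[name], sexes)
        ]
    for col, vals in indicators.items():
        out[col] = vals
    ind = out[[f"ind_{n}" for n in specs]].to_numpy(dtype=float)
    counts = (~np.isnan(ind)).sum(axis=1)
    if np.any(counts == 0):
        raise UndefinedAliError(
            "some patients have all ten components missing")
    out["ali"] = np.nansum(ind, axis=1) / counts
    out["ali_n"] = counts
    return out
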