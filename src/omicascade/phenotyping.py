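"""Viability phenotyping: from plate readings to regression-ready phenotypes.

Cellular drug sensitivity is measured as percent viable cells relative to
untreated control wells at each treatment concentration, then log-transformed
so the downstream linear-regression steps see an approximately normal
response.  Replicate wells are aggregated as a ratio of means (control wells
are plate-level in the assay, so the plate mean is the natural denominator).

The log base is a convention only: any base is an affine rescaling of any
other, so every regression t- and p-value downstream is base-invariant (this
is asserted by the test suite).  Natural log is the default and is recorded
in the table's metadata.  Percent values above 100 (treated wells outgrowing
control) are retained, not capped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError

__all__ = [
    "PlateReadings",
    "PhenotypeTable",
    "percent_viability",
    "log_transform_phenotype",
    "summarize_dose_response",
    "build_phenotype_table",
]

_LOG_BASES = {"e": math.e, "2": 2.0, "10": 10.0}


@dataclass(frozen=True)
class PlateReadings:
    """Replicate fluorescence readings for one sample at one concentration."""

    sample_id: str
    concentration: float
    treated_values: tuple[float, ...]
    control_values: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, vals in (
            ("treated", self.treated_values),
            ("control", self.control_values),
        ):
            if len(vals) == 0:
                raise ValidationError(
                    f"{self.sample_id}: no {name} readings at "
                    f"{self.concentration} uM"
                )
            if any(v <= 0 for v in vals):
                raise ValidationError(
                    f"{self.sample_id}: non-positive {name} reading at "
                    f"{self.concentration} uM"
                )


def percent_viability(readings: PlateReadings) -> float:
    """Percent survival: 100 x mean(treated) / mean(control).

    Scale-invariant — multiplying every reading on the plate by a constant
    leaves the ratio unchanged.
    """
    treated = float(np.mean(readings.treated_values))
    control = float(np.mean(readings.control_values))
    return 100.0 * treated / control


def log_transform_phenotype(percent, base: str | float = "e"):
    """Log of percent-viable (natural log by default).

    Accepts scalars or arrays; strictly monotone; raises
    :class:`~omicascade.errors.DomainError` on non-positive input.
    """
    arr = np.asarray(percent, dtype=float)
    if np.any(arr <= 0) or np.any(~np.isfinite(arr) & ~np.isnan(arr)):
        raise DomainError("percent viable must be > 0 for log transform")
    b = _LOG_BASES.get(str(base), None)
    if b is None:
        b = float(base)
        if b <= 0 or b == 1.0:
            raise DomainError(f"invalid log base {base!r}")
    out = np.log(arr) / np.log(b)
    return float(out) if np.isscalar(percent) else out


@dataclass
class PhenotypeTable:
    """Samples x concentrations viability phenotypes.

    ``percent_viable`` is the raw percent-survival matrix; ``log_pheno`` is
    its element-wise log under ``log_base`` and is what the association
    cascade regresses against.
    """

    percent_viable: pd.DataFrame  # samples x concentrations (float columns)
    log_base: str | float = "e"

    def __post_init__(self) -> None:
        if self.percent_viable.empty:
            raise ValidationError("phenotype table is empty")
        self.percent_viable.columns = [
            float(c) for c in self.percent_viable.columns
        ]
        vals = self.percent_viable.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValidationError("percent viable values must be > 0")

    @property
    def samples(self) -> list[str]:
        return list(self.percent_viable.index)

    @property
    def concentrations(self) -> list[float]:
        return [float(c) for c in self.percent_viable.columns]

    @property
    def log_pheno(self) -> pd.DataFrame:
        return self.percent_viable.apply(
            lambda col: log_transform_phenotype(col.to_numpy(), self.log_base)
        )

    def with_log_base(self, base: str | float) -> "PhenotypeTable":
        return PhenotypeTable(self.percent_viable.copy(), log_base=base)


def build_phenotype_table(
    readings: Sequence[PlateReadings], log_base: str | float = "e"
) -> PhenotypeTable:
    """Assemble per-sample, per-concentration percent viability from wells."""
    if not readings:
        raise ValidationError("no plate readings supplied")
    rows: dict[str, dict[float, float]] = {}
    for rd in readings:
        cell = rows.setdefault(rd.sample_id, {})
        if rd.concentration in cell:
            raise ValidationError(
                f"duplicate readings for {rd.sample_id} at "
                f"{rd.concentration} uM"
            )
        cell[rd.concentration] = percent_viability(rd)
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    df.index.name = "sample_id"
    return PhenotypeTable(df, log_base=log_base)


def summarize_dose_response(table: PhenotypeTable) -> pd.DataFrame:
    """Median, min and max percent viability per concentration.

    The median of an even-sized roster is the midpoint of the two central
    order statistics (the standard definition).
    """
    if table.percent_viable.empty:
        raise ValidationError("phenotype table is empty")
    pv = table.percent_viable
    out = pd.DataFrame(
        {
            "concentration": table.concentrations,
            "median": pv.median(axis=0).to_numpy(),
            "min": pv.min(axis=0).to_numpy(),
            "max": pv.max(axis=0).to_numpy(),
        }
    )
    return out
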