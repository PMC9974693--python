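"""Odour-activity (aroma-value) scoring of volatile compounds.

The aroma value of a compound is the ratio of its concentration to its
taste threshold in water; values >= 1 mark a likely contribution to the
perceived aroma, and compounds reaching an aroma value of 10 in at least
one sample are retained for calibration-model development.

Concentrations arrive in µg or mg per kg of mash or per litre; mash
density is taken as 1 kg/L so µg/kg and µg/L are numerically
interchangeable, and mg units are converted by a factor of 1000.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ALLOWED_UNITS",
    "AromaValueTable",
    "CompoundDefinition",
    "DEFAULT_MIN_AROMA_VALUE",
    "DEFAULT_INTERNAL_STANDARDS",
    "aroma_value",
    "compute_aroma_values",
    "load_compound_definitions",
    "load_concentrations",
    "model_solution_concentrations",
    "normalize_concentration",
    "reference_compounds",
    "reference_concentration_ranges",
    "round_half_away",
    "select_contributing_compounds",
]

logger = logging.getLogger(__name__)

#: Conversion factors to µg per (kg or L).  µg/kg and µg/L are treated as
#: equivalent (mash density ~ 1 kg/L).
ALLOWED_UNITS: Mapping[str, float] = {
    "ug/kg": 1.0,
    "ug/L": 1.0,
    "µg/kg": 1.0,
    "µg/L": 1.0,
    "mg/kg": 1000.0,
    "mg/L": 1000.0,
}

DEFAULT_MIN_AROMA_VALUE: float = 10.0

#: Compounds spiked into every sample as quantification references; they
#: carry no information about the sample and are excluded from scoring.
DEFAULT_INTERNAL_STANDARDS: tuple[str, ...] = ("2-Heptanone",)


def normalize_concentration(value: float, unit: str) -> float:
    """Express a concentration in µg per kg-or-L.

    Parameters
    ----------
    value
        Non-negative concentration in the given unit.
    unit
        One of ``ug/kg``, ``ug/L``, ``mg/kg``, ``mg/L`` (``µ`` spelling
        accepted).

    Raises
    ------
    ValueError
        If the unit is unknown or the value is negative.
    """
    try:
        factor = ALLOWED_UNITS[unit]
    except KeyError:
        raise ValueError(
            f"unknown concentration unit {unit!r}; expected one of "
            f"{sorted(set(ALLOWED_UNITS))}"
        ) from None
    if value < 0:
        raise ValueError(f"concentration must be non-negative, got {value}")
    return value * factor


def aroma_value(concentration_ug_l: float, threshold_ug_l: float) -> float:
    """Ratio of a concentration (µg/L) to a taste threshold (µg/L)."""
    if threshold_ug_l is None or not threshold_ug_l > 0:
        raise ValueError(
            f"taste threshold must be positive, got {threshold_ug_l!r}"
        )
    if concentration_ug_l < 0:
        raise ValueError(
            f"concentration must be non-negative, got {concentration_ug_l}"
        )
    return concentration_ug_l / threshold_ug_l


def round_half_away(x: float) -> float:
    """Round to the nearest integer with halves away from zero.

    Used when reporting aroma-value ranges (e.g. 18.5 -> 19), unlike
    banker's rounding which would give 18.
    """
    return float(np.sign(x) * np.floor(np.abs(x) + 0.5))


@dataclass(frozen=True)
class CompoundDefinition:
    """A volatile compound and its taste threshold in water (µg/L).

    ``taste_threshold`` may be ``None`` for compounds without a published
    threshold; such compounds are unscorable and are skipped (with a log
    message), never silently scored as zero.
    """

    name: str
    taste_threshold: float | None = None
    threshold_source: str = ""
    attribute_override: str | None = None

    def __post_init__(self) -> None:
        if self.taste_threshold is not None and not self.taste_threshold > 0:
            raise ValueError(
                f"{self.name}: taste threshold must be > 0, "
                f"got {self.taste_threshold}"
            )

    @property
    def scorable(self) -> bool:
        return self.taste_threshold is not None


@dataclass
class AromaValueTable:
    """Per-sample, per-compound aroma values with provenance.

    ``values`` is a sample × compound frame of dimensionless ratios; a
    cell is present only where both a concentration and a threshold
    exist.  ``concentrations_ug_l`` holds the normalized concentrations
    that entered each cell and ``thresholds_ug_l`` the denominators, so
    every value is reconstructible.  ``unscorable`` lists compounds that
    were measured but had no usable threshold.
    """

    values: pd.DataFrame
    concentrations_ug_l: pd.DataFrame
    thresholds_ug_l: pd.Series
    unscorable: tuple[str, ...] = field(default_factory=tuple)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def compounds(self) -> list[str]:
        return list(self.values.columns)

    def max_values(self) -> pd.Series:
        """Maximum aroma value per compound over all samples."""
        return self.values.max(axis=0, skipna=True)

    def rounded_range(self) -> pd.DataFrame:
        """Reported aroma-value range per compound, rounded half-away."""
        lo = self.values.min(axis=0, skipna=True).map(round_half_away)
        hi = self.values.max(axis=0, skipna=True).map(round_half_away)
        return pd.DataFrame({"min": lo, "max": hi})

    def to_long(self) -> pd.DataFrame:
        long = (
            self.values.rename_axis(index="sample_id", columns="compound")
            .stack()
            .rename("aroma_value")
            .reset_index()
        )
        return long


def compute_aroma_values(
    concentrations: pd.DataFrame,
    compounds: Mapping[str, CompoundDefinition],
    *,
    exclude: Iterable[str] = DEFAULT_INTERNAL_STANDARDS,
) -> AromaValueTable:
    """Score a long-format concentration table against taste thresholds.

    Parameters
    ----------
    concentrations
        Columns ``sample_id``, ``compound``, ``value``, ``unit``.
    compounds
        Compound definitions keyed by name.  Measured compounds without a
        definition or without a threshold are collected as unscorable.
    exclude
        Compound names (internal standards) dropped before scoring.
    """
    required = {"sample_id", "compound", "value", "unit"}
    missing = required - set(concentrations.columns)
    if missing:
        raise ValueError(f"concentration table missing columns {sorted(missing)}")
    excluded = set(exclude)
    df = concentrations[~concentrations["compound"].isin(excluded)].copy()
    df["ug_l"] = [
        normalize_concentration(v, u) for v, u in zip(df["value"], df["unit"])
    ]

    unscorable: list[str] = []
    for name in pd.unique(df["compound"]):
        definition = compounds.get(name)
        if definition is None or not definition.scorable:
            unscorable.append(name)
    if unscorable:
        logger.info(
            "excluding %d compound(s) without a taste threshold: %s",
            len(unscorable),
            ", ".join(sorted(unscorable)),
        )
    scorable = df[~df["compound"].isin(unscorable)]

    conc = scorable.pivot_table(
        index="sample_id", columns="compound", values="ug_l", aggfunc="mean"
    )
    thresholds = pd.Series(
        {c: compounds[c].taste_threshold for c in conc.columns}, name="threshold_ug_l"
    ).astype(float)
    values = conc.div(thresholds, axis=1)
    return AromaValueTable(
        values=values,
        concentrations_ug_l=conc,
        thresholds_ug_l=thresholds,
        unscorable=tuple(sorted(unscorable)),
    )


def select_contributing_compounds(
    table: AromaValueTable, min_value: float = DEFAULT_MIN_AROMA_VALUE
) -> list[str]:
    """Compounds whose maximum aroma value reaches or exceeds ``min_value``.

    The boundary is inclusive: a compound peaking at exactly ``min_value``
    is selected.
    """
    if table.values.empty:
        raise ValueError("aroma value table is empty")
    maxima = table.max_values()
    return sorted(maxima.index[maxima >= min_value])


# ---------------------------------------------------------------------------
# Table I/O and bundled reference data


def load_compound_definitions(path) -> dict[str, CompoundDefinition]:
    """Read a ``compounds.csv`` (name, taste_threshold_ug_L,
    threshold_source, attribute_override; empty threshold allowed)."""
    df = pd.read_csv(path)
    required = {"name", "taste_threshold_ug_L"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"compound table missing columns {sorted(missing)}")
    defs: dict[str, CompoundDefinition] = {}
    for row in df.itertuples(index=False):
        name = str(row.name)
        if name in defs:
            raise ValueError(f"duplicate compound name {name!r}")
        threshold = getattr(row, "taste_threshold_ug_L")
        threshold = None if pd.isna(threshold) else float(threshold)
        source = getattr(row, "threshold_source", "")
        override = getattr(row, "attribute_override", None)
        defs[name] = CompoundDefinition(
            name=name,
            taste_threshold=threshold,
            threshold_source="" if pd.isna(source) else str(source),
            attribute_override=None if pd.isna(override) else str(override),
        )
    return defs


def load_concentrations(path) -> pd.DataFrame:
    """Read a long-format concentration table
    (sample_id, compound, value, unit)."""
    df = pd.read_csv(path)
    required = {"sample_id", "compound", "value", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"concentration table missing columns {sorted(missing)}")
    return df


def _data_path(filename: str):
    return resources.files("aromacal.data").joinpath(filename)


def reference_compounds() -> dict[str, CompoundDefinition]:
    """The bundled set of volatiles detected in grape mash, with taste
    thresholds in water (µg/L) where published."""
    with resources.as_file(_data_path("compounds.csv")) as p:
        return load_compound_definitions(p)


def reference_concentration_ranges() -> pd.DataFrame:
    """Published grape-mash concentration ranges as a two-row-per-compound
    long table with pseudo-samples ``range_min`` and ``range_max``."""
    with resources.as_file(_data_path("concentration_ranges.csv")) as p:
        ranges = pd.read_csv(p)
    rows = []
    for row in ranges.itertuples(index=False):
        rows.append(("range_min", row.compound, float(row.conc_min), row.unit))
        rows.append(("range_max", row.compound, float(row.conc_max), row.unit))
    return pd.DataFrame(rows, columns=["sample_id", "compound", "value", "unit"])


def model_solution_concentrations() -> pd.DataFrame:
    """Aroma-compound compositions of the four aqueous grape model
    solutions (A–D) used for sensory evaluation, in µg/L.

    The constant sugar/tartaric-acid matrix (identical in all four
    solutions) is not part of the volatile scoring and is omitted.
    """
    with resources.as_file(_data_path("model_solutions.csv")) as p:
        return load_concentrations(p)
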