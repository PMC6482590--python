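"""UK front-of-pack (FOP) traffic-light classification of food products.

The UK FOP scheme colour-codes four nutrients — total fat, saturated fat
("saturates"), total sugars and salt — as green (low), amber (medium) or red
(high) from their content per 100 g, with a per-portion red override for
products sold in portions larger than 100 g.  The banding criteria are read
from a versioned YAML table shipped with the package
(``data/fop_thresholds_uk.yaml``) so that a different jurisdiction's bands can
be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from importlib import resources
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "Color",
    "NutrientProfile",
    "TrafficLightLabel",
    "ThresholdTable",
    "load_thresholds",
    "classify_nutrient",
    "label_product",
    "label_catalog",
    "LABEL_NUTRIENTS",
    "ConfigurationError",
]

#: the four label nutrients, in canonical order
LABEL_NUTRIENTS = ("fat", "saturates", "sugars", "salt")

#: catalog CSV column for each label nutrient (grams per 100 g)
CATALOG_NUTRIENT_COLUMNS = {
    "fat": "fat_100g",
    "saturates": "satfat_100g",
    "sugars": "sugars_100g",
    "salt": "salt_100g",
}


class ConfigurationError(ValueError):
    """Raised for an unknown nutrient name or an invalid threshold table."""


class Color(IntEnum):
    """Traffic-light colour, ordered by severity (GREEN < AMBER < RED)."""

    GREEN = 0
    AMBER = 1
    RED = 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name.lower()


@dataclass(frozen=True)
class NutrientBands:
    """Banding criteria for one nutrient (grams)."""

    green_max: float        # per 100 g; value <= green_max is GREEN
    amber_max: float        # per 100 g; green_max < value <= amber_max is AMBER
    portion_red: float      # per portion; exceeding it forces RED for portions > 100 g

    def __post_init__(self) -> None:
        if not (0 <= self.green_max <= self.amber_max):
            raise ConfigurationError(
                f"invalid bands: need 0 <= green_max <= amber_max, got "
                f"({self.green_max}, {self.amber_max})"
            )
        if self.portion_red <= 0:
            raise ConfigurationError("portion_red must be positive")


@dataclass(frozen=True)
class ThresholdTable:
    """The full banding table: one :class:`NutrientBands` per label nutrient."""

    nutrients: Mapping[str, NutrientBands]
    portion_override_threshold_g: float = 100.0
    schema: str = "uk-fop-food"

    def __post_init__(self) -> None:
        missing = set(LABEL_NUTRIENTS) - set(self.nutrients)
        if missing:
            raise ConfigurationError(f"threshold table missing nutrients: {sorted(missing)}")

    def bands(self, nutrient: str) -> NutrientBands:
        try:
            return self.nutrients[nutrient]
        except KeyError:
            raise ConfigurationError(
                f"unknown nutrient {nutrient!r}; expected one of {LABEL_NUTRIENTS}"
            ) from None


def load_thresholds(path=None) -> ThresholdTable:
    """Load a threshold table from YAML; default is the packaged UK food table."""
    if path is None:
        text = (resources.files("tlrct") / "data" / "fop_thresholds_uk.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    bands = {
        name: NutrientBands(
            green_max=float(spec["green_max"]),
            amber_max=float(spec["amber_max"]),
            portion_red=float(spec["portion_red"]),
        )
        for name, spec in raw["nutrients"].items()
    }
    return ThresholdTable(
        nutrients=bands,
        portion_override_threshold_g=float(raw.get("portion_override_threshold_g", 100.0)),
        schema=str(raw.get("schema", "unversioned")),
    )


#: packaged UK food thresholds, loaded once
DEFAULT_THRESHOLDS = load_thresholds()


@dataclass(frozen=True)
class NutrientProfile:
    """Label-relevant nutrient content of one product.

    Nutrients are grams per 100 g; ``pack_weight`` is the weight of the whole
    pack in grams and ``portion_weight`` the weight of a single portion
    (defaults to the whole pack).
    """

    fat: float
    saturates: float
    sugars: float
    salt: float
    pack_weight: float
    portion_weight: float | None = None

    def __post_init__(self) -> None:
        for name in LABEL_NUTRIENTS:
            v = getattr(self, name)
            if v is None or v != v or v < 0:
                raise ValueError(f"{name} must be a non-negative number, got {v!r}")
        if self.saturates > self.fat:
            raise ValueError(
                f"saturates ({self.saturates} g) cannot exceed total fat ({self.fat} g)"
            )
        if self.pack_weight <= 0:
            raise ValueError("pack_weight must be positive")
        if self.portion_weight is None:
            object.__setattr__(self, "portion_weight", self.pack_weight)
        elif self.portion_weight <= 0:
            raise ValueError("portion_weight must be positive")


@dataclass(frozen=True)
class TrafficLightLabel:
    """The four-colour FOP label of one product."""

    fat: Color
    saturates: Color
    sugars: Color
    salt: Color

    def colors(self) -> tuple[Color, Color, Color, Color]:
        return (self.fat, self.saturates, self.sugars, self.salt)


def classify_nutrient(
    nutrient: str,
    value_per_100g: float,
    portion_weight: float = 100.0,
    thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
    portion_override: bool = True,
) -> Color:
    """Classify one nutrient value into GREEN / AMBER / RED.

    Band boundaries are inclusive on the less-severe side (a value exactly at
    ``green_max`` is GREEN).  When the portion weighs more than the override
    threshold (100 g) and the per-portion amount exceeds the nutrient's
    ``portion_red`` cap, the colour is forced to RED regardless of the per-100 g
    band; the override can only worsen a colour.
    """
    bands = thresholds.bands(nutrient)
    if value_per_100g is None or value_per_100g != value_per_100g:
        raise ValueError(f"{nutrient}: missing value cannot be classified")
    if value_per_100g < 0:
        raise ValueError(f"{nutrient}: negative value {value_per_100g}")
    if portion_weight <= 0:
        raise ValueError("portion_weight must be positive")

    if value_per_100g <= bands.green_max:
        color = Color.GREEN
    elif value_per_100g <= bands.amber_max:
        color = Color.AMBER
    else:
        color = Color.RED

    if (
        portion_override
        and portion_weight > thresholds.portion_override_threshold_g
        and value_per_100g * portion_weight / 100.0 > bands.portion_red
    ):
        color = Color.RED
    return color


def label_product(
    profile: NutrientProfile,
    thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
    portion_override: bool = True,
) -> TrafficLightLabel:
    """Apply :func:`classify_nutrient` to all four slots of a profile."""
    return TrafficLightLabel(
        *(
            classify_nutrient(
                name,
                getattr(profile, name),
                portion_weight=profile.portion_weight,
                thresholds=thresholds,
                portion_override=portion_override,
            )
            for name in LABEL_NUTRIENTS
        )
    )


def label_catalog(
    catalog: pd.DataFrame,
    thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
    portion_override: bool = True,
) -> pd.DataFrame:
    """Label every product of a catalog table.

    Expects the catalog CSV schema (``fat_100g``, ``satfat_100g``,
    ``sugars_100g``, ``salt_100g``, ``pack_weight_g``, optional
    ``portion_weight_g``).  Returns a copy with one ``<nutrient>_color`` column
    per nutrient (strings, NA where the product cannot be labelled) and a
    boolean ``labelable`` column; a product missing any of the four nutrients
    is not labelled.
    """
    out = catalog.copy()
    nutrient_cols = [CATALOG_NUTRIENT_COLUMNS[n] for n in LABEL_NUTRIENTS]
    labelable = out[nutrient_cols].notna().all(axis=1)
    portion = out.get("portion_weight_g")
    if portion is None:
        portion = out["pack_weight_g"]
    portion = portion.fillna(out["pack_weight_g"])

    values = out[nutrient_cols].to_numpy(dtype=float)
    portions = portion.to_numpy(dtype=float)
    ok = labelable.to_numpy()
    colors: dict[str, list] = {n: [] for n in LABEL_NUTRIENTS}
    for i in range(len(out)):
        for j, n in enumerate(LABEL_NUTRIENTS):
            if not ok[i]:
                colors[n].append(pd.NA)
                continue
            c = classify_nutrient(
                n,
                values[i, j],
                portion_weight=portions[i],
                thresholds=thresholds,
                portion_override=portion_override,
            )
            colors[n].append(c.name.lower())
    for n in LABEL_NUTRIENTS:
        out[f"{n}_color"] = colors[n]
    out["labelable"] = labelable.to_numpy()
    return out
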