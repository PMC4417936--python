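"""Synthetic expression and lifespan data with the structure the decoding analysis assumes.

The generators emulate the experimental design of a dietary-restriction (DR)
study in *C. elegans*: animals are held at one of six discrete bacterial food
concentrations and, per animal, three neuron-pair fluorescence readouts are
measured (*tph-1* transcription in NSM and ADF, *daf-7* in ASI) alongside a
lifespan.  Expression readouts are modelled per (neuron, food) as Gaussian —
the distributional assumption of the downstream Bayes decoder — and lifespans
per (genotype, food) as Weibull.

Default parameters encode the qualitative phenotypes of the study system:

* wildtype ADF expression rises monotonically with food; NSM and ASI are
  non-monotonic with an interior peak, so no single readout identifies the
  food level on its own;
* ``tph1_null`` widens the dynamic range of the expression responses
  (serotonin signalling normally compresses it);
* ``daf7_null`` inflates inter-individual variability and flattens the ASI
  response (TGF-beta signalling normally suppresses noise);
* lifespan responds non-monotonically to food, and the mutants attenuate the
  range of that response while leaving its food-averaged baseline intact —
  the double mutant retains only ~40% of the wildtype range.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, field
from math import gamma as _gamma

import numpy as np
import pandas as pd
import yaml

NEURONS = ("NSM", "ADF", "ASI")

EXPRESSION_COLUMNS = [
    "animal_id", "genotype", "food_label", "food_cells_per_ml", "NSM", "ADF", "ASI",
]
LIFESPAN_COLUMNS = [
    "animal_id", "genotype", "food_label", "food_cells_per_ml", "age_days", "event",
]


@dataclass(frozen=True)
class FoodLevel:
    """One discrete bacterial food concentration (the stimulus class)."""

    label: str
    concentration: float  # bacterial cells/ml

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"concentration must be >= 0, got {self.concentration}")


@dataclass
class GenotypeSpec:
    """Per-genotype generative parameters.

    expr_params maps (neuron, food_label) -> (mean, sd) in intensity AU;
    lifespan_params maps food_label -> (weibull shape, weibull scale in days).
    functional_readouts lists the neurons whose underlying gene is intact —
    a mutant's reporter still fluoresces, but the readout is no longer a
    physiological signal.
    """

    name: str
    functional_readouts: tuple[str, ...]
    expr_params: dict[tuple[str, str], tuple[float, float]]
    lifespan_params: dict[str, tuple[float, float]]

    def validate(self, foods: list[FoodLevel]) -> None:
        for neuron in NEURONS:
            for food in foods:
                key = (neuron, food.label)
                if key not in self.expr_params:
                    raise ValueError(f"{self.name}: missing expr_params for {key}")
                mean, sd = self.expr_params[key]
                if sd < 0:
                    raise ValueError(f"{self.name}: sd < 0 for {key}")
        for food in foods:
            if food.label not in self.lifespan_params:
                raise ValueError(f"{self.name}: missing lifespan_params for {food.label}")
            shape, scale = self.lifespan_params[food.label]
            if shape <= 0 or scale <= 0:
                raise ValueError(f"{self.name}: weibull shape/scale must be > 0 for {food.label}")


@dataclass
class SyntheticConfig:
    foods: list[FoodLevel]
    genotypes: list[GenotypeSpec]
    n_per_condition: int = 120
    seed: int = 0
    truncate_at_zero: bool = False  # False: rejection-resample negatives; True: clip at 0
    censor_fraction: float = 0.0  # fraction of lifespan records right-censored

    def __post_init__(self) -> None:
        if self.n_per_condition < 1:
            raise ValueError("n_per_condition must be >= 1")
        if len(self.foods) < 2:
            raise ValueError("need at least 2 food levels")
        labels = [f.label for f in self.foods]
        if len(set(labels)) != len(labels):
            raise ValueError("food labels must be unique")
        concs = [f.concentration for f in self.foods]
        if sorted(concs) != concs:
            raise ValueError("foods must be ordered by concentration (0 first)")
        for g in self.genotypes:
            g.validate(self.foods)

    def genotype(self, name: str) -> GenotypeSpec:
        for g in self.genotypes:
            if g.name == name:
                return g
        available = ", ".join(g.name for g in self.genotypes)
        raise KeyError(f"unknown genotype {name!r}; available: {available}")


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

#: Six assay concentrations in bacterial cells/ml. Zero food = dietary
#: deprivation; 1e10 approximates ad libitum.
DEFAULT_CONCENTRATIONS = (0.0, 2e5, 2e7, 6e8, 2e9, 1e10)

_FOOD_LABELS = ("F0", "F1", "F2", "F3", "F4", "F5")

# Wildtype per-neuron mean expression across the six foods (AU), shaped so
# that ADF is strictly increasing while NSM and ASI peak at an interior food.
_WT_EXPR_MEANS = {
    "NSM": (50.0, 230.0, 420.0, 330.0, 210.0, 280.0),
    "ADF": (40.0, 130.0, 230.0, 330.0, 440.0, 560.0),
    "ASI": (60.0, 140.0, 320.0, 470.0, 390.0, 310.0),
}
_WT_EXPR_SD = {"NSM": 75.0, "ADF": 85.0, "ASI": 80.0}

# Wildtype mean lifespans (days) across the six foods: extension under
# moderate restriction, decline at zero food and ad libitum. Range 12 d.
_WT_LIFESPAN_MEANS = (24.0, 28.0, 30.0, 24.0, 20.0, 18.0)
_WT_WEIBULL_SHAPE = 5.0

# Per-genotype modifiers: dynamic-range gain applied to deviations of the
# expression means from their profile average, a variability (sd) gain, an
# ASI-specific range gain, and a lifespan-range gain (vs the food-averaged
# baseline). Double mutant lifespan gain 0.4 leaves 4.8/12 d of range.
_GENOTYPE_MODIFIERS = {
    # name: (expr_range_gain, sd_gain, asi_range_gain, lifespan_range_gain)
    "wildtype": (1.0, 1.0, 1.0, 1.0),
    "tph1_null": (1.4, 1.0, 1.4, 0.65),
    "daf7_null": (0.9, 1.8, 0.35, 0.6),
    "double_null": (1.3, 1.5, 0.5, 0.4),
}

_FUNCTIONAL_READOUTS = {
    "wildtype": ("NSM", "ADF", "ASI"),
    "tph1_null": ("ASI",),
    "daf7_null": ("NSM", "ADF"),
    "double_null": (),
}


def _scale_about_mean(values: tuple[float, ...], gain: float, floor: float = 5.0) -> tuple[float, ...]:
    centre = float(np.mean(values))
    return tuple(max(floor, centre + gain * (v - centre)) for v in values)


def _genotype_spec(name: str, foods: list[FoodLevel]) -> GenotypeSpec:
    range_gain, sd_gain, asi_gain, ls_gain = _GENOTYPE_MODIFIERS[name]
    expr_params: dict[tuple[str, str], tuple[float, float]] = {}
    for neuron in NEURONS:
        gain = asi_gain if neuron == "ASI" else range_gain
        means = _scale_about_mean(_WT_EXPR_MEANS[neuron], gain)
        sd = _WT_EXPR_SD[neuron] * sd_gain
        for food, mean in zip(foods, means):
            expr_params[(neuron, food.label)] = (mean, sd)
    lifespan_means = _scale_about_mean(_WT_LIFESPAN_MEANS, ls_gain, floor=1.0)
    # Weibull mean = scale * Gamma(1 + 1/shape); invert for the scale.
    gcorr = _gamma(1.0 + 1.0 / _WT_WEIBULL_SHAPE)
    lifespan_params = {
        food.label: (_WT_WEIBULL_SHAPE, m / gcorr) for food, m in zip(foods, lifespan_means)
    }
    return GenotypeSpec(
        name=name,
        functional_readouts=_FUNCTIONAL_READOUTS[name],
        expr_params=expr_params,
        lifespan_params=lifespan_params,
    )


def default_config(n_per_condition: int = 120, seed: int = 0) -> SyntheticConfig:
    """The default six-food, four-genotype study configuration."""
    foods = [FoodLevel(lab, c) for lab, c in zip(_FOOD_LABELS, DEFAULT_CONCENTRATIONS)]
    genotypes = [_genotype_spec(name, foods) for name in _GENOTYPE_MODIFIERS]
    return SyntheticConfig(foods=foods, genotypes=genotypes,
                           n_per_condition=n_per_condition, seed=seed)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _rng(config: SyntheticConfig, genotype: str, food_idx: int, stream: int) -> np.random.Generator:
    # keyed on the genotype name (not list position) so streams survive
    # config round-trips that reorder the genotype list
    gi = zlib.crc32(genotype.encode())
    return np.random.default_rng([config.seed, stream, gi, food_idx])


def _draw_nonnegative(rng: np.random.Generator, mean: float, sd: float, n: int,
                      clip: bool) -> np.ndarray:
    draws = rng.normal(mean, sd, size=n)
    if clip:
        return np.clip(draws, 0.0, None)
    # rejection resampling: redraw negative values until none remain
    neg = draws < 0
    while neg.any():
        draws[neg] = rng.normal(mean, sd, size=int(neg.sum()))
        neg = draws < 0
    return draws


def generate_expression(config: SyntheticConfig, genotype: str) -> pd.DataFrame:
    """Per-animal neuron-pair intensity table for one genotype.

    Each intensity is the summed fluorescence of the two cells of the pair,
    drawn from the genotype's Normal(mean, sd) for that (neuron, food) and
    constrained to be non-negative.
    """
    spec = config.genotype(genotype)
    rows = []
    for fi, food in enumerate(config.foods):
        rng = _rng(config, genotype, fi, stream=1)
        values = {
            neuron: _draw_nonnegative(
                rng, *spec.expr_params[(neuron, food.label)],
                config.n_per_condition, config.truncate_at_zero)
            for neuron in NEURONS
        }
        for i in range(config.n_per_condition):
            rows.append({
                "animal_id": f"{genotype}-{food.label}-{i:04d}",
                "genotype": genotype,
                "food_label": food.label,
                "food_cells_per_ml": food.concentration,
                **{neuron: values[neuron][i] for neuron in NEURONS},
            })
    return pd.DataFrame(rows, columns=EXPRESSION_COLUMNS)


def generate_lifespans(config: SyntheticConfig, genotype: str) -> pd.DataFrame:
    """Per-animal age-at-death table for one genotype (Weibull per food).

    With ``censor_fraction > 0``, that fraction of animals is right-censored
    at a uniform time before their death age (event flag 0).
    """
    spec = config.genotype(genotype)
    rows = []
    for fi, food in enumerate(config.foods):
        rng = _rng(config, genotype, fi, stream=2)
        shape, scale = spec.lifespan_params[food.label]
        ages = scale * rng.weibull(shape, size=config.n_per_condition)
        events = np.ones(config.n_per_condition, dtype=int)
        if config.censor_fraction > 0:
            censored = rng.random(config.n_per_condition) < config.censor_fraction
            ages = np.where(censored, ages * rng.uniform(0.3, 0.95, size=ages.shape), ages)
            events = np.where(censored, 0, 1)
        for i in range(config.n_per_condition):
            rows.append({
                "animal_id": f"{genotype}-{food.label}-{i:04d}",
                "genotype": genotype,
                "food_label": food.label,
                "food_cells_per_ml": food.concentration,
                "age_days": ages[i],
                "event": int(events[i]),
            })
    return pd.DataFrame(rows, columns=LIFESPAN_COLUMNS)


# ---------------------------------------------------------------------------
# Config serialization (flat YAML mapping)
# ---------------------------------------------------------------------------

def config_to_yaml(config: SyntheticConfig) -> str:
    doc = {
        "seed": config.seed,
        "n_per_condition": config.n_per_condition,
        "truncate_at_zero": config.truncate_at_zero,
        "censor_fraction": config.censor_fraction,
        "foods": {f.label: f.concentration for f in config.foods},
        "genotypes": {
            g.name: {
                "functional_readouts": list(g.functional_readouts),
                "expr_params": {
                    f"{neuron}/{label}": list(v)
                    for (neuron, label), v in g.expr_params.items()
                },
                "lifespan_params": {k: list(v) for k, v in g.lifespan_params.items()},
            }
            for g in config.genotypes
        },
    }
    return yaml.safe_dump(doc, sort_keys=True)


def config_from_yaml(text: str) -> SyntheticConfig:
    doc = yaml.safe_load(io.StringIO(text))
    foods = [FoodLevel(label, float(conc))
             for label, conc in sorted(doc["foods"].items(), key=lambda kv: kv[1])]
    genotypes = []
    for name, g in doc["genotypes"].items():
        expr_params = {}
        for key, (mean, sd) in g["expr_params"].items():
            neuron, label = key.split("/", 1)
            expr_params[(neuron, label)] = (float(mean), float(sd))
        lifespan_params = {k: (float(a), float(b)) for k, (a, b) in g["lifespan_params"].items()}
        genotypes.append(GenotypeSpec(
            name=name,
            functional_readouts=tuple(g["functional_readouts"]),
            expr_params=expr_params,
            lifespan_params=lifespan_params,
        ))
    return SyntheticConfig(
        foods=foods,
        genotypes=genotypes,
        n_per_condition=int(doc["n_per_condition"]),
        seed=int(doc["seed"]),
        truncate_at_zero=bool(doc.get("truncate_at_zero", False)),
        censor_fraction=float(doc.get("censor_fraction", 0.0)),
    )
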