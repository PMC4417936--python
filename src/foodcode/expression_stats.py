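"""Expression summary statistics: normalized mean profiles, dynamic range, variability.

The dynamic range (Delta-F) of one neuron readout within a genotype is the
difference between its highest and lowest per-food mean expression; the
inter-individual variability (sigma) is the standard deviation of the readout
distribution across animals at one food level.  Mean profiles are normalized
to the highest wildtype mean of the respective neuron when a wildtype group
is present, otherwise to the genotype's own highest mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import NEURONS

logger = logging.getLogger(__name__)

REFERENCE_GENOTYPE = "wildtype"


@dataclass
class ProfileSummary:
    """Per-condition summary plus per-(genotype, neuron) dynamic range.

    ``per_condition`` columns: genotype, neuron, food_label, food_cells_per_ml,
    n, mean, sd, sem, normalized_mean.  ``delta_f`` columns: genotype, neuron,
    delta_F. ``sigma`` (sd) is the per-condition ``sd`` column.
    """

    per_condition: pd.DataFrame
    delta_f: pd.DataFrame

    def condition(self, genotype: str, neuron: str, food_label: str) -> pd.Series:
        df = self.per_condition
        sel = df[(df.genotype == genotype) & (df.neuron == neuron) & (df.food_label == food_label)]
        if sel.empty:
            raise KeyError(f"no summary for ({genotype}, {neuron}, {food_label})")
        return sel.iloc[0]


def summarize(table: pd.DataFrame) -> ProfileSummary:
    """Per-(genotype, neuron, food) mean/sd/sem/n plus normalized means and Delta-F.

    Missing neuron values are excluded pairwise per neuron. Conditions with
    n = 1 report sd/sem as NaN; empty groups are dropped with a warning.
    """
    if table.empty:
        raise ValueError("expression table is empty")
    records = []
    for (genotype, food_label), group in table.groupby(["genotype", "food_label"], sort=False):
        conc = group["food_cells_per_ml"].iloc[0]
        for neuron in NEURONS:
            values = group[neuron].dropna().to_numpy(dtype=float)
            n = len(values)
            if n == 0:
                logger.warning("dropping empty group (%s, %s, %s)", genotype, neuron, food_label)
                continue
            mean = float(np.mean(values))
            sd = float(np.std(values, ddof=1)) if n >= 2 else np.nan
            sem = sd / np.sqrt(n) if n >= 2 else np.nan
            records.append({
                "genotype": genotype, "neuron": neuron, "food_label": food_label,
                "food_cells_per_ml": conc, "n": n, "mean": mean, "sd": sd, "sem": sem,
            })
    per_condition = pd.DataFrame.from_records(records)
    per_condition = per_condition.sort_values(
        ["genotype", "neuron", "food_cells_per_ml"]).reset_index(drop=True)

    # normalization reference: highest wildtype mean per neuron if present
    has_wt = (per_condition.genotype == REFERENCE_GENOTYPE).any()
    refs = {}
    for neuron in per_condition.neuron.unique():
        sub = per_condition[per_condition.neuron == neuron]
        if has_wt:
            ref = sub.loc[sub.genotype == REFERENCE_GENOTYPE, "mean"].max()
        else:
            ref = np.nan
        refs[neuron] = ref
    def _norm(row):
        ref = refs[row.neuron]
        if not has_wt or np.isnan(ref):
            sub = per_condition[(per_condition.neuron == row.neuron)
                                & (per_condition.genotype == row.genotype)]
            ref = sub["mean"].max()
        return row["mean"] / ref if ref else np.nan
    per_condition["normalized_mean"] = per_condition.apply(_norm, axis=1)

    delta_rows = []
    for (genotype, neuron), sub in per_condition.groupby(["genotype", "neuron"], sort=True):
        delta_rows.append({
            "genotype": genotype, "neuron": neuron,
            "delta_F": float(sub["mean"].max() - sub["mean"].min()),
        })
    return ProfileSummary(per_condition=per_condition, delta_f=pd.DataFrame(delta_rows))


def dynamic_range(summary: ProfileSummary, genotype: str, neuron: str) -> float:
    """Delta-F: max minus min of the per-food mean expression."""
    sub = summary.per_condition[(summary.per_condition.genotype == genotype)
                                & (summary.per_condition.neuron == neuron)]
    if len(sub) < 2:
        raise ValueError(f"need >= 2 food levels for ({genotype}, {neuron}); have {len(sub)}")
    return float(sub["mean"].max() - sub["mean"].min())


def variability(summary: ProfileSummary, genotype: str, neuron: str, food_label: str) -> float:
    """Sigma: sample sd (n-1 denominator) of the readout at one condition; NaN if n < 2."""
    row = summary.condition(genotype, neuron, food_label)
    return float(row["sd"])
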