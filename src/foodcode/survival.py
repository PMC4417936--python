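"""Lifespan summaries: Kaplan-Meier curves, mean-lifespan profiles, survival tests.

The lifespan response to food is characterised per genotype by its per-food
mean lifespans, the *range* of that profile (highest minus lowest per-food
mean) and its food-independent *baseline* (unweighted average of the per-food
means). Pairwise comparisons use the log-rank test and the early-weighted
Gehan-Breslow-Wilcoxon test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

logger = logging.getLogger(__name__)


@dataclass
class KaplanMeierCurve:
    """Right-continuous product-limit survival estimate."""

    timeline: np.ndarray  # event/censor times, ascending, starting at 0
    survival: np.ndarray  # S(t) at each timeline point
    n_at_risk: np.ndarray

    def __call__(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return out if out.size > 1 else float(out[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.timeline, "survival": self.survival,
                             "n_at_risk": self.n_at_risk})


@dataclass
class LifespanProfile:
    """Per-(genotype, food) mean lifespans plus per-genotype range and baseline."""

    per_condition: pd.DataFrame  # genotype, food_label, food_cells_per_ml, n, mean_lifespan
    per_genotype: pd.DataFrame  # genotype, range_days, baseline_days

    def range_days(self, genotype: str) -> float:
        return float(self.per_genotype.set_index("genotype").loc[genotype, "range_days"])

    def baseline_days(self, genotype: str) -> float:
        return float(self.per_genotype.set_index("genotype").loc[genotype, "baseline_days"])


def kaplan_meier(times, events) -> KaplanMeierCurve:
    """Product-limit estimator; S(0) = 1, steps down at each observed death."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        raise ValueError("Kaplan-Meier requires at least one observed death")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    timeline = sf.index.to_numpy(dtype=float)
    survival = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    return KaplanMeierCurve(timeline=timeline, survival=survival, n_at_risk=at_risk)


def mean_lifespan_profile(table: pd.DataFrame) -> LifespanProfile:
    """Arithmetic mean of observed death ages per (genotype, food), plus range/baseline.

    Censored animals are excluded from the means (counted and logged); the
    baseline is the unweighted average of the per-food means, not the pooled
    per-animal mean.
    """
    n_cens = int((table.event == 0).sum())
    if n_cens:
        logger.info("excluding %d censored animals from mean lifespans", n_cens)
    deaths = table[table.event == 1]
    rows = []
    for (genotype, label), group in deaths.groupby(["genotype", "food_label"], sort=False):
        if group.empty:
            continue
        rows.append({
            "genotype": genotype, "food_label": label,
            "food_cells_per_ml": group.food_cells_per_ml.iloc[0],
            "n": len(group), "mean_lifespan": float(group.age_days.mean()),
        })
    per_condition = pd.DataFrame(rows).sort_values(
        ["genotype", "food_cells_per_ml"]).reset_index(drop=True)
    geno_rows = []
    for genotype, sub in per_condition.groupby("genotype", sort=True):
        means = sub.mean_lifespan.to_numpy()
        geno_rows.append({
            "genotype": genotype,
            "range_days": float(means.max() - means.min()),
            "baseline_days": float(means.mean()),
        })
    return LifespanProfile(per_condition=per_condition, per_genotype=pd.DataFrame(geno_rows))


def range_attenuation(profile: LifespanProfile, reference: str, mutant: str) -> float:
    """Fractional reduction of the lifespan-response range in `mutant` vs `reference`."""
    ref = profile.range_days(reference)
    return (ref - profile.range_days(mutant)) / ref


def _two_sample(groupA: pd.DataFrame | tuple, groupB, weightings: str | None):
    def unpack(g):
        if isinstance(g, pd.DataFrame):
            return g.age_days.to_numpy(float), g.event.to_numpy(int)
        times, events = g
        return np.asarray(times, float), np.asarray(events, int)
    tA, eA = unpack(groupA)
    tB, eB = unpack(groupB)
    if len(tA) == 0 or len(tB) == 0 or eA.sum() == 0 or eB.sum() == 0:
        raise ValueError("both groups must contain observed deaths")
    res = _ll_logrank(tA, tB, event_observed_A=eA, event_observed_B=eB,
                      weightings=weightings)
    return float(res.test_statistic), float(res.p_value)


def logrank_test(groupA, groupB) -> tuple[float, float]:
    """Standard log-rank chi-square (1 df) and two-sided p-value.

    Groups are LifespanTable frames or (times, events) pairs.
    """
    return _two_sample(groupA, groupB, weightings=None)


def wilcoxon_test(groupA, groupB) -> tuple[float, float]:
    """Gehan-Breslow-Wilcoxon test: log-rank weighted by the number at risk."""
    return _two_sample(groupA, groupB, weightings="wilcoxon")
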