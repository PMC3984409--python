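"""Affinity-effect regressions, dual-tail screening, and cross-trial tests.

For each trial and microbial group, the effect index (per plant) is regressed
on the affinity index by ordinary least squares. An OTU is flagged as a
potentially important feedback candidate for a plant when it lies in the
upper or lower ``q`` tail (default 2.5 %) of BOTH the affinity index and that
plant's effect index within the trial. Per-trial candidate counts for the two
plants are compared across trials with a paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from psfscreen.data_model import PLANTS, IndexTable, ValidationError

__all__ = [
    "RegressionResult",
    "ScreenResult",
    "PairedTTestResult",
    "regress_effect_on_affinity",
    "screen_important",
    "count_by_plant",
    "paired_t_test",
    "summarize_significance",
    "significance_code",
]


@dataclass
class RegressionResult:
    trial_id: str
    group: str
    plant: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_otus: int

    @property
    def code(self) -> str:
        return significance_code(self.p_value)


@dataclass
class ScreenResult:
    trial_id: str
    group: str
    q: float
    important_ragweed: set[str]
    important_sunflower: set[str]

    @property
    def counts(self) -> tuple[int, int]:
        return len(self.important_ragweed), len(self.important_sunflower)

    def important(self, plant: str) -> set[str]:
        return self.important_ragweed if plant == "ragweed" else self.important_sunflower


@dataclass
class PairedTTestResult:
    mean_difference: float
    t_statistic: float
    df: int
    p_value: float


def significance_code(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _paired_indices(index_table: IndexTable, plant: str) -> tuple[np.ndarray, np.ndarray]:
    aff = index_table.affinity
    eff = index_table.effect(plant)
    ok = np.isfinite(aff) & np.isfinite(eff)
    return aff[ok], eff[ok]


def regress_effect_on_affinity(index_table: IndexTable, plant: str) -> RegressionResult:
    """OLS of a plant's effect index on the affinity index, one trial x group.

    OTUs missing either index are excluded pairwise. The p-value is the
    two-sided t-test on the slope.
    """
    aff, eff = _paired_indices(index_table, plant)
    if aff.size < 3:
        raise ValidationError("need at least 3 OTUs with both indices")
    if np.allclose(aff, aff[0]):
        raise ValidationError("affinity index has zero variance")
    if np.allclose(eff, eff[0]):
        # constant response: slope 0, no fit; p undefined -> 1
        return RegressionResult(
            index_table.trial_id, index_table.group, plant, 0.0, float(eff[0]), 0.0, 1.0, aff.size
        )
    fit = stats.linregress(aff, eff)
    return RegressionResult(
        trial_id=index_table.trial_id,
        group=index_table.group,
        plant=plant,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n_otus=aff.size,
    )


def _tail_set(otu_ids: Sequence[str], values: np.ndarray, q: float) -> set[str]:
    ok = np.isfinite(values)
    vals = values[ok]
    lo = np.quantile(vals, q)  # linear-interpolation empirical quantile
    hi = np.quantile(vals, 1.0 - q)
    ids = np.asarray(otu_ids, dtype=object)[ok]
    return set(ids[(vals <= lo) | (vals >= hi)])


def screen_important(index_table: IndexTable, plant: str, q: float = 0.025) -> set[str]:
    """OTUs in a tail of affinity AND a tail of the plant's effect index.

    Tails are two-sided: upper or lower ``q`` quantile of the non-missing
    values, ties at the threshold included. Monotone in q.
    """
    if not (0.0 < q < 0.5):
        raise ValidationError("q must lie in (0, 0.5)")
    aff_ok = np.isfinite(index_table.affinity)
    if aff_ok.sum() < np.ceil(1.0 / q):
        import warnings

        warnings.warn("fewer OTUs than 1/q: tail screen may be empty", stacklevel=2)
    a = _tail_set(index_table.otu_ids, index_table.affinity, q)
    e = _tail_set(index_table.otu_ids, index_table.effect(plant), q)
    return a & e


def screen_trial(index_table: IndexTable, q: float = 0.025) -> ScreenResult:
    return ScreenResult(
        trial_id=index_table.trial_id,
        group=index_table.group,
        q=q,
        important_ragweed=screen_important(index_table, "ragweed", q),
        important_sunflower=screen_important(index_table, "sunflower", q),
    )


def count_by_plant(screens: Sequence[ScreenResult]) -> pd.DataFrame:
    """Per-trial candidate counts, rows = trials, columns = group x plant."""
    rows: dict[str, dict[str, int]] = {}
    for s in screens:
        row = rows.setdefault(s.trial_id, {})
        for plant in PLANTS:
            row[f"{s.group}_{plant}"] = len(s.important(plant))
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "trial_id"
    return df


def paired_t_test(counts_a: Sequence[float], counts_b: Sequence[float]) -> PairedTTestResult:
    """Two-sided paired t-test of per-trial counts (a - b)."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValidationError("need two equal-length vectors with >= 2 pairs")
    d = a - b
    if np.allclose(d, d[0]):
        raise ValidationError("all paired differences identical: t undefined")
    t, p = stats.ttest_rel(a, b)
    return PairedTTestResult(
        mean_difference=float(d.mean()),
        t_statistic=float(t),
        df=a.size - 1,
        p_value=float(p),
    )


def summarize_significance(regressions: Sequence[RegressionResult], alpha: float = 0.05) -> float:
    """Fraction of affinity-effect regressions with p below alpha."""
    if not regressions:
        raise ValidationError("no regressions supplied")
    return sum(r.p_value < alpha for r in regressions) / len(regressions)
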