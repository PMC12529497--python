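"""Group comparisons and descriptive tables for condition-level readouts.

Two tests cover the reporting conventions of stiffness/treatment
experiments: one-way fixed-effects ANOVA across all conditions, and
two-sided Mann-Whitney U of each group against the control (exact
enumeration for small samples, normal approximation with tie and
continuity corrections otherwise).  Comparisons against the control are
reported unadjusted by default; Holm correction is available behind a
flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult", "ConditionDataset", "STAR_TIERS", "stars_for_p",
    "compare_anova", "compare_mannwhitney", "summarize_condition",
]

# significance tiers: (p threshold, stars), checked in order.  The top two
# tiers follow the reporting convention adopted here (****: p < 1e-5,
# ***: p < 5e-3); the remaining tiers are the conventional 0.01 / 0.05.
STAR_TIERS: tuple[tuple[float, str], ...] = (
    (1e-5, "****"), (5e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def stars_for_p(p: float,
                tiers: Sequence[tuple[float, str]] = STAR_TIERS) -> str:
    """Map a p-value to its significance stars ('ns' above every tier)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value must be in [0, 1], got {p}")
    for thr, stars in sorted(tiers):
        if p < thr:
            return stars
    return "ns"


@dataclass(frozen=True)
class ComparisonResult:
    """One hypothesis test: statistic, p-value and its star rating."""

    test: str
    groups: tuple[str, ...]
    statistic: float
    pvalue: float
    alpha: float = 0.05
    stars: str = ""

    def __post_init__(self):
        if not 0 <= self.pvalue <= 1:
            raise ValueError("p-value out of [0, 1]")
        if not self.stars:
            object.__setattr__(self, "stars", stars_for_p(self.pvalue))


@dataclass(frozen=True)
class ConditionDataset:
    """Per-cell scalar samples tagged by condition and replicate.

    ``data`` columns: condition, replicate, value; ``variable`` names the
    measured quantity (speed, traction, FA area, ...).
    """

    data: pd.DataFrame
    variable: str = "value"

    def __post_init__(self):
        need = {"condition", "replicate", "value"}
        if not need.issubset(self.data.columns):
            raise ValueError(f"data must have columns {sorted(need)}")
        if self.data.groupby("condition").size().min() < 1:
            raise ValueError("every condition needs at least one sample")

    @classmethod
    def from_samples(cls, samples: Mapping[str, Sequence[float]],
                     variable: str = "value",
                     replicate: str = "r1") -> "ConditionDataset":
        rows = [{"condition": c, "replicate": replicate, "value": v}
                for c, vals in samples.items() for v in vals]
        return cls(pd.DataFrame(rows), variable=variable)

    def groups(self) -> dict[str, np.ndarray]:
        return {c: g["value"].to_numpy()
                for c, g in self.data.groupby("condition", sort=False)}


def _check_group(name: str, x: np.ndarray, min_n: int = 1):
    if len(x) < min_n:
        raise ValueError(f"group {name!r}: need n >= {min_n}, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"group {name!r}: non-finite values")


def compare_anova(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
                  alpha: float = 0.05) -> ComparisonResult:
    """One-way fixed-effects ANOVA across >= 2 groups."""
    if not isinstance(groups, Mapping):
        groups = {f"g{i+1}": g for i, g in enumerate(groups)}
    arrs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrs) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for k, x in arrs.items():
        _check_group(k, x, min_n=2)
    vals = list(arrs.values())
    if all(np.ptp(x) == 0 for x in vals) and len({x[0] for x in vals}) == 1:
        # identical constant groups: no variance anywhere, F is 0/0
        F, p = 0.0, 1.0
    else:
        F, p = sps.f_oneway(*vals)
    return ComparisonResult("one-way ANOVA", tuple(arrs), float(F),
                            float(min(p, 1.0)), alpha)


def compare_mannwhitney(control: Sequence[float],
                        others: Mapping[str, Sequence[float]],
                        control_label: str = "control",
                        alpha: float = 0.05,
                        exact_max_n: int = 20,
                        adjust: str | None = None) -> list[ComparisonResult]:
    """Two-sided Mann-Whitney U of each group against the control.

    Exact enumeration of the U null distribution when both samples have
    ``n <= exact_max_n``; otherwise the normal approximation with tie and
    continuity corrections.  ``adjust='holm'`` applies the Holm step-down
    correction across the comparisons (off by default: each group is
    compared to the control as-is).
    """
    c = np.asarray(control, dtype=float)
    _check_group(control_label, c, min_n=1)
    if len(c) == 0:
        raise ValueError("empty control group")
    results = []
    for name, g in others.items():
        x = np.asarray(g, dtype=float)
        _check_group(name, x, min_n=1)
        method = ("exact" if len(c) <= exact_max_n and len(x) <= exact_max_n
                  else "asymptotic")
        U, p = sps.mannwhitneyu(x, c, alternative="two-sided", method=method)
        results.append(ComparisonResult(
            f"Mann-Whitney U ({method})", (name, control_label),
            float(U), float(min(p, 1.0)), alpha))
    if adjust == "holm":
        ps = np.array([r.pvalue for r in results])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * ps[idx])
            adj[idx] = min(running, 1.0)
        results = [ComparisonResult(r.test + " + Holm", r.groups,
                                    r.statistic, float(adj[i]), r.alpha)
                   for i, r in enumerate(results)]
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return results


def summarize_condition(ds: ConditionDataset) -> pd.DataFrame:
    """Descriptive table per condition: n, mean, SD, median, quartiles and
    1.5*IQR whisker bounds (linear-interpolation quantile convention)."""
    rows = []
    for cond, vals in ds.groups().items():
        q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interp
        iqr = q3 - q1
        inside = vals[(vals >= q1 - 1.5 * iqr) & (vals <= q3 + 1.5 * iqr)]
        rows.append({
            "condition": cond,
            "n": len(vals),
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "whisker_lo": float(inside.min()),
            "whisker_hi": float(inside.max()),
        })
    return pd.DataFrame(rows)
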