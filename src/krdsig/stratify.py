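"""Sample/cell stratification from scores and rank-based group comparisons.

Cells are labeled mutation-like vs wildtype-like above/below a fixed OE
cutoff (the scRNA default is -0.0025, where the bimodal score distribution
separates); bulk samples and risk scores are split at the median into
high/low groups. Ties exactly at a cutoff or at the median go to the lower
group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ValidationError

#: Fixed OE cutoff separating mutation-like from wildtype-like cells in the
#: bimodal single-cell score distribution.
DEFAULT_SC_CUTOFF = -0.0025


@dataclass
class ComparisonResult:
    statistic: float
    pvalue: float
    method: str


def parse_rule(rule: str) -> tuple[str, float | None]:
    """Parse ``"median"`` or ``"cutoff:<c>"`` into a (kind, value) pair."""
    if rule == "median":
        return "median", None
    if rule.startswith("cutoff:"):
        return "cutoff", float(rule.split(":", 1)[1])
    raise ValidationError(f"unknown stratification rule {rule!r}")


def assign_groups(
    scores: pd.Series | Sequence[float],
    rule: str = "median",
    samples: Sequence[str] | None = None,
    labels: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Label each sample by a fixed cutoff or by the score median.

    ``rule`` is ``"median"`` or ``"cutoff:<c>"``. Under the cutoff rule a
    sample is labeled ``mutation_like`` iff its score is strictly above the
    cutoff; under the median rule ``high`` iff strictly above the median
    (ties at the boundary go to the lower group). ``labels`` overrides the
    default (positive, negative) label pair. If every score is identical
    under the median rule, all samples go to the low group with a warning.
    """
    if isinstance(scores, pd.Series):
        if samples is None:
            samples = [str(s) for s in scores.index]
        values = scores.to_numpy(dtype=float)
    else:
        values = np.asarray(scores, dtype=float)
        if samples is None:
            samples = [f"sample{i}" for i in range(values.size)]
    kind, cut = parse_rule(rule)
    if kind == "median":
        if values.size < 2:
            raise ValidationError("median rule needs >= 2 samples")
        if np.ptp(values) == 0:
            warnings.warn("all scores identical; every sample labeled low", stacklevel=2)
        cut = float(np.median(values))
        pos, neg = labels or ("high", "low")
    else:
        pos, neg = labels or ("mutation_like", "wildtype_like")
    out = pd.DataFrame(
        {
            "sample": list(samples),
            "score": values,
            "label": np.where(values > cut, pos, neg),
        }
    )
    out.attrs.update({"rule": rule, "cutoff": cut, "tie_rule": "ties_to_lower"})
    return out


def compare_groups(
    values: Sequence[float], groups: Sequence[str]
) -> ComparisonResult:
    """Compare score distributions across groups.

    Two groups: two-sided Wilcoxon rank-sum, exact when the combined sample
    size is at most 20 and tie-free, otherwise the normal approximation with
    tie correction. Three or more groups: Kruskal-Wallis. Completely
    degenerate data (all values identical) returns statistic 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = list(dict.fromkeys(groups.tolist()))
    parts = [values[groups == g] for g in names]
    if len(names) < 2:
        raise ValidationError("need >= 2 groups to compare")
    if any(p.size == 0 for p in parts):
        raise ValidationError("every group must be nonempty")
    if np.ptp(values) == 0:
        method = "degenerate" if len(names) > 2 else "wilcoxon-exact"
        return ComparisonResult(0.0, 1.0, method)
    if len(names) == 2:
        n = values.size
        exact = n <= 20 and np.unique(values).size == n
        res = scipy.stats.mannwhitneyu(
            parts[0], parts[1], alternative="two-sided",
            method="exact" if exact else "asymptotic",
        )
        return ComparisonResult(
            float(res.statistic), float(res.pvalue),
            "wilcoxon-exact" if exact else "wilcoxon-normal",
        )
    stat, p = scipy.stats.kruskal(*parts)
    return ComparisonResult(float(stat), float(p), "kruskal-wallis")


def find_bimodal_cutoff(scores: Sequence[float], seed: int = 0) -> float:
    """Locate the valley between the two modes of a bimodal score vector.

    Fits a two-component Gaussian mixture and returns the point between the
    component means where their weighted densities cross (the decision
    boundary); falls back to the midpoint of the means if no crossing lies
    between them.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(scores, dtype=float).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, n_init=5, random_state=seed).fit(x)
    means = gm.means_.ravel()
    lo, hi = float(means.min()), float(means.max())
    grid = np.linspace(lo, hi, 2001)
    resp = gm.predict_proba(grid.reshape(-1, 1))
    hi_comp = int(np.argmax(means))
    crossing = np.nonzero(np.diff((resp[:, hi_comp] > 0.5).astype(int)))[0]
    if crossing.size:
        return float(0.5 * (grid[crossing[0]] + grid[crossing[0] + 1]))
    return float(0.5 * (lo + hi))
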