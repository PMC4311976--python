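"""Per-section summary statistics and group significance testing.

Individual values at a section level are the arithmetic mean of that
individual's 360 radial measurements; groups are compared with one-way
ANOVA followed by the Student-Newman-Keuls (SNK) stepwise range test on
ordered group means, reporting significant ordered pairs ("X > Y").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CANONICAL_FRACTIONS = (35.0, 50.0, 65.0)


def _fraction_row(fraction: float, fractions: np.ndarray) -> int:
    diffs = np.abs(np.asarray(fractions, dtype=float) - fraction)
    row = int(np.argmin(diffs))
    if diffs[row] > 1e-6:
        raise ValueError(f"no section at {fraction}% length")
    return row


def section_summary(
    maps_by_group: Mapping[str, Sequence[np.ndarray]],
    fraction: float,
    fractions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Group mean, sd and range of per-individual section means.

    ``maps_by_group`` holds (n_sections x 360) property matrices per
    individual (raw mm / mm^4 values for unscaled tables, standardized
    values otherwise).  ``fraction`` is the section level in percent of
    length; levels other than 35/50/65 are allowed but flagged.
    """
    if fractions is None:
        from .phantom import SECTION_FRACTIONS

        fractions = SECTION_FRACTIONS
    if fraction not in CANONICAL_FRACTIONS:
        warnings.warn(f"non-canonical section level {fraction}%")
    row = _fraction_row(fraction, fractions)
    records = []
    for group, arrs in maps_by_group.items():
        means = np.array([np.asarray(a, dtype=float)[row].mean() for a in arrs])
        records.append(
            dict(
                group=group,
                fraction_pct=fraction,
                n=len(means),
                mean=means.mean(),
                sd=means.std(ddof=1) if len(means) > 1 else 0.0,
                min=means.min(),
                max=means.max(),
            )
        )
    return pd.DataFrame(records)


def individual_section_means(
    maps_by_group: Mapping[str, Sequence[np.ndarray]],
    fraction: float,
    fractions: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Per-group arrays of individual 360-ray means at one section level."""
    if fractions is None:
        from .phantom import SECTION_FRACTIONS

        fractions = SECTION_FRACTIONS
    row = _fraction_row(fraction, fractions)
    return {
        g: np.array([np.asarray(a, dtype=float)[row].mean() for a in arrs])
        for g, arrs in maps_by_group.items()
    }


@dataclass
class AnovaSNKResult:
    f_statistic: float
    p_value: float
    significant_pairs: list[str]  # ordered "X > Y" comparisons at alpha
    table: pd.DataFrame  # per-pair q statistics and critical values
    ms_within: float
    df_within: int


def anova_snk(groups: Mapping[str, np.ndarray], alpha: float = 0.05) -> AnovaSNKResult:
    """One-way ANOVA plus Student-Newman-Keuls post hoc ordering.

    SNK compares ordered group means stepwise: the range spanning r means
    uses the studentized-range critical value q(alpha, r, df_within); a
    non-significant range blocks all ranges nested inside it.  The
    standard error uses the harmonic-mean allowance
    sqrt(MSw/2 * (1/n_i + 1/n_j)) so unequal group sizes are handled.
    """
    labels = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(labels) < 2 or any(len(d) < 2 for d in data):
        raise ValueError("need >= 2 groups with n >= 2 each")
    allvals = np.concatenate(data)
    n_total = allvals.size
    k = len(labels)
    if np.allclose(allvals, allvals[0]):
        return AnovaSNKResult(
            f_statistic=float("nan"), p_value=1.0, significant_pairs=[],
            table=pd.DataFrame(), ms_within=0.0, df_within=n_total - k,
        )
    f_stat, p_val = stats.f_oneway(*data)

    means = np.array([d.mean() for d in data])
    ns = np.array([len(d) for d in data])
    ssw = sum(((d - d.mean()) ** 2).sum() for d in data)
    df_w = n_total - k
    msw = ssw / df_w
    order = np.argsort(means)[::-1]  # descending
    om, on = means[order], ns[order]
    olab = [labels[i] for i in order]

    blocked: list[tuple[int, int]] = []
    rows = []
    pairs: list[str] = []
    for r in range(k, 1, -1):
        for i in range(0, k - r + 1):
            j = i + r - 1
            if any(i >= bi and j <= bj for bi, bj in blocked):
                continue
            se = np.sqrt(msw / 2.0 * (1.0 / on[i] + 1.0 / on[j])) if msw > 0 else 0.0
            diff = om[i] - om[j]
            if se == 0.0:
                q_obs = np.inf if diff > 0 else 0.0
            else:
                q_obs = diff / se
            q_crit = stats.studentized_range.ppf(1.0 - alpha, r, df_w)
            sig = bool(q_obs > q_crit)
            rows.append(
                dict(high=olab[i], low=olab[j], span=r, diff=diff,
                     q=q_obs, q_crit=q_crit, significant=sig)
            )
            if sig:
                pairs.append(f"{olab[i]} > {olab[j]}")
            else:
                blocked.append((i, j))
    return AnovaSNKResult(
        f_statistic=float(f_stat), p_value=float(p_val),
        significant_pairs=pairs, table=pd.DataFrame(rows),
        ms_within=float(msw), df_within=int(df_w),
    )


def summary_table(
    maps_by_group: Mapping[str, Sequence[np.ndarray]],
    property_name: str,
    fractions_pct: Sequence[float] = CANONICAL_FRACTIONS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Summary table (mean / sd / range / significant comparisons) per level."""
    blocks = []
    for frac in fractions_pct:
        summ = section_summary(maps_by_group, frac)
        res = anova_snk(individual_section_means(maps_by_group, frac), alpha=alpha)
        summ.insert(0, "property", property_name)
        summ["anova_F"] = res.f_statistic
        summ["anova_p"] = res.p_value
        summ["significant"] = "; ".join(res.significant_pairs)
        blocks.append(summ)
    return pd.concat(blocks, ignore_index=True)
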