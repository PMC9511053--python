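"""Paired before/after statistics, one-way ANOVA with Šídák correction,
and percent-change summaries.

The paired test is the classical two-tailed Student t on the within-unit
differences (Welch has no meaning for paired data; for the unpaired group
comparisons a Welch toggle exists but classical Student is the default).
Percent changes are reported exactly and in a "tilde-integer" mode that
truncates toward zero, the rounding rule consistent with headline "∼"
figures like 44.34 → ∼44.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "NephronRecord",
    "PairedTResult",
    "AnovaSidakResult",
    "paired_t",
    "sidak_adjust",
    "anova_sidak",
    "percent_change",
    "summarize_groups",
    "records_from_table",
    "VALID_GROUPS",
    "VALID_MEASURES",
]

VALID_GROUPS = ("placebo", "enalapril", "empagliflozin", "enalapril_empagliflozin")
VALID_MEASURES = ("sngfr_nl_min", "aff_diam_um", "eff_diam_um", "glom_vol_um3")


@dataclass(frozen=True)
class NephronRecord:
    """One paired before/after measurement of one nephron or glomerulus."""

    animal_id: str
    unit_id: str
    group: str
    measure: str
    value_before: float
    value_after: float

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(f"invalid group {self.group!r}; expected one of {VALID_GROUPS}")
        if self.measure not in VALID_MEASURES:
            raise ValueError(f"invalid measure {self.measure!r}; expected one of {VALID_MEASURES}")
        if not (math.isfinite(self.value_before) and math.isfinite(self.value_after)):
            raise ValueError("paired analysis requires finite before and after values")


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    mean_difference: float
    flags: list[str] = field(default_factory=list)


def paired_t(before, after) -> PairedTResult:
    """Two-tailed paired Student t-test; df = n − 1.

    Computed directly as the one-sample t on the differences
    ``d = after − before``: ``t = mean(d) / (sd(d)/√n)``.

    Degenerate conventions (documented): identical pairs give ``t = 0,
    p = 1`` with a ``zero_variance`` flag; zero-variance differences with a
    nonzero mean give ``p = 0.0`` (below machine resolution) with the same
    flag.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before and after must be 1D arrays of equal length")
    n = len(before)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    if not (np.all(np.isfinite(before)) and np.all(np.isfinite(after))):
        raise ValueError("non-finite values in paired data")

    d = after - before
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    df = n - 1
    if sd_d == 0.0:
        if mean_d == 0.0:
            return PairedTResult(t=0.0, df=df, p=1.0, mean_difference=0.0,
                                 flags=["zero_variance"])
        return PairedTResult(
            t=math.copysign(math.inf, mean_d), df=df, p=0.0,
            mean_difference=mean_d, flags=["zero_variance"],
        )
    t = mean_d / (sd_d / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return PairedTResult(t=float(t), df=df, p=p, mean_difference=mean_d)


def sidak_adjust(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Šídák multiple-comparison adjustment ``p_adj = 1 − (1 − p)^m``, capped at 1."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):  # p = 1 -> log1p(-1) = -inf -> adj = 1
        adj = np.minimum(1.0, -np.expm1(m * np.log1p(-p_arr)))
    return float(adj) if np.isscalar(p) or p_arr.ndim == 0 else adj


@dataclass
class AnovaSidakResult:
    f: float
    p: float
    df_between: int
    df_within: int
    comparisons: pd.DataFrame  # columns: group_a, group_b, t, df, p, p_adj


def anova_sidak(
    groups: dict[str, np.ndarray] | list[np.ndarray],
    comparisons: list[tuple] | None = None,
    equal_var: bool = True,
) -> AnovaSidakResult:
    """One-way ANOVA followed by Šídák-adjusted pairwise t-tests.

    ``comparisons`` selects the pairwise contrasts (default: all pairs);
    each pairwise p is adjusted by ``1 − (1 − p)^m`` with ``m`` the number
    of requested comparisons. ``equal_var=False`` switches the pairwise
    tests to Welch.
    """
    if isinstance(groups, dict):
        labels = list(groups)
        values = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        values = [np.asarray(g, dtype=float) for g in groups]
        labels = list(range(len(values)))
    if len(values) < 2:
        raise ValueError("need at least two groups")
    for lab, v in zip(labels, values):
        if len(v) == 0:
            raise ValueError(f"group {lab!r} is empty")
        if len(v) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 values")

    f, p = sps.f_oneway(*values)
    n_total = sum(len(v) for v in values)
    dfb, dfw = len(values) - 1, n_total - len(values)

    pairs = comparisons if comparisons is not None else list(combinations(labels, 2))
    m = len(pairs)
    by_label = dict(zip(labels, values))
    rows = []
    for a, b in pairs:
        res = sps.ttest_ind(by_label[a], by_label[b], equal_var=equal_var)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "t": float(res.statistic),
                "df": float(res.df),
                "p": float(res.pvalue),
                "p_adj": sidak_adjust(float(res.pvalue), m),
            }
        )
    return AnovaSidakResult(
        f=float(f), p=float(p), df_between=dfb, df_within=dfw,
        comparisons=pd.DataFrame(rows),
    )


def percent_change(mean_before: float, mean_after: float, mode: str = "exact"):
    """Percent reduction ``100 × (1 − after/before)``.

    ``mode='exact'`` returns the float; ``mode='tilde'`` truncates toward
    zero to an integer percent for comparison with headline "∼" figures.
    """
    if mean_before <= 0:
        raise ValueError("mean_before must be positive")
    pct = 100.0 * (1.0 - mean_after / mean_before)
    if mode == "exact":
        return pct
    if mode == "tilde":
        return math.trunc(pct)
    raise ValueError("mode must be 'exact' or 'tilde'")


def records_from_table(table: pd.DataFrame) -> list[NephronRecord]:
    """Build validated records from a tidy table with the record columns."""
    needed = ["animal_id", "unit_id", "group", "measure", "value_before", "value_after"]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"table missing columns: {missing}")
    return [
        NephronRecord(
            animal_id=str(r.animal_id),
            unit_id=str(r.unit_id),
            group=str(r.group),
            measure=str(r.measure),
            value_before=float(r.value_before),
            value_after=float(r.value_after),
        )
        for r in table.itertuples()
    ]


def summarize_groups(
    records: list[NephronRecord],
    unit: str = "nephron",
) -> pd.DataFrame:
    """Per (group, measure) summary: n, mean ± SD before/after, paired t, % change.

    ``unit='nephron'`` treats each nephron/glomerulus as one pair (matching
    per-unit paired plots); ``unit='animal'`` first averages units within
    each animal — a sensitivity analysis against pseudo-replication. With a
    single pair the SD is undefined and flagged rather than reported as 0.
    A caveat is logged when animal counts differ between groups.
    """
    if unit not in ("nephron", "animal"):
        raise ValueError("unit must be 'nephron' or 'animal'")
    if not records:
        raise ValueError("no records")

    df = pd.DataFrame([r.__dict__ for r in records])
    if unit == "animal":
        df = (
            df.groupby(["group", "measure", "animal_id"], as_index=False)
            .agg(value_before=("value_before", "mean"), value_after=("value_after", "mean"))
        )
        df["unit_id"] = df["animal_id"]

    rows = []
    for (group, measure), sub in df.groupby(["group", "measure"], sort=True):
        before = sub["value_before"].to_numpy(dtype=float)
        after = sub["value_after"].to_numpy(dtype=float)
        n = len(sub)
        flags: list[str] = []
        if n >= 2:
            res = paired_t(before, after)
            t_stat, p_val = res.t, res.p
            flags += res.flags
            sd_b = float(np.std(before, ddof=1))
            sd_a = float(np.std(after, ddof=1))
        else:
            t_stat = p_val = float("nan")
            sd_b = sd_a = float("nan")
            flags.append("sd_undefined")
        mean_b = float(np.mean(before))
        mean_a = float(np.mean(after))
        pct = percent_change(mean_b, mean_a) if mean_b > 0 else float("nan")
        rows.append(
            {
                "group": group,
                "measure": measure,
                "n_animals": int(sub["animal_id"].nunique()),
                "n_measurements": n,
                "mean_before": mean_b,
                "sd_before": sd_b,
                "mean_after": mean_a,
                "sd_after": sd_a,
                "test": "paired t (two-tailed)",
                "t": t_stat,
                "p": p_val,
                "percent_change": pct,
                "flags": ";".join(flags),
            }
        )
    out = pd.DataFrame(rows)
    for measure, sub in out.groupby("measure"):
        if sub["n_animals"].nunique() > 1:
            log.info(
                "unbalanced design for %s: animal counts differ between groups (%s)",
                measure, dict(zip(sub["group"], sub["n_animals"])),
            )
    return out
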