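"""Population summaries and significance testing.

Replicate-level cell-type counts and fractions (debris never enters a
denominator), seeded subsampling of measurement vectors, and the
significance procedure used throughout: one-way ANOVA followed by all
pairwise post hoc comparisons with Bonferroni correction at alpha = 0.05.
Proportions are compared on per-replicate fraction values, not pooled
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

ALPHA_DEFAULT = 0.05


def bonferroni_adjust(raw_ps, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: ``min(1, m * p)`` per comparison."""
    ps = np.asarray(raw_ps, dtype=float)
    m = len(ps) if m is None else m
    return np.minimum(1.0, m * ps)


@dataclass
class SampleRecord:
    replicate: str
    condition: str
    timepoint_h: float
    counts: dict[str, int]
    n_counted: int                    # debris excluded
    stalked_fraction: float           # (ST + PD) / n_counted
    mean_length_um: float = np.nan
    sd_length_um: float = np.nan
    mean_stalk_length_um: float = np.nan
    sd_stalk_length_um: float = np.nan
    empty: bool = False


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    t_stat: float
    raw_p: float
    adjusted_p: float
    significant: bool


@dataclass
class TestResult:
    f_stat: float
    df_between: int
    df_within: int
    raw_p: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    alpha: float = ALPHA_DEFAULT
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.pairwise])


def summarize(
    records: pd.DataFrame,
    group_cols: tuple[str, ...] = ("replicate", "condition", "timepoint_h"),
) -> list[SampleRecord]:
    """Aggregate per-cell records into replicate-level counts and fractions.

    ``records`` must carry ``final_type`` plus the grouping columns; length
    columns are summarized when present. Groups with no non-debris cells
    are returned flagged empty with an undefined fraction.
    """
    out: list[SampleRecord] = []
    for keys, grp in records.groupby(list(group_cols), sort=True, dropna=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        counts = grp["final_type"].value_counts().to_dict()
        counts = {k: int(v) for k, v in counts.items()}
        n_counted = int(sum(v for k, v in counts.items() if k != "debris"))
        stalked = sum(counts.get(k, 0) for k in ("ST", "PD", "stalked"))
        nondebris = grp[grp["final_type"] != "debris"]
        rec = SampleRecord(
            replicate=str(keys[0]),
            condition=str(keys[1]) if len(keys) > 1 else "",
            timepoint_h=float(keys[2]) if len(keys) > 2 else np.nan,
            counts=counts,
            n_counted=n_counted,
            stalked_fraction=stalked / n_counted if n_counted else np.nan,
            empty=n_counted == 0,
        )
        if n_counted and "cell_length_um" in grp:
            rec.mean_length_um = float(nondebris["cell_length_um"].mean())
            rec.sd_length_um = float(nondebris["cell_length_um"].std(ddof=1))
        if n_counted and "stalk_length_um" in grp:
            with_stalk = nondebris[nondebris["stalk_length_um"] > 0]
            if len(with_stalk):
                rec.mean_stalk_length_um = float(with_stalk["stalk_length_um"].mean())
                rec.sd_stalk_length_um = float(with_stalk["stalk_length_um"].std(ddof=1))
        out.append(rec)
    return out


def subsample_measurements(
    values: np.ndarray | pd.Series, n: int, seed: int = 0
) -> tuple[np.ndarray, bool]:
    """Uniformly subsample ``n`` values without replacement (seeded).

    Mirrors the study's fixed-size measurement samples (450 cells for cell
    length, 300 for stalk length). Groups smaller than ``n`` are returned
    whole with an under-size flag.
    """
    arr = np.asarray(values)
    if len(arr) <= n:
        return arr.copy(), len(arr) < n
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(arr), size=n, replace=False))
    return arr[idx], False


def anova_bonferroni(
    groups: dict[str, np.ndarray] | list[np.ndarray],
    alpha: float = ALPHA_DEFAULT,
    welch_pairwise: bool = False,
) -> TestResult:
    """One-way ANOVA plus Bonferroni-corrected pairwise post hoc t tests.

    ``F = (SSB/dfB) / (SSW/dfW)``; pairwise tests are pooled-variance two
    sample t tests by default (Welch by option); each raw p is multiplied
    by the number of pairs and capped at 1. Zero within-group variance
    with equal means yields an explicit degenerate result (F undefined).
    """
    if isinstance(groups, dict):
        names = list(groups.keys())
        data = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        names = [f"group{i}" for i in range(len(groups))]
        data = [np.asarray(g, dtype=float) for g in groups]
    if len(data) < 2:
        raise ValueError("need at least two groups")
    for name, g in zip(names, data):
        if len(g) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        if not np.all(np.isfinite(g)):
            raise ValueError(f"group {name!r} contains non-finite values")

    k = len(data)
    n_total = sum(len(g) for g in data)
    grand = np.concatenate(data).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in data)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in data)
    df_b, df_w = k - 1, n_total - k

    if ssw == 0 and ssb == 0:
        return TestResult(
            f_stat=np.nan, df_between=df_b, df_within=df_w,
            raw_p=np.nan, alpha=alpha, degenerate=True,
        )
    if ssw == 0:
        f_stat, raw_p = np.inf, 0.0
    else:
        f_stat = (ssb / df_b) / (ssw / df_w)
        raw_p = float(stats.f.sf(f_stat, df_b, df_w))

    pairs = []
    m = k * (k - 1) // 2
    for (ia, a), (ib, b) in combinations(enumerate(names), 2):
        ga, gb = data[ia], data[ib]
        t, p = stats.ttest_ind(ga, gb, equal_var=not welch_pairwise)
        adj = float(bonferroni_adjust([float(p)], m)[0]) if np.isfinite(p) else np.nan
        pairs.append(PairwiseComparison(
            group_a=a, group_b=b, t_stat=float(t), raw_p=float(p),
            adjusted_p=adj, significant=bool(adj <= alpha),
        ))
    return TestResult(
        f_stat=float(f_stat), df_between=df_b, df_within=df_w,
        raw_p=raw_p, pairwise=pairs, alpha=alpha,
    )


def sample_records_frame(records: list[SampleRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {k: v for k, v in r.__dict__.items() if k != "counts"}
        for cls, n in sorted(r.counts.items()):
            row[f"n_{cls}"] = n
        rows.append(row)
    return pd.DataFrame(rows)
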