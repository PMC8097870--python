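"""Group comparisons of normalised rates: one-way ANOVA + Tukey HSD.

Classical equal-variance ANOVA (no Welch correction) followed by all
pairwise comparisons with studentized-range adjusted p values; unbalanced
designs use the Tukey-Kramer standard error.  Each replicate value is
treated as one independent observation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """'*' p<0.05, '**' p<0.01, '***' p<0.001, '****' p<0.0001, else 'ns'."""
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return "ns"


@dataclass
class GroupData:
    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise DataError("need at least 2 groups")
        for k, v in self.groups.items():
            if v.ndim != 1 or v.size < 2:
                raise DataError(f"group {k!r} needs at least 2 values")

    @classmethod
    def from_csv(cls, path: str | Path) -> "GroupData":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls({k: g["value"].to_numpy() for k, g in df.groupby("group")})

    def to_csv(self, path: str | Path) -> None:
        rows = [{"group": k, "value": v} for k, vals in self.groups.items() for v in vals]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class ComparisonResult:
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # label_a, label_b, mean_diff, p_adj, stars


def one_way_anova(data: GroupData) -> tuple[float, float]:
    """Between/within mean-square F ratio and its p value.

    Degenerate inputs: zero variance everywhere with equal means gives
    F = 0, p = 1; zero within-group variance with unequal means gives
    F = inf, p = 0.
    """
    samples = list(data.groups.values())
    grand = np.concatenate(samples)
    ssb = sum(s.size * (s.mean() - grand.mean()) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    if ssw == 0.0:
        return (0.0, 1.0) if ssb == 0.0 else (np.inf, 0.0)
    f, p = sps.f_oneway(*samples)
    return float(f), float(p)


def tukey_hsd(data: GroupData) -> pd.DataFrame:
    """All-pairs Tukey HSD table with studentized-range adjusted p values.

    For exactly two groups the adjusted p equals the pooled-variance t-test
    p (the q = sqrt(2)*|t| identity), computed in that closed form to avoid
    quadrature error in the studentized-range tail.
    """
    labels = list(data.groups)
    samples = [data.groups[k] for k in labels]
    if len(labels) == 2:
        a, b = samples
        t, p = sps.ttest_ind(a, b, equal_var=True)
        rows = [{"label_a": labels[0], "label_b": labels[1],
                 "mean_diff": float(a.mean() - b.mean()), "p_adj": float(p),
                 "stars": significance_stars(float(p))}]
        return pd.DataFrame(rows)
    res = sps.tukey_hsd(*samples)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            p = float(np.clip(res.pvalue[i, j], 0.0, 1.0))
            rows.append({"label_a": labels[i], "label_b": labels[j],
                         "mean_diff": float(samples[i].mean() - samples[j].mean()),
                         "p_adj": p, "stars": significance_stars(p)})
    return pd.DataFrame(rows)


def compare_groups(data: GroupData) -> ComparisonResult:
    f, p = one_way_anova(data)
    return ComparisonResult(f_statistic=f, p_value=p, pairwise=tukey_hsd(data))


def write_report(result: ComparisonResult, csv_path: str | Path,
                 text_path: str | Path | None = None) -> None:
    result.pairwise.to_csv(csv_path, index=False)
    if text_path is not None:
        lines = [f"one-way ANOVA: F = {result.f_statistic:.4g}, p = {result.p_value:.4g}", ""]
        for _, r in result.pairwise.iterrows():
            lines.append(f"{r.label_a} vs {r.label_b}: diff = {r.mean_diff:+.4g}, "
                         f"p_adj = {r.p_adj:.4g} {r.stars}")
        Path(text_path).write_text("\n".join(lines) + "\n")
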