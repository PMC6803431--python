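"""Growth-trial metrics and cohort comparison.

Two growth metrics are reported side by side: the specific growth rate
SGR = 100 x (ln W_final - ln W_initial) / days (% per day) and the
simple weight-gain rate 100 x (W_final - W_initial) / W_initial (%).
Both appear in aquaculture growth trials and are not interchangeable, so
outputs always label which is which.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .stats import anova_tukey, welch_t


@dataclass(frozen=True)
class GrowthRecord:
    individual: str
    group: str
    initial_g: float
    final_g: float
    days: int

    def __post_init__(self) -> None:
        if self.initial_g <= 0 or self.final_g <= 0:
            raise ValidationError("weights must be positive")
        if self.days <= 0:
            raise ValidationError("trial days must be positive")


def sgr(initial_g: float, final_g: float, days: float) -> float:
    """Specific growth rate, percent body weight per day."""
    if initial_g <= 0 or final_g <= 0:
        raise ValidationError("weights must be positive")
    if days <= 0:
        raise ValidationError("days must be positive")
    return 100.0 * (math.log(final_g) - math.log(initial_g)) / days


def weight_gain_rate(initial_g: float, final_g: float) -> float:
    """Relative weight gain over the whole trial, percent."""
    if initial_g <= 0 or final_g <= 0:
        raise ValidationError("weights must be positive")
    return 100.0 * (final_g - initial_g) / initial_g


def growth_metrics(records) -> pd.DataFrame:
    """Per-individual SGR and weight-gain rate."""
    rows = [
        (r.individual, r.group, r.initial_g, r.final_g, r.days,
         sgr(r.initial_g, r.final_g, r.days),
         weight_gain_rate(r.initial_g, r.final_g))
        for r in records
    ]
    return pd.DataFrame(rows, columns=[
        "individual", "group", "initial_g", "final_g", "days",
        "sgr_pct_per_day", "weight_gain_pct",
    ])


def compare_growth(metrics: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Group comparison of final weights and SGR.

    Three or more groups go through one-way ANOVA + Tukey HSD; exactly
    two through a Welch t test. Keys of the pairwise maps are group-name
    pairs.
    """
    groups = list(metrics["group"].unique())
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups to compare")
    by_group = {g: metrics[metrics["group"] == g] for g in groups}
    if any(len(sub) < 2 for sub in by_group.values()):
        raise ValidationError("each group needs n >= 2")
    out: dict = {"groups": groups}
    for col, label in (("final_g", "final_weight"), ("sgr_pct_per_day", "sgr")):
        samples = [by_group[g][col].to_numpy() for g in groups]
        if len(groups) >= 3:
            res = anova_tukey(samples, alpha=alpha)
            out[label] = {
                "omnibus_p": res.omnibus_p,
                "pairwise": {
                    f"{groups[i]}-{groups[j]}": {"p": p, "significant": res.significant[(i, j)]}
                    for (i, j), p in res.pairwise_p.items()
                },
            }
        else:
            t, p = welch_t(samples[0], samples[1])
            out[label] = {
                "omnibus_p": p,
                "pairwise": {f"{groups[0]}-{groups[1]}": {"p": p, "significant": p < alpha}},
            }
    return out


def read_growth_table(path: str | Path) -> list[GrowthRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"individual", "group", "initial_g", "final_g", "days"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"growth table missing columns {sorted(missing)}")
    return [
        GrowthRecord(str(r.individual), str(r.group),
                     float(r.initial_g), float(r.final_g), int(r.days))
        for r in df.itertuples()
    ]
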