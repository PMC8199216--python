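"""Active/inactive discrimination statistics over per-compound score tables.

Scores are binding-affinity-like quantities in kcal/mol (docking scores,
intramolecular-H-bond-rewarded docking scores, MM-GBSA binding free
energies) where more negative is more favorable. Activity labels are
inputs — compounds with a determined IC50 are labelled active — and are
never inferred from the scores themselves.

Quartiles use linear interpolation between order statistics (numpy's
default, the "type 7" convention); the convention is embedded in every
report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ifpkit.errors import ConfigurationError

__all__ = [
    "ScoreTable",
    "GroupStats",
    "group_summary",
    "separation_assessment",
    "compare_score_kinds",
]

ACTIVE, INACTIVE = "active", "inactive"


@dataclass
class ScoreTable:
    """Per-compound scores with activity labels for one score kind."""

    compounds: list
    scores: np.ndarray
    activities: list
    kind: str = "score"

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.compounds)
        if not (len(self.scores) == len(self.activities) == n):
            raise ConfigurationError("compounds/scores/activities length mismatch")
        bad = set(self.activities) - {ACTIVE, INACTIVE}
        if bad:
            raise ConfigurationError(f"unknown activity labels {sorted(bad)}")
        if len(set(self.compounds)) != n:
            raise ConfigurationError(f"duplicate compound labels in kind {self.kind!r}")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kind: str = "score") -> "ScoreTable":
        """Build from a table with columns compound, score, activity."""
        return cls(compounds=df["compound"].tolist(),
                   scores=df["score"].to_numpy(dtype=float),
                   activities=df["activity"].tolist(), kind=kind)

    def group(self, activity: str) -> np.ndarray:
        mask = np.array([a == activity for a in self.activities])
        return self.scores[mask]


def _five_number(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    return {
        "n": int(len(values)),
        "mean": float(values.mean()),
        "min": float(values.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(values.max()),
        "whisker_low": float(q1 - 1.5 * iqr),
        "whisker_high": float(q3 + 1.5 * iqr),
    }


@dataclass
class GroupStats:
    """Box-plot summaries of both activity groups plus the mean gap."""

    kind: str
    active: dict
    inactive: dict
    mean_gap: float
    overlap: bool
    quartile_method: str = "linear interpolation (type 7)"
    separation: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, stats in (("active", self.active), ("inactive", self.inactive)):
            rows.append({"kind": self.kind, "group": name, **stats,
                         "mean_gap": self.mean_gap, "overlap": self.overlap})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "active": self.active,
                "inactive": self.inactive, "mean_gap": self.mean_gap,
                "overlap": self.overlap,
                "quartile_method": self.quartile_method,
                "separation": self.separation}


def group_summary(table: ScoreTable) -> GroupStats:
    """Five-number summary + mean per group and the between-group mean gap."""
    act = table.group(ACTIVE)
    inact = table.group(INACTIVE)
    for name, vals in ((ACTIVE, act), (INACTIVE, inact)):
        if len(vals) == 0:
            raise ConfigurationError(
                f"score kind {table.kind!r}: group {name!r} is empty")
    a = _five_number(act)
    i = _five_number(inact)
    gap = abs(a["mean"] - i["mean"])
    sep = separation_assessment(table)
    return GroupStats(kind=table.kind, active=a, inactive=i, mean_gap=gap,
                      overlap=sep["overlap"], separation=sep)


def separation_assessment(table: ScoreTable) -> dict:
    """Best single-threshold separation of the two groups.

    Scans the midpoints of adjacent sorted scores (plus one threshold below
    the minimum and one above the maximum) and classifies a compound as
    active iff its score is <= the threshold (more negative = more
    favorable). Returns the threshold minimizing misclassifications (ties
    resolved toward the more negative threshold), the misclassification
    count, and an overlap flag (True iff no threshold separates perfectly).
    """
    act = table.group(ACTIVE)
    inact = table.group(INACTIVE)
    if len(act) == 0 or len(inact) == 0:
        raise ConfigurationError(
            f"score kind {table.kind!r}: both activity groups required")
    srt = np.sort(table.scores)
    candidates = [float(srt[0]) - 1.0]
    candidates += [float(0.5 * (srt[k] + srt[k + 1])) for k in range(len(srt) - 1)]
    candidates += [float(srt[-1]) + 1.0]
    best_t, best_m = None, None
    for t in candidates:  # ascending, so the first minimum is the most negative
        mis = int(np.sum(act > t) + np.sum(inact <= t))
        if best_m is None or mis < best_m:
            best_t, best_m = t, mis
    return {"threshold": best_t, "misclassifications": best_m,
            "overlap": best_m > 0,
            "rule": "active iff score <= threshold"}


def compare_score_kinds(tables) -> pd.DataFrame:
    """Rank score kinds by discriminating power.

    Returns one row per kind with its group means, mean gap, best threshold
    and misclassification count, ranked by (misclassifications ascending,
    mean gap descending); exact ties keep input order and are flagged.
    """
    if len(tables) < 2:
        raise ConfigurationError("need >= 2 score kinds to compare")
    rows = []
    for order, t in enumerate(tables):
        g = group_summary(t)
        rows.append({
            "kind": t.kind,
            "n_active": g.active["n"], "n_inactive": g.inactive["n"],
            "mean_active": g.active["mean"], "mean_inactive": g.inactive["mean"],
            "mean_gap": g.mean_gap,
            "misclassifications": g.separation["misclassifications"],
            "threshold": g.separation["threshold"],
            "overlap": g.overlap,
            "_order": order,
        })
    df = pd.DataFrame(rows)
    df = df.sort_values(["misclassifications", "mean_gap", "_order"],
                        ascending=[True, False, True], kind="stable")
    df["rank"] = range(1, len(df) + 1)
    key = df[["misclassifications", "mean_gap"]].apply(tuple, axis=1)
    df["tied"] = key.duplicated(keep=False)
    return df.drop(columns="_order").reset_index(drop=True)
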