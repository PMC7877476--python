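"""Behavioral scoring and expertise-behavior correlations.

Behavioral performance is the ratio of correct trials to all scheduled
trials; unanswered trials (no button press within the response window) count
as incorrect.  Scalar correlations between expertise ratings and task
performance are Pearson r with a two-tailed p from the t distribution on
n - 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import CategoryScheme

__all__ = ["CorrelationResult", "performance", "behavioral_chance",
           "correlate", "behavioral_summary"]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t: float
    p: float  # two-tailed

    @property
    def df(self) -> int:
        return self.n - 2


def performance(record: pd.DataFrame) -> float:
    """Proportion correct out of all trials; unanswered counts as incorrect."""
    if len(record) == 0:
        raise ValueError("empty behavioral record")
    return float((record["outcome"] == "correct").sum() / len(record))


def behavioral_chance(task: str = "category",
                      scheme: CategoryScheme | None = None) -> float:
    """Expected accuracy of uniform guessing over the offered choices.

    task="category": every trial offers the 4 categories -> 0.25.
    task="subcategory" (post-scan assessment): each trial offers the
    subcategories of its own category (3 choices for three categories, 2 for
    the category containing the size-12 class); the expectation is weighted
    by trial frequency -> 0.375 for the default scheme.
    """
    scheme = scheme or CategoryScheme()
    if task == "category":
        return 1.0 / len(scheme.categories)
    if task != "subcategory":
        raise ValueError(f"unknown task {task!r}")
    total = sum(scheme.class_sizes.values())
    chance = 0.0
    for cat in scheme.categories:
        subs = [s for s in scheme.subcategories if scheme.parent[s] == cat]
        n_stim = sum(scheme.class_sizes[s] for s in subs)
        chance += (n_stim / total) * (1.0 / len(subs))
    return chance


def correlate(x, y) -> CorrelationResult:
    """Pearson correlation with exact t statistic and two-tailed p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    if abs(r) >= 1:
        t = float(np.sign(r) * np.inf)
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return CorrelationResult(r=r, n=n, t=float(t), p=float(p))


def behavioral_summary(cohort: pd.DataFrame,
                       records: dict[str, pd.DataFrame],
                       session: str = "fMRI") -> pd.DataFrame:
    """Per-subject performance table (subject, session, task, performance,
    chance) from raw per-trial records."""
    rows = []
    for sid, rec in records.items():
        for task in rec["task"].unique():
            sub = rec[rec["task"] == task]
            rows.append({
                "subject_id": sid, "session": session, "task": task,
                "performance": performance(sub),
                "chance": behavioral_chance(task),
            })
    return pd.DataFrame(rows)
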