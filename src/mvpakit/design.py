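"""Stimulus set and trial schedule construction.

The experiment presents 72 code snippets organised in a two-level label
hierarchy: 4 functional categories of 18 snippets each, subdivided into 11
concrete-algorithm subcategories (ten of size 6 and one of size 12).  Each
snippet is shown three times over 6 runs of 36 task trials, at most once per
run, with the per-run category frequency held exactly uniform (9 per run).
Every trial is 16 s long: 2 s fixation, 10 s code display, 4 s response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CategoryScheme",
    "StimulusSchedule",
    "SchemeError",
    "SchedulingError",
    "build_stimulus_set",
    "make_schedule",
    "run_duration_seconds",
    "write_events_tsv",
    "read_events_tsv",
]

FIXATION_S = 2.0
CODE_S = 10.0
RESPONSE_S = 4.0
TRIAL_S = FIXATION_S + CODE_S + RESPONSE_S  # 16 s


class SchemeError(ValueError):
    """A category scheme violates its structural constraints."""


class SchedulingError(RuntimeError):
    """The schedule constraint set could not be satisfied."""


@dataclass(frozen=True)
class CategoryScheme:
    """Two-level stimulus label hierarchy.

    Defaults use placeholder subcategory names; only the size structure
    (4 categories x 18 stimuli; ten subcategories of 6, one of 12) matters
    downstream.
    """

    categories: tuple[str, ...] = ("math", "search", "sort", "string")
    subcategories: tuple[str, ...] = (
        "math_a", "math_b", "math_c",
        "linear_search", "binary_search",
        "bubble_sort", "insertion_sort", "selection_sort",
        "string_a", "string_b", "string_c",
    )
    parent: dict[str, str] = field(default_factory=lambda: {
        "math_a": "math", "math_b": "math", "math_c": "math",
        "linear_search": "search", "binary_search": "search",
        "bubble_sort": "sort", "insertion_sort": "sort",
        "selection_sort": "sort",
        "string_a": "string", "string_b": "string", "string_c": "string",
    })
    class_sizes: dict[str, int] = field(default_factory=lambda: {
        "math_a": 6, "math_b": 6, "math_c": 6,
        "linear_search": 12, "binary_search": 6,
        "bubble_sort": 6, "insertion_sort": 6, "selection_sort": 6,
        "string_a": 6, "string_b": 6, "string_c": 6,
    })

    def validate(self) -> None:
        if len(self.categories) != 4:
            raise SchemeError(
                f"expected 4 categories, got {len(self.categories)}")
        if len(self.subcategories) != 11:
            raise SchemeError(
                f"expected 11 subcategories, got {len(self.subcategories)}")
        if set(self.parent) != set(self.subcategories):
            raise SchemeError("parent mapping must cover every subcategory")
        if set(self.class_sizes) != set(self.subcategories):
            raise SchemeError("class_sizes must cover every subcategory")
        sizes = sorted(self.class_sizes.values())
        if sizes != [6] * 10 + [12]:
            raise SchemeError(
                f"subcategory sizes must be ten 6s and one 12, got {sizes}")
        for cat in self.categories:
            subs = [s for s in self.subcategories if self.parent[s] == cat]
            total = sum(self.class_sizes[s] for s in subs)
            if total != 18:
                raise SchemeError(
                    f"category {cat!r} sizes sum to {total}, expected 18")
            big = [s for s in subs if self.class_sizes[s] == 12]
            if big and len(subs) != 2:
                raise SchemeError(
                    f"the size-12 subcategory's category {cat!r} must have "
                    f"exactly 2 subcategories, got {len(subs)}")
        if sum(self.class_sizes.values()) != 72:
            raise SchemeError("total stimulus count must be 72")


@dataclass(frozen=True)
class StimulusSchedule:
    """Trial-level schedule: one row per task trial across all runs."""

    entries: pd.DataFrame  # run, trial, stimulus_id, category, subcategory, onset
    n_runs: int = 6
    trials_per_run: int = 36
    dummy_trials_per_run: int = 1

    @property
    def n_trials(self) -> int:
        return len(self.entries)

    def run_entries(self, run: int) -> pd.DataFrame:
        return self.entries[self.entries["run"] == run]

    def validate(self) -> None:
        df = self.entries
        if len(df) != self.n_runs * self.trials_per_run:
            raise SchedulingError("trial count mismatch")
        counts = df.groupby("stimulus_id").size()
        if not (counts == 3).all():
            raise SchedulingError("every stimulus must appear exactly 3 times")
        per_run = df.groupby(["run", "stimulus_id"]).size()
        if (per_run > 1).any():
            raise SchedulingError("a stimulus appeared twice within a run")
        cat_per_run = df.groupby(["run", "category"]).size()
        if not (cat_per_run == self.trials_per_run // 4).all():
            raise SchedulingError("category counts per run are not balanced")
        for run in range(1, self.n_runs + 1):
            onsets = self.run_entries(run)["onset"].to_numpy()
            if not np.all(np.diff(onsets) > 0):
                raise SchedulingError(f"onsets not increasing in run {run}")


def build_stimulus_set(scheme: CategoryScheme | None = None) -> pd.DataFrame:
    """Enumerate the 72 stimulus records (id, category, subcategory)."""
    scheme = scheme or CategoryScheme()
    scheme.validate()
    rows = []
    sid = 0
    for sub in scheme.subcategories:
        for _ in range(scheme.class_sizes[sub]):
            rows.append({
                "stimulus_id": f"stim{sid:03d}",
                "category": scheme.parent[sub],
                "subcategory": sub,
            })
            sid += 1
    return pd.DataFrame(rows)


def _assign_runs(stimuli: pd.DataFrame, n_runs: int, trials_per_run: int,
                 rng: np.random.Generator, max_attempts: int = 1000
                 ) -> list[list[int]]:
    """Pick which runs each stimulus appears in (3 of n_runs each) so that
    each run holds exactly trials_per_run stimuli with uniform category counts.

    Rejection sampling run by run: fill runs sequentially, drawing from
    stimuli that still need appearances and have not been used in this run,
    respecting the per-run per-category quota.
    """
    n_stim = len(stimuli)
    cats = stimuli["category"].to_numpy()
    cat_labels = sorted(set(cats))
    quota_per_cat = trials_per_run // len(cat_labels)

    for _ in range(max_attempts):
        remaining = np.full(n_stim, 3)
        runs: list[list[int]] = []
        ok = True
        for run in range(n_runs):
            runs_left = n_runs - run
            chosen: list[int] = []
            for cat in cat_labels:
                idx = np.flatnonzero((cats == cat) & (remaining > 0))
                # stimuli that must appear in every remaining run go first
                must = idx[remaining[idx] == runs_left]
                if len(must) > quota_per_cat:
                    ok = False
                    break
                pool = idx[remaining[idx] < runs_left]
                need = quota_per_cat - len(must)
                if need > len(pool):
                    ok = False
                    break
                pick = rng.choice(pool, size=need, replace=False)
                chosen.extend(must.tolist())
                chosen.extend(pick.tolist())
            if not ok:
                break
            remaining[chosen] -= 1
            runs.append(chosen)
        if ok and (remaining == 0).all():
            return runs
    raise SchedulingError(
        f"could not satisfy schedule constraints in {max_attempts} attempts")


def make_schedule(stimuli: pd.DataFrame | None = None, n_runs: int = 6,
                  trials_per_run: int = 36, seed: int = 0,
                  dummy_trials_per_run: int = 1) -> StimulusSchedule:
    """Build a pseudo-randomized schedule under the balancing constraints.

    Each stimulus appears 3 times total, at most once per run; each run holds
    an equal number of trials from every category.  Deterministic given seed.
    """
    if stimuli is None:
        stimuli = build_stimulus_set()
    if n_runs * trials_per_run != 3 * len(stimuli):
        raise SchedulingError(
            f"{n_runs} runs x {trials_per_run} trials != "
            f"3 x {len(stimuli)} stimuli")
    rng = np.random.default_rng(seed)
    run_members = _assign_runs(stimuli, n_runs, trials_per_run, rng)

    rows = []
    dummy_offset = dummy_trials_per_run * TRIAL_S
    for run, members in enumerate(run_members, start=1):
        order = rng.permutation(members)
        # response-button mapping is randomized per trial for fidelity;
        # it has no downstream computational effect
        buttons = [rng.permutation(4) for _ in order]
        for t, (i, btn) in enumerate(zip(order, buttons), start=1):
            rec = stimuli.iloc[int(i)]
            rows.append({
                "run": run,
                "trial": t,
                "stimulus_id": rec["stimulus_id"],
                "category": rec["category"],
                "subcategory": rec["subcategory"],
                "onset": dummy_offset + (t - 1) * TRIAL_S,
                "duration": CODE_S,
                "button_map": "".join(str(b) for b in btn),
            })
    schedule = StimulusSchedule(
        entries=pd.DataFrame(rows), n_runs=n_runs,
        trials_per_run=trials_per_run,
        dummy_trials_per_run=dummy_trials_per_run)
    schedule.validate()
    return schedule


def run_duration_seconds(schedule: StimulusSchedule) -> float:
    """Total run duration: (task trials + dummy trials) x 16 s."""
    return (schedule.trials_per_run + schedule.dummy_trials_per_run) * TRIAL_S


def write_events_tsv(schedule: StimulusSchedule, path) -> None:
    """Write a BIDS-events-like TSV (onset/duration in s, run/trial 1-based)."""
    cols = ["onset", "duration", "run", "trial",
            "stimulus_id", "category", "subcategory"]
    schedule.entries[cols].to_csv(path, sep="\t", index=False)


def read_events_tsv(path, n_runs: int = 6, trials_per_run: int = 36,
                    dummy_trials_per_run: int = 1) -> StimulusSchedule:
    df = pd.read_csv(path, sep="\t")
    return StimulusSchedule(entries=df, n_runs=n_runs,
                            trials_per_run=trials_per_run,
                            dummy_trials_per_run=dummy_trials_per_run)
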