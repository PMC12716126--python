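"""Behavioral scoring of IGT data and manipulation-check statistics.

The primary behavioral outcome is the number of draws from the winning
decks (C and D) in the final 60 of 100 trials. Also here: per-deck choice
proportions, block-wise deck preference tables (5 blocks of 20 trials),
Cohen's d for manipulation checks, and the preregistered mood-responder
filter (negative-mood subjects must show a mood decrease of at least 3
points; neutral-mood subjects at most a 2-point change in either
direction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .orl_core import SubjectTrials
from .synthetic_study import StudyDataset
from .task_env import DECK_INDEX, DECKS

WINNING_IDX = (DECK_INDEX["C"], DECK_INDEX["D"])


def winning_draws_final60(trials: SubjectTrials, permissive: bool = False) -> int:
    """Count of C/D choices among trials 41-100.

    Requires exactly 100 trials; with ``permissive=True`` shorter series
    are scored over their last 60% (with a warning).
    """
    n = trials.n_trials
    if n == 100:
        window = trials.choices[40:]
    elif permissive:
        warnings.warn(f"subject {trials.subject}: {n} trials, scoring last 60%")
        window = trials.choices[int(round(0.4 * n)):]
    else:
        raise ValueError(f"expected exactly 100 trials, got {n} (use permissive=True)")
    return int(np.isin(window, WINNING_IDX).sum())


def deck_proportions(data: SubjectTrials | StudyDataset) -> pd.Series:
    """Selection fraction per deck over all trials (pooled for a study)."""
    if isinstance(data, StudyDataset):
        choices = np.concatenate([s.trials.choices for s in data.subjects])
    else:
        choices = data.choices
    if len(choices) == 0:
        raise ValueError("no trials")
    counts = np.bincount(choices, minlength=5)[1:5]
    return pd.Series(counts / counts.sum(), index=list(DECKS), name="proportion")


def block_preferences(study: StudyDataset, block_size: int = 20) -> pd.DataFrame:
    """Per-condition x block x deck proportion table (heatmap-ready, long).

    Rows: alcohol, mood, block (1-based), deck, proportion. Within each
    condition and block the four deck proportions sum to 1.
    """
    rows = []
    for (alcohol, mood), group in _by_cell(study):
        n_trials = group[0].trials.n_trials
        if n_trials % block_size != 0:
            raise ValueError(f"block_size {block_size} does not divide {n_trials} trials")
        n_blocks = n_trials // block_size
        choices = np.array([s.trials.choices for s in group])  # (n, T)
        for b in range(n_blocks):
            block = choices[:, b * block_size:(b + 1) * block_size]
            counts = np.bincount(block.ravel(), minlength=5)[1:5]
            props = counts / counts.sum()
            for d, deck in enumerate(DECKS):
                rows.append(
                    {"alcohol": alcohol, "mood": mood, "block": b + 1,
                     "deck": deck, "proportion": props[d]}
                )
    return pd.DataFrame(rows)


def _by_cell(study: StudyDataset):
    for alcohol in (0, 1):
        for mood in (0, 1):
            group = [s for s in study.subjects if s.alcohol == alcohol and s.mood == mood]
            if group:
                yield (alcohol, mood), group


def behavior_table(study: StudyDataset, permissive: bool = False) -> pd.DataFrame:
    """Per-subject behavioral summary: winning-deck score and deck proportions."""
    rows = []
    for s in study.subjects:
        props = deck_proportions(s.trials)
        rows.append(
            {
                "subject": s.subject,
                "alcohol": s.alcohol,
                "mood": s.mood,
                "winning_final60": winning_draws_final60(s.trials, permissive=permissive),
                **{f"prop_{d}": props[d] for d in DECKS},
            }
        )
    return pd.DataFrame(rows).set_index("subject")


def cohens_d(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Standardized mean difference (mean_a - mean_b) / pooled SD."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        raise ValueError("pooled SD is zero; effect size undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


@dataclass
class FilterResult:
    """Outcome of the mood-responder filter."""

    kept: StudyDataset
    excluded: list[tuple[str, str]]  # (subject, reason)

    @property
    def n_kept(self) -> int:
        return self.kept.n_subjects

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def mood_responder_filter(study: StudyDataset) -> FilterResult:
    """Preregistered exclusion of subjects who did not respond to the induction.

    Negative-mood condition: kept iff mood change (post - pre) <= -3, i.e. a
    decrease of exactly 3 counts as responding. Neutral condition: kept iff
    |change| <= 2. Missing ratings exclude the subject with reason
    "missing". Idempotent: filtering a filtered study removes nobody.
    """
    kept_ids: list[str] = []
    excluded: list[tuple[str, str]] = []
    for s in study.subjects:
        if s.mood_pre is None or s.mood_post is None or not (
            np.isfinite(s.mood_pre) and np.isfinite(s.mood_post)
        ):
            excluded.append((s.subject, "missing"))
            continue
        change = s.mood_post - s.mood_pre
        if s.mood == 1:
            if change <= -3:
                kept_ids.append(s.subject)
            else:
                excluded.append((s.subject, f"negative-mood non-responder (change {change:+.0f})"))
        else:
            if abs(change) <= 2:
                kept_ids.append(s.subject)
            else:
                excluded.append((s.subject, f"neutral-mood shifter (change {change:+.0f})"))
    return FilterResult(kept=study.subset(kept_ids), excluded=excluded)
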