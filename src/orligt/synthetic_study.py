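"""Synthetic 2x2 study generator.

Emulates a between-subjects alcohol (0/1) x mood-induction (0/1) design:
40 subjects per cell, each playing 100 IGT trials, with condition effects
injected on the reward learning rate (alcohol +0.13, negative mood +0.12,
no interaction, on the raw rate scale) and none on the punishment learning
rate. Cell (0, 0) is anchored at a reward rate of 0.167 and punishment
rate of 0.091. Mood/stress/intoxication ratings are generated so that
manipulation-check and responder-filter code can be exercised; they are
independent of choice behaviour by default.

Every subject's true parameters are kept in the dataset (the truth
manifest), which is what makes parameter-recovery studies possible.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .orl_core import OUTCOME_DIVISOR, ORLParams, PARAM_NAMES, SubjectTrials, simulate_agent
from .task_env import DECKS, PayoffSchedule, make_classic_schedule

CELLS = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of the synthetic study.

    Learning-rate cell means are ``base + alcohol_effect*alcohol +
    mood_effect*mood + interaction*alcohol*mood`` on the raw rate scale,
    truncated to (0, 1) when sampling subjects. The K', beta_F and beta_P
    population values are package choices (see docs/methods.md); they are
    tuned to produce a realistic deck-B-leaning choice pattern.
    """

    n_per_cell: int = 40
    n_trials: int = 100
    # reward learning rate: base mean and injected condition effects
    a_rew_base: float = 0.167
    a_rew_alcohol: float = 0.13
    a_rew_mood: float = 0.12
    a_rew_interaction: float = 0.0
    a_rew_sd: float = 0.18
    # punishment learning rate: no condition effects by default
    a_pun_base: float = 0.091
    a_pun_alcohol: float = 0.0
    a_pun_mood: float = 0.0
    a_pun_interaction: float = 0.0
    a_pun_sd: float = 0.06
    # population values for the remaining parameters (artifact choices)
    k_prime_mean: float = 0.3
    k_prime_sd: float = 0.5
    beta_f_mean: float = 1.5
    beta_f_sd: float = 0.5
    beta_p_mean: float = 1.0
    beta_p_sd: float = 0.5
    # manipulation-check generators: (mean, sd) of change / rating scores
    mood_change_negative: tuple[float, float] = (-3.19, 1.76)
    mood_change_neutral: tuple[float, float] = (-0.01, 1.32)
    stress_change_negative: tuple[float, float] = (4.05, 2.26)
    stress_change_neutral: tuple[float, float] = (0.35, 1.62)
    intox_alcohol: tuple[float, float] = (4.96, 1.85)
    intox_sober: tuple[float, float] = (1.06, 0.33)
    outcome_divisor: float = OUTCOME_DIVISOR
    seed: int = 0

    def a_rew_mean(self, alcohol: int, mood: int) -> float:
        return (
            self.a_rew_base
            + self.a_rew_alcohol * alcohol
            + self.a_rew_mood * mood
            + self.a_rew_interaction * alcohol * mood
        )

    def a_pun_mean(self, alcohol: int, mood: int) -> float:
        return (
            self.a_pun_base
            + self.a_pun_alcohol * alcohol
            + self.a_pun_mood * mood
            + self.a_pun_interaction * alcohol * mood
        )

    def validate(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for alcohol, mood in CELLS:
            for name, mean in (
                ("a_rew", self.a_rew_mean(alcohol, mood)),
                ("a_pun", self.a_pun_mean(alcohol, mood)),
            ):
                if not 0.0 < mean < 1.0:
                    raise ValueError(
                        f"{name} cell mean {mean:.3f} for cell {(alcohol, mood)} "
                        "falls outside (0, 1)"
                    )


@dataclass
class Subject:
    """One subject: trials, condition labels, ratings, and (synthetic) truth."""

    subject: str
    alcohol: int
    mood: int
    trials: SubjectTrials
    mood_pre: float
    mood_post: float
    stress_pre: float
    stress_post: float
    intox: float
    true_params: ORLParams | None = None

    @property
    def mood_change(self) -> float:
        return self.mood_post - self.mood_pre


@dataclass
class StudyDataset:
    """A complete study: subjects with trials, labels, and ratings."""

    subjects: list[Subject]
    synthetic: bool = False
    config: StudyConfig | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def all_trials(self) -> list[SubjectTrials]:
        return [s.trials for s in self.subjects]

    def metadata(self) -> pd.DataFrame:
        """Per-subject condition labels and ratings as a DataFrame."""
        return pd.DataFrame(
            {
                "subject": [s.subject for s in self.subjects],
                "alcohol": [s.alcohol for s in self.subjects],
                "mood": [s.mood for s in self.subjects],
                "mood_pre": [s.mood_pre for s in self.subjects],
                "mood_post": [s.mood_post for s in self.subjects],
                "stress_pre": [s.stress_pre for s in self.subjects],
                "stress_post": [s.stress_post for s in self.subjects],
                "intox": [s.intox for s in self.subjects],
            }
        )

    def subset(self, subject_ids: list[str]) -> "StudyDataset":
        keep = set(subject_ids)
        return StudyDataset(
            subjects=[s for s in self.subjects if s.subject in keep],
            synthetic=self.synthetic,
            config=self.config,
        )


@lru_cache(maxsize=256)
def _truncnorm_location(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location whose (lo, hi)-truncated normal has the requested mean.

    Truncation shifts the realized mean away from the location parameter;
    solving for the location keeps the documented cell means exact.
    """

    def realized_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(stats.truncnorm.mean(a, b, loc=loc, scale=sd))

    span = hi - lo
    return float(optimize.brentq(
        lambda loc: realized_mean(loc) - mean, lo - 10 * sd - span, hi + 10 * sd + span, xtol=1e-10
    ))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    loc = _truncnorm_location(mean, sd, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return float(stats.truncnorm.rvs(a, b, loc=loc, scale=sd, random_state=rng))


def generate_params(config: StudyConfig, cell: tuple[int, int], seed: int | np.random.Generator) -> ORLParams:
    """Sample one subject's true ORL parameters for a design cell.

    Bounded parameters (learning rates, K') come from truncated normals so
    cell means stay interpretable on the raw scale; beta_F and beta_P are
    unbounded and come from plain normals.
    """
    config.validate()
    alcohol, mood = cell
    if alcohol not in (0, 1) or mood not in (0, 1):
        raise ValueError(f"cell must be a pair of 0/1 indicators, got {cell}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = 1e-6
    return ORLParams(
        a_rew=_truncated_normal(rng, config.a_rew_mean(alcohol, mood), config.a_rew_sd, eps, 1 - eps),
        a_pun=_truncated_normal(rng, config.a_pun_mean(alcohol, mood), config.a_pun_sd, eps, 1 - eps),
        k_prime=_truncated_normal(rng, config.k_prime_mean, config.k_prime_sd, eps, 5 - eps),
        beta_f=float(rng.normal(config.beta_f_mean, config.beta_f_sd)),
        beta_p=float(rng.normal(config.beta_p_mean, config.beta_p_sd)),
    )


def _rating(rng: np.random.Generator, mean: float, sd: float) -> float:
    return float(np.clip(np.round(rng.normal(mean, sd)), 1, 10))


def generate_study(config: StudyConfig | None = None, schedule: PayoffSchedule | None = None) -> StudyDataset:
    """Generate a full synthetic study, reproducible from ``config.seed``."""
    config = config or StudyConfig()
    config.validate()
    schedule = schedule or make_classic_schedule()
    master = np.random.default_rng(config.seed)
    subjects: list[Subject] = []
    sid = itertools.count(1)
    for alcohol, mood in CELLS:
        for _ in range(config.n_per_cell):
            rng = np.random.default_rng(master.integers(0, 2**31 - 1))
            params = generate_params(config, (alcohol, mood), rng)
            name = f"S{next(sid):03d}"
            trials = simulate_agent(
                params, schedule, config.n_trials, rng, subject=name,
                outcome_divisor=config.outcome_divisor,
            )
            mood_mu, mood_sd = config.mood_change_negative if mood else config.mood_change_neutral
            stress_mu, stress_sd = config.stress_change_negative if mood else config.stress_change_neutral
            intox_mu, intox_sd = config.intox_alcohol if alcohol else config.intox_sober
            mood_pre = _rating(rng, 7.0, 1.2)
            stress_pre = _rating(rng, 3.0, 1.2)
            subjects.append(
                Subject(
                    subject=name,
                    alcohol=alcohol,
                    mood=mood,
                    trials=trials,
                    mood_pre=mood_pre,
                    mood_post=float(np.clip(np.round(mood_pre + rng.normal(mood_mu, mood_sd)), 1, 10)),
                    stress_pre=stress_pre,
                    stress_post=float(np.clip(np.round(stress_pre + rng.normal(stress_mu, stress_sd)), 1, 10)),
                    intox=_rating(rng, intox_mu, intox_sd),
                    true_params=params,
                )
            )
    return StudyDataset(subjects=subjects, synthetic=True, config=config)


def truth_manifest(dataset: StudyDataset) -> pd.DataFrame:
    """True per-subject parameters (synthetic data only)."""
    if not dataset.synthetic or any(s.true_params is None for s in dataset.subjects):
        raise ValueError("truth manifest is only available for synthetic datasets")
    rows = []
    for s in dataset.subjects:
        row = {"subject": s.subject, "alcohol": s.alcohol, "mood": s.mood}
        row.update(dict(zip(PARAM_NAMES, s.true_params.as_array())))
        rows.append(row)
    return pd.DataFrame(rows)


def trials_frame(dataset: StudyDataset) -> pd.DataFrame:
    """All trials in the long CSV dialect (deck letters, 1-based trial index)."""
    frames = []
    for s in dataset.subjects:
        t = s.trials
        frames.append(
            pd.DataFrame(
                {
                    "subject": s.subject,
                    "trial": np.arange(1, t.n_trials + 1),
                    "deck": [DECKS[c - 1] for c in t.choices],
                    "gain": t.gains,
                    "loss": t.losses,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_study(dataset: StudyDataset, outdir: str | Path) -> dict[str, Path]:
    """Write trials.csv, subjects.csv and (when synthetic) truth.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"trials": outdir / "trials.csv", "subjects": outdir / "subjects.csv"}
    trials_frame(dataset).to_csv(paths["trials"], index=False)
    dataset.metadata().to_csv(paths["subjects"], index=False)
    if dataset.synthetic:
        paths["truth"] = outdir / "truth.csv"
        truth_manifest(dataset).to_csv(paths["truth"], index=False)
    return paths
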