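"""Outcome-Representation Learning (ORL) model of IGT choice.

The model carries three latent 4-vectors across trials — expected value
``EV``, expected win frequency ``EF``, and perseveration strength ``PS`` —
and combines them into deck values

    V_j = EV_j + EF_j * beta_F + PS_j * beta_P

entered into a softmax (sensitivity fixed at 1) to produce choice
probabilities. Five free parameters:

``A_rew``
    reward learning rate in [0, 1]: how strongly EV and EF update after a
    non-negative outcome.
``A_pun``
    punishment learning rate in [0, 1]: the same for negative outcomes.
``K_prime``
    memory decay >= 0; the effective decay is K = 3**K_prime - 1, and after
    each choice the chosen deck's PS is set to 1/(1+K) while all other
    decks' PS are divided by (1+K).
``beta_F``
    win-frequency sensitivity (weight on EF).
``beta_P``
    perseveration tendency (weight on PS).

Updates after choosing deck j with scaled net outcome x (``sgn(0) = 0``;
x = 0 takes the reward branch):

    EV_j += A * (x - EV_j)                      A = A_rew if x >= 0 else A_pun
    EF_j += A * (sgn(x) - EF_j)                 same A
    EF_k += A' * (-sgn(x)/3 - EF_k), k != j     A' = the *opposite* rate

The unchosen-deck ("fictive" reversal-learning) update pushes the other
decks' expected frequencies in the direction opposite to the observed
outcome, split across the 3 unchosen decks, using the opposite learning
rate — see docs/methods.md for why this form was adopted.

Net outcomes are divided by :data:`OUTCOME_DIVISOR` (default 100) before
entering the model so that EV lives on a scale commensurate with
EF in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task_env import DECK_INDEX, PayoffSchedule, draw_outcome

#: Net payoffs are divided by this before entering the learning equations.
OUTCOME_DIVISOR = 100.0

_N_DECKS = 4


class InvalidOutcomeError(ValueError):
    """Raised when a trial outcome is not a finite number."""


@dataclass(frozen=True)
class ORLParams:
    """The five free parameters of the ORL model."""

    a_rew: float
    a_pun: float
    k_prime: float
    beta_f: float
    beta_p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.a_rew <= 1.0:
            raise ValueError(f"a_rew must be in [0, 1], got {self.a_rew}")
        if not 0.0 <= self.a_pun <= 1.0:
            raise ValueError(f"a_pun must be in [0, 1], got {self.a_pun}")
        if not self.k_prime >= 0.0:
            raise ValueError(f"k_prime must be >= 0, got {self.k_prime}")
        for name in ("beta_f", "beta_p"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def k(self) -> float:
        """Effective perseveration decay K = 3**K' - 1 (>= 0)."""
        return 3.0 ** self.k_prime - 1.0

    def as_array(self) -> np.ndarray:
        return np.array([self.a_rew, self.a_pun, self.k_prime, self.beta_f, self.beta_p])


PARAM_NAMES = ("a_rew", "a_pun", "k_prime", "beta_f", "beta_p")


@dataclass(frozen=True)
class LatentState:
    """Per-deck latent state: EV, EF, PS (each a length-4 vector)."""

    ev: np.ndarray
    ef: np.ndarray
    ps: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ev", "ef", "ps"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (_N_DECKS,):
                raise ValueError(f"{name} must be a length-4 vector")
            object.__setattr__(self, name, arr)


@dataclass
class SubjectTrials:
    """One subject's ordered trial sequence.

    ``choices`` holds 1-based deck indices (A=1 .. D=4); ``gains`` and
    ``losses`` are in currency units, losses non-negative.
    """

    subject: str
    choices: np.ndarray
    gains: np.ndarray
    losses: np.ndarray

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=int)
        self.gains = np.asarray(self.gains, dtype=float)
        self.losses = np.asarray(self.losses, dtype=float)
        n = len(self.choices)
        if len(self.gains) != n or len(self.losses) != n:
            raise ValueError("choices, gains and losses must have equal length")
        if n and not np.all((self.choices >= 1) & (self.choices <= 4)):
            raise ValueError("choices must be deck indices in 1..4")

    @property
    def n_trials(self) -> int:
        return len(self.choices)

    @property
    def net(self) -> np.ndarray:
        return self.gains - self.losses


def init_state() -> LatentState:
    """Zero-initialized latent state (all EV, EF, PS components 0)."""
    return LatentState(np.zeros(_N_DECKS), np.zeros(_N_DECKS), np.zeros(_N_DECKS))


def _check_choice(choice: int) -> int:
    if choice not in (1, 2, 3, 4):
        raise ValueError(f"choice must be a deck index in 1..4, got {choice!r}")
    return int(choice)


def update_state(state: LatentState, choice: int, x: float, params: ORLParams) -> LatentState:
    """One learning step after choosing ``choice`` and observing scaled outcome ``x``.

    Pure: returns a new state. Only the chosen deck's EV changes; EF updates
    for the chosen deck (toward sgn(x)) and, fictively, for the unchosen
    decks (toward -sgn(x)/3 with the opposite learning rate); PS decays for
    every deck and resets to 1/(1+K) for the chosen one.
    """
    j = _check_choice(choice) - 1
    if not np.isfinite(x):
        raise InvalidOutcomeError(f"outcome must be finite, got {x!r}")
    sx = float(np.sign(x))
    if x >= 0:
        a_chosen, a_other = params.a_rew, params.a_pun
    else:
        a_chosen, a_other = params.a_pun, params.a_rew

    ev = state.ev.copy()
    ev[j] += a_chosen * (x - ev[j])

    ef = state.ef.copy()
    ef_j_old = ef[j]
    ef += a_other * (-sx / 3.0 - ef)  # fictive update, all decks...
    ef[j] = ef_j_old + a_chosen * (sx - ef_j_old)  # ...chosen deck overridden

    decay = 1.0 / (1.0 + params.k)
    ps = state.ps * decay
    ps[j] = decay
    return LatentState(ev, ef, ps)


def deck_values(state: LatentState, params: ORLParams) -> np.ndarray:
    """Combined deck values V = EV + EF*beta_F + PS*beta_P."""
    return state.ev + state.ef * params.beta_f + state.ps * params.beta_p


def choice_probs(values: np.ndarray) -> np.ndarray:
    """Softmax choice probabilities (max-subtracted for stability)."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("deck values must be finite")
    z = values - values.max()
    e = np.exp(z)
    return e / e.sum()


def trial_loglik(state: LatentState, choice: int, params: ORLParams) -> float:
    """Log probability of the observed choice under the current state."""
    j = _check_choice(choice) - 1
    v = deck_values(state, params)
    z = v - v.max()
    return float(z[j] - np.log(np.exp(z).sum()))


def sequence_loglik(
    trials: SubjectTrials, params: ORLParams, outcome_divisor: float = OUTCOME_DIVISOR
) -> tuple[float, np.ndarray]:
    """Sequential log-likelihood of a subject's choices.

    For each trial, the choice is scored against the state *before* that
    trial's outcome is observed, then the state is updated. Returns the
    total and the per-trial vector (the pointwise vector feeds LOO).
    """
    if trials.n_trials == 0:
        raise ValueError("cannot score an empty trial sequence")
    xs = trials.net / outcome_divisor
    state = init_state()
    pointwise = np.empty(trials.n_trials)
    for t in range(trials.n_trials):
        c = int(trials.choices[t])
        pointwise[t] = trial_loglik(state, c, params)
        state = update_state(state, c, float(xs[t]), params)
    return float(pointwise.sum()), pointwise


try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _pointwise_kernel(choices, xs, a_rew, a_pun, k_prime, beta_f, beta_p):  # pragma: no cover
    S, T = choices.shape
    out = np.empty((S, T))
    v = np.empty(_N_DECKS)
    for s in range(S):
        ev = np.zeros(_N_DECKS)
        ef = np.zeros(_N_DECKS)
        ps = np.zeros(_N_DECKS)
        decay = 1.0 / (3.0 ** k_prime[s])  # = 1/(1+K)
        for t in range(T):
            c = choices[s, t] - 1
            vmax = -1e300
            for j in range(_N_DECKS):
                v[j] = ev[j] + ef[j] * beta_f[s] + ps[j] * beta_p[s]
                if v[j] > vmax:
                    vmax = v[j]
            sum_exp = 0.0
            for j in range(_N_DECKS):
                sum_exp += np.exp(v[j] - vmax)
            out[s, t] = v[c] - vmax - np.log(sum_exp)

            x = xs[s, t]
            if x >= 0.0:
                sx = 1.0 if x > 0.0 else 0.0
                a_chosen, a_other = a_rew[s], a_pun[s]
            else:
                sx = -1.0
                a_chosen, a_other = a_pun[s], a_rew[s]
            ev[c] += a_chosen * (x - ev[c])
            ef_c_old = ef[c]
            for j in range(_N_DECKS):
                ef[j] += a_other * (-sx / 3.0 - ef[j])
            ef[c] = ef_c_old + a_chosen * (sx - ef_c_old)
            for j in range(_N_DECKS):
                ps[j] *= decay
            ps[c] = decay
    return out


def pointwise_loglik_matrix(
    choices: np.ndarray,
    nets: np.ndarray,
    a_rew: np.ndarray,
    a_pun: np.ndarray,
    k_prime: np.ndarray,
    beta_f: np.ndarray,
    beta_p: np.ndarray,
    outcome_divisor: float = OUTCOME_DIVISOR,
) -> np.ndarray:
    """Vectorized pointwise log-likelihood over many (subject, parameter) rows.

    ``choices`` (int, 1..4) and ``nets`` (currency units) have shape (S, T);
    each parameter argument has shape (S,). Row s is scored with row s's
    parameters. Agrees with :func:`sequence_loglik` row-by-row to 1e-10; the
    samplers in :mod:`orligt.inference` run on this path. A numba-compiled
    kernel is used when available, with an equivalent numpy fallback.
    """
    choices = np.asarray(choices, dtype=int)
    if _HAVE_NUMBA:
        S = choices.shape[0]
        xs = np.ascontiguousarray(np.asarray(nets, float) / outcome_divisor)
        return _pointwise_kernel(
            np.ascontiguousarray(choices),
            xs,
            np.ascontiguousarray(np.broadcast_to(np.asarray(a_rew, float), (S,))),
            np.ascontiguousarray(np.broadcast_to(np.asarray(a_pun, float), (S,))),
            np.ascontiguousarray(np.broadcast_to(np.asarray(k_prime, float), (S,))),
            np.ascontiguousarray(np.broadcast_to(np.asarray(beta_f, float), (S,))),
            np.ascontiguousarray(np.broadcast_to(np.asarray(beta_p, float), (S,))),
        )
    return _pointwise_numpy(
        choices, nets, a_rew, a_pun, k_prime, beta_f, beta_p, outcome_divisor
    )


def _pointwise_numpy(
    choices: np.ndarray,
    nets: np.ndarray,
    a_rew: np.ndarray,
    a_pun: np.ndarray,
    k_prime: np.ndarray,
    beta_f: np.ndarray,
    beta_p: np.ndarray,
    outcome_divisor: float = OUTCOME_DIVISOR,
) -> np.ndarray:
    choices = np.asarray(choices, dtype=int)
    S, T = choices.shape
    xs = np.asarray(nets, dtype=float) / outcome_divisor
    a_rew = np.broadcast_to(np.asarray(a_rew, float), (S,))
    a_pun = np.broadcast_to(np.asarray(a_pun, float), (S,))
    beta_f = np.asarray(beta_f, float)[:, None]
    beta_p = np.asarray(beta_p, float)[:, None]
    decay = 1.0 / (3.0 ** np.asarray(k_prime, float))[:, None]  # 1/(1+K)

    ev = np.zeros((S, _N_DECKS))
    ef = np.zeros((S, _N_DECKS))
    ps = np.zeros((S, _N_DECKS))
    rows = np.arange(S)
    out = np.empty((S, T))
    for t in range(T):
        c = choices[:, t] - 1
        v = ev + ef * beta_f + ps * beta_p
        v = v - v.max(axis=1, keepdims=True)
        out[:, t] = v[rows, c] - np.log(np.exp(v).sum(axis=1))

        x = xs[:, t]
        pos = x >= 0
        sx = np.sign(x)
        a_chosen = np.where(pos, a_rew, a_pun)
        a_other = np.where(pos, a_pun, a_rew)

        ev[rows, c] += a_chosen * (x - ev[rows, c])
        ef_c_old = ef[rows, c]
        ef += a_other[:, None] * (-sx[:, None] / 3.0 - ef)
        ef[rows, c] = ef_c_old + a_chosen * (sx - ef_c_old)
        ps *= decay
        ps[rows, c] = decay[:, 0]
    return out


def simulate_agent(
    params: ORLParams,
    schedule: PayoffSchedule,
    n_trials: int,
    seed: int | np.random.Generator,
    subject: str = "sim",
    outcome_divisor: float = OUTCOME_DIVISOR,
) -> SubjectTrials:
    """Simulate an ORL agent playing ``n_trials`` draws on ``schedule``.

    Each choice is sampled from the softmax probabilities; the outcome is
    served deterministically from the schedule, tracking how many times the
    agent has drawn from each deck. Reproducible given the seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    letters = {v: k for k, v in DECK_INDEX.items()}
    state = init_state()
    draw_counts = {d: 0 for d in range(1, 5)}
    choices = np.empty(n_trials, dtype=int)
    gains = np.empty(n_trials)
    losses = np.empty(n_trials)
    for t in range(n_trials):
        p = choice_probs(deck_values(state, params))
        c = int(rng.choice(4, p=p)) + 1
        draw_counts[c] += 1
        outcome = draw_outcome(schedule, letters[c], draw_counts[c])
        choices[t] = c
        gains[t] = outcome.gain
        losses[t] = outcome.loss
        state = update_state(state, c, outcome.net / outcome_divisor, params)
    return SubjectTrials(subject=subject, choices=choices, gains=gains, losses=losses)
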