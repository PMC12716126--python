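"""Shared fixtures and the independent reference oracle.

``naive_orl_loglik`` is a deliberately plain, step-by-step transcription
of the ORL update equations, kept independent of the package's
implementation so that likelihood tests check two separately written
code paths against each other.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from orligt import StudyConfig, generate_study, make_classic_schedule


def naive_orl_loglik(
    choices,
    gains,
    losses,
    a_rew,
    a_pun,
    k_prime,
    beta_f,
    beta_p,
    divisor=100.0,
):
    """Scalar reference: per-trial log-likelihood of an ORL choice sequence.

    Written directly from the model definition with explicit loops and
    scalar arithmetic; no shared code with the package implementation.
    """
    ev = [0.0] * 4
    ef = [0.0] * 4
    ps = [0.0] * 4
    K = 3.0**k_prime - 1.0
    out = []
    for choice, gain, loss in zip(choices, gains, losses):
        j = int(choice) - 1
        values = [ev[d] + beta_f * ef[d] + beta_p * ps[d] for d in range(4)]
        m = max(values)
        denom = sum(math.exp(v - m) for v in values)
        out.append(values[j] - m - math.log(denom))

        x = (gain - loss) / divisor
        if x > 0:
            sgn = 1.0
        elif x < 0:
            sgn = -1.0
        else:
            sgn = 0.0
        if x >= 0:
            a_c, a_o = a_rew, a_pun
        else:
            a_c, a_o = a_pun, a_rew
        ev[j] = ev[j] + a_c * (x - ev[j])
        new_ef = []
        for d in range(4):
            if d == j:
                new_ef.append(ef[d] + a_c * (sgn - ef[d]))
            else:
                new_ef.append(ef[d] + a_o * (-sgn / 3.0 - ef[d]))
        ef = new_ef
        for d in range(4):
            ps[d] = ps[d] / (1.0 + K)
        ps[j] = 1.0 / (1.0 + K)
    return out


@pytest.fixture(scope="session")
def classic_schedule():
    return make_classic_schedule()


@pytest.fixture(scope="session")
def small_study():
    """12-subject synthetic study (3 per cell), shared across tests."""
    return generate_study(StudyConfig(n_per_cell=3, n_trials=100, seed=42))


@pytest.fixture(scope="session")
def random_params():
    """A bank of randomized but fixed parameter draws for property tests."""
    rng = np.random.default_rng(2024)
    return [
        dict(
            a_rew=float(rng.uniform(0.01, 0.99)),
            a_pun=float(rng.uniform(0.01, 0.99)),
            k_prime=float(rng.uniform(0.0, 3.0)),
            beta_f=float(rng.normal(0.0, 2.0)),
            beta_p=float(rng.normal(0.0, 2.0)),
        )
        for _ in range(100)
    ]
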