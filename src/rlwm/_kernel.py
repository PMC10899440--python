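"""JIT-compiled forward passes shared by the simulator and the likelihood.

Both kernels replay the same per-trial computation:

1. softmax policies over the WM and RL value rows for the current stimulus
   (shared inverse temperature ``beta``, max-subtraction for stability);
2. mixture ``w * pi_WM + (1 - w) * pi_RL`` with ``w = rho * min(1, K / ns)``;
3. lapse: ``(1 - eps) * pi + eps / 3``;
4. updates after feedback: delta rule on the RL row at rate ``alpha``; WM
   stores the reward exactly (one-shot learning); then every WM entry of the
   block decays toward the uninformative value ``Q0 = 1/3`` at rate ``phi``.

Value tables are re-initialised to ``Q0`` at block boundaries (each block has
fresh stimuli).  Timeout trials (``action < 0``) contribute nothing: no
likelihood term, no update, no decay.
"""

import numpy as np
from numba import njit

Q0 = 1.0 / 3.0
PROB_FLOOR = 1e-12  # applied inside the log only


@njit(cache=True)
def _policy(qwm, qrl, s, w, beta, eps, out):
    m = qwm[s, 0]
    if qwm[s, 1] > m:
        m = qwm[s, 1]
    if qwm[s, 2] > m:
        m = qwm[s, 2]
    e0 = np.exp(beta * (qwm[s, 0] - m))
    e1 = np.exp(beta * (qwm[s, 1] - m))
    e2 = np.exp(beta * (qwm[s, 2] - m))
    z = e0 + e1 + e2
    w0 = e0 / z
    w1 = e1 / z
    w2 = e2 / z

    m = qrl[s, 0]
    if qrl[s, 1] > m:
        m = qrl[s, 1]
    if qrl[s, 2] > m:
        m = qrl[s, 2]
    e0 = np.exp(beta * (qrl[s, 0] - m))
    e1 = np.exp(beta * (qrl[s, 1] - m))
    e2 = np.exp(beta * (qrl[s, 2] - m))
    z = e0 + e1 + e2
    r0 = e0 / z
    r1 = e1 / z
    r2 = e2 / z

    u = eps / 3.0
    out[0] = (1.0 - eps) * (w * w0 + (1.0 - w) * r0) + u
    out[1] = (1.0 - eps) * (w * w1 + (1.0 - w) * r1) + u
    out[2] = (1.0 - eps) * (w * w2 + (1.0 - w) * r2) + u


@njit(cache=True)
def _update(qwm, qrl, s, a, r, ns, alpha, phi):
    qrl[s, a] += alpha * (r - qrl[s, a])
    qwm[s, a] = r
    for i in range(ns):
        for j in range(3):
            qwm[i, j] += phi * (Q0 - qwm[i, j])


@njit(cache=True)
def nll_forward(alpha, phi, rho, epsilon, beta, K,
                stim, set_size, new_block, action, reward, valid, probs):
    """Replay realized choices; return the negative log-likelihood.

    ``probs`` (T, 3) receives the full policy at every trial (including
    invalid ones, for inspection); the NLL sums over valid trials only.
    """
    T = stim.shape[0]
    max_ns = 0
    for t in range(T):
        if set_size[t] > max_ns:
            max_ns = set_size[t]
    qwm = np.full((max_ns, 3), Q0)
    qrl = np.full((max_ns, 3), Q0)
    w = 0.0
    p = np.empty(3)
    nll = 0.0
    for t in range(T):
        ns = set_size[t]
        if new_block[t]:
            for i in range(ns):
                for j in range(3):
                    qwm[i, j] = Q0
                    qrl[i, j] = Q0
            kn = K / ns
            if kn > 1.0:
                kn = 1.0
            w = rho * kn
        s = stim[t]
        _policy(qwm, qrl, s, w, beta, epsilon, p)
        probs[t, 0] = p[0]
        probs[t, 1] = p[1]
        probs[t, 2] = p[2]
        if valid[t]:
            a = action[t]
            pa = p[a]
            if pa < PROB_FLOOR:
                pa = PROB_FLOOR
            nll -= np.log(pa)
            _update(qwm, qrl, s, a, reward[t], ns, alpha, phi)
    return nll


@njit(cache=True)
def simulate_forward(alpha, phi, rho, epsilon, beta, K,
                     stim, set_size, new_block, correct, uniforms,
                     actions, rewards, probs):
    """Generate choices by sampling each trial's policy with ``uniforms[t]``."""
    T = stim.shape[0]
    max_ns = 0
    for t in range(T):
        if set_size[t] > max_ns:
            max_ns = set_size[t]
    qwm = np.full((max_ns, 3), Q0)
    qrl = np.full((max_ns, 3), Q0)
    w = 0.0
    p = np.empty(3)
    for t in range(T):
        ns = set_size[t]
        if new_block[t]:
            for i in range(ns):
                for j in range(3):
                    qwm[i, j] = Q0
                    qrl[i, j] = Q0
            kn = K / ns
            if kn > 1.0:
                kn = 1.0
            w = rho * kn
        s = stim[t]
        _policy(qwm, qrl, s, w, beta, epsilon, p)
        probs[t, 0] = p[0]
        probs[t, 1] = p[1]
        probs[t, 2] = p[2]
        u = uniforms[t]
        if u < p[0]:
            a = 0
        elif u < p[0] + p[1]:
            a = 1
        else:
            a = 2
        r = 1.0 if a == correct[t] else 0.0
        actions[t] = a
        rewards[t] = r
        _update(qwm, qrl, s, a, r, ns, alpha, phi)
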