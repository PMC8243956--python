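"""Jitted inner loops for exemplar-by-exemplar weight updates.

Each input vector is sparse — one lexical unit, the causative unit, and four
semantic units — so one update touches at most 3 x 6 weights.  The loops below
exploit that; the dense reference implementation lives in ``learner.update``
and the two are held equal by tests.
"""

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a declared dependency

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def train_stream_xent(W, bias, use_bias, verb_ids, causative, sem, targets, lr):
    """Softmax cross-entropy delta rule, in stream order, in place."""
    n_in = W.shape[1]
    n_verbs = n_in - 5
    c_col = n_verbs
    s0 = n_verbs + 1
    z = np.empty(3)
    a = np.empty(3)
    for i in range(verb_ids.shape[0]):
        v = verb_ids[i]
        c = causative[i]
        t = targets[i]
        for k in range(3):
            zk = W[k, v]
            if c == 1:
                zk += W[k, c_col]
            for j in range(4):
                zk += W[k, s0 + j] * sem[i, j]
            if use_bias:
                zk += bias[k]
            z[k] = zk
        m = z[0]
        if z[1] > m:
            m = z[1]
        if z[2] > m:
            m = z[2]
        s = 0.0
        for k in range(3):
            a[k] = np.exp(z[k] - m)
            s += a[k]
        for k in range(3):
            tk = 1.0 if k == t else 0.0
            g = lr * (tk - a[k] / s)
            W[k, v] += g
            if c == 1:
                W[k, c_col] += g
            for j in range(4):
                W[k, s0 + j] += g * sem[i, j]
            if use_bias:
                bias[k] += g


@njit(cache=True)
def train_stream_lms(W, bias, use_bias, verb_ids, causative, sem, targets, lr):
    """Least-mean-squares delta rule on the linear outputs, in place."""
    n_in = W.shape[1]
    n_verbs = n_in - 5
    c_col = n_verbs
    s0 = n_verbs + 1
    z = np.empty(3)
    for i in range(verb_ids.shape[0]):
        v = verb_ids[i]
        c = causative[i]
        t = targets[i]
        for k in range(3):
            zk = W[k, v]
            if c == 1:
                zk += W[k, c_col]
            for j in range(4):
                zk += W[k, s0 + j] * sem[i, j]
            if use_bias:
                zk += bias[k]
            z[k] = zk
        for k in range(3):
            tk = 1.0 if k == t else 0.0
            g = lr * (tk - z[k])
            W[k, v] += g
            if c == 1:
                W[k, c_col] += g
            for j in range(4):
                W[k, s0 + j] += g * sem[i, j]
            if use_bias:
                bias[k] += g
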