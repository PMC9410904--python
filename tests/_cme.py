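"""Independent oracle: stationary chemical master equation on a truncated
state space, solved directly as a sparse linear system.

Used to validate the SSA implementation; shares no code with it.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve


def _solve_stationary(rows, cols, rates, n_states):
    A = sparse.coo_matrix((rates, (rows, cols)), shape=(n_states, n_states)).tolil()
    diag = np.asarray(A.sum(axis=0)).ravel()
    A.setdiag(A.diagonal() - diag)
    A = A.tocsr()
    # replace last equation with the normalization constraint
    A = A.tolil()
    A[n_states - 1, :] = 1.0
    b = np.zeros(n_states)
    b[n_states - 1] = 1.0
    pi = spsolve(A.tocsr(), b)
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


def _protein_moments(pi, protein_of_state):
    M = float((pi * protein_of_state).sum())
    var = float((pi * (protein_of_state - M) ** 2).sum())
    return M, var, var / M**2


def one_step_moments(k1, k2, lam1, lam2, rmax, pmax):
    """Stationary protein (mean, var, cv2) of the one-step model."""
    nr, npr = rmax + 1, pmax + 1

    def idx(r, p):
        return r * npr + p

    rows, cols, rates = [], [], []

    def add(src, dst, rate):
        if rate > 0:
            rows.append(dst)
            cols.append(src)
            rates.append(rate)

    for r in range(nr):
        for p in range(npr):
            s = idx(r, p)
            if r < rmax:
                add(s, idx(r + 1, p), k1)
            if p < pmax:
                add(s, idx(r, p + 1), k2 * r)
            if r > 0:
                add(s, idx(r - 1, p), lam1 * r)
            if p > 0:
                add(s, idx(r, p - 1), lam2 * p)
    pi = _solve_stationary(rows, cols, rates, nr * npr)
    protein = np.tile(np.arange(npr), nr)
    return _protein_moments(pi, protein)


def on_off_moments(k1, k_plus, k_minus, k2, lam1, lam2, rmax, pmax):
    """Stationary protein (mean, var, cv2) of the telegraph (ON-OFF) model."""
    nr, npr = rmax + 1, pmax + 1

    def idx(s, r, p):
        return (s * nr + r) * npr + p

    rows, cols, rates = [], [], []

    def add(src, dst, rate):
        if rate > 0:
            rows.append(dst)
            cols.append(src)
            rates.append(rate)

    for s in (0, 1):  # 1 = ON
        for r in range(nr):
            for p in range(npr):
                x = idx(s, r, p)
                if s == 1:
                    add(x, idx(0, r, p), k_minus)
                    if r < rmax:
                        add(x, idx(1, r + 1, p), k1)
                else:
                    add(x, idx(1, r, p), k_plus)
                if p < pmax:
                    add(x, idx(s, r, p + 1), k2 * r)
                if r > 0:
                    add(x, idx(s, r - 1, p), lam1 * r)
                if p > 0:
                    add(x, idx(s, r, p - 1), lam2 * p)
    pi = _solve_stationary(rows, cols, rates, 2 * nr * npr)
    protein = np.tile(np.arange(npr), 2 * nr)
    return _protein_moments(pi, protein)
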