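"""Independent brute-force oracles used by the tests.

These deliberately do not reuse the package's propensity or event machinery:
the master-equation generator below enumerates motor configurations of a
small static lattice directly from the model definition (attach, detach,
exclusion hop, walk-off at the plus-end), so the simulator can be checked
against the exact stationary law.
"""

from __future__ import annotations

import numpy as np


def master_equation_density(
    L: int, p: float, omega_a: float, omega_d: float
) -> np.ndarray:
    """Exact stationary per-site motor density of a static L-site lattice.

    Dynamics: attachment at rate omega_a per empty site, detachment at
    omega_d per motor, hop i -> i+1 at rate p when i+1 is empty, and a hop
    off the plus-end at rate p from the terminal site.  Enumerates all 2^L
    occupancy states, builds the master-equation generator and solves for
    its null vector.
    """
    n = 1 << L
    Q = np.zeros((n, n))

    def occupied(s: int, i: int) -> bool:
        return bool(s >> i & 1)

    for s in range(n):
        for i in range(L):
            if not occupied(s, i):
                Q[s, s | (1 << i)] += omega_a
            else:
                Q[s, s & ~(1 << i)] += omega_d
                if i + 1 < L:
                    if not occupied(s, i + 1):
                        Q[s, (s & ~(1 << i)) | (1 << (i + 1))] += p
                else:
                    Q[s, s & ~(1 << i)] += p  # walk off the plus-end
    np.fill_diagonal(Q, -Q.sum(axis=1))

    # stationary pi solves pi Q = 0 with sum(pi) = 1
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)

    density = np.zeros(L)
    for s in range(n):
        for i in range(L):
            if occupied(s, i):
                density[i] += pi[s]
    return density


def best_alignment_shift_bruteforce(
    reference: np.ndarray, other: np.ndarray, max_shift: int
) -> int:
    """Exhaustive search over all integer shifts minimizing the s.d. of the
    pointwise difference (smallest |shift| wins ties)."""
    results = []
    for shift in range(-max_shift, max_shift + 1):
        lo = max(0, shift)
        hi = min(reference.size, other.size + shift)
        if hi - lo < 2:
            continue
        sd = np.std(reference[lo:hi] - other[lo - shift:hi - shift])
        results.append((round(float(sd), 12), abs(shift), shift))
    results.sort()
    return results[0][2]


def batch_mean_se(samples: np.ndarray, n_batches: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Mean and standard error from contiguous batch means (handles
    autocorrelation between successive snapshots)."""
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[0] // n_batches * n_batches
    batches = samples[:n].reshape(n_batches, -1, *samples.shape[1:]).mean(axis=1)
    mean = batches.mean(axis=0)
    se = batches.std(axis=0, ddof=1) / np.sqrt(n_batches)
    return mean, se
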