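"""Numba kernel for the continuous-time simulation.

Exact thinning variant of Gillespie's direct method: per event class we use an
upper-bound propensity that is cheap to maintain (attachment: omega_a * L;
every per-motor reaction: rate_max * n_motors; hydrolysis and growth: exact),
draw the waiting time from the total bound rate and accept/reject the chosen
candidate with probability true_rate / bound_rate.  Rejections are null
events: the state is unchanged but time still advances, which reproduces the
exact trajectory distribution (Poisson thinning).  Per-step cost is O(1)
amortised; a scenario run of ~5e7 events takes seconds.

Conventions mirror :mod:`tiptraffic.model` exactly: hop rate is set by the
destination site's nucleotide state when the cap is enabled; a motor (or
train leader) on the terminal site steps off the plus-end at the fresh-GTP
destination rate; with a co-moving window, growth beyond the window drops the
minus-end site (removing any motor there).
"""

from __future__ import annotations

import numpy as np
from numba import njit

GTP = 0
GDP_PI = 1
GDP = 2

# indices into the counters array returned by the kernel
N_EVENTS = 0
N_ATTACH = 1
N_DETACH = 2
N_WALKOFF = 3
N_DROPPED = 4
N_STEPS = 5

ERR_NONE = 0
ERR_CAPACITY = 1   # append-mode lattice outgrew its preallocated capacity
ERR_STUCK = 2      # zero total propensity before sampling finished


@njit(cache=True)
def _simulate(
    L0, capacity, window,            # window <= 0 means unbounded growth
    p, p_slow, omega_a, omega_d, gamma,
    k_h1, k_h2, kc_on, kc_off, km_on, km_off, s,
    cap_on, trains_on, stab_on,
    seed,
    t_eq, n_samples, dt_sample,
    init_motor, init_cargo, init_nuc,
):
    np.random.seed(seed)

    occ = np.zeros(capacity, dtype=np.uint8)
    cargo = np.zeros(capacity, dtype=np.int32)
    nuc = np.full(capacity, GDP, dtype=np.uint8)
    L = L0
    occ[:L0] = init_motor
    cargo[:L0] = init_cargo
    nuc[:L0] = init_nuc

    # motor bookkeeping: mpos[slot] = site, midx[site] = slot or -1
    mpos = np.empty(capacity, dtype=np.int64)
    midx = np.full(capacity, -1, dtype=np.int64)
    n_mot = 0
    for i in range(L0):
        if occ[i]:
            mpos[n_mot] = i
            midx[i] = n_mot
            n_mot += 1

    n_gtp = 0
    n_pi = 0
    ptr = L  # lower bound on the minus-most non-GDP site index
    for i in range(L):
        if nuc[i] == GTP:
            n_gtp += 1
        elif nuc[i] == GDP_PI:
            n_pi += 1
        if nuc[i] != GDP and i < ptr:
            ptr = i

    origin = 0
    tip_rate = p_slow if cap_on else p  # stepping off the end: fresh-GTP destination

    snap_occ = np.zeros((n_samples, capacity), dtype=np.uint8)
    snap_cargo = np.zeros((n_samples, capacity), dtype=np.int32)
    snap_nuc = np.zeros((n_samples, capacity), dtype=np.uint8)
    snap_len = np.zeros(n_samples, dtype=np.int64)
    snap_origin = np.zeros(n_samples, dtype=np.int64)
    snap_time = np.zeros(n_samples, dtype=np.float64)
    counters = np.zeros(6, dtype=np.int64)

    per_motor = omega_d + p + kc_on + kc_off + km_on + km_off
    inv_s = 1.0 / s

    t = 0.0
    next_i = 0
    next_t = t_eq + dt_sample
    err = ERR_NONE

    while next_i < n_samples:
        r_att = omega_a * L
        r_mot = per_motor * n_mot
        r_hyd = (k_h1 * n_gtp + k_h2 * n_pi) if cap_on else 0.0
        r_tot = r_att + r_mot + r_hyd + gamma
        if r_tot <= 0.0:
            # frozen state: it holds at every remaining sample time
            while next_i < n_samples:
                snap_occ[next_i, :L] = occ[:L]
                snap_cargo[next_i, :L] = cargo[:L]
                snap_nuc[next_i, :L] = nuc[:L]
                snap_len[next_i] = L
                snap_origin[next_i] = origin
                snap_time[next_i] = next_t
                next_i += 1
                next_t += dt_sample
            break

        dt = -np.log(1.0 - np.random.random()) / r_tot
        t_new = t + dt
        while next_i < n_samples and next_t <= t_new:
            snap_occ[next_i, :L] = occ[:L]
            snap_cargo[next_i, :L] = cargo[:L]
            snap_nuc[next_i, :L] = nuc[:L]
            snap_len[next_i] = L
            snap_origin[next_i] = origin
            snap_time[next_i] = next_t
            next_i += 1
            next_t += dt_sample
        t = t_new
        if next_i >= n_samples:
            break
        counters[N_STEPS] += 1

        r = np.random.random() * r_tot
        if r < r_att:
            # candidate attachment at a uniform site; occupied -> null
            i = int(np.random.random() * L)
            if i >= L:
                i = L - 1
            if not occ[i]:
                occ[i] = 1
                mpos[n_mot] = i
                midx[i] = n_mot
                n_mot += 1
                counters[N_ATTACH] += 1
                counters[N_EVENTS] += 1
            continue
        r -= r_att

        if r < r_mot:
            slot = int(np.random.random() * n_mot)
            if slot >= n_mot:
                slot = n_mot - 1
            i = mpos[slot]
            # which per-motor reaction class
            u = r / n_mot  # uniform in [0, per_motor)
            if u < omega_d:
                # detachment; stabilized clustered motor-cargo -> thin by 1/s
                acc = True
                if stab_on and cargo[i] > 0:
                    left = i > 0 and occ[i - 1] and cargo[i - 1] > 0
                    right = i + 1 < L and occ[i + 1] and cargo[i + 1] > 0
                    if (left or right) and np.random.random() >= inv_s:
                        acc = False
                if acc:
                    last = n_mot - 1
                    mpos[slot] = mpos[last]
                    midx[mpos[last]] = slot
                    n_mot = last
                    occ[i] = 0
                    cargo[i] = 0
                    midx[i] = -1
                    counters[N_DETACH] += 1
                    counters[N_EVENTS] += 1
                continue
            u -= omega_d
            if u < p:
                if trains_on and cargo[i] > 0:
                    # only the leading motor of a train carries the hop event
                    if i + 1 < L and occ[i + 1] and cargo[i + 1] > 0:
                        continue
                    if i + 1 < L and occ[i + 1]:
                        continue  # blocked by a cargo-free motor
                    rate = tip_rate if i + 1 >= L else (
                        p_slow if (cap_on and nuc[i + 1] != GDP) else p)
                    if i + 1 >= L and stab_on and i > 0 and occ[i - 1] and cargo[i - 1] > 0:
                        rate *= inv_s  # stabilized cluster leaves the end slower
                    if np.random.random() * p >= rate:
                        continue
                    # rigid advance, leader first
                    tail = i
                    while tail - 1 >= 0 and occ[tail - 1] and cargo[tail - 1] > 0:
                        tail -= 1
                    for j in range(i, tail - 1, -1):
                        sl = midx[j]
                        if j + 1 < L:
                            occ[j + 1] = 1
                            cargo[j + 1] = cargo[j]
                            mpos[sl] = j + 1
                            midx[j + 1] = sl
                        else:
                            last = n_mot - 1
                            mpos[sl] = mpos[last]
                            midx[mpos[last]] = sl
                            n_mot = last
                            counters[N_WALKOFF] += 1
                        occ[j] = 0
                        cargo[j] = 0
                        midx[j] = -1
                    counters[N_EVENTS] += 1
                    continue
                # individual hop
                if i + 1 < L and occ[i + 1]:
                    continue
                rate = tip_rate if i + 1 >= L else (
                    p_slow if (cap_on and nuc[i + 1] != GDP) else p)
                if (i + 1 >= L and stab_on and cargo[i] > 0
                        and i > 0 and occ[i - 1] and cargo[i - 1] > 0):
                    rate *= inv_s  # stabilized cluster leaves the end slower
                if np.random.random() * p >= rate:
                    continue
                sl = midx[i]
                if i + 1 < L:
                    occ[i + 1] = 1
                    cargo[i + 1] = cargo[i]
                    mpos[sl] = i + 1
                    midx[i + 1] = sl
                else:
                    last = n_mot - 1
                    mpos[sl] = mpos[last]
                    midx[mpos[last]] = sl
                    n_mot = last
                    counters[N_WALKOFF] += 1
                occ[i] = 0
                cargo[i] = 0
                midx[i] = -1
                counters[N_EVENTS] += 1
                continue
            u -= p
            if u < kc_on:
                if cargo[i] == 0:
                    cargo[i] = 1
                    counters[N_EVENTS] += 1
                continue
            u -= kc_on
            if u < kc_off:
                if cargo[i] == 1:
                    cargo[i] = 0
                    counters[N_EVENTS] += 1
                continue
            u -= kc_off
            if u < km_on:
                if cargo[i] >= 1:
                    cargo[i] += 1
                    counters[N_EVENTS] += 1
                continue
            # km_off
            if cargo[i] >= 2:
                cargo[i] -= 1
                counters[N_EVENTS] += 1
            continue
        r -= r_mot

        if r < r_hyd:
            while ptr < L and nuc[ptr] == GDP:
                ptr += 1
            if r < k_h1 * n_gtp:
                k = int(r / k_h1)  # k-th GTP site, 0-based
                if k >= n_gtp:
                    k = n_gtp - 1
                seen = -1
                for i in range(ptr, L):
                    if nuc[i] == GTP:
                        seen += 1
                        if seen == k:
                            nuc[i] = GDP_PI
                            break
                n_gtp -= 1
                n_pi += 1
            else:
                r2 = r - k_h1 * n_gtp
                k = int(r2 / k_h2)
                if k >= n_pi:
                    k = n_pi - 1
                seen = -1
                for i in range(ptr, L):
                    if nuc[i] == GDP_PI:
                        seen += 1
                        if seen == k:
                            nuc[i] = GDP
                            break
                n_pi -= 1
            counters[N_EVENTS] += 1
            continue

        # growth
        if window > 0 and L >= window:
            # co-moving: drop the minus-end site, shift, append fresh GTP tip
            if occ[0]:
                sl = midx[0]
                last = n_mot - 1
                mpos[sl] = mpos[last]
                midx[mpos[last]] = sl
                n_mot = last
                counters[N_DROPPED] += 1
            if nuc[0] == GTP:
                n_gtp -= 1
            elif nuc[0] == GDP_PI:
                n_pi -= 1
            for i in range(1, L):
                occ[i - 1] = occ[i]
                cargo[i - 1] = cargo[i]
                nuc[i - 1] = nuc[i]
                midx[i - 1] = midx[i]
            occ[L - 1] = 0
            cargo[L - 1] = 0
            nuc[L - 1] = GTP
            midx[L - 1] = -1
            for sl in range(n_mot):
                mpos[sl] -= 1
            for sl in range(n_mot):
                midx[mpos[sl]] = sl
            n_gtp += 1
            ptr -= 1
            if ptr < 0:
                ptr = 0
            origin += 1
        else:
            if L >= capacity:
                err = ERR_CAPACITY
                break
            occ[L] = 0
            cargo[L] = 0
            nuc[L] = GTP
            midx[L] = -1
            n_gtp += 1
            L += 1
        counters[N_EVENTS] += 1

    if next_i < n_samples and err == ERR_NONE:
        err = ERR_STUCK
    return (snap_time, snap_occ, snap_cargo, snap_nuc, snap_len, snap_origin,
            counters, n_mot, err)
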