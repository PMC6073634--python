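"""Numba inner loops for the stochastic simulation algorithm.

The Gillespie direct method over the 2*N_G entry/exit channels is the hot
path; everything else (splitting, bookkeeping, analysis) lives in plain
Python.  Kernels draw uniforms from the numpy Generator passed in, so a run
is a pure function of (state, parameters, seed).

Status flags returned by kernels:
  0   target size reached / requested events completed
 -1   step budget exceeded (stalled growth)
 -2   assembly went extinct (N reached 0)
"""

from __future__ import annotations

import numpy as np
from numba import njit

OK = 0
STALLED = -1
EXTINCT = -2


@njit(cache=True)
def grow_kernel(counts, kf_rho, kb, beta, n_max, max_steps, rng):
    """Grow an assembly by SSA steps until N == n_max.

    ``kf_rho`` is the elementwise product k_f_i * rho_i.  The catalytic sum
    ``s_i = sum_j beta_ij n_j`` is maintained incrementally (O(N_G) per step).
    Returns (counts, elapsed_time, n_steps, flag).
    """
    ng = counts.shape[0]
    n = counts.copy()
    total_n = 0
    for i in range(ng):
        total_n += n[i]
    s = beta @ n.astype(np.float64)
    t = 0.0
    steps = 0
    while total_n < n_max:
        if total_n == 0:
            return n, t, steps, EXTINCT
        tot = 0.0
        for i in range(ng):
            c = 1.0 + s[i] / total_n
            tot += kf_rho[i] * total_n * c + kb[i] * n[i] * c
        if tot <= 0.0:
            return n, t, steps, STALLED
        u = rng.random() * tot
        acc = 0.0
        event = -1
        direction = 1
        for i in range(ng):
            acc += kf_rho[i] * total_n * (1.0 + s[i] / total_n)
            if acc >= u:
                event = i
                direction = 1
                break
        if event < 0:
            for i in range(ng):
                acc += kb[i] * n[i] * (1.0 + s[i] / total_n)
                if acc >= u:
                    event = i
                    direction = -1
                    break
        if event < 0:  # float round-off at u ~= tot: take the last open channel
            for i in range(ng - 1, -1, -1):
                if kf_rho[i] > 0.0 or n[i] > 0:
                    event = i
                    direction = 1 if kf_rho[i] > 0.0 else -1
                    break
        n[event] += direction
        total_n += direction
        for i in range(ng):
            s[i] += direction * beta[i, event]
        t += -np.log(rng.random()) / tot
        steps += 1
        if steps >= max_steps:
            return n, t, steps, STALLED
    return n, t, steps, OK


@njit(cache=True)
def equilibrium_kernel(counts, external, kf, kb, rho0, beta, max_events,
                       sample_every, rng):
    """No-fission run against a finite external supply.

    ``external[i]`` counts molecules of type i remaining outside; the
    effective concentration is rho0_i * external_i / external0_i, so the
    supply depletes as molecules join and is replenished by exits.  Samples
    (time, composition, external) every ``sample_every`` events.
    Returns (times, comps, exts, n_samples, flag).
    """
    ng = counts.shape[0]
    n = counts.copy()
    ext = external.copy()
    ext0 = external.astype(np.float64).copy()
    total_n = 0
    for i in range(ng):
        total_n += n[i]
    s = beta @ n.astype(np.float64)
    max_samples = max_events // sample_every + 2
    times = np.zeros(max_samples)
    comps = np.zeros((max_samples, ng), np.int64)
    exts = np.zeros((max_samples, ng), np.int64)
    t = 0.0
    k = 0
    times[k] = 0.0
    comps[k] = n
    exts[k] = ext
    k += 1
    for step in range(max_events):
        if total_n == 0:
            return times[:k], comps[:k], exts[:k], k, EXTINCT
        tot = 0.0
        for i in range(ng):
            c = 1.0 + s[i] / total_n
            rho_i = rho0[i] * ext[i] / ext0[i] if ext0[i] > 0 else 0.0
            tot += kf[i] * rho_i * total_n * c + kb[i] * n[i] * c
        if tot <= 0.0:
            return times[:k], comps[:k], exts[:k], k, STALLED
        u = rng.random() * tot
        acc = 0.0
        event = -1
        direction = 1
        for i in range(ng):
            rho_i = rho0[i] * ext[i] / ext0[i] if ext0[i] > 0 else 0.0
            acc += kf[i] * rho_i * total_n * (1.0 + s[i] / total_n)
            if acc >= u:
                event = i
                direction = 1
                break
        if event < 0:
            for i in range(ng):
                acc += kb[i] * n[i] * (1.0 + s[i] / total_n)
                if acc >= u:
                    event = i
                    direction = -1
                    break
        if event < 0:
            for i in range(ng - 1, -1, -1):
                if n[i] > 0:
                    event = i
                    direction = -1
                    break
        n[event] += direction
        ext[event] -= direction
        total_n += direction
        for i in range(ng):
            s[i] += direction * beta[i, event]
        t += -np.log(rng.random()) / tot
        if (step + 1) % sample_every == 0:
            times[k] = t
            comps[k] = n
            exts[k] = ext
            k += 1
    return times[:k], comps[:k], exts[:k], k, OK


@njit(cache=True)
def pgard_grow_kernel(mono, dimer, kf_rho, kb, k_dim, k_cleave, beta,
                      n_max, max_steps, rng):
    """Grow a dimer-extended assembly until the monomer-equivalent count N
    (free monomers + 2 x dimers) reaches n_max.

    Channels, scanned in this order so that with zero dimer rates and no
    dimers the uniform stream selects exactly the same events as
    :func:`grow_kernel`:

      entry of monomer i      kf_rho_i * N * Cm_i
      exit of monomer i       kb_i * n_i * Cm_i
      dimerisation (i, j)     k_dim * pair_ij * Cd_ij   (pair_ij = n_i n_j, or
                                                         n_i (n_i - 1) if i == j)
      cleavage of (i, j)      k_cleave * d_ij * Cd_ij

    Catalytic enhancements are computed on the fly from additive sub-site
    contributions: a monomer catalyst a enhances the (i, j) dimerisation by
    (beta_ia + beta_ja) / 2; a dimer catalyst (a, b) pairs its sub-sites with
    the two reaction slots, (beta_ia + beta_jb) / 2, a templating-like rule.
    For monomer entry/exit a dimer catalyst (a, b) contributes
    (beta_ia + beta_ib) / 2.

    Returns (mono, dimer, elapsed, steps, flag).
    """
    ng = mono.shape[0]
    n = mono.copy()
    d = dimer.copy()
    total_n = 0
    for i in range(ng):
        total_n += n[i]
    for i in range(ng):
        for j in range(ng):
            total_n += 2 * d[i, j]
    t = 0.0
    steps = 0
    fwd = np.zeros(ng)
    bwd = np.zeros(ng)
    dim_p = np.zeros((ng, ng))
    cle_p = np.zeros((ng, ng))
    while total_n < n_max:
        if total_n == 0:
            return n, d, t, steps, EXTINCT
        # dimers counted from each side
        r = np.zeros(ng)  # first-position monomer content of dimers
        c = np.zeros(ng)  # second-position monomer content
        for a in range(ng):
            for b in range(ng):
                if d[a, b] > 0:
                    r[a] += d[a, b]
                    c[b] += d[a, b]
        bn = beta @ n.astype(np.float64)
        br = beta @ r
        bc = beta @ c
        tot = 0.0
        for i in range(ng):
            cm = 1.0 + (bn[i] + 0.5 * (br[i] + bc[i])) / total_n
            fwd[i] = kf_rho[i] * total_n * cm
            bwd[i] = kb[i] * n[i] * cm
            tot += fwd[i] + bwd[i]
        if k_dim > 0.0 or k_cleave > 0.0:
            for i in range(ng):
                for j in range(ng):
                    cd = 1.0 + (0.5 * (bn[i] + bn[j]) + 0.5 * (br[i] + bc[j])) / total_n
                    pair = n[i] * (n[i] - 1) if i == j else n[i] * n[j]
                    dim_p[i, j] = k_dim * pair * cd
                    cle_p[i, j] = k_cleave * d[i, j] * cd
                    tot += dim_p[i, j] + cle_p[i, j]
        if tot <= 0.0:
            return n, d, t, steps, STALLED
        u = rng.random() * tot
        acc = 0.0
        done = False
        for i in range(ng):
            acc += fwd[i]
            if acc >= u:
                n[i] += 1
                total_n += 1
                done = True
                break
        if not done:
            for i in range(ng):
                acc += bwd[i]
                if acc >= u:
                    n[i] -= 1
                    total_n -= 1
                    done = True
                    break
        if not done and (k_dim > 0.0 or k_cleave > 0.0):
            for i in range(ng):
                if done:
                    break
                for j in range(ng):
                    acc += dim_p[i, j]
                    if acc >= u:
                        n[i] -= 1
                        n[j] -= 1
                        d[i, j] += 1
                        done = True
                        break
            if not done:
                for i in range(ng):
                    if done:
                        break
                    for j in range(ng):
                        acc += cle_p[i, j]
                        if acc >= u:
                            d[i, j] -= 1
                            n[i] += 1
                            n[j] += 1
                            done = True
                            break
        if not done:  # round-off fallback: basal entry of the first open type
            for i in range(ng):
                if kf_rho[i] > 0.0:
                    n[i] += 1
                    total_n += 1
                    done = True
                    break
        t += -np.log(rng.random()) / tot
        steps += 1
        if steps >= max_steps:
            return n, d, t, steps, STALLED
    return n, d, t, steps, OK
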