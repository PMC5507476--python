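"""Numba kernels for pairwise forces, energies, and overdamped relaxation.

Lineage codes: 0 = undetermined ICM, 1 = TE, 2 = EPI, 3 = PrE (see
:class:`blastosim.state.Lineage`).

The pair potential is ``V(d) = exp(-d) - S exp(-d / beta)``.  For TE-TE pairs
the attraction factor depends on the two polarity unit vectors e1, e2 and the
unit separation u via ``S = pref * (e1.e2 - (e1.u)(e2.u))`` (the cross-product
form of the polar factor, rewritten with the Lagrange identity so it holds in
2D and 3D alike).  Because S depends on the separation *direction*, the force
carries a tangential component; the kernels return the exact gradient of V.
"""

import numpy as np
from numba import njit

TE = 1
PRE = 3

STATUS_OK = 0
STATUS_OVERLAP = 1
STATUS_NONFINITE = 2

MAX_CAND = 96


@njit(cache=True)
def build_nn_adj(pos, lin, n, dim, rmax, filter_all, adj):
    """Halfway-point true-nearest-neighbor mask.

    ``adj[i, j] = 1`` iff the pair (i, j) is within ``rmax`` and no third
    cell lies strictly closer to the pair midpoint than the endpoints do.
    With ``filter_all`` the mask is built for every pair; otherwise only for
    pairs involving a TE cell (whose tight junctions couple them to the
    contact layer only), and pairs of non-TE cells are left unmasked (the
    caller ignores the mask for them).
    """
    # candidate lists: cells within rmax + 1 of each cell
    cand = np.empty((n, MAX_CAND), dtype=np.int32)
    ncand = np.zeros(n, dtype=np.int32)
    r2pre = (rmax + 1.0) * (rmax + 1.0)
    for i in range(n):
        for j in range(n):
            if j == i:
                continue
            d2 = 0.0
            for m in range(dim):
                dx = pos[j, m] - pos[i, m]
                d2 += dx * dx
            if d2 <= r2pre and ncand[i] < MAX_CAND:
                cand[i, ncand[i]] = j
                ncand[i] += 1
    for i in range(n):
        for j in range(n):
            adj[i, j] = 0
    r2max = rmax * rmax
    for i in range(n):
        for a in range(ncand[i]):
            j = cand[i, a]
            if j <= i:
                continue
            if (not filter_all) and lin[i] != TE and lin[j] != TE:
                continue
            d2 = 0.0
            for m in range(dim):
                dx = pos[j, m] - pos[i, m]
                d2 += dx * dx
            if d2 > r2max:
                continue
            # midpoint test against cells near i
            ok = True
            ref2 = 0.25 * d2 - 1e-9
            for b in range(ncand[i]):
                k = cand[i, b]
                if k == j:
                    continue
                dk2 = 0.0
                for m in range(dim):
                    dm = 0.5 * (pos[i, m] + pos[j, m]) - pos[k, m]
                    dk2 += dm * dm
                if dk2 < ref2:
                    ok = False
                    break
            if ok:
                adj[i, j] = 1
                adj[j, i] = 1
    return adj


@njit(cache=True)
def pair_accumulate(pos, lin, pol, n, dim, s_default, s_pre, s_neutral, beta,
                    pref, cut_te, cut_global, icm_global, rule3, neutral,
                    tangential, filter_all, filter_te_icm, use_te_adj, te_adj,
                    force, torque):
    """Accumulate forces (and 2D polarity torques) for all in-range pairs.

    ``torque`` is only filled in 2D: torque[i] = sum_j sin(alpha_j - alpha_i)
    over TE neighbors, i.e. minus the gradient of the alignment potential
    V_p = -cos(alpha_i - alpha_j).

    When ``use_te_adj`` is set (the 3D mode), TE-TE pairs additionally
    require ``te_adj[i, j] != 0``; the caller fills that mask with the
    halfway-point true-nearest-neighbor graph.
    """
    status = STATUS_OK
    for i in range(n):
        for m in range(dim):
            force[i, m] = 0.0
        torque[i] = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d2 = 0.0
            for m in range(dim):
                dx = pos[j, m] - pos[i, m]
                d2 += dx * dx
            both_te = lin[i] == TE and lin[j] == TE
            any_te = lin[i] == TE or lin[j] == TE
            if both_te:
                if d2 >= cut_te * cut_te:
                    continue
            else:
                no_cut = icm_global and not any_te
                if (not no_cut) and d2 > cut_global * cut_global:
                    continue
            if use_te_adj and te_adj[i, j] == 0:
                if both_te or filter_all or (any_te and filter_te_icm):
                    continue
            if d2 < 1e-12:
                status = STATUS_OVERLAP
                continue
            d = np.sqrt(d2)
            expd = np.exp(-d)
            expb = np.exp(-d / beta)
            if both_te:
                ee = 0.0
                eu1 = 0.0
                eu2 = 0.0
                for m in range(dim):
                    um = (pos[j, m] - pos[i, m]) / d
                    ee += pol[i, m] * pol[j, m]
                    eu1 += pol[i, m] * um
                    eu2 += pol[j, m] * um
                s_eff = pref * (ee - eu1 * eu2)
                dvdd = -expd + (s_eff / beta) * expb
                for m in range(dim):
                    um = (pos[j, m] - pos[i, m]) / d
                    f = dvdd * um
                    if tangential:
                        grad_s = pref * (eu2 * (pol[i, m] - eu1 * um)
                                         + eu1 * (pol[j, m] - eu2 * um)) / d
                        f += expb * grad_s
                    force[i, m] += f
                    force[j, m] -= f
                if dim == 2:
                    # sin(alpha_j - alpha_i) = e_i x e_j (z-component)
                    s_ang = pol[i, 0] * pol[j, 1] - pol[i, 1] * pol[j, 0]
                    torque[i] += s_ang
                    torque[j] -= s_ang
            else:
                if neutral:
                    s_eff = s_neutral
                elif rule3 and (lin[i] == PRE or lin[j] == PRE):
                    s_eff = s_pre
                else:
                    s_eff = s_default
                dvdd = -expd + (s_eff / beta) * expb
                for m in range(dim):
                    um = (pos[j, m] - pos[i, m]) / d
                    f = dvdd * um
                    force[i, m] += f
                    force[j, m] -= f
    return status


@njit(cache=True)
def total_energy(pos, lin, pol, n, dim, s_default, s_pre, s_neutral, beta,
                 pref, cut_te, cut_global, icm_global, rule3, neutral,
                 filter_all, filter_te_icm, use_te_adj, te_adj):
    """Sum of the pair potential over all in-range pairs (same range rules)."""
    e_tot = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d2 = 0.0
            for m in range(dim):
                dx = pos[j, m] - pos[i, m]
                d2 += dx * dx
            both_te = lin[i] == TE and lin[j] == TE
            any_te = lin[i] == TE or lin[j] == TE
            if both_te:
                if d2 >= cut_te * cut_te:
                    continue
            else:
                no_cut = icm_global and not any_te
                if (not no_cut) and d2 > cut_global * cut_global:
                    continue
            if use_te_adj and te_adj[i, j] == 0:
                if both_te or filter_all or (any_te and filter_te_icm):
                    continue
            d = np.sqrt(d2)
            if both_te:
                ee = 0.0
                eu1 = 0.0
                eu2 = 0.0
                for m in range(dim):
                    um = (pos[j, m] - pos[i, m]) / d
                    ee += pol[i, m] * pol[j, m]
                    eu1 += pol[i, m] * um
                    eu2 += pol[j, m] * um
                s_eff = pref * (ee - eu1 * eu2)
            elif neutral:
                s_eff = s_neutral
            elif rule3 and (lin[i] == PRE or lin[j] == PRE):
                s_eff = s_pre
            else:
                s_eff = s_default
            e_tot += np.exp(-d) - s_eff * np.exp(-d / beta)
    return e_tot


@njit(cache=True)
def relax_kernel(pos, lin, pol, n, dim, s_default, s_pre, s_neutral, beta,
                 pref, cut_te, cut_global, icm_global, rule3, neutral,
                 tangential, filter_all, filter_te_icm, use_te_adj, te_adj,
                 rebuild_every, dt, mobility_pol, max_steps, tol,
                 noise_pos, noise_ang, seed):
    """Euler integration of the overdamped dynamics for up to ``max_steps``.

    Per step: positions move by dt * force plus additive Gaussian noise of sd
    ``noise_pos`` per coordinate; TE polarities follow the damped alignment
    dynamics (angle equation in 2D, tangent-projected alignment in 3D) with
    angular noise of sd ``noise_ang``.  Stops early once the largest
    deterministic displacement ``dt * |F|`` falls below ``tol``.

    Returns (steps_used, last_max_displacement, status).
    """
    np.random.seed(seed)
    force = np.zeros((n, dim))
    torque = np.zeros(n)
    max_disp = 0.0
    steps_used = 0
    status = STATUS_OK
    for step in range(max_steps):
        if use_te_adj and rebuild_every > 0 and step % rebuild_every == 0:
            build_nn_adj(pos, lin, n, dim, cut_global, filter_all, te_adj)
        st = pair_accumulate(pos, lin, pol, n, dim, s_default, s_pre,
                             s_neutral, beta, pref, cut_te, cut_global,
                             icm_global, rule3, neutral, tangential,
                             filter_all, filter_te_icm, use_te_adj, te_adj,
                             force, torque)
        if st != STATUS_OK:
            status = st
        max_disp = 0.0
        for i in range(n):
            f2 = 0.0
            for m in range(dim):
                f2 += force[i, m] * force[i, m]
                step_m = dt * force[i, m]
                if noise_pos > 0.0:
                    step_m += noise_pos * np.random.normal()
                pos[i, m] += step_m
            disp = dt * np.sqrt(f2)
            if disp > max_disp:
                max_disp = disp
            if not np.isfinite(f2):
                status = STATUS_NONFINITE
        # polarity update after positions, from the same pre-step state
        for i in range(n):
            if lin[i] != TE:
                continue
            if dim == 2:
                dtheta = dt * mobility_pol * torque[i]
                if noise_ang > 0.0:
                    dtheta += noise_ang * np.random.normal()
                c = np.cos(dtheta)
                s = np.sin(dtheta)
                px = pol[i, 0]
                py = pol[i, 1]
                pol[i, 0] = c * px - s * py
                pol[i, 1] = s * px + c * py
            else:
                # damped alignment with TE neighbors, projected on the sphere
                gx = 0.0
                gy = 0.0
                gz = 0.0
                for j in range(n):
                    if j == i or lin[j] != TE:
                        continue
                    d2 = 0.0
                    for m in range(dim):
                        dx = pos[j, m] - pos[i, m]
                        d2 += dx * dx
                    if d2 >= cut_te * cut_te:
                        continue
                    if use_te_adj and te_adj[i, j] == 0:
                        continue
                    dot = (pol[i, 0] * pol[j, 0] + pol[i, 1] * pol[j, 1]
                           + pol[i, 2] * pol[j, 2])
                    gx += pol[j, 0] - dot * pol[i, 0]
                    gy += pol[j, 1] - dot * pol[i, 1]
                    gz += pol[j, 2] - dot * pol[i, 2]
                pol[i, 0] += dt * mobility_pol * gx
                pol[i, 1] += dt * mobility_pol * gy
                pol[i, 2] += dt * mobility_pol * gz
                if noise_ang > 0.0:
                    for m in range(3):
                        pol[i, m] += noise_ang * np.random.normal()
                norm = np.sqrt(pol[i, 0] ** 2 + pol[i, 1] ** 2 + pol[i, 2] ** 2)
                if norm > 0.0:
                    for m in range(3):
                        pol[i, m] /= norm
        steps_used = step + 1
        if max_disp < tol:
            break
    return steps_used, max_disp, status
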