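"""Compiled Metropolis kernel for the Cellular Potts Model.

One Monte Carlo step (MCS) performs ``width * height`` elementary copy
attempts.  All randomness is pre-drawn per MCS from a single
``numpy.random.Generator`` and passed in as arrays, so trajectories are a
pure function of the seed regardless of compilation details.

The total energy change of an attempt is assembled here from the base
adhesion/area terms plus the enabled model terms (basic persistence, Act,
actin-chain coupling, pseudopod pulling, tip adhesion).  The pure-Python
implementations of the same terms in :mod:`podcpm.core`,
:mod:`podcpm.persistence` and :mod:`podcpm.pseudopod` serve as the oracle
these kernels are tested against.

Parameter/flag vector layout (see :func:`pack_params` / :func:`pack_flags`):

    params = [T, lambda_p, lambda_act, max_act, actin_bonus, pull_F,
              r_max, tip_bonus]
    flags  = [persistence, act, actin_coupling, pulling, tip_adhesion,
              connectivity]
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["run_mcs", "compute_delta_h", "delta_h_state",
           "pack_params", "pack_flags",
           "P_T", "P_LAMP", "P_LAMACT", "P_MAXACT", "P_ACTBONUS", "P_PULL",
           "P_RMAX", "P_TIPB",
           "F_PERS", "F_ACT", "F_ACTIN", "F_PULL", "F_TIP", "F_CONN"]

# Moore offsets (dx, dy); order irrelevant but fixed
_OFF = np.array(
    [(-1, -1), (0, -1), (1, -1), (-1, 0), (1, 0), (-1, 1), (0, 1), (1, 1)],
    dtype=np.int64,
)
# Moore neighborhood including the central site (for Act GM and actin scan)
_OFF9 = np.vstack([_OFF, np.array([[0, 0]], dtype=np.int64)])

P_T, P_LAMP, P_LAMACT, P_MAXACT, P_ACTBONUS, P_PULL, P_RMAX, P_TIPB = range(8)
F_PERS, F_ACT, F_ACTIN, F_PULL, F_TIP, F_CONN = range(6)


def pack_params(temperature=20.0, lambda_p=0.0, lambda_act=0.0, max_act=1.0,
                actin_bonus=0.0, pull_strength=0.0, r_max=1.0,
                tip_bonus=0.0) -> np.ndarray:
    return np.array([temperature, lambda_p, lambda_act, max_act, actin_bonus,
                     pull_strength, r_max, tip_bonus], dtype=np.float64)


def pack_flags(persistence=False, act=False, actin=False, pull=False,
               tip=False, connectivity=False) -> np.ndarray:
    return np.array([persistence, act, actin, pull, tip, connectivity],
                    dtype=np.int64)


@njit(cache=True, inline="always")
def _gm_act(act, owner, x, y):
    """Geometric mean of activities over the Moore neighborhood (incl. the
    central site) restricted to sites sharing the central site's owner;
    0 for a medium site."""
    h, w = owner.shape
    o = owner[y, x]
    if o == 0:
        return 0.0
    prod = 1.0
    cnt = 0
    for k in range(9):
        xx = (x + _OFF9[k, 0]) % w
        yy = (y + _OFF9[k, 1]) % h
        if owner[yy, xx] == o:
            prod *= act[yy, xx]
            cnt += 1
    return prod ** (1.0 / cnt)


@njit(cache=True, inline="always")
def _tip_multiplier(owner, tips, tip_ok, sigma, x, y, r2max):
    """Tip-adhesion multiplier for involved cell ``sigma`` at the site
    changing identity: 0 (no applicable bonus), 1 (own tip XOR a foreign
    neighbor's tip within range) or 2 (both within range)."""
    h, w = owner.shape
    npod = tips.shape[1]
    has_foreign = False
    r_fo2 = 1.0e30
    for k in range(8):
        xx = (x + _OFF[k, 0]) % w
        yy = (y + _OFF[k, 1]) % h
        ou = owner[yy, xx]
        if ou != 0 and ou != sigma:
            has_foreign = True
            for p in range(npod):
                if tip_ok[ou, p]:
                    dx = x - tips[ou, p, 0]
                    dx -= w * np.rint(dx / w)
                    dy = y - tips[ou, p, 1]
                    dy -= h * np.rint(dy / h)
                    d2 = dx * dx + dy * dy
                    if d2 < r_fo2:
                        r_fo2 = d2
    if not has_foreign:
        return 0
    r_own2 = 1.0e30
    for p in range(npod):
        if tip_ok[sigma, p]:
            dx = x - tips[sigma, p, 0]
            dx -= w * np.rint(dx / w)
            dy = y - tips[sigma, p, 1]
            dy -= h * np.rint(dy / h)
            d2 = dx * dx + dy * dy
            if d2 < r_own2:
                r_own2 = d2
    m = 0
    if r_own2 <= r2max:
        m += 1
    if r_fo2 <= r2max:
        m += 1
    return m


@njit(cache=True, inline="always")
def _local_conn_ok(owner, x, y, losing):
    """True iff the losing cell's sites in the Moore ring of (x, y) form one
    Moore-connected component (cell vanishing entirely is allowed)."""
    h, w = owner.shape
    mem = np.zeros(8, dtype=np.bool_)
    cnt = 0
    start = -1
    for k in range(8):
        xx = (x + _OFF[k, 0]) % w
        yy = (y + _OFF[k, 1]) % h
        if owner[yy, xx] == losing:
            mem[k] = True
            cnt += 1
            if start < 0:
                start = k
    if cnt == 0:
        return True
    seen = np.zeros(8, dtype=np.bool_)
    stack = np.empty(8, dtype=np.int64)
    seen[start] = True
    stack[0] = start
    top = 1
    nseen = 1
    while top > 0:
        top -= 1
        k = stack[top]
        for j in range(8):
            if mem[j] and not seen[j]:
                if (abs(_OFF[j, 0] - _OFF[k, 0]) <= 1
                        and abs(_OFF[j, 1] - _OFF[k, 1]) <= 1):
                    seen[j] = True
                    nseen += 1
                    stack[top] = j
                    top += 1
    return nseen == cnt


@njit(cache=True)
def compute_delta_h(owner, ctype, jtable, area, tarea, lamv,
                    act, tvec, actin_owner, pod_vec, tips, tip_ok,
                    params, flags, x, y, xs, ys):
    """Total dH of copying the identity of source (xs, ys) onto target (x, y).

    Returns (dH, blocked); blocked attempts have acceptance probability 0.
    This is the single code path used by :func:`run_mcs`; tests compare it
    against full-Hamiltonian recomputation plus the reference model terms.
    """
    h, w = owner.shape
    so = owner[ys, xs]   # growing cell (source identity)
    to = owner[y, x]     # shrinking cell (target's current identity)
    # base adhesion: only pairs involving the target site change
    dh = 0.0
    for k in range(8):
        xx = (x + _OFF[k, 0]) % w
        yy = (y + _OFF[k, 1]) % h
        ou = owner[yy, xx]
        if ou != to:
            dh -= jtable[ctype[to], ctype[ou]]
        if ou != so:
            dh += jtable[ctype[so], ctype[ou]]
    # elastic area
    if so != 0:
        v = area[so]
        t = tarea[so]
        dh += lamv[so] * ((v + 1 - t) ** 2 - (v - t) ** 2)
    if to != 0:
        v = area[to]
        t = tarea[to]
        dh += lamv[to] * ((v - 1 - t) ** 2 - (v - t) ** 2)
    # update direction: unit vector from source toward target
    ddx = float(x - xs)
    ddx -= w * np.rint(ddx / w)
    ddy = float(y - ys)
    ddy -= h * np.rint(ddy / h)
    norm = math.sqrt(ddx * ddx + ddy * ddy)
    sx = ddx / norm
    sy = ddy / norm
    if flags[F_PERS] == 1:
        lam_p = params[P_LAMP]
        if so != 0:
            dh -= lam_p * area[so] * (sx * tvec[so, 0] + sy * tvec[so, 1])
        if to != 0:
            dh -= lam_p * area[to] * (sx * tvec[to, 0] + sy * tvec[to, 1])
    if flags[F_ACT] == 1:
        gm_src = _gm_act(act, owner, xs, ys)
        gm_tgt = _gm_act(act, owner, x, y)
        dh -= (params[P_LAMACT] / params[P_MAXACT]) * (gm_src - gm_tgt)
    if flags[F_ACTIN] == 1:
        bonus = params[P_ACTBONUS]
        for k in range(9):
            xx = (x + _OFF9[k, 0]) % w
            yy = (y + _OFF9[k, 1]) % h
            ao = actin_owner[yy, xx]
            if ao != 0:
                if ao == to:
                    return np.inf, True   # shrinking around own actin blocked
                if ao == so:
                    dh -= bonus
                    # single bonus regardless of how many actin sites are near
                    bonus = 0.0
    if flags[F_PULL] == 1:
        f = params[P_PULL]
        if so != 0 and area[so] > 0:
            dh -= f * (sx * pod_vec[so, 0] + sy * pod_vec[so, 1]) / area[so]
        if to != 0 and area[to] > 0:
            dh -= f * (sx * pod_vec[to, 0] + sy * pod_vec[to, 1]) / area[to]
    if flags[F_TIP] == 1:
        r2max = params[P_RMAX] * params[P_RMAX]
        e = params[P_TIPB]
        if so != 0:
            dh -= e * _tip_multiplier(owner, tips, tip_ok, so, x, y, r2max)
        if to != 0:
            dh += e * _tip_multiplier(owner, tips, tip_ok, to, x, y, r2max)
    return dh, False


@njit(cache=True)
def run_mcs(owner, ctype, jtable, area, tarea, lamv, sum_x, sum_y,
            act, tvec, actin_owner, pod_vec, tips, tip_ok,
            params, flags, targets, nbrs, urand):
    """Run one MCS worth of elementary copy attempts in place.

    ``targets`` (flat site indices), ``nbrs`` (Moore offset indices) and
    ``urand`` (uniforms for the Metropolis decision) must each hold one entry
    per attempt.  Returns the number of accepted copies.
    """
    h, w = owner.shape
    temperature = params[P_T]
    use_act = flags[F_ACT] == 1
    use_conn = flags[F_CONN] == 1
    n = targets.shape[0]
    accepted = 0
    for i in range(n):
        t = targets[i]
        y = t // w
        x = t - y * w
        k = nbrs[i]
        xs = (x + _OFF[k, 0]) % w
        ys = (y + _OFF[k, 1]) % h
        so = owner[ys, xs]
        to = owner[y, x]
        if so == to:
            continue
        if use_conn and to != 0 and not _local_conn_ok(owner, x, y, to):
            continue
        dh, blocked = compute_delta_h(owner, ctype, jtable, area, tarea, lamv,
                                      act, tvec, actin_owner, pod_vec,
                                      tips, tip_ok, params, flags,
                                      x, y, xs, ys)
        if blocked:
            continue
        if dh > 0.0 and urand[i] >= math.exp(-dh / temperature):
            continue
        # ---- accept: update ownership, areas, unwrapped centroid sums ----
        if to != 0:
            a = area[to]
            mx = sum_x[to] / a
            my = sum_y[to] / a
            sum_x[to] -= x + w * np.rint((mx - x) / w)
            sum_y[to] -= y + h * np.rint((my - y) / h)
            area[to] = a - 1
            if area[to] == 0:
                sum_x[to] = 0.0
                sum_y[to] = 0.0
        if so != 0:
            a = area[so]
            if a > 0:
                mx = sum_x[so] / a
                my = sum_y[so] / a
                sum_x[so] += x + w * np.rint((mx - x) / w)
                sum_y[so] += y + h * np.rint((my - y) / h)
            else:
                sum_x[so] += x
                sum_y[so] += y
            area[so] = a + 1
        owner[y, x] = so
        if use_act:
            act[y, x] = params[P_MAXACT] if so != 0 else 0.0
        elif so == 0:
            act[y, x] = 0.0
        accepted += 1
    return accepted


def delta_h_state(state, params, flags, x, y, xs, ys):
    """Convenience wrapper: evaluate :func:`compute_delta_h` on a
    :class:`~podcpm.core.CPMState` without mutating it (used to cross-check
    the kernel's incremental dH against full-Hamiltonian recomputation)."""
    return compute_delta_h(
        state.owner, state.ctype, state.contact.j,
        state.area, state.target_area, state.lambda_area,
        state.act, state.target_dir, state.actin_owner,
        state.pod_vector, state.tips, state.tip_ok,
        params, flags, x, y, xs, ys)
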