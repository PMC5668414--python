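"""Numba kernels: Ewald sums, the Metropolis MC loop, and Widom insertion.

All kernels work on flat float64/int64 arrays in reduced units (bead diameter
sigma = 1, k_B*T = 1).  Electrostatics is Ewald-summed with conducting
(tin-foil) boundary conditions: a minimum-image erfc real-space part within a
cutoff, a half-space reciprocal sum over integer wave vectors, and the
constant self term.  Reciprocal-space structure factors S(k) are carried
incrementally through the MC run.
"""

import math

import numpy as np
from numba import njit

SQRT_PI = math.sqrt(math.pi)


# ---------------------------------------------------------------------------
# Ewald building blocks
# ---------------------------------------------------------------------------


def make_kvectors(box_length: float, kmax: int):
    """Integer half-space wave vectors (K,3) with |n| <= kmax, excluding 0.

    Half space means nx>0, or nx=0 and ny>0, or nx=ny=0 and nz>0; the
    reciprocal-space coefficient carries the factor 2 for the mirrored half.
    """
    vecs = []
    for nx in range(0, kmax + 1):
        ylo = -kmax if nx > 0 else 0
        for ny in range(ylo, kmax + 1):
            zlo = -kmax if (nx > 0 or ny > 0) else 1
            for nz in range(zlo, kmax + 1):
                if nx * nx + ny * ny + nz * nz <= kmax * kmax and not (
                    nx == 0 and ny == 0 and nz == 0
                ):
                    vecs.append((nx, ny, nz))
    return np.asarray(vecs, dtype=np.int64).reshape(-1, 3)


def make_kcoef(kint: np.ndarray, box_length: float, alpha: float, bjerrum: float):
    """Per-k prefactor of the reciprocal energy U = sum_k c_k |S(k)|^2."""
    if len(kint) == 0:
        return np.zeros(0)
    V = box_length**3
    k2 = (2.0 * np.pi / box_length) ** 2 * (kint.astype(np.float64) ** 2).sum(axis=1)
    # 4*pi instead of 2*pi: the mirrored -k half of the sum is folded in.
    return 4.0 * np.pi * bjerrum / V * np.exp(-k2 / (4.0 * alpha**2)) / k2


@njit(cache=True)
def _fill_tables(x, y, z, L, kmax, exre, exim, eyre, eyim, ezre, ezim):
    """exp(i*2*pi*n*x/L) tables by recursion; ey/ez cover n in [-kmax, kmax]."""
    tp = 2.0 * np.pi / L
    cx, sx = np.cos(tp * x), np.sin(tp * x)
    exre[0], exim[0] = 1.0, 0.0
    for n in range(1, kmax + 1):
        exre[n] = exre[n - 1] * cx - exim[n - 1] * sx
        exim[n] = exre[n - 1] * sx + exim[n - 1] * cx
    cy, sy = np.cos(tp * y), np.sin(tp * y)
    eyre[kmax], eyim[kmax] = 1.0, 0.0
    for n in range(1, kmax + 1):
        eyre[kmax + n] = eyre[kmax + n - 1] * cy - eyim[kmax + n - 1] * sy
        eyim[kmax + n] = eyre[kmax + n - 1] * sy + eyim[kmax + n - 1] * cy
        eyre[kmax - n] = eyre[kmax + n]
        eyim[kmax - n] = -eyim[kmax + n]
    cz, sz = np.cos(tp * z), np.sin(tp * z)
    ezre[kmax], ezim[kmax] = 1.0, 0.0
    for n in range(1, kmax + 1):
        ezre[kmax + n] = ezre[kmax + n - 1] * cz - ezim[kmax + n - 1] * sz
        ezim[kmax + n] = ezre[kmax + n - 1] * sz + ezim[kmax + n - 1] * cz
        ezre[kmax - n] = ezre[kmax + n]
        ezim[kmax - n] = -ezim[kmax + n]


@njit(cache=True)
def _accum_sk(qv, kmax, kint, exre, exim, eyre, eyim, ezre, ezim, Sre, Sim):
    """Add qv * exp(i k.r) (tables already filled for r) into S(k)."""
    for k in range(kint.shape[0]):
        nx = kint[k, 0]
        ny = kint[k, 1] + kmax
        nz = kint[k, 2] + kmax
        are = exre[nx] * eyre[ny] - exim[nx] * eyim[ny]
        aim = exre[nx] * eyim[ny] + exim[nx] * eyre[ny]
        bre = are * ezre[nz] - aim * ezim[nz]
        bim = are * ezim[nz] + aim * ezre[nz]
        Sre[k] += qv * bre
        Sim[k] += qv * bim


@njit(cache=True)
def calc_structure_factor(pos, q, L, kmax, kint):
    K = kint.shape[0]
    Sre = np.zeros(K)
    Sim = np.zeros(K)
    exre = np.empty(kmax + 1)
    exim = np.empty(kmax + 1)
    eyre = np.empty(2 * kmax + 1)
    eyim = np.empty(2 * kmax + 1)
    ezre = np.empty(2 * kmax + 1)
    ezim = np.empty(2 * kmax + 1)
    for i in range(pos.shape[0]):
        if q[i] != 0.0:
            _fill_tables(pos[i, 0], pos[i, 1], pos[i, 2], L, kmax,
                         exre, exim, eyre, eyim, ezre, ezim)
            _accum_sk(q[i], kmax, kint, exre, exim, eyre, eyim, ezre, ezim, Sre, Sim)
    return Sre, Sim


@njit(cache=True)
def recip_energy(Sre, Sim, kcoef):
    u = 0.0
    for k in range(kcoef.shape[0]):
        u += kcoef[k] * (Sre[k] * Sre[k] + Sim[k] * Sim[k])
    return u


@njit(cache=True)
def self_energy(q, alpha, bjerrum):
    s = 0.0
    for i in range(q.shape[0]):
        s += q[i] * q[i]
    return -bjerrum * alpha / SQRT_PI * s


@njit(cache=True)
def real_space_energy(pos, q, L, bjerrum, alpha, rcut):
    """O(N^2) minimum-image erfc-screened Coulomb energy."""
    n = pos.shape[0]
    u = 0.0
    for i in range(n):
        if q[i] == 0.0:
            continue
        for j in range(i + 1, n):
            if q[j] == 0.0:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dx -= L * np.rint(dx / L)
            dy = pos[i, 1] - pos[j, 1]
            dy -= L * np.rint(dy / L)
            dz = pos[i, 2] - pos[j, 2]
            dz -= L * np.rint(dz / L)
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            if r < rcut:
                u += bjerrum * q[i] * q[j] * math.erfc(alpha * r) / r
    return u


@njit(cache=True)
def any_overlap(pos, rad, L):
    n = pos.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dx -= L * np.rint(dx / L)
            dy = pos[i, 1] - pos[j, 1]
            dy -= L * np.rint(dy / L)
            dz = pos[i, 2] - pos[j, 2]
            dz -= L * np.rint(dz / L)
            s = rad[i] + rad[j]
            if dx * dx + dy * dy + dz * dz < s * s - 1e-12:
                return True
    return False


# ---------------------------------------------------------------------------
# Bonded terms
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _mi_vec(ax, ay, az, bx, by, bz, L):
    dx = bx - ax
    dx -= L * np.rint(dx / L)
    dy = by - ay
    dy -= L * np.rint(dy / L)
    dz = bz - az
    dz -= L * np.rint(dz / L)
    return dx, dy, dz


@njit(cache=True)
def _angle_at(pos, a, b, c, L):
    """Interior angle at vertex b of the bonded triple (a, b, c)."""
    ux, uy, uz = _mi_vec(pos[b, 0], pos[b, 1], pos[b, 2], pos[a, 0], pos[a, 1], pos[a, 2], L)
    vx, vy, vz = _mi_vec(pos[b, 0], pos[b, 1], pos[b, 2], pos[c, 0], pos[c, 1], pos[c, 2], L)
    nu = math.sqrt(ux * ux + uy * uy + uz * uz)
    nv = math.sqrt(vx * vx + vy * vy + vz * vz)
    cth = (ux * vx + uy * vy + uz * vz) / (nu * nv)
    if cth > 1.0:
        cth = 1.0
    elif cth < -1.0:
        cth = -1.0
    return math.acos(cth)


@njit(cache=True)
def chain_bonded_energy(pos, start, ln, L, bond_k, r0, angle_k, theta0):
    ub = 0.0
    ua = 0.0
    for j in range(start, start + ln - 1):
        dx, dy, dz = _mi_vec(pos[j, 0], pos[j, 1], pos[j, 2],
                             pos[j + 1, 0], pos[j + 1, 1], pos[j + 1, 2], L)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        ub += bond_k * (r - r0) ** 2
    if angle_k != 0.0:
        for j in range(start + 1, start + ln - 1):
            th = _angle_at(pos, j - 1, j, j + 1, L)
            ua += angle_k * (th - theta0) ** 2
    return ub, ua


@njit(cache=True)
def total_bonded_energy(pos, chain_start, chain_len, L, bond_k, r0, angle_k, theta0):
    ub = 0.0
    ua = 0.0
    for c in range(chain_start.shape[0]):
        b, a = chain_bonded_energy(pos, chain_start[c], chain_len[c], L,
                                   bond_k, r0, angle_k, theta0)
        ub += b
        ua += a
    return ub, ua


@njit(cache=True)
def _local_bonded(pos, start, ln, j, L, bond_k, r0, angle_k, theta0):
    """Bond/angle energy of all terms touching bead j of a chain."""
    ub = 0.0
    ua = 0.0
    if j > start:
        dx, dy, dz = _mi_vec(pos[j - 1, 0], pos[j - 1, 1], pos[j - 1, 2],
                             pos[j, 0], pos[j, 1], pos[j, 2], L)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        ub += bond_k * (r - r0) ** 2
    if j < start + ln - 1:
        dx, dy, dz = _mi_vec(pos[j, 0], pos[j, 1], pos[j, 2],
                             pos[j + 1, 0], pos[j + 1, 1], pos[j + 1, 2], L)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        ub += bond_k * (r - r0) ** 2
    if angle_k != 0.0:
        for m in (j - 1, j, j + 1):
            if m - 1 >= start and m + 1 <= start + ln - 1:
                th = _angle_at(pos, m - 1, m, m + 1, L)
                ua += angle_k * (th - theta0) ** 2
    return ub, ua


# ---------------------------------------------------------------------------
# Per-move energy differences
# ---------------------------------------------------------------------------


@njit(cache=True)
def _du_single_bead(pos, q, rad, L, bjerrum, alpha, rcut, i, nx, ny, nz):
    """Real-space and hard-sphere change when bead i moves to (nx,ny,nz)."""
    n = pos.shape[0]
    du = 0.0
    qi = q[i]
    for j in range(n):
        if j == i:
            continue
        dxo = pos[i, 0] - pos[j, 0]
        dxo -= L * np.rint(dxo / L)
        dyo = pos[i, 1] - pos[j, 1]
        dyo -= L * np.rint(dyo / L)
        dzo = pos[i, 2] - pos[j, 2]
        dzo -= L * np.rint(dzo / L)
        dxn = nx - pos[j, 0]
        dxn -= L * np.rint(dxn / L)
        dyn = ny - pos[j, 1]
        dyn -= L * np.rint(dyn / L)
        dzn = nz - pos[j, 2]
        dzn -= L * np.rint(dzn / L)
        r2n = dxn * dxn + dyn * dyn + dzn * dzn
        s = rad[i] + rad[j]
        if r2n < s * s - 1e-12:
            return 0.0, True
        if qi != 0.0 and q[j] != 0.0:
            rn = math.sqrt(r2n)
            ro = math.sqrt(dxo * dxo + dyo * dyo + dzo * dzo)
            if rn < rcut:
                du += bjerrum * qi * q[j] * math.erfc(alpha * rn) / rn
            if ro < rcut:
                du -= bjerrum * qi * q[j] * math.erfc(alpha * ro) / ro
    return du, False


@njit(cache=True)
def _psi_rest(pos, q, L, bjerrum, alpha, rcut, lo, hi, x, y, z):
    """erfc-screened potential at (x,y,z) from all beads outside [lo, hi)."""
    u = 0.0
    for j in range(pos.shape[0]):
        if lo <= j < hi or q[j] == 0.0:
            continue
        dx = x - pos[j, 0]
        dx -= L * np.rint(dx / L)
        dy = y - pos[j, 1]
        dy -= L * np.rint(dy / L)
        dz = z - pos[j, 2]
        dz -= L * np.rint(dz / L)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < rcut:
            u += bjerrum * q[j] * math.erfc(alpha * r) / r
    return u


@njit(cache=True)
def _overlap_vs_rest(pos, rad, L, lo, hi, x, y, z, ri):
    for j in range(pos.shape[0]):
        if lo <= j < hi:
            continue
        dx = x - pos[j, 0]
        dx -= L * np.rint(dx / L)
        dy = y - pos[j, 1]
        dy -= L * np.rint(dy / L)
        dz = z - pos[j, 2]
        dz -= L * np.rint(dz / L)
        s = ri + rad[j]
        if dx * dx + dy * dy + dz * dz < s * s - 1e-12:
            return True
    return False


@njit(cache=True)
def _du_recip_from_dS(kcoef, Sre, Sim, dSre, dSim):
    du = 0.0
    for k in range(kcoef.shape[0]):
        du += kcoef[k] * (
            2.0 * Sre[k] * dSre[k] + dSre[k] * dSre[k]
            + 2.0 * Sim[k] * dSim[k] + dSim[k] * dSim[k]
        )
    return du


# ---------------------------------------------------------------------------
# The NVT Metropolis loop
# ---------------------------------------------------------------------------

MOVE_DISPLACE = 0
MOVE_TRANSLATE = 1
MOVE_CRANK = 2
MOVE_REPTATE = 3


@njit(cache=True)
def mc_run(pos, q, rad, L, bjerrum, alpha, rcut, kmax, kint, kcoef,
           chain_start, chain_len, bead_chain,
           bond_k, r0, angle_k, theta0,
           n_sweeps, sample_every, collect, tune,
           wcum, dmax, crank_max, rept_rmax, seed):
    """Run n_sweeps of NVT Metropolis MC in place.

    A sweep is N_tot attempted moves drawn from {bead displacement, chain
    translation, crankshaft/end rotation, reptation} with cumulative weights
    wcum.  Returns sampled frames, the bookkept energy trace (ES + bonded,
    hard spheres contribute zero in accepted states), per-move-type
    (attempts, accepts) counters and the (possibly tuned) max displacements.
    """
    np.random.seed(seed)
    ntot = pos.shape[0]
    nchain = chain_start.shape[0]
    K = kint.shape[0]

    Sre, Sim = calc_structure_factor(pos, q, L, kmax, kint)
    u_real = real_space_energy(pos, q, L, bjerrum, alpha, rcut)
    u_recip = recip_energy(Sre, Sim, kcoef)
    u_self = self_energy(q, alpha, bjerrum)
    u_bond, u_angle = total_bonded_energy(pos, chain_start, chain_len, L,
                                          bond_k, r0, angle_k, theta0)

    exre = np.empty(kmax + 1)
    exim = np.empty(kmax + 1)
    eyre = np.empty(2 * kmax + 1)
    eyim = np.empty(2 * kmax + 1)
    ezre = np.empty(2 * kmax + 1)
    ezim = np.empty(2 * kmax + 1)
    dSre = np.empty(K)
    dSim = np.empty(K)
    newpos = np.empty((pos.shape[0], 3))

    n_samples = n_sweeps // sample_every if collect else 0
    frames = np.empty((n_samples, ntot, 3))
    utrace = np.empty(n_samples)
    isamp = 0

    att = np.zeros(4, dtype=np.int64)
    acc = np.zeros(4, dtype=np.int64)
    att_win = np.zeros(4, dtype=np.int64)
    acc_win = np.zeros(4, dtype=np.int64)

    for sweep in range(n_sweeps):
        for _ in range(ntot):
            u = np.random.random()
            mt = 0
            while u > wcum[mt]:
                mt += 1
            att[mt] += 1
            att_win[mt] += 1

            if mt == MOVE_DISPLACE:
                i = np.random.randint(0, ntot)
                nx = pos[i, 0] + (np.random.random() - 0.5) * 2.0 * dmax[0]
                ny = pos[i, 1] + (np.random.random() - 0.5) * 2.0 * dmax[0]
                nz = pos[i, 2] + (np.random.random() - 0.5) * 2.0 * dmax[0]
                nx -= L * np.floor(nx / L)
                ny -= L * np.floor(ny / L)
                nz -= L * np.floor(nz / L)
                du_real, ov = _du_single_bead(pos, q, rad, L, bjerrum, alpha,
                                              rcut, i, nx, ny, nz)
                if ov:
                    continue
                du_b = 0.0
                du_a = 0.0
                c = bead_chain[i]
                if c >= 0:
                    ob, oa = _local_bonded(pos, chain_start[c], chain_len[c], i,
                                           L, bond_k, r0, angle_k, theta0)
                    ox, oy, oz = pos[i, 0], pos[i, 1], pos[i, 2]
                    pos[i, 0], pos[i, 1], pos[i, 2] = nx, ny, nz
                    nb, na = _local_bonded(pos, chain_start[c], chain_len[c], i,
                                           L, bond_k, r0, angle_k, theta0)
                    pos[i, 0], pos[i, 1], pos[i, 2] = ox, oy, oz
                    du_b = nb - ob
                    du_a = na - oa
                du_recip = 0.0
                if q[i] != 0.0 and K > 0:
                    for k in range(K):
                        dSre[k] = 0.0
                        dSim[k] = 0.0
                    _fill_tables(pos[i, 0], pos[i, 1], pos[i, 2], L, kmax,
                                 exre, exim, eyre, eyim, ezre, ezim)
                    _accum_sk(-q[i], kmax, kint, exre, exim, eyre, eyim,
                              ezre, ezim, dSre, dSim)
                    _fill_tables(nx, ny, nz, L, kmax,
                                 exre, exim, eyre, eyim, ezre, ezim)
                    _accum_sk(q[i], kmax, kint, exre, exim, eyre, eyim,
                              ezre, ezim, dSre, dSim)
                    du_recip = _du_recip_from_dS(kcoef, Sre, Sim, dSre, dSim)
                du = du_real + du_recip + du_b + du_a
                if du <= 0.0 or np.random.random() < math.exp(-du):
                    pos[i, 0], pos[i, 1], pos[i, 2] = nx, ny, nz
                    if q[i] != 0.0:
                        for k in range(K):
                            Sre[k] += dSre[k]
                            Sim[k] += dSim[k]
                    u_real += du_real
                    u_recip += du_recip
                    u_bond += du_b
                    u_angle += du_a
                    acc[mt] += 1
                    acc_win[mt] += 1

            elif mt == MOVE_TRANSLATE:
                if nchain == 0:
                    continue
                c = np.random.randint(0, nchain)
                st = chain_start[c]
                ln = chain_len[c]
                tx = (np.random.random() - 0.5) * 2.0 * dmax[1]
                ty = (np.random.random() - 0.5) * 2.0 * dmax[1]
                tz = (np.random.random() - 0.5) * 2.0 * dmax[1]
                du_real = 0.0
                ov = False
                for m in range(st, st + ln):
                    nx = pos[m, 0] + tx
                    ny = pos[m, 1] + ty
                    nz = pos[m, 2] + tz
                    nx -= L * np.floor(nx / L)
                    ny -= L * np.floor(ny / L)
                    nz -= L * np.floor(nz / L)
                    newpos[m, 0], newpos[m, 1], newpos[m, 2] = nx, ny, nz
                    if _overlap_vs_rest(pos, rad, L, st, st + ln, nx, ny, nz, rad[m]):
                        ov = True
                        break
                    if q[m] != 0.0:
                        du_real += q[m] * (
                            _psi_rest(pos, q, L, bjerrum, alpha, rcut,
                                      st, st + ln, nx, ny, nz)
                            - _psi_rest(pos, q, L, bjerrum, alpha, rcut,
                                        st, st + ln, pos[m, 0], pos[m, 1], pos[m, 2])
                        )
                if ov:
                    continue
                du_recip = 0.0
                if K > 0:
                    for k in range(K):
                        dSre[k] = 0.0
                        dSim[k] = 0.0
                    for m in range(st, st + ln):
                        if q[m] == 0.0:
                            continue
                        _fill_tables(pos[m, 0], pos[m, 1], pos[m, 2], L, kmax,
                                     exre, exim, eyre, eyim, ezre, ezim)
                        _accum_sk(-q[m], kmax, kint, exre, exim, eyre, eyim,
                                  ezre, ezim, dSre, dSim)
                        _fill_tables(newpos[m, 0], newpos[m, 1], newpos[m, 2],
                                     L, kmax, exre, exim, eyre, eyim, ezre, ezim)
                        _accum_sk(q[m], kmax, kint, exre, exim, eyre, eyim,
                                  ezre, ezim, dSre, dSim)
                    du_recip = _du_recip_from_dS(kcoef, Sre, Sim, dSre, dSim)
                du = du_real + du_recip  # internal geometry unchanged
                if du <= 0.0 or np.random.random() < math.exp(-du):
                    for m in range(st, st + ln):
                        pos[m, 0] = newpos[m, 0]
                        pos[m, 1] = newpos[m, 1]
                        pos[m, 2] = newpos[m, 2]
                    for k in range(K):
                        Sre[k] += dSre[k]
                        Sim[k] += dSim[k]
                    u_real += du_real
                    u_recip += du_recip
                    acc[mt] += 1
                    acc_win[mt] += 1

            elif mt == MOVE_CRANK:
                if nchain == 0:
                    continue
                c = np.random.randint(0, nchain)
                st = chain_start[c]
                ln = chain_len[c]
                if ln < 2:
                    continue
                j = st + np.random.randint(0, ln)
                ang = (np.random.random() - 0.5) * 2.0 * crank_max
                if st < j < st + ln - 1:
                    # rotate about the axis through the two bonded neighbours
                    ax, ay, az = _mi_vec(pos[j - 1, 0], pos[j - 1, 1], pos[j - 1, 2],
                                         pos[j + 1, 0], pos[j + 1, 1], pos[j + 1, 2], L)
                    piv0, piv1, piv2 = pos[j - 1, 0], pos[j - 1, 1], pos[j - 1, 2]
                else:
                    # end bead: rotate about a random axis through its neighbour
                    nb = j + 1 if j == st else j - 1
                    piv0, piv1, piv2 = pos[nb, 0], pos[nb, 1], pos[nb, 2]
                    while True:
                        ax = np.random.random() * 2.0 - 1.0
                        ay = np.random.random() * 2.0 - 1.0
                        az = np.random.random() * 2.0 - 1.0
                        if 1e-8 < ax * ax + ay * ay + az * az <= 1.0:
                            break
                an = math.sqrt(ax * ax + ay * ay + az * az)
                if an < 1e-12:
                    continue
                ax /= an
                ay /= an
                az /= an
                vx, vy, vz = _mi_vec(piv0, piv1, piv2,
                                     pos[j, 0], pos[j, 1], pos[j, 2], L)
                ca, sa = math.cos(ang), math.sin(ang)
                dot = ax * vx + ay * vy + az * vz
                cxx = ay * vz - az * vy
                cyy = az * vx - ax * vz
                czz = ax * vy - ay * vx
                rx = vx * ca + cxx * sa + ax * dot * (1.0 - ca)
                ry = vy * ca + cyy * sa + ay * dot * (1.0 - ca)
                rz = vz * ca + czz * sa + az * dot * (1.0 - ca)
                nx = piv0 + rx
                ny = piv1 + ry
                nz = piv2 + rz
                nx -= L * np.floor(nx / L)
                ny -= L * np.floor(ny / L)
                nz -= L * np.floor(nz / L)
                du_real, ov = _du_single_bead(pos, q, rad, L, bjerrum, alpha,
                                              rcut, j, nx, ny, nz)
                if ov:
                    continue
                ob, oa = _local_bonded(pos, st, ln, j, L, bond_k, r0, angle_k, theta0)
                ox, oy, oz = pos[j, 0], pos[j, 1], pos[j, 2]
                pos[j, 0], pos[j, 1], pos[j, 2] = nx, ny, nz
                nb_, na_ = _local_bonded(pos, st, ln, j, L, bond_k, r0, angle_k, theta0)
                pos[j, 0], pos[j, 1], pos[j, 2] = ox, oy, oz
                du_b = nb_ - ob
                du_a = na_ - oa
                du_recip = 0.0
                if q[j] != 0.0 and K > 0:
                    for k in range(K):
                        dSre[k] = 0.0
                        dSim[k] = 0.0
                    _fill_tables(pos[j, 0], pos[j, 1], pos[j, 2], L, kmax,
                                 exre, exim, eyre, eyim, ezre, ezim)
                    _accum_sk(-q[j], kmax, kint, exre, exim, eyre, eyim,
                              ezre, ezim, dSre, dSim)
                    _fill_tables(nx, ny, nz, L, kmax,
                                 exre, exim, eyre, eyim, ezre, ezim)
                    _accum_sk(q[j], kmax, kint, exre, exim, eyre, eyim,
                              ezre, ezim, dSre, dSim)
                    du_recip = _du_recip_from_dS(kcoef, Sre, Sim, dSre, dSim)
                du = du_real + du_recip + du_b + du_a
                if du <= 0.0 or np.random.random() < math.exp(-du):
                    pos[j, 0], pos[j, 1], pos[j, 2] = nx, ny, nz
                    if q[j] != 0.0:
                        for k in range(K):
                            Sre[k] += dSre[k]
                            Sim[k] += dSim[k]
                    u_real += du_real
                    u_recip += du_recip
                    u_bond += du_b
                    u_angle += du_a
                    acc[mt] += 1
                    acc_win[mt] += 1

            else:  # MOVE_REPTATE: slide positions along the contour
                if nchain == 0:
                    continue
                c = np.random.randint(0, nchain)
                st = chain_start[c]
                ln = chain_len[c]
                if ln < 2:
                    continue
                headward = np.random.random() < 0.5
                # indices of removed bead / attachment bead for the new end
                if headward:
                    rem = st
                    att_old = st + 1
                    grow_from = st + ln - 1
                else:
                    rem = st + ln - 1
                    att_old = st + ln - 2
                    grow_from = st
                # reverse-move feasibility: broken bond must fit the proposal ball
                dx, dy, dz = _mi_vec(pos[att_old, 0], pos[att_old, 1], pos[att_old, 2],
                                     pos[rem, 0], pos[rem, 1], pos[rem, 2], L)
                if dx * dx + dy * dy + dz * dz > rept_rmax * rept_rmax:
                    continue
                # draw the new end uniformly in a ball around the old end bead
                while True:
                    ux = (np.random.random() * 2.0 - 1.0)
                    uy = (np.random.random() * 2.0 - 1.0)
                    uz = (np.random.random() * 2.0 - 1.0)
                    if ux * ux + uy * uy + uz * uz <= 1.0:
                        break
                gx = pos[grow_from, 0] + ux * rept_rmax
                gy = pos[grow_from, 1] + uy * rept_rmax
                gz = pos[grow_from, 2] + uz * rept_rmax
                gx -= L * np.floor(gx / L)
                gy -= L * np.floor(gy / L)
                gz -= L * np.floor(gz / L)
                # new chain positions (charges stay with their indices)
                if headward:
                    for m in range(ln - 1):
                        newpos[st + m, 0] = pos[st + m + 1, 0]
                        newpos[st + m, 1] = pos[st + m + 1, 1]
                        newpos[st + m, 2] = pos[st + m + 1, 2]
                    newpos[st + ln - 1, 0] = gx
                    newpos[st + ln - 1, 1] = gy
                    newpos[st + ln - 1, 2] = gz
                else:
                    for m in range(ln - 1, 0, -1):
                        newpos[st + m, 0] = pos[st + m - 1, 0]
                        newpos[st + m, 1] = pos[st + m - 1, 1]
                        newpos[st + m, 2] = pos[st + m - 1, 2]
                    newpos[st, 0] = gx
                    newpos[st, 1] = gy
                    newpos[st, 2] = gz
                if _overlap_vs_rest(pos, rad, L, rem, rem + 1, gx, gy, gz, rad[rem]):
                    continue
                ov = False
                for m in range(st, st + ln):
                    if m == rem:
                        continue
                    dx, dy, dz = _mi_vec(pos[m, 0], pos[m, 1], pos[m, 2], gx, gy, gz, L)
                    s = rad[m] + rad[rem]
                    if dx * dx + dy * dy + dz * dz < s * s - 1e-12:
                        ov = True
                        break
                if ov:
                    continue
                du_real = 0.0
                for m in range(st, st + ln):
                    if q[m] == 0.0:
                        continue
                    du_real += q[m] * (
                        _psi_rest(pos, q, L, bjerrum, alpha, rcut, st, st + ln,
                                  newpos[m, 0], newpos[m, 1], newpos[m, 2])
                        - _psi_rest(pos, q, L, bjerrum, alpha, rcut, st, st + ln,
                                    pos[m, 0], pos[m, 1], pos[m, 2])
                    )
                # internal electrostatics old/new
                for m in range(st, st + ln):
                    if q[m] == 0.0:
                        continue
                    for m2 in range(m + 1, st + ln):
                        if q[m2] == 0.0:
                            continue
                        dx, dy, dz = _mi_vec(pos[m, 0], pos[m, 1], pos[m, 2],
                                             pos[m2, 0], pos[m2, 1], pos[m2, 2], L)
                        r = math.sqrt(dx * dx + dy * dy + dz * dz)
                        if r < rcut:
                            du_real -= bjerrum * q[m] * q[m2] * math.erfc(alpha * r) / r
                        dx, dy, dz = _mi_vec(newpos[m, 0], newpos[m, 1], newpos[m, 2],
                                             newpos[m2, 0], newpos[m2, 1], newpos[m2, 2], L)
                        r = math.sqrt(dx * dx + dy * dy + dz * dz)
                        if r < rcut:
                            du_real += bjerrum * q[m] * q[m2] * math.erfc(alpha * r) / r
                du_recip = 0.0
                if K > 0:
                    for k in range(K):
                        dSre[k] = 0.0
                        dSim[k] = 0.0
                    for m in range(st, st + ln):
                        if q[m] != 0.0:
                            _fill_tables(pos[m, 0], pos[m, 1], pos[m, 2], L, kmax,
                                         exre, exim, eyre, eyim, ezre, ezim)
                            _accum_sk(-q[m], kmax, kint, exre, exim, eyre, eyim,
                                      ezre, ezim, dSre, dSim)
                            _fill_tables(newpos[m, 0], newpos[m, 1], newpos[m, 2],
                                         L, kmax, exre, exim, eyre, eyim, ezre, ezim)
                            _accum_sk(q[m], kmax, kint, exre, exim, eyre, eyim,
                                      ezre, ezim, dSre, dSim)
                    du_recip = _du_recip_from_dS(kcoef, Sre, Sim, dSre, dSim)
                ob, oa = chain_bonded_energy(pos, st, ln, L, bond_k, r0, angle_k, theta0)
                for m in range(st, st + ln):
                    ox = pos[m, 0]
                    pos[m, 0] = newpos[m, 0]
                    newpos[m, 0] = ox
                    oy = pos[m, 1]
                    pos[m, 1] = newpos[m, 1]
                    newpos[m, 1] = oy
                    oz = pos[m, 2]
                    pos[m, 2] = newpos[m, 2]
                    newpos[m, 2] = oz
                nb_, na_ = chain_bonded_energy(pos, st, ln, L, bond_k, r0, angle_k, theta0)
                du_b = nb_ - ob
                du_a = na_ - oa
                du = du_real + du_recip + du_b + du_a
                if du <= 0.0 or np.random.random() < math.exp(-du):
                    for k in range(K):
                        Sre[k] += dSre[k]
                        Sim[k] += dSim[k]
                    u_real += du_real
                    u_recip += du_recip
                    u_bond += du_b
                    u_angle += du_a
                    acc[mt] += 1
                    acc_win[mt] += 1
                else:
                    for m in range(st, st + ln):  # restore old positions
                        pos[m, 0] = newpos[m, 0]
                        pos[m, 1] = newpos[m, 1]
                        pos[m, 2] = newpos[m, 2]

        if tune and (sweep + 1) % 50 == 0:
            for mi, slot in ((MOVE_DISPLACE, 0), (MOVE_TRANSLATE, 1)):
                if att_win[mi] > 0:
                    frac = acc_win[mi] / att_win[mi]
                    if frac > 0.45:
                        dmax[slot] = min(dmax[slot] * 1.1, L / 4.0)
                    elif frac < 0.35:
                        dmax[slot] = max(dmax[slot] * 0.9, 1e-3)
            for k4 in range(4):
                att_win[k4] = 0
                acc_win[k4] = 0

        if collect and (sweep + 1) % sample_every == 0:
            for i in range(ntot):
                frames[isamp, i, 0] = pos[i, 0]
                frames[isamp, i, 1] = pos[i, 1]
                frames[isamp, i, 2] = pos[i, 2]
            utrace[isamp] = u_real + u_recip + u_self + u_bond + u_angle
            isamp += 1

    return frames, utrace, att, acc, dmax


# ---------------------------------------------------------------------------
# Widom insertion (single beads, neutral ion groups, Rosenbluth chains)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _trial_energy(pos, q, rad, L, bjerrum, alpha, rcut, gpos, gq, grad, nplaced,
                  x, y, z, qt, rt):
    """HS + real-space energy of a trial point against system and placed
    group beads; returns (energy, overlap)."""
    u = 0.0
    for j in range(pos.shape[0]):
        dx = x - pos[j, 0]
        dx -= L * np.rint(dx / L)
        dy = y - pos[j, 1]
        dy -= L * np.rint(dy / L)
        dz = z - pos[j, 2]
        dz -= L * np.rint(dz / L)
        r2 = dx * dx + dy * dy + dz * dz
        s = rt + rad[j]
        if r2 < s * s - 1e-12:
            return 0.0, True
        if qt != 0.0 and q[j] != 0.0:
            r = math.sqrt(r2)
            if r < rcut:
                u += bjerrum * qt * q[j] * math.erfc(alpha * r) / r
    for m in range(nplaced):
        dx = x - gpos[m, 0]
        dx -= L * np.rint(dx / L)
        dy = y - gpos[m, 1]
        dy -= L * np.rint(dy / L)
        dz = z - gpos[m, 2]
        dz -= L * np.rint(dz / L)
        r2 = dx * dx + dy * dy + dz * dz
        s = rt + grad[m]
        if r2 < s * s - 1e-12:
            return 0.0, True
        if qt != 0.0 and gq[m] != 0.0:
            r = math.sqrt(r2)
            if r < rcut:
                u += bjerrum * qt * gq[m] * math.erfc(alpha * r) / r
    return u, False


@njit(cache=True)
def _stage_weight(pos, q, rad, L, bjerrum, alpha, rcut,
                  gpos, gq, grad, gprev, m, angle_k, theta0,
                  bond_rq, k_trial, ion_mix_R, V, Vball,
                  centers, tx, ty, tz, tw):
    """Grow group bead m of one partial insertion: proposes k_trial
    positions, returns the stage weight (0 when all trials die) and writes
    the selected position into gpos[m]."""
    nq = bond_rq.shape[0]
    ncen = 0
    if gprev[m] < 0 and gq[m] != 0.0:
        for b in range(m):
            if gq[b] * gq[m] < 0.0:
                centers[ncen, 0] = gpos[b, 0]
                centers[ncen, 1] = gpos[b, 1]
                centers[ncen, 2] = gpos[b, 2]
                ncen += 1
    wsum = 0.0
    for t in range(k_trial):
        imp = 1.0  # importance-weight factor 1/(V p)
        if gprev[m] < 0:
            if ncen > 0 and np.random.random() < 0.5:
                c = np.random.randint(0, ncen)
                while True:
                    ux = np.random.random() * 2.0 - 1.0
                    uy = np.random.random() * 2.0 - 1.0
                    uz = np.random.random() * 2.0 - 1.0
                    if ux * ux + uy * uy + uz * uz <= 1.0:
                        break
                x = centers[c, 0] + ux * ion_mix_R
                y = centers[c, 1] + uy * ion_mix_R
                z = centers[c, 2] + uz * ion_mix_R
                x -= L * np.floor(x / L)
                y -= L * np.floor(y / L)
                z -= L * np.floor(z / L)
            else:
                x = np.random.random() * L
                y = np.random.random() * L
                z = np.random.random() * L
            if ncen > 0:
                # p(r) = 0.5/V + 0.5 * n_inside / (ncen * Vball)
                nin = 0
                for c in range(ncen):
                    dx = x - centers[c, 0]
                    dx -= L * np.rint(dx / L)
                    dy = y - centers[c, 1]
                    dy -= L * np.rint(dy / L)
                    dz = z - centers[c, 2]
                    dz -= L * np.rint(dz / L)
                    if dx * dx + dy * dy + dz * dz <= ion_mix_R * ion_mix_R:
                        nin += 1
                imp = 1.0 / (0.5 + 0.5 * V * nin / (ncen * Vball))
        else:
            # bond vector from the parent chain bead
            p = gprev[m]
            rb = bond_rq[np.random.randint(0, nq)]
            while True:
                ux = np.random.random() * 2.0 - 1.0
                uy = np.random.random() * 2.0 - 1.0
                uz = np.random.random() * 2.0 - 1.0
                n2 = ux * ux + uy * uy + uz * uz
                if 1e-8 < n2 <= 1.0:
                    break
            n1 = math.sqrt(n2)
            x = gpos[p, 0] + rb * ux / n1
            y = gpos[p, 1] + rb * uy / n1
            z = gpos[p, 2] + rb * uz / n1
            x -= L * np.floor(x / L)
            y -= L * np.floor(y / L)
            z -= L * np.floor(z / L)
        u, ov = _trial_energy(pos, q, rad, L, bjerrum, alpha, rcut,
                              gpos, gq, grad, m, x, y, z, gq[m], grad[m])
        if (not ov) and angle_k != 0.0 and gprev[m] >= 0 and gprev[gprev[m]] >= 0:
            p = gprev[m]
            pp = gprev[p]
            ax1, ay1, az1 = _mi_vec(gpos[p, 0], gpos[p, 1], gpos[p, 2],
                                    gpos[pp, 0], gpos[pp, 1], gpos[pp, 2], L)
            bx1, by1, bz1 = _mi_vec(gpos[p, 0], gpos[p, 1], gpos[p, 2],
                                    x, y, z, L)
            na_ = math.sqrt(ax1 * ax1 + ay1 * ay1 + az1 * az1)
            nb2 = math.sqrt(bx1 * bx1 + by1 * by1 + bz1 * bz1)
            cth = (ax1 * bx1 + ay1 * by1 + az1 * bz1) / (na_ * nb2)
            if cth > 1.0:
                cth = 1.0
            elif cth < -1.0:
                cth = -1.0
            u += angle_k * (math.acos(cth) - theta0) ** 2
        if ov or u > 500.0:
            tw[t] = 0.0
        else:
            tw[t] = math.exp(-u) * imp
        tx[t], ty[t], tz[t] = x, y, z
        wsum += tw[t]
    if wsum <= 0.0:
        return 0.0
    pick = np.random.random() * wsum
    acc_ = 0.0
    sel = k_trial - 1
    for t in range(k_trial):
        acc_ += tw[t]
        if pick <= acc_:
            sel = t
            break
    gpos[m, 0], gpos[m, 1], gpos[m, 2] = tx[sel], ty[sel], tz[sel]
    return wsum / k_trial


@njit(cache=True)
def _insertion_ewald_corr(gpos, gq, L, bjerrum, alpha, kmax, kint, kcoef,
                          Sre, Sim, dSre, dSim,
                          exre, exim, eyre, eyim, ezre, ezim):
    """Reciprocal-space + self Ewald energy of inserting the completed
    group into the frame with structure factor (Sre, Sim)."""
    K = kint.shape[0]
    if K == 0:
        return 0.0
    for k in range(K):
        dSre[k] = 0.0
        dSim[k] = 0.0
    qsum2 = 0.0
    for m in range(gq.shape[0]):
        if gq[m] != 0.0:
            _fill_tables(gpos[m, 0], gpos[m, 1], gpos[m, 2], L, kmax,
                         exre, exim, eyre, eyim, ezre, ezim)
            _accum_sk(gq[m], kmax, kint, exre, exim, eyre, eyim,
                      ezre, ezim, dSre, dSim)
            qsum2 += gq[m] * gq[m]
    du = _du_recip_from_dS(kcoef, Sre, Sim, dSre, dSim)
    du += -bjerrum * alpha / SQRT_PI * qsum2
    return du


@njit(cache=True)
def widom_group(pos, q, rad, L, bjerrum, alpha, rcut, kmax, kint, kcoef,
                Sre, Sim, gprev, gq, grad,
                angle_k, theta0, bond_rq, n_ins, k_trial, seed,
                ion_mix_R=2.0, n_particles=16):
    """Sequential-Monte-Carlo Widom insertion of a neutral group.

    ``gprev[m]`` is the group index of the chain bead that bead m bonds to
    (-1 for free beads and for the first bead of a chain).  Bonded beads
    grow with trial bond vectors whose lengths come from the tabulated bond
    Boltzmann distribution ``bond_rq`` (the bond-length term then cancels
    from the weight); free counterions use an unbiased mixture proposal,
    half uniform in the box and half inside spheres of radius ``ion_mix_R``
    around placed opposite charges, with the exact 1/(V p) correction.
    Interleaving counterions with the charged monomers they neutralize (the
    caller's group order) keeps the partial group near-neutral.

    A population of ``n_particles`` partial insertions is grown bead by
    bead with systematic resampling between stages, which suppresses the
    weight degeneracy of plain Rosenbluth growth; the product of stage-mean
    weights is an unbiased estimator of exp(-mu_exc).  The reciprocal-space
    and self Ewald terms of the completed insertion enter as a final
    reweighting stage.  Returns one LOG-weight per replicate (n_ins //
    n_particles replicates, at least one); exp(-mu_exc) = <exp(logW)>, with
    dead replicates carrying logW = -inf (weight zero).
    """
    np.random.seed(seed)
    ng = gq.shape[0]
    K = kint.shape[0]
    M = n_particles
    n_rep = n_ins // M
    if n_rep < 1:
        n_rep = 1
    weights = np.full(n_rep, -np.inf)
    V = L * L * L
    Vball = 4.0 / 3.0 * np.pi * ion_mix_R**3
    centers = np.empty((ng, 3))
    exre = np.empty(kmax + 1)
    exim = np.empty(kmax + 1)
    eyre = np.empty(2 * kmax + 1)
    eyim = np.empty(2 * kmax + 1)
    ezre = np.empty(2 * kmax + 1)
    ezim = np.empty(2 * kmax + 1)
    dSre = np.empty(K)
    dSim = np.empty(K)
    tx = np.empty(k_trial)
    ty = np.empty(k_trial)
    tz = np.empty(k_trial)
    tw = np.empty(k_trial)
    gposP = np.empty((M, ng, 3))
    gposQ = np.empty((M, ng, 3))
    wvec = np.empty(M)
    tw_corr = np.empty(M)

    for rep in range(n_rep):
        logZ = 0.0
        alive = True
        for m in range(ng):
            tot = 0.0
            for i in range(M):
                wvec[i] = _stage_weight(pos, q, rad, L, bjerrum, alpha, rcut,
                                        gposP[i], gq, grad, gprev, m,
                                        angle_k, theta0, bond_rq, k_trial,
                                        ion_mix_R, V, Vball,
                                        centers, tx, ty, tz, tw)
                tot += wvec[i]
            if tot <= 0.0:
                alive = False
                break
            logZ += math.log(tot / M)
            if m < ng - 1:
                # systematic resampling of the partial insertions
                step = tot / M
                u0 = np.random.random() * step
                cum = 0.0
                j = 0
                for i in range(M):
                    target = u0 + i * step
                    while j < M - 1 and cum + wvec[j] < target:
                        cum += wvec[j]
                        j += 1
                    for mm in range(m + 1):
                        gposQ[i, mm, 0] = gposP[j, mm, 0]
                        gposQ[i, mm, 1] = gposP[j, mm, 1]
                        gposQ[i, mm, 2] = gposP[j, mm, 2]
                tmp = gposP
                gposP = gposQ
                gposQ = tmp
        if not alive:
            continue
        # final stage: Ewald reciprocal + self correction, averaged over the
        # population with the last stage weights (log-sum-exp form)
        dumin = 1e300
        for i in range(M):
            du = _insertion_ewald_corr(gposP[i], gq, L, bjerrum, alpha, kmax,
                                       kint, kcoef, Sre, Sim, dSre, dSim,
                                       exre, exim, eyre, eyim, ezre, ezim)
            tw_corr[i] = du
            if du < dumin:
                dumin = du
        tot = 0.0
        wtot = 0.0
        for i in range(M):
            tot += wvec[i] * math.exp(-(tw_corr[i] - dumin))
            wtot += wvec[i]
        weights[rep] = logZ - dumin + math.log(tot / wtot)
    return weights
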