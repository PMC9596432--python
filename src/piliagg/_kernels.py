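"""Numba kernels for the rigid-body Langevin integrator.

Everything here operates on flat numpy arrays so the hot loop (force
evaluation + BAOAB step) stays inside compiled code.  The public API lives in
:mod:`piliagg.dynamics`; nothing in this module is part of the package
surface.

Conventions
-----------
* positions are cell (body) centers, wrapped into ``[0, L)`` per axis;
* orientations are unit quaternions ``(w, x, y, z)``; adhesin world
  coordinates are always regenerated from the quaternion, never integrated;
* the random stream is an explicit xorshift64* state (one ``uint64``),
  advanced only inside the kernels, so a phase sequence is reproducible
  bit-for-bit from its seed;
* Langevin splitting is BAOAB (half kick, half drift, Ornstein-Uhlenbeck
  velocity refresh, half drift, half kick) for both linear and angular
  velocities, with isotropic rotational drag and inertia.

Adhesin world offsets are rotated on demand, only for cells that actually
appear in an interacting pair (or sit near a plate wall), and are kept in
structure-of-arrays layout (``Wx, Wy, Wz``) so the per-pair distance passes
vectorize.
"""

import numpy as np
from numba import njit

U64 = np.uint64
_ROOT6 = 2.0 ** (1.0 / 6.0)


# ---------------------------------------------------------------------------
# deterministic RNG (xorshift64* + Marsaglia polar normals)
# ---------------------------------------------------------------------------

def seed_rng_state(seed: int) -> np.ndarray:
    """SplitMix64-scrambled nonzero state for the xorshift64* stream."""
    with np.errstate(over="ignore"):
        x = U64(seed) + U64(0x9E3779B97F4A7C15)
        z = U64(x)
        z = U64(z ^ (z >> U64(30))) * U64(0xBF58476D1CE4E5B9)
        z = U64(z ^ (z >> U64(27))) * U64(0x94D049BB133111EB)
        z = U64(z ^ (z >> U64(31)))
    if z == U64(0):
        z = U64(0x9E3779B97F4A7C15)
    return np.array([z], dtype=np.uint64)


@njit(inline="always", cache=True)
def _next_u64(state):
    x = state[0]
    x ^= x >> U64(12)
    x ^= x << U64(25)
    x ^= x >> U64(27)
    state[0] = x
    return x * U64(0x2545F4914F6CDD1D)


@njit(inline="always", cache=True)
def _uniform(state):
    # in (0, 1): top 53 bits, offset by half an ulp so log() is safe
    return ((_next_u64(state) >> U64(11)) + 0.5) * (1.0 / 9007199254740992.0)


@njit(cache=True, fastmath=True)
def _fill_normals(state, out):
    """Fill a flat array with standard normals (Marsaglia polar pairs)."""
    n = out.size
    i = 0
    while i < n:
        while True:
            v1 = 2.0 * _uniform(state) - 1.0
            v2 = 2.0 * _uniform(state) - 1.0
            s = v1 * v1 + v2 * v2
            if 1e-300 < s < 1.0:
                break
        f = np.sqrt(-2.0 * np.log(s) / s)
        out[i] = v1 * f
        i += 1
        if i < n:
            out[i] = v2 * f
            i += 1


# ---------------------------------------------------------------------------
# quaternions
# ---------------------------------------------------------------------------

@njit(inline="always", cache=True)
def _quat_rotate_step(q, wx, wy, wz, h):
    """Left-multiply q by the rotation exp([w]*h) (world-frame angular velocity)."""
    w2 = wx * wx + wy * wy + wz * wz
    if w2 < 1e-28:
        return
    wmag = np.sqrt(w2)
    a = 0.5 * wmag * h  # half angle
    if a < 0.05:
        a2 = a * a
        c = 1.0 - a2 * 0.5 + a2 * a2 / 24.0
        s = (0.5 * h) * (1.0 - a2 / 6.0 + a2 * a2 / 120.0)  # sin(a)/|w|
    else:
        c = np.cos(a)
        s = np.sin(a) / wmag
    dx, dy, dz = s * wx, s * wy, s * wz
    qw, qx, qy, qz = q[0], q[1], q[2], q[3]
    nw = c * qw - dx * qx - dy * qy - dz * qz
    nx = c * qx + dx * qw + dy * qz - dz * qy
    ny = c * qy - dx * qz + dy * qw + dz * qx
    nz = c * qz + dx * qy - dy * qx + dz * qw
    norm = np.sqrt(nw * nw + nx * nx + ny * ny + nz * nz)
    q[0] = nw / norm
    q[1] = nx / norm
    q[2] = ny / norm
    q[3] = nz / norm


@njit(inline="always", cache=True)
def _rotate_local(quat, local, Wx, Wy, Wz, wdone, i):
    """Fill W*[i] = R(quat[i]) @ local (lazy, once per force evaluation)."""
    if wdone[i]:
        return
    w, x, y, z = quat[i, 0], quat[i, 1], quat[i, 2], quat[i, 3]
    r00 = 1.0 - 2.0 * (y * y + z * z)
    r01 = 2.0 * (x * y - w * z)
    r02 = 2.0 * (x * z + w * y)
    r10 = 2.0 * (x * y + w * z)
    r11 = 1.0 - 2.0 * (x * x + z * z)
    r12 = 2.0 * (y * z - w * x)
    r20 = 2.0 * (x * z - w * y)
    r21 = 2.0 * (y * z + w * x)
    r22 = 1.0 - 2.0 * (x * x + y * y)
    for k in range(local.shape[0]):
        lx, ly, lz = local[k, 0], local[k, 1], local[k, 2]
        Wx[i, k] = r00 * lx + r01 * ly + r02 * lz
        Wy[i, k] = r10 * lx + r11 * ly + r12 * lz
        Wz[i, k] = r20 * lx + r21 * ly + r22 * lz
    wdone[i] = 1


@njit(cache=True)
def _world_offsets(quat, local, W):
    """Adhesin world offsets W[i,k,:] for every cell (API helper, not hot)."""
    n = quat.shape[0]
    na = local.shape[0]
    Wx = np.empty((n, na))
    Wy = np.empty((n, na))
    Wz = np.empty((n, na))
    wdone = np.zeros(n, dtype=np.uint8)
    for i in range(n):
        _rotate_local(quat, local, Wx, Wy, Wz, wdone, i)
        for k in range(na):
            W[i, k, 0] = Wx[i, k]
            W[i, k, 1] = Wy[i, k]
            W[i, k, 2] = Wz[i, k]


# ---------------------------------------------------------------------------
# pair forces
# ---------------------------------------------------------------------------

@njit(inline="always", cache=True)
def _lj_mag_energy(r, s, eps, fcap):
    """(-dE/dr, E) of the truncated-shifted LJ at separation r (r < cutoff)."""
    sr6 = (s / r) ** 6
    mag = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
    if mag > fcap:
        mag = fcap
    e = eps + 4.0 * eps * (sr6 * sr6 - sr6)
    return mag, e


@njit(cache=True, fastmath=True)
def _build_pair_list(pos, box, rlist, pairs):
    """All-pairs neighbor search over cell centers (N is small)."""
    n = pos.shape[0]
    rl2 = rlist * rlist
    ibx, iby, ibz = 1.0 / box[0], 1.0 / box[1], 1.0 / box[2]
    cnt = 0
    for i in range(n - 1):
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        for j in range(i + 1, n):
            dx = pos[j, 0] - xi
            dy = pos[j, 1] - yi
            dz = pos[j, 2] - zi
            dx -= box[0] * np.rint(dx * ibx)
            dy -= box[1] * np.rint(dy * iby)
            dz -= box[2] * np.rint(dz * ibz)
            if dx * dx + dy * dy + dz * dz < rl2:
                pairs[cnt, 0] = i
                pairs[cnt, 1] = j
                cnt += 1
    return cnt


@njit(cache=True, fastmath=True)
def _compute_forces(
    pos, quat, local, box, pairs, npairs,
    sigB, sigP, eps, A, rc, fcap,
    plate_on, zlo, zhi,
    F, T, Wx, Wy, Wz, wdone,
):
    """Forces and torques about cell centers; returns potential energy.

    Only inter-cell atom pairs interact: body-body and body-adhesin repel
    (WCA), adhesin-adhesin bind (cosine well).  Plate walls, when active,
    repel every atom one-sidedly in z with the same WCA form.  ``Wx/Wy/Wz``
    and ``wdone`` are workspaces for the lazily rotated adhesin offsets.
    """
    n = pos.shape[0]
    na = local.shape[0]
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
        T[i, 0] = 0.0
        T[i, 1] = 0.0
        T[i, 2] = 0.0
        wdone[i] = 0
    arm = 0.0
    for k in range(na):
        r = np.sqrt(local[k, 0] ** 2 + local[k, 1] ** 2 + local[k, 2] ** 2)
        if r > arm:
            arm = r
    sBB = 2.0 * sigB
    sBP = sigB + sigP
    cutBB2 = (_ROOT6 * sBB) ** 2
    cutBP2 = (_ROOT6 * sBP) ** 2
    gateBP2 = (arm + _ROOT6 * sBP) ** 2
    gatePP2 = (2.0 * arm + rc) ** 2
    rc2 = rc * rc
    pi_over_rc = np.pi / rc
    ibx, iby, ibz = 1.0 / box[0], 1.0 / box[1], 1.0 / box[2]
    gate_any2 = max(cutBB2, gateBP2, gatePP2)
    reach2 = (arm + rc) ** 2
    # distance-pass workspaces (branchless passes over them vectorize)
    r2i = np.empty(na)
    r2j = np.empty(na)
    cand = np.empty(na, dtype=np.int64)
    U = 0.0
    for p in range(npairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dcx = pos[j, 0] - pos[i, 0]
        dcy = pos[j, 1] - pos[i, 1]
        dcz = pos[j, 2] - pos[i, 2]
        dcx -= box[0] * np.rint(dcx * ibx)
        dcy -= box[1] * np.rint(dcy * iby)
        dcz -= box[2] * np.rint(dcz * ibz)
        r2c = dcx * dcx + dcy * dcy + dcz * dcz
        if r2c > gate_any2:
            continue
        # body-body
        if r2c < cutBB2:
            r = np.sqrt(r2c)
            if r < 1e-9:
                r = 1e-9
            mag, e = _lj_mag_energy(r, sBB, eps, fcap)
            U += e
            fx = -mag * dcx / r
            fy = -mag * dcy / r
            fz = -mag * dcz / r
            F[i, 0] += fx
            F[i, 1] += fy
            F[i, 2] += fz
            F[j, 0] -= fx
            F[j, 1] -= fy
            F[j, 2] -= fz
        # one distance pass per direction feeds both the body-adhesin
        # cutoff and the adhesin-adhesin reach gate
        if r2c < gateBP2 or (A != 0.0 and r2c < gatePP2):
            _rotate_local(quat, local, Wx, Wy, Wz, wdone, i)
            _rotate_local(quat, local, Wx, Wy, Wz, wdone, j)
            for k in range(na):
                rx = dcx - Wx[i, k]
                ry = dcy - Wy[i, k]
                rz = dcz - Wz[i, k]
                r2i[k] = rx * rx + ry * ry + rz * rz
            for l in range(na):
                rx = dcx + Wx[j, l]
                ry = dcy + Wy[j, l]
                rz = dcz + Wz[j, l]
                r2j[l] = rx * rx + ry * ry + rz * rz
            # body(i) - adhesin(j,l)
            for l in range(na):
                if r2j[l] < cutBP2:
                    rx = dcx + Wx[j, l]
                    ry = dcy + Wy[j, l]
                    rz = dcz + Wz[j, l]
                    r = np.sqrt(r2j[l])
                    if r < 1e-9:
                        r = 1e-9
                    mag, e = _lj_mag_energy(r, sBP, eps, fcap)
                    U += e
                    fx = -mag * rx / r
                    fy = -mag * ry / r
                    fz = -mag * rz / r
                    F[i, 0] += fx
                    F[i, 1] += fy
                    F[i, 2] += fz
                    F[j, 0] -= fx
                    F[j, 1] -= fy
                    F[j, 2] -= fz
                    # reaction acts on adhesin l of cell j -> torque on j
                    T[j, 0] -= Wy[j, l] * fz - Wz[j, l] * fy
                    T[j, 1] -= Wz[j, l] * fx - Wx[j, l] * fz
                    T[j, 2] -= Wx[j, l] * fy - Wy[j, l] * fx
            # adhesin(i,k) - body(j)
            for k in range(na):
                if r2i[k] < cutBP2:
                    rx = dcx - Wx[i, k]
                    ry = dcy - Wy[i, k]
                    rz = dcz - Wz[i, k]
                    r = np.sqrt(r2i[k])
                    if r < 1e-9:
                        r = 1e-9
                    mag, e = _lj_mag_energy(r, sBP, eps, fcap)
                    U += e
                    fx = -mag * rx / r
                    fy = -mag * ry / r
                    fz = -mag * rz / r
                    F[i, 0] += fx
                    F[i, 1] += fy
                    F[i, 2] += fz
                    T[i, 0] += Wy[i, k] * fz - Wz[i, k] * fy
                    T[i, 1] += Wz[i, k] * fx - Wx[i, k] * fz
                    T[i, 2] += Wx[i, k] * fy - Wy[i, k] * fx
                    F[j, 0] -= fx
                    F[j, 1] -= fy
                    F[j, 2] -= fz
            # adhesin-adhesin binding: only adhesins within reach of the
            # other cell's contact sphere can touch (candidate pruning)
            if A != 0.0 and r2c < gatePP2:
                ncand = 0
                for l in range(na):
                    if r2j[l] < reach2:
                        cand[ncand] = l
                        ncand += 1
                if ncand > 0:
                    for k in range(na):
                        if r2i[k] > reach2:
                            continue
                        ax = dcx - Wx[i, k]
                        ay = dcy - Wy[i, k]
                        az = dcz - Wz[i, k]
                        for ci in range(ncand):
                            l = cand[ci]
                            rx = ax + Wx[j, l]
                            ry = ay + Wy[j, l]
                            rz = az + Wz[j, l]
                            r2 = rx * rx + ry * ry + rz * rz
                            if r2 < rc2:
                                r = np.sqrt(r2)
                                U += A * (1.0 + np.cos(pi_over_rc * r))
                                if r > 1e-12:
                                    mag = A * pi_over_rc * np.sin(pi_over_rc * r)
                                    fx = -mag * rx / r
                                    fy = -mag * ry / r
                                    fz = -mag * rz / r
                                    F[i, 0] += fx
                                    F[i, 1] += fy
                                    F[i, 2] += fz
                                    T[i, 0] += Wy[i, k] * fz - Wz[i, k] * fy
                                    T[i, 1] += Wz[i, k] * fx - Wx[i, k] * fz
                                    T[i, 2] += Wx[i, k] * fy - Wy[i, k] * fx
                                    F[j, 0] -= fx
                                    F[j, 1] -= fy
                                    F[j, 2] -= fz
                                    T[j, 0] -= Wy[j, l] * fz - Wz[j, l] * fy
                                    T[j, 1] -= Wz[j, l] * fx - Wx[j, l] * fz
                                    T[j, 2] -= Wx[j, l] * fy - Wy[j, l] * fx
    # plate walls (one-sided WCA per atom, z only)
    if plate_on:
        cutB = _ROOT6 * sigB
        cutP = _ROOT6 * sigP
        wall_reach = arm + cutB
        for i in range(n):
            zb = pos[i, 2]
            if zb - zlo > wall_reach and zhi - zb > wall_reach:
                continue
            _rotate_local(quat, local, Wx, Wy, Wz, wdone, i)
            for side in range(2):
                d = zb - zlo if side == 0 else zhi - zb
                sgn = 1.0 if side == 0 else -1.0
                if d < cutB:
                    if d < 1e-9:
                        d = 1e-9
                    mag, e = _lj_mag_energy(d, sigB, eps, fcap)
                    U += e
                    F[i, 2] += sgn * mag
            for k in range(na):
                za = zb + Wz[i, k]
                for side in range(2):
                    d = za - zlo if side == 0 else zhi - za
                    sgn = 1.0 if side == 0 else -1.0
                    if d < cutP:
                        if d < 1e-9:
                            d = 1e-9
                        mag, e = _lj_mag_energy(d, sigP, eps, fcap)
                        U += e
                        fz = sgn * mag
                        F[i, 2] += fz
                        T[i, 0] += Wy[i, k] * fz
                        T[i, 1] -= Wx[i, k] * fz
    return U


# ---------------------------------------------------------------------------
# BAOAB driver
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def run_steps(
    pos, quat, vel, angvel,
    local, box,
    nsteps, dt,
    mass, inertia, gamma_t, gamma_r, kBT,
    sigB, sigP, eps, A, rc, fcap,
    plate_on, zlo_init, zhi_init, plate_speed, gap_final,
    skin, rng_state,
    snap_every, snap_pos, snap_quat, snap_vel, snap_angvel,
):
    """Advance the system ``nsteps`` BAOAB steps in place.

    Returns (status, zlo, zhi, n_snapshots); status 0 = ok, 1 = non-finite
    coordinates detected (integration blow-up).  Snapshots are copied into
    the ``snap_*`` buffers every ``snap_every`` steps (if > 0).
    """
    n = pos.shape[0]
    na = local.shape[0]
    Wx = np.empty((n, na))
    Wy = np.empty((n, na))
    Wz = np.empty((n, na))
    wdone = np.zeros(n, dtype=np.uint8)
    F = np.empty((n, 3))
    T = np.empty((n, 3))
    disp = np.zeros((n, 3))
    noise = np.empty(6 * n)

    arm = 0.0
    for k in range(na):
        r = np.sqrt(local[k, 0] ** 2 + local[k, 1] ** 2 + local[k, 2] ** 2)
        if r > arm:
            arm = r
    rcut_cell = max(_ROOT6 * 2.0 * sigB, arm + _ROOT6 * (sigB + sigP), 2.0 * arm + rc)
    rlist = rcut_cell + skin
    pairs = np.empty((n * (n - 1) // 2, 2), dtype=np.int64)

    c1 = np.exp(-gamma_t * dt)
    c1r = np.exp(-gamma_r * dt)
    sv = np.sqrt(kBT * (1.0 - c1 * c1) / mass)
    sw = np.sqrt(kBT * (1.0 - c1r * c1r) / inertia)
    thermostat = gamma_t > 0.0 or gamma_r > 0.0
    half = 0.5 * dt
    hm = half / mass
    hI = half / inertia
    ib0, ib1, ib2 = 1.0 / box[0], 1.0 / box[1], 1.0 / box[2]
    zlo = zlo_init
    zhi = zhi_init

    npairs = _build_pair_list(pos, box, rlist, pairs)
    _compute_forces(pos, quat, local, box, pairs, npairs, sigB, sigP, eps, A, rc,
                    fcap, plate_on, zlo, zhi, F, T, Wx, Wy, Wz, wdone)
    nsnap = 0
    for istep in range(nsteps):
        # B: half kick
        for i in range(n):
            for d in range(3):
                vel[i, d] += hm * F[i, d]
                angvel[i, d] += hI * T[i, d]
        # A: half drift
        for i in range(n):
            for d in range(3):
                pos[i, d] += half * vel[i, d]
                disp[i, d] += half * vel[i, d]
            _quat_rotate_step(quat[i], angvel[i, 0], angvel[i, 1], angvel[i, 2], half)
        # O: velocity refresh
        if thermostat:
            _fill_normals(rng_state, noise)
            for i in range(n):
                for d in range(3):
                    vel[i, d] = c1 * vel[i, d] + sv * noise[6 * i + d]
                    angvel[i, d] = c1r * angvel[i, d] + sw * noise[6 * i + 3 + d]
        # A: half drift
        for i in range(n):
            for d in range(3):
                pos[i, d] += half * vel[i, d]
                disp[i, d] += half * vel[i, d]
            _quat_rotate_step(quat[i], angvel[i, 0], angvel[i, 1], angvel[i, 2], half)
        # wrap into box
        for i in range(n):
            pos[i, 0] -= box[0] * np.floor(pos[i, 0] * ib0)
            pos[i, 1] -= box[1] * np.floor(pos[i, 1] * ib1)
            pos[i, 2] -= box[2] * np.floor(pos[i, 2] * ib2)
        # plates close in
        if plate_on and zhi - zlo > gap_final:
            zlo += plate_speed * dt
            zhi -= plate_speed * dt
            if zhi - zlo < gap_final:
                mid = 0.5 * (zhi + zlo)
                zlo = mid - 0.5 * gap_final
                zhi = mid + 0.5 * gap_final
        # neighbor-list refresh on displacement criterion
        maxd2 = 0.0
        for i in range(n):
            d2 = disp[i, 0] ** 2 + disp[i, 1] ** 2 + disp[i, 2] ** 2
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > (0.5 * skin) ** 2:
            npairs = _build_pair_list(pos, box, rlist, pairs)
            for i in range(n):
                disp[i, 0] = 0.0
                disp[i, 1] = 0.0
                disp[i, 2] = 0.0
        _compute_forces(pos, quat, local, box, pairs, npairs, sigB, sigP, eps, A,
                        rc, fcap, plate_on, zlo, zhi, F, T, Wx, Wy, Wz, wdone)
        # B: half kick
        for i in range(n):
            for d in range(3):
                vel[i, d] += hm * F[i, d]
                angvel[i, d] += hI * T[i, d]
        if snap_every > 0 and (istep + 1) % snap_every == 0:
            snap_pos[nsnap] = pos
            snap_quat[nsnap] = quat
            snap_vel[nsnap] = vel
            snap_angvel[nsnap] = angvel
            nsnap += 1
        if (istep + 1) % 2000 == 0 or istep == nsteps - 1:
            ok = True
            for i in range(n):
                for d in range(3):
                    if not np.isfinite(pos[i, d]):
                        ok = False
            if not ok:
                return 1, zlo, zhi, nsnap
    return 0, zlo, zhi, nsnap


@njit(cache=True)
def forces_neighbor_list(pos, quat, local, box, sigB, sigP, eps, A, rc, fcap,
                         plate_on, zlo, zhi, skin):
    """One-shot force/torque/energy evaluation via the neighbor-list path."""
    n = pos.shape[0]
    na = local.shape[0]
    Wx = np.empty((n, na))
    Wy = np.empty((n, na))
    Wz = np.empty((n, na))
    wdone = np.zeros(n, dtype=np.uint8)
    arm = 0.0
    for k in range(na):
        r = np.sqrt(local[k, 0] ** 2 + local[k, 1] ** 2 + local[k, 2] ** 2)
        if r > arm:
            arm = r
    rcut_cell = max(_ROOT6 * 2.0 * sigB, arm + _ROOT6 * (sigB + sigP), 2.0 * arm + rc)
    pairs = np.empty((n * (n - 1) // 2, 2), dtype=np.int64)
    npairs = _build_pair_list(pos, box, rcut_cell + skin, pairs)
    F = np.empty((n, 3))
    T = np.empty((n, 3))
    U = _compute_forces(pos, quat, local, box, pairs, npairs, sigB, sigP, eps, A,
                        rc, fcap, plate_on, zlo, zhi, F, T, Wx, Wy, Wz, wdone)
    return F, T, U
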