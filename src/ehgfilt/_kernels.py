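"""Compiled per-sample recursions for the adaptive filter bank.

Every kernel consumes the desired signal ``d`` and interference reference
``x`` and returns ``(y, e, w, status)`` where ``y`` is the interference
estimate, ``e = d - y`` exactly, ``w`` the final tap vector and ``status``
0 on success, -1 on a detected numerical breakdown (remaining samples are
filled with NaN) and, for the FTF kernel, the number of rescue
reinitialisations performed.

Regressors are prewindowed: u(n) = [x(n), x(n-1), ..., x(n-L+1)] with zeros
before the record start.  All kernels emit the a priori output
y(n) = w(n-1)'u(n), so architectures solving the same least-squares problem
by different numerics (RLS / HRLS / QRD-RLS, and SWRLS / HSWRLS) produce
identical sequences up to rounding.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _fill_u(x, k, L, u):
    for i in range(L):
        j = k - i
        u[i] = x[j] if j >= 0 else 0.0


@njit(cache=True)
def _dot(a, b, L):
    s = 0.0
    for i in range(L):
        s += a[i] * b[i]
    return s


@njit(cache=True)
def _sgn(v):
    if v > 0.0:
        return 1.0
    if v < 0.0:
        return -1.0
    return 0.0


# ---------------------------------------------------------------------------
# LMS family


@njit(cache=True)
def lms_family(d, x, L, mu, mode):
    """mode: 0 LMS, 1 sign-error, 2 sign-data, 3 sign-sign."""
    n = d.shape[0]
    y = np.empty(n)
    e = np.empty(n)
    w = np.zeros(L)
    u = np.zeros(L)
    for k in range(n):
        _fill_u(x, k, L, u)
        yk = _dot(w, u, L)
        y[k] = yk
        ek = d[k] - yk
        e[k] = ek
        g = _sgn(ek) if (mode == 1 or mode == 3) else ek
        for i in range(L):
            ui = _sgn(u[i]) if (mode == 2 or mode == 3) else u[i]
            w[i] += mu * g * ui
    return y, e, w, 0


@njit(cache=True)
def nlms(d, x, L, mu, eps):
    n = d.shape[0]
    y = np.empty(n)
    e = np.empty(n)
    w = np.zeros(L)
    u = np.zeros(L)
    for k in range(n):
        _fill_u(x, k, L, u)
        yk = _dot(w, u, L)
        y[k] = yk
        ek = d[k] - yk
        e[k] = ek
        norm = eps + _dot(u, u, L)
        g = mu * ek / norm
        for i in range(L):
            w[i] += g * u[i]
    return y, e, w, 0


@njit(cache=True)
def blms(d, x, L, mu, block):
    """Block LMS: the averaged gradient over each block updates w once,
    which keeps the stable step-size range aligned with sample-wise LMS."""
    n = d.shape[0]
    y = np.empty(n)
    e = np.empty(n)
    w = np.zeros(L)
    u = np.zeros(L)
    grad = np.zeros(L)
    k0 = 0
    while k0 < n:
        k1 = min(k0 + block, n)
        for i in range(L):
            grad[i] = 0.0
        for k in range(k0, k1):
            _fill_u(x, k, L, u)
            yk = _dot(w, u, L)
            y[k] = yk
            ek = d[k] - yk
            e[k] = ek
            for i in range(L):
                grad[i] += ek * u[i]
        cnt = k1 - k0
        for i in range(L):
            w[i] += mu * grad[i] / cnt
        k0 = k1
    return y, e, w, 0


@njit(cache=True)
def fxlms(d, x, xf, yrawbuf, sec, L, mu):
    """Filtered-X LMS.  ``xf`` is the reference prefiltered by the secondary
    path, ``sec`` the secondary-path FIR the filter output passes through
    before subtraction (identity by default)."""
    n = d.shape[0]
    ns = sec.shape[0]
    y = np.empty(n)
    e = np.empty(n)
    w = np.zeros(L)
    u = np.zeros(L)
    uf = np.zeros(L)
    for k in range(n):
        _fill_u(x, k, L, u)
        yrawbuf[k] = _dot(w, u, L)
        # pass the adaptive output through the secondary path
        yk = 0.0
        for m in range(ns):
            j = k - m
            if j >= 0:
                yk += sec[m] * yrawbuf[j]
        y[k] = yk
        ek = d[k] - yk
        e[k] = ek
        _fill_u(xf, k, L, uf)
        for i in range(L):
            w[i] += mu * ek * uf[i]
    return y, e, w, 0


# ---------------------------------------------------------------------------
# RLS family (conventional, Householder square-root, Givens QR)


@njit(cache=True)
def rls(d, x, L, lam, delta):
    n = d.shape[0]
    y = np.empty(n)
    e = np.empty(n)
    w = np.zeros(L)
    u = np.zeros(L)
    Pu = np.zeros(L)
    P = np.eye(L) * delta
    for k in range(n):
        _fill_u(x, k, L, u)
        yk = _dot(w, u, L)
        y[k] = yk
        ek = d[k] - yk
        e[k] = ek
        for i in range(L):
            s = 0.0
            for j in range(L):
                s += P[i, j] * u[j]
            Pu[i] = s
        denom = lam + _dot(u, Pu, L)
        for i in range(L):
            w[i] += Pu[i] * ek / denom
        for i in range(L):
            for j in range(L):
                P[i, j] = (P[i, j] - Pu[i] * Pu[j] / denom) / lam
    return y, e, w, 0


@njit(cache=True)
def _backsolve(R, z, w, L):
    for i in range(L - 1, -1, -1):
        s = z[i]
        for j in range(i + 1, L):
            s -= R[i, j] * w[j]
        w[i] = s / R[i, i]


@njit(cache=True)
def qrd_rls(d, x, L, lam, delta):
    """Givens-rotation QR-decomposition RLS on the Cholesky factor of the
    exponentially weighted normal equations; same least squares as `rls`."""
    n = d.shape[0]
    y = np.empty(n)
    e = np.empty(n)
    w = np.zeros(L)
    u = np.zeros(L)
    row = np.zeros(L)
    R = np.eye(L) / np.sqrt(delta)
    z = np.zeros(L)
    sl = np.sqrt(lam)
    for k in range(n):
        _fill_u(x, k, L, u)
        _backsolve(R, z, w, L)
        yk = _dot(w, u, L)
        y[k] = yk
        e[k] = d[k] - yk
        for i in range(L):
            z[i] *= sl
            for j in range(i, L):
                R[i, j] *= sl
        for i in range(L):
            row[i] = u[i]
        dd = d[k]
        for i in range(L):
            b = row[i]
            if b == 0.0:
                continue
            a = R[i, i]
            r = np.hypot(a, b)
            c = a / r
            s = b / r
            R[i, i] = r
            row[i] = 0.0
            for j in range(i + 1, L):
                t = c * R[i, j] + s * row[j]
                row[j] = -s * R[i, j] + c * row[j]
                R[i, j] = t
            t = c * z[i] + s * dd
            dd = -s * z[i] + c * dd
            z[i] = t
    _backsolve(R, z, w, L)
    return y, e, w, 0


@njit(cache=True)
def hrls(d, x, L, lam, delta):
    """Householder square-root RLS: annihilates each incoming data row into
    the triangular factor with elementary reflections instead of rotations;
    same least squares as `rls` and `qrd_rls`."""
    n = d.shape[0]
    y = np.empty(n)
    e = np.empty(n)
    w = np.zeros(L)
    u = np.zeros(L)
    row = np.zeros(L)
    R = np.eye(L) / np.sqrt(delta)
    z = np.zeros(L)
    sl = np.sqrt(lam)
    for k in range(n):
        _fill_u(x, k, L, u)
        _backsolve(R, z, w, L)
        yk = _dot(w, u, L)
        y[k] = yk
        e[k] = d[k] - yk
        for i in range(L):
            z[i] *= sl
            for j in range(i, L):
                R[i, j] *= sl
        for i in range(L):
            row[i] = u[i]
        dd = d[k]
        for i in range(L):
            b = row[i]
            if b == 0.0:
                continue
            a = R[i, i]
            r = np.hypot(a, b)
            if a >= 0.0:
                r = -r
            v1 = a - r
            v2 = b
            vv = v1 * v1 + v2 * v2
            R[i, i] = r
            row[i] = 0.0
            for j in range(i + 1, L):
                beta = 2.0 * (v1 * R[i, j] + v2 * row[j]) / vv
                R[i, j] -= beta * v1
                row[j] -= beta * v2
            beta = 2.0 * (v1 * z[i] + v2 * dd) / vv
            z[i] -= beta * v1
            dd -= beta * v2
    _backsolve(R, z, w, L)
    return y, e, w, 0


# ---------------------------------------------------------------------------
# sliding-window RLS (direct and Householder square-root forms)


@njit(cache=True)
def swrls(d, x, L, lam, delta, win):
    """Exponentially weighted least squares over a sliding rectangular
    window: at each step the sample leaving the window is downdated with its
    decayed weight lam**win.  Direct form: the windowed normal equations are
    propagated exactly and solved by Cholesky factorisation each sample."""
    n = d.shape[0]
    y = np.empty(n)
    e = np.empty(n)
    w = np.zeros(L)
    u = np.zeros(L)
    uo = np.zeros(L)
    Phi = np.eye(L) / delta
    pvec = np.zeros(L)
    C = np.zeros((L, L))
    tmp = np.zeros(L)
    lam_win = lam**win
    for k in range(n):
        _fill_u(x, k, L, u)
        yk = _dot(w, u, L)
        y[k] = yk
        e[k] = d[k] - yk
        for i in range(L):
            for j in range(L):
                Phi[i, j] = lam * Phi[i, j] + u[i] * u[j]
            pvec[i] = lam * pvec[i] + u[i] * d[k]
        if k >= win:
            _fill_u(x, k - win, L, uo)
            for i in range(L):
                for j in range(L):
                    Phi[i, j] -= lam_win * uo[i] * uo[j]
                pvec[i] -= lam_win * uo[i] * d[k - win]
        # Cholesky: Phi = C C', then forward/back substitution
        ok = True
        for i in range(L):
            for j in range(i + 1):
                s = Phi[i, j]
                for m in range(j):
                    s -= C[i, m] * C[j, m]
                if i == j:
                    if s <= 0.0 or not np.isfinite(s):
                        ok = False
                        break
                    C[i, i] = np.sqrt(s)
                else:
                    C[i, j] = s / C[j, j]
            if not ok:
                break
        if not ok:
            for kk in range(k, n):
                y[kk] = np.nan
                e[kk] = np.nan
            return y, e, w, -1
        for i in range(L):
            s = pvec[i]
            for j in range(i):
                s -= C[i, j] * tmp[j]
            tmp[i] = s / C[i, i]
        for i in range(L - 1, -1, -1):
            s = tmp[i]
            for j in range(i + 1, L):
                s -= C[j, i] * w[j]
            w[i] = s / C[i, i]
    return y, e, w, 0


@njit(cache=True)
def hswrls(d, x, L, lam, delta, win):
    """Square-root form of `swrls`: Householder reflections append the new
    row, hyperbolic eliminations remove the expiring one."""
    n = d.shape[0]
    y = np.empty(n)
    e = np.empty(n)
    w = np.zeros(L)
    u = np.zeros(L)
    row = np.zeros(L)
    v = np.zeros(L)
    R = np.eye(L) / np.sqrt(delta)
    z = np.zeros(L)
    sl = np.sqrt(lam)
    slw = lam ** (0.5 * win)
    for k in range(n):
        _fill_u(x, k, L, u)
        _backsolve(R, z, w, L)
        yk = _dot(w, u, L)
        y[k] = yk
        e[k] = d[k] - yk
        for i in range(L):
            z[i] *= sl
            for j in range(i, L):
                R[i, j] *= sl
        for i in range(L):
            row[i] = u[i]
        dd = d[k]
        for i in range(L):
            b = row[i]
            if b == 0.0:
                continue
            a = R[i, i]
            r = np.hypot(a, b)
            if a >= 0.0:
                r = -r
            v1 = a - r
            v2 = b
            vv = v1 * v1 + v2 * v2
            R[i, i] = r
            row[i] = 0.0
            for j in range(i + 1, L):
                beta = 2.0 * (v1 * R[i, j] + v2 * row[j]) / vv
                R[i, j] -= beta * v1
                row[j] -= beta * v2
            beta = 2.0 * (v1 * z[i] + v2 * dd) / vv
            z[i] -= beta * v1
            dd -= beta * v2
        if k >= win:
            _fill_u(x, k - win, L, v)
            for i in range(L):
                v[i] *= slw
            zeta = slw * d[k - win]
            bad = False
            for i in range(L):
                b = v[i]
                if b == 0.0:
                    continue
                a = R[i, i]
                if abs(b) >= abs(a):
                    bad = True
                    break
                t = b / a
                g = 1.0 / np.sqrt(1.0 - t * t)
                for j in range(i, L):
                    Rij = R[i, j]
                    vj = v[j]
                    R[i, j] = g * (Rij - t * vj)
                    v[j] = g * (vj - t * Rij)
                zi = z[i]
                z[i] = g * (zi - t * zeta)
                zeta = g * (zeta - t * zi)
            if bad:
                for kk in range(k, n):
                    y[kk] = np.nan
                    e[kk] = np.nan
                return y, e, w, -1
    _backsolve(R, z, w, L)
    return y, e, w, 0


# ---------------------------------------------------------------------------
# least-squares lattice


@njit(cache=True)
def lsl(d, x, L, lam, soft):
    """Order-recursive least-squares lattice with a posteriori errors and a
    joint-process (ladder) section of L coefficients."""
    n = d.shape[0]
    y = np.empty(n)
    e = np.empty(n)
    fv = np.zeros(L)
    bv = np.zeros(L)
    Fv = np.zeros(L)
    Bv = np.zeros(L)
    gv = np.ones(L)
    bold = np.zeros(L)
    Bold = np.full(L, soft)
    gold = np.ones(L)
    Delta = np.zeros(L)
    p = np.zeros(L)
    F0 = soft
    tiny = 1e-30
    for k in range(n):
        xk = x[k]
        F0 = lam * F0 + xk * xk
        fv[0] = xk
        bv[0] = xk
        Fv[0] = F0
        Bv[0] = F0
        gv[0] = 1.0
        for m in range(1, L):
            D = lam * Delta[m - 1] + bold[m - 1] * fv[m - 1] / gold[m - 1]
            Delta[m - 1] = D
            Bo = Bold[m - 1]
            if Bo < tiny:
                Bo = tiny
            Fp = Fv[m - 1]
            if Fp < tiny:
                Fp = tiny
            fv[m] = fv[m - 1] - (D / Bo) * bold[m - 1]
            bv[m] = bold[m - 1] - (D / Fp) * fv[m - 1]
            Fv[m] = Fp - D * D / Bo
            Bv[m] = Bo - D * D / Fp
            if Fv[m] < tiny:
                Fv[m] = tiny
            if Bv[m] < tiny:
                Bv[m] = tiny
            g = gv[m - 1] - bv[m - 1] * bv[m - 1] / Bv[m - 1]
            if g < 1e-12:
                g = 1e-12
            gv[m] = g
        ek = d[k]
        for m in range(L):
            p[m] = lam * p[m] + bv[m] * ek / gv[m]
            ek = ek - (p[m] / Bv[m]) * bv[m]
        # re-derive e from y so the e = d - y contract holds bit-exactly
        y[k] = d[k] - ek
        e[k] = d[k] - y[k]
        for m in range(L):
            bold[m] = bv[m]
            Bold[m] = Bv[m]
            gold[m] = gv[m]
    # lattice weights are reflection coefficients, not transversal taps;
    # report the ladder coefficients p/B as the closest analogue
    w = np.zeros(L)
    for m in range(L):
        w[m] = p[m] / Bv[m]
    return y, e, w, 0


# ---------------------------------------------------------------------------
# fast transversal filter


@njit(cache=True)
def ftf(d, x, L, lam, soft):
    """Classic fast transversal RLS with rescue reinitialisation: when the
    conversion factor leaves (0, 1] or a variable turns non-finite, the
    prediction section restarts (the joint-process weights are kept).
    Returns the rescue count as status."""
    n = d.shape[0]
    y = np.empty(n)
    e = np.empty(n)
    w = np.zeros(L)
    a = np.zeros(L)
    b = np.zeros(L)
    kg = np.zeros(L)
    kext = np.zeros(L + 1)
    u = np.zeros(L)
    up = np.zeros(L)
    F = soft
    B = soft
    gamma = 1.0
    rescues = 0
    for k in range(n):
        _fill_u(x, k, L, u)
        _fill_u(x, k - 1, L, up)
        ef = x[k] - _dot(a, up, L)
        efp = gamma * ef
        Fn = lam * F + ef * efp
        gF = ef / (lam * F)
        kext[0] = gF
        for i in range(L):
            kext[i + 1] = kg[i] - gF * a[i]
        gamma_ext = gamma * lam * F / Fn
        for i in range(L):
            a[i] += efp * kg[i]
        mu_last = kext[L]
        eb = lam * B * mu_last
        for i in range(L):
            kg[i] = kext[i] + mu_last * b[i]
        eta = 1.0 - gamma_ext * mu_last * eb
        ok = eta > 0.0 and np.isfinite(eta)
        if ok:
            gamma_n = gamma_ext / eta
            ok = 0.0 < gamma_n <= 1.0001 and np.isfinite(gamma_n)
        if ok:
            ebp = gamma_n * eb
            Bn = lam * B + eb * ebp
            ok = Bn > 0.0 and Fn > 0.0 and np.isfinite(Bn) and np.isfinite(Fn)
        if not ok:
            # rescue: restart the prediction section, keep the weights
            for i in range(L):
                a[i] = 0.0
                b[i] = 0.0
                kg[i] = 0.0
            F = soft
            B = soft
            gamma = 1.0
            rescues += 1
            yk = _dot(w, u, L)
            y[k] = yk
            e[k] = d[k] - yk
            continue
        for i in range(L):
            b[i] += ebp * kg[i]
        F = Fn
        B = Bn
        gamma = gamma_n
        ep = d[k] - _dot(w, u, L)
        y[k] = d[k] - ep
        e[k] = ep
        epp = gamma * ep
        for i in range(L):
            w[i] += epp * kg[i]
    return y, e, w, rescues
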