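"""Numba kernels for polychoric correlation estimation.

Bivariate-normal rectangle probabilities use Genz's BVND quadrature
(Gauss-Legendre with 6/12/20 nodes depending on |rho|, plus the
near-singular expansion for |rho| >= 0.925).  The pairwise ML rho is found
by bounded Brent minimisation of the negative table log-likelihood.

Everything here works on 0-based category codes whose empty categories
have already been collapsed away, with per-column thresholds padded by
+/-BIG sentinels standing in for +/-infinity.
"""

import math

import numpy as np
from numba import njit

BIG = 1e10
RHO_CAP = 0.999
_SQRT2 = math.sqrt(2.0)
_TWOPI = 2.0 * math.pi

# Gauss-Legendre abscissae/weights (half rules; symmetric completion in code).
_GL_X = np.array(
    [
        # 6-point rule
        -0.9324695142031521, -0.6612093864662645, -0.2386191860831969,
        0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
        # 12-point rule
        -0.9815606342467192, -0.9041172563704749, -0.7699026741943047,
        -0.5873179542866175, -0.3678314989981802, -0.1252334085114689,
        0.0, 0.0, 0.0, 0.0,
        # 20-point rule
        -0.9931285991850949, -0.9639719272779138, -0.9122344282513259,
        -0.8391169718222188, -0.7463319064601508, -0.6360536807265150,
        -0.5108670019508271, -0.3737060887154196, -0.2277858511416451,
        -0.0765265211334973,
    ]
).reshape(3, 10)
_GL_W = np.array(
    [
        0.1713244923791704, 0.3607615730481386, 0.4679139345726910,
        0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
        0.04717533638651183, 0.1069393259953184, 0.1600783285433462,
        0.2031674267230659, 0.2334925365383548, 0.2491470458134028,
        0.0, 0.0, 0.0, 0.0,
        0.01761400713915212, 0.04060142980038694, 0.06267204833410906,
        0.08327674157670475, 0.1019301198172404, 0.1181945319615184,
        0.1316886384491766, 0.1420961093183821, 0.1491729864726037,
        0.1527533871307259,
    ]
).reshape(3, 10)


@njit(cache=True)
def phid(x):
    """Standard normal CDF."""
    return 0.5 * math.erfc(-x / _SQRT2)


@njit(cache=True)
def bvnu(dh, dk, r):
    """Upper-tail bivariate normal probability P(X > dh, Y > dk)."""
    if dh >= BIG or dk >= BIG:
        return 0.0
    if dh <= -BIG:
        if dk <= -BIG:
            return 1.0
        return phid(-dk)
    if dk <= -BIG:
        return phid(-dh)
    if r == 0.0:
        return phid(-dh) * phid(-dk)

    h = dh
    k = dk
    hk = h * k
    bvn = 0.0
    ar = abs(r)
    if ar < 0.3:
        ng = 0
        lg = 3
    elif ar < 0.75:
        ng = 1
        lg = 6
    else:
        ng = 2
        lg = 10

    if ar < 0.925:
        hs = (h * h + k * k) / 2.0
        asr = math.asin(r) / 2.0
        for i in range(lg):
            for s in (-1.0, 1.0):
                sn = math.sin(asr * (s * _GL_X[ng, i] + 1.0))
                bvn += _GL_W[ng, i] * math.exp((sn * hk - hs) / (1.0 - sn * sn))
        bvn = bvn * asr / _TWOPI + phid(-h) * phid(-k)
    else:
        if r < 0.0:
            k = -k
            hk = -hk
        if ar < 1.0:
            a2 = (1.0 - r) * (1.0 + r)
            a = math.sqrt(a2)
            bs = (h - k) * (h - k)
            c = (4.0 - hk) / 8.0
            d = (12.0 - hk) / 16.0
            asr = -(bs / a2 + hk) / 2.0
            if asr > -100.0:
                bvn = (
                    a
                    * math.exp(asr)
                    * (1.0 - c * (bs - a2) * (1.0 - d * bs / 5.0) / 3.0
                       + c * d * a2 * a2 / 5.0)
                )
            if -hk < 100.0:
                b = math.sqrt(bs)
                sp = math.sqrt(_TWOPI) * phid(-b / a)
                bvn -= math.exp(-hk / 2.0) * sp * b * (
                    1.0 - c * bs * (1.0 - d * bs / 5.0) / 3.0
                )
            a = a / 2.0
            for i in range(lg):
                for s in (-1.0, 1.0):
                    x2 = a * (s * _GL_X[ng, i] + 1.0)
                    xs = x2 * x2
                    rs = math.sqrt(1.0 - xs)
                    asr = -(bs / xs + hk) / 2.0
                    if asr > -100.0:
                        sp = 1.0 + c * xs * (1.0 + d * xs)
                        ep = math.exp(-hk * (1.0 - rs) / (2.0 * (1.0 + rs))) / rs
                        bvn += a * _GL_W[ng, i] * math.exp(asr) * (ep - sp)
            bvn = -bvn / _TWOPI
        if r > 0.0:
            bvn += phid(-max(h, k))
        else:
            bvn = -bvn
            if k > h:
                bvn += phid(k) - phid(h)
    if bvn < 0.0:
        return 0.0
    if bvn > 1.0:
        return 1.0
    return bvn


@njit(cache=True)
def rect_prob(a1, b1, a2, b2, r):
    """P(a1 < X <= b1, a2 < Y <= b2) under standard bivariate normal."""
    p = bvnu(a1, a2, r) - bvnu(b1, a2, r) - bvnu(a1, b2, r) + bvnu(b1, b2, r)
    if p < 0.0:
        return 0.0
    return p


@njit(cache=True)
def table_nll(rho, table, tx, ty, c1, c2):
    """Negative log-likelihood of a c1 x c2 contingency table at rho.

    tx has c1+1 entries (with -BIG/+BIG sentinels), ty has c2+1.
    """
    nll = 0.0
    for i in range(c1):
        for j in range(c2):
            nij = table[i, j]
            if nij > 0.0:
                p = rect_prob(tx[i], tx[i + 1], ty[j], ty[j + 1], rho)
                if p < 1e-16:
                    p = 1e-16
                nll -= nij * math.log(p)
    return nll


@njit(cache=True)
def fit_rho(table, tx, ty, c1, c2, lo, hi, xtol):
    """Bounded Brent minimisation of table_nll over [lo, hi].

    Returns (rho, nll_at_rho).
    """
    golden = 0.3819660112501051
    a = lo
    b = hi
    x = w = v = a + golden * (b - a)
    fx = fw = fv = table_nll(x, table, tx, ty, c1, c2)
    d = 0.0
    e = 0.0
    for _ in range(200):
        m = 0.5 * (a + b)
        tol1 = 1.4901161193847656e-08 * abs(x) + xtol / 3.0
        tol2 = 2.0 * tol1
        if abs(x - m) <= tol2 - 0.5 * (b - a):
            break
        use_golden = True
        if abs(e) > tol1:
            r = (x - w) * (fx - fv)
            q = (x - v) * (fx - fw)
            p = (x - v) * q - (x - w) * r
            q = 2.0 * (q - r)
            if q > 0.0:
                p = -p
            q = abs(q)
            etemp = e
            e = d
            if abs(p) < abs(0.5 * q * etemp) and p > q * (a - x) and p < q * (b - x):
                d = p / q
                u = x + d
                if (u - a) < tol2 or (b - u) < tol2:
                    d = tol1 if m - x >= 0.0 else -tol1
                use_golden = False
        if use_golden:
            e = (b - x) if x < m else (a - x)
            d = golden * e
        if abs(d) >= tol1:
            u = x + d
        else:
            u = x + (tol1 if d > 0.0 else -tol1)
        fu = table_nll(u, table, tx, ty, c1, c2)
        if fu <= fx:
            if u < x:
                b = x
            else:
                a = x
            v, fv = w, fw
            w, fw = x, fx
            x, fx = u, fu
        else:
            if u < x:
                a = u
            else:
                b = u
            if fu <= fw or w == x:
                v, fv = w, fw
                w, fw = u, fu
            elif fu <= fv or v == x or v == w:
                v, fv = u, fu
    return x, fx


@njit(cache=True)
def pair_table(xi, yi, c1, c2):
    """Contingency table of two 0-based code vectors."""
    table = np.zeros((c1, c2))
    for t in range(xi.shape[0]):
        table[xi[t], yi[t]] += 1.0
    return table


@njit(cache=True)
def _pearson_codes(xi, yi):
    n = xi.shape[0]
    sx = 0.0
    sy = 0.0
    for t in range(n):
        sx += xi[t]
        sy += yi[t]
    mx = sx / n
    my = sy / n
    sxy = 0.0
    sxx = 0.0
    syy = 0.0
    for t in range(n):
        dx = xi[t] - mx
        dy = yi[t] - my
        sxy += dx * dy
        sxx += dx * dx
        syy += dy * dy
    if sxx <= 0.0 or syy <= 0.0:
        return 0.0
    return sxy / math.sqrt(sxx * syy)


# pairwise estimate status codes
STATUS_OK = 0
STATUS_BOUNDARY = 1
STATUS_FALLBACK = 2


@njit(cache=True)
def poly_matrix_kernel(codes, ncat, tau, rho_cap, xtol):
    """Polychoric correlation matrix from collapsed 0-based codes.

    codes: (n, p) int64; ncat[j] categories in column j; tau[j, :ncat[j]+1]
    thresholds padded with -BIG/+BIG sentinels at the ends.
    Returns (R, status) with status per pair.
    """
    n, p = codes.shape
    R = np.eye(p)
    status = np.zeros((p, p), dtype=np.int8)
    for i in range(p):
        for j in range(i):
            table = pair_table(codes[:, i], codes[:, j], ncat[i], ncat[j])
            rho, nll = fit_rho(
                table, tau[i], tau[j], ncat[i], ncat[j], -rho_cap, rho_cap, xtol
            )
            st = STATUS_OK
            if not math.isfinite(nll):
                rho = _pearson_codes(codes[:, i], codes[:, j])
                st = STATUS_FALLBACK
            elif rho > rho_cap - 1e-3:
                rho = rho_cap
                st = STATUS_BOUNDARY
            elif rho < -rho_cap + 1e-3:
                rho = -rho_cap
                st = STATUS_BOUNDARY
            R[i, j] = rho
            R[j, i] = rho
            status[i, j] = st
            status[j, i] = st
    return R, status
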