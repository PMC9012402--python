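"""Compiled (numba) energy/force kernels used by the simulation engine.

Every kernel accumulates forces in place into ``F`` (kcal/mol/A) and returns
the term energy (kcal/mol).  Pair distances honor the orthorhombic minimum
image when ``pbc`` is true.  The scalar formulas mirror
:mod:`rescg.potentials`; the two paths are cross-checked in the test suite.

Numerical safety: near-collinear angle/dihedral geometries are handled by
clamping the relevant sine/cross-product magnitudes so forces stay finite
(the energy is exact away from the degenerate set).
"""

import math

import numpy as np
from numba import njit

_SIN_CLAMP = 1e-6       # min |sin theta| in angle gradients
_CROSS_CLAMP = 1e-12    # min |b x b'|^2 in dihedral gradients


@njit(cache=True, inline="always")
def _dvec(pos, i, j, box, pbc):
    """Minimum-image vector from i to j."""
    d = np.empty(3)
    d[0] = pos[j, 0] - pos[i, 0]
    d[1] = pos[j, 1] - pos[i, 1]
    d[2] = pos[j, 2] - pos[i, 2]
    if pbc:
        d[0] -= box[0] * round(d[0] / box[0])
        d[1] -= box[1] * round(d[1] / box[1])
        d[2] -= box[2] * round(d[2] / box[2])
    return d


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------

@njit(cache=True)
def bonds_ef(pos, idx, func, b0, k1, k2, box, pbc, F):
    E = 0.0
    for n in range(idx.shape[0]):
        i, j = idx[n, 0], idx[n, 1]
        d = _dvec(pos, i, j, box, pbc)
        b = math.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
        db = b - b0[n]
        if func[n] == 1:
            E += k1[n] * db * db
            dE = 2.0 * k1[n] * db
        else:  # quartic
            db2 = db * db
            E += k1[n] * db2 + k2[n] * db2 * db2
            dE = 2.0 * k1[n] * db + 4.0 * k2[n] * db * db2
        g = dE / b
        for a in range(3):
            F[i, a] += g * d[a]
            F[j, a] -= g * d[a]
    return E


@njit(cache=True, inline="always")
def _angle_grad(pos, i, j, k, box, pbc, gi, gj, gk):
    """theta at vertex j and d(theta)/dr for the three particles."""
    u = _dvec(pos, j, i, box, pbc)
    v = _dvec(pos, j, k, box, pbc)
    lu = math.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
    lv = math.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
    ct = (u[0] * v[0] + u[1] * v[1] + u[2] * v[2]) / (lu * lv)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    theta = math.acos(ct)
    st = math.sqrt(1.0 - ct * ct)
    if st < _SIN_CLAMP:
        st = _SIN_CLAMP
    for a in range(3):
        gi[a] = (ct * u[a] / lu - v[a] / lv) / (lu * st)
        gk[a] = (ct * v[a] / lv - u[a] / lu) / (lv * st)
        gj[a] = -gi[a] - gk[a]
    return theta


@njit(cache=True, inline="always")
def _spline_eval(x, x0, dx, nseg, seg0, breaks, coefs):
    s = int((x - x0) / dx)
    if s < 0:
        s = 0
    elif s >= nseg:
        s = nseg - 1
    t = x - breaks[seg0 + s]
    c = coefs[:, seg0 + s]
    E = ((c[0] * t + c[1]) * t + c[2]) * t + c[3]
    dE = (3.0 * c[0] * t + 2.0 * c[1]) * t + c[2]
    return E, dE


@njit(cache=True)
def angles_ef(pos, idx, func, theta0, kk, tab_id,
              tab_x0, tab_dx, tab_nseg, tab_seg0, tab_lo, tab_hi,
              tab_breaks, tab_coefs, box, pbc, F, clamp_counter):
    E = 0.0
    gi = np.empty(3)
    gj = np.empty(3)
    gk = np.empty(3)
    for n in range(idx.shape[0]):
        i, j, k = idx[n, 0], idx[n, 1], idx[n, 2]
        theta = _angle_grad(pos, i, j, k, box, pbc, gi, gj, gk)
        if func[n] == 1:
            d = theta - theta0[n]
            E += kk[n] * d * d
            dE = 2.0 * kk[n] * d
        else:  # tabulated
            t = tab_id[n]
            x = theta
            if x < tab_lo[t]:
                x = tab_lo[t]
                clamp_counter[0] += 1
            elif x > tab_hi[t]:
                x = tab_hi[t]
                clamp_counter[0] += 1
            e, dE = _spline_eval(x, tab_x0[t], tab_dx[t], tab_nseg[t],
                                 tab_seg0[t], tab_breaks, tab_coefs)
            E += e
            if theta < tab_lo[t] or theta > tab_hi[t]:
                dE = 0.0
        for a in range(3):
            F[i, a] -= dE * gi[a]
            F[j, a] -= dE * gj[a]
            F[k, a] -= dE * gk[a]
    return E


@njit(cache=True, inline="always")
def _dihedral_grad(pos, i, j, k, l, box, pbc, fi, fj, fk, fl):
    """phi and the four gradient vectors scaled for unit dE/dphi.

    Returns phi in (-pi, pi]; on return ``f*`` hold d(phi)/dr.
    """
    b1 = _dvec(pos, i, j, box, pbc)
    b2 = _dvec(pos, j, k, box, pbc)
    b3 = _dvec(pos, k, l, box, pbc)
    mx = b1[1] * b2[2] - b1[2] * b2[1]
    my = b1[2] * b2[0] - b1[0] * b2[2]
    mz = b1[0] * b2[1] - b1[1] * b2[0]
    nx = b2[1] * b3[2] - b2[2] * b3[1]
    ny = b2[2] * b3[0] - b2[0] * b3[2]
    nz = b2[0] * b3[1] - b2[1] * b3[0]
    b2n = math.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
    m2 = mx * mx + my * my + mz * mz
    n2 = nx * nx + ny * ny + nz * nz
    # phi = atan2(|b2| * b1.n, m.n)
    phi = math.atan2(b2n * (b1[0] * nx + b1[1] * ny + b1[2] * nz),
                     mx * nx + my * ny + mz * nz)
    if m2 < _CROSS_CLAMP:
        m2 = _CROSS_CLAMP
    if n2 < _CROSS_CLAMP:
        n2 = _CROSS_CLAMP
    if b2n < 1e-9:
        b2n = 1e-9
    ci = -b2n / m2
    cl = b2n / n2
    t = (b1[0] * b2[0] + b1[1] * b2[1] + b1[2] * b2[2]) / (b2n * b2n)
    u = (b3[0] * b2[0] + b3[1] * b2[1] + b3[2] * b2[2]) / (b2n * b2n)
    fi[0] = ci * mx
    fi[1] = ci * my
    fi[2] = ci * mz
    fl[0] = cl * nx
    fl[1] = cl * ny
    fl[2] = cl * nz
    for a in range(3):
        fj[a] = -(1.0 + t) * fi[a] + u * fl[a]
        fk[a] = t * fi[a] - (1.0 + u) * fl[a]
    return phi


@njit(cache=True, inline="always")
def _wrap_pi(x):
    y = (x + math.pi) % (2.0 * math.pi)
    if y <= 0.0:
        y += 2.0 * math.pi
    return y - math.pi


@njit(cache=True)
def dihedrals_ef(pos, idx, func, phi0, mult, kk, sig, tab_id,
                 tab_x0, tab_dx, tab_nseg, tab_seg0,
                 tab_breaks, tab_coefs, box, pbc, F):
    E = 0.0
    fi = np.empty(3)
    fj = np.empty(3)
    fk = np.empty(3)
    fl = np.empty(3)
    for n in range(idx.shape[0]):
        phi = _dihedral_grad(pos, idx[n, 0], idx[n, 1], idx[n, 2], idx[n, 3],
                             box, pbc, fi, fj, fk, fl)
        fcode = func[n]
        if fcode == 1 or fcode == 32:
            E += kk[n] * (1.0 + math.cos(mult[n] * (phi - phi0[n])))
            dE = -kk[n] * mult[n] * math.sin(mult[n] * (phi - phi0[n]))
        elif fcode == 21:  # gaussian
            d = _wrap_pi(phi - phi0[n])
            s2 = sig[n] * sig[n]
            e = -kk[n] * math.exp(-d * d / (2.0 * s2))
            E += e
            dE = -e * d / s2
        else:  # tabulated (periodic)
            t = tab_id[n]
            x0 = tab_x0[t]
            span = tab_dx[t] * tab_nseg[t]
            x = x0 + (phi - x0) % span
            if x < x0:
                x += span
            e, dE = _spline_eval(x, x0, tab_dx[t], tab_nseg[t],
                                 tab_seg0[t], tab_breaks, tab_coefs)
            E += e
        for a in range(3):
            F[idx[n, 0], a] -= dE * fi[a]
            F[idx[n, 1], a] -= dE * fj[a]
            F[idx[n, 2], a] -= dE * fk[a]
            F[idx[n, 3], a] -= dE * fl[a]
    return E


# ---------------------------------------------------------------------------
# simple pair terms
# ---------------------------------------------------------------------------

@njit(cache=True)
def go_contacts_ef(pos, idx, sigma, eps, box, pbc, F):
    E = 0.0
    for n in range(idx.shape[0]):
        i, j = idx[n, 0], idx[n, 1]
        d = _dvec(pos, i, j, box, pbc)
        r = math.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
        sr = sigma[n] / r
        sr10 = sr ** 10
        sr12 = sr10 * sr * sr
        E += eps[n] * (5.0 * sr12 - 6.0 * sr10)
        dE = eps[n] * 60.0 * (sr10 - sr12) / r
        g = dE / r
        for a in range(3):
            F[i, a] += g * d[a]
            F[j, a] -= g * d[a]
    return E


@njit(cache=True)
def gauss_pairs_ef(pos, idx, r0, eps, w, box, pbc, F):
    E = 0.0
    for n in range(idx.shape[0]):
        i, j = idx[n, 0], idx[n, 1]
        d = _dvec(pos, i, j, box, pbc)
        r = math.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
        dr = r - r0[n]
        w2 = w[n] * w[n]
        e = -eps[n] * math.exp(-dr * dr / (2.0 * w2))
        E += e
        dE = -e * dr / w2
        g = dE / r
        for a in range(3):
            F[i, a] += g * d[a]
            F[j, a] -= g * d[a]
    return E


@njit(cache=True, fastmath=True)
def exv_pairs_ef(pos, pairs, sigma2, eps, kind, box, pbc, F):
    """Excluded volume over a candidate pair list with precomputed per-pair
    parameters.  ``kind`` 0: r^-12 with cutoff 2*sigma and -2^-12*eps shift;
    1: LJ truncated at its minimum (cutoff sigma, 3SPN.2C DNA pairs);
    2: skip (both particles Ashbaugh-Hatch-active)."""
    E = 0.0
    shift = 2.0 ** -12
    bx, by, bz = box[0], box[1], box[2]
    for n in range(pairs.shape[0]):
        k = kind[n]
        if k == 2:
            continue
        i, j = pairs[n, 0], pairs[n, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        if pbc:
            dx -= bx * round(dx / bx)
            dy -= by * round(dy / by)
            dz -= bz * round(dz / bz)
        r2 = dx * dx + dy * dy + dz * dz
        s2 = sigma2[n]
        if k == 1:
            if r2 >= s2:
                continue
            sr6 = (s2 / r2) ** 3
            E += eps[n] * (sr6 * sr6 - 2.0 * sr6) + eps[n]
            g = eps[n] * 12.0 * (sr6 - sr6 * sr6) / r2
        else:
            if r2 >= 4.0 * s2:
                continue
            sr12 = (s2 / r2) ** 6
            E += eps[n] * (sr12 - shift)
            g = -12.0 * eps[n] * sr12 / r2
        F[i, 0] += g * dx
        F[i, 1] += g * dy
        F[i, 2] += g * dz
        F[j, 0] -= g * dx
        F[j, 1] -= g * dy
        F[j, 2] -= g * dz
    return E


@njit(cache=True, fastmath=True)
def ele_pairs_ef(pos, pairs, qq, pref, lam_d, cutoff, box, pbc, F):
    """Debye-Hueckel over a candidate pair list; qq is the per-pair charge
    product and pref = COULOMB/eps_r."""
    E = 0.0
    c2 = cutoff * cutoff
    bx, by, bz = box[0], box[1], box[2]
    for n in range(pairs.shape[0]):
        i, j = pairs[n, 0], pairs[n, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        if pbc:
            dx -= bx * round(dx / bx)
            dy -= by * round(dy / by)
            dz -= bz * round(dz / bz)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= c2:
            continue
        r = math.sqrt(r2)
        e = pref * qq[n] * math.exp(-r / lam_d) / r
        E += e
        g = -e * (1.0 / r + 1.0 / lam_d) / r
        F[i, 0] += g * dx
        F[i, 1] += g * dy
        F[i, 2] += g * dz
        F[j, 0] -= g * dx
        F[j, 1] -= g * dy
        F[j, 2] -= g * dz
    return E


@njit(cache=True, fastmath=True)
def hps_pairs_ef(pos, pairs, s2arr, lam, eps, cutoff, box, pbc, F):
    """Ashbaugh-Hatch (HPS/KH) over a candidate pair list with per-pair
    sigma^2, lambda and eps precomputed (arithmetic-mean sigma/lambda,
    geometric-mean eps)."""
    E = 0.0
    c2 = cutoff * cutoff
    rt2 = 2.0 ** (1.0 / 3.0)   # (2^(1/6))^2
    bx, by, bz = box[0], box[1], box[2]
    for n in range(pairs.shape[0]):
        i, j = pairs[n, 0], pairs[n, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        if pbc:
            dx -= bx * round(dx / bx)
            dy -= by * round(dy / by)
            dz -= bz * round(dz / bz)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= c2:
            continue
        s2 = s2arr[n]
        ep = eps[n]
        la = lam[n]
        sr6 = (s2 / r2) ** 3
        sr12 = sr6 * sr6
        elj = 4.0 * ep * (sr12 - sr6)
        glj = 4.0 * ep * (-12.0 * sr12 + 6.0 * sr6) / r2
        if r2 <= rt2 * s2:
            E += elj + (1.0 - la) * ep
            g = glj
        else:
            E += la * elj
            g = la * glj
        F[i, 0] += g * dx
        F[i, 1] += g * dy
        F[i, 2] += g * dz
        F[j, 0] -= g * dx
        F[j, 1] -= g * dy
        F[j, 2] -= g * dz
    return E


@njit(cache=True, fastmath=True)
def lj_pairs_ef(pos, pairs, s2arr, eps, cutoff, box, pbc, F):
    E = 0.0
    c2 = cutoff * cutoff
    bx, by, bz = box[0], box[1], box[2]
    for n in range(pairs.shape[0]):
        i, j = pairs[n, 0], pairs[n, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        if pbc:
            dx -= bx * round(dx / bx)
            dy -= by * round(dy / by)
            dz -= bz * round(dz / bz)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= c2:
            continue
        sr6 = (s2arr[n] / r2) ** 3
        E += 4.0 * eps[n] * (sr6 * sr6 - sr6)
        g = 4.0 * eps[n] * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r2
        F[i, 0] += g * dx
        F[i, 1] += g * dy
        F[i, 2] += g * dz
        F[j, 0] -= g * dx
        F[j, 1] -= g * dy
        F[j, 2] -= g * dz
    return E


# ---------------------------------------------------------------------------
# Morse split and modulator (shared by the DNA / protein-DNA site terms)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _morse_rep(r, eps, alpha, r0):
    if r >= r0:
        return 0.0, 0.0
    u = math.exp(-alpha * (r - r0))
    return eps * (1.0 - u) ** 2, 2.0 * eps * alpha * u * (1.0 - u)


@njit(cache=True, inline="always")
def _morse_attr(r, eps, alpha, r0):
    if r < r0:
        return -eps, 0.0
    u = math.exp(-alpha * (r - r0))
    return eps * (1.0 - u) ** 2 - eps, 2.0 * eps * alpha * u * (1.0 - u)


@njit(cache=True, inline="always")
def _fmod_gate(dtheta, gamma):
    a = abs(dtheta)
    if a < gamma:
        return 1.0, 0.0
    if a >= 2.0 * gamma:
        return 0.0, 0.0
    c = math.cos(math.pi * dtheta / (2.0 * gamma))
    return 1.0 - c * c, (math.pi / (2.0 * gamma)) * math.sin(
        math.pi * dtheta / gamma)


@njit(cache=True)
def stack_ef(pos, idx, eps, alpha, r0, theta0, gamma, box, pbc, F):
    """Intra-strand base stacking: E = Morse_rep(r) + f(dtheta) Morse_attr(r),
    r between the two bases, theta at the 5' base against its sugar."""
    E = 0.0
    gs = np.empty(3)
    gb5 = np.empty(3)
    gb3 = np.empty(3)
    for n in range(idx.shape[0]):
        s, b5, b3 = idx[n, 0], idx[n, 1], idx[n, 2]
        d = _dvec(pos, b5, b3, box, pbc)
        r = math.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
        erep, drep = _morse_rep(r, eps[n], alpha[n], r0[n])
        eatt, datt = _morse_attr(r, eps[n], alpha[n], r0[n])
        theta = _angle_grad(pos, s, b5, b3, box, pbc, gs, gb5, gb3)
        f, df = _fmod_gate(theta - theta0[n], gamma[n])
        E += erep + f * eatt
        dEdr = drep + f * datt
        dEdth = df * eatt
        g = dEdr / r
        for a in range(3):
            F[b5, a] += g * d[a]
            F[b3, a] -= g * d[a]
            F[s, a] -= dEdth * gs[a]
            F[b5, a] -= dEdth * gb5[a]
            F[b3, a] -= dEdth * gb3[a]
    return E


@njit(cache=True)
def basepair_ef(pos, cand, sugar_of, code, wc_eps, wc_alpha, wc_r0,
                wc_th1, wc_th2, wc_phi0, wc_gamma, cutoff, box, pbc, F):
    """Watson-Crick base pairing over base-base candidate pairs.

    ``cand`` rows are (Bi, Bj) base particle indices; per-base ``sugar_of``
    and ``code`` (A0 C1 G2 T3) resolve geometry and parameters.  The WC
    parameter arrays are indexed 0 = A.T, 1 = G.C; non-WC combinations
    contribute nothing.  E = rep(r) + 1/2 (1 + cos dphi) f(dth1) f(dth2)
    attr(r); the repulsive Morse part is ungated.
    """
    E = 0.0
    g1i = np.empty(3)
    g1j = np.empty(3)
    g1k = np.empty(3)
    g2i = np.empty(3)
    g2j = np.empty(3)
    g2k = np.empty(3)
    fi = np.empty(3)
    fj = np.empty(3)
    fk = np.empty(3)
    fl = np.empty(3)
    c2 = cutoff * cutoff
    for n in range(cand.shape[0]):
        bi, bj = cand[n, 0], cand[n, 1]
        ci, cj = code[bi], code[bj]
        # WC: A(0)-T(3) or G(2)-C(1)
        if ci + cj == 3 and (ci == 0 or ci == 3):
            t = 0
        elif ci + cj == 3:
            t = 1
        else:
            continue
        d = _dvec(pos, bi, bj, box, pbc)
        r2 = d[0] ** 2 + d[1] ** 2 + d[2] ** 2
        if r2 >= c2:
            continue
        r = math.sqrt(r2)
        si, sj = sugar_of[bi], sugar_of[bj]
        erep, drep = _morse_rep(r, wc_eps[t], wc_alpha[t], wc_r0[t])
        eatt, datt = _morse_attr(r, wc_eps[t], wc_alpha[t], wc_r0[t])
        th1 = _angle_grad(pos, si, bi, bj, box, pbc, g1i, g1j, g1k)
        th2 = _angle_grad(pos, bi, bj, sj, box, pbc, g2i, g2j, g2k)
        f1, df1 = _fmod_gate(th1 - wc_th1[t], wc_gamma[t])
        f2, df2 = _fmod_gate(th2 - wc_th2[t], wc_gamma[t])
        phi = _dihedral_grad(pos, si, bi, bj, sj, box, pbc, fi, fj, fk, fl)
        dphi = _wrap_pi(phi - wc_phi0[t])
        h = 0.5 * (1.0 + math.cos(dphi))
        E += erep + h * f1 * f2 * eatt
        dEdr = drep + h * f1 * f2 * datt
        dEdth1 = h * df1 * f2 * eatt
        dEdth2 = h * f1 * df2 * eatt
        dEdphi = -0.5 * math.sin(dphi) * f1 * f2 * eatt
        g = dEdr / r
        for a in range(3):
            F[bi, a] += g * d[a]
            F[bj, a] -= g * d[a]
            F[si, a] -= dEdth1 * g1i[a]
            F[bi, a] -= dEdth1 * g1j[a]
            F[bj, a] -= dEdth1 * g1k[a]
            F[bi, a] -= dEdth2 * g2i[a]
            F[bj, a] -= dEdth2 * g2j[a]
            F[sj, a] -= dEdth2 * g2k[a]
            F[si, a] -= dEdphi * fi[a]
            F[bi, a] -= dEdphi * fj[a]
            F[bj, a] -= dEdphi * fk[a]
            F[sj, a] -= dEdphi * fl[a]
    return E


@njit(cache=True)
def cross_stack_ef(pos, cand, sugar_of, base3_of, code,
                   cs_eps, cs_alpha, cs_r0, cs_th3, cs_thcs, cs_gamma,
                   cutoff, box, pbc, F):
    """Cross stacking: for each WC-compatible candidate (Bi, Bj), the 3'
    sequence neighbors across the duplex interact:
    E = f(dth3) f(dthCS) Morse_attr(r) with r between Bi and base3(Bj)
    (and symmetrically Bj with base3(Bi))."""
    E = 0.0
    g1i = np.empty(3)
    g1j = np.empty(3)
    g1k = np.empty(3)
    g2i = np.empty(3)
    g2j = np.empty(3)
    g2k = np.empty(3)
    c2 = cutoff * cutoff
    for n in range(cand.shape[0]):
        bi, bj = cand[n, 0], cand[n, 1]
        ci, cj = code[bi], code[bj]
        if ci + cj != 3:
            continue
        t = 0 if (ci == 0 or ci == 3) else 1
        for rep in range(2):
            if rep == 0:
                bx, by = bi, base3_of[bj]
            else:
                bx, by = bj, base3_of[bi]
            if by < 0:
                continue
            d = _dvec(pos, bx, by, box, pbc)
            r2 = d[0] ** 2 + d[1] ** 2 + d[2] ** 2
            if r2 >= c2:
                continue
            r = math.sqrt(r2)
            sx, sy = sugar_of[bx], sugar_of[by]
            eatt, datt = _morse_attr(r, cs_eps[t], cs_alpha[t], cs_r0[t])
            th3 = _angle_grad(pos, sx, bx, by, box, pbc, g1i, g1j, g1k)
            thcs = _angle_grad(pos, bx, by, sy, box, pbc, g2i, g2j, g2k)
            f3, df3 = _fmod_gate(th3 - cs_th3[t], cs_gamma[t])
            fcs, dfcs = _fmod_gate(thcs - cs_thcs[t], cs_gamma[t])
            E += f3 * fcs * eatt
            dEdr = f3 * fcs * datt
            dEdth3 = df3 * fcs * eatt
            dEdthcs = f3 * dfcs * eatt
            g = dEdr / r
            for a in range(3):
                F[bx, a] += g * d[a]
                F[by, a] -= g * d[a]
                F[sx, a] -= dEdth3 * g1i[a]
                F[bx, a] -= dEdth3 * g1j[a]
                F[by, a] -= dEdth3 * g1k[a]
                F[bx, a] -= dEdthcs * g2i[a]
                F[by, a] -= dEdthcs * g2j[a]
                F[sy, a] -= dEdthcs * g2k[a]
    return E


@njit(cache=True, inline="always")
def _vec_angle_grad(pos, a1, a2, b1, b2, box, pbc, ga1, ga2, gb1, gb2):
    """Angle between vectors (a1->a2) and (b1->b2) and its gradients."""
    u = _dvec(pos, a1, a2, box, pbc)
    v = _dvec(pos, b1, b2, box, pbc)
    lu = math.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
    lv = math.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
    ct = (u[0] * v[0] + u[1] * v[1] + u[2] * v[2]) / (lu * lv)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    theta = math.acos(ct)
    st = math.sqrt(1.0 - ct * ct)
    if st < _SIN_CLAMP:
        st = _SIN_CLAMP
    for a in range(3):
        du = (ct * u[a] / lu - v[a] / lv) / (lu * st)
        dv = (ct * v[a] / lv - u[a] / lu) / (lv * st)
        ga2[a] = du
        ga1[a] = -du
        gb2[a] = dv
        gb1[a] = -dv
    return theta


@njit(cache=True)
def pwmcos_ef(pos, site_base, s_ca, s_prev, s_next, s_eps, s_r0,
              s_th1, s_th2, s_th3, s_w, s_gamma,
              sugar_of, base5_of, base3_of, box, pbc, F):
    """PWMcos protein-DNA recognition.

    ``site_base`` rows pair a site record index with a base particle;
    ``s_eps`` carries the PWM-resolved depth for that (site, base-type)
    combination, precomputed by the caller.  theta1 is the sugar-base-Calpha
    angle, theta2 the angle of the strand direction (5' base -> 3' base)
    against base->Calpha, theta3 the angle of the Calpha backbone direction
    (j-1 -> j+1) against base->Calpha.  Cutoff r0 + 5 A per site.
    """
    E = 0.0
    g1i = np.empty(3)
    g1j = np.empty(3)
    g1k = np.empty(3)
    ga1 = np.empty(3)
    ga2 = np.empty(3)
    gb1 = np.empty(3)
    gb2 = np.empty(3)
    ha1 = np.empty(3)
    ha2 = np.empty(3)
    hb1 = np.empty(3)
    hb2 = np.empty(3)
    for n in range(site_base.shape[0]):
        s = site_base[n, 0]
        b = site_base[n, 1]
        j = s_ca[s]
        d = _dvec(pos, b, j, box, pbc)
        r = math.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
        if r >= s_r0[s] + 5.0:
            continue
        eps = s_eps[n]
        if eps == 0.0:
            continue
        sb = sugar_of[b]
        b5 = base5_of[b]
        b3 = base3_of[b]
        if b5 < 0:
            b5 = b
        if b3 < 0:
            b3 = b
        if b5 == b3:
            continue
        dr = r - s_r0[s]
        w2 = s_w[s] * s_w[s]
        eg = -eps * math.exp(-dr * dr / (2.0 * w2))
        deg = -eg * dr / w2
        th1 = _angle_grad(pos, sb, b, j, box, pbc, g1i, g1j, g1k)
        f1, df1 = _fmod_gate(th1 - s_th1[s], s_gamma[s])
        th2 = _vec_angle_grad(pos, b5, b3, b, j, box, pbc, ga1, ga2, gb1, gb2)
        f2, df2 = _fmod_gate(th2 - s_th2[s], s_gamma[s])
        th3 = _vec_angle_grad(pos, s_prev[s], s_next[s], b, j, box, pbc,
                              ha1, ha2, hb1, hb2)
        f3, df3 = _fmod_gate(th3 - s_th3[s], s_gamma[s])
        E += eg * f1 * f2 * f3
        dEdr = deg * f1 * f2 * f3
        dEdt1 = eg * df1 * f2 * f3
        dEdt2 = eg * f1 * df2 * f3
        dEdt3 = eg * f1 * f2 * df3
        g = dEdr / r
        for a in range(3):
            F[b, a] += g * d[a]
            F[j, a] -= g * d[a]
            F[sb, a] -= dEdt1 * g1i[a]
            F[b, a] -= dEdt1 * g1j[a]
            F[j, a] -= dEdt1 * g1k[a]
            F[b5, a] -= dEdt2 * ga1[a]
            F[b3, a] -= dEdt2 * ga2[a]
            F[b, a] -= dEdt2 * gb1[a]
            F[j, a] -= dEdt2 * gb2[a]
            F[s_prev[s], a] -= dEdt3 * ha1[a]
            F[s_next[s], a] -= dEdt3 * ha2[a]
            F[b, a] -= dEdt3 * hb1[a]
            F[j, a] -= dEdt3 * hb2[a]
    return E


@njit(cache=True)
def hb_sites_ef(pos, p_idx, s_idx, ca, ca_prev, ca_next,
                r0, th1_0, th2_0, eps, w, gamma, box, pbc, F):
    """Backbone hydrogen-bond sites: E = Gaussian(r) f(dth1) f(dth2) with r
    from phosphate to Calpha; pre-defined pairs, cutoff r0 + 5 A."""
    E = 0.0
    g1i = np.empty(3)
    g1j = np.empty(3)
    g1k = np.empty(3)
    ha1 = np.empty(3)
    ha2 = np.empty(3)
    hb1 = np.empty(3)
    hb2 = np.empty(3)
    for n in range(p_idx.shape[0]):
        p = p_idx[n]
        j = ca[n]
        d = _dvec(pos, p, j, box, pbc)
        r = math.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
        if r >= r0[n] + 5.0:
            continue
        dr = r - r0[n]
        w2 = w[n] * w[n]
        eg = -eps[n] * math.exp(-dr * dr / (2.0 * w2))
        deg = -eg * dr / w2
        th1 = _angle_grad(pos, s_idx[n], p, j, box, pbc, g1i, g1j, g1k)
        f1, df1 = _fmod_gate(th1 - th1_0[n], gamma[n])
        th2 = _vec_angle_grad(pos, ca_prev[n], ca_next[n], p, j, box, pbc,
                              ha1, ha2, hb1, hb2)
        f2, df2 = _fmod_gate(th2 - th2_0[n], gamma[n])
        E += eg * f1 * f2
        dEdr = deg * f1 * f2
        dEdt1 = eg * df1 * f2
        dEdt2 = eg * f1 * df2
        g = dEdr / r
        for a in range(3):
            F[p, a] += g * d[a]
            F[j, a] -= g * d[a]
            F[s_idx[n], a] -= dEdt1 * g1i[a]
            F[p, a] -= dEdt1 * g1j[a]
            F[j, a] -= dEdt1 * g1k[a]
            F[ca_prev[n], a] -= dEdt2 * ha1[a]
            F[ca_next[n], a] -= dEdt2 * ha2[a]
            F[p, a] -= dEdt2 * hb1[a]
            F[j, a] -= dEdt2 * hb2[a]
    return E


# ---------------------------------------------------------------------------
# cell-linked-list pair construction
# ---------------------------------------------------------------------------

@njit(cache=True)
def bin_particles(pos, subset, origin, edge, ncell, pbc):
    """Cell id per subset member (flattened 3-D index)."""
    out = np.empty(subset.shape[0], dtype=np.int64)
    for n in range(subset.shape[0]):
        i = subset[n]
        cx = int(math.floor((pos[i, 0] - origin[0]) / edge[0]))
        cy = int(math.floor((pos[i, 1] - origin[1]) / edge[1]))
        cz = int(math.floor((pos[i, 2] - origin[2]) / edge[2]))
        if pbc:
            cx %= ncell[0]
            cy %= ncell[1]
            cz %= ncell[2]
        else:
            cx = min(max(cx, 0), ncell[0] - 1)
            cy = min(max(cy, 0), ncell[1] - 1)
            cz = min(max(cz, 0), ncell[2] - 1)
        out[n] = (cx * ncell[1] + cy) * ncell[2] + cz
    return out


@njit(cache=True)
def _excluded(i, j, n_particles, excl_keys):
    a, b = (i, j) if i < j else (j, i)
    key = a * n_particles + b
    lo, hi = 0, excl_keys.shape[0]
    while lo < hi:
        mid = (lo + hi) // 2
        if excl_keys[mid] < key:
            lo = mid + 1
        else:
            hi = mid
    return lo < excl_keys.shape[0] and excl_keys[lo] == key


@njit(cache=True, fastmath=True)
def build_pairs_same(pos, members, cell_start, cell_order, neigh, r_p,
                     n_particles, excl_keys, box, pbc, out):
    """Candidate pairs within one subset; each pair once with i < j.

    ``neigh`` is the resolved neighboring-cell table (n_cells x n_offsets,
    -1 padded for open boundaries).  Fills ``out`` and returns the pair
    count, or -1 if the buffer is too small (the caller grows it and
    retries).  Pairs come out grouped by i for cache-friendly force loops.
    """
    rp2 = r_p * r_p
    cap = out.shape[0]
    nout = 0
    bx, by, bz = box[0], box[1], box[2]
    for ci in range(cell_start.shape[0] - 1):
        for ia in range(cell_start[ci], cell_start[ci + 1]):
            i = members[cell_order[ia]]
            xi = pos[i, 0]
            yi = pos[i, 1]
            zi = pos[i, 2]
            for m in range(neigh.shape[1]):
                ck = neigh[ci, m]
                if ck < 0:
                    continue
                for ib in range(cell_start[ck], cell_start[ck + 1]):
                    j = members[cell_order[ib]]
                    if i >= j:
                        continue
                    dx = pos[j, 0] - xi
                    dy = pos[j, 1] - yi
                    dz = pos[j, 2] - zi
                    if pbc:
                        dx -= bx * round(dx / bx)
                        dy -= by * round(dy / by)
                        dz -= bz * round(dz / bz)
                    if dx * dx + dy * dy + dz * dz >= rp2:
                        continue
                    if excl_keys.shape[0] and _excluded(
                            i, j, n_particles, excl_keys):
                        continue
                    if nout >= cap:
                        return -1
                    out[nout, 0] = i
                    out[nout, 1] = j
                    nout += 1
    return nout


@njit(cache=True, fastmath=True)
def build_pairs_cross(pos, members_a, cell_start_a, cell_order_a,
                      members_b, cell_start_b, cell_order_b,
                      neigh, r_p, n_particles, excl_keys, box, pbc, out):
    """Candidate pairs between two disjoint subsets (a, b); same contract
    as :func:`build_pairs_same`."""
    rp2 = r_p * r_p
    cap = out.shape[0]
    nout = 0
    bx, by, bz = box[0], box[1], box[2]
    for ci in range(cell_start_a.shape[0] - 1):
        for ia in range(cell_start_a[ci], cell_start_a[ci + 1]):
            i = members_a[cell_order_a[ia]]
            xi = pos[i, 0]
            yi = pos[i, 1]
            zi = pos[i, 2]
            for m in range(neigh.shape[1]):
                ck = neigh[ci, m]
                if ck < 0:
                    continue
                for ib in range(cell_start_b[ck], cell_start_b[ck + 1]):
                    j = members_b[cell_order_b[ib]]
                    dx = pos[j, 0] - xi
                    dy = pos[j, 1] - yi
                    dz = pos[j, 2] - zi
                    if pbc:
                        dx -= bx * round(dx / bx)
                        dy -= by * round(dy / by)
                        dz -= bz * round(dz / bz)
                    if dx * dx + dy * dy + dz * dz >= rp2:
                        continue
                    if excl_keys.shape[0] and _excluded(
                            i, j, n_particles, excl_keys):
                        continue
                    if nout >= cap:
                        return -1
                    out[nout, 0] = i
                    out[nout, 1] = j
                    nout += 1
    return nout


# ---------------------------------------------------------------------------
# integrator helpers (fused to avoid temporaries in the hot loop)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def kick_drift(pos, vel, accel, dt):
    """v += dt/2 * a;  r += dt * v  (in place)."""
    n = pos.shape[0]
    h = 0.5 * dt
    for i in range(n):
        for a in range(3):
            vel[i, a] += h * accel[i, a]
            pos[i, a] += dt * vel[i, a]


@njit(cache=True, fastmath=True)
def assemble_kick(vel, accel, grad_forces, inv_m_int, friction, noise, dt):
    """a = F/m - gamma*v + xi;  v += dt/2 * a  (in place; noise may be
    zero-length when gamma is zero)."""
    n = vel.shape[0]
    h = 0.5 * dt
    has_noise = noise.shape[0] == n
    for i in range(n):
        im = inv_m_int[i]
        for a in range(3):
            acc = grad_forces[i, a] * im
            if friction != 0.0:
                acc -= friction * vel[i, a]
            if has_noise:
                acc += noise[i, a]
            accel[i, a] = acc
            vel[i, a] += h * acc
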