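"""Numba kernels for extended-phase-graph echo-train simulation.

State layout: ``fp[k]`` holds the transverse configuration F(+k),
``fm[k]`` holds F(-k) and ``z[k]`` the longitudinal configuration Z(k),
for dephasing orders k = 0..K.  The conjugate symmetry F(-k) = F*(+k)
does not hold in general, so both signs are stored; Z(-k) = Z*(k) is
implicit.  One unit of gradient dephasing is applied per half echo
spacing, so orders grow by at most two per echo and K = 2 * n_echoes
is exact (higher orders can never refocus into F(0) within the train).
"""

import numpy as np
from numba import njit

__all__ = ["epg_train_batch"]


@njit(cache=False)
def _apply_rf(fp, fm, z, kmax, theta, phase):
    """Mix (F(+k), F(-k)*, Z(k)) with the RF rotation for orders 0..kmax."""
    half = 0.5 * theta
    c2 = np.cos(half) ** 2
    s2 = np.sin(half) ** 2
    s = np.sin(theta)
    c = np.cos(theta)
    eip = np.exp(1j * phase)
    eim = np.exp(-1j * phase)
    t11 = c2 + 0.0j
    t12 = eip * eip * s2
    t13 = -1j * eip * s
    t21 = eim * eim * s2
    t22 = c2 + 0.0j
    t23 = 1j * eim * s
    t31 = -0.5j * eim * s
    t32 = 0.5j * eip * s
    t33 = c + 0.0j
    for k in range(kmax + 1):
        a = fp[k]
        b = np.conj(fm[k])
        zz = z[k]
        fp[k] = t11 * a + t12 * b + t13 * zz
        fm[k] = np.conj(t21 * a + t22 * b + t23 * zz)
        z[k] = t31 * a + t32 * b + t33 * zz


@njit(cache=False)
def _relax(fp, fm, z, kmax, e1, e2):
    for k in range(kmax + 1):
        fp[k] *= e2
        fm[k] *= e2
        z[k] *= e1
    z[0] += 1.0 - e1


@njit(cache=False)
def _grad_shift(fp, fm, kmax):
    """Shift all transverse orders up by one (unit dephasing)."""
    for k in range(kmax + 1, 0, -1):
        fp[k] = fp[k - 1]
    for k in range(kmax + 1):
        fm[k] = fm[k + 1]
    fm[kmax + 1] = 0.0
    fp[0] = fm[0]


@njit(cache=False)
def _train(theta0, refocus, cpmg_phase, esp, t1, t2, out):
    n = refocus.shape[0]
    kcap = 2 * n + 2
    fp = np.zeros(kcap + 2, np.complex128)
    fm = np.zeros(kcap + 2, np.complex128)
    z = np.zeros(kcap + 2, np.complex128)
    z[0] = 1.0
    e2 = np.exp(-esp / (2.0 * t2))
    e1 = np.exp(-esp / (2.0 * t1))
    _apply_rf(fp, fm, z, 0, theta0, 0.0)
    kmax = 0
    for e in range(n):
        _relax(fp, fm, z, kmax, e1, e2)
        _grad_shift(fp, fm, kmax)
        kmax = min(kmax + 1, kcap)
        _apply_rf(fp, fm, z, kmax, refocus[e], cpmg_phase)
        _relax(fp, fm, z, kmax, e1, e2)
        _grad_shift(fp, fm, kmax)
        kmax = min(kmax + 1, kcap)
        out[e] = fp[0]


@njit(cache=False)
def epg_train_batch(theta0s, theta1s, theta2s, cpmg_phase, esp, t1s, t2s, n_echoes):
    """Echo-train F(0) signals for a batch of (profile angle, T1, T2) rows.

    The train uses the SS-FSE pulse structure: excitation ``theta0``,
    first refocusing pulse ``theta1``, then ``theta2`` for every later
    pulse.  Returns a complex (batch, n_echoes) array; echo e (1-based)
    occurs at time e * esp after excitation.
    """
    b = t2s.shape[0]
    out = np.empty((b, n_echoes), np.complex128)
    refocus = np.empty(n_echoes, np.float64)
    for i in range(b):
        refocus[0] = theta1s[i]
        for e in range(1, n_echoes):
            refocus[e] = theta2s[i]
        _train(theta0s[i], refocus, cpmg_phase, esp, t1s[i], t2s[i], out[i])
    return out


@njit(cache=False)
def epg_train_general(theta0, refocus, cpmg_phase, esp, t1, t2):
    """Single echo train with an arbitrary per-echo refocusing schedule."""
    out = np.empty(refocus.shape[0], np.complex128)
    _train(theta0, refocus, cpmg_phase, esp, t1, t2, out)
    return out
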