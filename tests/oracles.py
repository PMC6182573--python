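"""Independent brute-force reference implementations used only by tests.

Everything here is written as literal per-trial, per-frequency summation of
the estimator formulas, deliberately sharing no code path with the package
(including a from-scratch analytic-signal construction), so that agreement
is meaningful.
"""

import numpy as np


def analytic_signal(z):
    """Textbook discrete analytic signal via the full FFT multiplier."""
    z = np.asarray(z, dtype=float)
    n = z.size
    spec = np.fft.fft(z)
    h = np.zeros(n)
    h[0] = 1.0
    if n % 2 == 0:
        h[n // 2] = 1.0
        h[1 : n // 2] = 2.0
    else:
        h[1 : (n + 1) // 2] = 2.0
    return np.fft.ifft(spec * h)


def measure_by_summation(measure, u, v):
    """Direct-summation evaluation of one measure from coefficients (N, F)."""
    u = np.asarray(u, dtype=complex)
    v = np.asarray(v, dtype=complex)
    n, f = u.shape
    s_uv = np.zeros(f, dtype=complex)
    s_uu = np.zeros(f)
    s_vv = np.zeros(f)
    for i in range(n):
        for k in range(f):
            s_uv[k] += u[i, k] * np.conj(v[i, k])
            s_uu[k] += abs(u[i, k]) ** 2
            s_vv[k] += abs(v[i, k]) ** 2
    s_uv /= n
    s_uu /= n
    s_vv /= n
    coh = s_uv / np.sqrt(s_uu * s_vv)

    if measure == "coh":
        return np.abs(coh)
    if measure == "icoh1":
        return coh.imag
    if measure == "eic1":
        return np.abs(analytic_signal(coh.imag))
    if measure == "lcoh":
        return coh.imag**2 / (1.0 - coh.real**2)
    if measure == "plv":
        acc = np.zeros(f, dtype=complex)
        for i in range(n):
            for k in range(f):
                acc[k] += np.exp(1j * (np.angle(u[i, k]) - np.angle(v[i, k])))
        return np.abs(acc / n)
    if measure == "pli":
        acc = np.zeros(f)
        for i in range(n):
            for k in range(f):
                acc[k] += np.sign((u[i, k] * np.conj(v[i, k])).imag)
        return np.abs(acc / n)
    if measure == "wpli":
        num = np.zeros(f)
        den = np.zeros(f)
        for i in range(n):
            for k in range(f):
                im = (u[i, k] * np.conj(v[i, k])).imag
                num[k] += im
                den[k] += abs(im)
        return np.abs(num / n) / (den / n)
    if measure in ("icoh2", "eic2"):
        num = np.zeros(f)
        den = np.zeros(f)
        for i in range(n):
            im_i = np.array([(u[i, k] * np.conj(v[i, k])).imag for k in range(f)])
            env_i = np.abs(analytic_signal(im_i))
            num += im_i
            den += env_i
        icoh2 = (num / n) / (den / n)
        if measure == "icoh2":
            return icoh2
        return np.abs(analytic_signal(icoh2))
    raise ValueError(measure)
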