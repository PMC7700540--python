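"""Independent brute-force recomputations of every feature.

Everything here is written as plain loops and direct O(n^2) transforms,
deliberately avoiding the vectorized code paths of the package, so the
feature suite is checked against genuinely independent arithmetic.
Cubic-spline interpolation (a library primitive) is shared; the sifting
logic, extrema detection, transforms and statistics are not.
"""

from __future__ import annotations

import cmath
import math

import numpy as np
from scipy.interpolate import CubicSpline


def naive_mean(s):
    return sum(s) / len(s)


def naive_median(s):
    v = sorted(s)
    n = len(v)
    mid = n // 2
    return v[mid] if n % 2 else (v[mid - 1] + v[mid]) / 2.0


def naive_std(s):
    m = naive_mean(s)
    return math.sqrt(sum((x - m) ** 2 for x in s) / (len(s) - 1))


def naive_var(s):
    m = naive_mean(s)
    return sum((x - m) ** 2 for x in s) / (len(s) - 1)


def naive_mode(s):
    lo, hi = min(s), max(s)
    if lo == hi:
        return lo
    width = (hi - lo) / 10.0
    counts = [0] * 10
    for x in s:
        i = int((x - lo) / width)
        if i == 10:  # the max lands in the last bin
            i = 9
        counts[i] += 1
    best = max(range(10), key=lambda i: (counts[i], -i))
    return lo + (best + 0.5) * width


def naive_quantile(s, p):
    """Linear-interpolation (type 7) quantile."""
    v = sorted(s)
    h = (len(v) - 1) * p
    lo = int(math.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def naive_peaks(s):
    q1 = naive_quantile(s, 0.25)
    q3 = naive_quantile(s, 0.75)
    below = [x for x in s if x < q1]
    above = [x for x in s if x > q3]
    neg = min(below) if below else min(s)
    pos = max(above) if above else max(s)
    return neg, pos


def naive_zcr(s):
    nz = [x for x in s if x != 0.0]
    crossings = 0
    for a, b in zip(nz, nz[1:]):
        if (a > 0) != (b > 0):
            crossings += 1
    return crossings / (len(s) - 1)


def naive_energy(s):
    return sum(x * x for x in s) / len(s)


def naive_magnitude_mean(frame_axes):
    total = 0.0
    for x, y, z in frame_axes:
        total += math.sqrt(x * x + y * y + z * z)
    return total / len(frame_axes)


def naive_sma(frame_axes, absolute=False):
    total = 0.0
    for x, y, z in frame_axes:
        if absolute:
            total += abs(x) + abs(y) + abs(z)
        else:
            total += x + y + z
    return total / len(frame_axes)


def naive_corr(u, v):
    mu, mv = naive_mean(u), naive_mean(v)
    su = math.sqrt(sum((x - mu) ** 2 for x in u))
    sv = math.sqrt(sum((x - mv) ** 2 for x in v))
    if su == 0.0 or sv == 0.0:
        return 0.0
    cov = sum((x - mu) * (y - mv) for x, y in zip(u, v))
    return cov / (su * sv)


def naive_dft(s):
    """Direct O(n^2) DFT; coefficients for k = 0..n//2."""
    n = len(s)
    return [
        sum(s[t] * cmath.exp(-2j * math.pi * k * t / n) for t in range(n))
        for k in range(n // 2 + 1)
    ]


def _hann(n):
    return [0.5 - 0.5 * math.cos(2.0 * math.pi * t / n) for t in range(n)]


def naive_fundamental(s, rate):
    if max(s) == min(s):
        return 0.0
    w = _hann(len(s))
    coef = naive_dft([x * h for x, h in zip(s, w)])
    power = [abs(c) ** 2 for c in coef]
    k = max(range(1, len(power)), key=lambda i: (power[i], -i))
    return k * rate / len(s)


def naive_phase(s, rate):
    if max(s) == min(s):
        return 0.0
    w = _hann(len(s))
    coef_w = naive_dft([x * h for x, h in zip(s, w)])
    power = [abs(c) ** 2 for c in coef_w]
    k = max(range(1, len(power)), key=lambda i: (power[i], -i))
    return cmath.phase(naive_dft(list(s))[k])


def naive_spectral_entropy(s, rate):
    coef = naive_dft(list(s))
    power = [abs(c) ** 2 for c in coef[1:]]  # band (0, Nyquist]
    total = sum(power)
    if total == 0.0:
        return 0.0
    ent = 0.0
    for p in power:
        p /= total
        if p > 0.0:
            ent -= p * math.log(p)
    return ent / math.log(len(power))


# --- independently coded EMD / Hilbert path ---------------------------------


def _loop_extrema(h):
    maxima, minima = [], []
    for i in range(1, len(h) - 1):
        if h[i] > h[i - 1] and h[i] > h[i + 1]:
            maxima.append(i)
        elif h[i] < h[i - 1] and h[i] < h[i + 1]:
            minima.append(i)
    return maxima, minima


def _loop_envelope(idx, h, n):
    if len(idx) < 2:
        return None
    k = min(2, len(idx))
    t, v = [], []
    for j in range(k - 1, -1, -1):
        t.append(-idx[j])
        v.append(h[idx[j]])
    for j in idx:
        t.append(j)
        v.append(h[j])
    for j in range(len(idx) - 1, len(idx) - 1 - k, -1):
        t.append(2 * (n - 1) - idx[j])
        v.append(h[idx[j]])
    seen, tt, vv = set(), [], []
    for a, b in zip(t, v):
        if a not in seen:
            seen.add(a)
            tt.append(a)
            vv.append(b)
    order = sorted(range(len(tt)), key=lambda i: tt[i])
    tt = [tt[i] for i in order]
    vv = [vv[i] for i in order]
    return CubicSpline(tt, vv)(np.arange(n))


def naive_emd(series, sd_threshold=0.2, max_sifts=10, max_imfs=8):
    """Sifting re-implemented with explicit loops; same published constants."""
    residue = [float(x) for x in series]
    n = len(residue)
    imfs = []
    while len(imfs) < max_imfs:
        maxima, minima = _loop_extrema(residue)
        if len(maxima) < 2 or len(minima) < 2:
            break
        h = list(residue)
        for _ in range(max_sifts):
            maxima, minima = _loop_extrema(h)
            upper = _loop_envelope(maxima, h, n)
            lower = _loop_envelope(minima, h, n)
            if upper is None or lower is None:
                break
            h_new = [h[i] - (upper[i] + lower[i]) / 2.0 for i in range(n)]
            denom = sum(x * x for x in h)
            if denom == 0.0:
                h = h_new
                break
            sd = sum((a - b) ** 2 for a, b in zip(h, h_new)) / denom
            h = h_new
            if sd < sd_threshold:
                break
        imfs.append(h)
        residue = [residue[i] - h[i] for i in range(n)]
    return imfs, residue


def naive_analytic(s):
    """Analytic signal via the direct full DFT (one-sided doubling)."""
    n = len(s)
    coef = [
        sum(s[t] * cmath.exp(-2j * math.pi * k * t / n) for t in range(n))
        for k in range(n)
    ]
    half = [0j] * n
    half[0] = coef[0]
    if n % 2 == 0:
        half[n // 2] = coef[n // 2]
        top = n // 2
    else:
        top = (n + 1) // 2
    for k in range(1, top):
        half[k] = 2.0 * coef[k]
    return [
        sum(half[k] * cmath.exp(2j * math.pi * k * t / n) for k in range(n)) / n
        for t in range(n)
    ]


def naive_hht(series, rate, n_imfs=3):
    total = sum(x * x for x in series)
    imfs, _ = naive_emd(series)
    out = []
    for i in range(n_imfs):
        if i < len(imfs) and total > 0.0:
            imf = imfs[i]
            energy = sum(x * x for x in imf) / total
            analytic = naive_analytic(imf)
            amp = naive_mean([abs(a) for a in analytic])
            phase = [cmath.phase(a) for a in analytic]
            unwrapped = [phase[0]]
            for p in phase[1:]:
                d = p - unwrapped[-1]
                while d > math.pi:
                    d -= 2 * math.pi
                while d < -math.pi:
                    d += 2 * math.pi
                unwrapped.append(unwrapped[-1] + d)
            dphi = [b - a for a, b in zip(unwrapped, unwrapped[1:])]
            margin = max(1, len(dphi) // 10)
            interior = dphi[margin:-margin] if len(dphi) > 2 * margin else dphi
            freq = naive_mean(interior) * rate / (2 * math.pi)
            out.extend([energy, amp, freq])
        else:
            out.extend([0.0, 0.0, 0.0])
    return out
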