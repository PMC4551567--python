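"""Numerical kernels for the multicompartment membrane integrator.

Compiled with numba when available; the same code runs (slowly) in pure
Python otherwise.  All kernel quantities use a consistent unit system:
mV, ms, nA, μS, nF, mM; membrane current densities in μA/cm².
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(fn):
            return fn

        return deco


FARADAY = 96485.33212  # C/mol


@njit(cache=True)
def exprelr(x: float) -> float:
    """x / (exp(x) - 1), continuous through the removable singularity."""
    if abs(x) < 1e-7:
        return 1.0 - 0.5 * x
    return x / (math.exp(x) - 1.0)


@njit(cache=True)
def alpha_m(v: float) -> float:
    return 6.0 * exprelr(-0.1 * (v + 30.0))


@njit(cache=True)
def beta_m(v: float) -> float:
    return 20.0 * math.exp(-(v + 55.0) / 18.0)


@njit(cache=True)
def alpha_h(v: float) -> float:
    return 0.4 * math.exp(-(v + 50.0) / 20.0)


@njit(cache=True)
def beta_h(v: float) -> float:
    return 6.0 / (1.0 + math.exp(-0.1 * (v + 20.0)))


@njit(cache=True)
def alpha_n(v: float) -> float:
    return 0.2 * exprelr(-0.1 * (v + 40.0))


@njit(cache=True)
def beta_n(v: float) -> float:
    return 0.4 * math.exp(-(v + 50.0) / 80.0)


@njit(cache=True)
def alpha_a(v: float, printed: bool) -> float:
    if not printed:
        # source-model form: numerator and exponential share the (V+90) shift
        return 0.06 * exprelr(-0.1 * (v + 90.0))
    # as-printed variant has a true singularity at V = -40; clamp
    den = math.exp(-0.1 * (v + 40.0)) - 1.0
    if abs(den) < 1e-6:
        den = -1e-6 if den <= 0 else 1e-6
    val = -0.006 * (v + 90.0) / den
    return val if val > 0.0 else 0.0


@njit(cache=True)
def beta_a(v: float) -> float:
    return 0.1 * math.exp(-(v + 30.0) / 10.0)


@njit(cache=True)
def alpha_ha(v: float) -> float:
    return 0.04 * math.exp(-(v + 70.0) / 20.0)


@njit(cache=True)
def beta_ha(v: float) -> float:
    return 0.6 / (1.0 + math.exp(-0.1 * (v + 90.0)))


@njit(cache=True)
def alpha_c(v: float) -> float:
    return 3.0 * exprelr(-0.1 * (v + 13.0))


@njit(cache=True)
def beta_c(v: float) -> float:
    return 10.0 * math.exp(-(v + 38.0) / 18.0)


@njit(cache=True)
def kca_saturation(ca: float) -> float:
    x = ca / 0.001
    return x / (1.0 + x)


@njit(cache=True)
def simulate_kernel(
    nsteps: int,
    dt: float,
    v: np.ndarray,          # (n,) mV, modified in place
    m: np.ndarray, h: np.ndarray, n_: np.ndarray,
    a: np.ndarray, ha: np.ndarray, c: np.ndarray,
    ca: np.ndarray,         # (n,) mM
    gna: np.ndarray, gkdr: np.ndarray, ga: np.ndarray,
    gca: np.ndarray, gkca: np.ndarray, gl: np.ndarray,  # μS per compartment
    el: np.ndarray,         # (n,) mV leak reversal
    gca_density: np.ndarray,  # mS/cm² (for the Ca influx term)
    ca_factor: np.ndarray,  # mM/ms per (μA/cm²) of inward Ca current
    ena: float, ek: float, eca: float,
    ca_rest: float, ca_tau: float,
    cap: np.ndarray,        # (n,) nF
    gax: np.ndarray,        # (n-1,) μS axial conductances
    ve: np.ndarray,         # (n,) mV extracellular potential shape
    stim_scale: np.ndarray,  # (nsteps,) multiplier of ve at each new time
    alpha_a_printed: bool,
    monitor: int,
    spike_threshold: float,
    detect_from: float,      # ms: ignore crossings before this time
    detect_until: float,     # ms: ignore crossings after this time
    record: np.ndarray,      # (nrec, n) or (0, 0); row k = state at step k*rec_stride
    rec_stride: int,
    stop_on_spike: bool,
) -> tuple[int, float, float]:
    """Backward-Euler integration of the cable equation with active membrane.

    Returns (spiked, spike_time_ms, peak_monitor_mv).
    """
    n = v.shape[0]
    lower = np.empty(n)
    diag = np.empty(n)
    upper = np.empty(n)
    rhs = np.empty(n)
    cprime = np.empty(n)
    dprime = np.empty(n)

    spiked = 0
    spike_time = -1.0
    peak = v[monitor]
    prev_mon = v[monitor]
    nrec = record.shape[0]
    if nrec > 0:
        for i in range(n):
            record[0, i] = v[i]

    for step in range(nsteps):
        t_new = (step + 1) * dt
        s = stim_scale[step]

        # implicit (unconditionally stable, [0,1]-preserving) gate update
        for i in range(n):
            vi = v[i]
            am = alpha_m(vi); bm = beta_m(vi)
            ah = alpha_h(vi); bh = beta_h(vi)
            an = alpha_n(vi); bn = beta_n(vi)
            aa = alpha_a(vi, alpha_a_printed); ba = beta_a(vi)
            aha = alpha_ha(vi); bha = beta_ha(vi)
            ac = alpha_c(vi); bc = beta_c(vi)
            m[i] = (m[i] + dt * am) / (1.0 + dt * (am + bm))
            h[i] = (h[i] + dt * ah) / (1.0 + dt * (ah + bh))
            n_[i] = (n_[i] + dt * an) / (1.0 + dt * (an + bn))
            a[i] = (a[i] + dt * aa) / (1.0 + dt * (aa + ba))
            ha[i] = (ha[i] + dt * aha) / (1.0 + dt * (aha + bha))
            c[i] = (c[i] + dt * ac) / (1.0 + dt * (ac + bc))

            # calcium pool: influx from I_Ca, first-order return to rest
            ica = gca_density[i] * c[i] ** 3 * (vi - eca)  # μA/cm²
            ca_new = (ca[i] + dt * (-ca_factor[i] * ica + ca_rest / ca_tau)) / (1.0 + dt / ca_tau)
            ca[i] = ca_new if ca_new > ca_rest else ca_rest

            g_na = gna[i] * m[i] ** 3 * h[i]
            g_k = gkdr[i] * n_[i] ** 4
            g_a = ga[i] * a[i] ** 3 * ha[i]
            g_ca = gca[i] * c[i] ** 3
            g_kca = gkca[i] * kca_saturation(ca[i])
            g_tot = g_na + g_k + g_a + g_ca + g_kca + gl[i]
            i_eq = (g_na * ena + (g_k + g_a + g_kca) * ek + g_ca * eca + gl[i] * el[i])

            diag[i] = cap[i] / dt + g_tot
            rhs[i] = cap[i] / dt * vi + i_eq
            lower[i] = 0.0
            upper[i] = 0.0

        for i in range(n - 1):
            g = gax[i]
            diag[i] += g
            diag[i + 1] += g
            upper[i] = -g
            lower[i + 1] = -g
            dve = (ve[i + 1] - ve[i]) * s
            rhs[i] += g * dve
            rhs[i + 1] -= g * dve

        # Thomas algorithm
        cprime[0] = upper[0] / diag[0]
        dprime[0] = rhs[0] / diag[0]
        for i in range(1, n):
            denom = diag[i] - lower[i] * cprime[i - 1]
            cprime[i] = upper[i] / denom
            dprime[i] = (rhs[i] - lower[i] * dprime[i - 1]) / denom
        v[n - 1] = dprime[n - 1]
        for i in range(n - 2, -1, -1):
            v[i] = dprime[i] - cprime[i] * v[i + 1]

        for i in range(n):
            if not math.isfinite(v[i]):
                return -1, t_new, peak  # integration failure marker

        mon = v[monitor]
        if mon > peak:
            peak = mon
        if (spiked == 0 and prev_mon < spike_threshold <= mon
                and detect_from <= t_new <= detect_until):
            spiked = 1
            spike_time = t_new
            if stop_on_spike and nrec == 0:
                return spiked, spike_time, peak
        prev_mon = mon

        if nrec > 0 and (step + 1) % rec_stride == 0:
            k = (step + 1) // rec_stride
            if k < nrec:
                for i in range(n):
                    record[k, i] = v[i]

    return spiked, spike_time, peak
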