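"""Numba inner loop for the per-variant mixture update.

One call performs a full sweep over variants in the given permutation order,
sampling each variant's mixture-component indicator and effect from their
joint full conditional and updating the residual in place. All randomness is
supplied by the caller (one uniform and one standard normal per variant), so
the sweep is a pure deterministic function of its inputs.

Layout/precision choices: the design matrix is float32 in Fortran order so
each column is a contiguous stream; the score accumulations use a float32
weighted-residual vector refreshed by the caller every sweep (single-sweep
drift only), while the residual itself is carried in float64. The
per-component log-determinant and quadratic coefficients depend only on
(variant, component) within a sweep and are precomputed vectorized by the
caller.
"""

import numpy as np
from numba import njit

N_COMP = 4


@njit(cache=True, fastmath=True)
def mixture_sweep(
    Wf,          # float32[::1, :] n x m standardized design, F-order
    w,           # float64[:] reliability weights
    resid,       # float64[:] y - Xb - a - Wv, float64 (updated in place)
    wr32,        # float32[:] w * resid (refreshed by caller; updated in place)
    v,           # float64[:] variant effects (updated in place)
    z,           # int64[:] component indicators 0..3 (updated in place)
    logP,        # float64[:, :] C x 4 log mixture proportions per class
    cls,         # int64[:] per-variant class index 0..C-1
    Sw,          # float64[:] sum_j w_j W_ij^2
    halflogdet,  # float64[:, :] m x 4; 0.5*log(1 + tau2_d*Sw_i/s2e), col 0 = 0
    halfcoef,    # float64[:, :] m x 4; 0.5*tau2_d/(s2e*(tau2_d*Sw_i + s2e))
    tau2,        # float64[:] component prior variances (tau2[0] == 0)
    s2e,         # float64 residual variance
    perm,        # int64[:] visit order
    unif,        # float64[:] one uniform per visit
    gauss,       # float64[:] one standard normal per visit
):
    n, m = Wf.shape
    logL = np.empty(N_COMP)
    p = np.empty(N_COMP)
    for t in range(m):
        i = perm[t]
        c = cls[i]
        col = Wf[:, i]
        acc = np.float32(0.0)
        for j in range(n):
            acc += col[j] * wr32[j]
        # score with variant i's own contribution folded back in
        rhs = np.float64(acc) + Sw[i] * v[i]
        rhs2 = rhs * rhs

        mx = logP[c, 0]
        logL[0] = mx
        for d in range(1, N_COMP):
            logL[d] = logP[c, d] - halflogdet[i, d] + rhs2 * halfcoef[i, d]
            if logL[d] > mx:
                mx = logL[d]
        tot = 0.0
        for d in range(N_COMP):
            p[d] = np.exp(logL[d] - mx)
            tot += p[d]
        target = unif[t] * tot
        zi = N_COMP - 1
        csum = 0.0
        for d in range(N_COMP):
            csum += p[d]
            if target <= csum:
                zi = d
                break

        if zi == 0:
            v_new = 0.0
        else:
            prec = Sw[i] / s2e + 1.0 / tau2[zi]
            mean = rhs / (s2e * prec)
            v_new = mean + gauss[t] / np.sqrt(prec)

        dv = v[i] - v_new
        if dv != 0.0:
            dv32 = np.float32(dv)
            for j in range(n):
                resid[j] += col[j] * dv
                wr32[j] += np.float32(w[j]) * col[j] * dv32
        v[i] = v_new
        z[i] = zi


@njit(cache=True, fastmath=True)
def mixture_sweep_dosage(
    X8,          # int8[::1, :] n x m raw dosages {0,1,2}, F-order
    mu,          # float64[:] column means
    inv_s,       # float64[:] reciprocal column scales
    wcolsum,     # float64[:] sum_j w_j (x_ij - mu_i) * inv_s_i
    w,           # float64[:] reliability weights
    resid,       # float64[:] float64 residual (updated in place)
    wr32,        # float32[:] w * resid (refreshed by caller; updated in place)
    swr,         # float64[1] running sum_j w_j resid_j (refreshed by caller)
    v, z, logP, cls, Sw, halflogdet, halfcoef, tau2, s2e, perm, unif, gauss,
):
    """Dosage-specialized sweep: identical math to ``mixture_sweep`` with the
    standardized column (x - mu)/s reconstructed from int8 dosages, so the
    dominant memory stream is one byte per genotype."""
    n, m = X8.shape
    logL = np.empty(N_COMP)
    p = np.empty(N_COMP)
    for t in range(m):
        i = perm[t]
        c = cls[i]
        col = X8[:, i]
        acc = np.float32(0.0)
        for j in range(n):
            acc += np.float32(col[j]) * wr32[j]
        dot = (np.float64(acc) - mu[i] * swr[0]) * inv_s[i]
        rhs = dot + Sw[i] * v[i]
        rhs2 = rhs * rhs

        mx = logP[c, 0]
        logL[0] = mx
        for d in range(1, N_COMP):
            logL[d] = logP[c, d] - halflogdet[i, d] + rhs2 * halfcoef[i, d]
            if logL[d] > mx:
                mx = logL[d]
        tot = 0.0
        for d in range(N_COMP):
            p[d] = np.exp(logL[d] - mx)
            tot += p[d]
        target = unif[t] * tot
        zi = N_COMP - 1
        csum = 0.0
        for d in range(N_COMP):
            csum += p[d]
            if target <= csum:
                zi = d
                break

        if zi == 0:
            v_new = 0.0
        else:
            prec = Sw[i] / s2e + 1.0 / tau2[zi]
            mean = rhs / (s2e * prec)
            v_new = mean + gauss[t] / np.sqrt(prec)

        dv = v[i] - v_new
        if dv != 0.0:
            mi = mu[i]
            si = inv_s[i]
            for j in range(n):
                wij = (np.float64(col[j]) - mi) * si * dv
                resid[j] += wij
                wr32[j] += np.float32(w[j] * wij)
            swr[0] += wcolsum[i] * dv
        v[i] = v_new
        z[i] = zi


def sweep_tables(Sw: np.ndarray, tau2: np.ndarray, s2e: float):
    """(halflogdet, halfcoef) m x 4 tables for one sweep at fixed s2e."""
    t = np.asarray(tau2)[None, :]
    den = t * Sw[:, None] + s2e
    halflogdet = 0.5 * np.log(den / s2e)
    halfcoef = 0.5 * t / (s2e * den)
    return halflogdet, halfcoef
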