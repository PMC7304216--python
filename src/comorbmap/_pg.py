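"""Polya-Gamma PG(1, z) sampling (Devroye alternating-series method).

Latent PG variables turn the binary-logit full conditionals of the
baseline-category model into Gaussians, which is what makes a pure Gibbs
sweep possible. The sampler follows the standard exact scheme: a mixture
proposal (truncated inverse-Gaussian on (0, t], truncated exponential on
(t, inf), t = 0.64) for the Jacobi J*(1, z/2) variable, accepted or rejected
via the alternating partial sums of the series density; PG(1, z) = J*/4.

Identity used in tests: E[PG(1, z)] = tanh(z/2) / (2 z).

Compiled with numba; the single sequential loop over a numpy Generator keeps
draws bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_TRUNC = 0.64
_SQRT2 = math.sqrt(2.0)


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * math.erfc(-x / _SQRT2)


@njit(cache=True)
def _mass_texpon(z):
    """P(proposal falls in the exponential right tail), computed in logs."""
    t = _TRUNC
    fz = 0.125 * math.pi * math.pi + 0.5 * z * z
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    phi_b = _norm_cdf(b)
    phi_a = _norm_cdf(a)
    xb = x0 - z + math.log(phi_b) if phi_b > 0.0 else -1.0e308
    xa = x0 + z + math.log(phi_a) if phi_a > 0.0 else -1.0e308
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _rtigauss(z, gen):
    """Inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, t]."""
    t = _TRUNC
    z = abs(z)
    x = t + 1.0
    if z < 1.0 / t:  # mu > t: scale-free rejection from the 1/chi^2 tail
        alpha = 0.0
        while gen.random() > alpha:
            e1 = gen.standard_exponential()
            e2 = gen.standard_exponential()
            while e1 * e1 > 2.0 * e2 / t:
                e1 = gen.standard_exponential()
                e2 = gen.standard_exponential()
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            alpha = math.exp(-0.5 * z * z * x)
    else:
        mu = 1.0 / z
        while x > t:
            y = gen.standard_normal()
            y = y * y
            muy = mu * y
            x = mu + 0.5 * mu * muy - 0.5 * mu * math.sqrt(muy * (4.0 + muy))
            if gen.random() > mu / (mu + x):
                x = mu * mu / x
    return x


@njit(cache=True)
def _a_coef(n, x):
    """n-th alternating-series coefficient of the J*(1) density at x."""
    t = _TRUNC
    np5 = n + 0.5
    if x > t:
        return math.pi * np5 * math.exp(-np5 * np5 * math.pi * math.pi * x / 2.0)
    return (math.pi * np5 * math.pow(2.0 / (math.pi * x), 1.5)
            * math.exp(-2.0 * np5 * np5 / x))


@njit(cache=True)
def pg_draw(psi, gen):
    """One draw from PG(1, psi)."""
    z = abs(psi) * 0.5
    fz = 0.125 * math.pi * math.pi + 0.5 * z * z
    ratio = _mass_texpon(z)
    while True:
        if gen.random() < ratio:
            x = _TRUNC + gen.standard_exponential() / fz
        else:
            x = _rtigauss(z, gen)
        s = _a_coef(0, x)
        y = gen.random() * s
        n = 0
        accepted = False
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    accepted = True
                    break
            else:
                s += _a_coef(n, x)
                if y > s:
                    break
            if n > 300:  # series converges in a handful of terms; safety net
                accepted = True
                break
        if accepted:
            return x * 0.25


@njit(cache=True)
def pg_array(psi, gen):
    """Independent PG(1, psi_i) draws for a vector of tilts."""
    out = np.empty(psi.shape[0])
    for i in range(psi.shape[0]):
        out[i] = pg_draw(psi[i], gen)
    return out


def polya_gamma(psi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """PG(1, psi) draws, elementwise over ``psi``, using ``rng``'s stream."""
    psi = np.ascontiguousarray(psi, dtype=np.float64)
    return pg_array(psi, rng)


def pg_mean(psi: np.ndarray) -> np.ndarray:
    """Closed-form E[PG(1, psi)] = tanh(psi/2)/(2 psi), = 1/4 at psi = 0."""
    psi = np.asarray(psi, dtype=float)
    out = np.full(psi.shape, 0.25)
    nz = psi != 0
    out = np.where(nz, np.tanh(psi / 2.0) / np.where(nz, 2.0 * psi, 1.0), out)
    return out
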