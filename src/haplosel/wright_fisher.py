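"""Discrete Wright-Fisher machinery for expected folded site frequency spectra.

The expected SFS under mutation, drift, selection and a single size change is
computed on a discrete Wright-Fisher grid: a population of N diploids (2N
chromosomes), deterministic allele-frequency change by additive selection
(genotype fitnesses 1, 1+s/2, 1+s), binomial resampling, and a constant
influx of new mutations at count 1. The ancestral size is rescaled to a
small reference value (N1 = 100 diploids) so the matrices stay tractable;
scaled parameters (Nes, t2/N) are preserved.

Because the discrete-grid spectrum differs from the diffusion limit by
O(1/N), every expectation is computed at two grid sizes (N1 and 2*N1, with
s halved and t2 doubled in the finer system) and Richardson-extrapolated.
At N1 = 100 this leaves a relative error of ~1e-4 on the neutral folded
shape at n = 16, versus ~2% for the raw 2N = 200 grid.

Conventions:

- selection coefficient s <= 0 for deleterious mutations; s is clamped at
  -1 (lethal), below which a mutation cannot segregate;
- ``t2`` is measured in generations of the reference-size system; the
  post-change size is ``N2 = n2_ratio * N1``;
- returned spectra are expected *counts* per unit mutation influx (one new
  mutation per generation across the whole class); bin 0 carries only the
  mass of population-segregating sites that appear invariant in the
  sample. The truly invariant remainder of a finite class of L sites is L
  minus the influx-scaled sum of all returned bins.

Numerical notes: second-epoch transition matrices are sparsified (binomial
rows are narrow bands) and all expectations are memoized, so optimizer
sweeps and replicate fits that revisit the same (s, N2, t2) triples are
nearly free. Demography parameters are meant to be snapped to a coarse
lattice by callers (see dfe.FitOptions) to make those revisits frequent.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import scipy.sparse as sp
from scipy.special import gammaln

from .config import N_REF

_BASE_TWO_N = 2 * N_REF
_SPARSE_EPS = 1e-13


class SFSComputationError(RuntimeError):
    """Raised when an expected spectrum is non-finite or ill-posed."""


def _binom_pmf_matrix(n_trials: int, probs: np.ndarray) -> np.ndarray:
    """Column j holds Binomial(n_trials, probs[j]) over outcomes 0..n_trials.

    Built from 1-D log-binomial coefficients plus two outer products, so the
    2-D work is a single exp().
    """
    k = np.arange(n_trials + 1, dtype=float)
    p = np.asarray(probs, dtype=float)
    coef = gammaln(n_trials + 1.0) - gammaln(k + 1.0) - gammaln(n_trials - k + 1.0)
    safe = np.clip(p, 1e-300, 1.0 - 1e-16)
    logpmf = coef[:, None] + np.outer(k, np.log(safe)) + np.outer(n_trials - k, np.log1p(-safe))
    out = np.exp(logpmf)
    edge0 = p == 0.0
    edge1 = p == 1.0
    out[:, edge0] = 0.0
    out[0, edge0] = 1.0
    out[:, edge1] = 0.0
    out[-1, edge1] = 1.0
    return out


def selection_shift(x: np.ndarray, s: float) -> np.ndarray:
    """One generation of deterministic additive selection on frequency x."""
    s = max(float(s), -1.0)
    x = np.asarray(x, dtype=float)
    num = x * (1.0 + s / 2.0 + s * x / 2.0)
    den = 1.0 + s * x
    with np.errstate(divide="ignore", invalid="ignore"):
        xp = np.where(den > 0.0, num / den, 0.0)
    return np.clip(xp, 0.0, 1.0)


@lru_cache(maxsize=64)
def _segregating_transition_sparse(two_n: int, s: float):
    """CSR transition matrix restricted to segregating states 1..2N-1."""
    x = np.arange(1, two_n) / two_n
    M = _binom_pmf_matrix(two_n, selection_shift(x, s))[1:two_n, :]
    M[M < _SPARSE_EPS] = 0.0
    return sp.csr_matrix(M)


@lru_cache(maxsize=512)
def _equilibrium_segregating(two_n: int, s: float) -> np.ndarray:
    """Expected standing counts over derived-allele counts 1..2N-1.

    Solves v = A v + e1 where A is the transition matrix restricted to
    segregating states and e1 injects one new mutation per generation.
    """
    A = _segregating_transition_sparse(two_n, s).toarray()
    e1 = np.zeros(two_n - 1)
    e1[0] = 1.0
    return np.linalg.solve(np.eye(two_n - 1) - A, e1)


def _two_epoch_segregating(two_n1: int, two_n2: int, t2: int, s: float) -> tuple[np.ndarray, int]:
    """Standing counts after t2 generations at size 2N2, starting from the
    2N1 equilibrium; influx continues during the second epoch.

    The influx is 2N*mu new copies per generation at fixed per-copy mutation
    rate, i.e. proportional to the current size: one per generation in the
    ancestral epoch, 2N2/2N1 per generation after the size change. This
    size-scaled influx is what makes an expansion inflate the rare classes.
    """
    v = _equilibrium_segregating(two_n1, s)
    if t2 <= 0:
        return v, two_n1
    if two_n2 != two_n1:
        probs = np.arange(1, two_n1) / two_n1
        B = _binom_pmf_matrix(two_n2, probs)
        v = (B @ v)[1:two_n2]
    A = _segregating_transition_sparse(two_n2, s)
    e1 = np.zeros(two_n2 - 1)
    e1[0] = two_n2 / two_n1
    for _ in range(int(t2)):
        v = A @ v + e1
    return v, two_n2


def _fold(xi: np.ndarray, n: int) -> np.ndarray:
    half = n // 2
    out = np.zeros(half + 1)
    out[0] = xi[0] + xi[n]
    for i in range(1, half + 1):
        out[i] = xi[i] if i == n - i else xi[i] + xi[n - i]
    return out


def _sample_folded(base_two_n: int, n2_ratio: float, t2: float, s: float, n: int) -> np.ndarray:
    two_n2 = max(int(round(n2_ratio * base_two_n)), n + 2, 4)
    v, two_n = _two_epoch_segregating(base_two_n, two_n2, int(round(t2)), round(float(s), 12))
    probs = np.arange(1, two_n) / two_n
    B = _binom_pmf_matrix(n, probs)
    return _fold(B @ v, n)


@lru_cache(maxsize=65536)
def _expected_folded_cached(
    n: int, s: float, n2_ratio: float, t2: float, base_two_n: int, extrapolate: bool
) -> tuple:
    f1 = _sample_folded(base_two_n, n2_ratio, t2, s, n)
    if extrapolate:
        f2 = _sample_folded(2 * base_two_n, n2_ratio, 2.0 * t2, s / 2.0, n)
        f1 = 2.0 * f2 - f1
    return tuple(np.maximum(f1, 0.0))


def expected_folded_sfs(
    n: int,
    s: float = 0.0,
    n2_ratio: float = 1.0,
    t2: float = 0.0,
    mutation_scale: float = 1.0,
    base_two_n: int = _BASE_TWO_N,
    extrapolate: bool = True,
) -> np.ndarray:
    """Expected folded sample SFS (bins 0..n//2) under the two-epoch model.

    Parameters
    ----------
    n : sample size in alleles (>= 2).
    s : per-copy selection coefficient (<= 0 for deleterious; additive).
    n2_ratio : post-change size relative to the ancestral reference size.
    t2 : duration of the second epoch, in reference-size generations.
    mutation_scale : influx of new mutations per generation for the class.

    With ``t2 = 0`` the result is the ancestral equilibrium regardless of
    ``n2_ratio``. Bin 0 counts population-segregating sites that are
    monomorphic within the sample (both absent and fixed-in-sample, the
    latter folded down by the AN=AC -> invariant convention).
    """
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    if n2_ratio <= 0:
        raise ValueError("n2_ratio must be > 0")
    if t2 < 0:
        raise ValueError("t2 must be >= 0")
    e = np.array(
        _expected_folded_cached(
            int(n), round(float(s), 12), round(float(n2_ratio), 6),
            round(float(t2), 3), int(base_two_n), bool(extrapolate),
        )
    )
    if not np.all(np.isfinite(e)):
        raise SFSComputationError(
            f"non-finite expected SFS at s={s}, n2_ratio={n2_ratio}, t2={t2}"
        )
    return mutation_scale * e


def neutral_folded_shape(n: int) -> np.ndarray:
    """Closed-form neutral equilibrium folded shape over bins 1..n//2.

    E[eta_i] proportional to 1/i + 1/(n-i), halved on the middle bin for
    even n; normalized to sum to one. Used as an independent oracle.
    """
    i = np.arange(1, n // 2 + 1)
    w = 1.0 / i + 1.0 / (n - i)
    w[i == n - i] /= 2.0
    return w / w.sum()


def clear_caches() -> None:
    _segregating_transition_sparse.cache_clear()
    _equilibrium_segregating.cache_clear()
    _expected_folded_cached.cache_clear()
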