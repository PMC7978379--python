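"""Steady-state distribution of the two-state (telegraph) model of transcription.

The two-state model describes a promoter that switches stochastically between
an inactive and an active state. Activation occurs at rate ``k_on``,
inactivation at rate ``k_off``, and while active the gene produces transcripts
at rate ``k_syn``. Each transcript degrades independently at rate λ, which is
fixed to 1 here so that all rates are expressed per mean mRNA lifetime. In the
bursty regime (``k_off`` ≫ ``k_on``) the process produces bursts of
transcription at frequency ``k_on`` (the burst frequency), each contributing on
average ``k_syn / k_off`` transcripts (the burst size).

At steady state the transcript count follows the Poisson-beta distribution: a
Poisson whose rate is ``k_syn`` scaled by a Beta(``k_on``, ``k_off``) variate,

    p ~ Beta(k_on, k_off),   n | p ~ Poisson(p * k_syn).

The marginal pmf is evaluated by Gauss-Jacobi quadrature against the Beta
weight, with an exact confluent-hypergeometric expression

    P(n) = k_syn^n / n! * B(k_on + n, k_off) / B(k_on, k_off)
           * 1F1(k_on + n; k_on + k_off + n; -k_syn)

as the cross-check and fallback in parameter regimes where high-order Jacobi
nodes become numerically unstable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from .errors import InvalidParameterError

__all__ = [
    "TwoStateKinetics",
    "CountDistribution",
    "pmf",
    "prob_zero",
    "sample",
    "poisson_baseline",
    "monoallelic_surfaces",
]

#: Probability mass left beyond the automatic truncation bound.
DEFAULT_TAIL_TOL = 1e-9


@dataclass(frozen=True)
class TwoStateKinetics:
    """Kinetic parameters of the two-state model, per mean mRNA lifetime.

    Parameters
    ----------
    k_on
        Promoter activation rate; equals the burst frequency. Must be > 0.
    k_off
        Promoter inactivation rate. Must be > 0.
    k_syn
        Transcription rate while the promoter is active. Must be >= 0;
        ``k_syn == 0`` is the degenerate, permanently silent allele.
    """

    k_on: float
    k_off: float
    k_syn: float

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_syn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float, np.integer, np.floating)) and math.isfinite(v)):
                raise InvalidParameterError(f"{name} must be a finite number, got {v!r}")
        if self.k_on <= 0 or self.k_off <= 0:
            raise InvalidParameterError(
                f"k_on and k_off must be strictly positive, got ({self.k_on}, {self.k_off})"
            )
        if self.k_syn < 0:
            raise InvalidParameterError(f"k_syn must be non-negative, got {self.k_syn}")

    @property
    def burst_frequency(self) -> float:
        """Bursts per mean mRNA lifetime (= ``k_on``)."""
        return float(self.k_on)

    @property
    def burst_size(self) -> float:
        """Mean transcripts produced per burst (= ``k_syn / k_off``)."""
        return float(self.k_syn) / float(self.k_off)

    @property
    def mean(self) -> float:
        """Steady-state mean transcript count, ``k_syn * k_on / (k_on + k_off)``."""
        return float(self.k_syn) * float(self.k_on) / (float(self.k_on) + float(self.k_off))


@dataclass(frozen=True)
class CountDistribution:
    """A truncated distribution over transcript counts 0..n_max.

    ``probabilities[n]`` is P(N = n); ``tail_mass`` is the residual probability
    beyond ``n_max``. The stored mass plus the tail always sums to one.
    """

    probabilities: np.ndarray
    tail_mass: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "probabilities", np.asarray(self.probabilities, dtype=float))

    @property
    def n_max(self) -> int:
        return int(self.probabilities.size - 1)

    def cdf(self) -> np.ndarray:
        """Cumulative distribution over the stored support."""
        return np.cumsum(self.probabilities)

    def __getitem__(self, n) -> float:
        return self.probabilities[n]


def _pmf_hyp(a: float, b: float, s: float, ns: np.ndarray) -> np.ndarray:
    """Exact Poisson-beta pmf at counts ``ns`` via the 1F1 closed form."""
    ns = np.asarray(ns, dtype=float)
    logc = ns * np.log(s) - special.gammaln(ns + 1.0) + special.betaln(a + ns, b) - special.betaln(a, b)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        h = special.hyp1f1(a + ns, a + b + ns, -s)
        out = np.where(h > 0.0, np.exp(logc + np.log(np.where(h > 0.0, h, 1.0))), 0.0)
    bad = ~np.isfinite(h) | ((h <= 0.0) & (logc > 0.0))
    if np.any(bad):
        import mpmath as mp

        for i in np.nonzero(bad)[0]:
            n = ns[i]
            val = mp.e ** (
                n * mp.log(s)
                - mp.loggamma(n + 1)
                + mp.log(mp.beta(a + n, b))
                - mp.log(mp.beta(a, b))
            ) * mp.hyp1f1(a + n, a + b + n, -s)
            out[i] = float(val)
    return out


def _pmf_jacobi(a: float, b: float, s: float, ns: np.ndarray, m: int) -> np.ndarray:
    """Gauss-Jacobi quadrature of Poisson(n; p*s) against the Beta(a, b) weight."""
    with np.errstate(all="ignore"):
        x, w = special.roots_jacobi(m, b - 1.0, a - 1.0)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(w))):
        raise FloatingPointError("unstable Jacobi nodes")
    p = (x + 1.0) / 2.0
    ns = np.asarray(ns, dtype=float)
    mu = p * s
    with np.errstate(divide="ignore", invalid="ignore"):
        logpois = ns[:, None] * np.log(mu)[None, :] - mu[None, :] - special.gammaln(ns + 1.0)[:, None]
    logpois = np.where((mu[None, :] == 0.0) & (ns[:, None] > 0), -np.inf, logpois)
    lognorm = -(a + b - 1.0) * math.log(2.0) - special.betaln(a, b)
    return math.exp(lognorm) * (np.exp(logpois) @ w)


def _p0_exact(a: float, b: float, s: float) -> float:
    """P(0) = 1F1(k_on; k_on + k_off; -k_syn), exact."""
    with np.errstate(over="ignore", invalid="ignore"):
        v = float(special.hyp1f1(a, a + b, -s))
    if not math.isfinite(v) or v < 0.0 or v > 1.0:
        import mpmath as mp

        v = float(mp.hyp1f1(a, a + b, -s))
    return min(1.0, max(0.0, v))


def pmf_at(kin: TwoStateKinetics, ns: np.ndarray, *, rtol: float = 1e-10) -> np.ndarray:
    """Poisson-beta probabilities at an arbitrary vector of counts.

    Adaptive Gauss-Jacobi quadrature (50 nodes, doubled until successive
    estimates agree within ``rtol`` absolutely) with the hypergeometric closed
    form as fallback when the Jacobi recurrence loses stability (very large
    shape parameters) or fails to converge. P(0) is always anchored to its
    exact hypergeometric value.
    """
    _validate(kin)
    ns = np.atleast_1d(np.asarray(ns))
    if kin.k_syn == 0:
        return np.where(ns == 0, 1.0, 0.0).astype(float)
    a, b, s = float(kin.k_on), float(kin.k_off), float(kin.k_syn)
    out = None
    try:
        prev = _pmf_jacobi(a, b, s, ns, 50)
        for m in (100, 200):
            cur = _pmf_jacobi(a, b, s, ns, m)
            if np.max(np.abs(cur - prev)) < rtol:
                out = cur
                break
            prev = cur
    except FloatingPointError:
        pass
    if out is None:
        out = _pmf_hyp(a, b, s, ns)
    # anchor P(0) to the exact confluent-hypergeometric value
    zero = ns == 0
    if np.any(zero):
        out = np.where(zero, _p0_exact(a, b, s), out)
    return np.clip(out, 0.0, 1.0)


def _auto_n_max(kin: TwoStateKinetics, tail_tol: float) -> tuple[np.ndarray, int]:
    """Smallest truncation with cumulative mass >= 1 - tail_tol.

    The initial search bound is ``ceil(10 * mean + 50)``; it is extended
    (doubled) in the rare heavy-tailed cases where that cap still leaves more
    than the requested tail, so the returned distribution always satisfies the
    tail bound.
    """
    cap = int(math.ceil(10.0 * kin.mean + 50.0))
    hi = cap
    for _ in range(12):
        probs = pmf_at(kin, np.arange(hi + 1))
        cum = np.cumsum(probs)
        if cum[-1] >= 1.0 - tail_tol:
            n_max = int(np.searchsorted(cum, 1.0 - tail_tol))
            return probs[: n_max + 1], n_max
        hi = 2 * hi + 50
    return probs, hi  # pragma: no cover - unreachable within the parameter box


def pmf(
    kin: TwoStateKinetics,
    n_max: int | None = None,
    *,
    tail_tol: float = DEFAULT_TAIL_TOL,
) -> CountDistribution:
    """Steady-state transcript-count distribution of the two-state model.

    Parameters
    ----------
    kin
        Kinetic parameters.
    n_max
        Truncation bound. ``None`` selects the smallest bound whose cumulative
        mass reaches ``1 - tail_tol``.
    tail_tol
        Target residual mass beyond the automatic truncation.

    Returns
    -------
    CountDistribution
        Probabilities for counts ``0..n_max`` plus the residual tail mass.
    """
    _validate(kin)
    if n_max is not None:
        if n_max < 0:
            raise InvalidParameterError(f"n_max must be >= 0, got {n_max}")
        probs = pmf_at(kin, np.arange(int(n_max) + 1))
    else:
        probs, _ = _auto_n_max(kin, tail_tol)
    tail = max(0.0, 1.0 - float(np.sum(probs)))
    return CountDistribution(probabilities=probs, tail_mass=tail)


def prob_zero(kin: TwoStateKinetics) -> float:
    """Probability that an allele shows zero transcripts at sampling time.

    Evaluated through the exact confluent-hypergeometric form
    ``P(0) = 1F1(k_on; k_on + k_off; -k_syn)``, which stays accurate at large
    ``k_syn`` where naive quadrature underflows.
    """
    _validate(kin)
    if kin.k_syn == 0:
        return 1.0
    return _p0_exact(float(kin.k_on), float(kin.k_off), float(kin.k_syn))


def sample(
    kin: TwoStateKinetics,
    n_cells: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw i.i.d. steady-state transcript counts for ``n_cells`` cells.

    Each draw takes ``p ~ Beta(k_on, k_off)`` followed by
    ``count ~ Poisson(p * k_syn)``, i.e. one cross-sectional snapshot per cell
    under the ergodicity assumption.
    """
    _validate(kin)
    if n_cells < 1:
        raise InvalidParameterError(f"n_cells must be >= 1, got {n_cells}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if kin.k_syn == 0:
        return np.zeros(int(n_cells), dtype=np.int64)
    p = rng.beta(kin.k_on, kin.k_off, size=int(n_cells))
    return rng.poisson(p * kin.k_syn).astype(np.int64)


def poisson_baseline(counts: np.ndarray, *, tail_tol: float = DEFAULT_TAIL_TOL) -> CountDistribution:
    """Poisson null model with the sample mean as rate estimator.

    The single-parameter alternative to the two-state model: ignores bursting
    entirely and predicts counts as ``Poisson(mean(counts))``.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise InvalidParameterError("counts must be non-empty")
    if np.any(counts < 0):
        raise InvalidParameterError("counts must be non-negative")
    rate = float(np.mean(counts))
    if rate == 0.0:
        return CountDistribution(probabilities=np.array([1.0]), tail_mass=0.0)
    from scipy.stats import poisson as poisson_dist

    hi = int(math.ceil(10.0 * rate + 50.0))
    n_max = int(poisson_dist.ppf(1.0 - tail_tol, rate))
    n_max = min(max(n_max, 0), hi)
    probs = poisson_dist.pmf(np.arange(n_max + 1), rate)
    return CountDistribution(probabilities=probs, tail_mass=max(0.0, 1.0 - float(probs.sum())))


def monoallelic_surfaces(
    bf_grid: np.ndarray,
    bs_grid: np.ndarray,
    k_syn_fixed: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Monoallelic-expression probabilities over a burst-frequency/size grid.

    For two alleles with identical kinetics, a cell is monoallelic when
    exactly one allele shows zero transcripts. With ``P0`` the per-allele
    silence probability at a grid point,

        P(mono)             = 2 * P0 * (1 - P0)
        P(mono | expressed) = 2 * P0 / (1 + P0)

    Each grid point sets ``k_on = bf`` and ``k_off = k_syn_fixed / bs`` so that
    burst size varies through ``k_off`` at fixed synthesis rate.

    Returns
    -------
    (cond, marg)
        Two ``len(bf_grid) x len(bs_grid)`` matrices: the conditional
        probability of monoallelic expression given any expression, and the
        unconditional probability.
    """
    bf_grid = np.asarray(bf_grid, dtype=float)
    bs_grid = np.asarray(bs_grid, dtype=float)
    if np.any(bf_grid <= 0) or np.any(bs_grid <= 0):
        raise InvalidParameterError("grid values must be strictly positive")
    cond = np.empty((bf_grid.size, bs_grid.size))
    marg = np.empty_like(cond)
    for i, bf in enumerate(bf_grid):
        for j, bs in enumerate(bs_grid):
            p0 = prob_zero(TwoStateKinetics(k_on=bf, k_off=k_syn_fixed / bs, k_syn=k_syn_fixed))
            marg[i, j] = 2.0 * p0 * (1.0 - p0)
            cond[i, j] = 2.0 * p0 / (1.0 + p0)
    return cond, marg


def _validate(kin: TwoStateKinetics) -> None:
    if not isinstance(kin, TwoStateKinetics):
        raise InvalidParameterError(f"expected TwoStateKinetics, got {type(kin).__name__}")
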