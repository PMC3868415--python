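"""Variant-discovery design under a folded site-frequency spectrum.

A biallelic locus with minor allele frequency p is "detected" in a sample
of n diploid people (m = 2n chromosomes) when both alleles are seen; a
stricter catalog rule requires each allele at least k times.  Averaging the
detection probability over the population's folded site-frequency spectrum
(SFS) gives the two design metrics for a catalog of common variants:

* sensitivity — P(each allele seen ≥ k times | MAF ≥ c),
* PPV        — P(MAF ≥ c | each allele seen ≥ k times).

Under the standard neutral infinitely-many-sites model with constant
population size, the folded SFS density is proportional to 1/[p(1−p)] on
(0, 1/2] (the unfolded 1/p spectrum plus its mirror 1/(1−p)).  The density
is improperly integrable at p → 0, where the PPV denominator picks up the
mass of rare variants that sneak past the k-threshold; the integrand
P_k(p)/[p(1−p)] behaves like C(2n,k) p^{k−1} there and is handled
analytically at the endpoint rather than fed raw to the integrator.

Binomial tail probabilities are evaluated through the regularized
incomplete beta function (scipy's binomial CDF), never by naive summation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Literal, Sequence

import numpy as np
from scipy import integrate, special

from .errors import DomainError, NumericalError, ValidationError

_QUAD_EPSABS = 1e-12
_QUAD_EPSREL = 1e-8
_QUAD_LIMIT = 200


# ---------------------------------------------------------------------------
# sample design and folded SFS models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleDesign:
    """A discovery design: n diploid people, threshold of k copies of each
    allele, and target minor-allele-frequency cutoff c."""

    n_people: int
    k: int = 1
    c: float = 0.05

    def __post_init__(self) -> None:
        if self.n_people < 1:
            raise ValidationError(f"n_people must be >= 1, got {self.n_people}")
        if not 1 <= self.k <= self.n_people:
            raise ValidationError(
                f"k must satisfy 1 <= k <= n_people={self.n_people}, got {self.k}"
            )
        if not 0.0 < self.c <= 0.5:
            raise ValidationError(f"MAF cutoff c must lie in (0, 0.5], got {self.c}")

    @property
    def m_chromosomes(self) -> int:
        return 2 * self.n_people


class FoldedSFS:
    """Folded minor-allele-frequency spectrum on (0, 1/2].

    Three flavours:

    * :meth:`neutral` — continuous density ∝ 1/[p(1−p)] (constant-size
      neutral infinitely-many-sites model);
    * :meth:`finite` — discrete grid p = i/(2N), i = 1..N, with the same
      weights, for a finite population of N diploids;
    * :meth:`custom` — arbitrary tabulated (p, weight) pairs, e.g. a
      growth-skewed spectrum.

    Weights are unnormalized: every downstream use is a ratio.
    """

    def __init__(
        self,
        kind: Literal["neutral_constant", "finite_2N", "custom"],
        support: np.ndarray | None = None,
        weights: np.ndarray | None = None,
    ) -> None:
        self.kind = kind
        if kind == "neutral_constant":
            self.support = None
            self.weights = None
            return
        assert support is not None and weights is not None
        support = np.asarray(support, dtype=float)
        weights = np.asarray(weights, dtype=float)
        if support.size < 2:
            raise ValidationError("a discrete SFS needs at least 2 support points")
        if np.any(weights < 0):
            raise ValidationError("SFS weights must be non-negative")
        if np.any((support <= 0) | (support > 0.5)):
            raise ValidationError("SFS support must lie in (0, 0.5]")
        order = np.argsort(support)
        self.support = support[order]
        self.weights = weights[order]

    # -- constructors ------------------------------------------------------

    @classmethod
    def neutral(cls) -> "FoldedSFS":
        return cls("neutral_constant")

    @classmethod
    def finite(cls, N: int) -> "FoldedSFS":
        if N < 2:
            raise ValidationError(f"finite population size N must be >= 2, got {N}")
        p = np.arange(1, N + 1) / (2.0 * N)
        return cls("finite_2N", p, 1.0 / (p * (1.0 - p)))

    @classmethod
    def custom(cls, support: Sequence[float], weights: Sequence[float]) -> "FoldedSFS":
        return cls("custom", np.asarray(support), np.asarray(weights))

    # -- evaluation --------------------------------------------------------

    @property
    def is_discrete(self) -> bool:
        return self.kind != "neutral_constant"

    def density(self, p: np.ndarray | float) -> np.ndarray | float:
        """Unnormalized density 1/[p(1−p)] (continuous neutral case only)."""
        if self.is_discrete:
            raise DomainError("density() is defined only for the continuous neutral SFS")
        return 1.0 / (np.asarray(p) * (1.0 - np.asarray(p)))


# ---------------------------------------------------------------------------
# detection probabilities
# ---------------------------------------------------------------------------

def detect_prob(p: float, n_people: int) -> float:
    """Probability both alleles appear at least once in n people:
    1 − (1−p)^{2n} − p^{2n}, evaluated in log-space."""
    if not 0.0 < p <= 0.5:
        raise DomainError(f"minor allele frequency must lie in (0, 0.5], got {p}")
    if n_people < 1:
        raise DomainError(f"n_people must be >= 1, got {n_people}")
    m = 2 * n_people
    return -math.expm1(m * math.log1p(-p)) - math.exp(m * math.log(p))


def detect_prob_k(p: float, n_people: int, k: int) -> float:
    """Probability each allele appears at least k times in n people:
    P(k ≤ X ≤ 2n−k) for X ~ Binomial(2n, p)."""
    if not 0.0 < p <= 0.5:
        raise DomainError(f"minor allele frequency must lie in (0, 0.5], got {p}")
    if not 1 <= k <= n_people:
        raise DomainError(f"k must satisfy 1 <= k <= n_people={n_people}, got {k}")
    return float(_detect_prob_k_vec(np.float64(p), 2 * n_people, k))


def _detect_prob_k_vec(p: np.ndarray, m: int, k: int) -> np.ndarray:
    # P(k <= X <= m-k) for X ~ Bin(m, p), via the regularized incomplete
    # beta representation of the binomial survival function:
    # P(X >= j) = I_p(j, m-j+1) = betainc(j, m-j+1, p)
    out = special.betainc(k, m - k + 1, p) - special.betainc(m - k + 1, k, p)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# sensitivity and PPV
# ---------------------------------------------------------------------------

def _quad(func, a: float, b: float, **kw) -> float:
    val, err = integrate.quad(
        func, a, b, epsabs=_QUAD_EPSABS, epsrel=_QUAD_EPSREL, limit=_QUAD_LIMIT, **kw
    )
    if not math.isfinite(val):
        raise NumericalError(f"quadrature on [{a}, {b}] returned {val}")
    if err > max(_QUAD_EPSABS, abs(val) * 1e-6):
        raise NumericalError(
            f"quadrature on [{a}, {b}] achieved tolerance {err:.3e} only"
        )
    return val


def _weighted_mean_continuous(d: SampleDesign, a: float, b: float) -> float:
    """∫_a^b P_k(p)/[p(1−p)] dp for the neutral density."""
    m, k = d.m_chromosomes, d.k

    def integrand(p: float) -> float:
        if p <= 0.0:
            # limit of P_k(p)/[p(1-p)] as p -> 0: 2n for k=1, else 0
            return float(m) if k == 1 else 0.0
        return detect_prob_k(p, d.n_people, k) / (p * (1.0 - p))

    return _quad(integrand, a, b)


def sensitivity(d: SampleDesign, sfs: FoldedSFS) -> float:
    """Expected fraction of loci with MAF ≥ c that pass the k-threshold.

    Continuous SFS: ∫_c^{1/2} P_k f dp / ∫_c^{1/2} f dp; discrete SFS uses
    the analogous sums over the support points with p ≥ c.
    """
    if d.c >= 0.5:
        raise DomainError("MAF cutoff c = 0.5 leaves a degenerate support [c, 0.5]")
    if sfs.is_discrete:
        mask = sfs.support >= d.c
        if not np.any(mask):
            raise DomainError(f"no SFS support points at or above c={d.c}")
        w = sfs.weights[mask]
        pk = _detect_prob_k_vec(sfs.support[mask], d.m_chromosomes, d.k)
        return float(np.sum(pk * w) / np.sum(w))
    num = _weighted_mean_continuous(d, d.c, 0.5)
    den = math.log((0.5 * (1 - d.c)) / (d.c * 0.5))  # ∫ 1/[p(1-p)] = log[p/(1-p)]
    return num / den


def ppv(d: SampleDesign, sfs: FoldedSFS) -> float:
    """Expected fraction of threshold-passing loci whose true MAF is ≥ c.

    The denominator integrates over the full (0, 1/2] support; in the
    continuous neutral case the p → 0 endpoint is improper but the
    integrand P_k(p)/[p(1−p)] vanishes like p^{k−1} for k ≥ 2 (finite
    limit 2n at k = 1), so the integral converges for every k ≥ 1.
    """
    if sfs.is_discrete:
        pk = _detect_prob_k_vec(sfs.support, d.m_chromosomes, d.k)
        den = float(np.sum(pk * sfs.weights))
        if den <= 0.0:
            raise DomainError("no locus passes the threshold under this SFS")
        mask = sfs.support >= d.c
        num = float(np.sum(pk[mask] * sfs.weights[mask]))
        return num / den
    # split at c: the numerator is one of the two pieces, and quad should
    # not have to discover the C0 kink at c on its own
    above = _weighted_mean_continuous(d, d.c, 0.5)
    below = _weighted_mean_continuous(d, 0.0, d.c)
    return above / (above + below)


def roc_sweep(n_people: int, c: float, sfs: FoldedSFS) -> Iterator[tuple[int, float, float]]:
    """Yield (k, sensitivity, ppv) for every threshold k = 1..n_people.

    Sensitivity is non-increasing in k; PPV generally increases with k.
    This is the operating-characteristic curve a designer scans to pick k.
    """
    for k in range(1, n_people + 1):
        d = SampleDesign(n_people=n_people, k=k, c=c)
        yield k, sensitivity(d, sfs), ppv(d, sfs)


def plan_design(
    min_sensitivity: float,
    min_ppv: float,
    c: float,
    sfs: FoldedSFS,
    n_max: int,
) -> tuple[int, int] | None:
    """Smallest (n, then k) design meeting both targets, or None.

    Scans n upward; for each n, sensitivity decreases and PPV increases
    with k, so feasible k form an interval and the smallest feasible k is
    returned.  When no design within n_max works, returns None (the best
    achieved pair is available via roc_sweep diagnostics).
    """
    if not (0.0 < min_sensitivity < 1.0 and 0.0 < min_ppv < 1.0):
        return None

    def sens(n: int, k: int) -> float:
        return sensitivity(SampleDesign(n_people=n, k=k, c=c), sfs)

    def pv(n: int, k: int) -> float:
        return ppv(SampleDesign(n_people=n, k=k, c=c), sfs)

    for n in range(1, n_max + 1):
        if sens(n, 1) < min_sensitivity:
            continue
        # largest k keeping sensitivity on target (sensitivity falls with k)
        lo, hi = 1, n
        if sens(n, n) >= min_sensitivity:
            k_max = n
        else:
            while hi - lo > 1:  # invariant: sens(lo) ok, sens(hi) not
                mid = (lo + hi) // 2
                if sens(n, mid) >= min_sensitivity:
                    lo = mid
                else:
                    hi = mid
            k_max = lo
        if pv(n, k_max) < min_ppv:
            continue  # PPV is non-decreasing in k; best attempt failed
        # smallest k in [1, k_max] reaching the PPV target
        lo, hi = 1, k_max
        while hi > lo:  # invariant: pv(hi) ok
            mid = (lo + hi) // 2
            if pv(n, mid) >= min_ppv:
                hi = mid
            else:
                lo = mid + 1
        k = hi
        # PPV monotonicity in k is an observation, not a theorem: verify
        if sens(n, k) >= min_sensitivity and pv(n, k) >= min_ppv:
            return (n, k)
    return None
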