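"""Two-locus linkage disequilibrium statistics and the allele-frequency
bound on r².

The squared correlation r² between the allele indicators at two biallelic
loci cannot reach 1 unless the two loci have matching minor allele
frequencies.  After relabelling loci and alleles so that both frequencies
are minor (≤ 1/2) and p_A ≥ p_B, the sharp upper bound is

    r²_max = (1 − p_A) p_B / [p_A (1 − p_B)].

Two loci with very different observed r² can therefore be at very different
*fractions* of their attainable LD, which matters when r² is read as a
proxy for tagging power.

All statistics here are gametic: they are computed from haplotype
(gamete) frequencies, never from diploid genotype counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import DomainError, ValidationError

_SUM_TOL = 1e-9  # renormalize-and-warn threshold for frequency sums


@dataclass(frozen=True)
class TwoLocusHaplotypes:
    """Haplotype frequencies for a pair of biallelic loci.

    Alleles are A/a at the first locus and B/b at the second; fields are
    the population frequencies of the four gametes AB, Ab, aB, ab.
    Frequencies must be non-negative and sum to 1 (renormalized with a
    warning if the deviation is below 1e-9, rejected beyond).
    """

    p_AB: float
    p_Ab: float
    p_aB: float
    p_ab: float

    def __post_init__(self) -> None:
        freqs = (self.p_AB, self.p_Ab, self.p_aB, self.p_ab)
        if any(f < 0 or f > 1 for f in freqs):
            raise ValidationError(f"haplotype frequencies must lie in [0,1]: {freqs}")
        total = math.fsum(freqs)
        if abs(total - 1.0) > _SUM_TOL:
            raise ValidationError(
                f"haplotype frequencies sum to {total!r}, beyond tolerance {_SUM_TOL}"
            )
        if total != 1.0:
            if abs(total - 1.0) > 1e-12:  # silent below fp accumulation noise
                warnings.warn(
                    f"renormalizing haplotype frequencies (sum deviated by {total - 1.0:.2e})",
                    stacklevel=3,
                )
            object.__setattr__(self, "p_AB", self.p_AB / total)
            object.__setattr__(self, "p_Ab", self.p_Ab / total)
            object.__setattr__(self, "p_aB", self.p_aB / total)
            object.__setattr__(self, "p_ab", self.p_ab / total)

    @classmethod
    def from_margins(cls, p_A: float, p_B: float, p_AB: float) -> "TwoLocusHaplotypes":
        """Build a table from the two allele frequencies and the AB gamete
        frequency, validating the Fréchet feasibility bounds
        max(0, p_A + p_B − 1) ≤ p_AB ≤ min(p_A, p_B)."""
        lo = max(0.0, p_A + p_B - 1.0)
        hi = min(p_A, p_B)
        if p_AB < lo - 1e-15:
            raise ValidationError(
                f"p_AB={p_AB} violates the lower Fréchet bound max(0, p_A+p_B-1)={lo}"
            )
        if p_AB > hi + 1e-15:
            raise ValidationError(
                f"p_AB={p_AB} violates the upper Fréchet bound min(p_A, p_B)={hi}"
            )
        p_AB = min(max(p_AB, lo), hi)
        return cls(p_AB, p_A - p_AB, p_B - p_AB, 1.0 - p_A - p_B + p_AB)

    @property
    def p_A(self) -> float:
        return self.p_AB + self.p_Ab

    @property
    def p_B(self) -> float:
        return self.p_AB + self.p_aB

    def _require_polymorphic(self) -> None:
        if not 0.0 < self.p_A < 1.0:
            raise DomainError(f"first locus is monomorphic (p_A={self.p_A})")
        if not 0.0 < self.p_B < 1.0:
            raise DomainError(f"second locus is monomorphic (p_B={self.p_B})")


@dataclass(frozen=True)
class AlleleFreqPair:
    """Canonical minor-allele frequency pair with 0 < p_B ≤ p_A ≤ 1/2.

    Use :meth:`canonical` to fold arbitrary allele frequencies onto this
    domain; the flags record which relabellings were applied.
    """

    p_A: float
    p_B: float
    folded_A: bool = False
    folded_B: bool = False
    swapped: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.p_B <= self.p_A <= 0.5):
            raise DomainError(
                f"allele frequencies must satisfy 0 < p_B <= p_A <= 0.5, "
                f"got ({self.p_A}, {self.p_B})"
            )

    @classmethod
    def canonical(cls, p_A: float, p_B: float) -> "AlleleFreqPair":
        """Fold each frequency to its minor allele and order so p_A ≥ p_B."""
        if not (0.0 < p_A < 1.0 and 0.0 < p_B < 1.0):
            raise DomainError(f"allele frequencies must lie in (0,1): ({p_A}, {p_B})")
        folded_A = p_A > 0.5
        folded_B = p_B > 0.5
        a = 1.0 - p_A if folded_A else p_A
        b = 1.0 - p_B if folded_B else p_B
        swapped = b > a
        if swapped:
            a, b = b, a
            folded_A, folded_B = folded_B, folded_A
        return cls(a, b, folded_A, folded_B, swapped)


def d_coefficient(h: TwoLocusHaplotypes) -> float:
    """Standard LD coefficient D = p_AB − p_A·p_B, bounded by ±1/4."""
    h._require_polymorphic()
    return h.p_AB - h.p_A * h.p_B


def r_coefficient(h: TwoLocusHaplotypes) -> float:
    """Signed correlation r = D / sqrt(p_A p_a p_B p_b) between the two
    allele indicators; r = 1 iff p_A = p_B = p_AB."""
    h._require_polymorphic()
    p_A, p_B = h.p_A, h.p_B
    denom = math.sqrt(p_A * (1.0 - p_A) * p_B * (1.0 - p_B))
    return d_coefficient(h) / denom


def r_squared(h: TwoLocusHaplotypes) -> float:
    """Squared allele-indicator correlation r² ∈ [0, 1].

    Invariant under relabelling alleles at either locus, and never exceeds
    max_r_squared of the canonicalized margins.
    """
    r = r_coefficient(h)
    return min(r * r, 1.0)


def max_r_squared(f: AlleleFreqPair) -> float:
    """Sharp upper bound on r² given the minor allele frequencies:
    (1 − p_A) p_B / [p_A (1 − p_B)].  Equals 1 iff p_A = p_B."""
    return ((1.0 - f.p_A) * f.p_B) / (f.p_A * (1.0 - f.p_B))


def relative_r_squared(h: TwoLocusHaplotypes) -> float:
    """Observed r² as a fraction of the maximum attainable given the
    margins; 1 means the pair is at its allele-frequency-permitted LD
    ceiling even if the raw r² is small."""
    h._require_polymorphic()
    bound = max_r_squared(AlleleFreqPair.canonical(h.p_A, h.p_B))
    return r_squared(h) / bound


def relative_r_squared_from_value(p_A: float, p_B: float, r2: float) -> float:
    """Relative r² for a reported r² value and allele-frequency pair,
    without the full haplotype table."""
    if not 0.0 <= r2 <= 1.0:
        raise DomainError(f"r2 must lie in [0,1], got {r2}")
    bound = max_r_squared(AlleleFreqPair.canonical(p_A, p_B))
    if r2 > bound + 1e-12:
        raise DomainError(
            f"r2={r2} exceeds the maximum {bound} attainable at margins ({p_A}, {p_B})"
        )
    return min(r2 / bound, 1.0)
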