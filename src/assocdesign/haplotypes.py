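"""Exact multi-locus haplotype distributions with phenotype maps.

A :class:`HaplotypeTable` is a finite distribution over allele vectors; a
:class:`PhenotypeMap` assigns each haplotype a phenotype value, either as a
sum of per-allele effects or as an explicit lookup.  All statistics —
marginal allele frequencies, pairwise LD, phenotype moments and
locus–phenotype squared correlations — are computed by exact enumeration
over the table, so these models serve as ground truth for the power and
simulation modules.

Three canonical constructions illustrate how a non-causal marker can carry
a misleading association signal:

* :func:`marker_risk_protective` — a marker in LD with a risk locus and a
  protective locus; the two causal contributions can cancel at the marker,
  leaving it uncorrelated with the phenotype (or reversed in sign) even
  though LD with the risk locus is substantial.
* :func:`multiple_risk_haplotypes` — a marker allele that tags two distinct
  rare risk alleles is perfectly correlated with the phenotype while each
  causal locus individually is not.
* :func:`epistatic_disease` — two causal loci interact so that neither is
  marginally associated with disease, yet a non-causal marker tracking the
  interaction is perfectly associated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from . import ld
from .errors import DomainError, ValidationError

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class HaplotypeTable:
    """Distribution over haplotypes at an ordered set of loci.

    ``loci`` are the locus labels; ``haplotypes`` maps each allele vector
    (a tuple of allele labels, one per locus) to its population frequency.
    """

    loci: tuple[str, ...]
    haplotypes: tuple[tuple[tuple[str, ...], float], ...]

    def __post_init__(self) -> None:
        if len(self.loci) < 1:
            raise ValidationError("a haplotype table needs at least one locus")
        seen: set[tuple[str, ...]] = set()
        for alleles, freq in self.haplotypes:
            if len(alleles) != len(self.loci):
                raise ValidationError(
                    f"haplotype {alleles} has {len(alleles)} alleles for "
                    f"{len(self.loci)} loci"
                )
            if alleles in seen:
                raise ValidationError(f"duplicated haplotype {alleles}")
            seen.add(alleles)
            if freq < 0:
                raise ValidationError(f"negative frequency {freq} for {alleles}")
        total = math.fsum(f for _, f in self.haplotypes)
        if abs(total - 1.0) > _SUM_TOL:
            raise ValidationError(
                f"haplotype frequencies sum to {total!r}, beyond tolerance {_SUM_TOL}"
            )

    @classmethod
    def from_dict(
        cls, loci: Sequence[str], table: Mapping[tuple[str, ...], float]
    ) -> "HaplotypeTable":
        return cls(tuple(loci), tuple((tuple(h), float(f)) for h, f in table.items()))

    def _locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise DomainError(f"unknown locus {locus!r}; table has {self.loci}") from None

    def alleles_at(self, locus: str) -> tuple[str, ...]:
        i = self._locus_index(locus)
        out: list[str] = []
        for alleles, freq in self.haplotypes:
            if freq > 0 and alleles[i] not in out:
                out.append(alleles[i])
        return tuple(out)


@dataclass(frozen=True)
class PhenotypeMap:
    """Phenotype rule over a haplotype table.

    ``additive`` mode sums per-(locus, allele) effects; ``explicit`` mode
    looks the haplotype up directly.  ``diploid_additive`` ploidy forms a
    genotype as a random union of two independent haplotypes and adds
    their values (Hardy–Weinberg); the default is haploid.
    """

    mode: Literal["additive", "explicit"]
    effects: Mapping[tuple[str, str], float] | None = None
    explicit: Mapping[tuple[str, ...], float] | None = None
    ploidy: Literal["haploid", "diploid_additive"] = "haploid"

    def haplotype_value(self, t: HaplotypeTable, alleles: tuple[str, ...]) -> float:
        if self.mode == "additive":
            if self.effects is None:
                raise ValidationError("additive map requires effects")
            return math.fsum(
                self.effects.get((locus, allele), 0.0)
                for locus, allele in zip(t.loci, alleles)
            )
        if self.explicit is None:
            raise ValidationError("explicit map requires a haplotype->value table")
        try:
            return float(self.explicit[alleles])
        except KeyError:
            raise ValidationError(f"phenotype map does not cover haplotype {alleles}") from None


# ---------------------------------------------------------------------------
# enumeration statistics
# ---------------------------------------------------------------------------

def marginal_freq(t: HaplotypeTable, locus: str, allele: str) -> float:
    """Population frequency of ``allele`` at ``locus``."""
    i = t._locus_index(locus)
    if allele not in {h[i] for h, _ in t.haplotypes}:
        raise DomainError(f"allele {allele!r} does not occur at locus {locus!r}")
    return math.fsum(f for h, f in t.haplotypes if h[i] == allele)


def collapse_two_locus(
    t: HaplotypeTable, locus_a: str, locus_b: str
) -> ld.TwoLocusHaplotypes:
    """Marginalize the table to a 2x2 gamete table over two biallelic loci.

    The first listed allele at each locus plays the "A"/"B" role.  A locus
    paired with itself yields the perfect-coupling table.
    """
    ia, ib = t._locus_index(locus_a), t._locus_index(locus_b)
    alleles_a, alleles_b = t.alleles_at(locus_a), t.alleles_at(locus_b)
    if len(alleles_a) != 2:
        raise DomainError(
            f"locus {locus_a!r} is not biallelic in the table (alleles {alleles_a})"
        )
    if len(alleles_b) != 2:
        raise DomainError(
            f"locus {locus_b!r} is not biallelic in the table (alleles {alleles_b})"
        )
    A, B = alleles_a[0], alleles_b[0]
    cells = {"AB": 0.0, "Ab": 0.0, "aB": 0.0, "ab": 0.0}
    for h, f in t.haplotypes:
        key = ("A" if h[ia] == A else "a") + ("B" if h[ib] == B else "b")
        cells[key] += f
    return ld.TwoLocusHaplotypes(cells["AB"], cells["Ab"], cells["aB"], cells["ab"])


def pairwise_r2(t: HaplotypeTable, locus_a: str, locus_b: str) -> float:
    """Gametic r² between two biallelic loci of the table."""
    return ld.r_squared(collapse_two_locus(t, locus_a, locus_b))


def phenotype_moments(t: HaplotypeTable, m: PhenotypeMap) -> tuple[float, float]:
    """Exact (mean, variance) of the phenotype under the table.

    Haploid: moments of the per-haplotype values.  Diploid additive: the
    genotype value is the sum over two independent haplotypes, so the mean
    doubles and the variance doubles.
    """
    vals = [(m.haplotype_value(t, h), f) for h, f in t.haplotypes]
    mean = math.fsum(v * f for v, f in vals)
    var = math.fsum((v - mean) ** 2 * f for v, f in vals)
    if m.ploidy == "diploid_additive":
        return 2.0 * mean, 2.0 * var
    return mean, var


def locus_phenotype_corr2(t: HaplotypeTable, m: PhenotypeMap, locus: str) -> float:
    """Squared Pearson correlation between the allele indicator at
    ``locus`` and the phenotype, by exact enumeration.

    For diploid additive phenotypes the indicator is the allele dosage
    (0/1/2); independence of the two gametes makes both covariance and
    variances exactly twice their haploid values, so the squared
    correlation coincides with the haploid one.
    """
    i = t._locus_index(locus)
    alleles = t.alleles_at(locus)
    if len(alleles) != 2:
        raise DomainError(f"locus {locus!r} is not biallelic (alleles {alleles})")
    target = alleles[0]
    p = marginal_freq(t, locus, target)
    _, var_phi = phenotype_moments(t, m)
    if var_phi <= 0.0:
        raise DomainError("phenotype variance is zero; correlation undefined")
    # haploid moments suffice (see docstring); compute covariance directly
    mean_phi = math.fsum(m.haplotype_value(t, h) * f for h, f in t.haplotypes)
    e_x_phi = math.fsum(
        m.haplotype_value(t, h) * f for h, f in t.haplotypes if h[i] == target
    )
    cov = e_x_phi - p * mean_phi
    var_x = p * (1.0 - p)
    var_phi_hap = math.fsum(
        (m.haplotype_value(t, h) - mean_phi) ** 2 * f for h, f in t.haplotypes
    )
    return (cov * cov) / (var_x * var_phi_hap)


def disease_probabilities(
    t: HaplotypeTable, m: PhenotypeMap, threshold: float
) -> dict[tuple[str, ...], float]:
    """Binary disease coding: indicator of phenotype >= threshold per
    haplotype (haploid semantics)."""
    return {
        h: (1.0 if m.haplotype_value(t, h) >= threshold else 0.0)
        for h, _ in t.haplotypes
    }


# ---------------------------------------------------------------------------
# canonical constructions
# ---------------------------------------------------------------------------

def marker_risk_protective(
    u: float, v: float, w: float, x: float
) -> tuple[HaplotypeTable, PhenotypeMap]:
    """Marker M in LD with a risk locus R and a protective locus P.

    Four haplotypes over loci (M, R, P): the neutral background M0R0P0 at
    frequency u, the marker-only haplotype M1R0P0 at v, the marker+risk
    haplotype M1R1P0 at w, and the marker+protective haplotype M1R0P1 at
    x.  The R1/M0 haplotype does not exist (no recombination has separated
    the loci) and P1 co-occurs only with M1.  Phenotype: +1 per R1 allele,
    −1 per P1 allele, haploid.

    With x = 0 the protective locus is absent and the marker–phenotype
    squared correlation factorizes as r²(M,R) · corr²(R, φ).  With x = w
    the risk and protective contributions cancel at the marker: corr(M, φ)
    = 0 despite r²(M,R) > 0.  With x > w the marker–phenotype relationship
    reverses sign.
    """
    freqs = (u, v, w, x)
    if any(f < 0 for f in freqs):
        raise DomainError(f"haplotype frequencies must be non-negative: {freqs}")
    if abs(math.fsum(freqs) - 1.0) > _SUM_TOL:
        raise DomainError(f"haplotype frequencies must sum to 1: {freqs}")
    t = HaplotypeTable.from_dict(
        ("M", "R", "P"),
        {
            ("M0", "R0", "P0"): u,
            ("M1", "R0", "P0"): v,
            ("M1", "R1", "P0"): w,
            ("M1", "R0", "P1"): x,
        },
    )
    m = PhenotypeMap(mode="additive", effects={("R", "R1"): 1.0, ("P", "P1"): -1.0})
    return t, m


def multiple_risk_haplotypes(y: float) -> tuple[HaplotypeTable, PhenotypeMap]:
    """Marker allele tagging two distinct risk alleles (multiplicity of
    causal factors).

    Three haplotypes over (M, R1, R2): the marker allele M1 has frequency
    2y and each M1 haplotype carries exactly one risk allele, at either
    the first or the second risk locus (each risk allele has frequency y).
    The phenotype counts risk alleles, so the marker indicator equals the
    phenotype: corr²(M, φ) = 1, while each causal locus alone explains
    only (1 − 2y)/(2(1 − y)) of the phenotype variance.
    """
    if not 0.0 < y < 0.5:
        raise DomainError(f"y must lie in (0, 1/2), got {y}")
    t = HaplotypeTable.from_dict(
        ("M", "R1", "R2"),
        {
            ("M1", "r1", "r0"): y,   # risk allele at the first causal locus
            ("M1", "r0", "r1"): y,   # risk allele at the second causal locus
            ("M0", "r0", "r0"): 1.0 - 2.0 * y,
        },
    )
    m = PhenotypeMap(
        mode="additive", effects={("R1", "r1"): 1.0, ("R2", "r1"): 1.0}
    )
    return t, m


def epistatic_disease() -> tuple[HaplotypeTable, PhenotypeMap]:
    """Haploid epistasis model: disease iff the A and B loci carry the
    coupling combination (AB or ab); marker allele C tracks exactly those
    haplotypes.

    The four A/B haplotypes are equifrequent, so each causal locus is
    marginally independent of disease (corr² = 0) while the marker is
    perfectly associated (corr² = 1).
    """
    t = HaplotypeTable.from_dict(
        ("A", "B", "C"),
        {
            ("A", "B", "C"): 0.25,
            ("A", "b", "c"): 0.25,
            ("a", "B", "c"): 0.25,
            ("a", "b", "C"): 0.25,
        },
    )
    m = PhenotypeMap(
        mode="explicit",
        explicit={
            ("A", "B", "C"): 1.0,
            ("A", "b", "c"): 0.0,
            ("a", "B", "c"): 0.0,
            ("a", "b", "C"): 1.0,
        },
    )
    return t, m
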