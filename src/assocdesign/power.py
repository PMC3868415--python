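"""Case-control allelic power, required sample size, and the 1/r²
sample-size inflation factor.

The test throughout is the 1-df Pearson chi-square on the 2×2 table of
case/control allele counts (2n alleles per group of n diploid people),
without continuity correction.  Power is computed from the noncentral
chi-square distribution with noncentrality

    λ = (q_case − q_control)² / [ q̄(1−q̄) (1/(2 n_case) + 1/(2 n_control)) ],

where q̄ is the pooled allele frequency.  This standard two-proportion form
is validated against simulation (the montecarlo module), not assumed.

When a causal locus is tested indirectly through a marker in LD with it at
level r², and the marker is conditionally independent of the phenotype
given the causal locus, the sample size needed at the marker is inflated
by the factor 1/r².  :func:`inflation_check` verifies this numerically for
single-causal-locus models and refuses multi-causal tables, where the
conditional-independence assumption fails and the required sample size can
be arbitrarily larger — or infinite, when opposing causal contributions
cancel exactly at the marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import DomainError, ValidationError
from .haplotypes import (
    HaplotypeTable,
    PhenotypeMap,
    collapse_two_locus,
    marginal_freq,
    pairwise_r2,
)


@dataclass(frozen=True)
class PowerQuery:
    """Inputs for a 1-df allelic chi-square power computation."""

    q_case: float
    q_control: float
    n_case: int
    n_control: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name, q in (("q_case", self.q_case), ("q_control", self.q_control)):
            if not 0.0 < q < 1.0:
                raise DomainError(f"{name} must lie strictly in (0,1), got {q}")
        if self.n_case < 1 or self.n_control < 1:
            raise ValidationError("group sizes must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must lie in (0,1), got {self.alpha}")


@dataclass(frozen=True)
class PenetranceModel:
    """Disease probability given carrier (f1) / non-carrier (f0) status of
    the risk allele at a single causal locus, haploid coding."""

    f1: float
    f0: float

    def __post_init__(self) -> None:
        for name, f in (("f1", self.f1), ("f0", self.f0)):
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"penetrance {name} must lie in [0,1], got {f}")
        if self.f1 == self.f0 == 0.0 or self.f1 == self.f0 == 1.0:
            raise ValidationError(
                "penetrances both 0 or both 1 give no association or degenerate sampling"
            )


def noncentrality(q: PowerQuery) -> float:
    """Two-proportion noncentrality parameter λ of the allelic test."""
    m1, m0 = 2 * q.n_case, 2 * q.n_control
    pooled = (m1 * q.q_case + m0 * q.q_control) / (m1 + m0)
    return (q.q_case - q.q_control) ** 2 / (
        pooled * (1.0 - pooled) * (1.0 / m1 + 1.0 / m0)
    )


def allelic_power(q: PowerQuery) -> float:
    """Power of the 1-df allelic chi-square test; exactly alpha under the
    null q_case = q_control."""
    crit = stats.chi2.ppf(1.0 - q.alpha, df=1)
    if q.q_case == q.q_control:
        return q.alpha
    lam = noncentrality(q)
    return float(stats.ncx2.sf(crit, df=1, nc=lam))


def required_n(
    q_case: float,
    q_control: float,
    alpha: float = 0.05,
    target_power: float = 0.8,
) -> int:
    """Smallest equal per-group n with allelic power >= target_power.

    Geometric bracketing followed by integer bisection; power is strictly
    increasing in n for q_case != q_control, so the result is a fixed
    point: power(n) >= target > power(n-1).
    """
    if q_case == q_control:
        raise DomainError("q_case = q_control: no finite sample size attains power > alpha")
    if not alpha < target_power < 1.0:
        raise DomainError(f"target power must lie in (alpha, 1), got {target_power}")

    def power_at(n: int) -> float:
        return allelic_power(PowerQuery(q_case, q_control, n, n, alpha))

    hi = 1
    while power_at(hi) < target_power:
        hi *= 2
        if hi > 2**40:  # unreachable by monotonicity, guards fp pathologies
            raise DomainError("required sample size exceeds 2^40; effect too small")
    lo = hi // 2 if hi > 1 else 0
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi


def inflation_factor(r2: float) -> float:
    """Sample-size multiplier 1/r² for indirect testing through a marker in
    LD r² with the causal locus (conditional independence assumed)."""
    if not 0.0 < r2 <= 1.0:
        raise DomainError(
            f"r2 must lie in (0,1]; a marker with r2={r2} cannot detect the locus"
        )
    return 1.0 / r2


def joint_false_positive(alpha: float, n_studies: int) -> dict:
    """Probability that n independent studies all reject a true null:
    alpha^n.  The independence assumption is stated in the output because
    shared ancestry between study samples violates it in practice."""
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha must lie in (0,1), got {alpha}")
    if n_studies < 1:
        raise DomainError(f"n_studies must be >= 1, got {n_studies}")
    return {
        "probability": alpha**n_studies,
        "alpha": alpha,
        "n_studies": n_studies,
        "assumes": "studies are fully independent (no shared ancestry between samples)",
    }


# ---------------------------------------------------------------------------
# marker-level case/control frequencies from exact haplotype models
# ---------------------------------------------------------------------------

def _haplotype_disease_probs(
    t: HaplotypeTable,
    disease: PenetranceModel | PhenotypeMap,
    causal_locus: str | None = None,
    risk_allele: str | None = None,
    threshold: float | None = None,
) -> dict[tuple[str, ...], float]:
    """P(disease | haplotype) for every haplotype of the table."""
    if isinstance(disease, PenetranceModel):
        if causal_locus is None or risk_allele is None:
            raise ValidationError(
                "a PenetranceModel needs causal_locus and risk_allele"
            )
        i = t._locus_index(causal_locus)
        return {
            h: (disease.f1 if h[i] == risk_allele else disease.f0)
            for h, _ in t.haplotypes
        }
    if threshold is not None:
        return {
            h: (1.0 if disease.haplotype_value(t, h) >= threshold else 0.0)
            for h, _ in t.haplotypes
        }
    # no threshold: the map's values are taken as disease probabilities
    probs = {h: disease.haplotype_value(t, h) for h, _ in t.haplotypes}
    if any(not 0.0 <= v <= 1.0 for v in probs.values()):
        raise ValidationError(
            "phenotype values outside [0,1] cannot be disease probabilities; "
            "pass a threshold to binarize the phenotype"
        )
    return probs


def marker_case_control_freqs(
    t: HaplotypeTable,
    disease: PenetranceModel | PhenotypeMap,
    marker_locus: str,
    marker_allele: str | None = None,
    causal_locus: str | None = None,
    risk_allele: str | None = None,
    threshold: float | None = None,
) -> tuple[float, float]:
    """Exact marker allele frequencies in cases and controls by Bayes
    inversion over the haplotype distribution:

        q_case = P(marker allele | disease),  q_control = P(marker allele | healthy).

    Retrospective (case-control) ascertainment: cases and controls are
    i.i.d. draws from these conditional distributions; the population
    prevalence enters only through the inversion.
    """
    probs = _haplotype_disease_probs(t, disease, causal_locus, risk_allele, threshold)
    return _freqs_from_probs(t, probs, marker_locus, marker_allele)


def _freqs_from_probs(
    t: HaplotypeTable,
    probs: dict[tuple[str, ...], float],
    marker_locus: str,
    marker_allele: str | None,
) -> tuple[float, float]:
    i = t._locus_index(marker_locus)
    if marker_allele is None:
        marker_allele = t.alleles_at(marker_locus)[0]
    prevalence = math.fsum(f * probs[h] for h, f in t.haplotypes)
    if not 0.0 < prevalence < 1.0:
        raise DomainError(
            f"population disease prevalence is {prevalence}; "
            "case-control ascertainment is degenerate"
        )
    num_case = math.fsum(
        f * probs[h] for h, f in t.haplotypes if h[i] == marker_allele
    )
    num_control = math.fsum(
        f * (1.0 - probs[h]) for h, f in t.haplotypes if h[i] == marker_allele
    )
    return num_case / prevalence, num_control / (1.0 - prevalence)


def _causal_loci_of(t: HaplotypeTable, disease: PhenotypeMap) -> list[str]:
    """Loci on which the disease probability actually depends."""
    out = []
    for locus in t.loci:
        i = t._locus_index(locus)
        by_rest: dict[tuple, set[float]] = {}
        for h, _ in t.haplotypes:
            rest = h[:i] + h[i + 1:]
            by_rest.setdefault(rest, set()).add(disease.haplotype_value(t, h))
        if any(len(v) > 1 for v in by_rest.values()):
            out.append(locus)
    return out


@dataclass(frozen=True)
class InflationCheck:
    """Result of the exact marker-vs-causal sample-size comparison."""

    n_causal: int
    n_marker: int | None  # None: marker carries no signal, no finite n
    ratio: float  # inf when n_marker is None
    r2: float
    inflation_1_over_r2: float


def inflation_check(
    t: HaplotypeTable,
    disease: PenetranceModel | PhenotypeMap,
    marker_locus: str,
    causal_locus: str | None = None,
    risk_allele: str | None = None,
    threshold: float | None = None,
    alpha: float = 0.05,
    target_power: float = 0.8,
) -> InflationCheck:
    """Compare the exact required sample size at a marker with the 1/r²
    prediction, for a single-causal-locus haplotype model.

    Refuses tables in which disease probability depends on more than one
    locus: there the conditional-independence assumption behind 1/r² fails
    and :func:`marker_case_control_freqs` should be used directly.  In the
    small-effect limit (f1 → f0) the exact ratio converges to 1/r²; for
    larger effects the two drift apart.
    """
    probs = _haplotype_disease_probs(t, disease, causal_locus, risk_allele, threshold)
    explicit = PhenotypeMap(mode="explicit", explicit=probs)
    causal = _causal_loci_of(t, explicit)
    if len(causal) != 1:
        raise DomainError(
            f"disease probability depends on loci {causal}; the 1/r2 "
            "comparison requires exactly one causal locus — use "
            "marker_case_control_freqs for multi-causal models"
        )
    the_causal = causal[0]
    if causal_locus is not None and the_causal != causal_locus:
        raise DomainError(
            f"disease depends on {the_causal!r}, not the declared {causal_locus!r}"
        )
    q1_c, q0_c = _freqs_from_probs(t, probs, the_causal, None)
    q1_m, q0_m = _freqs_from_probs(t, probs, marker_locus, None)
    r2 = pairwise_r2(t, marker_locus, the_causal)
    factor = math.inf if r2 <= 0.0 else 1.0 / r2
    n_causal = required_n(q1_c, q0_c, alpha, target_power)
    if math.isclose(q1_m, q0_m, abs_tol=1e-12):
        return InflationCheck(n_causal, None, math.inf, r2, factor)
    n_marker = required_n(q1_m, q0_m, alpha, target_power)
    return InflationCheck(n_causal, n_marker, n_marker / n_causal, r2, factor)
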