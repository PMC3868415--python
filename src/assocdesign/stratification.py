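"""Confounding by population stratification in case-control studies.

A structured population is a mixture of subpopulations i = 1..I with
sampling weights γ_i, disease prevalences p_i and allele frequencies q_i.
Under case-control ascertainment from the mixture, the allele frequencies
among cases and controls are the prevalence-weighted mixtures

    q_case    = Σ γ_i p_i q_i / Σ γ_i p_i
    q_control = Σ γ_i (1−p_i) q_i / Σ γ_i (1−p_i).

Spurious association at a locus with no causal role arises exactly when
q_case ≠ q_control, which happens if and only if the γ-weighted covariance
between prevalence and allele frequency,

    cov = Σ γ_i p_i q_i − (Σ γ_i p_i)(Σ γ_i q_i),

is non-zero.  Mere population structure (differing q_i) is therefore
necessary but not sufficient: the structure must covary with prevalence
under the sampling scheme.  The magnitude of the confounding is summarised
by δ = |q_case − q_control| (reported as ``delta_case_control_freq_diff``;
it is this module's operationalization of the stratification-magnitude
parameter, not a claim of equivalence with other published δ measures).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError, ValidationError

_GAMMA_TOL = 1e-12


@dataclass(frozen=True)
class StructuredPopulation:
    """Per-subpopulation sampling weights, prevalences and allele
    frequencies; ``labels`` are optional display names."""

    gamma: tuple[float, ...]
    prevalence: tuple[float, ...]
    allele_freq: tuple[float, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        I = len(self.gamma)
        if I < 1:
            raise ValidationError("need at least one subpopulation")
        if len(self.prevalence) != I or len(self.allele_freq) != I:
            raise ValidationError("gamma, prevalence and allele_freq lengths differ")
        if self.labels is not None and len(self.labels) != I:
            raise ValidationError("labels length differs from the number of subpopulations")
        if any(g < 0 for g in self.gamma):
            raise ValidationError(f"sampling weights must be non-negative: {self.gamma}")
        if abs(math.fsum(self.gamma) - 1.0) > _GAMMA_TOL:
            raise ValidationError(
                f"sampling weights sum to {math.fsum(self.gamma)!r}, "
                f"beyond tolerance {_GAMMA_TOL}"
            )
        if any(not 0.0 <= p <= 1.0 for p in self.prevalence):
            raise ValidationError(f"prevalences must lie in [0,1]: {self.prevalence}")
        if any(not 0.0 <= q <= 1.0 for q in self.allele_freq):
            raise ValidationError(f"allele frequencies must lie in [0,1]: {self.allele_freq}")

    @classmethod
    def from_arrays(
        cls,
        gamma: Sequence[float],
        prevalence: Sequence[float],
        allele_freq: Sequence[float],
        labels: Sequence[str] | None = None,
    ) -> "StructuredPopulation":
        return cls(
            tuple(float(g) for g in gamma),
            tuple(float(p) for p in prevalence),
            tuple(float(q) for q in allele_freq),
            tuple(labels) if labels is not None else None,
        )


def case_control_freqs(s: StructuredPopulation) -> tuple[float, float]:
    """Mixture allele frequencies among cases and controls under
    case-control sampling from the structured population."""
    g = np.asarray(s.gamma)
    p = np.asarray(s.prevalence)
    q = np.asarray(s.allele_freq)
    prev = float(np.sum(g * p))
    if not 0.0 < prev < 1.0:
        raise DomainError(
            f"mixture prevalence Σγp = {prev}; case-control sampling is degenerate"
        )
    q_case = float(np.sum(g * p * q) / prev)
    q_control = float(np.sum(g * (1.0 - p) * q) / (1.0 - prev))
    return q_case, q_control


def confounding_covariance(s: StructuredPopulation) -> float:
    """γ-weighted covariance between prevalence and allele frequency;
    zero iff q_case = q_control (an algebraic identity)."""
    g = np.asarray(s.gamma)
    p = np.asarray(s.prevalence)
    q = np.asarray(s.allele_freq)
    return float(np.sum(g * p * q) - np.sum(g * p) * np.sum(g * q))


def is_confounded(s: StructuredPopulation, tol: float = 1e-12) -> bool:
    """True when the sampling scheme will manufacture a spurious
    case-control frequency difference at this locus."""
    if tol < 0:
        raise ValidationError(f"tolerance must be >= 0, got {tol}")
    return abs(confounding_covariance(s)) > tol


def delta_stratification(s: StructuredPopulation) -> float:
    """Magnitude of the confounding, δ = |q_case − q_control|
    (``delta_case_control_freq_diff``)."""
    q_case, q_control = case_control_freqs(s)
    return abs(q_case - q_control)


def expected_table(
    s: StructuredPopulation, n_case: int, n_control: int
) -> np.ndarray:
    """Expected 2×2 allele-count table [[case·q, case·(1−q)], [...]] with
    2·n alleles per group; rows sum to 2 n_case and 2 n_control."""
    if n_case < 1 or n_control < 1:
        raise ValidationError("group sizes must be >= 1")
    q_case, q_control = case_control_freqs(s)
    m1, m0 = 2 * n_case, 2 * n_control
    return np.array(
        [[m1 * q_case, m1 * (1.0 - q_case)], [m0 * q_control, m0 * (1.0 - q_control)]]
    )


# ---------------------------------------------------------------------------
# reference two- and three-subpopulation scenarios
# ---------------------------------------------------------------------------

#: Scenario keys: prevalence differs only / allele frequency differs only /
#: both differ (confounded) / three groups where both differ yet the
#: printed parameters were described as unconfounded (see the warning).
SCENARIOS = (
    "prevalence_only",
    "allele_freq_only",
    "both_confounded",
    "three_group_uncorrelated",
)


def build_scenario(name: str) -> StructuredPopulation:
    """Canonical structured-population examples.

    * ``prevalence_only``:   (p₁,p₂,q₁,q₂,γ₁,γ₂) = (1/16, 1/4, 1/6, 1/6, 1/2, 1/2)
      — structure absent, no spurious association.
    * ``allele_freq_only``:  (1/16, 1/16, 1/6, 7/12, 1/2, 1/2)
      — structure present but prevalences equal, no spurious association.
    * ``both_confounded``:   (1/16, 1/4, 1/6, 7/12, 1/2, 1/2)
      — both differ; the allele is spuriously enriched among cases
      (q_case = 1/2 vs q_control = 19/54).
    * ``three_group_uncorrelated``: (p₁..p₃, q₁..q₃, γ₁..γ₃) =
      (1/100, 1/50, 7/100, 1/4, 3/8, 1/3, 1/2, 1/3, 1/6) — a published
      example presented as satisfying the no-confounding condition, but the
      γ-weighted covariance of these printed parameters is 11/21600 ≠ 0, a
      small residual confounding; a warning is emitted.
    """
    if name == "prevalence_only":
        return StructuredPopulation.from_arrays(
            (0.5, 0.5), (1 / 16, 1 / 4), (1 / 6, 1 / 6), ("pop1", "pop2")
        )
    if name == "allele_freq_only":
        return StructuredPopulation.from_arrays(
            (0.5, 0.5), (1 / 16, 1 / 16), (1 / 6, 7 / 12), ("pop1", "pop2")
        )
    if name == "both_confounded":
        return StructuredPopulation.from_arrays(
            (0.5, 0.5), (1 / 16, 1 / 4), (1 / 6, 7 / 12), ("pop1", "pop2")
        )
    if name == "three_group_uncorrelated":
        warnings.warn(
            "the printed parameters of this scenario give a small non-zero "
            "prevalence/allele-frequency covariance (11/21600); it is not "
            "exactly unconfounded under the covariance criterion",
            stacklevel=2,
        )
        return StructuredPopulation.from_arrays(
            (1 / 2, 1 / 3, 1 / 6),
            (1 / 100, 1 / 50, 7 / 100),
            (1 / 4, 3 / 8, 1 / 3),
            ("pop1", "pop2", "pop3"),
        )
    raise ValidationError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
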