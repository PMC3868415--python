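"""Seeded Monte-Carlo oracles for the analytic calculators.

Case-control panels are sampled retrospectively: the case and control
allele counts are independent binomial draws from the conditional allele
frequencies (q_case, q_control) implied by a structured population or a
haplotype disease model.  The allelic chi-square test is then applied and
empirical rejection rates estimated.  A separate sampler draws minor
allele frequencies from a folded SFS and estimates discovery sensitivity
and PPV empirically.

All randomness flows from one root seed through named child streams
(numpy SeedSequence spawning), so identical configs reproduce outputs
bit-for-bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .errors import DomainError, ValidationError
from .haplotypes import HaplotypeTable, PhenotypeMap
from .power import PenetranceModel, marker_case_control_freqs
from .sfs import FoldedSFS, SampleDesign
from .stratification import StructuredPopulation, case_control_freqs


@dataclass(frozen=True)
class SimConfig:
    """Replication count, root seed, panel sizes, test size and how
    individual genotypes are formed (``allele``: 2n draws per group;
    ``hw_genotype``: n diploids from Hardy–Weinberg, allele counts summed —
    distributionally identical, exercised separately)."""

    reps: int
    seed: int
    n_case: int = 500
    n_control: int = 500
    alpha: float = 0.05
    sampling: Literal["allele", "hw_genotype"] = "allele"

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValidationError(f"reps must be >= 1, got {self.reps}")
        if self.n_case < 1 or self.n_control < 1:
            raise ValidationError("group sizes must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must lie in (0,1), got {self.alpha}")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic child generator for a named substream."""
        # crc32 keeps the stream key deterministic across processes
        # (str.hash is salted per interpreter run)
        child = np.random.SeedSequence(
            self.seed, spawn_key=(zlib.crc32(stream.encode()) % 2**31,)
        )
        return np.random.default_rng(child)


def _conditional_freqs(
    source,
    disease_kwargs: dict | None = None,
) -> tuple[float, float]:
    """(q_case, q_control) for a StructuredPopulation or a
    (HaplotypeTable, disease rule) source."""
    if isinstance(source, StructuredPopulation):
        return case_control_freqs(source)
    if isinstance(source, tuple) and len(source) == 2:
        table, disease = source
        if not isinstance(table, HaplotypeTable):
            raise ValidationError("haplotype source must be (HaplotypeTable, disease rule)")
        if not isinstance(disease, (PenetranceModel, PhenotypeMap)):
            raise ValidationError("disease rule must be a PenetranceModel or PhenotypeMap")
        return marker_case_control_freqs(table, disease, **(disease_kwargs or {}))
    raise ValidationError(f"unsupported panel source {type(source)!r}")


def _draw_counts(
    rng: np.random.Generator, n_people: int, q: float, reps: int, sampling: str
) -> np.ndarray:
    if sampling == "allele":
        return rng.binomial(2 * n_people, q, size=reps)
    # Hardy-Weinberg diploids: genotype dosage Bin(2, q) per person
    return rng.binomial(2, q, size=(reps, n_people)).sum(axis=1)


def sample_panel(
    source, cfg: SimConfig, disease_kwargs: dict | None = None
) -> np.ndarray:
    """One 2×2 allele-count table [[case minor, case major],
    [control minor, control major]], reproducible under the config seed."""
    q_case, q_control = _conditional_freqs(source, disease_kwargs)
    for name, q in (("q_case", q_case), ("q_control", q_control)):
        if not 0.0 < q < 1.0:
            raise DomainError(f"degenerate conditional frequency {name}={q}")
    rng = cfg.rng("panel")
    a = _draw_counts(rng, cfg.n_case, q_case, 1, cfg.sampling)[0]
    c = _draw_counts(rng, cfg.n_control, q_control, 1, cfg.sampling)[0]
    return np.array(
        [[a, 2 * cfg.n_case - a], [c, 2 * cfg.n_control - c]], dtype=np.int64
    )


def chisq_2x2(table: np.ndarray) -> tuple[float, float]:
    """1-df Pearson chi-square without continuity correction; raises on a
    zero margin, where the statistic is undefined."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise ValidationError("counts must be non-negative")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise DomainError("zero row/column margin: chi-square test undefined")
    n = t.sum()
    stat = n * (t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]) ** 2 / (
        rows[0] * rows[1] * cols[0] * cols[1]
    )
    return float(stat), float(stats.chi2.sf(stat, df=1))


@dataclass(frozen=True)
class RejectionRate:
    rate: float
    se: float
    n_tested: int
    n_degenerate: int  # zero-margin replicates, excluded from the rate


def empirical_rejection_rate(
    source, cfg: SimConfig, disease_kwargs: dict | None = None
) -> RejectionRate:
    """Fraction of replicate panels on which the allelic test rejects at
    cfg.alpha, with its binomial Monte-Carlo standard error."""
    q_case, q_control = _conditional_freqs(source, disease_kwargs)
    rng = cfg.rng("rejection")
    a = _draw_counts(rng, cfg.n_case, q_case, cfg.reps, cfg.sampling)
    c = _draw_counts(rng, cfg.n_control, q_control, cfg.reps, cfg.sampling)
    m1, m0 = 2 * cfg.n_case, 2 * cfg.n_control
    col_minor = a + c
    degenerate = (col_minor == 0) | (col_minor == m1 + m0)
    ok = ~degenerate
    n_tot = m1 + m0
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = (
            n_tot
            * (a * (m0 - c) - (m1 - a) * c).astype(float) ** 2
            / (m1 * m0 * col_minor * (n_tot - col_minor))
        )
    crit = stats.chi2.ppf(1.0 - cfg.alpha, df=1)
    n_tested = int(ok.sum())
    if n_tested == 0:
        raise DomainError("every replicate had a zero margin")
    rate = float(np.mean(stat[ok] > crit))
    se = float(np.sqrt(rate * (1.0 - rate) / n_tested))
    return RejectionRate(rate, se, n_tested, int(degenerate.sum()))


@dataclass(frozen=True)
class DiscoveryEstimate:
    sensitivity: float
    sensitivity_se: float
    ppv: float
    ppv_se: float
    n_eligible: int  # draws with true MAF >= c
    n_passed: int    # draws passing the k-threshold


def _sample_maf(sfs: FoldedSFS, rng: np.random.Generator, reps: int) -> np.ndarray:
    """Inverse-CDF draws from the normalized folded SFS.  The continuous
    neutral density is steep near 0, so its CDF is tabulated on a 10^4
    point log-spaced grid over (1e-4, 0.5]."""
    if sfs.is_discrete:
        w = sfs.weights / sfs.weights.sum()
        return rng.choice(sfs.support, size=reps, p=w)
    grid = np.logspace(np.log10(1e-4), np.log10(0.5), 10_000)
    # CDF of 1/[p(1-p)] on [a, p]: log[p/(1-p)] - log[a/(1-a)]
    cdf = np.log(grid / (1.0 - grid)) - np.log(grid[0] / (1.0 - grid[0]))
    cdf /= cdf[-1]
    u = rng.random(reps)
    return np.interp(u, cdf, grid)


def empirical_discovery(
    design: SampleDesign, sfs: FoldedSFS, cfg: SimConfig
) -> DiscoveryEstimate:
    """Monte-Carlo estimate of discovery sensitivity and PPV: draw a true
    MAF from the SFS, draw the sample allele count Bin(2n, p), pass iff
    each allele appears at least k times."""
    rng = cfg.rng("discovery")
    p = _sample_maf(sfs, rng, cfg.reps)
    m = design.m_chromosomes
    x = rng.binomial(m, p)
    passed = (x >= design.k) & (x <= m - design.k)
    eligible = p >= design.c
    n_eligible = int(eligible.sum())
    n_passed = int(passed.sum())
    if n_eligible == 0 or n_passed == 0:
        raise DomainError(
            "no eligible/passing draws; increase reps or revisit the design"
        )
    sens = float(np.mean(passed[eligible]))
    ppv = float(np.mean(eligible[passed]))
    return DiscoveryEstimate(
        sensitivity=sens,
        sensitivity_se=float(np.sqrt(sens * (1 - sens) / n_eligible)),
        ppv=ppv,
        ppv_se=float(np.sqrt(ppv * (1 - ppv) / n_passed)),
        n_eligible=n_eligible,
        n_passed=n_passed,
    )
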