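"""Exact haplotype-model engine: marginals, pairwise LD, phenotype moments
and locus-phenotype correlations, checked against brute-force enumeration."""

import math

import numpy as np
import pytest

from assocdesign import (
    DomainError,
    HaplotypeTable,
    PhenotypeMap,
    ValidationError,
    epistatic_disease,
    locus_phenotype_corr2,
    marginal_freq,
    marker_risk_protective,
    multiple_risk_haplotypes,
    pairwise_r2,
    phenotype_moments,
)


def enumeration_corr2(t: HaplotypeTable, m: PhenotypeMap, locus: str) -> float:
    """Independent oracle: squared correlation by direct weighted moments
    over the (indicator, phenotype) joint distribution."""
    i = t.loci.index(locus)
    target = t.alleles_at(locus)[0]
    x = np.array([1.0 if h[i] == target else 0.0 for h, _ in t.haplotypes])
    phi = np.array([m.haplotype_value(t, h) for h, _ in t.haplotypes])
    w = np.array([f for _, f in t.haplotypes])
    ex, ephi = np.sum(w * x), np.sum(w * phi)
    cov = np.sum(w * (x - ex) * (phi - ephi))
    vx = np.sum(w * (x - ex) ** 2)
    vphi = np.sum(w * (phi - ephi) ** 2)
    return cov**2 / (vx * vphi)


def random_model(rng) -> tuple[HaplotypeTable, PhenotypeMap]:
    n_loci = int(rng.integers(2, 4))
    haps = [
        tuple(f"L{j}_{a}" for j, a in enumerate(bits))
        for bits in np.ndindex(*(2,) * n_loci)
    ]
    f = rng.dirichlet(np.ones(len(haps)))
    t = HaplotypeTable.from_dict(
        [f"L{j}" for j in range(n_loci)], dict(zip(haps, f))
    )
    phi = {h: float(v) for h, v in zip(haps, rng.normal(size=len(haps)))}
    return t, PhenotypeMap(mode="explicit", explicit=phi)


class TestMarginalFreq:
    def test_marker_risk_protective_marker_freq(self):
        t, _ = marker_risk_protective(0.5, 0.0, 0.25, 0.25)
        assert marginal_freq(t, "M", "M1") == pytest.approx(0.5)

    def test_multiple_risk_marker_freq_is_2y(self):
        t, _ = multiple_risk_haplotypes(0.1)
        assert marginal_freq(t, "M", "M1") == pytest.approx(0.2)

    def test_single_haplotype_table(self):
        t = HaplotypeTable.from_dict(("L",), {("x",): 1.0})
        assert marginal_freq(t, "L", "x") == 1.0

    def test_unknown_locus_or_allele(self):
        t, _ = epistatic_disease()
        with pytest.raises(DomainError):
            marginal_freq(t, "Z", "A")
        with pytest.raises(DomainError):
            marginal_freq(t, "A", "Z")


class TestPairwiseR2:
    def test_marker_risk_ld(self):
        t, _ = marker_risk_protective(0.5, 0.0, 0.25, 0.25)
        assert pairwise_r2(t, "M", "R") == pytest.approx(1 / 3)

    def test_epistatic_causal_loci_independent(self):
        t, _ = epistatic_disease()
        assert pairwise_r2(t, "A", "B") == pytest.approx(0.0, abs=1e-15)

    def test_locus_with_itself(self):
        t, _ = epistatic_disease()
        assert pairwise_r2(t, "A", "A") == pytest.approx(1.0)

    def test_monomorphic_locus_rejected(self):
        t, _ = marker_risk_protective(0.5, 0.25, 0.25, 0.0)  # x=0: P fixed at P0
        with pytest.raises(DomainError, match="biallelic"):
            pairwise_r2(t, "M", "P")


class TestPhenotypeMoments:
    def test_marker_risk_protective_moments(self):
        t, m = marker_risk_protective(0.5, 0.0, 0.25, 0.25)
        mean, var = phenotype_moments(t, m)
        assert mean == pytest.approx(0.0, abs=1e-15)
        assert var == pytest.approx(0.5)

    def test_constant_map_zero_variance(self):
        t, _ = epistatic_disease()
        const = PhenotypeMap(mode="explicit", explicit={h: 2.0 for h, _ in t.haplotypes})
        assert phenotype_moments(t, const)[1] == pytest.approx(0.0, abs=1e-15)

    def test_multiple_risk_mean_is_2y(self):
        t, m = multiple_risk_haplotypes(0.15)
        assert phenotype_moments(t, m)[0] == pytest.approx(0.3)

    def test_diploid_additive_doubles_moments(self):
        t, m = multiple_risk_haplotypes(0.15)
        md = PhenotypeMap(mode="additive", effects=m.effects, ploidy="diploid_additive")
        mean_h, var_h = phenotype_moments(t, m)
        mean_d, var_d = phenotype_moments(t, md)
        assert mean_d == pytest.approx(2 * mean_h)
        assert var_d == pytest.approx(2 * var_h)


class TestLocusPhenotypeCorr2:
    def test_risk_locus_explains_two_thirds(self):
        t, m = marker_risk_protective(0.5, 0.0, 0.25, 0.25)
        assert locus_phenotype_corr2(t, m, "R") == pytest.approx(2 / 3)

    def test_marker_uncorrelated_when_x_equals_w(self):
        t, m = marker_risk_protective(0.5, 0.0, 0.25, 0.25)
        assert locus_phenotype_corr2(t, m, "M") == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("y", [0.05, 0.2, 0.4])
    def test_multiple_risk_marker_perfect(self, y):
        t, m = multiple_risk_haplotypes(y)
        assert locus_phenotype_corr2(t, m, "M") == pytest.approx(1.0)

    def test_multiple_risk_causal_closed_form(self):
        # each causal locus explains (1-2y)/(2(1-y)) of the variance;
        # the closed form was derived independently and is checked against
        # the enumeration oracle here
        for y in (0.1, 0.2, 0.3):
            t, m = multiple_risk_haplotypes(y)
            expected = (1 - 2 * y) / (2 * (1 - y))
            assert locus_phenotype_corr2(t, m, "R1") == pytest.approx(expected)
            assert locus_phenotype_corr2(t, m, "R1") == pytest.approx(
                enumeration_corr2(t, m, "R1"), abs=1e-12
            )
        t, m = multiple_risk_haplotypes(0.2)
        assert locus_phenotype_corr2(t, m, "R1") == pytest.approx(0.375)

    def test_epistatic_model(self):
        t, m = epistatic_disease()
        assert locus_phenotype_corr2(t, m, "A") == pytest.approx(0.0, abs=1e-15)
        assert locus_phenotype_corr2(t, m, "B") == pytest.approx(0.0, abs=1e-15)
        assert locus_phenotype_corr2(t, m, "C") == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        t, _ = epistatic_disease()
        const = PhenotypeMap(mode="explicit", explicit={h: 1.0 for h, _ in t.haplotypes})
        with pytest.raises(DomainError, match="variance"):
            locus_phenotype_corr2(t, const, "A")

    def test_agrees_with_enumeration_on_random_models(self, rng):
        checked = 0
        while checked < 300:
            t, m = random_model(rng)
            locus = t.loci[int(rng.integers(len(t.loci)))]
            if len(t.alleles_at(locus)) != 2:
                continue
            _, var = phenotype_moments(t, m)
            if var < 1e-12:
                continue
            assert locus_phenotype_corr2(t, m, locus) == pytest.approx(
                enumeration_corr2(t, m, locus), abs=1e-12
            )
            checked += 1


class TestAttenuationIdentity:
    """With a single causal locus R and marker M conditionally independent
    of the phenotype given R, corr²(M, φ) = r²(M, R) · corr²(R, φ) — the
    algebra behind the 1/r² inflation factor."""

    def test_no_protective_locus_factorizes(self, rng):
        for _ in range(100):
            u, v, w = rng.dirichlet(np.ones(3))
            if min(u, w) < 1e-3 or v + w < 1e-3 or u + v < 1e-3:
                continue
            t, m = marker_risk_protective(u, v, w, 0.0)
            lhs = locus_phenotype_corr2(t, m, "M")
            rhs = pairwise_r2(t, "M", "R") * locus_phenotype_corr2(t, m, "R")
            assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_additive_phenotype_on_r_attenuates_by_r2(self, rng):
        # two-locus tables, phenotype depends only on R: corr²(M, φ) = r²(M, R)
        for _ in range(100):
            f = rng.dirichlet(np.ones(4))
            pa, pb = f[0] + f[1], f[0] + f[2]
            if not (1e-3 < pa < 1 - 1e-3 and 1e-3 < pb < 1 - 1e-3):
                continue
            t = HaplotypeTable.from_dict(
                ("M", "R"),
                {
                    ("M1", "R1"): f[0],
                    ("M1", "R0"): f[1],
                    ("M0", "R1"): f[2],
                    ("M0", "R0"): f[3],
                },
            )
            m = PhenotypeMap(mode="additive", effects={("R", "R1"): 1.7})
            assert locus_phenotype_corr2(t, m, "M") == pytest.approx(
                pairwise_r2(t, "M", "R"), abs=1e-10
            )


class TestBuilders:
    def test_marker_risk_protective_reversal(self):
        # x > w flips the sign of cov(M, phi)
        def cov_m_phi(u, v, w, x):
            t, m = marker_risk_protective(u, v, w, x)
            i = t.loci.index("M")
            mean_phi = sum(m.haplotype_value(t, h) * f for h, f in t.haplotypes)
            pm1 = marginal_freq(t, "M", "M1")
            e = sum(
                m.haplotype_value(t, h) * f for h, f in t.haplotypes if h[i] == "M1"
            )
            return e - pm1 * mean_phi

        assert cov_m_phi(0.5, 0.0, 0.3, 0.2) > 0
        assert cov_m_phi(0.5, 0.0, 0.2, 0.3) < 0
        assert cov_m_phi(0.5, 0.0, 0.25, 0.25) == pytest.approx(0.0, abs=1e-15)

    def test_builder_input_validation(self):
        with pytest.raises(DomainError):
            marker_risk_protective(0.5, 0.5, 0.25, 0.25)  # sums to 1.5
        with pytest.raises(DomainError):
            marker_risk_protective(0.75, -0.25, 0.25, 0.25)
        with pytest.raises(DomainError):
            multiple_risk_haplotypes(0.5)

    def test_table_validation(self):
        with pytest.raises(ValidationError, match="duplicated"):
            HaplotypeTable(("L",), ((("x",), 0.5), (("x",), 0.5)))
        with pytest.raises(ValidationError, match="sum"):
            HaplotypeTable.from_dict(("L",), {("x",): 0.5, ("y",): 0.3})
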