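# assocdesign

Population-genetic design calculators for case-control association
studies. The package is aimed at statistical geneticists and
methods-minded epidemiologists who want the quantitative versions of five
recurring design questions, each answered by a small exact calculator
rather than a genome-scale pipeline:

1. **How much LD is even possible between two loci?** The squared allele
   correlation r² between two biallelic loci is bounded by their allele
   frequencies. After relabelling so both frequencies are minor
   (p_A, p_B ≤ ½, p_A ≥ p_B),

       r²max = (1 − p_A) p_B / [p_A (1 − p_B)],

   which equals 1 only when p_A = p_B. The `ld` module computes D, r, r²,
   r²max, and the observed r² as a fraction of its ceiling.

2. **How many people does a variant-discovery panel need?** A locus with
   minor allele frequency p shows both alleles in n people with
   probability 1 − (1−p)^{2n} − p^{2n}; requiring each allele ≥ k times
   gives a binomial tail P_k(p). Averaging P_k over a folded
   site-frequency spectrum f(p) ∝ 1/[p(1−p)] (neutral, constant
   population size) yields the catalog's **sensitivity**
   ∫_c^{½} P_k f dp / ∫_c^{½} f dp for loci with MAF ≥ c and its **PPV**
   ∫_c^{½} P_k f dp / ∫_0^{½} P_k f dp. The `sfs` module evaluates these
   by adaptive quadrature (or sums, for discrete spectra) and searches
   for the smallest design meeting sensitivity/PPV targets.

3. **What does testing a marker instead of the causal locus cost?** The
   1-df allelic chi-square power is computed from the noncentral
   chi-square distribution; when a marker is in LD r² with a single
   causal locus and carries no other signal, the required sample size
   inflates by 1/r². The `power` and `haplotypes` modules verify this
   exactly from haplotype models — and expose the constructions where it
   fails: a risk plus a protective locus cancelling at the marker, a
   marker tagging two rare risk alleles (perfectly associated while
   neither causal locus is), and a haploid epistasis model whose causal
   loci show r² = 0 with disease while a non-causal marker shows r² = 1.

4. **When does population structure confound?** For subpopulations with
   sampling weights γᵢ, prevalences pᵢ and allele frequencies qᵢ, the
   case/control frequencies are q_case = Σγᵢpᵢqᵢ/Σγᵢpᵢ and
   q_control = Σγᵢ(1−pᵢ)qᵢ/Σγᵢ(1−pᵢ); they differ iff the γ-weighted
   covariance Σγᵢpᵢqᵢ − (Σγᵢpᵢ)(Σγᵢqᵢ) is non-zero. Structure alone is
   not enough — it must covary with prevalence (`stratification`).

5. **How much do independent replications buy?** Under true independence,
   n studies jointly false-positive with probability αⁿ; shared ancestry
   between samples breaks the assumption, which the output states.

Every analytic quantity has a seeded Monte-Carlo oracle in `montecarlo`.

## Worked example

```python
>>> from assocdesign import (AlleleFreqPair, max_r_squared, FoldedSFS,
...                          SampleDesign, sensitivity, ppv)
>>> max_r_squared(AlleleFreqPair.canonical(1/3, 1/51))
0.040000000000000015
```

Two loci with minor allele frequencies 1/3 and 1/51 can never exceed
r² = 1/25: an observed r² of 1/40 is 62.5% of what these frequencies
allow, so "low LD" here is mostly an allele-frequency artefact.

```python
>>> design = SampleDesign(n_people=250, k=30, c=0.05)
>>> neutral = FoldedSFS.neutral()
>>> sensitivity(design, neutral)
0.9339129745075513
>>> 1 - ppv(design, neutral)
0.00704432188597337
```

Requiring each allele 30 times in 250 people catalogs 93.4% of loci with
MAF > 0.05 while only 0.70% of the accepted loci are actually rarer than
that — a few hundred samples suffice to build a common-variant catalog.

The same numbers from the shell:

```bash
assocdesign discovery --n 250 --k 30 --c 0.05
assocdesign ld --freqs 0.3333333,0.0196078 --r2 0.025
assocdesign strata --scenario both_confounded
```

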