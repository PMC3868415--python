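"""TSV/JSON readers and writers and the synthetic fixture generator.

All tabular inputs are tiny parameter tables, so the formats are plain
tab-delimited text with a header row ('#' lines are comments):

* haplotype tables — one column per locus plus ``freq`` (and optionally
  ``phenotype`` for an explicit map);
* structured populations — columns ``subpop gamma prevalence allele_freq``;
* custom folded SFS — columns ``maf weight``.

:func:`generate_fixtures` writes the canonical scenario files plus
randomized instances whose ground truth (r², covariance, …) is embedded in
the returned manifest, so every module is testable without any download.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import ld
from .errors import ValidationError
from .haplotypes import (
    HaplotypeTable,
    PhenotypeMap,
    epistatic_disease,
    marker_risk_protective,
    multiple_risk_haplotypes,
)
from .sfs import FoldedSFS
from .stratification import (
    SCENARIOS,
    StructuredPopulation,
    build_scenario,
    confounding_covariance,
)

_POP_COLUMNS = ["subpop", "gamma", "prevalence", "allele_freq"]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file") from None
    if df.empty:
        raise ValidationError(f"{path}: no data rows")
    return df


def read_haplotype_table(path: str | Path) -> tuple[HaplotypeTable, PhenotypeMap | None]:
    """Load a haplotype table; returns the optional explicit phenotype map
    when the file carries a ``phenotype`` column."""
    df = _read_tsv(path)
    if "freq" not in df.columns:
        raise ValidationError(f"{path}: missing required 'freq' column")
    loci = [c for c in df.columns if c not in ("freq", "phenotype")]
    if not loci:
        raise ValidationError(f"{path}: no locus columns")
    try:
        freqs = df["freq"].astype(float)
    except ValueError as e:
        raise ValidationError(f"{path}: non-numeric frequency ({e})") from None
    table = HaplotypeTable(
        tuple(loci),
        tuple(
            (tuple(row[locus] for locus in loci), float(freq))
            for (_, row), freq in zip(df.iterrows(), freqs)
        ),
    )
    pmap = None
    if "phenotype" in df.columns:
        explicit = {
            tuple(row[locus] for locus in loci): float(row["phenotype"])
            for _, row in df.iterrows()
        }
        pmap = PhenotypeMap(mode="explicit", explicit=explicit)
    return table, pmap


def write_haplotype_table(
    path: str | Path, t: HaplotypeTable, m: PhenotypeMap | None = None
) -> None:
    rows = []
    for h, f in t.haplotypes:
        row = dict(zip(t.loci, h))
        row["freq"] = repr(f)
        if m is not None:
            row["phenotype"] = repr(m.haplotype_value(t, h))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_structured_population(path: str | Path) -> StructuredPopulation:
    df = _read_tsv(path)
    missing = [c for c in _POP_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    try:
        return StructuredPopulation.from_arrays(
            df["gamma"].astype(float),
            df["prevalence"].astype(float),
            df["allele_freq"].astype(float),
            df["subpop"],
        )
    except ValueError as e:
        raise ValidationError(f"{path}: {e}") from None


def write_structured_population(path: str | Path, s: StructuredPopulation) -> None:
    labels = s.labels or tuple(f"pop{i+1}" for i in range(len(s.gamma)))
    pd.DataFrame(
        {
            "subpop": labels,
            "gamma": [repr(g) for g in s.gamma],
            "prevalence": [repr(p) for p in s.prevalence],
            "allele_freq": [repr(q) for q in s.allele_freq],
        }
    ).to_csv(path, sep="\t", index=False)


def read_custom_sfs(path: str | Path) -> FoldedSFS:
    df = _read_tsv(path)
    for col in ("maf", "weight"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column '{col}'")
    return FoldedSFS.custom(df["maf"].astype(float), df["weight"].astype(float))


# ---------------------------------------------------------------------------
# fixture generator
# ---------------------------------------------------------------------------

def _random_two_locus(rng: np.random.Generator) -> ld.TwoLocusHaplotypes:
    f = rng.dirichlet(np.ones(4))
    # reject tables with a (numerically) monomorphic locus
    while min(f[0] + f[1], f[0] + f[2]) < 1e-3 or max(f[0] + f[1], f[0] + f[2]) > 1 - 1e-3:
        f = rng.dirichlet(np.ones(4))
    return ld.TwoLocusHaplotypes(*f)


def random_population(
    rng: np.random.Generator, n_subpops: int, confounded: bool
) -> StructuredPopulation:
    """Random structured population; when ``confounded`` is False the
    allele frequencies are projected onto the γ-orthogonal complement of
    the prevalence vector (then recentred into [0,1]), which zeroes the
    prevalence/frequency covariance by construction."""
    g = rng.dirichlet(np.ones(n_subpops))
    p = rng.uniform(0.01, 0.3, n_subpops)
    q = rng.uniform(0.05, 0.95, n_subpops)
    if not confounded:
        pbar = np.sum(g * p)
        qbar = np.sum(g * q)
        cov = np.sum(g * (p - pbar) * (q - qbar))
        varp = np.sum(g * (p - pbar) ** 2)
        q = q - (cov / varp) * (p - pbar)  # γ-weighted residual of q on p
        q = np.clip(q, 0.0, 1.0)
        # clipping can reintroduce covariance; retry until clean
        s = StructuredPopulation.from_arrays(g, p, q)
        if abs(confounding_covariance(s)) > 1e-12:
            return random_population(rng, n_subpops, confounded)
        return s
    s = StructuredPopulation.from_arrays(g, p, q)
    if abs(confounding_covariance(s)) < 1e-6:  # accidentally balanced
        return random_population(rng, n_subpops, confounded)
    return s


def generate_fixtures(seed: int, out_dir: str | Path) -> dict:
    """Write the canonical scenario files and randomized instances with
    embedded ground truth; deterministic under the seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: dict = {"seed": seed, "files": {}}

    # canonical structured populations
    import warnings as _warnings

    for name in SCENARIOS:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            s = build_scenario(name)
        fname = f"population_{name}.tsv"
        write_structured_population(out / fname, s)
        manifest["files"][fname] = {
            "kind": "structured_population",
            "covariance": confounding_covariance(s),
        }

    # canonical haplotype models
    builders = {
        "haplotypes_marker_risk_protective.tsv": marker_risk_protective(0.5, 0.0, 0.25, 0.25),
        "haplotypes_multiple_risk.tsv": multiple_risk_haplotypes(0.1),
        "haplotypes_epistatic.tsv": epistatic_disease(),
    }
    for fname, (t, m) in builders.items():
        write_haplotype_table(out / fname, t, m)
        manifest["files"][fname] = {"kind": "haplotype_table", "loci": list(t.loci)}

    # an example growth-skewed custom SFS (rare variants over-represented
    # relative to the constant-size neutral spectrum)
    p_grid = np.linspace(0.005, 0.5, 100)
    weights = 1.0 / (p_grid**1.5)
    pd.DataFrame({"maf": p_grid, "weight": weights}).to_csv(
        out / "sfs_growth_skewed.tsv", sep="\t", index=False
    )
    manifest["files"]["sfs_growth_skewed.tsv"] = {"kind": "custom_sfs"}

    # randomized two-locus tables with recorded r²
    two_locus = []
    for i in range(10):
        h = _random_two_locus(rng)
        two_locus.append(
            {
                "p_AB": h.p_AB, "p_Ab": h.p_Ab, "p_aB": h.p_aB, "p_ab": h.p_ab,
                "r2": ld.r_squared(h),
            }
        )
    manifest["random_two_locus"] = two_locus

    # randomized structured populations with recorded covariance
    pops = []
    for i in range(5):
        for confounded in (True, False):
            n_sub = int(rng.integers(2, 7))
            s = random_population(rng, n_sub, confounded)
            fname = f"population_random_{i}_{'conf' if confounded else 'null'}.tsv"
            write_structured_population(out / fname, s)
            pops.append(
                {
                    "file": fname,
                    "confounded": confounded,
                    "covariance": confounding_covariance(s),
                }
            )
            manifest["files"][fname] = {"kind": "structured_population"}
    manifest["random_populations"] = pops

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
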