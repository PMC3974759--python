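"""Synthetic multi-omic cohorts with planted association structure.

The generator emulates the shape of a lymphoblastoid-cell-line
pharmacogenomics study: ~58 samples, genome-wide biallelic SNPs, thousands
of gene expression traits, ~200 expressed miRNAs, and log-viability
phenotypes at four drug concentrations (3, 5, 7, 10 uM).  A configurable
number of (SNP, miRNA, gene) triads is planted with the causal chain the
discovery cascade is designed to detect::

    SNP --(effect_qtl_mirna)--> miRNA --(effect_mirna_gene, < 0)--> gene
     \\--(effect_qtl_gene)------------------------------------^
    gene --(effect_gene_pheno x dose_scaling[c])--> log-viability at dose c

Effects are path coefficients on standardized parents (genotype is
standardized by its population moments 2f, 2f(1-f); each mediator is
standardized by its analytic population SD before feeding the next
equation), with i.i.d. Gaussian residual noise of SD ``noise_sd`` in every
structural equation.  With this convention the marginal (composite)
standardized slope of gene on SNP is ``effect_qtl_gene + effect_mirna_gene *
effect_qtl_mirna / sqrt(effect_qtl_mirna**2 + noise_sd**2)`` — direct path
plus indirect path through the miRNA — which :func:`composite_snp_gene_slope`
exposes for truth-checking.

Non-planted features are pure noise, so a null cohort (zero planted effects)
calibrates the cascade's false-discovery behaviour.  All randomness derives
from the single ``seed`` via named substreams, and a fixed seed reproduces
the cohort bit-for-bit.

The structural signal is mapped affinely onto a realistic percent-viable
scale (per-dose medians falling from 88% at 3 uM to 56% at 10 uM, ln-scale
spread growing with dose); affine maps leave every downstream p-value
unchanged, so this is presentation only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .assoc import ExpressionMatrix, GenotypeMatrix
from .errors import ConfigError
from .phenotyping import PhenotypeTable

__all__ = [
    "CohortSpec",
    "PlantedTriad",
    "SyntheticCohort",
    "generate_cohort",
    "generate_null_cohort",
    "composite_snp_gene_slope",
]

_DEFAULT_CONCENTRATIONS = (3.0, 5.0, 7.0, 10.0)

# substream labels (spawn keys) so each matrix has its own independent stream
_STREAMS = {"genotypes": 1, "mirna": 2, "gene": 3, "pheno": 4, "placement": 5}


@dataclass(frozen=True)
class CohortSpec:
    """Generator configuration; defaults mirror the emulated study.

    ``dose_scaling`` defaults to concentration / 5 uM, i.e. planted phenotype
    effects grow linearly with dose so inter-individual spread is larger at
    higher concentrations.
    """

    n_samples: int = 58
    n_snps: int = 5000
    n_genes: int = 13000
    n_mirnas: int = 201
    concentrations: tuple[float, ...] = _DEFAULT_CONCENTRATIONS
    n_planted_triads: int = 5
    effect_qtl_gene: float = 0.8
    effect_qtl_mirna: float = 0.8
    effect_mirna_gene: float = -0.8
    effect_gene_pheno: float = 0.8
    dose_scaling: tuple[float, ...] | None = None
    noise_sd: float = 1.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "concentrations", tuple(float(c) for c in self.concentrations)
        )
        if self.dose_scaling is not None:
            object.__setattr__(
                self, "dose_scaling", tuple(float(d) for d in self.dose_scaling)
            )

    def resolved_dose_scaling(self) -> tuple[float, ...]:
        if self.dose_scaling is not None:
            return self.dose_scaling
        return tuple(c / 5.0 for c in self.concentrations)

    def validate(self) -> None:
        for name in ("n_samples", "n_snps", "n_genes", "n_mirnas"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"invariant violated: {name} > 0")
        if not self.concentrations:
            raise ConfigError("invariant violated: at least one concentration")
        if self.n_planted_triads < 0:
            raise ConfigError("invariant violated: n_planted_triads >= 0")
        if self.n_planted_triads > min(self.n_snps, self.n_genes, self.n_mirnas):
            raise ConfigError(
                "invariant violated: n_planted_triads <= "
                "min(n_snps, n_genes, n_mirnas)"
            )
        if self.n_planted_triads > 0 and not self.effect_mirna_gene < 0:
            raise ConfigError(
                "invariant violated: effect_mirna_gene < 0 "
                "(planted regulation must be repressive)"
            )
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("invariant violated: maf_range within (0, 0.5]")
        if not self.noise_sd > 0:
            raise ConfigError("invariant violated: noise_sd > 0")
        ds = self.resolved_dose_scaling()
        if len(ds) != len(self.concentrations):
            raise ConfigError(
                "invariant violated: dose_scaling length matches concentrations"
            )

    def replace(self, **kw) -> "CohortSpec":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class PlantedTriad:
    """Identity of one planted causal chain."""

    snp_id: str
    mirna_id: str
    gene_id: str


@dataclass
class SyntheticCohort:
    """One generated cohort plus the ground truth of what was planted."""

    genotypes: GenotypeMatrix
    gene_expr: ExpressionMatrix
    mirna_expr: ExpressionMatrix
    phenotypes: PhenotypeTable
    truth: list[PlantedTriad]
    maf: pd.Series  # true (generative) coded-allele frequency per SNP
    spec: CohortSpec

    def __post_init__(self) -> None:
        roster = self.genotypes.samples
        for other in (
            self.gene_expr.samples,
            self.mirna_expr.samples,
            self.phenotypes.samples,
        ):
            if other != roster:
                raise ConfigError(
                    "invariant violated: all matrices share an identical, "
                    "ordered sample roster"
                )
        for t in self.truth:
            if (
                t.snp_id not in self.genotypes.calls.columns
                or t.gene_id not in self.gene_expr.values.columns
                or t.mirna_id not in self.mirna_expr.values.columns
            ):
                raise ConfigError(
                    f"invariant violated: truth identities reference existing "
                    f"columns ({t})"
                )


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


def composite_snp_gene_slope(spec: CohortSpec) -> float:
    """Marginal standardized slope of a planted gene on its SNP's z-score.

    Direct path plus the indirect path through the (standardized) miRNA.
    """
    rho = spec.effect_qtl_mirna / np.sqrt(
        spec.effect_qtl_mirna**2 + spec.noise_sd**2
    )
    return float(spec.effect_qtl_gene + spec.effect_mirna_gene * rho)


def _pheno_median(conc: float) -> float:
    # percent-viable median falling linearly from 88% at 3 uM to 56% at 10 uM
    return 88.0 - (conc - 3.0) * (88.0 - 56.0) / 7.0


def _pheno_ln_sd(conc: float) -> float:
    # ln-scale spread grows with dose (0.10 at 3 uM to 0.30 at 10 uM)
    return 0.10 + (conc - 3.0) * (0.30 - 0.10) / 7.0


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort with ``spec.n_planted_triads`` planted causal chains."""
    spec.validate()
    n = spec.n_samples
    samples = [f"S{i+1:04d}" for i in range(n)]
    snp_ids = [f"snp{i+1:05d}" for i in range(spec.n_snps)]
    gene_ids = [f"gene{i+1:05d}" for i in range(spec.n_genes)]
    mirna_ids = [f"mir{i+1:04d}" for i in range(spec.n_mirnas)]

    g_rng = _rng(spec.seed, "genotypes")
    lo, hi = spec.maf_range
    maf = g_rng.uniform(lo, hi, size=spec.n_snps)
    geno = g_rng.binomial(2, maf[None, :], size=(n, spec.n_snps)).astype(float)

    sd = spec.noise_sd
    mirna = _rng(spec.seed, "mirna").standard_normal((n, spec.n_mirnas)) * sd
    gene = _rng(spec.seed, "gene").standard_normal((n, spec.n_genes)) * sd
    ph_rng = _rng(spec.seed, "pheno")
    n_conc = len(spec.concentrations)
    pheno_noise = ph_rng.standard_normal((n, n_conc)) * sd

    k = spec.n_planted_triads
    place = _rng(spec.seed, "placement")
    truth: list[PlantedTriad] = []
    signal = np.zeros((n, n_conc))  # planted structural phenotype signal
    if k > 0:
        snp_idx = place.choice(spec.n_snps, size=k, replace=False)
        gene_idx = place.choice(spec.n_genes, size=k, replace=False)
        mirna_idx = place.choice(spec.n_mirnas, size=k, replace=False)
        mir_sd = np.sqrt(spec.effect_qtl_mirna**2 + sd**2)
        rho = spec.effect_qtl_mirna / mir_sd
        gene_var = (
            spec.effect_qtl_gene**2
            + spec.effect_mirna_gene**2
            + 2.0 * spec.effect_qtl_gene * spec.effect_mirna_gene * rho
            + sd**2
        )
        ds = np.asarray(spec.resolved_dose_scaling())
        for si, gi, mi in zip(snp_idx, gene_idx, mirna_idx):
            f = maf[si]
            z = (geno[:, si] - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))
            mirna[:, mi] += spec.effect_qtl_mirna * z
            mir_std = mirna[:, mi] / mir_sd
            gene[:, gi] += (
                spec.effect_qtl_gene * z + spec.effect_mirna_gene * mir_std
            )
            gene_std = gene[:, gi] / np.sqrt(gene_var)
            signal += spec.effect_gene_pheno * np.outer(gene_std, ds)
            truth.append(
                PlantedTriad(snp_ids[si], mirna_ids[mi], gene_ids[gi])
            )

    # map the structural log-viability (signal + noise, population SD known
    # per dose) affinely onto a realistic ln-percent scale per concentration
    ds = np.asarray(spec.resolved_dose_scaling())
    raw = signal + pheno_noise
    raw_sd = np.sqrt((spec.effect_gene_pheno * ds) ** 2 * k + sd**2)
    log_pct = np.empty_like(raw)
    for j, conc in enumerate(spec.concentrations):
        log_pct[:, j] = (
            np.log(_pheno_median(conc))
            + _pheno_ln_sd(conc) * raw[:, j] / raw_sd[j]
        )
    percent = np.exp(log_pct)

    cohort = SyntheticCohort(
        genotypes=GenotypeMatrix(
            pd.DataFrame(geno, index=samples, columns=snp_ids)
        ),
        gene_expr=ExpressionMatrix(
            pd.DataFrame(gene, index=samples, columns=gene_ids)
        ),
        mirna_expr=ExpressionMatrix(
            pd.DataFrame(mirna, index=samples, columns=mirna_ids)
        ),
        phenotypes=PhenotypeTable(
            pd.DataFrame(
                percent, index=samples, columns=list(spec.concentrations)
            ),
            log_base="e",
        ),
        truth=truth,
        maf=pd.Series(maf, index=snp_ids, name="maf"),
        spec=spec,
    )
    return cohort


def generate_null_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Same marginal structure, zero planted effects, empty truth list."""
    null_spec = spec.replace(n_planted_triads=0)
    null_spec.validate()
    return generate_cohort(null_spec)
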