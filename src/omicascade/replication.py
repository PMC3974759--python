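"""Cross-cohort triage of discovered markers.

Three screens applied to cascade output against an independent cohort or
panel:

* **entity replication** — does a discovered gene/miRNA associate with the
  drug-sensitivity phenotype in the second cohort at p < 0.05 at *any*
  concentration (the replicating concentration is recorded per entity);
* **pair replication** — does a discovered negative gene-miRNA correlation
  hold in the second cohort with the same sign at the strict threshold
  (r < 0, p <= 1e-4);
* **allele-frequency screen** — SNPs whose coded-allele frequency differs by
  more than 0.30 (absolute) between the two cohorts are flagged as potential
  population-specific markers.  When per-SNP allele labels are supplied the
  screen detects swapped ref/alt coding (complement check) and harmonizes it,
  and excludes strand-ambiguous (A/T, C/G) SNPs whose labels disagree;
* **drug-response panel evaluation** — candidate-gene expression is
  correlated against -log10(GI50) across a cancer cell-line panel, pass at
  p < 0.05 (GI50 is stored raw; the transform is applied internally, so
  larger transformed values mean more drug-sensitive lines).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assoc import (
    AssociationRecord,
    ExpressionMatrix,
    GenotypeMatrix,
    fit_slope,
    pearson_with_sign,
)
from .errors import ValidationError
from .phenotyping import PhenotypeTable

__all__ = [
    "ReplicationReport",
    "FrequencyComparison",
    "replicate_entities",
    "replicate_negative_pairs",
    "allele_frequency_screen",
    "evaluate_vs_gi50",
]

logger = logging.getLogger("omicascade.replication")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class ReplicationReport:
    """Replication outcome for one candidate entity or pair."""

    entity_id: str
    entity_type: str  # gene | miRNA | SNP | pair
    discovery_p: float | None
    replication_p: float | None  # None => NS / missing
    replicated: bool
    concentration: float | None = None  # dose at which it replicated
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class FrequencyComparison:
    """Coded-allele frequency comparison for one SNP across two cohorts."""

    snp_id: str
    freq_cohort_a: float
    freq_cohort_b: float
    abs_diff: float
    flagged: bool
    flags: tuple[str, ...] = ()


def replicate_entities(
    candidates: Sequence[tuple[str, str]],
    expr_b: Mapping[str, ExpressionMatrix],
    pheno_b: PhenotypeTable,
    alpha: float = 0.05,
    discovery_p: Mapping[str, float] | None = None,
) -> list[ReplicationReport]:
    """Test each (id, type) candidate against every cohort-B phenotype.

    ``expr_b`` maps entity type ("gene", "miRNA") to the second cohort's
    expression matrix.  A candidate replicates if any concentration gives
    p < alpha; candidates absent from cohort B get a missing flag, not an
    error.
    """
    discovery_p = discovery_p or {}
    log_ph = pheno_b.log_pheno
    out: list[ReplicationReport] = []
    for entity_id, entity_type in candidates:
        if entity_type not in expr_b:
            raise ValidationError(f"no cohort-B matrix for {entity_type!r}")
        mat = expr_b[entity_type].values
        if entity_id not in mat.columns:
            out.append(
                ReplicationReport(
                    entity_id, entity_type,
                    discovery_p.get(entity_id), None, False,
                    flags=("missing_in_cohort_b",),
                )
            )
            continue
        x = mat[entity_id].to_numpy(dtype=float)
        best_p, best_conc = None, None
        for conc in pheno_b.concentrations:
            rec = fit_slope(
                x, log_ph[conc].to_numpy(dtype=float),
                x_id=entity_id, y_id=f"pheno@{conc}",
            )
            if best_p is None or rec.p < best_p:
                best_p, best_conc = rec.p, conc
        replicated = best_p is not None and best_p < alpha
        out.append(
            ReplicationReport(
                entity_id, entity_type,
                discovery_p.get(entity_id),
                best_p if replicated else None,
                replicated,
                concentration=best_conc if replicated else None,
            )
        )
    return out


def replicate_negative_pairs(
    pairs: Sequence[tuple[str, str]],
    gene_expr_b: ExpressionMatrix,
    mirna_expr_b: ExpressionMatrix,
    alpha_strict: float = 1e-4,
    discovery_p: Mapping[tuple[str, str], float] | None = None,
) -> list[ReplicationReport]:
    """Re-test (gene, miRNA) pairs in cohort B: pass iff r < 0, p <= alpha."""
    discovery_p = discovery_p or {}
    out: list[ReplicationReport] = []
    for gene, mirna in pairs:
        pair_id = f"{gene}~{mirna}"
        if (
            gene not in gene_expr_b.values.columns
            or mirna not in mirna_expr_b.values.columns
        ):
            out.append(
                ReplicationReport(
                    pair_id, "pair",
                    discovery_p.get((gene, mirna)), None, False,
                    flags=("missing_in_cohort_b",),
                )
            )
            continue
        rec = pearson_with_sign(
            gene_expr_b.values[gene].to_numpy(dtype=float),
            mirna_expr_b.values[mirna].to_numpy(dtype=float),
            required_sign="negative",
            x_id=gene, y_id=mirna, alpha=alpha_strict,
        )
        out.append(
            ReplicationReport(
                pair_id, "pair",
                discovery_p.get((gene, mirna)),
                rec.p if rec.passed else None,
                bool(rec.passed),
            )
        )
    return out


def _is_strand_ambiguous(ref: str, alt: str) -> bool:
    return _COMPLEMENT.get(ref.upper()) == alt.upper()


def allele_frequency_screen(
    genotypes_a: GenotypeMatrix,
    genotypes_b: GenotypeMatrix,
    snp_list: Sequence[str] | None = None,
    alleles_a: Mapping[str, tuple[str, str]] | None = None,
    alleles_b: Mapping[str, tuple[str, str]] | None = None,
    diff_threshold: float = 0.30,
) -> list[FrequencyComparison]:
    """Compare coded-allele frequencies of the same SNPs across two cohorts.

    Flags SNPs with absolute frequency difference > ``diff_threshold``
    (default 0.30).  When both cohorts supply (ref, alt) allele labels:
    a swapped ref/alt coding in cohort B is auto-harmonized (frequency
    complemented) with a warning; SNPs with mismatched labels that are
    strand-ambiguous (A/T or C/G) are excluded with a warning.  Symmetric in
    the two cohorts.
    """
    snps = list(
        snp_list
        if snp_list is not None
        else [s for s in genotypes_a.snp_ids if s in set(genotypes_b.snp_ids)]
    )
    freq_a = genotypes_a.allele_freq
    freq_b = genotypes_b.allele_freq
    out: list[FrequencyComparison] = []
    for snp in snps:
        if snp not in freq_a.index or snp not in freq_b.index:
            raise ValidationError(f"SNP {snp!r} absent from a cohort")
        fa = float(freq_a[snp])
        fb = float(freq_b[snp])
        flags: tuple[str, ...] = ()
        if alleles_a and alleles_b and snp in alleles_a and snp in alleles_b:
            ra, aa = (s.upper() for s in alleles_a[snp])
            rb, ab = (s.upper() for s in alleles_b[snp])
            if (ra, aa) != (rb, ab):
                if _is_strand_ambiguous(ra, aa) or _is_strand_ambiguous(rb, ab):
                    logger.warning(
                        "excluding strand-ambiguous SNP %s with mismatched "
                        "allele labels (%s/%s vs %s/%s)", snp, ra, aa, rb, ab,
                    )
                    continue
                if (ra, aa) == (ab, rb) or (ra, aa) == (
                    _COMPLEMENT.get(ab, "?"), _COMPLEMENT.get(rb, "?")
                ):
                    logger.warning(
                        "harmonizing swapped allele coding for SNP %s", snp
                    )
                    fb = 1.0 - fb
                    flags = ("harmonized_swap",)
                elif (ra, aa) == (
                    _COMPLEMENT.get(rb, "?"), _COMPLEMENT.get(ab, "?")
                ):
                    flags = ("strand_flip",)  # same coded allele, other strand
                else:
                    logger.warning(
                        "excluding SNP %s with irreconcilable alleles "
                        "(%s/%s vs %s/%s)", snp, ra, aa, rb, ab,
                    )
                    continue
        diff = abs(fa - fb)
        out.append(
            FrequencyComparison(
                snp_id=snp,
                freq_cohort_a=fa,
                freq_cohort_b=fb,
                abs_diff=diff,
                flagged=diff > diff_threshold,
                flags=flags,
            )
        )
    return out


def evaluate_vs_gi50(
    candidate_genes: Sequence[str],
    panel_expression: ExpressionMatrix,
    panel_gi50: pd.Series,
    alpha: float = 0.05,
) -> list[AssociationRecord]:
    """Correlate candidate-gene expression with -log10(GI50) across a panel.

    ``panel_gi50`` holds raw (molar) GI50 per cell line; lines missing from
    either input are dropped listwise per the shared roster.
    """
    if np.any(panel_gi50.to_numpy(dtype=float) <= 0):
        raise ValidationError("GI50 values must be positive (molar)")
    roster = [s for s in panel_expression.samples if s in panel_gi50.index]
    if len(roster) < 3:
        raise ValidationError(
            "fewer than 3 cell lines shared between expression and GI50"
        )
    y = -np.log10(panel_gi50.loc[roster].to_numpy(dtype=float))
    out: list[AssociationRecord] = []
    for gene in candidate_genes:
        if gene not in panel_expression.values.columns:
            raise ValidationError(f"gene {gene!r} absent from panel expression")
        x = panel_expression.values.loc[roster, gene].to_numpy(dtype=float)
        out.append(
            pearson_with_sign(
                x, y, "any", x_id=gene, y_id="-log10(GI50)",
                step_label="GI50", alpha=alpha,
            )
        )
    return out
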