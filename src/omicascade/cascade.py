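"""Six-step sequential association cascade and triad assembly.

Per treatment concentration, entirely independently:

1. gene expression vs log-viability, keep genes with p < alpha_loose;
2. miRNA expression vs log-viability, keep miRNAs with p < alpha_loose;
3. every surviving (gene, miRNA) pair: Pearson correlation must be negative
   (repressive regulation) with p <= alpha_strict;
4. every SNP vs every step-3 gene (additive dosage model), p <= alpha_strict;
5. step-4 SNPs vs step-3 miRNAs, p < alpha_loose;
6. step-5 SNPs vs log-viability, p <= alpha_strict.

A (SNP, miRNA, gene) triad is reported when all six memberships hold
simultaneously at a concentration; triads are deduplicated across
concentrations for the unique summary.  Loose steps use strict inequality
(p < 0.05), strict steps non-strict (p <= 1e-4); an entity eliminated at an
earlier step never re-enters.

Step results are plain DataFrames of the *passing* tests (one row per test,
with n, beta/r, se, t, p), which keeps genome-wide scans memory-bounded and
makes every step unit-testable in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assoc import ExpressionMatrix, GenotypeMatrix, bulk_pearson, bulk_slope
from .errors import AlignmentError, ConfigError
from .phenotyping import PhenotypeTable

__all__ = [
    "CascadeConfig",
    "Triad",
    "CascadeResult",
    "step1_pheno_gene",
    "step2_pheno_mirna",
    "step3_negative_pairs",
    "step4_snp_gene",
    "step5_snp_mirna",
    "step6_snp_pheno",
    "assemble_triads",
    "join_triads",
    "summarize_unique",
    "run_cascade",
    "triads_frame",
]


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds of the cascade.

    ``alpha_loose`` gates steps 1, 2 and 5 (strict inequality);
    ``alpha_strict`` gates steps 3, 4 and 6 (non-strict inequality).
    ``maf_floor`` optionally drops SNPs whose minor-allele frequency is below
    the floor before steps 4-6 (default 0: no filter).
    """

    alpha_loose: float = 0.05
    alpha_strict: float = 1e-4
    concentrations: tuple[float, ...] | None = None
    maf_floor: float = 0.0

    def validate(self) -> None:
        if not (0.0 < self.alpha_strict <= self.alpha_loose < 1.0):
            raise ConfigError(
                "invariant violated: 0 < alpha_strict <= alpha_loose < 1"
            )
        if not (0.0 <= self.maf_floor < 0.5):
            raise ConfigError("invariant violated: 0 <= maf_floor < 0.5")


@dataclass(frozen=True)
class Triad:
    """One final (SNP, miRNA, gene) association at one concentration."""

    snp_id: str
    mirna_id: str
    gene_id: str
    concentration: float
    p_s1: float
    p_s2: float
    p_s3: float
    p_s4: float
    p_s5: float
    p_s6: float
    r_s3: float

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.snp_id, self.mirna_id, self.gene_id)


@dataclass
class CascadeResult:
    steps: dict[str, pd.DataFrame]  # "S1".."S6" -> passing records
    triads: list[Triad]
    unique_summary: dict[str, int]
    step_counts: pd.DataFrame  # per-concentration entity counts per step


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _check_same_roster(a: Sequence[str], b: Sequence[str], what: str) -> None:
    if set(a) != set(b):
        diff = sorted(set(a) ^ set(b))
        raise AlignmentError(f"sample rosters differ for {what}: {diff}")


def _aligned_values(
    df: pd.DataFrame, roster: Sequence[str], what: str
) -> np.ndarray:
    _check_same_roster(df.index, roster, what)
    return df.reindex(index=list(roster)).to_numpy(dtype=float)


def _concs(cfg: CascadeConfig, pheno: PhenotypeTable) -> list[float]:
    if cfg.concentrations is None:
        return pheno.concentrations
    missing = set(cfg.concentrations) - set(pheno.concentrations)
    if missing:
        raise ConfigError(
            f"configured concentrations absent from phenotype table: "
            f"{sorted(missing)}"
        )
    return [float(c) for c in cfg.concentrations]


# ---------------------------------------------------------------------------
# steps 1-2: phenotype vs expression
# ---------------------------------------------------------------------------

_EXPR_COLS = ["concentration", "feature_id", "n", "beta", "se", "t", "p"]


def _step_expr_vs_pheno(
    pheno: PhenotypeTable,
    expr: ExpressionMatrix,
    cfg: CascadeConfig,
    what: str,
) -> pd.DataFrame:
    cfg.validate()
    roster = pheno.samples
    X = _aligned_values(expr.values, roster, what)
    log_ph = pheno.log_pheno
    rows = []
    for conc in _concs(cfg, pheno):
        y = log_ph[conc].to_numpy(dtype=float)
        res = bulk_slope(X, y)
        keep = (res["p"] < cfg.alpha_loose) & ~res["degenerate"]
        idx = np.flatnonzero(keep)
        if idx.size:
            rows.append(
                pd.DataFrame(
                    {
                        "concentration": conc,
                        "feature_id": np.asarray(expr.feature_ids)[idx],
                        "n": res["n"][idx],
                        "beta": res["beta"][idx],
                        "se": res["se"][idx],
                        "t": res["t"][idx],
                        "p": res["p"][idx],
                    }
                )
            )
    if not rows:
        return pd.DataFrame(columns=_EXPR_COLS)
    return pd.concat(rows, ignore_index=True)


def step1_pheno_gene(
    pheno: PhenotypeTable, genes: ExpressionMatrix, cfg: CascadeConfig
) -> pd.DataFrame:
    """Genes whose expression associates with log-viability (p < alpha_loose)."""
    return _step_expr_vs_pheno(pheno, genes, cfg, "gene expression")


def step2_pheno_mirna(
    pheno: PhenotypeTable, mirnas: ExpressionMatrix, cfg: CascadeConfig
) -> pd.DataFrame:
    """miRNAs whose expression associates with log-viability (p < alpha_loose)."""
    return _step_expr_vs_pheno(pheno, mirnas, cfg, "miRNA expression")


# ---------------------------------------------------------------------------
# step 3: negative gene-miRNA correlation
# ---------------------------------------------------------------------------

def step3_negative_pairs(
    s1: pd.DataFrame,
    s2: pd.DataFrame,
    gene_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    cfg: CascadeConfig,
) -> pd.DataFrame:
    """(gene, miRNA) pairs with r < 0 and p <= alpha_strict, per concentration."""
    cfg.validate()
    _check_same_roster(
        gene_expr.values.index, mirna_expr.values.index, "gene vs miRNA"
    )
    roster = gene_expr.samples
    rows = []
    concs = sorted(set(s1["concentration"]) & set(s2["concentration"]))
    for conc in concs:
        genes = sorted(s1.loc[s1["concentration"] == conc, "feature_id"])
        mirnas = sorted(s2.loc[s2["concentration"] == conc, "feature_id"])
        if not genes or not mirnas:
            continue
        A = gene_expr.values.loc[roster, genes].to_numpy(dtype=float)
        B = mirna_expr.values.loc[roster, mirnas].to_numpy(dtype=float)
        res = bulk_pearson(A, B)
        keep = (
            (res["r"] < 0.0)
            & (res["p"] <= cfg.alpha_strict)
            & ~res["degenerate"]
        )
        gi, mi = np.nonzero(keep)
        if gi.size:
            rows.append(
                pd.DataFrame(
                    {
                        "concentration": conc,
                        "gene_id": np.asarray(genes)[gi],
                        "mirna_id": np.asarray(mirnas)[mi],
                        "n": res["n"][gi, mi],
                        "r": res["r"][gi, mi],
                        "p": res["p"][gi, mi],
                    }
                )
            )
    cols = ["concentration", "gene_id", "mirna_id", "n", "r", "p"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# steps 4-6: genotype associations (additive model)
# ---------------------------------------------------------------------------

def _snp_pool(genotypes: GenotypeMatrix, cfg: CascadeConfig) -> list[str]:
    if cfg.maf_floor <= 0.0:
        return genotypes.snp_ids
    freq = genotypes.allele_freq
    maf = np.minimum(freq, 1.0 - freq)
    return list(freq.index[maf >= cfg.maf_floor])


def _snp_scan(
    genotypes: GenotypeMatrix,
    snp_ids: Sequence[str],
    targets: Mapping[str, np.ndarray],
    alpha: float,
    strict: bool,
    conc: float,
    target_col: str,
) -> pd.DataFrame:
    """Regress each target vector on each SNP dosage; keep passing pairs."""
    G = genotypes.calls.loc[:, list(snp_ids)].to_numpy(dtype=float)
    rows = []
    for target_id, y in targets.items():
        res = bulk_slope(G, y)
        passed = (
            (res["p"] <= alpha) if strict else (res["p"] < alpha)
        ) & ~res["degenerate"]
        idx = np.flatnonzero(passed)
        if idx.size:
            rows.append(
                pd.DataFrame(
                    {
                        "concentration": conc,
                        "snp_id": np.asarray(snp_ids)[idx],
                        target_col: target_id,
                        "n": res["n"][idx],
                        "beta": res["beta"][idx],
                        "se": res["se"][idx],
                        "t": res["t"][idx],
                        "p": res["p"][idx],
                    }
                )
            )
    cols = ["concentration", "snp_id", target_col, "n", "beta", "se", "t", "p"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.concat(rows, ignore_index=True)


def step4_snp_gene(
    s3: pd.DataFrame,
    gene_expr: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    cfg: CascadeConfig,
) -> pd.DataFrame:
    """(SNP, gene) eQTL pairs at p <= alpha_strict for step-3 survivor genes."""
    cfg.validate()
    roster = genotypes.samples
    _check_same_roster(gene_expr.values.index, roster, "genotype vs gene")
    pool = _snp_pool(genotypes, cfg)
    out = []
    for conc in sorted(set(s3["concentration"])):
        genes = sorted(set(s3.loc[s3["concentration"] == conc, "gene_id"]))
        targets = {
            g: gene_expr.values.loc[roster, g].to_numpy(dtype=float)
            for g in genes
        }
        out.append(
            _snp_scan(
                genotypes, pool, targets, cfg.alpha_strict, True, conc,
                "gene_id",
            )
        )
    cols = ["concentration", "snp_id", "gene_id", "n", "beta", "se", "t", "p"]
    out = [df for df in out if len(df)]
    if not out:
        return pd.DataFrame(columns=cols)
    return pd.concat(out, ignore_index=True)


def step5_snp_mirna(
    s4: pd.DataFrame,
    s3: pd.DataFrame,
    mirna_expr: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    cfg: CascadeConfig,
) -> pd.DataFrame:
    """Step-4 SNPs vs step-3 miRNAs at p < alpha_loose."""
    cfg.validate()
    roster = genotypes.samples
    _check_same_roster(mirna_expr.values.index, roster, "genotype vs miRNA")
    out = []
    for conc in sorted(set(s4["concentration"])):
        snps = sorted(set(s4.loc[s4["concentration"] == conc, "snp_id"]))
        mirnas = sorted(set(s3.loc[s3["concentration"] == conc, "mirna_id"]))
        if not snps or not mirnas:
            continue
        targets = {
            m: mirna_expr.values.loc[roster, m].to_numpy(dtype=float)
            for m in mirnas
        }
        out.append(
            _snp_scan(
                genotypes, snps, targets, cfg.alpha_loose, False, conc,
                "mirna_id",
            )
        )
    cols = ["concentration", "snp_id", "mirna_id", "n", "beta", "se", "t", "p"]
    out = [df for df in out if len(df)]
    if not out:
        return pd.DataFrame(columns=cols)
    return pd.concat(out, ignore_index=True)


def step6_snp_pheno(
    s5: pd.DataFrame,
    genotypes: GenotypeMatrix,
    pheno: PhenotypeTable,
    cfg: CascadeConfig,
) -> pd.DataFrame:
    """Step-5 SNPs vs log-viability at p <= alpha_strict (additive GWAS)."""
    cfg.validate()
    roster = genotypes.samples
    _check_same_roster(pheno.percent_viable.index, roster, "genotype vs pheno")
    log_ph = pheno.log_pheno
    out = []
    for conc in sorted(set(s5["concentration"])):
        snps = sorted(set(s5.loc[s5["concentration"] == conc, "snp_id"]))
        if not snps:
            continue
        y = log_ph.loc[roster, conc].to_numpy(dtype=float)
        out.append(
            _snp_scan(
                genotypes, snps, {"log_pheno": y}, cfg.alpha_strict, True,
                conc, "target",
            ).drop(columns=["target"])
        )
    cols = ["concentration", "snp_id", "n", "beta", "se", "t", "p"]
    out = [df for df in out if len(df)]
    if not out:
        return pd.DataFrame(columns=cols)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# triad assembly
# ---------------------------------------------------------------------------

def join_triads(
    concentration: float,
    genes_s1: Mapping[str, float],
    mirnas_s2: Mapping[str, float],
    pairs_s3: Mapping[tuple[str, str], tuple[float, float]],
    pairs_s4: Mapping[tuple[str, str], float],
    pairs_s5: Mapping[tuple[str, str], float],
    snps_s6: Mapping[str, float],
) -> list[Triad]:
    """Join the six survivor structures into triads for one concentration.

    ``pairs_s3`` maps (gene, miRNA) -> (r, p); the other pair mappings map to
    p.  A triad requires all six memberships simultaneously.
    """
    by_snp_mirnas: dict[str, list[str]] = {}
    for (snp, mirna) in pairs_s5:
        by_snp_mirnas.setdefault(snp, []).append(mirna)
    triads: list[Triad] = []
    for (snp, gene), p4 in pairs_s4.items():
        if snp not in snps_s6 or gene not in genes_s1:
            continue
        for mirna in by_snp_mirnas.get(snp, ()):
            if mirna not in mirnas_s2 or (gene, mirna) not in pairs_s3:
                continue
            r3, p3 = pairs_s3[(gene, mirna)]
            triads.append(
                Triad(
                    snp_id=snp,
                    mirna_id=mirna,
                    gene_id=gene,
                    concentration=float(concentration),
                    p_s1=genes_s1[gene],
                    p_s2=mirnas_s2[mirna],
                    p_s3=p3,
                    p_s4=p4,
                    p_s5=pairs_s5[(snp, mirna)],
                    p_s6=snps_s6[snp],
                    r_s3=r3,
                )
            )
    triads.sort(key=lambda t: (t.concentration, t.key))
    return triads


def assemble_triads(
    s1: pd.DataFrame,
    s2: pd.DataFrame,
    s3: pd.DataFrame,
    s4: pd.DataFrame,
    s5: pd.DataFrame,
    s6: pd.DataFrame,
    cfg: CascadeConfig | None = None,
) -> list[Triad]:
    """Assemble triads from the six step outputs, per concentration."""
    triads: list[Triad] = []
    concs = sorted(set(s6["concentration"])) if len(s6) else []
    for conc in concs:
        sel = lambda df: df[df["concentration"] == conc]  # noqa: E731
        triads.extend(
            join_triads(
                conc,
                dict(zip(sel(s1)["feature_id"], sel(s1)["p"])),
                dict(zip(sel(s2)["feature_id"], sel(s2)["p"])),
                {
                    (g, m): (r, p)
                    for g, m, r, p in zip(
                        sel(s3)["gene_id"], sel(s3)["mirna_id"],
                        sel(s3)["r"], sel(s3)["p"],
                    )
                },
                dict(
                    zip(
                        zip(sel(s4)["snp_id"], sel(s4)["gene_id"]),
                        sel(s4)["p"],
                    )
                ),
                dict(
                    zip(
                        zip(sel(s5)["snp_id"], sel(s5)["mirna_id"]),
                        sel(s5)["p"],
                    )
                ),
                dict(zip(sel(s6)["snp_id"], sel(s6)["p"])),
            )
        )
    return triads


def summarize_unique(triads: Sequence[Triad]) -> dict[str, int]:
    """Deduplicate triads by (SNP, miRNA, gene) across concentrations."""
    keys = {t.key for t in triads}
    return {
        "n_unique_triads": len(keys),
        "n_snps": len({k[0] for k in keys}),
        "n_mirnas": len({k[1] for k in keys}),
        "n_genes": len({k[2] for k in keys}),
    }


def triads_frame(triads: Sequence[Triad]) -> pd.DataFrame:
    """Triad list as a table, one row per triad with all six step p-values."""
    cols = [
        "snp_id", "mirna_id", "gene_id", "concentration",
        "p_s1", "p_s2", "p_s3", "p_s4", "p_s5", "p_s6", "r_s3",
    ]
    return pd.DataFrame(
        [{c: getattr(t, c) for c in cols} for t in triads], columns=cols
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _step_counts(
    steps: dict[str, pd.DataFrame],
    triads: Sequence[Triad],
    concs: Sequence[float],
) -> pd.DataFrame:
    rows = []
    for conc in concs:
        sel = {
            k: df[df["concentration"] == conc] for k, df in steps.items()
        }
        tri = [t for t in triads if t.concentration == conc]
        rows.append(
            {
                "concentration": conc,
                "s1_genes": sel["S1"]["feature_id"].nunique(),
                "s2_mirnas": sel["S2"]["feature_id"].nunique(),
                "s3_genes": sel["S3"]["gene_id"].nunique(),
                "s3_mirnas": sel["S3"]["mirna_id"].nunique(),
                "s4_genes": sel["S4"]["gene_id"].nunique(),
                "s4_snps": sel["S4"]["snp_id"].nunique(),
                "s5_snps": sel["S5"]["snp_id"].nunique(),
                "s5_mirnas": sel["S5"]["mirna_id"].nunique(),
                "s6_snps": sel["S6"]["snp_id"].nunique(),
                "final_triads": len(tri),
                "final_snps": len({t.snp_id for t in tri}),
                "final_mirnas": len({t.mirna_id for t in tri}),
                "final_genes": len({t.gene_id for t in tri}),
            }
        )
    return pd.DataFrame(rows)


def run_cascade(
    genotypes: GenotypeMatrix,
    gene_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    pheno: PhenotypeTable,
    cfg: CascadeConfig | None = None,
) -> CascadeResult:
    """Run all six steps and assemble triads, one concentration at a time.

    Matrices are aligned to the genotype matrix's sample order by identifier
    before any statistics are computed; a roster set mismatch raises
    :class:`~omicascade.errors.AlignmentError`.
    """
    cfg = cfg or CascadeConfig()
    cfg.validate()
    roster = genotypes.samples
    gene_expr = ExpressionMatrix(
        gene_expr.values.reindex(
            index=_roster_checked(gene_expr.values.index, roster, "genes")
        )
    )
    mirna_expr = ExpressionMatrix(
        mirna_expr.values.reindex(
            index=_roster_checked(mirna_expr.values.index, roster, "miRNAs")
        )
    )
    pheno = PhenotypeTable(
        pheno.percent_viable.reindex(
            index=_roster_checked(
                pheno.percent_viable.index, roster, "phenotypes"
            )
        ),
        log_base=pheno.log_base,
    )

    s1 = step1_pheno_gene(pheno, gene_expr, cfg)
    s2 = step2_pheno_mirna(pheno, mirna_expr, cfg)
    s3 = step3_negative_pairs(s1, s2, gene_expr, mirna_expr, cfg)
    s4 = step4_snp_gene(s3, gene_expr, genotypes, cfg)
    s5 = step5_snp_mirna(s4, s3, mirna_expr, genotypes, cfg)
    s6 = step6_snp_pheno(s5, genotypes, pheno, cfg)
    triads = assemble_triads(s1, s2, s3, s4, s5, s6, cfg)
    steps = {"S1": s1, "S2": s2, "S3": s3, "S4": s4, "S5": s5, "S6": s6}
    return CascadeResult(
        steps=steps,
        triads=triads,
        unique_summary=summarize_unique(triads),
        step_counts=_step_counts(steps, triads, _concs(cfg, pheno)),
    )


def _roster_checked(
    have: Sequence[str], roster: Sequence[str], what: str
) -> list[str]:
    _check_same_roster(have, roster, what)
    return list(roster)
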