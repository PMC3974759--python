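"""File formats, run configuration, and the end-to-end pipeline.

Canonical on-disk dialect is TSV (tab-separated, header row, first column the
sample id); genotypes may alternatively be ingested from a minimal VCF (GT
field only).  Every file this package writes starts with ``#``-prefixed
provenance lines (package version, config hash, seed) that all readers skip.
P-values are written in scientific notation with 6 significant digits;
comparisons are always performed on full-precision in-memory values.

:func:`run_pipeline` ties simulate -> cascade -> replicate together, writes a
machine-readable manifest (JSON, with a sha256 checksum per output), and is
byte-for-byte reproducible for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import ExpressionMatrix, GenotypeMatrix
from .cascade import CascadeConfig, run_cascade, triads_frame
from .errors import AlignmentError, ConfigError, ParseError
from .phenotyping import PhenotypeTable, PlateReadings, build_phenotype_table
from .replication import (
    allele_frequency_screen,
    replicate_entities,
    replicate_negative_pairs,
)
from .synthetic import CohortSpec, SyntheticCohort, generate_cohort

__all__ = [
    "read_genotype_table",
    "write_genotype_table",
    "write_genotype_vcf",
    "read_expression_table",
    "write_expression_table",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_plate_readings",
    "write_cohort",
    "RunConfig",
    "load_run_config",
    "run_pipeline",
]

logger = logging.getLogger("omicascade.io")

_GT_TOKENS = {"0": 0.0, "1": 1.0, "2": 2.0, "NA": np.nan, "": np.nan}
_FLOAT_FMT = "%.10g"  # data matrices: full practical precision
_PVAL_FMT = "%.6g"  # statistic/record tables: 6 significant digits


# ---------------------------------------------------------------------------
# provenance headers
# ---------------------------------------------------------------------------

def _provenance(meta: Mapping[str, object] | None) -> str:
    lines = [f"# omicascade_version={__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}={v}")
    return "\n".join(lines) + "\n"


def _write_table(
    df: pd.DataFrame,
    path: Path,
    meta: Mapping[str, object] | None,
    float_format: str = _FLOAT_FMT,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance(meta))
        df.to_csv(fh, sep="\t", float_format=float_format, lineterminator="\n")


def _check_header_duplicates(path: Path, what: str) -> None:
    # pandas mangles duplicate column names on read; inspect the raw header
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")[1:]
            seen: set[str] = set()
            for c in cols:
                if c in seen:
                    raise ParseError(f"{path}: duplicate {what} id {c!r}")
                seen.add(c)
            return


def _read_raw(path: Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype=str, comment="#", index_col=0,
        keep_default_na=False,
    )


def _header_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotype_table(path: str | Path) -> GenotypeMatrix:
    """Read genotypes from TSV (cells 0/1/2/NA) or minimal VCF (by suffix)."""
    path = Path(path)
    if path.suffix.lower() in (".vcf", ".gz", ".bcf"):
        return _read_genotype_vcf(path)
    _check_header_duplicates(path, "SNP")
    raw = _read_raw(path)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    vals = np.empty(raw.shape, dtype=float)
    arr = raw.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            tok = str(arr[i, j]).strip()
            if tok not in _GT_TOKENS:
                raise ParseError(
                    f"{path}: row {raw.index[i]!r}, column "
                    f"{raw.columns[j]!r}: invalid genotype {tok!r}"
                )
            vals[i, j] = _GT_TOKENS[tok]
    return GenotypeMatrix(
        pd.DataFrame(vals, index=raw.index, columns=raw.columns)
    )


def _read_genotype_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF  # GT-only ingestion; optional heavy import

    vcf = VCF(str(path), gts012=True)  # gt_types: 0/1/2 dosage, 3 = missing
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    cols: list[np.ndarray] = []
    for variant in vcf:
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        gt = variant.gt_types.astype(float)
        gt[gt == 3] = np.nan
        snp_ids.append(vid)
        cols.append(gt)
    vcf.close()
    if not snp_ids:
        raise ParseError(f"{path}: no variants found")
    mat = np.column_stack(cols)
    return GenotypeMatrix(pd.DataFrame(mat, index=samples, columns=snp_ids))


def write_genotype_table(
    genotypes: GenotypeMatrix,
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    df = genotypes.calls.copy()
    out = df.astype(object)
    for col in out.columns:
        vals = df[col]
        out[col] = np.where(
            vals.isna(), "NA", vals.fillna(0).astype(int).astype(str)
        )
    out.index.name = "sample_id"
    _write_table(out, Path(path), meta)


def write_genotype_vcf(
    genotypes: GenotypeMatrix, path: str | Path
) -> None:
    """Write a minimal GT-only unphased VCF (synthetic coordinates)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        calls = genotypes.calls
        for j, snp in enumerate(genotypes.snp_ids):
            gts = [
                gt_map.get(v, "./.") if np.isfinite(v) else "./."
                for v in calls[snp].to_numpy(dtype=float)
            ]
            fh.write(
                f"1\t{j + 1}\t{snp}\tA\tG\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# expression / phenotypes
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a samples x features TSV; blank cells become missing."""
    path = Path(path)
    raw = _read_raw(path)
    vals = np.empty(raw.shape, dtype=float)
    arr = raw.to_numpy()
    for j in range(raw.shape[1]):
        for i in range(raw.shape[0]):
            tok = str(arr[i, j]).strip()
            if tok in ("", "NA"):
                vals[i, j] = np.nan
                continue
            try:
                vals[i, j] = float(tok)
            except ValueError:
                raise ParseError(
                    f"{path}: row {raw.index[i]!r}, column "
                    f"{raw.columns[j]!r}: non-numeric value {tok!r}"
                ) from None
    return ExpressionMatrix(
        pd.DataFrame(vals, index=raw.index, columns=raw.columns)
    )


def write_expression_table(
    expr: ExpressionMatrix,
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    df = expr.values.copy()
    df.index.name = "sample_id"
    _write_table(df, Path(path), meta)


def read_phenotype_table(path: str | Path) -> PhenotypeTable:
    """Read a percent-viable table; the log base is read from the header."""
    path = Path(path)
    meta = _header_meta(path)
    raw = _read_raw(path)
    vals = np.empty(raw.shape, dtype=float)
    arr = raw.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            tok = str(arr[i, j]).strip()
            try:
                vals[i, j] = np.nan if tok in ("", "NA") else float(tok)
            except ValueError:
                raise ParseError(
                    f"{path}: row {raw.index[i]!r}, column "
                    f"{raw.columns[j]!r}: non-numeric value {tok!r}"
                ) from None
    cols = [float(c) for c in raw.columns]
    return PhenotypeTable(
        pd.DataFrame(vals, index=raw.index, columns=cols),
        log_base=meta.get("log_base", "e"),
    )


def write_phenotype_table(
    pheno: PhenotypeTable,
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    df = pheno.percent_viable.copy()
    df.index.name = "sample_id"
    full_meta = {"log_base": pheno.log_base}
    full_meta.update(meta or {})
    _write_table(df, Path(path), full_meta)


def read_plate_readings(path: str | Path) -> list[PlateReadings]:
    """Read long-format raw wells: sample_id, concentration, well_type, value."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "concentration", "well_type", "value"}
    if not required <= set(df.columns):
        raise ParseError(
            f"{path}: expected columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    bad = ~df["well_type"].isin(["treated", "control"])
    if bad.any():
        row = df.index[bad][0]
        raise ParseError(
            f"{path}: row {row}: well_type must be treated|control, "
            f"got {df.loc[row, 'well_type']!r}"
        )
    out = []
    for (sample, conc), grp in df.groupby(
        ["sample_id", "concentration"], sort=True
    ):
        out.append(
            PlateReadings(
                sample_id=str(sample),
                concentration=float(conc),
                treated_values=tuple(
                    grp.loc[grp["well_type"] == "treated", "value"].astype(float)
                ),
                control_values=tuple(
                    grp.loc[grp["well_type"] == "control", "value"].astype(float)
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# cohort writing
# ---------------------------------------------------------------------------

def write_cohort(
    cohort: SyntheticCohort,
    out_dir: str | Path,
    meta: Mapping[str, object] | None = None,
    vcf: bool = False,
) -> dict[str, Path]:
    """Write all cohort tables (and truth) as TSV; optionally genotypes as VCF."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out_dir / "genotypes.tsv",
        "gene_expr": out_dir / "gene_expression.tsv",
        "mirna_expr": out_dir / "mirna_expression.tsv",
        "phenotypes": out_dir / "phenotypes.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_genotype_table(cohort.genotypes, paths["genotypes"], meta)
    write_expression_table(cohort.gene_expr, paths["gene_expr"], meta)
    write_expression_table(cohort.mirna_expr, paths["mirna_expr"], meta)
    write_phenotype_table(cohort.phenotypes, paths["phenotypes"], meta)
    truth = pd.DataFrame(
        [(t.snp_id, t.mirna_id, t.gene_id) for t in cohort.truth],
        columns=["snp_id", "mirna_id", "gene_id"],
    ).set_index("snp_id")
    _write_table(truth, paths["truth"], meta)
    if vcf:
        paths["genotypes_vcf"] = out_dir / "genotypes.vcf"
        write_genotype_vcf(cohort.genotypes, paths["genotypes_vcf"])
    return paths


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs.

    Either ``simulate`` is set (a cohort is generated) or the four input
    paths are; ``replication`` optionally points at a second cohort's files.
    """

    seed: int = 0
    log_level: str = "INFO"
    simulate: CohortSpec | None = None
    genotypes: str | None = None
    genes: str | None = None
    mirnas: str | None = None
    phenotypes: str | None = None
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    replication: dict[str, str] | None = None
    write_vcf: bool = False

    def validate(self) -> None:
        self.cascade.validate()
        if self.simulate is not None:
            self.simulate.validate()
        else:
            for name in ("genotypes", "genes", "mirnas", "phenotypes"):
                p = getattr(self, name)
                if p is None:
                    raise ConfigError(
                        f"invariant violated: {name} path required when not "
                        "simulating"
                    )
                if not Path(p).exists():
                    raise ConfigError(f"input path does not exist: {p}")
        if self.replication is not None:
            for key in ("genotypes_b", "genes_b", "mirnas_b", "phenotypes_b"):
                p = self.replication.get(key)
                if p is None or not Path(p).exists():
                    raise ConfigError(
                        f"replication input missing or absent: {key}={p}"
                    )

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "log_level": self.log_level,
            "simulate": (
                dataclasses.asdict(self.simulate) if self.simulate else None
            ),
            "genotypes": self.genotypes,
            "genes": self.genes,
            "mirnas": self.mirnas,
            "phenotypes": self.phenotypes,
            "cascade": dataclasses.asdict(self.cascade),
            "replication": self.replication,
            "write_vcf": self.write_vcf,
        }
        return d

    def sha256(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML (or JSON, a YAML subset)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    sim = data.pop("simulate", None)
    casc = data.pop("cascade", {})
    cfg = RunConfig(
        simulate=CohortSpec(**sim) if sim else None,
        cascade=CascadeConfig(
            **{
                k: (tuple(v) if isinstance(v, list) else v)
                for k, v in casc.items()
            }
        ),
        **data,
    )
    return cfg


def load_cohort_spec(path: str | Path) -> CohortSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    try:
        return CohortSpec(**data)
    except TypeError as exc:
        raise ConfigError(f"bad cohort spec {path}: {exc}") from None


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all configured stages; write outputs, run log and manifest.

    Returns the manifest dict.  On stage failure the manifest is still
    written with a FAILED marker and the exception re-raised.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"config_sha256": config.sha256(), "seed": config.seed}
    manifest: dict = {
        "omicascade_version": __version__,
        "config_sha256": config.sha256(),
        "seed": config.seed,
        "status": "ok",
        "outputs": {},
    }
    written: list[Path] = []

    def emit(path: Path) -> None:
        written.append(path)

    stage = "setup"
    try:
        # ---- inputs -------------------------------------------------------
        if config.simulate is not None:
            stage = "simulate"
            logger.info("simulating cohort (seed=%d)", config.seed)
            spec = config.simulate.replace(seed=config.seed)
            cohort = generate_cohort(spec)
            paths = write_cohort(
                cohort, out_dir / "simulated", meta, vcf=config.write_vcf
            )
            for p in paths.values():
                emit(p)
            genotypes, gene_expr = cohort.genotypes, cohort.gene_expr
            mirna_expr, pheno = cohort.mirna_expr, cohort.phenotypes
        else:
            stage = "load"
            genotypes = read_genotype_table(config.genotypes)
            gene_expr = read_expression_table(config.genes)
            mirna_expr = read_expression_table(config.mirnas)
            pheno = read_phenotype_table(config.phenotypes)

        # ---- cascade ------------------------------------------------------
        stage = "cascade"
        logger.info("running 6-step cascade")
        result = run_cascade(
            genotypes, gene_expr, mirna_expr, pheno, config.cascade
        )
        for label, df in result.steps.items():
            p = out_dir / f"step_{label}.tsv"
            _write_table(df.set_index(df.columns[0]), p, meta, _PVAL_FMT)
            emit(p)
        p = out_dir / "triads.tsv"
        tf = triads_frame(result.triads)
        _write_table(tf.set_index("snp_id") if len(tf) else tf, p, meta, _PVAL_FMT)
        emit(p)
        p = out_dir / "unique_summary.json"
        p.write_text(
            json.dumps(result.unique_summary, indent=2, sort_keys=True) + "\n"
        )
        emit(p)
        p = out_dir / "step_counts.tsv"
        _write_table(result.step_counts.set_index("concentration"), p, meta)
        emit(p)

        # ---- replication --------------------------------------------------
        if config.replication is not None:
            stage = "replicate"
            logger.info("replicating against cohort B")
            rep = config.replication
            geno_b = read_genotype_table(rep["genotypes_b"])
            genes_b = read_expression_table(rep["genes_b"])
            mirnas_b = read_expression_table(rep["mirnas_b"])
            pheno_b = read_phenotype_table(rep["phenotypes_b"])
            tri = result.triads
            cands = sorted({(t.gene_id, "gene") for t in tri}) + sorted(
                {(t.mirna_id, "miRNA") for t in tri}
            )
            ents = replicate_entities(
                cands, {"gene": genes_b, "miRNA": mirnas_b}, pheno_b,
                alpha=config.cascade.alpha_loose,
            )
            pairs = sorted({(t.gene_id, t.mirna_id) for t in tri})
            reps = replicate_negative_pairs(
                pairs, genes_b, mirnas_b,
                alpha_strict=config.cascade.alpha_strict,
            )
            freqs = allele_frequency_screen(
                genotypes, geno_b, sorted({t.snp_id for t in tri})
            )
            p = out_dir / "replication_entities.tsv"
            _write_table(
                pd.DataFrame([dataclasses.asdict(r) for r in ents]).set_index(
                    "entity_id"
                )
                if ents
                else pd.DataFrame(),
                p, meta,
            )
            emit(p)
            p = out_dir / "replication_pairs.tsv"
            _write_table(
                pd.DataFrame([dataclasses.asdict(r) for r in reps]).set_index(
                    "entity_id"
                )
                if reps
                else pd.DataFrame(),
                p, meta,
            )
            emit(p)
            p = out_dir / "frequency_screen.tsv"
            _write_table(
                pd.DataFrame([dataclasses.asdict(f) for f in freqs]).set_index(
                    "snp_id"
                )
                if freqs
                else pd.DataFrame(),
                p, meta,
            )
            emit(p)

        # ---- run log ------------------------------------------------------
        stage = "finalize"
        p = out_dir / "run.json"
        p.write_text(
            json.dumps(
                {
                    "omicascade_version": __version__,
                    "seed": config.seed,
                    "config": config.to_dict(),
                    "thresholds": {
                        "alpha_loose": config.cascade.alpha_loose,
                        "alpha_strict": config.cascade.alpha_strict,
                    },
                },
                indent=2,
                sort_keys=True,
                default=str,
            )
            + "\n"
        )
        emit(p)
    except Exception:
        manifest["status"] = "FAILED"
        manifest["failed_stage"] = stage
        manifest["outputs"] = {
            str(p.relative_to(out_dir)): _sha256_file(p)
            for p in written
            if p.exists()
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        raise

    manifest["outputs"] = {
        str(p.relative_to(out_dir)): _sha256_file(p) for p in written
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
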