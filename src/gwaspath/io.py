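"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as dosage VCF (FORMAT DS), as a MACH-style dosage TSV with
a companion SNP info table, or as PLINK bed/bim/fam hard calls. Gene
annotation is BED (0-based half-open on disk, converted to the internal
1-based inclusive convention on read); gene sets are GMT; summary
statistics, gene results and enrichment tables are TSV with fixed headers.
Every writer/reader pair round-trips its internal representation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from gwaspath.assoc import SUMMARY_COLUMNS
from gwaspath.types import GeneModel, GeneSetCollection, GenotypeMatrix, SnpInfo

GENE_RESULT_COLUMNS = ["gene_id", "chr", "start", "end", "n_snps", "stat", "p", "n_sims"]
ENRICHMENT_COLUMNS = [
    "set", "n_genes", "es", "nes", "p", "fdr_q",
    "frac_random_p", "frac_random_fdr", "validated",
]


def _parse_chrom(label: str):
    """Numeric chromosome where possible; unknown labels pass through."""
    s = str(label)
    if s.lower().startswith("chr"):
        s = s[3:]
    try:
        return int(s)
    except ValueError:
        return s


# ---------------------------------------------------------------- dosage TSV

def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Sample-by-SNP dosage matrix plus a companion ``.info.tsv`` SNP table."""
    path = Path(path)
    frame = pd.DataFrame(
        genotypes.dosages,
        index=pd.Index(genotypes.sample_ids, name="sample_id"),
        columns=genotypes.snp_ids,
    )
    frame.to_csv(path, sep="\t", float_format="%.6g", na_rep="NA")
    info = pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "chr": [s.chromosome for s in genotypes.snps],
            "pos": [s.position for s in genotypes.snps],
            "ref_allele": [s.ref_allele for s in genotypes.snps],
            "alt_allele": [s.alt_allele for s in genotypes.snps],
            "target_maf": [s.target_maf for s in genotypes.snps],
        }
    )
    info.to_csv(_info_path(path), sep="\t", index=False)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col="sample_id", na_values="NA")
    info = pd.read_csv(_info_path(path), sep="\t")
    snps = [
        SnpInfo(
            snp_id=str(r.snp_id),
            chromosome=_parse_chrom(r.chr),
            position=int(r.pos),
            ref_allele=str(r.ref_allele),
            alt_allele=str(r.alt_allele),
            target_maf=float(r.target_maf),
        )
        for r in info.itertuples()
    ]
    frame = frame[[s.snp_id for s in snps]]
    return GenotypeMatrix(
        [str(s) for s in frame.index], snps, frame.to_numpy(dtype=float)
    )


def _info_path(path: Path) -> Path:
    return path.with_name(path.name.removesuffix(".tsv") + ".info.tsv")


# ----------------------------------------------------------------------- VCF

def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Minimal dosage VCF: one DS value per sample, TMAF kept in INFO."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(s.chromosome for s in genotypes.snps):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=TMAF,Number=1,Type=Float,'
                 'Description="Target minor allele frequency">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Estimated alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.sample_ids) + "\n")
        for j, snp in enumerate(genotypes.snps):
            ds = [
                "." if np.isnan(d) else f"{d:.6g}"
                for d in genotypes.dosages[:, j]
            ]
            fh.write(
                f"{snp.chromosome}\t{snp.position}\t{snp.snp_id}\t"
                f"{snp.ref_allele}\t{snp.alt_allele}\t.\t.\t"
                f"TMAF={snp.target_maf:.6g}\tDS\t" + "\t".join(ds) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a dosage VCF via cyvcf2 (DS format field required)."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snps: list[SnpInfo] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        ds = np.where(ds < -0.5, np.nan, ds)  # cyvcf2 encodes '.' as negative fill
        tmaf = var.INFO.get("TMAF")
        freq = float(tmaf) if tmaf is not None else float(
            min(np.nanmean(ds) / 2.0, 1 - np.nanmean(ds) / 2.0) or 0.25
        )
        snps.append(
            SnpInfo(
                snp_id=var.ID or f"{var.CHROM}:{var.POS}",
                chromosome=_parse_chrom(var.CHROM),
                position=var.POS,
                ref_allele=var.REF,
                alt_allele=var.ALT[0] if var.ALT else "N",
                target_maf=max(freq, 1e-6),
            )
        )
        columns.append(ds)
    return GenotypeMatrix(sample_ids, snps, np.column_stack(columns))


# ------------------------------------------------------------ PLINK bed trio

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major
# 2-bit codes, alt allele as A1: 00 hom-alt, 10 het, 11 hom-ref, 01 missing
_CODE_FOR_ALT_COUNT = {2: 0b00, 1: 0b10, 0: 0b11}
_ALT_COUNT_FOR_CODE = {0b00: 2.0, 0b10: 1.0, 0b11: 0.0, 0b01: np.nan}


def write_plink(genotypes: GenotypeMatrix, prefix: str | Path) -> None:
    """Hard-call bed/bim/fam trio (dosages rounded to nearest genotype)."""
    prefix = Path(prefix)
    n = genotypes.n_samples
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for s in genotypes.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position}\t"
                     f"{s.alt_allele}\t{s.ref_allele}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in genotypes.sample_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        n_bytes = (n + 3) // 4
        for j in range(genotypes.n_snps):
            col = genotypes.dosages[:, j]
            buf = bytearray(n_bytes)
            for i in range(n):
                code = (
                    0b01 if np.isnan(col[i])
                    else _CODE_FOR_ALT_COUNT[int(round(col[i]))]
                )
                buf[i // 4] |= code << (2 * (i % 4))
            fh.write(bytes(buf))


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep="\t", header=None,
        names=["chr", "snp_id", "cm", "pos", "a1", "a2"],
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
    )
    sample_ids = fam["iid"].astype(str).tolist()
    n = len(sample_ids)
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "rb") as fh:
        if fh.read(3) != _BED_MAGIC:
            raise ValueError(f"{prefix}.bed: not a SNP-major PLINK bed file")
        raw = fh.read()
    if len(raw) != n_bytes * len(bim):
        raise ValueError(f"{prefix}.bed: size inconsistent with bim/fam")
    dosages = np.empty((n, len(bim)))
    codes = np.frombuffer(raw, dtype=np.uint8).reshape(len(bim), n_bytes)
    lut = np.array([_ALT_COUNT_FOR_CODE[c] for c in range(4)])
    for j in range(len(bim)):
        bits = codes[j]
        per_sample = np.empty(n_bytes * 4, dtype=np.uint8)
        for k in range(4):
            per_sample[k::4] = (bits >> (2 * k)) & 0b11
        dosages[:, j] = lut[per_sample[:n]]
    snps = []
    for r in bim.itertuples():
        freq = np.nanmean(dosages[:, r.Index]) / 2.0
        maf = min(freq, 1.0 - freq)
        snps.append(
            SnpInfo(
                snp_id=str(r.snp_id),
                chromosome=_parse_chrom(r.chr),
                position=int(r.pos),
                ref_allele=str(r.a2),
                alt_allele=str(r.a1),
                target_maf=float(np.clip(maf, 1e-6, 0.5)),
            )
        )
    return GenotypeMatrix(sample_ids, snps, dosages)


# ----------------------------------------------------------------- BED genes

def write_gene_bed(genes: list[GeneModel], path: str | Path) -> None:
    """Genes as 4-column BED (0-based half-open on disk)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")


def read_gene_bed(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 BED columns")
            try:
                start0, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            genes.append(
                GeneModel(
                    gene_id=fields[3],
                    chromosome=_parse_chrom(fields[0]),
                    start=start0 + 1,
                    end=end,
                )
            )
    return genes


# ----------------------------------------------------------------------- GMT

def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need name, description, >=1 gene"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


# -------------------------------------------------------------- result TSVs

def write_summary_stats(frame: pd.DataFrame, path: str | Path) -> None:
    cols = SUMMARY_COLUMNS + [c for c in frame.columns if c not in SUMMARY_COLUMNS]
    frame[cols].to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMMARY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: summary-stat file lacks columns {missing}")
    return frame


def write_gene_results(frame: pd.DataFrame, path: str | Path) -> None:
    frame[GENE_RESULT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_results(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: gene-result file lacks columns {missing}")
    return frame


def write_enrichment_table(frame: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ENRICHMENT_COLUMNS if c in frame.columns]
    frame[cols].to_csv(path, sep="\t", index=False)


def write_phenotype_tsv(
    battery_frame: pd.DataFrame, age: np.ndarray, sex: np.ndarray, path: str | Path
) -> None:
    """Phenotype/covariate table: sample_id, test_1..test_k, age, sex."""
    out = battery_frame.copy()
    out["age"] = age
    out["sex"] = sex.astype(int)
    out.to_csv(path, sep="\t")


def read_phenotype_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
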