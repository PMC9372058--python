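"""VCF and phenotype-table input/output.

Biallelic SNPs only: indel, multiallelic and non-ACGT records are
skipped with a running count.  Allele orientation is fixed at read
time; downstream modules never re-read files.  Per-sample platform
labels travel in a ``##sample_platforms=`` header line (and can be
supplied separately when reading foreign VCFs).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import (
    ARRAY,
    MISSING,
    WGS,
    DosageMatrix,
    FormatError,
    GenotypeMatrix,
    HaplotypePanel,
    VariantTable,
)

__all__ = ["VcfData", "read_vcf", "write_vcf", "write_dosage_vcf", "read_phenotypes"]

_VALID = frozenset("ACGT")


@dataclass
class VcfData:
    """Result of :func:`read_vcf`."""

    variants: VariantTable
    genotypes: GenotypeMatrix | None
    haplotypes: HaplotypePanel | None
    n_skipped: int


def _parse_platform_header(raw_header: str, samples: list[str]) -> dict[str, str]:
    for line in raw_header.splitlines():
        if line.startswith("##sample_platforms="):
            spec = line.split("=", 1)[1]
            out = {}
            for item in spec.split(","):
                sid, plat = item.split(":")
                out[sid] = plat
            return out
    return {}


def read_vcf(
    path: str | Path,
    require_phased: bool = False,
    default_platform: str = WGS,
) -> VcfData:
    """Read a VCF 4.x file of biallelic SNPs.

    Returns genotype counts (and, when ``require_phased``, a
    :class:`HaplotypePanel` instead).  Records that are not biallelic
    ACGT SNPs are skipped and counted.  An unphased genotype under
    ``require_phased`` raises with the offending locus.
    """
    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    platforms = _parse_platform_header(vcf.raw_header, samples)
    plat = np.array([platforms.get(s, default_platform) for s in samples], dtype=object)

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    ids: list[str] = []
    flags: list[frozenset] = []
    geno_rows: list[np.ndarray] = []
    hap_rows: list[np.ndarray] = []
    n_skipped = 0
    seen: set[tuple] = set()

    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if ref not in _VALID or alt not in _VALID or ref == alt:
            n_skipped += 1
            continue
        key = (rec.CHROM, rec.POS, ref, alt)
        if key in seen:
            raise FormatError(f"duplicate variant {key}")
        seen.add(key)
        gts = rec.genotypes  # list of [a1, a2, phased]
        g = np.empty(len(samples), dtype=np.int8)
        h = np.empty(2 * len(samples), dtype=np.uint8)
        for i, gt in enumerate(gts):
            a1, a2 = gt[0], gt[1]
            if a1 < 0 or a2 < 0:
                if require_phased:
                    raise FormatError(
                        f"missing genotype in phased panel at {rec.CHROM}:{rec.POS}"
                    )
                g[i] = MISSING
                h[2 * i] = h[2 * i + 1] = 0
                continue
            if require_phased and not gt[2]:
                raise FormatError(f"unphased record at {rec.CHROM}:{rec.POS}")
            g[i] = a1 + a2
            h[2 * i], h[2 * i + 1] = a1, a2
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(ref)
        alts.append(alt)
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}:{ref}:{alt}")
        filt = rec.FILTER  # None means PASS in cyvcf2
        flags.append(frozenset() if filt is None else frozenset(filt.split(";")))
        geno_rows.append(g)
        hap_rows.append(h)
    vcf.close()

    table = VariantTable.from_arrays(chroms, poss, refs, alts, ids, flags)
    if require_phased:
        haps = (
            np.stack(hap_rows, axis=1)
            if hap_rows
            else np.zeros((2 * len(samples), 0), dtype=np.uint8)
        )
        panel = HaplotypePanel(table, samples, plat, haps)
        return VcfData(table, None, panel, n_skipped)
    geno = (
        np.stack(geno_rows, axis=1)
        if geno_rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(table, samples, plat, geno)
    return VcfData(table, gm, None, n_skipped)


def _vcf_header(
    sample_ids: list[str],
    platform: np.ndarray,
    fmt_lines: list[str],
    table: "pd.DataFrame | None" = None,
) -> str:
    plat_spec = ",".join(f"{s}:{p}" for s, p in zip(sample_ids, platform))
    contigs = []
    if table is not None and len(table):
        seen = dict.fromkeys(table["chrom"])
        contigs = [f"##contig=<ID={c}>" for c in seen]
    lines = [
        "##fileformat=VCFv4.2",
        '##FILTER=<ID=PASS,Description="All filters passed">',
        *contigs,
        *fmt_lines,
        f"##sample_platforms={plat_spec}",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids),
    ]
    return "\n".join(lines)


def write_vcf(data: GenotypeMatrix | HaplotypePanel, path: str | Path) -> None:
    """Write genotypes (unphased ``/``) or a phased panel (``|``)."""
    phased = isinstance(data, HaplotypePanel)
    table = data.variants.df
    fmt = ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    with open(path, "w") as fh:
        fh.write(_vcf_header(list(data.sample_ids), data.platform, fmt, table) + "\n")
        if phased:
            h = data.haplotypes
            for j in range(len(table)):
                row = table.iloc[j]
                gts = "\t".join(
                    f"{h[2 * i, j]}|{h[2 * i + 1, j]}" for i in range(data.n_samples)
                )
                fh.write(
                    f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                    f"\t.\t{_filter_str(row.filter_flags)}\t.\tGT\t{gts}\n"
                )
        else:
            v = data.values
            enc = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
            for j in range(len(table)):
                row = table.iloc[j]
                gts = "\t".join(enc[int(v[i, j])] for i in range(data.n_samples))
                fh.write(
                    f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                    f"\t.\t{_filter_str(row.filter_flags)}\t.\tGT\t{gts}\n"
                )


def _filter_str(flags: frozenset) -> str:
    if not flags or flags == frozenset({"PASS"}):
        return "PASS"
    return ";".join(sorted(flags))


def write_dosage_vcf(dm: DosageMatrix, path: str | Path) -> None:
    """Write imputed dosages with DS FORMAT and quality INFO fields."""
    table = dm.variants.df
    fmt = [
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="ALT dosage">',
        '##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation R2">',
        '##INFO=<ID=R2_ARR,Number=1,Type=Float,Description="R2 in array samples">',
        '##INFO=<ID=R2_WGS,Number=1,Type=Float,Description="R2 in WGS samples">',
        '##INFO=<ID=ER2,Number=1,Type=Float,Description="Leave-one-out empirical R2">',
        '##INFO=<ID=GENOTYPED,Number=0,Type=Flag,Description="Typed variant">',
    ]
    with open(path, "w") as fh:
        fh.write(_vcf_header(list(dm.sample_ids), dm.platform, fmt, table) + "\n")
        for j in range(len(table)):
            row = table.iloc[j]
            info = [
                f"R2={dm.r2_all[j]:.4f}",
                f"R2_ARR={dm.r2_array[j]:.4f}",
                f"R2_WGS={dm.r2_wgs[j]:.4f}",
            ]
            if dm.genotyped[j]:
                info.append(f"ER2={dm.er2[j]:.4f}")
                info.append("GENOTYPED")
            ds = "\t".join(f"{dm.dosages[i, j]:.3f}" for i in range(dm.n_samples))
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t{';'.join(info)}\tDS\t{ds}\n"
            )


def read_dosage_vcf(path: str | Path) -> DosageMatrix:
    """Read back a dosage VCF written by :func:`write_dosage_vcf`."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    platforms = _parse_platform_header(vcf.raw_header, samples)
    plat = np.array([platforms.get(s, WGS) for s in samples], dtype=object)
    rows = {k: [] for k in ("chrom", "pos", "ref", "alt", "id")}
    ds_cols, genotyped, r2a, r2r, r2w, er2 = [], [], [], [], [], []
    for rec in vcf:
        rows["chrom"].append(rec.CHROM)
        rows["pos"].append(rec.POS)
        rows["ref"].append(rec.REF)
        rows["alt"].append(rec.ALT[0])
        rows["id"].append(rec.ID or ".")
        ds_cols.append(np.asarray(rec.format("DS"), dtype=float).ravel())
        g = rec.INFO.get("GENOTYPED") is not None
        genotyped.append(g)
        r2a.append(float(rec.INFO.get("R2")))
        r2r.append(float(rec.INFO.get("R2_ARR")))
        r2w.append(float(rec.INFO.get("R2_WGS")))
        er2.append(float(rec.INFO.get("ER2")) if g else np.nan)
    vcf.close()
    table = VariantTable.from_arrays(
        rows["chrom"], rows["pos"], rows["ref"], rows["alt"], rows["id"]
    )
    return DosageMatrix(
        table,
        samples,
        plat,
        np.stack(ds_cols, axis=1) if ds_cols else np.zeros((len(samples), 0)),
        np.asarray(genotyped, dtype=bool),
        np.asarray(r2a),
        np.asarray(r2r),
        np.asarray(r2w),
        np.asarray(er2),
    )


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the phenotype/covariate TSV.

    Requires a ``sample_id`` column; ``phenotype`` is coded 1=control,
    2=case in the file (PLINK convention) and mapped to 0/1 here, with
    NA allowed.  Any other value is a parse error naming the row.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError("phenotype table lacks required column 'sample_id'")
    if "phenotype" in df.columns:
        mapped = []
        for i, v in enumerate(df["phenotype"]):
            if pd.isna(v):
                mapped.append(np.nan)
            elif int(v) in (1, 2):
                mapped.append(int(v) - 1)
            else:
                raise FormatError(f"phenotype value {v!r} outside coding at row {i}")
        df["phenotype"] = mapped
    return df


def unmatched_samples(df: pd.DataFrame, sample_ids: list[str]) -> dict[str, list[str]]:
    """Cross-check a phenotype table against genotype sample IDs."""
    table_ids = set(df["sample_id"])
    geno_ids = set(sample_ids)
    return {
        "genotyped_not_in_table": sorted(geno_ids - table_ids),
        "table_not_genotyped": sorted(table_ids - geno_ids),
    }


def write_phenotypes(
    path: str | Path,
    sample_ids: list[str],
    phenotype: np.ndarray,
    sex: np.ndarray,
    ancestry: np.ndarray,
    platform: np.ndarray,
) -> None:
    """Write the simulator's phenotype/covariate TSV (phenotype 1/2)."""
    pd.DataFrame(
        {
            "sample_id": sample_ids,
            "phenotype": np.asarray(phenotype, dtype=int) + 1,
            "sex": np.asarray(sex, dtype=int),
            "ancestry": np.asarray(ancestry, dtype=int),
            "platform": platform,
        }
    ).to_csv(path, sep="\t", index=False)
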