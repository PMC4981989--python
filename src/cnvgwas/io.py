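"""Readers and writers for the pipeline's file formats.

Tabular data are TSV with a header line; missing values are written ``NA``;
floats use 6 significant digits (scientific notation below 1e-4).  CNVR
catalogues are BED (0-based half-open; a 1-based inclusive dialect converts
on read).  SNP dosages are read from a wide TSV or from VCF (GT or DS
fields).  Writers prepend comment lines with the package version, a config
hash and the seed so every output records its provenance.
"""

from __future__ import annotations

import hashlib
import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .calling import CNVRegion

logger = logging.getLogger("cnvgwas")

__version__ = "0.1.0"
NA = "NA"
FLOAT_FMT = "%.6g"

__all__ = [
    "read_intensities", "write_intensities",
    "read_probes", "write_probes",
    "read_regions", "write_regions",
    "read_phenotypes", "write_phenotypes",
    "read_snp_dosages", "write_snp_dosages", "write_vcf",
    "write_table", "read_table",
    "flip_dosages",
]


def _header_comment(kind: str, meta: Optional[dict] = None) -> str:
    meta = dict(meta or {})
    tag = " ".join(f"{k}={v}" for k, v in sorted(meta.items()))
    return f"# cnvgwas v{__version__} {kind} {tag}".rstrip()


def config_hash(obj) -> str:
    """Short stable hash of a configuration representation."""
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, kind: str = "table",
                meta: Optional[dict] = None, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(kind, meta) + "\n")
        df.to_csv(fh, sep="\t", na_rep=NA, float_format=FLOAT_FMT, index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[NA],
                       index_col=index_col)


# ----------------------------------------------------------------------
# intensities
# ----------------------------------------------------------------------

def write_intensities(df: pd.DataFrame, path, dialect: str = "LRR",
                      meta: Optional[dict] = None) -> None:
    """Samples x probes matrix; first column is the sample id."""
    meta = dict(meta or {}, dialect=dialect)
    write_table(df.rename_axis("sample_id"), path, kind="intensities", meta=meta)


def read_intensities(path, dialect: str = "LRR") -> pd.DataFrame:
    """Read a samples x probes intensity TSV.

    ``dialect='XY'`` (summed allele intensities) is median-centred per probe
    on read so both dialects share the same location convention: the modal
    (diploid) class sits near zero.
    """
    if dialect not in ("LRR", "XY"):
        raise ValueError(f"unknown intensity dialect {dialect!r}")
    # duplicate detection must look at the raw header: pandas de-duplicates
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split("\t")[1:]
                break
        else:
            raise ValueError(f"{path}: empty intensity file")
    dupes = [c for c in header if header.count(c) > 1]
    if dupes:
        raise ValueError(f"duplicate probe columns: {sorted(set(dupes))}")
    df = pd.read_csv(path, sep="\t", comment="#", na_values=[NA], index_col=0)
    bad = df.apply(lambda c: ~(pd.to_numeric(c, errors="coerce").notna() | c.isna()))
    if bad.any().any():
        r = bad.any(axis=1).idxmax()
        c = bad.loc[r].idxmax()
        raise ValueError(f"non-numeric intensity at sample {r!r}, probe {c!r}")
    df = df.astype(float)
    if dialect == "XY":
        df = df - df.median(axis=0)
    return df


# ----------------------------------------------------------------------
# probes & regions
# ----------------------------------------------------------------------

def write_probes(probes: pd.DataFrame, path, meta=None) -> None:
    write_table(probes[["probe_id", "chrom", "pos"]], path,
                kind="probes", meta=meta, index=False)


def read_probes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=[NA],
                     dtype={"chrom": str})
    return df[["probe_id", "chrom", "pos"]]


def write_regions(regions: Iterable[CNVRegion], path, meta=None) -> None:
    """BED: chrom, start, end, name (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write(_header_comment("regions", meta) + "\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\n")


def read_regions(path, one_based: bool = False) -> list:
    """Read a CNVR catalogue; keeps autosomes only, sorted by position.

    ``one_based=True`` converts a 1-based inclusive catalogue to the internal
    0-based half-open convention (start-1, end).
    """
    regions, dropped = [], 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: malformed BED row {line!r}")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if one_based:
                start -= 1
            region = CNVRegion(name, chrom, start, end)
            if not region.is_autosomal:
                dropped += 1
                continue
            regions.append(region)
    if dropped:
        logger.info("read_regions: dropped %d non-autosomal rows", dropped)
    regions.sort(key=lambda r: (r.chrom.rjust(2, "0") if r.chrom.isdigit()
                                else r.chrom, r.start))
    return regions


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------

def write_phenotypes(pheno: pd.DataFrame, path, meta=None) -> None:
    write_table(pheno.rename_axis("sample_id"), path, kind="phenotypes", meta=meta)


def read_phenotypes(path) -> pd.DataFrame:
    return read_table(path)


# ----------------------------------------------------------------------
# SNP dosages
# ----------------------------------------------------------------------

DOSAGE_TOL = 1e-6


def write_snp_dosages(positions: pd.DataFrame, dosages: pd.DataFrame, path,
                      meta=None) -> None:
    """Wide TSV: snp, chrom, pos, effect_allele, other_allele, <per-sample dosage>."""
    out = positions.copy()
    out = out.join(dosages.T)
    write_table(out.rename_axis("snp"), path, kind="snp_dosages", meta=meta)


def _check_dosage_range(dosages: pd.DataFrame) -> None:
    vals = dosages.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < -DOSAGE_TOL or finite.max() > 2 + DOSAGE_TOL):
        raise ValueError(
            f"dosage outside [0,2]: range ({finite.min()}, {finite.max()})"
        )


def read_snp_dosages(path):
    """Read SNP dosages from TSV or VCF.

    Returns (positions, dosages): positions indexed by SNP id with columns
    chrom, pos, effect_allele, other_allele; dosages samples x SNPs (effect-
    allele counts in [0,2]).  VCF is detected by extension; GT genotypes are
    converted to ALT-allele counts, a DS field is used verbatim when present.
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        return _read_vcf_dosages(path)
    df = pd.read_csv(path, sep="\t", comment="#", na_values=[NA], index_col=0,
                     dtype={"chrom": str})
    info_cols = ["chrom", "pos", "effect_allele", "other_allele"]
    positions = df[info_cols]
    dosages = df.drop(columns=info_cols).T.astype(float)
    dosages.index.name = "sample_id"
    _check_dosage_range(dosages)
    return positions, dosages


def _read_vcf_dosages(path):
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, data = [], {}
    for var in vcf:
        snp = var.ID or f"{var.CHROM}:{var.POS}"
        rows.append((snp, str(var.CHROM).removeprefix("chr"), var.POS,
                     var.ALT[0] if var.ALT else ".", var.REF))
        if "DS" in (var.FORMAT or []):
            ds = np.asarray(var.format("DS"), dtype=float).ravel()
        else:
            gts = var.genotype.array()[:, :2]
            ds = np.where((gts < 0).any(axis=1), np.nan,
                          (gts > 0).sum(axis=1)).astype(float)
        data[snp] = ds
    positions = pd.DataFrame(
        rows, columns=["snp", "chrom", "pos", "effect_allele", "other_allele"]
    ).set_index("snp")
    dosages = pd.DataFrame(data, index=pd.Index(samples, name="sample_id"))
    _check_dosage_range(dosages)
    return positions, dosages


def write_vcf(positions: pd.DataFrame, dosages: pd.DataFrame, path,
              meta=None) -> None:
    """Minimal VCF 4.2 with per-sample DS (effect-allele dosage)."""
    samples = list(dosages.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=cnvgwas_v{__version__}\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for snp, row in positions.iterrows():
            ds = "\t".join(FLOAT_FMT % v for v in dosages[snp])
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{snp}\t"
                     f"{row['other_allele']}\t{row['effect_allele']}\t.\t.\t.\tDS\t{ds}\n")


def flip_dosages(positions: pd.DataFrame, dosages: pd.DataFrame, snps) -> tuple:
    """Swap effect/other allele for the given SNPs; dosage d becomes 2-d."""
    positions = positions.copy()
    dosages = dosages.copy()
    for snp in snps:
        ea = positions.loc[snp, "effect_allele"]
        positions.loc[snp, "effect_allele"] = positions.loc[snp, "other_allele"]
        positions.loc[snp, "other_allele"] = ea
        dosages[snp] = 2.0 - dosages[snp]
    return positions, dosages
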