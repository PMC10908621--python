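"""Reading and writing dosage matrices, read counts, VCFs, GRMs and pedigrees.

On-disk conventions:

* dosage CSV — header row of SNP ids, first column individual ids, integer
  cells; "NA", an empty cell, or "-9" mark a missing call (always written
  back as "NA");
* read counts — either a pair of aligned CSV matrices (reference counts and
  alternate counts; total depth = ref + alt) or a VCF 4.x with a per-sample
  FORMAT/AD field. VCF ingestion uses AD exclusively — the estimators
  consume raw counts, never genotype calls — and skips multiallelic records
  (the read model is biallelic);
* GRM — square CSV (full symmetric matrix with ids) or long triplet CSV
  (id1, id2, value, n_snps_used for the upper triangle incl. diagonal),
  written at full float precision so a round-trip is lossless.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import GRM, GenotypeMatrix, ReadCounts, as_ploidy

__all__ = [
    "MISSING_TOKENS",
    "read_dosage_csv",
    "write_dosage_csv",
    "read_counts",
    "read_counts_csv_pair",
    "read_counts_vcf",
    "write_counts_csv_pair",
    "write_counts_vcf",
    "write_grm",
    "read_grm",
    "read_ploidy",
    "write_pedigree_csv",
]

logger = logging.getLogger("polygrm")

MISSING_TOKENS = ["NA", "", "-9"]


def _read_matrix_csv(path, orientation: str = "individuals-by-snps") -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, na_values=MISSING_TOKENS,
                     keep_default_na=False, dtype=str)
    if orientation == "snps-by-individuals":
        df = df.T
    elif orientation != "individuals-by-snps":
        raise ValueError(f"unknown orientation {orientation!r}")
    return df


def _to_numeric(df: pd.DataFrame, path, integer: bool = True) -> np.ndarray:
    try:
        vals = df.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError):
        for i, row in enumerate(df.itertuples(index=False)):
            for j, cell in enumerate(row):
                if cell is not None and not pd.isna(cell):
                    try:
                        float(cell)
                    except (ValueError, TypeError):
                        raise ValueError(
                            f"{path}: malformed cell {cell!r} at row "
                            f"'{df.index[i]}', column '{df.columns[j]}'"
                        ) from None
        raise
    if integer:
        obs = vals[~np.isnan(vals)]
        if obs.size and np.any(obs != np.round(obs)):
            raise ValueError(f"{path}: non-integer values present")
    return vals


def read_dosage_csv(path, ploidy, orientation: str = "individuals-by-snps") -> GenotypeMatrix:
    """Read a dosage matrix CSV and validate every call against its ploidy."""
    df = _read_matrix_csv(path, orientation)
    vals = _to_numeric(df, path)
    g = GenotypeMatrix(vals, list(df.index), list(df.columns))
    g.validate_ploidy(as_ploidy(ploidy, g.n_individuals))
    n_missing = int(np.isnan(vals).sum())
    if n_missing:
        logger.info("%s: %d missing dosage cells", path, n_missing)
    return g


def write_dosage_csv(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(g.values, index=g.individual_ids, columns=g.snp_ids)
    df.to_csv(path, na_rep="NA", float_format="%g")


def read_counts_csv_pair(ref_path, alt_path,
                         orientation: str = "individuals-by-snps") -> ReadCounts:
    """Read paired reference/alternate count matrices; depth = ref + alt."""
    ref = _read_matrix_csv(ref_path, orientation)
    alt = _read_matrix_csv(alt_path, orientation)
    if list(ref.index) != list(alt.index) or list(ref.columns) != list(alt.columns):
        raise ValueError("ref and alt count matrices have mismatched labels")
    y = _to_numeric(ref, ref_path)
    a = _to_numeric(alt, alt_path)
    y = np.nan_to_num(y, nan=0.0).astype(np.int64)
    a = np.nan_to_num(a, nan=0.0).astype(np.int64)
    return ReadCounts(y, y + a, list(ref.index), list(ref.columns))


def read_counts_vcf(path) -> ReadCounts:
    """Read reference/total read counts from FORMAT/AD of a biallelic VCF.

    Multiallelic records are skipped (with a logged count), never split.
    Missing AD entries become depth 0 (a missing call). SNP ids are
    "CHROM:POS_REF_ALT".
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ys, ds, ids = [], [], []
    n_multi = n_no_ad = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        ad = var.format("AD")
        if ad is None:
            n_no_ad += 1
            continue
        ad = np.asarray(ad, dtype=np.int64)
        ad[ad < 0] = 0  # cyvcf2 encodes missing as negative sentinels
        ys.append(ad[:, 0])
        ds.append(ad[:, 0] + ad[:, 1])
        ids.append(f"{var.CHROM}:{var.POS}_{var.REF}_{var.ALT[0]}")
    if n_multi:
        logger.info("%s: skipped %d multiallelic records", path, n_multi)
    if n_no_ad:
        raise ValueError(f"{path}: {n_no_ad} biallelic records lack FORMAT/AD")
    if not ids:
        raise ValueError(f"{path}: no usable biallelic records with AD")
    return ReadCounts(np.column_stack(ys), np.column_stack(ds), samples, ids)


def read_counts(path, fmt: str = "csv-pair", **kwargs) -> ReadCounts:
    """Dispatch read-count ingestion: ``fmt`` is 'vcf' or 'csv-pair'.

    For 'csv-pair', ``path`` is a (ref_path, alt_path) pair.
    """
    if fmt == "vcf":
        return read_counts_vcf(path)
    if fmt == "csv-pair":
        ref_path, alt_path = path
        return read_counts_csv_pair(ref_path, alt_path, **kwargs)
    raise ValueError(f"unknown read-count format {fmt!r}")


def write_counts_csv_pair(rc: ReadCounts, ref_path, alt_path) -> None:
    pd.DataFrame(rc.ref_reads, index=rc.individual_ids, columns=rc.snp_ids).to_csv(ref_path)
    alt = rc.depth - rc.ref_reads
    pd.DataFrame(alt, index=rc.individual_ids, columns=rc.snp_ids).to_csv(alt_path)


def write_counts_vcf(rc: ReadCounts, path) -> None:
    """Write counts as a minimal biallelic VCF 4.2 with FORMAT AD/DP.

    SNPs whose id parses as "CHROM:POS_REF_ALT" keep those coordinates;
    otherwise they are placed consecutively on a synthetic contig.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths (ref,alt)">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(rc.individual_ids) + "\n")
        for j, snp in enumerate(rc.snp_ids):
            chrom, pos, ref, alt = "1", str(j + 1), "A", "C"
            if ":" in snp and "_" in snp:
                try:
                    loc, ref, alt = snp.split("_")
                    chrom, pos = loc.split(":")
                except ValueError:
                    pass
            cells = []
            for i in range(rc.n_individuals):
                y, d = rc.ref_reads[i, j], rc.depth[i, j]
                cells.append(f"{y},{d - y}:{d}")
            fh.write("\t".join([chrom, pos, snp, ref, alt, ".", ".", ".", "AD:DP"]
                               + cells) + "\n")


def write_grm(grm: GRM, path, layout: str = "square") -> None:
    """Write a GRM as a square CSV or a long (id1,id2,value,n) triplet CSV."""
    if layout == "square":
        df = pd.DataFrame(grm.values, index=grm.individual_ids,
                          columns=grm.individual_ids)
        df.to_csv(path, na_rep="NA", float_format="%.17g")
    elif layout == "long-triplet":
        n = grm.n_individuals
        iu = np.triu_indices(n)
        ids = np.asarray(grm.individual_ids)
        df = pd.DataFrame({
            "id1": ids[iu[0]],
            "id2": ids[iu[1]],
            "value": grm.values[iu],
            "n_snps_used": grm.n_snps_used[iu],
        })
        df.to_csv(path, index=False, na_rep="NA", float_format="%.17g")
    else:
        raise ValueError(f"unknown GRM layout {layout!r}")


def read_grm(path, layout: str = "square") -> GRM:
    """Read a GRM written by :func:`write_grm` (lossless round-trip)."""
    if layout == "square":
        df = pd.read_csv(path, index_col=0, na_values=["NA"], keep_default_na=False,
                         float_precision="round_trip")
        vals = df.to_numpy(dtype=float)
        n_used = np.where(np.isnan(vals), 0, 1).astype(np.int64)
        return GRM(vals, n_used, list(df.index))
    if layout == "long-triplet":
        df = pd.read_csv(path, na_values=["NA"], keep_default_na=False,
                         float_precision="round_trip")
        ids = list(dict.fromkeys(list(df["id1"]) + list(df["id2"])))
        index = {s: k for k, s in enumerate(ids)}
        n = len(ids)
        vals = np.full((n, n), np.nan)
        n_used = np.zeros((n, n), dtype=np.int64)
        for r in df.itertuples(index=False):
            a, b = index[r.id1], index[r.id2]
            vals[a, b] = vals[b, a] = r.value
            n_used[a, b] = n_used[b, a] = r.n_snps_used
        return GRM(vals, n_used, ids)
    raise ValueError(f"unknown GRM layout {layout!r}")


def read_ploidy(path, individual_ids: list[str]) -> np.ndarray:
    """Read a per-individual ploidy CSV (columns id, ploidy), order-matched."""
    df = pd.read_csv(path)
    if not {"id", "ploidy"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'id' and 'ploidy'")
    table = dict(zip(df["id"].astype(str), df["ploidy"]))
    missing = [i for i in individual_ids if i not in table]
    if missing:
        raise ValueError(f"{path}: no ploidy for individuals {missing[:5]}")
    return as_ploidy([table[i] for i in individual_ids], len(individual_ids))


def write_pedigree_csv(ped: pd.DataFrame, path) -> None:
    ped.to_csv(path, index=False, na_rep="NA")
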