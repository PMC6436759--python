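"""Readers, writers and the run manifest.

Formats: summary statistics as headered TSV (``snp_id, chrom, pos`` and
either ``z`` or ``beta``+``se``); gene sets as GMT; gene coordinates as BED
(0-based half-open, converted internally to 1-based inclusive); reference
genotypes as VCF (diploid GT, dosage = ALT allele count, ``./.`` missing).
Chromosome names are normalised by stripping a leading ``chr``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .refpanel import ReferencePanel

__all__ = [
    "read_sumstats",
    "read_gmt",
    "write_gmt",
    "read_bed",
    "read_vcf_dosages",
    "write_vcf_dosages",
    "write_matrix",
    "read_matrix",
    "write_results",
    "read_results",
    "write_manifest",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    pass


def normalize_chrom(c) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


def read_sumstats(path) -> pd.DataFrame:
    """Normalised summary statistics: columns snp_id, chrom, pos, z.

    A ``z`` column wins over ``beta``/``se`` when both are present (conflict
    logged); rows with non-finite values or se <= 0 are dropped with counts
    logged.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    cols = set(df.columns)
    required = {"snp_id", "chrom", "pos"}
    if not required <= cols:
        raise FormatError(
            f"summary statistics need columns {sorted(required)}; found {sorted(cols)}"
        )
    if "z" in cols:
        if {"beta", "se"} <= cols:
            logger.warning("both z and beta/se present; using z")
        z = pd.to_numeric(df["z"], errors="coerce")
    elif {"beta", "se"} <= cols:
        beta = pd.to_numeric(df["beta"], errors="coerce")
        se = pd.to_numeric(df["se"], errors="coerce")
        bad_se = ~(se > 0)
        if bad_se.any():
            logger.info("dropping %d rows with se <= 0", int(bad_se.sum()))
        z = beta / se.where(~bad_se)
    else:
        raise FormatError(
            f"need a z column or beta+se columns; found {sorted(cols)}"
        )
    out = pd.DataFrame(
        {
            "snp_id": df["snp_id"].astype(str),
            "chrom": df["chrom"].map(normalize_chrom),
            "pos": pd.to_numeric(df["pos"], errors="coerce"),
            "z": z,
        }
    )
    n0 = len(out)
    out = out.dropna().reset_index(drop=True)
    out["pos"] = out["pos"].astype(int)
    if len(out) < n0:
        logger.info("dropped %d malformed summary-statistic rows", n0 - len(out))
    return out


def read_gmt(path):
    """Gene sets from GMT (name, description, genes...); returns GeneSetDB."""
    from .assembly import GeneSetDB

    sets, descriptions = {}, {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: GMT line needs name, description, >=1 gene")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            sets[name] = list(dict.fromkeys(genes))  # de-duplicate, keep order
            descriptions[name] = desc
    return GeneSetDB(sets=sets, descriptions=descriptions)


def write_gmt(db, path) -> None:
    with open(path, "w") as fh:
        for name, genes in db.sets.items():
            desc = db.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_bed(path) -> pd.DataFrame:
    """Gene intervals from BED; 0-based half-open converted to 1-based inclusive."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: BED needs chrom, start, end, name")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: non-integer coordinates") from exc
            rows.append(
                {
                    "gene": parts[3],
                    "chrom": normalize_chrom(parts[0]),
                    "start": start + 1,  # 1-based inclusive
                    "end": end,
                }
            )
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def read_vcf_dosages(path, m: int = 10):
    """Reference panel from a VCF: GT-derived ALT dosages, 0/1/2, NaN missing.

    Returns (panel, meta) where meta is a DataFrame (snp_id, chrom, pos).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, rows = [], [], [], []
    for var in vcf:
        sid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        ids.append(sid)
        chroms.append(normalize_chrom(var.CHROM))
        poss.append(var.POS)
        gts = var.genotype.array()[:, :2].astype(float)
        gts[gts < 0] = np.nan  # missing
        rows.append(np.nansum(gts, axis=1) + np.where(np.isnan(gts).all(axis=1), np.nan, 0.0))
    vcf.close()
    G = np.column_stack(rows) if rows else np.empty((len(samples), 0))
    panel = ReferencePanel(G_ref=G, snp_ids=ids, sample_ids=samples, m=m)
    meta = pd.DataFrame({"snp_id": ids, "chrom": chroms, "pos": poss})
    return panel, meta


def write_vcf_dosages(path, G, snp_ids, sample_ids, chroms, positions) -> None:
    """Minimal diploid VCF writer (GT only); dosage 0/1/2 -> 0/0, 0/1, 1/1."""
    G = np.asarray(G)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for j, sid in enumerate(snp_ids):
            calls = [
                "./." if np.isnan(G[i, j]) else gt_map[int(round(G[i, j]))]
                for i in range(G.shape[0])
            ]
            fh.write(
                f"{chroms[j]}\t{positions[j]}\t{sid}\tA\tG\t.\tPASS\t.\tGT\t"
                + "\t".join(calls) + "\n"
            )


def write_matrix(path, matrix, index) -> None:
    """Dense matrix as TSV with an index header row/column."""
    pd.DataFrame(np.asarray(matrix), index=index, columns=index).to_csv(path, sep="\t")


def read_matrix(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), list(df.index.astype(str))


def write_results(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(path, inputs: dict, params: dict, seed) -> None:
    """Run manifest: input content hashes, parameters, seed, version."""
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": seed,
        "parameters": params,
        "inputs": {
            name: {"path": str(p), "sha256_16": _file_hash(p)}
            for name, p in inputs.items()
            if p is not None and Path(p).exists()
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
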