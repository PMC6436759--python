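"""Building testable SNP sets from gene sets, coordinates and a panel.

Pipeline per gene set: size-filter the database (3-200 genes), map summary-
statistic SNPs to member genes within a 5 kb window of the gene body
(boundaries inclusive), drop SNPs with reference-panel minor allele
frequency below 3%, LD-prune within each gene at r^2 > 0.5 (halving the
threshold down to 0.0625 while the set still holds 1,500 or more SNPs), and
attach the reference-panel correlation matrix.  Sets still at or above the
cap after the final threshold are flagged untestable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CorrMatrix, MappedSet, ZVector
from .refpanel import EmptySetError, ReferencePanel, approximate_correlation

__all__ = [
    "GeneSetDB",
    "filter_db_by_size",
    "map_snps_to_genes",
    "maf_filter",
    "ld_prune",
    "assemble_set",
    "MIN_GENES",
    "MAX_GENES",
    "WINDOW_BP",
    "MAF_MIN",
    "R2_THRESHOLDS",
    "SNP_CAP",
]

logger = logging.getLogger(__name__)

MIN_GENES = 3
MAX_GENES = 200
WINDOW_BP = 5000
MAF_MIN = 0.03
#: successive halvings of the within-gene pruning threshold
R2_THRESHOLDS = (0.5, 0.25, 0.125, 0.0625)
SNP_CAP = 1500


@dataclass
class GeneSetDB:
    """Named collections of gene symbols with optional descriptions."""

    sets: dict
    descriptions: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def source_id(self, name: str) -> tuple[str, str]:
        """Source database and identifier, parsed from 'NAME%SOURCE%ID' names."""
        parts = name.split("%")
        if len(parts) >= 3:
            return parts[1], parts[2]
        return "", ""


def filter_db_by_size(db: GeneSetDB, min_genes: int = MIN_GENES,
                      max_genes: int = MAX_GENES) -> GeneSetDB:
    """Keep sets with a gene count in [min_genes, max_genes]."""
    kept = {n: g for n, g in db.sets.items() if min_genes <= len(g) <= max_genes}
    logger.info("size filter: %d of %d sets retained", len(kept), len(db.sets))
    if not kept:
        logger.warning("no gene sets pass the size filter")
    return GeneSetDB(
        sets=kept,
        descriptions={n: db.descriptions.get(n, "") for n in kept},
    )


def map_snps_to_genes(
    sumstats: pd.DataFrame, annotation: pd.DataFrame, window_bp: int = WINDOW_BP
) -> dict:
    """SNP ids mapped to each gene within [start - window, end + window].

    Both window boundaries are inclusive; gene coordinates are 1-based
    inclusive (see the BED reader).  SNPs on chromosomes absent from the
    annotation are skipped with a log message.
    """
    out: dict[str, list[str]] = {}
    known = set(annotation["chrom"])
    unknown = set(sumstats["chrom"]) - known
    if unknown:
        n = int(sumstats["chrom"].isin(unknown).sum())
        logger.info("skipping %d SNPs on chromosomes absent from annotation: %s",
                    n, sorted(unknown))
    by_chrom = {
        c: sub.sort_values("pos") for c, sub in sumstats.groupby("chrom")
    }
    for row in annotation.itertuples(index=False):
        sub = by_chrom.get(row.chrom)
        if sub is None:
            out.setdefault(row.gene, [])
            continue
        lo = np.searchsorted(sub["pos"].to_numpy(), row.start - window_bp, side="left")
        hi = np.searchsorted(sub["pos"].to_numpy(), row.end + window_bp, side="right")
        snps = sub["snp_id"].to_numpy()[lo:hi].tolist()
        out.setdefault(row.gene, []).extend(snps)
    # de-duplicate within gene, preserving position order
    return {g: list(dict.fromkeys(s)) for g, s in out.items()}


def maf_filter(panel: ReferencePanel, snps) -> list:
    """SNPs with panel MAF >= 3% (strictly-below-3% dropped)."""
    found, missing = panel.resolve(snps)
    if missing:
        logger.info("%d SNPs not in panel dropped during MAF filter", len(missing))
    if not found:
        return []
    mafs = panel.maf(found)
    return [s for s, f in zip(found, mafs) if f >= MAF_MIN]


def _greedy_prune(corr2: np.ndarray, threshold: float) -> np.ndarray:
    """Indices kept by the greedy position-ordered all-pairs rule.

    Scanning pairs in position order, the lower-position SNP of an offending
    pair survives.
    """
    n = corr2.shape[0]
    alive = np.ones(n, dtype=bool)
    for i in range(n):
        if not alive[i]:
            continue
        for j in range(i + 1, n):
            if alive[j] and corr2[i, j] > threshold:
                alive[j] = False
    return np.flatnonzero(alive)


def ld_prune(
    panel: ReferencePanel, gene_snps: dict, r2_initial: float = 0.5,
    cap: int = SNP_CAP,
) -> tuple[dict, bool, float]:
    """Within-gene greedy LD pruning with threshold escalation.

    Returns (pruned gene->snps map, testable flag, final threshold).  If the
    union of pruned SNPs still holds >= cap SNPs at the final threshold the
    set is untestable.
    """
    thresholds = [t for t in R2_THRESHOLDS if t <= r2_initial] or [r2_initial]
    corr_cache: dict[str, np.ndarray] = {}
    for gene, snps in gene_snps.items():
        if len(snps) > 1:
            Gg = panel.columns(snps)
            c = np.corrcoef(Gg.T)
            corr_cache[gene] = c * c
    final_t = thresholds[0]
    for t in thresholds:
        final_t = t
        pruned = {}
        for gene, snps in gene_snps.items():
            if len(snps) <= 1:
                pruned[gene] = list(snps)
                continue
            keep = _greedy_prune(corr_cache[gene], t)
            pruned[gene] = [snps[i] for i in keep]
        total = len({s for ss in pruned.values() for s in ss})
        if total < cap:
            return pruned, True, t
    logger.warning("set still holds >= %d SNPs after pruning at r2 > %g; untestable",
                   cap, final_t)
    return pruned, False, final_t


def assemble_set(
    set_name: str,
    genes,
    sumstats: pd.DataFrame,
    annotation: pd.DataFrame,
    panel: ReferencePanel,
    window_bp: int = WINDOW_BP,
    cap: int = SNP_CAP,
) -> MappedSet:
    """Window-map, MAF-filter, LD-prune and correlate one gene set.

    Provenance counts satisfy
    ``snps_in = retained + dropped_window + dropped_maf + dropped_prune``
    where ``snps_in`` is the number of unique summary-statistic SNPs on the
    chromosomes of member genes (SNPs missing from the reference panel are
    counted under ``dropped_maf``).
    """
    genes = list(dict.fromkeys(genes))
    ann = annotation[annotation["gene"].isin(genes)]
    missing_genes = set(genes) - set(ann["gene"])
    if missing_genes:
        logger.info("set %s: %d genes lack coordinates", set_name, len(missing_genes))
    chroms = set(ann["chrom"])
    candidates = sumstats[sumstats["chrom"].isin(chroms)]
    snps_in = int(candidates["snp_id"].nunique())

    gene_map = map_snps_to_genes(candidates, ann, window_bp)
    windowed = {s for ss in gene_map.values() for s in ss}
    dropped_window = snps_in - len(windowed)

    maf_ok_union: set = set()
    gene_maf: dict[str, list] = {}
    for g, ss in gene_map.items():
        kept = maf_filter(panel, ss)
        gene_maf[g] = kept
        maf_ok_union.update(kept)
    dropped_maf = len(windowed) - len(maf_ok_union)

    provenance = {
        "snps_in": snps_in,
        "dropped_window": dropped_window,
        "dropped_maf": dropped_maf,
    }

    if not maf_ok_union:
        provenance.update({"dropped_prune": 0, "retained": 0})
        return MappedSet(set_name=set_name, genes=[(g, []) for g in genes],
                         z=None, sigma=None, provenance=provenance,
                         testable=False, reason="no SNPs after filters")

    pruned, testable, final_t = ld_prune(panel, gene_maf, cap=cap)
    provenance["prune_threshold"] = final_t
    retained_union = {s for ss in pruned.values() for s in ss}
    provenance["dropped_prune"] = len(maf_ok_union) - len(retained_union)
    provenance["retained"] = len(retained_union)

    gene_lists = [(g, pruned.get(g, [])) for g in genes]
    if not testable:
        return MappedSet(set_name=set_name, genes=gene_lists, z=None, sigma=None,
                         provenance=provenance, testable=False,
                         reason=f"set >= {cap} SNPs after pruning at r2 > {final_t}")

    # set-level SNP order: by (chrom, pos), de-duplicated across genes
    zmap = candidates.drop_duplicates("snp_id").set_index("snp_id")
    ordered = sorted(
        retained_union,
        key=lambda s: (str(zmap.loc[s, "chrom"]), int(zmap.loc[s, "pos"]), s),
    )
    z = ZVector(zmap.loc[ordered, "z"].to_numpy(), snp_ids=ordered)
    try:
        sigma = approximate_correlation(panel, ordered)
    except EmptySetError:
        return MappedSet(set_name=set_name, genes=gene_lists, z=None, sigma=None,
                         provenance=provenance, testable=False,
                         reason="no set SNP resolvable in panel")
    return MappedSet(set_name=set_name, genes=gene_lists, z=z, sigma=sigma,
                     provenance=provenance, testable=True)
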