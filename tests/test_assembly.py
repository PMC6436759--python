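"""Set assembly: size filter, SNP-gene window mapping, MAF filter, pruning."""

import numpy as np
import pandas as pd
import pytest

from gbjgsa.assembly import (
    GeneSetDB,
    assemble_set,
    filter_db_by_size,
    ld_prune,
    maf_filter,
    map_snps_to_genes,
)
from gbjgsa.refpanel import ReferencePanel


class TestSizeFilter:
    def test_boundaries(self):
        db = GeneSetDB(sets={
            "tiny": [f"g{i}" for i in range(2)],
            "min": [f"g{i}" for i in range(3)],
            "mid": [f"g{i}" for i in range(50)],
            "max": [f"g{i}" for i in range(200)],
            "big": [f"g{i}" for i in range(201)],
        })
        kept = filter_db_by_size(db)
        assert set(kept.sets) == {"min", "mid", "max"}

    def test_empty_result_is_empty_db(self):
        db = GeneSetDB(sets={"tiny": ["a", "b"]})
        assert len(filter_db_by_size(db)) == 0


def toy_mapping_inputs():
    ann = pd.DataFrame([
        {"gene": "gA", "chrom": "1", "start": 100_000, "end": 110_000},
        {"gene": "gB", "chrom": "1", "start": 112_000, "end": 118_000},
    ])
    positions = [94_999, 95_000, 99_000, 105_000, 110_500, 113_000,
                 123_000, 123_001, 140_000, 200_000]
    ss = pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(len(positions))],
        "chrom": "1",
        "pos": positions,
        "z": 0.0,
    })
    return ss, ann


class TestWindowMapping:
    def test_boundary_inclusive_at_exactly_window(self):
        ss, ann = toy_mapping_inputs()
        mapping = map_snps_to_genes(ss, ann, window_bp=5000)
        assert "s1" in mapping["gA"]      # start - 5000 exactly
        assert "s0" not in mapping["gA"]  # start - 5001

    def test_matches_interval_oracle(self):
        ss, ann = toy_mapping_inputs()
        mapping = map_snps_to_genes(ss, ann, window_bp=5000)
        for row in ann.itertuples(index=False):
            expect = set(
                ss.loc[
                    (ss.pos >= row.start - 5000) & (ss.pos <= row.end + 5000),
                    "snp_id",
                ]
            )
            assert set(mapping[row.gene]) == expect

    def test_multi_gene_snp_in_both_lists(self):
        ss, ann = toy_mapping_inputs()
        mapping = map_snps_to_genes(ss, ann, window_bp=5000)
        # s4 at 110,500 is inside gA's window (end+5000) and gB's (start-5000)
        assert "s4" in mapping["gA"] and "s4" in mapping["gB"]

    def test_unknown_chromosome_skipped(self):
        ss, ann = toy_mapping_inputs()
        ss2 = pd.concat([ss, pd.DataFrame([{"snp_id": "sX", "chrom": "9",
                                            "pos": 105_000, "z": 0.0}])])
        mapping = map_snps_to_genes(ss2, ann)
        assert all("sX" not in v for v in mapping.values())


class TestMafFilter:
    def _panel(self, cols):
        G = np.array(cols, dtype=float).T
        return ReferencePanel(G_ref=G, snp_ids=[f"s{i}" for i in range(G.shape[1])], m=0)

    def test_zero_maf_dropped(self):
        panel = self._panel([[0, 0, 0, 0, 1], [0, 0, 0, 0, 0]])
        assert maf_filter(panel, ["s0", "s1"]) == ["s0"]

    def test_exact_three_percent_retained(self):
        # mean dosage/2 = 0.03 exactly: 3 alt alleles over 50 diploids
        col = [0] * 47 + [1, 1, 1]
        other = [0, 1] * 25
        panel = self._panel([col, other])
        assert "s0" in maf_filter(panel, ["s0", "s1"])

    def test_matches_direct_frequency_count(self, rng):
        G = rng.binomial(2, rng.uniform(0.01, 0.5, 12), size=(300, 12)).astype(float)
        panel = ReferencePanel(G_ref=G, snp_ids=[f"s{i}" for i in range(12)], m=0)
        got = maf_filter(panel, panel.snp_ids)
        p = G.mean(axis=0) / 2
        expect = [f"s{i}" for i in range(12) if min(p[i], 1 - p[i]) >= 0.03]
        assert got == expect


def correlated_panel(rng, n, blocks):
    """Panel whose columns come in blocks of controlled correlation."""
    cols, ids = [], []
    k = 0
    for size, rho in blocks:
        latent = rng.standard_normal((n, 1))
        for _ in range(size):
            noise = rng.standard_normal((n, 1))
            x = np.sqrt(rho) * latent + np.sqrt(1 - rho) * noise
            cols.append((x.ravel() > 0).astype(float) + (x.ravel() > 1).astype(float))
            ids.append(f"s{k}")
            k += 1
    return ReferencePanel(G_ref=np.column_stack(cols), snp_ids=ids, m=0)


class TestLdPrune:
    def test_pair_above_threshold_keeps_lower_position(self, rng):
        panel = correlated_panel(rng, 500, [(2, 0.9)])
        r2 = np.corrcoef(panel.G_ref.T)[0, 1] ** 2
        assert r2 > 0.5
        pruned, testable, t = ld_prune(panel, {"g": ["s0", "s1"]})
        assert pruned["g"] == ["s0"]
        assert testable and t == 0.5

    def test_uncorrelated_set_unchanged(self, rng):
        panel = correlated_panel(rng, 400, [(1, 0.0)] * 5)
        snps = panel.snp_ids
        pruned, testable, _ = ld_prune(panel, {"g": snps})
        assert pruned["g"] == snps

    def test_tight_block_matches_greedy_oracle(self, rng):
        panel = correlated_panel(rng, 800, [(30, 0.92)])
        snps = panel.snp_ids
        pruned, _, t = ld_prune(panel, {"g": snps})
        # independent greedy pass over the r2 matrix
        r2 = np.corrcoef(panel.G_ref.T) ** 2
        alive = np.ones(30, bool)
        for i in range(30):
            if not alive[i]:
                continue
            for j in range(i + 1, 30):
                if alive[j] and r2[i, j] > t:
                    alive[j] = False
        assert pruned["g"] == [snps[i] for i in np.flatnonzero(alive)]

    def test_post_prune_r2_bound(self, rng):
        panel = correlated_panel(rng, 600, [(10, 0.8), (8, 0.6)])
        gene_snps = {"g1": panel.snp_ids[:10], "g2": panel.snp_ids[10:]}
        pruned, _, t = ld_prune(panel, gene_snps)
        for g, snps in pruned.items():
            if len(snps) > 1:
                r2 = np.corrcoef(panel.columns(snps).T) ** 2
                off = ~np.eye(len(snps), dtype=bool)
                assert r2[off].max() <= t + 1e-12

    def test_threshold_escalation_and_untestable(self, rng):
        panel = correlated_panel(rng, 300, [(1, 0.0)] * 30)
        gene_snps = {"g": panel.snp_ids}
        pruned, testable, t = ld_prune(panel, gene_snps, cap=10)
        # mutually uncorrelated SNPs survive every threshold: untestable
        assert not testable and t == 0.0625


def assembly_fixture(null_resources):
    res = null_resources
    genes = [f"gene{i}" for i in range(4)]
    return genes, res


class TestAssembleSet:
    def test_no_mapped_snps_flags_empty(self, null_resources):
        mapped = assemble_set("empty", ["nogene1", "nogene2", "nogene3"],
                              null_resources.sumstats, null_resources.annotation,
                              null_resources.panel)
        assert not mapped.testable and mapped.reason

    def test_composition_equals_manual_steps(self, null_resources):
        genes, res = assembly_fixture(null_resources)
        mapped = assemble_set("combo", genes, res.sumstats, res.annotation, res.panel)
        ann = res.annotation[res.annotation.gene.isin(genes)]
        gene_map = map_snps_to_genes(res.sumstats, ann)
        gene_maf = {g: maf_filter(res.panel, s) for g, s in gene_map.items()}
        pruned, testable, _ = ld_prune(res.panel, gene_maf)
        manual = {s for ss in pruned.values() for s in ss}
        assert testable == mapped.testable
        assert manual == set(mapped.z.snp_ids)

    def test_duplicate_gene_idempotent(self, null_resources):
        genes, res = assembly_fixture(null_resources)
        m1 = assemble_set("a", genes, res.sumstats, res.annotation, res.panel)
        m2 = assemble_set("a", genes + [genes[0]], res.sumstats, res.annotation,
                          res.panel)
        assert m1.z.snp_ids == m2.z.snp_ids
        assert np.array_equal(m1.z.z, m2.z.z)

    def test_provenance_conservation(self, null_resources):
        genes, res = assembly_fixture(null_resources)
        mapped = assemble_set("a", genes, res.sumstats, res.annotation, res.panel)
        pr = mapped.provenance
        assert pr["snps_in"] == (pr["retained"] + pr["dropped_window"]
                                 + pr["dropped_maf"] + pr["dropped_prune"])

    def test_deterministic_rerun(self, null_resources):
        genes, res = assembly_fixture(null_resources)
        m1 = assemble_set("a", genes, res.sumstats, res.annotation, res.panel)
        m2 = assemble_set("a", genes, res.sumstats, res.annotation, res.panel)
        assert m1.z.snp_ids == m2.z.snp_ids
        assert np.array_equal(m1.sigma.sigma, m2.sigma.sigma)
        assert m1.provenance == m2.provenance
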