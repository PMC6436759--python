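"""Synthetic LD-structured genotypes, phenotypes and power experiments.

The generator emulates the structure of the study that motivated this
package: a reference panel of ~350 unrelated individuals; gene sets of ten
genes, each holding 7-25 SNPs after pruning; within-gene LD (exchangeable or
AR(1) latent haplotype correlation, independent across genes); minor allele
frequencies of at least 3%.  Phenotypes follow the linear disease model

    Y_i = sum_{j=1}^{a*b} beta * G_ij + e_i,   e_i ~ N(0, 1),

where ``a`` of the genes carry ``b`` causal SNPs each (or ``a*b`` causal
SNPs are placed uniformly at random when ``random_placement`` is set).

Dosages are built by thresholding two latent MVN haplotype draws per
individual at the allele-frequency quantile and summing, which attenuates
the latent correlation; targets on dosage r^2 are therefore stated on the
realised scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .containers import CorrMatrix, ZVector
from .gof import (
    bj_test,
    gbj_test,
    ghc_test,
    minp_test,
    quadratic_test,
    single_z_pvalue,
)
from .marginal import ScoreInputs, estimate_correlation, fit_null_glm, score_statistics

__all__ = [
    "SimDesign",
    "SetLayout",
    "PowerEstimate",
    "sample_layout",
    "generate_genotypes",
    "generate_phenotype",
    "select_causal",
    "power_experiment",
    "stepdown_experiment",
    "sparsity_regime",
    "moderate_regime_max",
    "StudyResources",
    "generate_study_resources",
]

ALL_TESTS = ("gbj", "bj", "ghc", "minp", "quadratic")


@dataclass
class SimDesign:
    """One cell of the simulation grid.

    Defaults mirror the study conditions: sets of ten genes with 7-25 SNPs,
    a reference-panel-sized sample of 350, testing at alpha = 0.01, 100
    replicates per power cell (4,000 for a Type I error run).
    """

    n_panel: int = 350
    n_study: int = 350
    n_genes: int = 10
    snp_range: tuple[int, int] = (7, 25)
    ld: str = "exchangeable"          # or "ar1"
    ld_param_range: tuple[float, float] = (0.1, 0.6)
    maf_range: tuple[float, float] = (0.03, 0.5)
    a: int = 0                        # causal genes
    b: int = 0                        # causal SNPs per causal gene
    beta: float = 0.0
    random_placement: bool = False
    alpha: float = 0.01
    reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.reps < 1:
            raise ValueError("a, b must be nonnegative and reps positive")
        if self.a > self.n_genes:
            raise ValueError("more causal genes than genes")
        if self.a * self.b > self.n_genes * self.snp_range[0] and not self.random_placement:
            # may still be satisfiable per layout; checked at selection time
            pass
        if not (0 < self.alpha < 1):
            raise ValueError("alpha in (0,1)")
        if self.ld not in ("exchangeable", "ar1"):
            raise ValueError("ld must be 'exchangeable' or 'ar1'")


@dataclass
class SetLayout:
    """Realised structure of one simulated gene set."""

    sizes: list[int]
    gene_corrs: list[np.ndarray]      # latent haplotype correlation per gene
    mafs: np.ndarray                  # per SNP
    gene_names: list[str] = field(default_factory=list)
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.gene_names:
            self.gene_names = [f"gene{g}" for g in range(len(self.sizes))]
        if not self.snp_ids:
            self.snp_ids = [f"snp{g}_{i}" for g, sz in enumerate(self.sizes) for i in range(sz)]

    @property
    def d(self) -> int:
        return int(sum(self.sizes))

    def gene_slices(self) -> list[slice]:
        out, start = [], 0
        for sz in self.sizes:
            out.append(slice(start, start + sz))
            start += sz
        return out

    def latent_corr(self) -> np.ndarray:
        """Block-diagonal latent correlation over the whole set."""
        R = np.eye(self.d)
        for sl, C in zip(self.gene_slices(), self.gene_corrs):
            R[sl, sl] = C
        return R


def _gene_corr(size: int, model: str, param: float) -> np.ndarray:
    if model == "exchangeable":
        C = np.full((size, size), param)
        np.fill_diagonal(C, 1.0)
    else:
        idx = np.arange(size)
        C = param ** np.abs(np.subtract.outer(idx, idx))
    return C


def sample_layout(design: SimDesign, rng: np.random.Generator) -> SetLayout:
    """Draw the gene sizes, LD strengths and allele frequencies of one set."""
    lo, hi = design.snp_range
    sizes = rng.integers(lo, hi + 1, size=design.n_genes).tolist()
    params = rng.uniform(*design.ld_param_range, size=design.n_genes)
    corrs = [_gene_corr(sz, design.ld, p) for sz, p in zip(sizes, params)]
    mafs = rng.uniform(design.maf_range[0], design.maf_range[1], size=int(sum(sizes)))
    return SetLayout(sizes=sizes, gene_corrs=corrs, mafs=mafs)


def generate_genotypes(layout: SetLayout, n: int, rng: np.random.Generator) -> np.ndarray:
    """Diploid dosages: two latent MVN haplotypes thresholded per SNP.

    An allele is present when the latent value falls below the allele
    frequency quantile; dosage is the sum over the two haplotypes, so columns
    are Binomial(2, maf) marginally with LD-driven within-gene correlation.
    """
    d = layout.d
    G = np.zeros((n, d))
    thresholds = norm.ppf(layout.mafs)
    for sl, C in zip(layout.gene_slices(), layout.gene_corrs):
        L = np.linalg.cholesky(C + 1e-10 * np.eye(C.shape[0]))
        for _hap in range(2):
            H = rng.standard_normal((n, C.shape[0])) @ L.T
            G[:, sl] += (H < thresholds[sl]).astype(float)
    return G


def select_causal(
    layout: SetLayout, a: int, b: int, rng: np.random.Generator,
    random_placement: bool = False,
) -> np.ndarray:
    """Indices of causal SNPs: first b SNPs of a random genes, or uniform."""
    if a * b == 0:
        return np.array([], dtype=int)
    if random_placement:
        return rng.choice(layout.d, size=min(a * b, layout.d), replace=False)
    eligible = [g for g, sz in enumerate(layout.sizes) if sz >= b]
    if len(eligible) < a:
        raise ValueError("not enough genes large enough to hold b causal SNPs")
    genes = rng.choice(eligible, size=a, replace=False)
    slices = layout.gene_slices()
    return np.concatenate([np.arange(slices[g].start, slices[g].start + b) for g in genes])


def generate_phenotype(
    G: np.ndarray, causal_idx, beta: float, rng: np.random.Generator
) -> np.ndarray:
    """Continuous phenotype from the additive disease model with N(0,1) noise."""
    n = G.shape[0]
    y = rng.standard_normal(n)
    causal_idx = np.asarray(causal_idx, dtype=int)
    if causal_idx.size:
        y = y + beta * G[:, causal_idx].sum(axis=1)
    return y


# ---------------------------------------------------------------------------
# sparsity bookkeeping


def sparsity_regime(n_signals: int, d: int) -> str:
    """Classify a signal count: very sparse (< d^(1/4)), moderately sparse
    (d^(1/4) to d^(1/2)), dense (> d^(1/2))."""
    if n_signals < d ** 0.25:
        return "very_sparse"
    if n_signals <= d ** 0.5:
        return "moderately_sparse"
    return "dense"


def moderate_regime_max(d: int) -> int:
    """Largest signal count in the moderately sparse regime."""
    return int(np.floor(d ** 0.5))


# ---------------------------------------------------------------------------
# experiments


@dataclass
class PowerEstimate:
    """Per-test rejection proportions with Monte-Carlo standard errors."""

    design: SimDesign
    power: dict
    se: dict
    reps: int
    regime: str = ""

    def __post_init__(self) -> None:
        for name, p in self.power.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"power for {name} outside [0,1]")


def _marginal_stats(G, y):
    inputs = ScoreInputs(G=G, X=np.ones((G.shape[0], 1)), Y=y, family="gaussian")
    fit = fit_null_glm(inputs.X, inputs.Y, "gaussian")
    z = score_statistics(inputs, fit)
    sigma = estimate_correlation(inputs, fit)
    return z, sigma


def _run_tests(z: ZVector, sigma: CorrMatrix, tests) -> dict:
    out = {}
    for name in tests:
        if name == "gbj":
            out[name] = gbj_test(z, sigma).p_value
        elif name == "bj":
            out[name] = bj_test(z).p_value
        elif name == "ghc":
            out[name] = ghc_test(z, sigma).p_value
        elif name == "minp":
            out[name] = minp_test(z, sigma).p_value
        elif name == "quadratic":
            out[name] = quadratic_test(z, sigma).p_value
        else:
            raise ValueError(f"unknown test {name!r}")
    return out


def power_experiment(design: SimDesign, tests=ALL_TESTS) -> PowerEstimate:
    """Rejection proportion of each set test over seeded replicates.

    Each replicate draws a fresh gene set, study genotypes and phenotype,
    computes marginal score statistics and their estimated correlation from
    the individual-level data, and records rejections at ``design.alpha``.
    """
    rng = np.random.default_rng(design.seed)
    hits = {name: 0 for name in tests}
    for _ in range(design.reps):
        layout = sample_layout(design, rng)
        G = generate_genotypes(layout, design.n_study, rng)
        causal = select_causal(layout, design.a, design.b, rng, design.random_placement)
        y = generate_phenotype(G, causal, design.beta, rng)
        z, sigma = _marginal_stats(G, y)
        pvals = _run_tests(z, sigma, tests)
        for name, p in pvals.items():
            hits[name] += p < design.alpha
    power = {k: v / design.reps for k, v in hits.items()}
    se = {k: float(np.sqrt(p * (1 - p) / design.reps)) for k, p in power.items()}
    regime = sparsity_regime(design.a * design.b, design.n_genes * sum(design.snp_range) // 2)
    return PowerEstimate(design=design, power=power, se=se, reps=design.reps, regime=regime)


@dataclass
class StudyResources:
    """Synthetic genome-scale inputs for the assembly and pathway layers."""

    panel: "object"                 # ReferencePanel
    sumstats: "object"              # DataFrame: snp_id, chrom, pos, z
    annotation: "object"            # DataFrame: gene, chrom, start, end
    layout: SetLayout
    causal_genes: list


def generate_study_resources(
    design: SimDesign | None = None,
    n_genes: int = 30,
    causal_genes: int = 0,
    b: int = 0,
    beta: float = 0.0,
    seed: int = 0,
    gene_spacing: int = 50_000,
    snp_spacing: int = 120,
):
    """A synthetic genome slice: reference panel, summary statistics, genes.

    Genes sit on chromosome 1 at regular spacing with SNPs laid out inside
    the gene body; the panel and the study sample are independent draws from
    the same LD model, and summary statistics are marginal score statistics
    from a study phenotype with ``causal_genes`` genes of ``b`` causal SNPs.
    """
    import pandas as pd

    from .refpanel import ReferencePanel

    design = design or SimDesign()
    rng = np.random.default_rng(seed)
    base = SimDesign(**{**design.__dict__, "n_genes": n_genes})
    layout = sample_layout(base, rng)
    slices = layout.gene_slices()
    # coordinates: gene g occupies [start, start + (size-1)*snp_spacing]
    ann_rows, snp_ids, chroms, positions = [], [], [], []
    for g, (sz, sl) in enumerate(zip(layout.sizes, slices)):
        start = 10_000 + g * gene_spacing
        end = start + (sz - 1) * snp_spacing
        gene = f"gene{g}"
        ann_rows.append({"gene": gene, "chrom": "1", "start": start, "end": end})
        for i in range(sz):
            snp_ids.append(f"rs{g}_{i}")
            chroms.append("1")
            positions.append(start + i * snp_spacing)
    layout.snp_ids = snp_ids
    annotation = pd.DataFrame(ann_rows)

    G_panel = generate_genotypes(layout, design.n_panel, rng)
    panel = ReferencePanel(G_ref=G_panel, snp_ids=snp_ids, m=0)

    G_study = generate_genotypes(layout, design.n_study, rng)
    causal_list = []
    causal_idx = np.array([], dtype=int)
    if causal_genes > 0 and b > 0:
        genes = rng.choice(n_genes, size=causal_genes, replace=False)
        causal_list = [f"gene{g}" for g in genes]
        causal_idx = np.concatenate(
            [np.arange(slices[g].start, slices[g].start + min(b, layout.sizes[g]))
             for g in genes]
        )
    y = generate_phenotype(G_study, causal_idx, beta, rng)
    z, _sigma = _marginal_stats_z_only(G_study, y)
    sumstats = pd.DataFrame(
        {"snp_id": snp_ids, "chrom": chroms, "pos": positions, "z": z}
    )
    return StudyResources(panel=panel, sumstats=sumstats, annotation=annotation,
                          layout=layout, causal_genes=causal_list)


def _marginal_stats_z_only(G, y):
    inputs = ScoreInputs(G=G, X=np.ones((G.shape[0], 1)), Y=y, family="gaussian")
    fit = fit_null_glm(inputs.X, inputs.Y, "gaussian")
    return score_statistics(inputs, fit).z, None


def _gene_pvalue(name, z_gene, sig_gene):
    if z_gene.size == 1:
        return single_z_pvalue(float(z_gene[0]))
    zv = ZVector(z_gene)
    cm = CorrMatrix(sig_gene)
    return _run_tests(zv, cm, (name if name != "minp" else "minp",))[name]


def stepdown_experiment(design: SimDesign, tests=ALL_TESTS) -> PowerEstimate:
    """Step-down power: each test removes its own most significant gene.

    Per replicate, every test scores each member gene with its own gene-level
    version (the minimum-p test uses the gene holding the smallest SNP
    p-value), removes all SNPs of its top gene, and re-tests the remaining
    genes at ``design.alpha``.
    """
    rng = np.random.default_rng(design.seed)
    hits = {name: 0 for name in tests}
    for _ in range(design.reps):
        layout = sample_layout(design, rng)
        G = generate_genotypes(layout, design.n_study, rng)
        causal = select_causal(layout, design.a, design.b, rng, design.random_placement)
        y = generate_phenotype(G, causal, design.beta, rng)
        z, sigma = _marginal_stats(G, y)
        slices = layout.gene_slices()
        for name in tests:
            if name == "minp":
                absz = np.abs(z.z)
                top = int(np.argmax([absz[sl].max() for sl in slices]))
            else:
                gene_ps = [
                    _gene_pvalue(name, z.z[sl], sigma.sigma[sl, sl]) for sl in slices
                ]
                top = int(np.argmin(gene_ps))
            keep = np.ones(layout.d, dtype=bool)
            keep[slices[top]] = False
            z_red = ZVector(z.z[keep])
            sig_red = CorrMatrix(sigma.sigma[np.ix_(keep, keep)])
            p = _run_tests(z_red, sig_red, (name,))[name]
            hits[name] += p < design.alpha
    power = {k: v / design.reps for k, v in hits.items()}
    se = {k: float(np.sqrt(p * (1 - p) / design.reps)) for k, p in power.items()}
    return PowerEstimate(design=design, power=power, se=se, reps=design.reps)
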