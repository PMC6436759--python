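"""Shared domain containers.

The objects here carry the quantities that flow between modules: per-SNP
marginal z-statistics (``ZVector``), their estimated correlation matrix
(``CorrMatrix``), the outcome of a goodness-of-fit set test (``GofResult``),
and a pathway after SNP-gene mapping and filtering (``MappedSet``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: regularisation bound for off-diagonal correlations
CORR_EPS = 1e-6

#: analytic p-values below this are floored and flagged
P_FLOOR = 1e-12


@dataclass
class ZVector:
    """Marginal z-statistics for the SNPs of one set.

    Under the null of no set effect, ``z ~ MVN(0, Sigma)``; the set test asks
    whether the mean vector is zero.
    """

    z: np.ndarray
    snp_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float).ravel()
        if self.z.size < 1:
            raise ValueError("ZVector requires at least one statistic")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("ZVector entries must be finite")
        if self.snp_ids is None:
            self.snp_ids = [f"snp{j}" for j in range(self.z.size)]
        if len(self.snp_ids) != self.z.size:
            raise ValueError("snp_ids length does not match z")

    @property
    def d(self) -> int:
        return int(self.z.size)


@dataclass
class CorrMatrix:
    """Estimated correlation matrix of the z-statistics (LD-driven)."""

    sigma: np.ndarray
    source: str = "individual_level"

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("sigma must be square")
        if not np.allclose(s, s.T, atol=1e-8):
            raise ValueError("sigma must be symmetric")
        if self.source not in {"individual_level", "reference_panel", "identity"}:
            raise ValueError(f"unknown source {self.source!r}")
        self.sigma = s

    @property
    def d(self) -> int:
        return int(self.sigma.shape[0])

    def offdiag(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries, flattened."""
        iu = np.triu_indices(self.d, k=1)
        return self.sigma[iu]

    def is_identity(self, tol: float = 1e-12) -> bool:
        return bool(np.all(np.abs(self.offdiag()) <= tol)) if self.d > 1 else True

    @classmethod
    def identity(cls, d: int) -> "CorrMatrix":
        return cls(np.eye(d), source="identity")


@dataclass
class GofResult:
    """Outcome of one supremum-type goodness-of-fit set test.

    ``statistic`` is the maximum over indices of the per-index
    log-likelihood-ratio terms (0 when no index qualifies); ``boundary`` holds
    the per-index thresholds implied by the observed statistic during p-value
    inversion (``+inf`` where the index never attains the maximum).
    """

    test: str
    statistic: float
    p_value: float
    d: int
    per_index_terms: np.ndarray | None = None
    mu_hats: np.ndarray | None = None
    boundary: np.ndarray | None = None
    p_floored: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("statistic must be nonnegative")
        if not (P_FLOOR <= self.p_value <= 1.0):
            raise ValueError("p_value outside [1e-12, 1]")


@dataclass
class MappedSet:
    """A pathway after SNP-gene mapping, MAF filtering, and LD pruning."""

    set_name: str
    genes: list[tuple[str, list[str]]]
    z: ZVector | None
    sigma: CorrMatrix | None
    provenance: dict = field(default_factory=dict)
    testable: bool = True
    reason: str = ""

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_snps(self) -> int:
        return 0 if self.z is None else self.z.d

    def snp_gene_map(self) -> dict[str, list[str]]:
        """SNP id -> list of member genes it is attributed to."""
        out: dict[str, list[str]] = {}
        for gene, snps in self.genes:
            for s in snps:
                out.setdefault(s, []).append(gene)
        return out
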