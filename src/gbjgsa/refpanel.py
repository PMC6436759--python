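"""Correlation approximation from a reference LD panel.

When only precalculated summary statistics are available, the correlation of
the z-statistics cannot be computed from study genotypes.  It is instead
approximated from a reference panel of genotypes drawn from a comparable
population: the score-statistic correlation formula is evaluated with the
panel genotypes, a modified design matrix ``X = (1, PC_1, ..., PC_m)`` built
from panel-wide principal components, and a constant in place of the fitted
means.  With a constant mean the GLM weight matrix is a scalar multiple of
the identity and cancels, so the approximation reduces to the correlation of
the PC-residualised panel genotypes; with ``m = 0`` it is exactly the Pearson
correlation of the panel genotype columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import CorrMatrix
from .marginal import _regularize

__all__ = ["ReferencePanel", "reference_design", "approximate_correlation"]

logger = logging.getLogger(__name__)


class EmptySetError(ValueError):
    """Raised when no SNP of a requested set is resolvable in the panel."""


@dataclass
class ReferencePanel:
    """Reference genotype dosage panel.

    Parameters
    ----------
    G_ref : (n_r, d) array of dosages in [0, 2]; missing entries NaN
        (mean-imputed on construction).
    snp_ids : identifiers aligned with the summary statistics.
    m : number of principal components for the modified design matrix,
        mimicking the covariates of the original analysis.
    """

    G_ref: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str] | None = None
    m: int = 10
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.G_ref = np.array(self.G_ref, dtype=float, copy=True)
        if self.G_ref.ndim != 2:
            raise ValueError("G_ref must be 2-D")
        if self.G_ref.shape[0] < 2:
            raise ValueError("need at least 2 reference individuals")
        if len(self.snp_ids) != self.G_ref.shape[1]:
            raise ValueError("snp_ids length mismatch")
        if np.isnan(self.G_ref).any():
            means = np.nanmean(self.G_ref, axis=0)
            idx = np.where(np.isnan(self.G_ref))
            self.G_ref[idx] = np.take(means, idx[1])
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    @property
    def n_r(self) -> int:
        return int(self.G_ref.shape[0])

    @property
    def d(self) -> int:
        return int(self.G_ref.shape[1])

    def maf(self, snps=None) -> np.ndarray:
        """Panel minor allele frequencies, min(p, 1-p) with p = mean dosage/2."""
        cols = self.columns(snps) if snps is not None else self.G_ref
        p = cols.mean(axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def resolve(self, snps) -> tuple[list[str], list[str]]:
        """Split requested SNP ids into (found, missing), preserving order."""
        found = [s for s in snps if s in self._index]
        missing = [s for s in snps if s not in self._index]
        return found, missing

    def columns(self, snps) -> np.ndarray:
        return self.G_ref[:, [self._index[s] for s in snps]]


def reference_design(panel: ReferencePanel) -> np.ndarray:
    """Modified design matrix (1, PC_1, ..., PC_m) from the whole panel.

    PCs are score vectors of the column-standardised panel genotype matrix,
    computed once genome-wide (not per gene set), ordered by decreasing
    variance explained.
    """
    if panel.m >= panel.n_r - 1:
        raise ValueError(
            f"m = {panel.m} principal components require n_r > m + 1 "
            f"(panel has {panel.n_r})"
        )
    ones = np.ones((panel.n_r, 1))
    if panel.m == 0:
        return ones
    Gs = panel.G_ref - panel.G_ref.mean(axis=0)
    sd = Gs.std(axis=0)
    keep = sd > 0
    Gs = Gs[:, keep] / sd[keep]
    # PC scores via SVD of the standardized matrix
    U, S, _ = np.linalg.svd(Gs, full_matrices=False)
    scores = U[:, : panel.m] * S[: panel.m]
    return np.hstack([ones, scores])


def approximate_correlation(panel: ReferencePanel, snp_subset=None) -> CorrMatrix:
    """Reference-panel approximation to the z-statistic correlation matrix.

    Evaluates the genotype-level correlation formula with panel genotypes and
    the PC design matrix; unresolvable SNPs are dropped with a warning.
    """
    if snp_subset is None:
        snps = list(panel.snp_ids)
    else:
        snps, missing = panel.resolve(snp_subset)
        if missing:
            logger.warning(
                "%d of %d SNPs unresolvable in reference panel; dropped",
                len(missing), len(snp_subset),
            )
        if not snps:
            raise EmptySetError("no SNP of the set is resolvable in the panel")
    X = reference_design(panel)
    G = panel.columns(snps)
    # constant fitted mean -> scalar weight matrix, cancels in the ratio;
    # residualise genotypes on the PC design and correlate
    Q, _ = np.linalg.qr(X)
    Gt = G - Q @ (Q.T @ G)
    denom2 = np.einsum("ij,ij->j", Gt, Gt)
    if np.any(denom2 <= 1e-12):
        j = int(np.flatnonzero(denom2 <= 1e-12)[0])
        raise ValueError(f"SNP {snps[j]!r} has no residual variance in the panel")
    s = 1.0 / np.sqrt(denom2)
    sigma = (Gt.T @ Gt) * s[:, None] * s[None, :]
    sigma = _regularize(sigma)
    return CorrMatrix(sigma, source="reference_panel")
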