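"""Model/Results interface for a single gene-set test.

``GeneSetTest`` holds the marginal z-statistics and their correlation for
one SNP set — built directly, from genotype-level data, or from summary
statistics plus a reference panel — and ``fit()`` runs the requested
set-based tests, returning a ``GeneSetTestResult`` with statistics,
p-values and a printable summary table.

Example
-------
>>> import numpy as np
>>> from gbjgsa import GeneSetTest
>>> rng = np.random.default_rng(0)
>>> G = rng.integers(0, 3, size=(200, 8)).astype(float)
>>> y = rng.standard_normal(200)
>>> res = GeneSetTest.from_genotypes(G, y).fit()
>>> 0 <= res.p_value <= 1
True
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CorrMatrix, GofResult, ZVector
from .gof import (
    bj_test,
    gbj_test,
    ghc_test,
    minp_test,
    quadratic_test,
    single_z_pvalue,
)
from .marginal import (
    ScoreInputs,
    estimate_correlation,
    fit_null_glm,
    score_statistics,
)

__all__ = ["GeneSetTest", "GeneSetTestResult"]

_TESTS = {
    "gbj": lambda z, s: gbj_test(z, s),
    "bj": lambda z, s: bj_test(z),
    "ghc": lambda z, s: ghc_test(z, s),
    "minp": lambda z, s: minp_test(z, s),
    "quadratic": lambda z, s: quadratic_test(z, s),
}


class GeneSetTest:
    """Self-contained association test between one SNP set and a phenotype.

    Parameters
    ----------
    z : per-SNP marginal z-statistics (ZVector or array).
    sigma : their correlation matrix (CorrMatrix or array); identity if None.
    name : optional set label carried into results.
    """

    def __init__(self, z, sigma=None, name: str = ""):
        self.z = z if isinstance(z, ZVector) else ZVector(np.asarray(z, dtype=float))
        if sigma is None:
            sigma = CorrMatrix.identity(self.z.d)
        elif not isinstance(sigma, CorrMatrix):
            sigma = CorrMatrix(np.asarray(sigma, dtype=float))
        if sigma.d != self.z.d:
            raise ValueError("z and sigma dimensions disagree")
        self.sigma = sigma
        self.name = name

    @classmethod
    def from_genotypes(cls, G, y, X=None, family: str = "gaussian",
                       snp_ids=None, name: str = "") -> "GeneSetTest":
        """Build from genotype-level data via the null-GLM score machinery.

        ``X`` defaults to an intercept column; it must contain one if given.
        """
        G = np.asarray(G, dtype=float)
        n = G.shape[0]
        if X is None:
            X = np.ones((n, 1))
        inputs = ScoreInputs(G=G, X=X, Y=y, family=family)
        fit = fit_null_glm(inputs.X, inputs.Y, family)
        z = score_statistics(inputs, fit)
        if snp_ids is not None:
            z = ZVector(z.z, snp_ids=list(snp_ids))
        sigma = estimate_correlation(inputs, fit)
        obj = cls(z, sigma, name=name)
        obj.null_fit = fit
        return obj

    @classmethod
    def from_summary_stats(cls, z, snp_ids, panel, name: str = "") -> "GeneSetTest":
        """Build from precalculated z-statistics and a reference LD panel."""
        from .refpanel import approximate_correlation

        found, missing = panel.resolve(snp_ids)
        if missing:
            keep = [i for i, s in enumerate(snp_ids) if s in set(found)]
            z = np.asarray(z, dtype=float)[keep]
            snp_ids = found
        sigma = approximate_correlation(panel, snp_ids)
        return cls(ZVector(np.asarray(z, dtype=float), snp_ids=list(snp_ids)),
                   sigma, name=name)

    def fit(self, tests=("gbj",)) -> "GeneSetTestResult":
        """Run the requested tests; 'gbj' drives the headline p-value."""
        if isinstance(tests, str):
            tests = (tests,)
        results: dict[str, GofResult] = {}
        for t in tests:
            if t not in _TESTS:
                raise ValueError(f"unknown test {t!r}; choose from {sorted(_TESTS)}")
            if self.z.d == 1:
                p = single_z_pvalue(float(self.z.z[0]))
                results[t] = GofResult(test=t, statistic=abs(float(self.z.z[0])),
                                       p_value=max(p, 1e-12), d=1)
            else:
                results[t] = _TESTS[t](self.z, self.sigma)
        return GeneSetTestResult(model=self, results=results, primary=tests[0])


@dataclass
class GeneSetTestResult:
    """Fitted set-test results with a statsmodels-style summary table."""

    model: GeneSetTest
    results: dict
    primary: str = "gbj"
    extra: dict = field(default_factory=dict)

    @property
    def statistic(self) -> float:
        return self.results[self.primary].statistic

    @property
    def p_value(self) -> float:
        return self.results[self.primary].p_value

    @property
    def p_floored(self) -> bool:
        return self.results[self.primary].p_floored

    def __getitem__(self, test: str) -> GofResult:
        return self.results[test]

    def summary(self) -> str:
        z = self.model.z
        off = self.model.sigma.offdiag()
        lines = [
            "Gene set association test",
            "=" * 46,
            f"Set:              {self.model.name or '(unnamed)'}",
            f"SNPs (d):         {z.d}",
            f"max |z|:          {np.max(np.abs(z.z)):.3f}",
            f"mean |corr|:      {np.mean(np.abs(off)) if off.size else 0.0:.3f}",
            f"Sigma source:     {self.model.sigma.source}",
            "-" * 46,
            f"{'test':<12}{'statistic':>14}{'p-value':>14}",
        ]
        for name, res in self.results.items():
            flag = " (floored)" if res.p_floored else ""
            lines.append(f"{name:<12}{res.statistic:>14.4f}{res.p_value:>14.3e}{flag}")
        lines.append("=" * 46)
        return "\n".join(lines)
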