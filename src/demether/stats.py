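"""Exact tests and cross-segregation expectations used by the analyses.

The tests are implemented from first principles so each is verifiable by
enumeration: Fisher's exact test sums hypergeometric point probabilities,
the two-sided binomial test sums binomial point probabilities, the Yates
chi-square is the closed-form 2x2 formula, and the two-sample t uses the
pooled-variance Student statistic.  scipy contributes only continuous
distribution functions (chi-square and t survival functions); the
hypergeometric and binomial enumerations are computed directly with
log-gamma arithmetic.

Two-sided p-values follow the "sum of outcomes no more likely than the
observed one" convention (the dominant one; two-sided definitions for
discrete tests vary), with a 1 + 1e-7 relative slack when comparing point
probabilities to absorb floating-point ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from math import exp, lgamma, sqrt
from typing import Callable, Hashable, Mapping, Sequence

import numpy as np
from scipy import stats as _sps

_REL_TIE = 1 + 1e-7


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    degenerate: bool = False


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return lgamma_vec(n + 1) - lgamma_vec(k + 1) - lgamma_vec(n - k + 1)


lgamma_vec = np.vectorize(lgamma, otypes=[float])


def _check_table(a: int, b: int, c: int, d: int) -> None:
    if min(a, b, c, d) < 0:
        raise ValueError("2x2 table counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("2x2 table must have at least one positive margin")


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums the hypergeometric probability of every table with the observed
    margins whose point probability does not exceed the observed table's.
    Degenerate margins (an empty row or column) give p = 1 by convention.
    """
    _check_table(a, b, c, d)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    k = np.arange(lo, hi + 1)
    logp = _log_comb(r1, k) + _log_comb(r2, c1 - k) - _log_comb(n, c1)
    pmf = np.exp(logp)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * _REL_TIE].sum()))


def chi2_yates(a: int, b: int, c: int, d: int) -> TestResult:
    """Yates-corrected chi-square for a 2x2 table, with its two-tailed p.

    chi2 = N * (max(|ad - bc| - N/2, 0))^2 / (r1 r2 c1 c2), 1 df.  The
    correction is clipped at zero so it can never overshoot past
    independence.  A zero margin is an error (the statistic is undefined).
    """
    _check_table(a, b, c, d)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if 0 in (r1, r2, c1, c2):
        raise ValueError("chi-square undefined for a zero margin")
    n = r1 + r2
    num = max(abs(a * d - b * c) - n / 2, 0.0)
    stat = n * num * num / (r1 * r2 * c1 * c2)
    return TestResult(stat, float(_sps.chi2.sf(stat, df=1)))


def binomial_two_sided(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p-value for k successes in n trials.

    Sums P(X = i) over all outcomes i whose point probability does not
    exceed P(X = k).
    """
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    if not (0 < p0 < 1):
        raise ValueError("p0 must be in (0, 1)")
    i = np.arange(n + 1)
    logp = _log_comb(n, i) + i * np.log(p0) + (n - i) * np.log1p(-p0)
    pmf = np.exp(logp)
    return float(min(1.0, pmf[pmf <= pmf[k] * _REL_TIE].sum()))


def t_two_sample(x: Sequence[float], y: Sequence[float], welch: bool = False) -> TestResult:
    """Two-tailed two-sample t test (pooled-variance Student by default).

    ``welch=True`` switches to the unequal-variance form.  With zero
    variance in both groups the result is degenerate: p = 1 for equal
    means, p = 0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two values")
    nx, ny = len(x), len(y)
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if welch:
        se2 = vx / nx + vy / ny
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)) if se2 else 1.0
    else:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se2 = sp2 * (1 / nx + 1 / ny)
        df = nx + ny - 2
    if se2 == 0:
        if mx == my:
            return TestResult(0.0, 1.0, degenerate=True)
        return TestResult(np.inf if mx > my else -np.inf, 0.0, degenerate=True)
    stat = (mx - my) / sqrt(se2)
    return TestResult(float(stat), float(2 * _sps.t.sf(abs(stat), df)))


# ---------------------------------------------------------------------------
# segregation expectations

Haplotype = tuple[int, ...]
Genotype = tuple[tuple[int, int], ...]  # per locus: (maternal allele, paternal allele)


@dataclass(frozen=True)
class Parent:
    """Diploid parent as two phased haplotypes over the model's loci."""

    hap1: Haplotype
    hap2: Haplotype

    def __post_init__(self) -> None:
        if len(self.hap1) != len(self.hap2):
            raise ValueError("haplotypes differ in length")


@dataclass(frozen=True)
class CrossModel:
    """Two parents, a linkage chain, and an optional progeny selection rule.

    ``map_distances[i]`` is the Haldane map distance in Morgans between
    locus i and locus i+1, or None for unlinked loci.  ``selection`` keeps
    only progeny genotypes for which it returns True (e.g. "mutant
    homozygous at the causal locus"); probabilities are renormalized over
    the survivors.
    """

    loci: tuple[str, ...]
    mother: Parent
    father: Parent
    map_distances: tuple[float | None, ...] = ()
    selection: Callable[[Genotype], bool] | None = None

    def __post_init__(self) -> None:
        L = len(self.loci)
        if len(self.mother.hap1) != L or len(self.father.hap1) != L:
            raise ValueError("parent haplotypes do not match the locus list")
        if L > 1 and len(self.map_distances) != L - 1:
            raise ValueError(
                f"need {L - 1} adjacent map distances for {L} loci, "
                f"got {len(self.map_distances)}"
            )
        for d in self.map_distances:
            if d is not None and d < 0:
                raise ValueError("map distances must be non-negative")


def haldane(d: float) -> float:
    """Recombination fraction for a map distance of ``d`` Morgans."""
    return 0.5 * (1.0 - exp(-2.0 * d))


def gamete_probabilities(parent: Parent, map_distances: Sequence[float | None]) -> dict[Haplotype, float]:
    """Exact gamete-class probabilities for one parent under Haldane linkage."""
    L = len(parent.hap1)
    probs: dict[Haplotype, float] = {}
    for sources in product((0, 1), repeat=L):
        p = 0.5
        for i in range(L - 1):
            d = map_distances[i]
            r = 0.5 if d is None else haldane(d)
            p *= r if sources[i] != sources[i + 1] else 1.0 - r
        hap = tuple(
            (parent.hap1 if s == 0 else parent.hap2)[i] for i, s in enumerate(sources)
        )
        probs[hap] = probs.get(hap, 0.0) + p
    return probs


def segregation_expectation(model: CrossModel) -> dict[Genotype, float]:
    """Progeny genotype-class probabilities, after any selection rule.

    Probabilities sum to 1 over the surviving classes.
    """
    mg = gamete_probabilities(model.mother, model.map_distances)
    fg = gamete_probabilities(model.father, model.map_distances)
    out: dict[Genotype, float] = {}
    for (mh, mp), (fh, fp) in product(mg.items(), fg.items()):
        geno: Genotype = tuple(zip(mh, fh))
        if model.selection is not None and not model.selection(geno):
            continue
        out[geno] = out.get(geno, 0.0) + mp * fp
    total = sum(out.values())
    if total == 0:
        raise ValueError("selection rule rejects every progeny class")
    return {g: p / total for g, p in out.items()}


def phenotype_probabilities(
    model: CrossModel, phenotype: Callable[[Genotype], Hashable]
) -> dict[Hashable, float]:
    """Collapse progeny genotype classes into phenotype classes."""
    out: dict[Hashable, float] = {}
    for geno, p in segregation_expectation(model).items():
        label = phenotype(geno)
        out[label] = out.get(label, 0.0) + p
    return out
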