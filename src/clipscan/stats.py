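"""Enrichment and distributional statistics, plus the degenerate motif scanner.

The hypergeometric tail is computed by an explicit log-space sum so that
p-values far below the double-precision underflow limit (~1e-308) remain
meaningful on the log scale. Fisher's exact test and the two-sample KS test
delegate to scipy; the paired Wilcoxon signed-rank test is computed here
because the exact small-sample null must tolerate tied differences
(midranks with a sign-flip enumeration), which scipy's exact method refuses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln, logsumexp

from .intervals import ValidationError


@dataclass(frozen=True)
class OverlapSpec:
    """Hypergeometric overlap: k successes in n draws from N with K successes."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValidationError("need K, n <= N and all counts >= 0")
        if not (0 <= self.k <= min(self.K, self.n)):
            raise ValidationError("need 0 <= k <= min(K, n)")


@dataclass
class TestResult:
    method: str
    statistic: float
    p: float
    sidedness: str = "two-sided"
    log10_p: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.log10_p is None:
            with np.errstate(divide="ignore"):
                self.log10_p = float(np.log10(self.p)) if self.p > 0 else -np.inf


def log_hypergeom_tail(spec: OverlapSpec) -> float:
    """Natural-log upper tail ln P(X >= k), exact, stable to arbitrarily small p."""
    N, K, n, k = spec.N, spec.K, spec.n, spec.k
    if k <= 0:
        return 0.0
    ks = np.arange(k, min(K, n) + 1)
    if ks.size == 0:
        return -np.inf
    logpmf = (
        gammaln(K + 1) - gammaln(ks + 1) - gammaln(K - ks + 1)
        + gammaln(N - K + 1) - gammaln(n - ks + 1) - gammaln(N - K - n + ks + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(logsumexp(logpmf))


def hypergeom_tail(spec: OverlapSpec) -> TestResult:
    """Upper-tail hypergeometric test P(X >= k) for overlap enrichment."""
    logp = log_hypergeom_tail(spec)
    return TestResult(
        method="hypergeometric",
        statistic=float(spec.k),
        p=float(min(1.0, np.exp(logp))),
        sidedness="greater",
        log10_p=logp / np.log(10),
    )


def hypergeom_overlap_report(
    list_a, list_b, population
) -> tuple[OverlapSpec, TestResult]:
    """Overlap of two gene lists against a population universe."""
    pop = set(population)
    a, b = set(list_a), set(list_b)
    if not a <= pop or not b <= pop:
        raise ValidationError("list elements outside population")
    spec = OverlapSpec(N=len(pop), K=len(b), n=len(a), k=len(a & b))
    return spec, hypergeom_tail(spec)


def fisher_exact(table, sidedness: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 table.

    ``greater`` tests enrichment in cell (0,0); two-sided sums tables at
    least as improbable as the observed one.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValidationError("table must be 2x2 with non-negative cells")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return TestResult("fisher", np.nan, 1.0, sidedness, flags=["zero-margin"])
    alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[sidedness]
    odds, p = sps.fisher_exact(table, alternative=alt)
    return TestResult("fisher", float(odds), float(p), sidedness)


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float, alternative: str) -> float:
    """Exact sign-flip null for the signed-rank statistic with midranks.

    Ranks are doubled so midranks (multiples of 0.5) become integers, and the
    distribution of W+ is built by convolution over the 2^n equiprobable sign
    assignments.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * dist + 0.5 * shifted
    w2 = int(np.rint(2 * w_plus))
    p_ge = dist[w2:].sum()  # P(W+ >= w_obs)
    p_le = dist[: w2 + 1].sum()
    if alternative == "greater":
        return float(p_ge)
    if alternative == "less":
        return float(p_le)
    return float(min(1.0, 2 * min(p_ge, p_le)))


def wilcoxon_paired(x, y, alternative: str = "two-sided", exact_max_n: int = 25) -> TestResult:
    """Paired Wilcoxon signed-rank test on differences ``y - x``.

    Zero differences are dropped; ties get midranks. The null is exact
    (sign-flip enumeration) up to ``exact_max_n`` informative pairs and a
    normal approximation with tie correction above. ``alternative='greater'``
    tests whether y tends to exceed x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    d = y - x
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult("wilcoxon-signed-rank", 0.0, 1.0, alternative,
                          flags=["all-zero-differences"])
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        p = _signed_rank_exact_p(ranks, w_plus, alternative)
        return TestResult("wilcoxon-signed-rank", w_plus, p, alternative)
    mean = n * (n + 1) / 4.0
    # variance with tie correction on midranks
    var = float(np.sum(ranks**2)) / 4.0
    if var == 0:
        return TestResult("wilcoxon-signed-rank", w_plus, 1.0, alternative,
                          flags=["degenerate"])
    if alternative == "greater":
        z = (w_plus - mean - 0.5) / np.sqrt(var)
        p = float(sps.norm.sf(z))
    elif alternative == "less":
        z = (w_plus - mean + 0.5) / np.sqrt(var)
        p = float(sps.norm.cdf(z))
    else:
        z = (w_plus - mean - np.sign(w_plus - mean) * 0.5) / np.sqrt(var)
        p = float(min(1.0, 2 * sps.norm.sf(abs(z))))
    return TestResult("wilcoxon-signed-rank", w_plus, p, alternative)


def ks_one_sided(sample_a, sample_b) -> TestResult:
    """One-sided two-sample KS test of D+ = sup_x [ECDF_b(x) - ECDF_a(x)].

    Rejects when ``sample_b`` is stochastically smaller than ``sample_a``
    (b's ECDF sits above a's, e.g. a downward shift of b).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be nonempty")
    res = sps.ks_2samp(b, a, alternative="greater", method="asymp")
    return TestResult("ks-one-sided", float(res.statistic), float(res.pvalue), "greater")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def qvalues(
    pvalues, lambdas: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Storey q-values with smoothed pi0 estimation.

    pi0 is estimated from the tail counts #{p > lambda}/(m (1-lambda)) on a
    lambda grid (default 0.05..0.95 step 0.05) smoothed by a cubic
    polynomial and evaluated at the largest lambda.

    Returns (q, pi0).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy(), 1.0
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    lambdas = np.asarray(lambdas, dtype=float)
    if m < 100 or p.min() >= lambdas.max():
        pi0 = 1.0
    else:
        pi0_l = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
        coef = np.polyfit(lambdas, pi0_l, 3)
        pi0 = float(np.polyval(coef, lambdas.max()))
        pi0 = min(1.0, max(pi0, 1.0 / m))
    q = np.minimum(pi0 * bh_fdr(p), 1.0)
    return q, pi0


@dataclass(frozen=True)
class MotifSpec:
    """A degenerate homopolymer motif: ``base`` repeated ``length`` times,
    allowing up to ``max_substitutions`` positions to carry ``allowed``.

    The default is the U-rich element U6 with at most one G substitution
    (7 accepted hexamers). ``N`` never matches.
    """

    length: int = 6
    base: str = "T"
    allowed: str = "G"
    max_substitutions: int = 1

    def __post_init__(self) -> None:
        if self.max_substitutions > self.length:
            raise ValidationError("max_substitutions must be <= length")

    def accepted_kmers(self) -> set[str]:
        """All k-mers the spec accepts (enumerated, not scanned)."""
        from itertools import combinations

        out = {self.base * self.length}
        for nsub in range(1, self.max_substitutions + 1):
            for pos in combinations(range(self.length), nsub):
                word = list(self.base * self.length)
                for i in pos:
                    word[i] = self.allowed
                out.add("".join(word))
        return out


def motif_scan(sequence: str, spec: MotifSpec | None = None) -> list[int]:
    """Positions of all windows matching the degenerate motif.

    RNA input (U) is treated as DNA (T). Overlapping matches are all
    reported; ``N`` (or any symbol other than base/allowed) never matches.
    """
    if spec is None:
        spec = MotifSpec()
    seq = sequence.upper().replace("U", "T")
    L, k = len(seq), spec.length
    if L < k:
        return []
    arr = np.frombuffer(seq.encode(), dtype="S1")
    is_base = arr == spec.base.encode()
    is_allowed = arr == spec.allowed.encode()
    ok = (is_base | is_allowed).astype(np.int64)
    sub = is_allowed.astype(np.int64)
    ok_c = np.concatenate([[0], np.cumsum(ok)])
    sub_c = np.concatenate([[0], np.cumsum(sub)])
    starts = np.arange(L - k + 1)
    all_ok = (ok_c[starts + k] - ok_c[starts]) == k
    nsub = sub_c[starts + k] - sub_c[starts]
    hits = starts[all_ok & (nsub <= spec.max_substitutions)]
    return [int(h) for h in hits]
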