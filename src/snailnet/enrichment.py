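"""Fisher-exact term enrichment with Benjamini-Hochberg FDR control.

All hypergeometric arithmetic is done in log space (log-gamma), so p-values
far below double underflow thresholds of naive factorial arithmetic (the
10^-200 scale routinely produced by genome-wide 2x2 tables) are computed
accurately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError


def _log_binom(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, sided: str = "two-sided"
) -> float:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    ``two-sided`` sums the probabilities of all tables (with the observed
    margins) whose hypergeometric probability is at most the observed
    table's; ``greater`` sums the upper tail over the [0][0] cell.
    """
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ValidationError("contingency counts must be non-negative")
    n = a + b + c + d
    if n < 1:
        raise ValidationError("contingency table total must be >= 1")
    if sided not in ("two-sided", "greater"):
        raise ValidationError(f"unknown sidedness '{sided}'")

    r1, c1 = a + b, a + c
    lo = max(0, r1 - (b + d))
    hi = min(r1, c1)
    x = np.arange(lo, hi + 1)
    logp = (
        _log_binom(np.float64(r1), x.astype(float))
        + _log_binom(np.float64(c + d), (c1 - x).astype(float))
        - _log_binom(np.float64(n), np.float64(c1))
    )
    obs = logp[x == a][0]
    if sided == "greater":
        keep = x >= a
    else:
        keep = logp <= obs + 1e-7  # relative tolerance against FP ties
    p = float(np.exp(logsumexp(logp[keep]) - logsumexp(logp)))
    return min(max(p, np.finfo(float).tiny), 1.0)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Input order is preserved; q_i = min over j with p_(j) >= p_(i) of
    p_(j) * m / j, clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's 2x2 over-representation outcome."""

    term_id: str
    term_name: str
    k: int  # term-positive genes in the set
    n: int  # set size
    K: int  # term-positive genes in the background
    N: int  # background size
    pvalue: float
    qvalue: float


def term_enrichment(
    gene_set: Iterable[str],
    background: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    term_names: Mapping[str, str] | None = None,
    sided: str = "greater",
) -> list[EnrichmentResult]:
    """Test each term for over-representation in ``gene_set``.

    For every term with at least one background gene, the 2x2 table
    (k, n-k; K-k, N-n-K+k) is tested one-sided (over-representation) by
    default, and q-values are BH-adjusted across all tested terms. Results
    are sorted by (pvalue, term_id).
    """
    gs = set(gene_set)
    bg = set(background)
    if not gs <= bg:
        extra = sorted(gs - bg)[:5]
        raise ValidationError(
            f"gene_set must be a subset of background; e.g. {extra} missing"
        )
    term_names = term_names or {}
    n, N = len(gs), len(bg)

    term_bg: dict[str, set[str]] = {}
    for gene in bg:
        for term in term_map.get(gene, ()):
            term_bg.setdefault(term, set()).add(gene)

    rows = []
    for term in sorted(term_bg):
        K = len(term_bg[term])
        k = len(term_bg[term] & gs)
        p = fisher_exact_2x2(k, n - k, K - k, N - n - (K - k), sided=sided)
        rows.append((term, k, K, p))
    qvals = benjamini_hochberg([r[3] for r in rows]) if rows else []
    results = [
        EnrichmentResult(
            term_id=term,
            term_name=term_names.get(term, ""),
            k=k,
            n=n,
            K=K,
            N=N,
            pvalue=p,
            qvalue=float(q),
        )
        for (term, k, K, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.pvalue, r.term_id))
    return results


def compare_two_sets(kA: int, nA: int, kB: int, nB: int) -> float:
    """Two-sided Fisher exact comparison of a term's frequency in two sets.

    Tests whether kA of nA differs from kB of nB, e.g. the number of
    metabolic-process genes among two differentially-expressed gene sets.
    """
    if kA > nA or kB > nB:
        raise ValidationError("k must not exceed n for either set")
    return fisher_exact_2x2(kA, nA - kA, kB, nB - kB, sided="two-sided")
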