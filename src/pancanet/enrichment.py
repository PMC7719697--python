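"""Two-sided hypergeometric term enrichment with Bonferroni control.

For a query of n genes against a term of K genes in a universe of N, with k
genes overlapping, the two-sided p-value is twice the smaller of the two
inclusive tails of Hypergeometric(N, K, n), capped at 1; the direction is
*enriched* when the upper tail is the smaller. Bonferroni control multiplies
by the number of tested terms. The term filter then applies, in order:
a strict significance cut (Bonferroni p <= 1e-5 kept), a blacklist of
generic uninformative terms, resolution of positive/negative-regulation
term pairs to the more significant member, and removal of categories with
fewer than three surviving terms (judged artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .core import InvalidParameterError

POS_PREFIX = "positive regulation of "
NEG_PREFIX = "negative regulation of "


def hypergeom_two_sided(k: int, n: int, K: int, N: int) -> tuple[float, str]:
    """Two-sided hypergeometric p-value and direction for an overlap of k.

    Both tails include the point probability P(X = k); the p-value is
    min(1, 2 * min(upper, lower)).
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise InvalidParameterError(
            f"inconsistent counts: k={k}, n={n}, K={K}, N={N}"
        )
    upper = float(hypergeom.sf(k - 1, N, K, n))
    lower = float(hypergeom.cdf(k, N, K, n))
    p = min(1.0, 2.0 * min(upper, lower))
    direction = "enriched" if upper < lower else "depleted"
    return p, direction


def bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Multiply by the number of tests, cap at 1, preserve order."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any()):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


@dataclass(frozen=True)
class EnrichmentResult:
    """One tested term with its overlap counts and p-values."""

    term: str
    k: int
    n: int
    K: int
    N: int
    p_two_sided: float
    p_bonferroni: float
    direction: str
    category: str = ""


def enrich(
    query: Iterable[str],
    term_sets: Mapping[str, Sequence[str]],
    universe: Iterable[str],
    categories: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Test every term set against the query within the universe.

    Query and term genes outside the universe are ignored. Bonferroni uses
    the number of tested terms.
    """
    uni = set(universe)
    if not uni:
        raise InvalidParameterError("universe must be non-empty")
    q = set(query) & uni
    categories = categories or {}
    raw: list[tuple[str, int, int, int, float, str]] = []
    for term in sorted(term_sets):
        members = set(term_sets[term]) & uni
        k = len(q & members)
        p, direction = hypergeom_two_sided(k, len(q), len(members), len(uni))
        raw.append((term, k, len(members), len(uni), p, direction))
    adj = bonferroni([r[4] for r in raw])
    return [
        EnrichmentResult(
            term=term,
            k=k,
            n=len(q),
            K=K,
            N=N,
            p_two_sided=p,
            p_bonferroni=float(a),
            direction=direction,
            category=categories.get(term, ""),
        )
        for (term, k, K, N, p, direction), a in zip(raw, adj)
    ]


def _base_term(term: str) -> tuple[str, str] | None:
    """(base name, 'pos'|'neg') when the term carries a regulation prefix."""
    if term.startswith(POS_PREFIX):
        return term[len(POS_PREFIX):], "pos"
    if term.startswith(NEG_PREFIX):
        return term[len(NEG_PREFIX):], "neg"
    return None


def filter_terms(
    results: Sequence[EnrichmentResult],
    strict_p: float = 1e-5,
    min_category_count: int = 3,
    generic_blacklist: Sequence[str] = (),
    resolve_pos_neg: bool = True,
) -> list[EnrichmentResult]:
    """Apply the four-step term filter, in this fixed order:

    1. keep terms with Bonferroni p <= ``strict_p``;
    2. drop terms whose name exactly matches the generic blacklist;
    3. for positive/negative-regulation pairs of the same base process,
       keep only the more significant member (ties keep the positive form);
    4. drop every category with fewer than ``min_category_count`` survivors.
    """
    kept = [r for r in results if r.p_bonferroni <= strict_p]
    blacklist = set(generic_blacklist)
    kept = [r for r in kept if r.term not in blacklist]

    if resolve_pos_neg:
        groups: dict[str, list[EnrichmentResult]] = {}
        for r in kept:
            parsed = _base_term(r.term)
            if parsed is not None:
                groups.setdefault(parsed[0], []).append(r)
        drop: set[str] = set()
        for base, members in groups.items():
            signs = {_base_term(r.term)[1] for r in members}
            if signs == {"pos", "neg"}:
                best = min(
                    members,
                    key=lambda r: (r.p_bonferroni, _base_term(r.term)[1] != "pos"),
                )
                drop |= {r.term for r in members if r.term != best.term}
        kept = [r for r in kept if r.term not in drop]

    counts: dict[str, int] = {}
    for r in kept:
        counts[r.category] = counts.get(r.category, 0) + 1
    return [r for r in kept if counts[r.category] >= min_category_count]
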