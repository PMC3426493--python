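"""Downstream pattern statistics on domain-level asymmetry calls:

* clustering of non-synonymous changes within domains (per-copy FET of a
  domain's N/S against the rest of the protein);
* assortment of faster-evolving domains between the two copies against a
  random-assortment null;
* per-domain-family asymmetry frequency with hypergeometric over/under-
  representation tests;
* a Wald–Wolfowitz runs test for the tendency of copy-specific
  substitutions to occupy contiguous, non-interleaved regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .seqio import ParasymError


# ---------------------------------------------------------------------------
# clustering of non-synonymous changes within domains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainClusterResult:
    pair_id: str
    copy_id: str
    domain_name: str
    table: tuple[int, int, int, int]   # (N_dom, S_dom, N_other, S_other)
    p_value: float
    clustered: bool


def clustering_test(
    pair_id: str,
    copy_id: str,
    per_domain_counts: dict[str, tuple[int, int]],
    alpha: float = 0.05,
) -> list[DomainClusterResult]:
    """One-sided FET per domain: is the domain enriched for
    non-synonymous changes relative to the other domains of the same
    protein, with synonymous changes as the background? Requires at least
    two domains."""
    if len(per_domain_counts) < 2:
        raise ParasymError(f"{pair_id}: clustering needs >= 2 domains")
    total_n = sum(n for n, _ in per_domain_counts.values())
    total_s = sum(s for _, s in per_domain_counts.values())
    out = []
    for name, (n_dom, s_dom) in per_domain_counts.items():
        n_other = total_n - n_dom
        s_other = total_s - s_dom
        table = (n_dom, s_dom, n_other, s_other)
        if sum(table) == 0:
            p = 1.0
        else:
            _, p = stats.fisher_exact(
                [[n_dom, s_dom], [n_other, s_other]], alternative="greater"
            )
        p = float(min(p, 1.0))
        odds_dom = n_dom / (s_dom + 1)
        odds_other = n_other / (s_other + 1)
        out.append(
            DomainClusterResult(
                pair_id, copy_id, name, table, p,
                clustered=bool(p <= alpha and odds_dom > odds_other),
            )
        )
    return out


# ---------------------------------------------------------------------------
# assortment of asymmetric domains across proteins
# ---------------------------------------------------------------------------

def expected_exactly_one(domain_counts: list[int], k_asymmetric: int) -> float:
    """Closed-form expectation of the number of proteins with exactly one
    asymmetric domain when k_asymmetric labels are assigned uniformly
    without replacement over all domain slots."""
    total = sum(domain_counts)
    if k_asymmetric == 0:
        return 0.0
    if k_asymmetric > total:
        raise ParasymError("more asymmetric domains than slots")
    return float(
        sum(
            stats.hypergeom.pmf(1, total, n_p, k_asymmetric)
            for n_p in domain_counts
        )
    )


def assortment_analysis(
    asymmetric_flags: list[list[bool]],
    n_perms: int = 10_000,
    seed: int = 0,
) -> dict:
    """Observed vs expected number of multi-domain proteins with exactly
    one asymmetrically evolving domain, under uniform random assortment of
    the observed total number of asymmetric domains over all domain slots
    (per-protein domain counts preserved). p is the permutation upper-tail
    probability of seeing at least the observed count."""
    if not asymmetric_flags:
        raise ParasymError("no proteins supplied")
    domain_counts = [len(flags) for flags in asymmetric_flags]
    k = sum(sum(f) for f in asymmetric_flags)
    observed = sum(1 for f in asymmetric_flags if sum(f) == 1)
    if k == 0:
        return {
            "observed_exactly_one": observed, "expected_exactly_one": 0.0,
            "ratio": float("nan"), "p_value": 1.0, "n_asymmetric": 0,
        }
    expected = expected_exactly_one(domain_counts, k)
    rng = np.random.default_rng(seed)
    total = sum(domain_counts)
    bounds = np.cumsum([0] + domain_counts)
    ge = 0
    for _ in range(n_perms):
        slots = rng.choice(total, size=k, replace=False)
        per_protein = np.histogram(slots, bins=bounds)[0]
        if (per_protein == 1).sum() >= observed:
            ge += 1
    return {
        "observed_exactly_one": observed,
        "expected_exactly_one": expected,
        "ratio": observed / expected if expected > 0 else float("inf"),
        "p_value": (ge + 1) / (n_perms + 1),
        "n_asymmetric": k,
    }


def faster_copy_concordance(faster_copies_per_pair: list[list[str]]) -> float:
    """Among pairs with >= 2 asymmetric domains, the fraction where every
    faster-evolving domain copy belongs to the same paralog."""
    eligible = [fc for fc in faster_copies_per_pair if len(fc) >= 2]
    if not eligible:
        raise ParasymError("no pairs with >= 2 asymmetric domains")
    concordant = sum(1 for fc in eligible if len(set(fc)) == 1)
    return concordant / len(eligible)


# ---------------------------------------------------------------------------
# per-family asymmetry frequency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyFrequency:
    domain_name: str
    n_tested: int
    n_asymmetric: int
    fraction: float
    p_over: float
    p_under: float


def family_asymmetry_frequency(dsa_results) -> list[FamilyFrequency]:
    """Per domain family: how often its instances were called asymmetric,
    with hypergeometric over-/under-representation p-values against the
    pooled asymmetric fraction across all families."""
    tested: dict[str, int] = {}
    asym: dict[str, int] = {}
    for r in dsa_results:
        name = r.domain_name
        if name is None:
            continue
        tested[name] = tested.get(name, 0) + 1
        asym[name] = asym.get(name, 0) + int(r.significant)
    total = sum(tested.values())
    total_asym = sum(asym.values())
    out = []
    for name in sorted(tested):
        n, k = tested[name], asym[name]
        p_over = float(stats.hypergeom.sf(k - 1, total, total_asym, n))
        p_under = float(stats.hypergeom.cdf(k, total, total_asym, n))
        out.append(FamilyFrequency(name, n, k, k / n, p_over, p_under))
    return out


# ---------------------------------------------------------------------------
# interleaving (runs) test
# ---------------------------------------------------------------------------

def _runs_pmf(n1: int, n2: int) -> dict[int, float]:
    """Exact conditional distribution of the number of runs given n1/n2
    labels of each kind (all orderings equally likely)."""
    denom = math.comb(n1 + n2, n1)
    pmf: dict[int, float] = {}
    for k in range(1, min(n1, n2) + 1):
        r = 2 * k
        pmf[r] = 2 * math.comb(n1 - 1, k - 1) * math.comb(n2 - 1, k - 1) / denom
        r = 2 * k + 1
        val = (
            math.comb(n1 - 1, k) * math.comb(n2 - 1, k - 1)
            + math.comb(n1 - 1, k - 1) * math.comb(n2 - 1, k)
        ) / denom
        if val:
            pmf[r] = pmf.get(r, 0.0) + val
    return pmf


def interleaving_runs_test(labels: list[str]) -> tuple[int, float]:
    """Wald–Wolfowitz runs test on position-ordered copy labels for the
    alternative of too few runs (contiguous, non-interleaved substitution
    regions). Exact conditional p for n <= 20, normal approximation with
    continuity correction above."""
    kinds = sorted(set(labels))
    if len(kinds) != 2:
        raise ParasymError("runs test needs positions from both copies")
    x = np.array([labels[i] != labels[i - 1] for i in range(1, len(labels))])
    runs = int(x.sum()) + 1
    n1 = sum(1 for l in labels if l == kinds[0])
    n2 = len(labels) - n1
    n = n1 + n2
    if n <= 20:
        pmf = _runs_pmf(n1, n2)
        p = sum(v for r, v in pmf.items() if r <= runs)
    else:
        mu = 1 + 2 * n1 * n2 / n
        var = 2 * n1 * n2 * (2 * n1 * n2 - n) / (n**2 * (n - 1))
        z = (runs - mu + 0.5) / math.sqrt(var)
        p = float(stats.norm.cdf(z))
    return runs, float(min(p, 1.0))


def stouffer_combine(p_values: list[float]) -> float:
    """Combine one-sided p-values across genes by Stouffer's method:
    Z = sum(z_i) / sqrt(k) with z_i the upper-tail normal score."""
    if not p_values:
        raise ParasymError("no p-values to combine")
    z = stats.norm.isf(np.clip(p_values, 1e-300, 1 - 1e-16))
    return float(stats.norm.sf(z.sum() / math.sqrt(len(z))))
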