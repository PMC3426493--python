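"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own lookup tables: translation goes
through Bio.Seq, probabilities through fractions/math.comb, and pathway or
ancestral-state enumeration is explicit.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}


def aa(codon: str) -> str:
    return str(Seq(codon).translate())


def fisher_exact_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided FET by exhaustive enumeration of all tables with the
    observed margins, point-probability rule, exact rational arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x: int) -> Fraction:
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1))

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    total = sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs)
    return float(total)


def ng86_sites_oracle(codon: str) -> tuple[float, float]:
    """Enumerate all nine single-nucleotide changes; per position, the
    synonymous fraction of the non-stop changes."""
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOPS:
                continue
            tot += 1
            syn += aa(alt) == aa(codon)
        s += syn / tot
    return s, 3.0 - s


def ng86_paths_oracle(anc: str, des: str):
    """Enumerate all shortest mutational pathways; average the (S, N) step
    classification over the stop-free ones."""
    diff = [k for k in range(3) if anc[k] != des[k]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur = anc
        s = n = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + des[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                ok = False
                break
            if aa(cur) == aa(nxt):
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            results.append((s, n))
    if not results:
        return None  # no stop-free pathway
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


def branch_counts_oracle(seq1: str, seq2: str, seqo: str):
    """Pure-python per-branch NG86 counting on a short trio: explicit
    majority/outgroup ancestral assignment, pathway-averaged substitutions,
    ancestor/descendant-averaged sites, JC-corrected rates."""
    assert len(seq1) == len(seq2) == len(seqo)
    out = {name: {"N": 0.0, "S": 0.0, "N_sites": 0.0, "S_sites": 0.0}
           for name in ("copy1", "copy2", "outgroup")}
    for i in range(0, len(seq1), 3):
        codons = [s[i : i + 3] for s in (seq1, seq2, seqo)]
        if any(set(c) - set("ACGT") or c in STOPS for c in codons):
            continue
        c1, c2, co = codons
        if c1 == c2 or c1 == co:
            anc = c1
        elif c2 == co:
            anc = c2
        else:
            anc = co
        for name, leaf in zip(("copy1", "copy2", "outgroup"), codons):
            path = ng86_paths_oracle(anc, leaf)
            if path is not None:
                out[name]["S"] += path[0]
                out[name]["N"] += path[1]
            sa, na = ng86_sites_oracle(anc)
            sl, nl = ng86_sites_oracle(leaf)
            out[name]["S_sites"] += (sa + sl) / 2
            out[name]["N_sites"] += (na + nl) / 2
    for stats in out.values():
        for kind in ("N", "S"):
            sites = stats[kind + "_sites"]
            p = stats[kind] / sites if sites else 0.0
            stats["d" + kind] = (
                -0.75 * math.log(1 - 4 * p / 3) if p < 0.75 else float("nan")
            )
    return out


def runs_distribution_oracle(n1: int, n2: int) -> dict[int, Fraction]:
    """Exact runs distribution by enumerating all distinct orderings of a
    two-symbol multiset (feasible for n1 + n2 <= 10)."""
    counts: dict[int, int] = {}
    total = 0
    for perm in set(itertools.permutations("a" * n1 + "b" * n2)):
        runs = 1 + sum(perm[i] != perm[i - 1] for i in range(1, len(perm)))
        counts[runs] = counts.get(runs, 0) + 1
        total += 1
    return {r: Fraction(c, total) for r, c in counts.items()}


def rank_sum_exact_oracle(group_a, group_b) -> float:
    """One-sided (a lower) rank-sum p by enumerating all assignments of
    the pooled values to groups."""
    import scipy.stats as st

    pooled = list(group_a) + list(group_b)
    na = len(group_a)
    ranks = st.rankdata(pooled)
    obs = sum(ranks[:na])
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), na):
        total += 1
        if sum(ranks[list(combo)]) <= obs:
            count += 1
    return count / total
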