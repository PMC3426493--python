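"""Fisher-exact asymmetry testing of duplicate branches at four levels:

* WPA  — whole-protein analysis: region = background = whole protein;
* CDA  — combined-domain analysis: non-synonymous counts from the union of
  domain columns, synonymous background from the whole protein (default;
  a switch restricts the background to the region instead);
* DSA  — domain-specific analysis: one test per domain, whole-protein
  synonymous background;
* LINKER — the non-domain complement, whole-protein background.

The 2x2 table contrasts (N, S) between the two duplicate branches; the
two-sided exact p sums all tables with fixed margins whose probability
does not exceed the observed one. Benjamini–Hochberg FDR is applied across
the units of one level within a run; the faster copy is the branch with
the larger add-one-smoothed N/(S+1) odds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counting import BranchCounts, branch_counts, infer_ancestral_codons
from .seqio import CodonTrioAlignment, DomainArchitecture, ParasymError

LEVELS = ("WPA", "CDA", "DSA", "LINKER")


def fisher_exact_2x2(n1: int, s1: int, n2: int, s2: int) -> float:
    """Two-sided Fisher exact p for the table [[n1, s1], [n2, s2]]
    (point-probability rule). An all-zero table returns p = 1 with a
    warning."""
    for v in (n1, s1, n2, s2):
        if v < 0 or int(v) != v:
            raise ParasymError(f"counts must be non-negative integers, got {v}")
    if n1 + s1 + n2 + s2 == 0:
        warnings.warn("empty contingency table, p = 1", stacklevel=2)
        return 1.0
    _, p = stats.fisher_exact([[n1, s1], [n2, s2]], alternative="two-sided")
    return float(min(p, 1.0))


def round_half_away(x: float) -> int:
    """Round fractional NG86 counts half-away-from-zero to integers."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def domain_columns(
    arch: DomainArchitecture, n_columns: int
) -> dict[str, np.ndarray]:
    """0-based codon columns per domain (amino-acid position k maps to
    codon column k)."""
    out = {}
    for name, start, end in arch.intervals:
        if end > n_columns:
            raise ParasymError(f"{arch.protein_id}/{name}: domain beyond alignment")
        cols = np.arange(start - 1, end)
        out[name] = np.concatenate([out[name], cols]) if name in out else cols
    return out


def region_columns(
    arch: DomainArchitecture, n_columns: int, level: str, domain_name: str | None = None
) -> np.ndarray:
    """Column set for a test level: whole protein (WPA), union of domains
    (CDA), one domain (DSA) or the non-domain complement (LINKER)."""
    if level == "WPA":
        return np.arange(n_columns)
    per_domain = domain_columns(arch, n_columns)
    union = (
        np.unique(np.concatenate(list(per_domain.values())))
        if per_domain else np.array([], dtype=np.int64)
    )
    if level == "CDA":
        cols = union
    elif level == "DSA":
        if domain_name is None:
            raise ParasymError("DSA requires a domain name")
        cols = per_domain[domain_name]
    elif level == "LINKER":
        cols = np.setdiff1d(np.arange(n_columns), union)
    else:
        raise ParasymError(f"unknown level {level!r}")
    if cols.size == 0:
        raise ParasymError(f"empty region for level {level}")
    return cols


def build_table(
    bc: BranchCounts,
    level: str = "WPA",
    region_bc: BranchCounts | None = None,
    background: str = "protein",
) -> tuple[int, int, int, int]:
    """(N1, S1, N2, S2) for the FET: non-synonymous counts from the region
    of interest, synonymous counts from the whole protein (``background =
    'protein'``, the default for CDA/DSA/LINKER) or from the region itself
    (WPA, or ``background='region'``). Fractional counts are rounded
    half-away-from-zero."""
    if level not in LEVELS:
        raise ParasymError(f"unknown level {level!r}")
    if level == "WPA":
        region_bc = bc
    if region_bc is None:
        raise ParasymError(f"level {level} requires region counts")
    s_source = bc if (level != "WPA" and background == "protein") else region_bc
    return (
        round_half_away(region_bc["copy1"].N),
        round_half_away(s_source["copy1"].S),
        round_half_away(region_bc["copy2"].N),
        round_half_away(s_source["copy2"].S),
    )


def bh_fdr(p_values: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (monotone)."""
    if len(p_values) == 0:
        return []
    _, q, _, _ = multipletests(p_values, method="fdr_bh")
    return [float(v) for v in q]


def faster_copy_from_table(n1: int, s1: int, n2: int, s2: int) -> str:
    odds1 = n1 / (s1 + 1)
    odds2 = n2 / (s2 + 1)
    if odds1 > odds2:
        return "copy1"
    if odds2 > odds1:
        return "copy2"
    return "tie"


@dataclass(frozen=True)
class AsymmetryResult:
    """One FET outcome at one level for one unit (protein or domain)."""

    pair_id: str
    level: str
    domain_name: str | None
    table: tuple[int, int, int, int]
    p_value: float
    q_value: float
    faster_copy: str

    @property
    def significant(self) -> bool:
        """Survives the run's FDR threshold (stored in q_value vs the
        threshold used by test_asymmetry)."""
        return self._significant

    _significant: bool = False


def test_asymmetry(
    pairs: list[tuple[CodonTrioAlignment, DomainArchitecture | None]],
    level: str,
    fdr: float = 0.10,
    cda_background: str = "protein",
) -> list[AsymmetryResult]:
    """Run the FET at one level over a batch of admitted duplicate pairs
    (callers enforce the dS filter and architecture identity). Returns one
    result per protein (WPA/CDA/LINKER) or per domain (DSA), with BH FDR
    computed across all units of the batch."""
    records = []
    for trio, arch in pairs:
        assignment = infer_ancestral_codons(trio)
        whole = branch_counts(trio, assignment=assignment)
        units: list[tuple[str | None, np.ndarray]] = []
        if level == "WPA":
            units = [(None, np.arange(trio.n_columns))]
        else:
            if arch is None:
                raise ParasymError(f"{trio.pair_id}: level {level} requires an architecture")
            if level == "DSA":
                for name in dict.fromkeys(arch.domain_names):
                    units.append((name, region_columns(arch, trio.n_columns, "DSA", name)))
            else:
                units.append((None, region_columns(arch, trio.n_columns, level)))
        for domain_name, cols in units:
            region = branch_counts(trio, columns=cols, assignment=assignment)
            table = build_table(whole, level, region, background=cda_background)
            records.append((trio.pair_id, domain_name, table))
    pvals = [fisher_exact_2x2(*t) for _, _, t in records]
    qvals = bh_fdr(pvals)
    results = []
    for (pair_id, domain_name, table), p, q in zip(records, pvals, qvals):
        results.append(
            AsymmetryResult(
                pair_id=pair_id, level=level, domain_name=domain_name,
                table=table, p_value=p, q_value=q,
                faster_copy=faster_copy_from_table(*table),
                _significant=bool(q <= fdr),
            )
        )
    return results


def bootstrap_support(
    trio: CodonTrioAlignment,
    level: str = "WPA",
    n_reps: int = 100,
    seed: int = 0,
    p_threshold: float = 0.05,
    arch: DomainArchitecture | None = None,
    domain_name: str | None = None,
) -> float:
    """Codon bootstrap: resample alignment columns with replacement,
    re-run the FET per replicate, and report the fraction of replicates
    significant at the p-threshold implied by the original run's FDR
    cut."""
    rng = np.random.default_rng(seed)
    n = trio.n_columns
    region = (
        np.arange(n) if level == "WPA"
        else region_columns(arch, n, level, domain_name)
    )
    assignment = infer_ancestral_codons(trio)
    hits = 0
    for _ in range(n_reps):
        resampled = rng.integers(0, n, size=n)
        whole = branch_counts(trio, columns=resampled, assignment=assignment)
        if level == "WPA":
            region_bc = whole
        else:
            in_region = np.isin(resampled, region)
            region_bc = branch_counts(
                trio, columns=resampled[in_region], assignment=assignment
            )
        table = build_table(whole, level, region_bc)
        if fisher_exact_2x2(*table) <= p_threshold:
            hits += 1
    return hits / n_reps


def sampled_wpa_control(
    trio: CodonTrioAlignment,
    target_length: int,
    n_reps: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Length-matched WPA control: repeat the whole-protein FET on random
    column subsets (without replacement) of the given length, mimicking the
    reduced alignment length of a domain-level test; returns the flagged
    fraction at alpha."""
    if target_length <= 0:
        raise ParasymError("target_length must be positive")
    n = trio.n_columns
    if target_length > n:
        raise ParasymError("target_length exceeds alignment length")
    rng = np.random.default_rng(seed)
    assignment = infer_ancestral_codons(trio)
    hits = 0
    for _ in range(n_reps):
        cols = rng.choice(n, size=target_length, replace=False)
        bc = branch_counts(trio, columns=cols, assignment=assignment)
        table = build_table(bc, level="WPA")
        if fisher_exact_2x2(*table) <= alpha:
            hits += 1
    return hits / n_reps
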