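"""Per-branch substitution counting on a duplicate-pair-plus-outgroup trio.

The duplication-node ancestral codon is inferred per column by parsimony
(majority codon among copy1/copy2/outgroup, outgroup tie-break), and each
branch's synonymous / non-synonymous substitutions are classified by the
Nei–Gojobori (1986) pathway-averaging convention. Site counts follow NG86
with stop-codon exclusion; dN and dS apply the Jukes–Cantor multiple-hit
correction. This is a self-contained counting engine playing the role the
original analysis delegated to codeml's free-ratios branch model.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genetics import (
    CODON_AA,
    N_CODONS,
    SENSE_CODONS,
    STOP_CODONS,
)
from .seqio import BRANCHES, CodonTrioAlignment, ParasymError


class SaturationError(ParasymError):
    """Raised when a proportion of differences exceeds the Jukes–Cantor
    correctable range (p >= 3/4)."""


# ---------------------------------------------------------------------------
# NG86 site and substitution counting
# ---------------------------------------------------------------------------

def count_sites_ng86(codon: str) -> tuple[float, float]:
    """NG86 synonymous / non-synonymous site counts for one sense codon.

    Per codon position, the synonymous fraction is the share of the
    single-nucleotide changes that do not create a stop codon and preserve
    the amino acid; position contributions sum to S_sites + N_sites = 3.
    """
    codon = codon.upper()
    if codon not in SENSE_CODONS:
        raise ParasymError(f"not a sense codon: {codon!r}")
    aa = CODON_AA[SENSE_CODONS.index(codon)]
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if CODON_AA[SENSE_CODONS.index(alt)] == aa:
                syn += 1
        # every sense codon has at least one non-stop change per position,
        # so each position contributes exactly one site: S + N = 3 always
        s += syn / valid
    return s, 3.0 - s


def count_substitutions_ng86(anc: str, des: str) -> tuple[float, float, bool]:
    """NG86 pathway-averaged (S, N) substitution counts between two sense
    codons, plus a flag set when no fully stop-free shortest pathway exists
    (counts then average the non-stop steps of all pathways)."""
    anc, des = anc.upper(), des.upper()
    for c in (anc, des):
        if c not in SENSE_CODONS:
            raise ParasymError(f"not a sense codon: {c!r}")
    diff = [k for k in range(3) if anc[k] != des[k]]
    if not diff:
        return 0.0, 0.0, False
    path_counts = []
    flagged_counts = []
    for order in itertools.permutations(diff):
        cur = anc
        s = n = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + des[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                cur = nxt
                continue
            if cur not in STOP_CODONS:
                if CODON_AA[SENSE_CODONS.index(cur)] == CODON_AA[SENSE_CODONS.index(nxt)]:
                    s += 1
                else:
                    n += 1
            cur = nxt
        (path_counts if ok else flagged_counts).append((s, n))
    if path_counts:
        s = float(np.mean([c[0] for c in path_counts]))
        n = float(np.mean([c[1] for c in path_counts]))
        return s, n, False
    s = float(np.mean([c[0] for c in flagged_counts]))
    n = float(np.mean([c[1] for c in flagged_counts]))
    return s, n, True


def _build_tables():
    site_s = np.empty(N_CODONS)
    site_n = np.empty(N_CODONS)
    for i, c in enumerate(SENSE_CODONS):
        site_s[i], site_n[i] = count_sites_ng86(c)
    sub_s = np.zeros((N_CODONS, N_CODONS))
    sub_n = np.zeros((N_CODONS, N_CODONS))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i != j:
                sub_s[i, j], sub_n[i, j], _ = count_substitutions_ng86(ci, cj)
    return site_s, site_n, sub_s, sub_n


SITE_S, SITE_N, SUB_S, SUB_N = _build_tables()


# ---------------------------------------------------------------------------
# ancestral inference (Fitch parsimony on the 3-leaf star)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AncestralAssignment:
    """Per-column duplication-node ancestral codons and per-branch
    fractional (n, s) substitution attribution. Masked columns hold
    ancestor -1 and contribute zero counts."""

    ancestor: np.ndarray          # (n_columns,) codon index, -1 masked
    ambiguous: np.ndarray         # (n_columns,) bool: all three leaves distinct
    n_by_branch: dict[str, np.ndarray]
    s_by_branch: dict[str, np.ndarray]


def infer_ancestral_codons(trio: CodonTrioAlignment) -> AncestralAssignment:
    """Majority-rule parsimony per codon column: the ancestral codon is the
    codon shared by at least two of {copy1, copy2, outgroup}; when all
    three differ the outgroup codon is taken and the column flagged
    ambiguous."""
    mat = trio.codon_matrix()
    c1, c2, co = mat
    valid = (mat >= 0).all(axis=0)
    anc = np.where(
        c1 == c2, c1, np.where(c1 == co, c1, np.where(c2 == co, c2, co))
    )
    anc = np.where(valid, anc, -1)
    ambiguous = valid & (c1 != c2) & (c1 != co) & (c2 != co)
    n_by, s_by = {}, {}
    for branch, leaf in zip(BRANCHES, (c1, c2, co)):
        n = np.zeros(mat.shape[1])
        s = np.zeros(mat.shape[1])
        n[valid] = SUB_N[anc[valid], leaf[valid]]
        s[valid] = SUB_S[anc[valid], leaf[valid]]
        n_by[branch] = n
        s_by[branch] = s
    return AncestralAssignment(anc, ambiguous, n_by, s_by)


# ---------------------------------------------------------------------------
# branch counts, rates, dS filter
# ---------------------------------------------------------------------------

def jukes_cantor(p: float) -> float:
    """JC69 distance correction d = -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} >= 3/4, distance saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class BranchStat:
    """NG86 counts and corrected rates for one branch of the trio."""

    N: float
    S: float
    N_sites: float
    S_sites: float
    dN: float          # nan when saturated or sites are 0
    dS: float
    saturated_N: bool = False
    saturated_S: bool = False

    @property
    def omega(self) -> float | None:
        """dN/dS; undefined (None) when dS is 0 or either rate saturated."""
        if math.isnan(self.dN) or math.isnan(self.dS) or self.dS == 0:
            return None
        return self.dN / self.dS


@dataclass(frozen=True)
class BranchCounts:
    """Per-branch substitution counts for one trio (branches: copy1, copy2,
    outgroup, all measured from the duplication-node ancestor)."""

    pair_id: str
    branches: dict[str, BranchStat]
    n_unmasked_columns: int
    n_ambiguous_columns: int = 0

    def __getitem__(self, branch: str) -> BranchStat:
        return self.branches[branch]


def _branch_stat(N, S, n_sites, s_sites) -> BranchStat:
    def corrected(count, sites):
        if sites <= 0:
            return float("nan"), False
        p = count / sites
        try:
            return jukes_cantor(p), False
        except SaturationError:
            return float("nan"), True

    dN, sat_n = corrected(N, n_sites)
    dS, sat_s = corrected(S, s_sites)
    return BranchStat(N, S, n_sites, s_sites, dN, dS, sat_n, sat_s)


def branch_counts(
    trio: CodonTrioAlignment,
    columns: np.ndarray | list[int] | None = None,
    assignment: AncestralAssignment | None = None,
) -> BranchCounts:
    """Sum NG86 substitution and site counts per branch over the given
    codon columns (default: all). Sites are averaged between the ancestral
    and descendant codon of each column (symmetric convention)."""
    if assignment is None:
        assignment = infer_ancestral_codons(trio)
    mat = trio.codon_matrix()
    n_cols = mat.shape[1]
    if columns is None:
        weights = np.ones(n_cols)
    else:
        cols = np.asarray(columns, dtype=np.int64)
        if cols.size and (cols.min() < 0 or cols.max() >= n_cols):
            raise ParasymError("column subset out of range")
        # repeated columns (bootstrap resampling) keep their multiplicity
        weights = np.bincount(cols, minlength=n_cols).astype(float)
    valid = assignment.ancestor >= 0
    w = weights * valid
    anc_safe = np.where(valid, assignment.ancestor, 0)
    stats = {}
    for branch, leaf_row in zip(BRANCHES, mat):
        leaf_safe = np.where(valid, leaf_row, 0)
        N = float((assignment.n_by_branch[branch] * w).sum())
        S = float((assignment.s_by_branch[branch] * w).sum())
        n_sites = float(((SITE_N[anc_safe] + SITE_N[leaf_safe]) / 2.0 * w).sum())
        s_sites = float(((SITE_S[anc_safe] + SITE_S[leaf_safe]) / 2.0 * w).sum())
        stats[branch] = _branch_stat(N, S, n_sites, s_sites)
    return BranchCounts(
        trio.pair_id,
        stats,
        n_unmasked_columns=int(w.sum()),
        n_ambiguous_columns=int((assignment.ambiguous * weights).sum()),
    )


def ds_filter(bc: BranchCounts, lo: float = 0.2, hi: float = 2.0) -> bool:
    """Admission filter on the duplicate branches: both dS values must be
    reasonably large (>= lo, default 0.2) yet unsaturated (<= hi, default
    2.0). Undefined dS fails the filter with a warning."""
    for branch in ("copy1", "copy2"):
        ds = bc[branch].dS
        if math.isnan(ds):
            warnings.warn(
                f"{bc.pair_id}/{branch}: dS undefined (saturated or no sites); "
                "pair rejected", stacklevel=2,
            )
            return False
        if not (lo <= ds <= hi):
            return False
    return True


def pairwise_stat(trio: CodonTrioAlignment, role_x: str, role_y: str) -> BranchStat:
    """Direct two-sequence NG86 comparison between two members of the trio
    (no ancestral inference); used for distance-based initialization and
    for measuring the near-saturated duplicate-to-outgroup path."""
    mat = trio.codon_matrix()
    rows = {b: mat[i] for i, b in enumerate(BRANCHES)}
    x, y = rows[role_x], rows[role_y]
    valid = (x >= 0) & (y >= 0)
    xv, yv = x[valid], y[valid]
    N = float(SUB_N[xv, yv].sum())
    S = float(SUB_S[xv, yv].sum())
    n_sites = float(((SITE_N[xv] + SITE_N[yv]) / 2.0).sum())
    s_sites = float(((SITE_S[xv] + SITE_S[yv]) / 2.0).sum())
    return _branch_stat(N, S, n_sites, s_sites)


def read_branch_counts_tsv(path) -> dict[str, BranchCounts]:
    """Import externally computed per-branch counts (columns pair_id,
    branch, N, S, dN, dS), e.g. parsed codeml output, as BranchCounts with
    site counts unavailable (set to nan)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = {}
    for pid, grp in df.groupby("pair_id", sort=False):
        stats = {}
        for r in grp.itertuples():
            stats[str(r.branch)] = BranchStat(
                N=float(r.N), S=float(r.S),
                N_sites=float("nan"), S_sites=float("nan"),
                dN=float(r.dN), dS=float(r.dS),
            )
        missing = set(BRANCHES) - set(stats)
        if missing:
            raise ParasymError(f"{pid}: missing branches {sorted(missing)}")
        out[str(pid)] = BranchCounts(str(pid), stats, n_unmasked_columns=0)
    return out
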