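"""Synthetic-data generators: codon trios evolved on the unrooted
three-leaf tree under the GY94 model (with optional per-domain, per-branch
omega overrides), matching domain architectures, paired expression profiles
with controllable overlap, and the null-simulation false-positive
experiment for the Fisher-exact asymmetry pipeline.

The default null scenario mirrors the study conditions: neutral evolution
(omega = 1 on every branch), equal duplicate branch lengths chosen so each
duplicate branch shows dS near 0.6 under the counting engine, and an
outgroup branch long enough that the leaf-to-outgroup synonymous distance
approaches saturation (dS near 2), kappa = 2, uniform sense-codon root
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import asymmetry as _asymmetry
from .genetics import CODON_AA, N_CODONS, SENSE_CODONS
from .model import CodonModelParams, _transition_matrix, uniform_pi
from .seqio import (
    BRANCHES,
    CodonTrioAlignment,
    DomainArchitecture,
    ExpressionProfile,
    ParasymError,
)

# Duplicate-branch length (expected substitutions per codon) giving
# counting-engine dS ~ 0.6 per duplicate branch, and outgroup branch length
# making the duplicate-leaf-to-outgroup synonymous path ~ 2 (near the
# admission ceiling, matching the observation that the fish-mouse distance
# is close to saturation).
NULL_T_DUPLICATE = 0.45
NULL_T_OUTGROUP = 6.0


@dataclass(frozen=True)
class SimulationScenario:
    """One generative setting for trio simulation."""

    n_codons: int
    t_by_branch: dict[str, float] = field(
        default_factory=lambda: {
            "copy1": NULL_T_DUPLICATE,
            "copy2": NULL_T_DUPLICATE,
            "outgroup": NULL_T_OUTGROUP,
        }
    )
    kappa: float = 2.0
    pi: np.ndarray | None = None        # None -> uniform over 61 sense codons
    omega_by_branch: dict[str, float] = field(
        default_factory=lambda: {b: 1.0 for b in BRANCHES}
    )
    # domain layout: (name, start_aa, end_aa) 1-based inclusive
    domain_layout: tuple[tuple[str, int, int], ...] = ()
    # (domain_name, branch) -> omega override inside that domain
    omega_overrides: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_codons < 1:
            raise ParasymError("n_codons must be >= 1")
        for d in (self.t_by_branch, self.omega_by_branch):
            for b in BRANCHES:
                if d[b] < 0:
                    raise ParasymError(f"negative rate for branch {b}")
        for name, start, end in self.domain_layout:
            if not (1 <= start <= end <= self.n_codons):
                raise ParasymError(f"domain {name} outside sequence")

    def resolved_pi(self) -> np.ndarray:
        return uniform_pi() if self.pi is None else np.asarray(self.pi, float)


def _segments(scenario: SimulationScenario):
    """Split 0-based codon columns into (columns, domain_name-or-None)
    segments following the layout."""
    covered = np.full(scenario.n_codons, -1)
    for k, (name, start, end) in enumerate(scenario.domain_layout):
        covered[start - 1 : end] = k
    segs = []
    for k, (name, _, _) in enumerate(scenario.domain_layout):
        segs.append((np.flatnonzero(covered == k), name))
    free = np.flatnonzero(covered < 0)
    if free.size:
        segs.append((free, None))
    return segs


def _sample_rows(p: np.ndarray, rows: np.ndarray, rng: np.random.Generator):
    """Sample one categorical draw per element of `rows` from matrix row
    p[rows[i], :]."""
    cum = np.cumsum(p, axis=1)
    u = rng.random(rows.size)
    return (u[:, None] > cum[rows]).sum(axis=1)


def simulate_trio(
    scenario: SimulationScenario, pair_id: str = "sim"
) -> tuple[CodonTrioAlignment, str]:
    """Draw a root (duplication-node) sequence from pi and evolve it
    independently along the three branches under GY94 transition matrices,
    applying per-domain omega overrides segment-wise. Returns the leaf trio
    and the true ancestral sequence."""
    rng = np.random.default_rng(scenario.seed)
    pi = scenario.resolved_pi()
    root = _sample_rows(pi[None, :], np.zeros(scenario.n_codons, dtype=np.int64), rng)
    leaves = {}
    for branch in BRANCHES:
        des = np.empty(scenario.n_codons, dtype=np.int64)
        for cols, domain in _segments(scenario):
            omega = scenario.omega_overrides.get(
                (domain, branch), scenario.omega_by_branch[branch]
            )
            params = CodonModelParams(
                scenario.kappa, pi,
                {b: omega for b in BRANCHES},
                {b: scenario.t_by_branch[branch] for b in BRANCHES},
            )
            p = _transition_matrix(params, branch)
            des[cols] = _sample_rows(p, root[cols], rng)
        leaves[branch] = des
    decode = np.array(SENSE_CODONS)

    def to_seq(idx):
        return "".join(decode[idx])

    trio = CodonTrioAlignment(
        pair_id, to_seq(leaves["copy1"]), to_seq(leaves["copy2"]),
        to_seq(leaves["outgroup"]),
    )
    return trio, to_seq(root)


def nonsynonymous_changes_vs_truth(trio: CodonTrioAlignment, ancestor: str) -> dict[str, int]:
    """Count codon columns whose amino acid differs from the true ancestor,
    per branch (a truth-record diagnostic for the simulator)."""
    anc_aa = [CODON_AA[SENSE_CODONS.index(ancestor[i : i + 3])]
              for i in range(0, len(ancestor), 3)]
    out = {}
    for branch, seq in trio.sequences().items():
        leaf_aa = [CODON_AA[SENSE_CODONS.index(seq[i : i + 3])]
                   for i in range(0, len(seq), 3)]
        out[branch] = sum(a != b for a, b in zip(anc_aa, leaf_aa))
    return out


def simulate_domain_scenario(
    layout: tuple[tuple[str, int, int], ...],
    omega_fast: float,
    target_branch: str,
    scenario: SimulationScenario,
    fast_domains: tuple[str, ...] | None = None,
    pair_id: str = "sim",
) -> tuple[CodonTrioAlignment, dict[str, DomainArchitecture], str]:
    """Scenario where selected domains (default: the first) evolve at
    omega_fast on one branch while everything else keeps the background
    omega; emits identical architectures for all three proteins."""
    if fast_domains is None:
        fast_domains = (layout[0][0],)
    overrides = dict(scenario.omega_overrides)
    for name in fast_domains:
        overrides[(name, target_branch)] = omega_fast
    scen = replace(scenario, domain_layout=tuple(layout), omega_overrides=overrides)
    trio, ancestor = simulate_trio(scen, pair_id=pair_id)
    archs = {
        role: DomainArchitecture(f"{pair_id}|{role}", tuple(layout))
        for role in BRANCHES
    }
    return trio, archs, ancestor


def false_positive_experiment(
    n_reps: int = 1000,
    n_codons: int = 10_000,
    alpha: float = 0.05,
    fdr: float = 0.10,
    seed: int = 0,
    scenario: SimulationScenario | None = None,
) -> float:
    """Null calibration of the whole-protein FET pipeline: simulate
    replicate trios under neutral, rate-symmetric evolution, run the
    counting engine and the two-sided FET per replicate, apply BH FDR
    across replicates, and report the fraction with p <= alpha that
    survive the FDR cut."""
    from .counting import branch_counts

    base = scenario or SimulationScenario(n_codons=n_codons)
    pvals = np.empty(n_reps)
    root_rng = np.random.default_rng(seed)
    child_seeds = root_rng.integers(0, 2**31 - 1, size=n_reps)
    for i in range(n_reps):
        scen = replace(base, n_codons=n_codons, seed=int(child_seeds[i]))
        trio, _ = simulate_trio(scen, pair_id=f"null{i}")
        bc = branch_counts(trio)
        table = _asymmetry.build_table(bc, level="WPA")
        pvals[i] = _asymmetry.fisher_exact_2x2(*table)
    qvals = _asymmetry.bh_fdr(list(pvals))
    flagged = (pvals <= alpha) & (np.asarray(qvals) <= fdr)
    return float(flagged.mean())


def simulate_expression(
    n_pairs: int,
    target_jaccard: float,
    n_terms: int,
    stages: tuple[str, ...] = ("stage1",),
    seed: int = 0,
    vocabulary_size: int = 10_000,
) -> list[tuple[ExpressionProfile, ExpressionProfile]]:
    """Paired per-stage anatomy-term sets whose expected Jaccard overlap
    equals target_jaccard. Each gene gets n_terms terms per stage; the
    shared count k solves J = k / (2*n_terms - k), randomized between
    floor and ceil so the expectation matches exactly."""
    if not 0.0 <= target_jaccard <= 1.0:
        raise ParasymError("target_jaccard must be in [0, 1]")
    if n_terms < 1:
        raise ParasymError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    k_exact = 2.0 * n_terms * target_jaccard / (1.0 + target_jaccard)
    pairs = []
    for p in range(n_pairs):
        profiles = ({}, {})
        for stage in stages:
            k = int(np.floor(k_exact))
            if rng.random() < (k_exact - k):
                k += 1
            need = 2 * n_terms - k
            if need > vocabulary_size:
                raise ParasymError("vocabulary too small for requested sets")
            terms = rng.choice(vocabulary_size, size=need, replace=False)
            shared = [f"term{t}" for t in terms[:k]]
            uniq1 = [f"term{t}" for t in terms[k : n_terms]]
            uniq2 = [f"term{t}" for t in terms[n_terms : need]]
            set1 = frozenset(shared + uniq1)
            set2 = frozenset(shared + uniq2)
            if set1:
                profiles[0][stage] = set1
            if set2:
                profiles[1][stage] = set2
        pairs.append(
            (
                ExpressionProfile(f"pair{p}|copy1", profiles[0]),
                ExpressionProfile(f"pair{p}|copy2", profiles[1]),
            )
        )
    return pairs
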