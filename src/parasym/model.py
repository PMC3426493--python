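"""Goldman–Yang (1994) codon substitution model on the unrooted three-leaf
trio tree: rate matrices, Felsenstein-pruning likelihood, free vs
equal-omega constrained fits, and the likelihood-ratio test for asymmetric
evolution of the two duplicate branches.

Parameters per branch b: length t_b in expected substitutions per codon
(each branch's generator is rescaled to unit mean rate at that branch's
omega) and omega_b = dN/dS. kappa (transition/transversion rate ratio) and
the codon frequencies pi (F3x4 by default) are shared across branches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .counting import branch_counts
from .genetics import (
    IS_SYNONYMOUS,
    IS_TRANSITION,
    N_CODONS,
    SENSE_CODONS,
    SINGLE_STEP,
)
from .seqio import BRANCHES, CodonTrioAlignment, ParasymError

_PI_FLOOR = 1e-6


@dataclass(frozen=True)
class CodonModelParams:
    """GY94 parameters for the three-branch trio tree."""

    kappa: float
    pi: np.ndarray                      # (61,) sense-codon frequencies
    omega_by_branch: dict[str, float]
    t_by_branch: dict[str, float]

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        if pi.shape != (N_CODONS,):
            raise ParasymError(f"pi must have shape ({N_CODONS},)")
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ParasymError("pi must sum to 1 (tolerance 1e-9)")
        if not (np.isfinite(self.kappa) and self.kappa > 0):
            raise ParasymError("kappa must be positive and finite")
        for d in (self.omega_by_branch, self.t_by_branch):
            for b in BRANCHES:
                v = d.get(b)
                if v is None or not np.isfinite(v) or v < 0:
                    raise ParasymError(f"invalid parameter for branch {b}: {v}")


def uniform_pi() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f3x4_frequencies(trio: CodonTrioAlignment) -> np.ndarray:
    """Empirical F3x4 codon frequencies: the product of position-specific
    nucleotide frequencies over the trio's unmasked codons, renormalized
    over the 61 sense codons with a small floor against zeros."""
    counts = np.zeros((3, 4))
    nt_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    for seq in trio.sequences().values():
        su = seq.upper()
        for col in trio.unmasked_columns():
            for pos in range(3):
                counts[pos, nt_index[su[3 * col + pos]]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, nt_index[c[0]]] * freqs[1, nt_index[c[1]]] * freqs[2, nt_index[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    pi = np.maximum(pi, _PI_FLOOR)
    return pi / pi.sum()


def rate_matrix(params: CodonModelParams, branch: str) -> np.ndarray:
    """GY94 generator for one branch: q_ij = pi_j * kappa^[transition] *
    omega^[non-synonymous] for single-nucleotide changes, 0 otherwise;
    rows sum to zero; rescaled so the mean rate at equilibrium is 1."""
    omega = params.omega_by_branch[branch]
    fac = np.where(SINGLE_STEP, 1.0, 0.0)
    fac = fac * np.where(IS_TRANSITION, params.kappa, 1.0)
    fac = fac * np.where(IS_SYNONYMOUS, 1.0, omega)
    q = fac * params.pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -(params.pi * np.diag(q)).sum()
    if mean_rate > 0:
        q = q / mean_rate
    return q


def _transition_matrix(params: CodonModelParams, branch: str) -> np.ndarray:
    """P(t) = expm(Q t) via symmetric eigendecomposition (GY94 is
    reversible)."""
    q = rate_matrix(params, branch)
    t = params.t_by_branch[branch]
    if t == 0:
        return np.eye(N_CODONS)
    sqrt_pi = np.sqrt(params.pi)
    b = q * (sqrt_pi[:, None] / sqrt_pi[None, :])
    b = (b + b.T) / 2.0  # symmetrize against rounding
    w, u = np.linalg.eigh(b)
    e = np.exp(w * t)
    p = (u * e[None, :]) @ u.T
    p = p * (sqrt_pi[None, :] / sqrt_pi[:, None])
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


def _site_patterns(trio: CodonTrioAlignment):
    mat = trio.codon_matrix()
    cols = trio.unmasked_columns()
    obs = mat[:, cols]
    patterns, counts = np.unique(obs, axis=1, return_counts=True)
    return patterns, counts


def log_likelihood(
    trio: CodonTrioAlignment,
    params: CodonModelParams,
    _patterns=None,
) -> float:
    """Felsenstein pruning on the unrooted 3-leaf tree, rooted at the
    single internal node: per column, sum over the 61 ancestral states of
    pi_a times the three branch transition probabilities to the observed
    leaf codons; product over unmasked columns."""
    patterns, counts = _patterns if _patterns is not None else _site_patterns(trio)
    lik = params.pi[:, None] * np.ones((1, patterns.shape[1]))
    for branch, leaf in zip(BRANCHES, patterns):
        p = _transition_matrix(params, branch)
        lik = lik * p[:, leaf]
    col_lik = lik.sum(axis=0)
    if np.any(col_lik <= 0) or not np.all(np.isfinite(col_lik)):
        bad = int(np.argmin(col_lik))
        raise ParasymError(f"non-finite column likelihood at pattern {bad}")
    return float(np.dot(np.log(col_lik), counts))


@dataclass(frozen=True)
class LikelihoodFit:
    params: CodonModelParams
    lnL: float
    model_tag: str       # "free" | "constrained"
    converged: bool
    n_starts: int = 1


_LOG_BOUNDS = (math.log(1e-4), math.log(50.0))


def _initial_guess(trio: CodonTrioAlignment) -> CodonModelParams:
    """Counting-based starting point. Branch lengths come from pairwise
    NG86 distances split by the three-point formula (parsimony badly
    underestimates the long outgroup branch, so per-branch parsimony
    counts are not used for t); omega per branch from parsimony dN/dS."""
    from .counting import pairwise_stat

    n_cols = max(len(trio.unmasked_columns()), 1)

    def dist(x, y):
        st = pairwise_stat(trio, x, y)
        dn = st.dN if math.isfinite(st.dN) else 3.0
        ds = st.dS if math.isfinite(st.dS) else 3.0
        return (dn * st.N_sites + ds * st.S_sites) / n_cols

    d12 = dist("copy1", "copy2")
    d1o = dist("copy1", "outgroup")
    d2o = dist("copy2", "outgroup")
    t = {
        "copy1": float(np.clip((d12 + d1o - d2o) / 2.0, 2e-3, 20.0)),
        "copy2": float(np.clip((d12 + d2o - d1o) / 2.0, 2e-3, 20.0)),
        "outgroup": float(np.clip((d1o + d2o - d12) / 2.0, 2e-3, 20.0)),
    }
    bc = branch_counts(trio)
    omega = {}
    for b in BRANCHES:
        om = bc[b].omega
        omega[b] = float(np.clip(om if om is not None else 1.0, 0.01, 10.0))
    return CodonModelParams(2.0, f3x4_frequencies(trio), omega, t)


def _pack(params: CodonModelParams, constrained: bool) -> np.ndarray:
    x = [math.log(params.kappa)]
    x += [math.log(max(params.t_by_branch[b], 1e-4)) for b in BRANCHES]
    if constrained:
        om = (params.omega_by_branch["copy1"] + params.omega_by_branch["copy2"]) / 2
        x += [math.log(max(om, 1e-4)),
              math.log(max(params.omega_by_branch["outgroup"], 1e-4))]
    else:
        x += [math.log(max(params.omega_by_branch[b], 1e-4)) for b in BRANCHES]
    return np.array(x)


def _unpack(x: np.ndarray, pi: np.ndarray, constrained: bool) -> CodonModelParams:
    vals = np.exp(x)
    t = dict(zip(BRANCHES, vals[1:4]))
    if constrained:
        omega = {"copy1": vals[4], "copy2": vals[4], "outgroup": vals[5]}
    else:
        omega = dict(zip(BRANCHES, vals[4:7]))
    return CodonModelParams(vals[0], pi, omega, t)


def fit(
    trio: CodonTrioAlignment,
    constrain_equal_omega: bool,
    n_starts: int = 3,
    seed: int = 0,
    init: CodonModelParams | None = None,
) -> LikelihoodFit:
    """Maximize the GY94 log-likelihood over kappa, the three branch
    lengths and the branch omegas (constrained model ties
    omega_copy1 = omega_copy2; the outgroup omega stays free in both
    models). pi is fixed at the trio's empirical F3x4 frequencies.

    The first start is a counting-based guess (optionally overridden by
    ``init``); additional starts perturb it multiplicatively with a seeded
    RNG. Convergence tolerance is 1e-6 on lnL.
    """
    patterns = _site_patterns(trio)
    guess = init if init is not None else _initial_guess(trio)
    pi = guess.pi
    rng = np.random.default_rng(seed)

    def neg_lnl(x):
        try:
            return -log_likelihood(trio, _unpack(x, pi, constrain_equal_omega),
                                   _patterns=patterns)
        except (ParasymError, FloatingPointError):
            return 1e12

    x0 = _pack(guess, constrain_equal_omega)
    bounds = [_LOG_BOUNDS] * len(x0)
    best = None
    any_converged = False
    for start in range(max(n_starts, 1)):
        xs = x0 if start == 0 else np.clip(
            x0 + rng.normal(0.0, 0.5, size=x0.shape), *_LOG_BOUNDS
        )
        res = optimize.minimize(
            neg_lnl, xs, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-9, "gtol": 1e-7, "maxfun": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
        any_converged = any_converged or bool(res.success)
    params = _unpack(best.x, pi, constrain_equal_omega)
    return LikelihoodFit(
        params=params,
        lnL=-float(best.fun),
        model_tag="constrained" if constrain_equal_omega else "free",
        converged=any_converged and math.isfinite(best.fun),
        n_starts=max(n_starts, 1),
    )


def lrt_asymmetry(free: LikelihoodFit, constrained: LikelihoodFit,
                  tol: float = 1e-4) -> tuple[float, float]:
    """LRT statistic 2*|lnL_free - lnL_constrained| against chi-square with
    one degree of freedom (the single tied omega)."""
    if not (free.converged and constrained.converged):
        raise ParasymError("LRT requires two converged fits")
    delta = free.lnL - constrained.lnL
    if delta < -tol:
        raise ParasymError(
            f"free-model lnL {free.lnL:.6f} below constrained {constrained.lnL:.6f}"
        )
    statistic = 2.0 * abs(delta)
    return statistic, float(stats.chi2.sf(statistic, df=1))


def lrt_for_trio(
    trio: CodonTrioAlignment, n_starts: int = 3, seed: int = 0
) -> tuple[LikelihoodFit, LikelihoodFit, float, float]:
    """Convenience: fit both models and run the LRT. The free fit is also
    started from the constrained optimum, which guarantees
    lnL_free >= lnL_constrained up to optimizer tolerance."""
    constrained = fit(trio, True, n_starts=n_starts, seed=seed)
    free = fit(trio, False, n_starts=n_starts, seed=seed + 1)
    free_from_c = fit(trio, False, n_starts=1, init=constrained.params)
    if free_from_c.lnL > free.lnL:
        free = replace(free_from_c, n_starts=free.n_starts + 1)
    statistic, p = lrt_asymmetry(free, constrained)
    return free, constrained, statistic, p
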