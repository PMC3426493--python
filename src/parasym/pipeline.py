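"""End-to-end orchestration: admission filters, per-branch counting and/or
likelihood-ratio testing, Fisher-exact asymmetry at every requested level,
downstream pattern and divergence analyses, expression overlap, and TSV
report writing with a run manifest.

No silent drops: every excluded pair appears in exclusions.tsv with a
reason code (architecture_mismatch, ds_filter, non_convergence,
missing_architecture).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .asymmetry import (
    LEVELS,
    AsymmetryResult,
    domain_columns,
    test_asymmetry,
)
from .counting import BranchCounts, branch_counts, ds_filter
from .divergence import compare_score_distributions, mean_substitution_score
from .expression import divergence_compare, stage_overlap
from .genetics import CODON_AA, CODON_INDEX
from .model import lrt_for_trio
from .patterns import (
    assortment_analysis,
    clustering_test,
    faster_copy_concordance,
    family_asymmetry_frequency,
    interleaving_runs_test,
    stouffer_combine,
)
from .seqio import (
    BRANCHES,
    CodonTrioAlignment,
    DomainArchitecture,
    ExpressionProfile,
    ParasymError,
    architectures_identical,
)

logger = logging.getLogger("parasym")


@dataclass(frozen=True)
class PairInput:
    """One duplicate pair: the trio alignment, optional per-role domain
    architectures, and optional expression profiles for the two copies."""

    trio: CodonTrioAlignment
    architectures: dict[str, DomainArchitecture] | None = None
    expression: tuple[ExpressionProfile, ExpressionProfile] | None = None

    @property
    def architecture(self) -> DomainArchitecture | None:
        return None if self.architectures is None else self.architectures["copy1"]


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str | Path
    levels: tuple[str, ...] = ("WPA", "CDA", "DSA", "LINKER")
    fdr: float = 0.10
    alpha: float = 0.05
    cluster_alpha: float = 0.05
    ds_lo: float = 0.2
    ds_hi: float = 2.0
    cda_background: str = "protein"
    engine: str = "counting"          # counting | likelihood | both
    seed: int = 0

    def __post_init__(self):
        if self.ds_lo > self.ds_hi:
            raise ParasymError("ds_lo must not exceed ds_hi")
        for name in ("fdr", "alpha", "cluster_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParasymError(f"{name} must be in [0, 1]")
        if self.engine not in ("counting", "likelihood", "both"):
            raise ParasymError(f"unknown engine {self.engine!r}")
        bad = set(self.levels) - set(LEVELS)
        if bad:
            raise ParasymError(f"unknown levels {sorted(bad)}")


def translate_codon_sequence(seq: str) -> str:
    """Aligned nucleotide string to amino acids; masked codons become X."""
    out = []
    for i in range(0, len(seq), 3):
        idx = CODON_INDEX.get(seq[i : i + 3].upper(), -1)
        out.append(CODON_AA[idx] if idx >= 0 else "X")
    return "".join(out)


def admit_pairs(
    pairs: list[PairInput], config: PipelineConfig
) -> tuple[list[PairInput], dict[str, BranchCounts], list[dict]]:
    """Architecture-identity and dS admission filters; returns admitted
    pairs, their whole-protein branch counts, and exclusion records."""
    admitted, counts, exclusions = [], {}, []
    for pair in pairs:
        pid = pair.trio.pair_id
        if pair.architectures is not None:
            archs = [pair.architectures[r] for r in BRANCHES]
            if not architectures_identical(*archs):
                exclusions.append({"pair_id": pid, "reason": "architecture_mismatch"})
                continue
        bc = branch_counts(pair.trio)
        if not ds_filter(bc, lo=config.ds_lo, hi=config.ds_hi):
            exclusions.append({"pair_id": pid, "reason": "ds_filter"})
            continue
        admitted.append(pair)
        counts[pid] = bc
    return admitted, counts, exclusions


def _asym_to_frame(results: list[AsymmetryResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair_id": r.pair_id, "level": r.level,
                "domain_name": r.domain_name or "",
                "N1": r.table[0], "S1": r.table[1],
                "N2": r.table[2], "S2": r.table[3],
                "p_value": r.p_value, "q_value": r.q_value,
                "significant": r.significant, "faster_copy": r.faster_copy,
            }
            for r in results
        ]
    )


def _per_domain_ns(pair: PairInput) -> dict[str, dict[str, tuple[int, int]]]:
    """Rounded per-domain (N, S) counts per duplicate copy."""
    from .asymmetry import round_half_away

    trio = pair.trio
    cols_by_domain = domain_columns(pair.architecture, trio.n_columns)
    out = {b: {} for b in ("copy1", "copy2")}
    for name, cols in cols_by_domain.items():
        bc = branch_counts(trio, columns=cols)
        for b in ("copy1", "copy2"):
            out[b][name] = (round_half_away(bc[b].N), round_half_away(bc[b].S))
    return out


def _unique_substitution_labels(pair: PairInput) -> list[str]:
    """Position-ordered labels of amino-acid positions uniquely mutated in
    exactly one copy relative to the parsimony ancestor (outgroup codon as
    proxy where the copies disagree both ways)."""
    from .counting import infer_ancestral_codons

    assignment = infer_ancestral_codons(pair.trio)
    mat = pair.trio.codon_matrix()
    labels = []
    for col in np.flatnonzero(assignment.ancestor >= 0):
        anc = assignment.ancestor[col]
        d1 = CODON_AA[mat[0, col]] != CODON_AA[anc]
        d2 = CODON_AA[mat[1, col]] != CODON_AA[anc]
        if d1 and not d2:
            labels.append("copy1")
        elif d2 and not d1:
            labels.append("copy2")
    return labels


def run_pipeline(pairs: list[PairInput], config: PipelineConfig) -> dict:
    """Execute the full analysis over a batch of duplicate pairs and write
    one TSV per analysis plus a JSON run manifest into config.out_dir.
    Returns the report bundle as a dict of DataFrames / dicts."""
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings = {}
    bundle: dict[str, object] = {}

    step = time.time()
    admitted, counts, exclusions = admit_pairs(pairs, config)
    timings["admission"] = time.time() - step
    excl_df = pd.DataFrame(exclusions, columns=["pair_id", "reason"])

    # per-branch counts report
    step = time.time()
    count_rows = []
    for pid, bc in counts.items():
        for b in BRANCHES:
            st = bc[b]
            count_rows.append({
                "pair_id": pid, "branch": b, "N": st.N, "S": st.S,
                "N_sites": st.N_sites, "S_sites": st.S_sites,
                "dN": st.dN, "dS": st.dS,
                "omega": st.omega if st.omega is not None else float("nan"),
            })
    bundle["branch_counts"] = pd.DataFrame(count_rows)
    timings["counting"] = time.time() - step

    # likelihood engine
    if config.engine in ("likelihood", "both"):
        step = time.time()
        lrt_rows = []
        for pair in admitted:
            pid = pair.trio.pair_id
            try:
                free, constrained, stat, p = lrt_for_trio(
                    pair.trio, n_starts=1, seed=config.seed
                )
            except ParasymError as exc:
                exclusions.append({"pair_id": pid, "reason": "non_convergence"})
                logger.warning("LRT failed for %s: %s", pid, exc)
                continue
            lrt_rows.append({
                "pair_id": pid, "lnL_free": free.lnL,
                "lnL_constrained": constrained.lnL,
                "statistic": stat, "p_value": p,
                "omega1": free.params.omega_by_branch["copy1"],
                "omega2": free.params.omega_by_branch["copy2"],
                "converged": free.converged and constrained.converged,
            })
        bundle["lrt"] = pd.DataFrame(lrt_rows)
        timings["likelihood"] = time.time() - step
        excl_df = pd.DataFrame(exclusions, columns=["pair_id", "reason"])

    # FET asymmetry per level
    step = time.time()
    with_arch = [p for p in admitted if p.architectures is not None]
    asym_by_level: dict[str, list[AsymmetryResult]] = {}
    if config.engine in ("counting", "both"):
        for level in config.levels:
            if level == "WPA":
                units = [(p.trio, p.architecture) for p in admitted]
            else:
                units = [(p.trio, p.architecture) for p in with_arch]
            if not units:
                continue
            results = test_asymmetry(
                units, level, fdr=config.fdr, cda_background=config.cda_background
            )
            asym_by_level[level] = results
            bundle[f"asymmetry_{level.lower()}"] = _asym_to_frame(results)
    timings["fet"] = time.time() - step

    # downstream domain patterns (need DSA results and architectures)
    if "DSA" in asym_by_level:
        step = time.time()
        dsa = asym_by_level["DSA"]
        sig_by_pair: dict[str, list[AsymmetryResult]] = {}
        for r in dsa:
            sig_by_pair.setdefault(r.pair_id, []).append(r)

        cluster_rows = []
        flags_per_protein = []
        faster_per_pair = []
        runs_rows = []
        for pair in with_arch:
            pid = pair.trio.pair_id
            res = sig_by_pair.get(pid, [])
            flags = [r.significant for r in res]
            if len(pair.architecture.domain_names) >= 2:
                flags_per_protein.append(flags)
                per_dom = _per_domain_ns(pair)
                for copy_id in ("copy1", "copy2"):
                    for cr in clustering_test(
                        pid, copy_id, per_dom[copy_id], alpha=config.cluster_alpha
                    ):
                        cluster_rows.append({
                            "pair_id": cr.pair_id, "copy": cr.copy_id,
                            "domain_name": cr.domain_name,
                            "N_dom": cr.table[0], "S_dom": cr.table[1],
                            "N_other": cr.table[2], "S_other": cr.table[3],
                            "p_value": cr.p_value, "clustered": cr.clustered,
                        })
            fasters = [r.faster_copy for r in res if r.significant]
            if len(fasters) >= 2:
                faster_per_pair.append(fasters)
            labels = _unique_substitution_labels(pair)
            if len(set(labels)) == 2:
                runs, p_runs = interleaving_runs_test(labels)
                runs_rows.append({
                    "pair_id": pid, "n_positions": len(labels),
                    "runs": runs, "p_value": p_runs,
                })
        bundle["clustering"] = pd.DataFrame(cluster_rows)
        if flags_per_protein:
            bundle["assortment"] = assortment_analysis(
                flags_per_protein, seed=config.seed
            )
        if faster_per_pair:
            bundle["faster_copy_concordance"] = faster_copy_concordance(faster_per_pair)
        runs_df = pd.DataFrame(runs_rows)
        bundle["interleaving"] = runs_df
        if len(runs_df):
            bundle["interleaving_combined_p"] = stouffer_combine(
                list(runs_df["p_value"])
            )
        timings["patterns"] = time.time() - step

        # BLOSUM62 divergence scores per domain
        step = time.time()
        score_rows = []
        sig_lookup = {
            (r.pair_id, r.domain_name): r.significant for r in dsa
        }
        for pair in with_arch:
            pid = pair.trio.pair_id
            aa1 = translate_codon_sequence(pair.trio.seq_copy1)
            aa2 = translate_codon_sequence(pair.trio.seq_copy2)
            for name, start, end in pair.architecture.intervals:
                ds = mean_substitution_score(
                    aa1[start - 1 : end], aa2[start - 1 : end], pid, name
                )
                if ds.mean_score is None:
                    continue
                score_rows.append({
                    "pair_id": pid, "domain_name": name,
                    "n_substituted_positions": ds.n_substituted_positions,
                    "mean_score": ds.mean_score,
                    "asymmetric": bool(sig_lookup.get((pid, name), False)),
                })
        scores_df = pd.DataFrame(score_rows)
        bundle["domain_scores"] = scores_df
        if len(scores_df):
            asym_scores = list(scores_df[scores_df.asymmetric]["mean_score"])
            sym_scores = list(scores_df[~scores_df.asymmetric]["mean_score"])
            if asym_scores and sym_scores:
                stat, p = compare_score_distributions(asym_scores, sym_scores)
                bundle["score_comparison"] = {
                    "statistic": stat, "p_value": p,
                    "n_asymmetric": len(asym_scores), "n_symmetric": len(sym_scores),
                }
        timings["divergence"] = time.time() - step

        # expression divergence
        step = time.time()
        expr_rows = []
        asym_pairs = {
            pid for pid, res in sig_by_pair.items() if any(r.significant for r in res)
        }
        for pair in with_arch:
            if pair.expression is None:
                continue
            pid = pair.trio.pair_id
            for ov in stage_overlap(*pair.expression, pair_id=pid):
                expr_rows.append({
                    "pair_id": pid, "stage": ov.stage, "jaccard": ov.jaccard,
                    "asymmetric": pid in asym_pairs,
                })
        expr_df = pd.DataFrame(expr_rows)
        bundle["expression_overlap"] = expr_df
        if len(expr_df):
            a = list(expr_df[expr_df.asymmetric]["jaccard"])
            b = list(expr_df[~expr_df.asymmetric]["jaccard"])
            if a and b:
                stat, p = divergence_compare(a, b)
                bundle["expression_comparison"] = {"statistic": stat, "p_value": p}
        timings["expression"] = time.time() - step

    bundle["exclusions"] = excl_df

    # write reports
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    manifest = {
        "parasym_version": __version__,
        "seed": config.seed,
        "thresholds": {
            "fdr": config.fdr, "alpha": config.alpha,
            "cluster_alpha": config.cluster_alpha,
            "ds_lo": config.ds_lo, "ds_hi": config.ds_hi,
        },
        "engine": config.engine,
        "levels": list(config.levels),
        "n_pairs_input": len(pairs),
        "n_pairs_admitted": len(admitted),
        "input_checksum": _pairs_checksum(pairs),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "scalars": {
            k: v for k, v in bundle.items()
            if isinstance(v, (int, float, dict)) and k != "exclusions"
        },
        "elapsed_s": round(time.time() - t0, 3),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    bundle["manifest"] = manifest
    return bundle


def _pairs_checksum(pairs: list[PairInput]) -> str:
    h = hashlib.sha256()
    for pair in pairs:
        h.update(pair.trio.pair_id.encode())
        for seq in pair.trio.sequences().values():
            h.update(seq.encode())
    return h.hexdigest()[:16]
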