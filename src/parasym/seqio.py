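"""Readers, writers and validation for the pipeline's external data.

Inputs are pre-aligned in-frame codon trios (FASTA), protein domain
architectures (TSV), spatio-temporal expression annotations (TSV) and the
unrooted three-leaf guide tree (newick). All result reports are TSV.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import STOP_CODONS, encode_codon_sequence

BRANCHES = ("copy1", "copy2", "outgroup")

#: default record-id suffix convention assigning trio roles
DEFAULT_ROLE_SUFFIXES = {b: f"|{b}" for b in BRANCHES}

_VALID_CHARS = frozenset("ACGTN-")


class ParasymError(ValueError):
    """Base class for validation failures."""


class TrioValidationError(ParasymError):
    pass


class DomainTableError(ParasymError):
    pass


class ExpressionTableError(ParasymError):
    pass


# ---------------------------------------------------------------------------
# codon trio alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonTrioAlignment:
    """Aligned coding sequences of a duplicate pair plus outgroup ortholog.

    The two duplicates descend from the duplication node; the outgroup
    (mouse ortholog in the original study design) roots the comparison.
    """

    pair_id: str
    seq_copy1: str
    seq_copy2: str
    seq_outgroup: str

    def __post_init__(self):
        seqs = (self.seq_copy1, self.seq_copy2, self.seq_outgroup)
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise TrioValidationError(
                f"{self.pair_id}: unequal sequence lengths {sorted(len(s) for s in seqs)}"
            )
        (length,) = lengths
        if length % 3:
            raise TrioValidationError(
                f"{self.pair_id}: alignment length {length} not divisible by 3"
            )
        for role, seq in zip(BRANCHES, seqs):
            bad = set(seq.upper()) - _VALID_CHARS
            if bad:
                raise TrioValidationError(
                    f"{self.pair_id}/{role}: invalid characters {sorted(bad)}"
                )
            self._check_internal_stops(role, seq.upper(), length // 3)

    def _check_internal_stops(self, role: str, seq: str, n_cols: int):
        for col in range(n_cols - 1):  # terminal stop codon is tolerated
            codon = seq[3 * col : 3 * col + 3]
            if codon in STOP_CODONS:
                raise TrioValidationError(
                    f"{self.pair_id}/{role}: internal stop codon {codon} "
                    f"at codon column {col + 1}"
                )

    @property
    def n_columns(self) -> int:
        return len(self.seq_copy1) // 3

    def sequences(self) -> dict[str, str]:
        return dict(zip(BRANCHES, (self.seq_copy1, self.seq_copy2, self.seq_outgroup)))

    def codon_matrix(self) -> np.ndarray:
        """(3, n_columns) sense-codon index matrix; -1 where the codon in
        that sequence is gapped, ambiguous, or a (terminal) stop."""
        return np.vstack([
            encode_codon_sequence(self.seq_copy1.upper()),
            encode_codon_sequence(self.seq_copy2.upper()),
            encode_codon_sequence(self.seq_outgroup.upper()),
        ])

    def unmasked_columns(self) -> np.ndarray:
        """Indices of codon columns clean (sense codon) in all three
        sequences; only these enter any counting or likelihood."""
        return np.flatnonzero((self.codon_matrix() >= 0).all(axis=0))


def read_trio_fasta(
    path,
    pair_id: str | None = None,
    role_suffixes: dict[str, str] | None = None,
) -> CodonTrioAlignment:
    """Read one aligned trio from a FASTA file with exactly three records
    whose ids carry role suffixes (default ``|copy1``, ``|copy2``,
    ``|outgroup``)."""
    role_suffixes = role_suffixes or DEFAULT_ROLE_SUFFIXES
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 3:
        raise TrioValidationError(f"{path}: expected 3 records, found {len(records)}")
    by_role: dict[str, str] = {}
    for rec in records:
        for role, suffix in role_suffixes.items():
            if rec.id.endswith(suffix):
                if role in by_role:
                    raise TrioValidationError(f"{path}: duplicate role {role}")
                by_role[role] = str(rec.seq)
                break
        else:
            raise TrioValidationError(f"{path}: record id {rec.id!r} matches no role")
    missing = set(BRANCHES) - set(by_role)
    if missing:
        raise TrioValidationError(f"{path}: missing roles {sorted(missing)}")
    if pair_id is None:
        pair_id = records[0].id.rsplit("|", 1)[0]
    return CodonTrioAlignment(pair_id, by_role["copy1"], by_role["copy2"], by_role["outgroup"])


def write_trio_fasta(trio: CodonTrioAlignment, path, role_suffixes=None) -> None:
    role_suffixes = role_suffixes or DEFAULT_ROLE_SUFFIXES
    records = [
        SeqRecord(Seq(seq), id=f"{trio.pair_id}{role_suffixes[role]}", description="")
        for role, seq in trio.sequences().items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# protein domain architectures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered, non-overlapping Pfam-like domain intervals on a protein.

    Coordinates are 1-based inclusive amino-acid positions on the aligned
    protein (codon columns / 3).
    """

    protein_id: str
    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        ordered = tuple(sorted(self.intervals, key=lambda iv: (iv[1], iv[2])))
        object.__setattr__(self, "intervals", ordered)
        prev_end = 0
        for name, start, end in ordered:
            if not (isinstance(start, (int, np.integer)) and isinstance(end, (int, np.integer))):
                raise DomainTableError(f"{self.protein_id}/{name}: non-integer coordinates")
            if start < 1 or start > end:
                raise DomainTableError(
                    f"{self.protein_id}/{name}: bad interval ({start}, {end})"
                )
            if start <= prev_end:
                raise DomainTableError(
                    f"{self.protein_id}/{name}: interval ({start}, {end}) overlaps previous"
                )
            prev_end = end

    @property
    def domain_names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.intervals)


def architectures_identical(
    a1: DomainArchitecture, a2: DomainArchitecture, a3: DomainArchitecture
) -> bool:
    """True iff the ordered domain-name sequences agree across all three
    proteins (coordinates may differ). This is the admission criterion for
    a duplicate pair: both copies and the outgroup ortholog must share the
    architecture."""
    return a1.domain_names == a2.domain_names == a3.domain_names


_DOMAIN_COLUMNS = ["protein_id", "domain_name", "start_aa", "end_aa"]


def read_domain_table(path) -> dict[str, DomainArchitecture]:
    """Read a TSV of domain intervals into one architecture per protein."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return {}
    missing = set(_DOMAIN_COLUMNS) - set(df.columns)
    if missing:
        raise DomainTableError(f"{path}: missing columns {sorted(missing)}")
    for col in ("start_aa", "end_aa"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals != vals.round()).any():
            raise DomainTableError(f"{path}: non-integer values in {col}")
        df[col] = vals.astype(int)
    out = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        out[str(pid)] = DomainArchitecture(
            str(pid),
            tuple(
                (str(r.domain_name), int(r.start_aa), int(r.end_aa))
                for r in grp.itertuples()
            ),
        )
    return out


def write_domain_table(archs, path) -> None:
    rows = [
        {"protein_id": a.protein_id, "domain_name": n, "start_aa": s, "end_aa": e}
        for a in (archs.values() if isinstance(archs, dict) else archs)
        for n, s, e in a.intervals
    ]
    pd.DataFrame(rows, columns=_DOMAIN_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# spatio-temporal expression profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionProfile:
    """Per-developmental-stage sets of anatomy terms where a gene is
    expressed (ZFIN-style annotation)."""

    gene_id: str
    stages: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        for stage, terms in self.stages.items():
            if not terms:
                raise ExpressionTableError(f"{self.gene_id}/{stage}: empty term set")
        object.__setattr__(
            self, "stages", {s: frozenset(t) for s, t in self.stages.items()}
        )


_EXPR_COLUMNS = ["gene_id", "stage", "anatomy_term"]


def read_expression_table(path) -> dict[str, ExpressionProfile]:
    """Read a TSV (gene_id, stage, anatomy_term; one term per row) into
    per-gene profiles, aggregating terms into per-stage sets."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_EXPR_COLUMNS) - set(df.columns)
    if missing:
        raise ExpressionTableError(f"{path}: missing columns {sorted(missing)}")
    if df[_EXPR_COLUMNS].isna().any().any():
        raise ExpressionTableError(f"{path}: malformed rows with missing fields")
    out: dict[str, ExpressionProfile] = {}
    for gid, grp in df.groupby("gene_id", sort=False):
        stages = {
            str(stage): frozenset(sub["anatomy_term"])
            for stage, sub in grp.groupby("stage", sort=False)
        }
        out[str(gid)] = ExpressionProfile(str(gid), stages)
    return out


def write_expression_table(profiles, path) -> None:
    rows = [
        {"gene_id": p.gene_id, "stage": stage, "anatomy_term": term}
        for p in (profiles.values() if isinstance(profiles, dict) else profiles)
        for stage, terms in sorted(p.stages.items())
        for term in sorted(terms)
    ]
    pd.DataFrame(rows, columns=_EXPR_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# guide tree
# ---------------------------------------------------------------------------

def read_tree_newick(path_or_string) -> dict[str, float]:
    """Read the unrooted three-leaf guide tree; returns branch lengths
    keyed by role (leaf labels must be copy1/copy2/outgroup)."""
    if isinstance(path_or_string, (str, Path)) and Path(str(path_or_string)).exists():
        tree = dendropy.Tree.get(path=str(path_or_string), schema="newick")
    else:
        tree = dendropy.Tree.get(data=str(path_or_string), schema="newick")
    lengths = {}
    for leaf in tree.leaf_node_iter():
        label = (leaf.taxon.label if leaf.taxon else "").replace(" ", "_")
        if label not in BRANCHES:
            raise ParasymError(f"unexpected leaf label {label!r}")
        lengths[label] = float(leaf.edge.length or 0.0)
    missing = set(BRANCHES) - set(lengths)
    if missing:
        raise ParasymError(f"tree missing leaves {sorted(missing)}")
    return lengths


def write_tree_newick(t_by_branch: dict[str, float], path) -> None:
    newick = "({}:{:g},{}:{:g},{}:{:g});\n".format(
        "copy1", t_by_branch["copy1"],
        "copy2", t_by_branch["copy2"],
        "outgroup", t_by_branch["outgroup"],
    )
    Path(path).write_text(newick)
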