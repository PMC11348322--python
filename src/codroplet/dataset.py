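"""Labeled protein-pair datasets derived from condensate membership tables.

The positive class is built from co-membership: every unordered pair of
proteins found together in a condensate (of at most ``n_max`` members) is a
positive.  The negative class pairs proteins drawn from small condensates
(at most ``m`` members) that never co-occur in any condensate of the full
table.  A self-pair extension adds (P, P) positives for every condensate
protein and (Q, Q) negatives for proteins outside the condensate world with
no direct protein–protein-interaction link into it.  Sequences longer than
1,024 residues are excluded, redundancy is removed at 50% global-alignment
identity, and the train/test split is condensate-aware so that no condensate
contributes positive pairs to both sides.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align, SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinRecord",
    "PairExample",
    "CondensateTable",
    "PPINetwork",
    "SplitSpec",
    "read_fasta",
    "build_positive_pairs",
    "build_negative_pairs",
    "build_self_pair_dataset",
    "redundancy_filter",
    "filter_by_length",
    "split_by_condensate",
    "rebalance",
    "global_identity",
    "write_pairs_tsv",
    "read_pairs_tsv",
]


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.protein_id}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PairExample:
    """An unordered labeled protein pair (ids stored in lexicographic order)."""

    id_a: str
    id_b: str
    label: int
    source_condensates: frozenset = frozenset()
    is_self_pair: bool = False

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.id_a > self.id_b:
            a, b = self.id_b, self.id_a
            object.__setattr__(self, "id_a", a)
            object.__setattr__(self, "id_b", b)
        object.__setattr__(self, "source_condensates", frozenset(self.source_condensates))

    @property
    def key(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


@dataclass
class CondensateTable:
    """Mapping condensate id -> member protein ids (no empty condensates)."""

    members: dict[str, frozenset]

    def __post_init__(self) -> None:
        self.members = {cid: frozenset(ids) for cid, ids in self.members.items()}
        for cid, ids in self.members.items():
            if not ids:
                raise ValueError(f"condensate {cid!r} has no members")

    @classmethod
    def from_tsv(cls, path) -> "CondensateTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"condensate_id", "protein_id"}
        if not required.issubset(df.columns):
            raise ValueError(f"condensate table needs columns {sorted(required)}, got {list(df.columns)}")
        grouped = df.groupby("condensate_id")["protein_id"].apply(frozenset)
        return cls(dict(grouped))

    def restrict(self, protein_ids) -> "CondensateTable":
        """Drop proteins outside ``protein_ids`` (and condensates left empty)."""
        keep = frozenset(protein_ids)
        members = {cid: ids & keep for cid, ids in self.members.items()}
        return CondensateTable({cid: ids for cid, ids in members.items() if ids})

    def all_proteins(self) -> frozenset:
        out: frozenset = frozenset()
        for ids in self.members.values():
            out |= ids
        return out

    def co_occurring(self) -> set[tuple[str, str]]:
        """Every unordered pair found together in at least one condensate."""
        pairs: set[tuple[str, str]] = set()
        for ids in self.members.values():
            for a, b in itertools.combinations(sorted(ids), 2):
                pairs.add((a, b))
        return pairs


@dataclass
class PPINetwork:
    """Undirected protein–protein interaction edges."""

    edges: set

    def __post_init__(self) -> None:
        cleaned = set()
        for a, b in self.edges:
            if a == b:
                continue
            cleaned.add((min(a, b), max(a, b)))
        self.edges = cleaned

    @classmethod
    def from_tsv(cls, path) -> "PPINetwork":
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = list(df.columns[:2])
        return cls(set(zip(df[cols[0]], df[cols[1]])))

    def neighbors(self, protein_id: str) -> set:
        out = set()
        for a, b in self.edges:
            if a == protein_id:
                out.add(b)
            elif b == protein_id:
                out.add(a)
        return out

    def touches(self, protein_id: str, group: frozenset) -> bool:
        return any((min(protein_id, g), max(protein_id, g)) in self.edges
                   for g in group if g != protein_id)


@dataclass
class SplitSpec:
    """Condensate-aware train/test split specification."""

    train_fraction: float = 0.8
    seed: int = 0
    assignment: dict = field(default_factory=dict)  # condensate_id -> "train" | "test"

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")


def read_fasta(path) -> list[ProteinRecord]:
    return [ProteinRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# Pair construction
# ---------------------------------------------------------------------------

def build_positive_pairs(condensates: CondensateTable, n_max: int = 50) -> list[PairExample]:
    """All unordered within-condensate pairs (condensates of <= n_max members).

    Pairs appearing in several condensates are emitted once with the union of
    their source condensates.
    """
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    sources: dict[tuple[str, str], set] = {}
    for cid, ids in sorted(condensates.members.items()):
        if len(ids) > n_max:
            logger.info("skipping condensate %s with %d members (> n_max=%d)", cid, len(ids), n_max)
            continue
        for a, b in itertools.combinations(sorted(ids), 2):
            sources.setdefault((a, b), set()).add(cid)
    return [PairExample(a, b, 1, frozenset(src)) for (a, b), src in sorted(sources.items())]


def build_negative_pairs(condensates: CondensateTable, m: int = 12) -> list[PairExample]:
    """Cross-condensate negatives from small condensates.

    Candidate proteins are the members of condensates with at most ``m``
    members; every unordered candidate pair that co-occurs in *no* condensate
    of the full table is a negative.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    candidates: set = set()
    for ids in condensates.members.values():
        if len(ids) <= m:
            candidates |= ids
    co = condensates.co_occurring()
    out = []
    for a, b in itertools.combinations(sorted(candidates), 2):
        if (a, b) not in co:
            out.append(PairExample(a, b, 0))
    return out


def build_self_pair_dataset(
    condensates: CondensateTable,
    ppi: PPINetwork,
    all_proteins: list[ProteinRecord],
    identity_threshold: float = 0.5,
    identity_fn=None,
) -> list[PairExample]:
    """Self-pair extension: (P, P) positives and PPI-excluded (Q, Q) negatives.

    Positives are every condensate protein; negative candidates are proteins
    in no condensate and with no direct interaction edge to any condensate
    protein.  Both pools pass the redundancy filter before pairing.
    """
    by_id = {r.protein_id: r for r in all_proteins}
    cond_proteins = condensates.all_proteins()
    pos_records = [by_id[p] for p in sorted(cond_proteins) if p in by_id]
    neg_records = [
        r for r in all_proteins
        if r.protein_id not in cond_proteins and not ppi.touches(r.protein_id, cond_proteins)
    ]
    pos_records = redundancy_filter(pos_records, identity_threshold, identity_fn)
    neg_records = redundancy_filter(neg_records, identity_threshold, identity_fn)
    if not neg_records:
        logger.warning("self-pair negative pool is empty after PPI exclusion and filtering")
    out = [PairExample(r.protein_id, r.protein_id, 1, is_self_pair=True) for r in pos_records]
    out += [PairExample(r.protein_id, r.protein_id, 0, is_self_pair=True) for r in neg_records]
    return out


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

_ALIGNER = None


def global_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment sequence identity: matches / alignment columns."""
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = Align.PairwiseAligner(
            mode="global", match_score=1.0, mismatch_score=0.0,
            open_gap_score=-0.5, extend_gap_score=-0.1,
        )
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    counts = aln.counts()
    total = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / total if total else 0.0


def redundancy_filter(records: list[ProteinRecord], identity_threshold: float = 0.5,
                      identity_fn=None) -> list[ProteinRecord]:
    """Greedy longest-first representative selection.

    A record is kept iff its identity to every already-kept record is at most
    ``identity_threshold``.  The comparator is pluggable; the default is
    global-alignment identity.
    """
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError("identity_threshold must be in (0, 1]")
    if identity_fn is None:
        identity_fn = global_identity
    kept: list[ProteinRecord] = []
    for rec in sorted(records, key=lambda r: (-r.length, r.protein_id)):
        if all(identity_fn(rec.sequence, k.sequence) <= identity_threshold for k in kept):
            kept.append(rec)
        else:
            logger.info("redundancy filter dropped %s", rec.protein_id)
    return kept


def filter_by_length(records: list[ProteinRecord], max_len: int = 1024) -> list[ProteinRecord]:
    """Exclude (not truncate) sequences longer than ``max_len`` residues."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    return [r for r in records if r.length <= max_len]


# ---------------------------------------------------------------------------
# Splitting and rebalancing
# ---------------------------------------------------------------------------

def split_by_condensate(pairs: list[PairExample], condensates: CondensateTable,
                        spec: SplitSpec) -> tuple[list[PairExample], list[PairExample]]:
    """Condensate-aware split: no condensate feeds positives to both sides.

    Condensates are assigned whole to train or test (random order, greedy
    until the train side holds the target fraction of within-condensate pair
    weight).  A positive pair goes to test only if all its source condensates
    are test-assigned, to train only if all are train-assigned; straddling
    pairs are dropped.  Negatives — and self pairs, which relate no two
    distinct proteins and so cannot leak a pair across the split — are
    split at the same fraction with no condensate constraint.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x5B117]))
    cids = sorted(condensates.members.keys())
    order = rng.permutation(len(cids))
    weight = {cid: len(condensates.members[cid]) * (len(condensates.members[cid]) - 1) // 2
              for cid in cids}
    total = sum(weight.values()) or 1
    assignment: dict[str, str] = {}
    acc = 0
    for idx in order:
        cid = cids[idx]
        if acc / total < spec.train_fraction:
            assignment[cid] = "train"
            acc += weight[cid]
        else:
            assignment[cid] = "test"
    spec.assignment = assignment

    train: list[PairExample] = []
    test: list[PairExample] = []
    negatives: list[PairExample] = []
    dropped = 0
    for pair in pairs:
        if pair.label == 0 or pair.is_self_pair:
            negatives.append(pair)
            continue
        if not pair.source_condensates:
            raise ValueError(f"positive pair {pair.key} carries no source condensates")
        sides = {assignment.get(cid) for cid in pair.source_condensates}
        if sides == {"train"}:
            train.append(pair)
        elif sides == {"test"}:
            test.append(pair)
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d positive pairs straddling the condensate split", dropped)

    neg_order = rng.permutation(len(negatives))
    n_train = int(round(spec.train_fraction * len(negatives)))
    for rank, idx in enumerate(neg_order):
        (train if rank < n_train else test).append(negatives[idx])
    return train, test


def rebalance(pairs: list[PairExample], seed: int = 0) -> list[PairExample]:
    """Oversample the minority class with replacement to a 1:1 ratio."""
    pos = [p for p in pairs if p.label == 1]
    neg = [p for p in pairs if p.label == 0]
    if not pos or not neg:
        raise ValueError("rebalance requires both classes to be nonempty")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBA1A]))
    minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
    if len(minority) < len(majority):
        logger.info("resampling: %d positives / %d negatives -> %d / %d",
                    len(pos), len(neg), len(majority), len(majority))
    extra_idx = rng.integers(0, len(minority), size=len(majority) - len(minority))
    out = list(majority) + list(minority) + [minority[i] for i in extra_idx]
    rng.shuffle(out)
    return out


# ---------------------------------------------------------------------------
# Pairs TSV I/O
# ---------------------------------------------------------------------------

def write_pairs_tsv(path, pairs: list[PairExample]) -> None:
    df = pd.DataFrame({
        "protein_a": [p.id_a for p in pairs],
        "protein_b": [p.id_b for p in pairs],
        "label": [p.label for p in pairs],
        "is_self_pair": [int(p.is_self_pair) for p in pairs],
        "sources": [";".join(sorted(p.source_condensates)) for p in pairs],
    })
    df.to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path) -> list[PairExample]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str},
                     keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        sources = frozenset(s for s in str(row.sources).split(";") if s)
        out.append(PairExample(row.protein_a, row.protein_b, int(row.label),
                               sources, bool(int(row.is_self_pair))))
    return out
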