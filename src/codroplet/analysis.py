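"""Downstream analyses over pairwise co-condensation score tables.

These operate on the model's outputs: comparing membraneless-organelle
(MLO) protein sets against size-matched random samples, scoring
scaffold–client relations, enumerating proteome-scale pair sets, counting
high-scoring partners per protein, and contrasting the amino-acid
composition of the most- and least-connected quintiles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import AMINO_ACIDS

__all__ = [
    "ScoreTable",
    "CompositionReport",
    "DEFAULT_CATEGORIES",
    "enumerate_proteome_pairs",
    "partner_counts",
    "quintile_partition",
    "composition_difference",
    "mlo_vs_random",
    "scaffold_client_scores",
]


class ScoreTable:
    """Order-free lookup of pairwise scores in [0, 1]."""

    def __init__(self, scores: dict | None = None):
        self._scores: dict[tuple[str, str], float] = {}
        if scores:
            for (a, b), s in scores.items():
                self[a, b] = s

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def __setitem__(self, pair, score: float) -> None:
        a, b = pair
        score = float(score)
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"score for ({a}, {b}) outside [0, 1]: {score}")
        self._scores[self._key(a, b)] = score

    def __getitem__(self, pair) -> float:
        a, b = pair
        try:
            return self._scores[self._key(a, b)]
        except KeyError:
            raise KeyError(f"no score for pair ({a}, {b})") from None

    def __contains__(self, pair) -> bool:
        return self._key(*pair) in self._scores

    def __len__(self) -> int:
        return len(self._scores)

    def items(self):
        return self._scores.items()

    def proteins(self) -> list[str]:
        out = set()
        for a, b in self._scores:
            out.add(a)
            out.add(b)
        return sorted(out)

    @classmethod
    def from_csv(cls, path) -> "ScoreTable":
        df = pd.read_csv(path, dtype={"protein_a": str, "protein_b": str})
        table = cls()
        for row in df.itertuples(index=False):
            table[row.protein_a, row.protein_b] = row.score
        return table

    def to_csv(self, path) -> None:
        rows = [(a, b, s) for (a, b), s in sorted(self._scores.items())]
        pd.DataFrame(rows, columns=["protein_a", "protein_b", "score"]).to_csv(path, index=False)


def enumerate_proteome_pairs(protein_ids: list[str]):
    """All unordered distinct pairs and their closed-form count n(n-1)/2.

    Returns ``(generator, count)``; the generator streams pairs without
    materialising the full proteome-scale list.
    """
    if len(set(protein_ids)) != len(protein_ids):
        raise ValueError("protein ids must be unique")
    n = len(protein_ids)
    count = n * (n - 1) // 2
    return itertools.combinations(protein_ids, 2), count


def partner_counts(scores: ScoreTable, threshold: float = 0.8) -> dict[str, int]:
    """Per protein, the number of partners scoring strictly above ``threshold``."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    counts = {p: 0 for p in scores.proteins()}
    for (a, b), s in scores.items():
        if s > threshold:
            counts[a] += 1
            counts[b] += 1
    return counts


def quintile_partition(counts: dict[str, int]) -> tuple[list[str], list[str]]:
    """Top and bottom 20% of proteins by partner count (ties broken by id).

    Each returned set has exactly ``floor(n / 5)`` proteins.
    """
    if len(counts) < 5:
        raise ValueError("quintile partition needs at least 5 proteins")
    ranked = sorted(counts, key=lambda p: (-counts[p], p))
    k = len(ranked) // 5
    return ranked[:k], ranked[-k:]


DEFAULT_CATEGORIES: dict[str, str] = {}
for _cat, _residues in {
    "positively charged": "RKH",
    "negatively charged": "DE",
    "aromatic": "FWY",
    "disorder-promoting": "GPSA",
    "hydrophobic": "LIVMC",
    "hydrophilic": "NQT",
}.items():
    for _r in _residues:
        DEFAULT_CATEGORIES[_r] = _cat


@dataclass
class CompositionReport:
    """Per-amino-acid composition contrast between two protein sets."""

    table: pd.DataFrame  # index: amino acid; columns: mean_a, mean_b, difference, se, p_value, category

    def __getitem__(self, aa: str) -> pd.Series:
        return self.table.loc[aa]


def _fractions(sequences: list[str]) -> np.ndarray:
    rows = []
    for seq in sequences:
        if not seq:
            continue
        counts = np.array([seq.count(aa) for aa in AMINO_ACIDS], dtype=float)
        total = counts.sum()
        if total == 0:
            continue
        rows.append(counts / total)
    if not rows:
        raise ValueError("no usable sequences in set")
    return np.array(rows)


def composition_difference(set_a: list[str], set_b: list[str],
                           categories: dict[str, str] | None = None) -> CompositionReport:
    """Amino-acid composition contrast (set A minus set B).

    Per protein, the 20 residue fractions (summing to 1); per amino acid, the
    mean fraction in each set, the difference of means, its standard error
    sqrt(s_a^2/n_a + s_b^2/n_b), and a Welch two-sample t-test p-value.
    """
    categories = categories or DEFAULT_CATEGORIES
    fa, fb = _fractions(set_a), _fractions(set_b)
    mean_a, mean_b = fa.mean(axis=0), fb.mean(axis=0)
    var_a = fa.var(axis=0, ddof=1) if fa.shape[0] > 1 else np.zeros(20)
    var_b = fb.var(axis=0, ddof=1) if fb.shape[0] > 1 else np.zeros(20)
    se = np.sqrt(var_a / fa.shape[0] + var_b / fb.shape[0])
    pvals = np.full(20, np.nan)
    if fa.shape[0] > 1 and fb.shape[0] > 1:
        pvals = stats.ttest_ind(fa, fb, axis=0, equal_var=False).pvalue
    table = pd.DataFrame({
        "mean_a": mean_a,
        "mean_b": mean_b,
        "difference": mean_a - mean_b,
        "se": se,
        "p_value": pvals,
        "category": [categories[aa] for aa in AMINO_ACIDS],
    }, index=list(AMINO_ACIDS))
    return CompositionReport(table)


def _within_set_scores(protein_set: list[str], scores: ScoreTable) -> list[float]:
    return [scores[a, b] for a, b in itertools.combinations(sorted(protein_set), 2)]


def mlo_vs_random(mlo_proteins: list[str], background_pool: list[str], scores: ScoreTable,
                  k_samples: int = 5, seed: int = 0) -> dict:
    """MLO within-set score distribution vs size-matched random samples.

    Collects all within-set pairwise scores for the MLO and for ``k_samples``
    random subsets of the background pool of the same size (sampled without
    replacement), reporting each score list and its median.
    """
    if len(background_pool) < len(mlo_proteins):
        raise ValueError("background pool is smaller than the MLO set")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x310]))
    mlo_scores = _within_set_scores(mlo_proteins, scores)
    samples = []
    pool = sorted(background_pool)
    for _ in range(k_samples):
        subset = list(rng.choice(pool, size=len(mlo_proteins), replace=False))
        vals = _within_set_scores(subset, scores)
        samples.append({"proteins": subset, "scores": vals,
                        "median": float(np.median(vals)) if vals else float("nan")})
    return {
        "mlo": {"proteins": sorted(mlo_proteins), "scores": mlo_scores,
                "median": float(np.median(mlo_scores)) if mlo_scores else float("nan")},
        "random_samples": samples,
    }


def scaffold_client_scores(scaffold_id: str, in_set: list[str], out_set: list[str],
                           scores: ScoreTable) -> dict:
    """Mean scaffold score against an in-set vs an out-set of partners."""
    def collect(partners):
        vals = []
        for p in partners:
            if (scaffold_id, p) not in scores:
                raise KeyError(f"no score for pair ({scaffold_id}, {p})")
            vals.append(scores[scaffold_id, p])
        return vals

    in_scores, out_scores = collect(in_set), collect(out_set)
    return {
        "scaffold": scaffold_id,
        "mean_in": float(np.mean(in_scores)) if in_scores else float("nan"),
        "mean_out": float(np.mean(out_scores)) if out_scores else float("nan"),
        "in_scores": in_scores,
        "out_scores": out_scores,
    }
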