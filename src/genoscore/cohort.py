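"""Cohort-level analytics: standardized totals, anticodons, gene statistics.

Across a cohort the four component scores are each z-standardized
(x_new = (x - mu) / sigma, population sigma), averaged, and min-max rescaled
to [0, 1] to give the standardized total. For a single genome (or a fully
degenerate cohort) the standardization step is skipped and the raw combined
score is reported instead.

Anticodon analytics cover the 62-member anticodon alphabet (61 sense-codon
anticodons plus TCA, the selenocysteine anticodon read from the UGA stop).
Anticodons beginning with A — codons ending in U — are nearly absent from
prokaryotic genomes with the sole exception of arginine's ACG, so the
default "rare" set is the 15 A-starting anticodons other than ACG.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .features import FeatureSet, ProteinGene
from .scores import ComponentScores

logger = logging.getLogger(__name__)

__all__ = [
    "ANTICODON_ALPHABET",
    "RARE_ANTICODONS",
    "CohortScoreTable",
    "AnticodonTable",
    "GeneStats",
    "standardize_and_combine",
    "anticodon_frequency",
    "rare_anticodon_by_group",
    "gene_stats",
    "score_distribution",
    "format_percent",
]

_COMPONENT_COLUMNS = ("sequence_quality", "rrna", "trna", "essential")

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(codon: str) -> str:
    return codon.translate(_COMPLEMENT)[::-1]


def _build_alphabet() -> tuple[str, ...]:
    # anticodons of the 61 sense codons, plus TCA (anticodon of UGA,
    # used by selenocysteine tRNA)
    bases = "ACGT"
    sense = {
        b1 + b2 + b3
        for b1 in bases for b2 in bases for b3 in bases
        if b1 + b2 + b3 not in _STOP_CODONS
    }
    return tuple(sorted({_revcomp(c) for c in sense} | {"TCA"}))


#: The 62 anticodons a genome's tRNA pool can draw on.
ANTICODON_ALPHABET: tuple[str, ...] = _build_alphabet()

#: Default rare set: anticodons starting with A, minus arginine's ACG.
RARE_ANTICODONS: frozenset[str] = frozenset(
    a for a in ANTICODON_ALPHABET if a.startswith("A") and a != "ACG"
)


@dataclass
class CohortScoreTable:
    """Per-genome scores with cohort standardization bookkeeping.

    ``rows`` holds one row per genome: genome_name, the four components,
    raw_combined and standardized_total. ``component_stats`` records the
    cohort mean/sigma used per component; ``rescale_bounds`` the min/max of
    the averaged z-scores before rescaling (``None`` when standardization
    was skipped).
    """

    rows: pd.DataFrame
    component_stats: dict[str, tuple[float, float]] = field(default_factory=dict)
    rescale_bounds: tuple[float, float] | None = None


def standardize_and_combine(
    scores: Sequence[ComponentScores],
    names: Sequence[str] | None = None,
) -> CohortScoreTable:
    """Standardize each component across the cohort, average, rescale to [0,1].

    Population sigma is used: the cohort being scored is the whole universe
    of interest, not a sample from one. A component with sigma = 0 carries
    no ranking information and contributes z = 0 for every genome. For a
    cohort of one, or one whose averaged z-scores are all identical, the
    standardized total falls back to the raw combined score.
    """
    if not scores:
        raise ValueError("cohort must contain at least one genome")
    if names is None:
        names = [f"genome_{i + 1}" for i in range(len(scores))]
    if len(names) != len(scores):
        raise ValueError("names and scores must have equal length")

    rows = pd.DataFrame(
        [{"genome_name": n, **s.as_dict()} for n, s in zip(names, scores)]
    )
    stats: dict[str, tuple[float, float]] = {}
    if len(scores) == 1:
        rows["standardized_total"] = rows["raw_combined"]
        return CohortScoreTable(rows, stats, None)

    z_columns = []
    for column in _COMPONENT_COLUMNS:
        x = rows[column].to_numpy(dtype=float)
        mu = float(x.mean())
        sigma = float(x.std(ddof=0))
        stats[column] = (mu, sigma)
        z_columns.append(np.zeros_like(x) if sigma == 0.0 else (x - mu) / sigma)
    averaged = np.mean(z_columns, axis=0)
    lo, hi = float(averaged.min()), float(averaged.max())
    if math.isclose(lo, hi, abs_tol=1e-12):
        rows["standardized_total"] = rows["raw_combined"]
        return CohortScoreTable(rows, stats, None)
    rows["standardized_total"] = (averaged - lo) / (hi - lo)
    return CohortScoreTable(rows, stats, (lo, hi))


@dataclass
class AnticodonTable:
    """Cohort-wide anticodon occurrence counts and the rare-anticodon set."""

    counts: dict[str, int]
    rare_set: frozenset[str] = RARE_ANTICODONS

    @property
    def rare_observed(self) -> dict[str, int]:
        return {a: c for a, c in self.counts.items() if a in self.rare_set and c > 0}

    def to_frame(self) -> pd.DataFrame:
        """Full 62-row table (plus 'unknown' if tallied), rose-plot ready."""
        rows = [
            {"anticodon": a, "count": self.counts.get(a, 0), "rare": a in self.rare_set}
            for a in ANTICODON_ALPHABET
        ]
        if self.counts.get("unknown"):
            rows.append({"anticodon": "unknown", "count": self.counts["unknown"], "rare": False})
        return pd.DataFrame(rows)


def anticodon_frequency(
    feature_sets: Iterable[FeatureSet],
    rare_set: frozenset[str] | None = None,
) -> AnticodonTable:
    """Count anticodon occurrences over all non-pseudo tRNAs in the cohort.

    Optional tRNAs (selenocysteine etc.) are included in the tally; pseudo
    predictions are not. Unknown or ambiguous anticodons are tallied under
    "unknown", outside the 62-member alphabet.
    """
    counts: Counter[str] = Counter()
    for fs in feature_sets:
        for trna in fs.trnas:
            if trna.pseudo:
                continue
            counts["unknown" if trna.anticodon is None else trna.anticodon] += 1
    return AnticodonTable(dict(counts), RARE_ANTICODONS if rare_set is None else rare_set)


def _has_rare(fs: FeatureSet, rare_set: frozenset[str]) -> bool:
    return any(not t.pseudo and t.anticodon in rare_set for t in fs.trnas)


def rare_anticodon_by_group(
    feature_sets: Sequence[FeatureSet],
    groups: Sequence[str],
    rare_set: frozenset[str] | None = None,
) -> pd.DataFrame:
    """Per group (e.g. genus): how many genomes carry >= 1 rare anticodon.

    A genome counts once if any of its non-pseudo tRNAs carries an
    anticodon in the rare set. Returns columns group, n_genomes,
    n_with_rare, percent (exact; see :func:`format_percent` for display).
    Genomes with an empty group label fall under "unassigned".
    """
    if len(feature_sets) != len(groups):
        raise ValueError("feature_sets and groups must have equal length")
    rare = RARE_ANTICODONS if rare_set is None else rare_set
    tally: dict[str, list[int]] = {}
    for fs, group in zip(feature_sets, groups):
        label = group or "unassigned"
        n, n_rare = tally.setdefault(label, [0, 0])
        tally[label][0] = n + 1
        tally[label][1] = n_rare + int(_has_rare(fs, rare))
    rows = [
        {
            "group": g,
            "n_genomes": n,
            "n_with_rare": r,
            "percent": 100.0 * r / n,
        }
        for g, (n, r) in sorted(tally.items())
    ]
    return pd.DataFrame(rows)


def format_percent(value: float) -> str:
    """Display a percentage the way the score reports print it.

    Values of one percent or more are shown as whole numbers with exact
    halves rounded down (87.5 -> "87"); sub-percent values keep one decimal
    (0.1378 -> "0.1"). Exact values are always retained in the data; this
    affects display only.
    """
    if value >= 1.0:
        whole = math.floor(value)
        return str(whole + 1) if value - whole > 0.5 else str(whole)
    return f"{math.floor(value * 10 + 0.5) / 10:.1f}" if value > 0 else "0"


@dataclass(frozen=True)
class GeneStats:
    """Mean protein-gene length (nt) and gene density (genes per kb)."""

    mean_gene_length: float
    gene_density: float


def gene_stats(genes: Sequence[ProteinGene], total_size: int) -> GeneStats:
    """Average gene length and genes per kilobase of assembly."""
    if total_size <= 0:
        raise ValueError("total_size must be > 0")
    if not genes:
        logger.warning("no protein genes: gene stats degenerate to (0, 0)")
        return GeneStats(0.0, 0.0)
    mean_length = sum(g.length_nt for g in genes) / len(genes)
    return GeneStats(mean_length, 1000.0 * len(genes) / total_size)


def score_distribution(
    table: CohortScoreTable,
    groups: Sequence[str] | None = None,
    bin_edges: Sequence[float] = tuple(np.round(np.linspace(0.0, 1.0, 11), 2)),
) -> pd.DataFrame:
    """Percent of genomes per score bin, per metadata group and score column.

    Bins are right-closed — a bin is labelled by the largest value in its
    range — with the lowest bin additionally including its left edge so the
    bins cover [0, 1] exactly. Returns tidy rows (group, score, bin,
    percent); within each (group, score) the percents sum to 100.
    """
    edges = list(bin_edges)
    if sorted(edges) != edges or len(set(edges)) != len(edges):
        raise ValueError("bin edges must be strictly increasing")
    if edges[0] > 0.0 or edges[-1] < 1.0:
        raise ValueError("bin edges must cover [0, 1]")
    rows = table.rows
    n = len(rows)
    if groups is None:
        labels = pd.Series(["all"] * n)
    else:
        if len(groups) != n:
            raise ValueError("groups must match the number of genomes")
        labels = pd.Series([g or "unassigned" for g in groups])
    columns = [c for c in (*_COMPONENT_COLUMNS, "raw_combined", "standardized_total")
               if c in rows.columns]
    out = []
    for group in sorted(labels.unique()):
        mask = (labels == group).to_numpy()
        for column in columns:
            binned = pd.cut(
                rows.loc[mask, column],
                bins=edges,
                right=True,
                include_lowest=True,
                labels=[f"{e:g}" for e in edges[1:]],
            )
            pct = binned.value_counts(normalize=True, sort=False) * 100.0
            for bin_label, percent in pct.items():
                out.append(
                    {"group": group, "score": column, "bin": str(bin_label),
                     "percent": float(percent)}
                )
    return pd.DataFrame(out)
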