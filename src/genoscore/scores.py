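"""The four per-genome completeness scores and their raw combination.

Each component lives on [0, 1] (the three feature scores are floored at
0.1) and the raw combined score is their arithmetic mean:

* sequence quality — good bases over good + bad + 10 kb penalties per extra
  contig (drafts only) and per N-gap;
* rRNA — 0.1 base plus a 0.3/0.2/0.1 tier per molecule type (5S/16S/23S)
  for an ideal-length / half-length / any prediction;
* tRNA — 1.0 minus 0.1 per standard amino acid with no non-pseudo tRNA,
  floored at 0.1;
* essential genes — 1.0 minus 0.01 per missing marker domain, floored
  at 0.1.

Scores are computed unrounded in double precision; display rounding to two
decimals happens only in the report writers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .assembly import AssemblyMetrics, GenomeAssembly, compute_assembly_metrics
from .config import ScoringConfig, strip_version
from .features import (
    STANDARD_AMINO_ACIDS,
    DomainHit,
    FeatureSet,
    RRNAGene,
    TRNAGene,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ComponentScores",
    "sequence_quality_score",
    "rrna_score",
    "trna_score",
    "essential_gene_score",
    "raw_combined",
    "score_genome",
]


@dataclass(frozen=True)
class ComponentScores:
    """The four component scores of one genome plus their mean."""

    sequence_quality: float
    rrna: float
    trna: float
    essential: float
    raw_combined: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sequence_quality": self.sequence_quality,
            "rrna": self.rrna,
            "trna": self.trna,
            "essential": self.essential,
            "raw_combined": self.raw_combined,
        }


def sequence_quality_score(
    metrics: AssemblyMetrics,
    status: str = "draft",
    config: ScoringConfig | None = None,
) -> float:
    """Good bases over good + bad + contig and gap penalties.

    Every contig after the first adds ``contig_penalty_bp`` to the
    denominator — unless the genome is flagged complete, in which case
    additional contigs are assumed to be extra replicons and draw no
    penalty. Every counted N-gap adds ``gap_penalty_bp`` regardless of
    status. Each penalty approximates the sequence a break costs in
    practice (about one missed gene per contig edge, scaled up tenfold so
    fragmentation is not cheap).
    """
    config = config or ScoringConfig()
    if metrics.good_bases == 0:
        logger.warning("degenerate assembly: no A/C/G/T bases at all; sequence score 0")
        return 0.0
    denominator = metrics.good_bases + metrics.bad_bases
    if status != "complete":
        denominator += config.contig_penalty_bp * max(0, metrics.contig_count - 1)
    denominator += config.gap_penalty_bp * metrics.gap_count
    return metrics.good_bases / denominator


def rrna_score(rrnas: list[RRNAGene], config: ScoringConfig | None = None) -> float:
    """0.1 base plus the best tier attained per molecule type.

    Per type: +0.3 if any prediction falls in the ideal length window,
    else +0.2 if any exceeds half the window minimum, else +0.1 if any
    prediction exists at all. One full-length copy demonstrates
    completeness, so with multi-copy operons the best prediction wins.
    An over-long prediction (beyond the window maximum) still earns the
    0.2 tier but is logged — unrealistically long calls usually flag a
    predictor artifact or N-contaminated rDNA.
    """
    config = config or ScoringConfig()
    full, half, any_ = config.rrna_tier_increments
    score = config.rrna_base
    for molecule, window in config.rrna_ranges.items():
        best = 0.0
        for gene in rrnas:
            if gene.molecule != molecule:
                continue
            if window.min_ideal <= gene.length <= window.max_ideal:
                tier = full
            elif gene.length > 0.5 * window.min_ideal:
                tier = half
                if gene.length > window.max_ideal:
                    logger.warning(
                        "over-long %s prediction (%d > %d bases)",
                        molecule, gene.length, window.max_ideal,
                    )
            else:
                tier = any_
            best = max(best, tier)
        score += best
    return score


def trna_score(trnas: list[TRNAGene], config: ScoringConfig | None = None) -> float:
    """1.0 minus 0.1 per standard amino acid with no non-pseudo tRNA.

    Pseudo-flagged predictions never demonstrate coverage; selenocysteine
    and undetermined calls are outside the 20 and neither help nor hurt.
    Floored at 0.1 (reached at 9 or more missing amino acids).
    """
    config = config or ScoringConfig()
    covered = {
        t.amino_acid for t in trnas if not t.pseudo and t.amino_acid in STANDARD_AMINO_ACIDS
    }
    missing = len(STANDARD_AMINO_ACIDS) - len(covered)
    return max(config.trna_floor, 1.0 - config.trna_decrement * missing)


def essential_gene_score(
    domains: list[DomainHit], config: ScoringConfig | None = None
) -> float:
    """1.0 minus 0.01 per missing essential domain, floored at 0.1.

    Presence is per distinct accession — extra copies of a family add
    nothing, because the score counts missing families, not abundance.
    """
    config = config or ScoringConfig()
    panel = set(config.essential_domains)
    present = {strip_version(d.domain_accession) for d in domains} & panel
    missing = len(panel) - len(present)
    return max(config.essential_floor, 1.0 - config.essential_decrement * missing)


def raw_combined(
    sequence_quality: float, rrna: float, trna: float, essential: float
) -> float:
    """Arithmetic mean of the four component scores."""
    return (sequence_quality + rrna + trna + essential) / 4.0


def score_genome(
    assembly: GenomeAssembly | AssemblyMetrics,
    features: FeatureSet,
    config: ScoringConfig | None = None,
    status: str | None = None,
) -> ComponentScores:
    """Compute all four components and the raw combined score for one genome.

    ``assembly`` may be a full :class:`GenomeAssembly` (metrics are computed,
    status taken from it unless overridden) or precomputed
    :class:`AssemblyMetrics` (``status`` then defaults to draft).
    """
    config = config or ScoringConfig()
    if isinstance(assembly, GenomeAssembly):
        metrics = compute_assembly_metrics(assembly, config)
        status = status if status is not None else assembly.status
    else:
        metrics = assembly
        status = status if status is not None else "draft"
    seq = sequence_quality_score(metrics, status, config)
    rrna = rrna_score(features.rrnas, config)
    trna = trna_score(features.trnas, config)
    essential = essential_gene_score(features.domains, config)
    return ComponentScores(seq, rrna, trna, essential, raw_combined(seq, rrna, trna, essential))
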