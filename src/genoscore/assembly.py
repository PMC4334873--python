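"""Assembly ingestion, base/contig/gap metrics, fingerprints and size filters.

The sequence-quality component of the total score is driven entirely by the
counts computed here: "good" bases (A/C/G/T), "bad" bases (any IUPAC code
other than A/C/G/T/N), and runs of N long enough to count as assembly gaps.
Deduplication across repositories uses a nested MD5 fingerprint — per-contig
digests, sorted and re-hashed — so byte-identical assemblies collapse
regardless of contig order or naming.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .config import ScoringConfig

logger = logging.getLogger(__name__)

__all__ = [
    "Contig",
    "GenomeAssembly",
    "AssemblyMetrics",
    "SizeClass",
    "read_fasta",
    "write_fasta",
    "compute_assembly_metrics",
    "genome_fingerprint",
    "classify_by_size",
    "dedupe_cohort",
]

# IUPAC nucleotide codes, plus '-' and '.' gap characters occasionally left
# by aligners; anything else on ingest is an error.
_IUPAC = set("ACGTUNRYSWKMBDHV-.")
_GOOD = frozenset("ACGT")


@dataclass(frozen=True)
class Contig:
    """One contig/scaffold/replicon: an id and an uppercase sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if not self.sequence:
            raise ValueError(f"contig {self.id!r} has an empty sequence")


class SizeClass(str, Enum):
    """Outcome of the total-size filter."""

    RETAINED = "retained"
    PLASMID_TOO_SMALL = "plasmid_too_small"
    EUKARYOTE_TOO_LARGE = "eukaryote_too_large"


@dataclass
class GenomeAssembly:
    """An ordered set of contigs with a sequencing status and open metadata.

    ``status`` is ``"complete"`` (every replicon closed — extra contigs are
    assumed to be plasmids/chromosomes and draw no penalty) or ``"draft"``.
    It always comes from the caller/manifest, never from the sequence.
    """

    name: str
    contigs: list[Contig]
    status: str = "draft"
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError(f"assembly {self.name!r} has no contigs")
        if self.status not in ("complete", "draft"):
            raise ValueError(f"status must be 'complete' or 'draft', got {self.status!r}")
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate contig id {dup!r} in assembly {self.name!r}")

    @property
    def total_size(self) -> int:
        return sum(len(c.sequence) for c in self.contigs)


@dataclass(frozen=True)
class AssemblyMetrics:
    """Base-class counts feeding the sequence-quality score.

    good + bad + n_bases + sum of counted gap-run lengths == total_size.
    ``n_bases`` are N's sitting outside any counted gap run; they belong to
    neither numerator nor denominator of the score.
    """

    good_bases: int
    bad_bases: int
    n_bases: int
    contig_count: int
    gap_count: int
    gap_run_bases: int
    total_size: int


def read_fasta(
    path: str | Path,
    name: str | None = None,
    status: str = "draft",
    metadata: Mapping[str, str] | None = None,
) -> GenomeAssembly:
    """Read a multi-FASTA assembly (one record per contig).

    Sequences are uppercased so soft-masked bases count as ordinary sequence;
    masking is annotation, not assembly quality. Status and metadata come
    from the caller, never from the file.
    """
    path = Path(path)
    contigs: list[Contig] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad_chars = set(seq) - _IUPAC
        if bad_chars:
            raise ValueError(
                f"{path}: record {record.id!r} contains non-IUPAC characters: "
                + ",".join(sorted(bad_chars))
            )
        contigs.append(Contig(record.id, seq))
    if not contigs:
        raise ValueError(f"{path}: no contigs")
    return GenomeAssembly(
        name=name if name is not None else path.stem,
        contigs=contigs,
        status=status,
        metadata=dict(metadata or {}),
    )


def write_fasta(assembly: GenomeAssembly, path: str | Path, width: int = 70) -> None:
    """Write an assembly as multi-FASTA, wrapping sequence lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for contig in assembly.contigs:
            fh.write(f">{contig.id}\n")
            seq = contig.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_N_RUN = re.compile(r"N+")


def compute_assembly_metrics(
    assembly: GenomeAssembly, config: ScoringConfig | None = None
) -> AssemblyMetrics:
    """Count good/bad/N bases and gap runs across all contigs.

    A gap is a maximal run of N of length >= ``config.gap_min_run``; runs are
    found per contig and never span contig boundaries. N's in shorter runs
    are tallied as ``n_bases`` and are neither good nor bad.
    """
    config = config or ScoringConfig()
    good = bad = loose_n = gap_count = gap_bases = total = 0
    for contig in assembly.contigs:
        seq = contig.sequence
        total += len(seq)
        n_total = seq.count("N")
        good_c = sum(seq.count(b) for b in "ACGT")
        good += good_c
        bad += len(seq) - good_c - n_total
        run_n = 0
        for match in _N_RUN.finditer(seq):
            run_len = match.end() - match.start()
            if run_len >= config.gap_min_run:
                gap_count += 1
                run_n += run_len
        gap_bases += run_n
        loose_n += n_total - run_n
    return AssemblyMetrics(
        good_bases=good,
        bad_bases=bad,
        n_bases=loose_n,
        contig_count=len(assembly.contigs),
        gap_count=gap_count,
        gap_run_bases=gap_bases,
        total_size=total,
    )


def genome_fingerprint(assembly: GenomeAssembly) -> str:
    """Nested-MD5 fingerprint of an assembly.

    Each contig's uppercase sequence is MD5-hashed; the hex digests are
    sorted lexicographically, joined with commas (no spaces), and the joined
    string is MD5-hashed again. Sorting makes the fingerprint invariant to
    contig order; ids and descriptions are excluded because names drift
    between repositories while sequences do not.
    """
    digests = sorted(
        hashlib.md5(c.sequence.upper().encode("ascii")).hexdigest()
        for c in assembly.contigs
    )
    return hashlib.md5(",".join(digests).encode("ascii")).hexdigest()


def classify_by_size(
    metrics: AssemblyMetrics | int, config: ScoringConfig | None = None
) -> SizeClass:
    """Apply the total-size filter (strict inequalities; bounds retained)."""
    config = config or ScoringConfig()
    size = metrics if isinstance(metrics, int) else metrics.total_size
    if size < config.min_retained_size:
        return SizeClass.PLASMID_TOO_SMALL
    if size > config.max_retained_size:
        return SizeClass.EUKARYOTE_TOO_LARGE
    return SizeClass.RETAINED


def dedupe_cohort(
    assemblies: Iterable[GenomeAssembly],
) -> tuple[list[GenomeAssembly], dict[str, list[str]]]:
    """Collapse byte-identical assemblies by fingerprint.

    Returns (unique, duplicates): one representative per fingerprint (first
    encountered, in input order) and, for every fingerprint shared by more
    than one assembly, the full list of member names.
    """
    assemblies = list(assemblies)
    if not assemblies:
        raise ValueError("dedupe_cohort requires at least one assembly")
    unique: list[GenomeAssembly] = []
    members: dict[str, list[str]] = {}
    for asm in assemblies:
        fp = genome_fingerprint(asm)
        if fp not in members:
            unique.append(asm)
            members[fp] = []
        members[fp].append(asm.name)
    duplicates = {fp: names for fp, names in members.items() if len(names) > 1}
    n_dupes = sum(len(v) - 1 for v in duplicates.values())
    if n_dupes:
        logger.info("dedupe: %d duplicate assemblies in %d groups", n_dupes, len(duplicates))
    return unique, duplicates
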