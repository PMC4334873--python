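"""Seeded synthetic assemblies and feature sets with controllable completeness.

The generator emulates exactly the degradation modes the quality score
measures — fragmentation into contigs, N-gap runs, non-ACGT bases, missing
rRNA/tRNA/essential-domain predictions — and nothing else: no read errors,
no homology, no real gene content. Count-valued degradations (contigs, gaps,
bad bases, missing amino acids, missing domains) are placed constructively,
so the realized counts match the parameters exactly and tests can assert
exact scores; only base composition is stochastic.

All randomness flows from a single integer seed; per-genome streams are
derived by stable splitting, so a cohort member's content depends only on
the cohort seed and its index.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .assembly import Contig, GenomeAssembly
from .cohort import RARE_ANTICODONS
from .config import ScoringConfig, default_essential_domains
from .features import (
    STANDARD_AMINO_ACIDS,
    DomainHit,
    FeatureSet,
    ProteinGene,
    RRNAGene,
    TRNAGene,
)

__all__ = [
    "SimulationParams",
    "AMINO_ACID_ANTICODONS",
    "simulate_assembly",
    "simulate_features",
    "simulate_cohort",
]

# Codons of the standard genetic code per amino acid (DNA alphabet);
# anticodons are their reverse complements.
_CODONS: Mapping[str, tuple[str, ...]] = {
    "Ala": ("GCT", "GCC", "GCA", "GCG"),
    "Arg": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "Asn": ("AAT", "AAC"),
    "Asp": ("GAT", "GAC"),
    "Cys": ("TGT", "TGC"),
    "Gln": ("CAA", "CAG"),
    "Glu": ("GAA", "GAG"),
    "Gly": ("GGT", "GGC", "GGA", "GGG"),
    "His": ("CAT", "CAC"),
    "Ile": ("ATT", "ATC", "ATA"),
    "Leu": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "Lys": ("AAA", "AAG"),
    "Met": ("ATG",),
    "Phe": ("TTT", "TTC"),
    "Pro": ("CCT", "CCC", "CCA", "CCG"),
    "Ser": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "Thr": ("ACT", "ACC", "ACA", "ACG"),
    "Trp": ("TGG",),
    "Tyr": ("TAT", "TAC"),
    "Val": ("GTT", "GTC", "GTA", "GTG"),
    "SeC": ("TGA",),
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Anticodon candidates per amino acid (reverse complements of its codons).
AMINO_ACID_ANTICODONS: Mapping[str, tuple[str, ...]] = {
    aa: tuple(sorted(c.translate(_COMPLEMENT)[::-1] for c in codons))
    for aa, codons in _CODONS.items()
}

_BAD_CHARS = "RYSWKMBDHV"


def _default_rrna_profile() -> dict[str, str]:
    return {"5S": "ideal", "16S": "ideal", "23S": "ideal"}


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of one synthetic genome.

    Defaults describe a clean finished-quality draft: a single 4 Mb contig
    at 50% GC with no gaps or bad bases, full tRNA coverage, ideal-length
    rRNAs, all essential domains present. Degradations are switched on by
    raising the respective counts/rates.

    ``rrna_profile`` maps each molecule (5S/16S/23S) to one of
    ``absent`` (no prediction), ``short`` (<= half the ideal minimum),
    ``half_min`` (between half the minimum and the minimum), ``ideal``
    (inside the ideal window) or ``overlong`` (beyond the window maximum).
    """

    seed: int = 0
    genome_size: int = 4_000_000
    contig_count: int = 1
    gap_count: int = 0
    gap_length: int = 50
    bad_base_rate: float = 0.0
    gc_content: float = 0.5
    missing_amino_acids: int = 0
    pseudo_trna_count: int = 0
    rrna_profile: Mapping[str, str] = field(default_factory=_default_rrna_profile)
    missing_domains: int = 0
    rare_anticodon_probability: float = 0.0
    status: str = "draft"

    def __post_init__(self) -> None:
        if self.contig_count < 1:
            raise ValueError("contig_count must be >= 1")
        for name in ("genome_size", "gap_count", "gap_length", "pseudo_trna_count",
                     "missing_domains"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("bad_base_rate", "gc_content", "rare_anticodon_probability"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.missing_amino_acids <= len(STANDARD_AMINO_ACIDS):
            raise ValueError("missing_amino_acids must lie in [0, 20]")
        bad_profiles = set(self.rrna_profile.values()) - {
            "absent", "short", "half_min", "ideal", "overlong"
        }
        if bad_profiles:
            raise ValueError(f"unknown rrna_profile values: {sorted(bad_profiles)}")

    def replace(self, **changes) -> "SimulationParams":
        return dataclasses.replace(self, **changes)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return letters[rng.choice(4, size=n, p=p)]


def simulate_assembly(
    params: SimulationParams,
    name: str = "sim",
    config: ScoringConfig | None = None,
) -> GenomeAssembly:
    """Build a synthetic assembly whose metrics match the parameters exactly.

    ``genome_size`` counts the good + bad bases; counted N-gap runs (of
    exactly ``gap_length`` N each) are inserted on top of that, distributed
    round-robin over contigs at evenly spaced interior positions so runs
    never touch contig ends or each other. Bad bases replace good bases at
    evenly spaced positions, cycling through the ambiguous IUPAC codes.
    Deterministic for a fixed seed.
    """
    config = config or ScoringConfig()
    if params.gap_count and params.gap_length < config.gap_min_run:
        raise ValueError(
            f"gap_length ({params.gap_length}) below gap_min_run "
            f"({config.gap_min_run}): runs would not count as gaps"
        )
    if params.genome_size < params.contig_count:
        raise ValueError("genome_size must be >= contig_count")
    rng = np.random.default_rng([params.seed, 0])

    genome = _random_bases(rng, params.genome_size, params.gc_content)
    n_bad = round(params.bad_base_rate * params.genome_size)
    if n_bad:
        positions = np.array(
            [(params.genome_size * (k + 1)) // (n_bad + 1) for k in range(n_bad)]
        )
        if len(np.unique(positions)) != n_bad:
            raise ValueError("bad_base_rate too high for genome_size")
        for k, pos in enumerate(positions):
            genome[pos] = ord(_BAD_CHARS[k % len(_BAD_CHARS)])

    # split into contigs of near-equal size
    bounds = [(params.genome_size * i) // params.contig_count
              for i in range(params.contig_count + 1)]
    pieces = [genome[bounds[i]: bounds[i + 1]] for i in range(params.contig_count)]

    # distribute gap runs round-robin and insert at evenly spaced offsets
    gaps_per_contig = [0] * params.contig_count
    for g in range(params.gap_count):
        gaps_per_contig[g % params.contig_count] += 1
    contigs: list[Contig] = []
    run = "N" * params.gap_length
    for i, piece in enumerate(pieces):
        text = piece.tobytes().decode("ascii")
        g = gaps_per_contig[i]
        if g:
            m = len(text)
            if m < 2 * (g + 1):
                raise ValueError(
                    f"contig {i} too short ({m} bp) to hold {g} separated gap runs"
                )
            offsets = [(m * j) // (g + 1) for j in range(1, g + 1)]
            parts = []
            prev = 0
            for off in offsets:
                parts.append(text[prev:off])
                prev = off
            parts.append(text[prev:])
            text = run.join(parts)
        contigs.append(Contig(f"{name}_c{i + 1}", text))
    return GenomeAssembly(name=name, contigs=contigs, status=params.status,
                          metadata={"source": "sim"})


def simulate_features(
    params: SimulationParams,
    essential_domains: Sequence[str] | None = None,
    name: str = "sim",
    config: ScoringConfig | None = None,
) -> FeatureSet:
    """Build a feature set with exactly the requested completeness.

    Exactly ``20 - missing_amino_acids`` standard amino acids get at least
    one non-pseudo tRNA (which amino acids are covered is seeded-random);
    anticodons avoid the rare set except with ``rare_anticodon_probability``
    per tRNA. rRNA lengths are drawn per molecule according to
    ``rrna_profile``; exactly ``missing_domains`` essential accessions are
    absent from the domain hits. Protein genes are generated at roughly one
    per kilobase with lengths around 950 nt, matching typical bacterial
    gene statistics.
    """
    config = config or ScoringConfig()
    if essential_domains is None:
        essential_domains = config.essential_domains or default_essential_domains()
    if params.missing_domains > len(essential_domains):
        raise ValueError(
            f"missing_domains ({params.missing_domains}) exceeds panel size "
            f"({len(essential_domains)})"
        )
    rng = np.random.default_rng([params.seed, 1])

    # --- tRNAs -------------------------------------------------------------
    order = rng.permutation(len(STANDARD_AMINO_ACIDS))
    n_covered = len(STANDARD_AMINO_ACIDS) - params.missing_amino_acids
    covered = [STANDARD_AMINO_ACIDS[i] for i in sorted(order[:n_covered])]
    missing = [STANDARD_AMINO_ACIDS[i] for i in sorted(order[n_covered:])]
    trnas: list[TRNAGene] = []
    for aa in covered:
        for _ in range(int(rng.integers(1, 4))):
            trnas.append(TRNAGene(aa, _draw_anticodon(rng, aa, params), False))
    if rng.random() < 0.5 and n_covered:  # an optional selenocysteine tRNA
        trnas.append(TRNAGene("SeC", "TCA", False))
    for k in range(params.pseudo_trna_count):
        # pseudo predictions preferentially for missing amino acids, so the
        # pseudo-exclusion rule is actually exercised
        aa = missing[k % len(missing)] if missing else covered[k % len(covered)]
        trnas.append(TRNAGene(aa, _draw_anticodon(rng, aa, params), True))

    # --- rRNAs -------------------------------------------------------------
    rrnas: list[RRNAGene] = []
    for molecule, profile in params.rrna_profile.items():
        window = config.rrna_ranges[molecule]
        if profile == "absent":
            continue
        if profile == "ideal":
            length = int(rng.integers(window.min_ideal, window.max_ideal + 1))
        elif profile == "half_min":
            length = int(rng.integers(window.min_ideal // 2 + 1, window.min_ideal))
        elif profile == "short":
            length = int(rng.integers(1, max(2, window.min_ideal // 2 + 1)))
        else:  # overlong
            length = int(rng.integers(window.max_ideal + 1, 2 * window.max_ideal))
        rrnas.append(RRNAGene(molecule, length))

    # --- protein genes -----------------------------------------------------
    n_genes = max(1, params.genome_size // 1000)
    lengths = np.clip(np.rint(rng.normal(950.0, 150.0, size=n_genes)), 90, None)
    genes = [ProteinGene(f"{name}_g{i + 1}", int(length))
             for i, length in enumerate(lengths)]

    # --- essential-domain hits --------------------------------------------
    absent = set(
        rng.choice(len(essential_domains), size=params.missing_domains, replace=False)
    )
    domains = [
        DomainHit(acc, genes[i % len(genes)].id)
        for i, acc in enumerate(essential_domains)
        if i not in absent
    ]
    return FeatureSet(name, trnas, rrnas, genes, domains)


def _draw_anticodon(rng: np.random.Generator, aa: str, params: SimulationParams) -> str:
    candidates = AMINO_ACID_ANTICODONS[aa]
    rare = [a for a in candidates if a in RARE_ANTICODONS]
    common = [a for a in candidates if a not in RARE_ANTICODONS]
    if rare and (not common or rng.random() < params.rare_anticodon_probability):
        pool = rare
    else:
        pool = common
    return pool[int(rng.integers(len(pool)))]


def simulate_cohort(
    n: int,
    seed: int = 0,
    template: SimulationParams | None = None,
    group_profiles: Mapping[str, Mapping[str, object]] | None = None,
    jitter: Mapping[str, tuple[float, float]] | None = None,
    config: ScoringConfig | None = None,
) -> list[tuple[GenomeAssembly, FeatureSet, dict[str, str]]]:
    """Simulate a cohort of genomes with group-structured degradation.

    ``group_profiles`` maps a group label (used as the genus metadata field)
    to parameter overrides applied on top of ``template``; genomes are
    assigned to groups round-robin. ``jitter`` maps a parameter name to an
    inclusive (low, high) range resampled per genome — integer-valued for
    count parameters, uniform for rates — applied after the group override.
    Each genome's stream is derived from ``(seed, index)``, so content is
    independent of cohort order and size.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    template = template or SimulationParams()
    labels = sorted(group_profiles) if group_profiles else ["all"]
    out: list[tuple[GenomeAssembly, FeatureSet, dict[str, str]]] = []
    for i in range(n):
        label = labels[i % len(labels)]
        overrides: dict = dict(group_profiles[label]) if group_profiles else {}
        genome_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        if jitter:
            jit_rng = np.random.default_rng([seed, i, 2])
            for fname, (low, high) in jitter.items():
                if fname in overrides:
                    continue  # a group profile pins the field; jitter the rest
                current = getattr(template, fname)
                if isinstance(current, float):
                    overrides[fname] = float(jit_rng.uniform(low, high))
                else:
                    overrides[fname] = int(jit_rng.integers(int(low), int(high) + 1))
        params = template.replace(seed=genome_seed, **overrides)
        genome_name = f"g{i + 1:04d}_{label}"
        assembly = simulate_assembly(params, name=genome_name, config=config)
        features = simulate_features(params, name=genome_name, config=config)
        metadata = {"genus": label, "source": "sim", "status": params.status}
        out.append((assembly, features, metadata))
    return out
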