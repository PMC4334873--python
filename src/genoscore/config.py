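"""Scoring configuration: every numeric constant of the quality-score rules.

The defaults encode the published scoring scheme: 10,000 bp penalties for
extra contigs and for N-gaps, ideal rRNA length windows (23S 2900-3500,
16S 1450-1700, 5S 100-120), the 0.1-per-missing-amino-acid tRNA decrement,
the 0.01-per-missing-domain essential-gene decrement, both with a 0.1 floor,
and the 138,500 / 18,000,000 bp size filters that separate stray plasmids
and eukaryotic assemblies from prokaryotic genomes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "RRNARange",
    "ScoringConfig",
    "default_essential_domains",
    "load_config",
    "strip_version",
]

_DEFAULT_DOMAIN_RESOURCE = "essential_domains_synthetic.txt"


def strip_version(accession: str) -> str:
    """Drop a trailing version suffix from a Pfam-style accession.

    ``PF00312.14`` -> ``PF00312``. Idempotent; accessions without a dot are
    returned unchanged.
    """
    return accession.split(".", 1)[0]


def default_essential_domains() -> tuple[str, ...]:
    """Load the bundled 102-entry essential-domain accession panel.

    The bundled panel is a synthetic stand-in of broadly conserved
    prokaryotic Pfam-A families; swap in your own list via
    :attr:`ScoringConfig.essential_domains` to score against a different
    marker set.
    """
    text = (
        resources.files("genoscore.data")
        .joinpath(_DEFAULT_DOMAIN_RESOURCE)
        .read_text(encoding="utf-8")
    )
    return _parse_domain_lines(text.splitlines())


def _parse_domain_lines(lines) -> tuple[str, ...]:
    out: list[str] = []
    for line in lines:
        entry = line.split("#", 1)[0].strip()
        if entry:
            out.append(strip_version(entry))
    return tuple(out)


def load_essential_domains(path: str | Path) -> tuple[str, ...]:
    """Read an accession list file (one accession per line, # comments)."""
    return _parse_domain_lines(Path(path).read_text(encoding="utf-8").splitlines())


@dataclass(frozen=True)
class RRNARange:
    """Ideal (full-length) window for one rRNA molecule type, in bases."""

    min_ideal: int
    max_ideal: int

    def __post_init__(self) -> None:
        if not 0 < self.min_ideal < self.max_ideal:
            raise ValueError(
                f"invalid rRNA range: ({self.min_ideal}, {self.max_ideal})"
            )


def _default_rrna_ranges() -> Mapping[str, RRNARange]:
    return {
        "23S": RRNARange(2900, 3500),
        "16S": RRNARange(1450, 1700),
        "5S": RRNARange(100, 120),
    }


@dataclass(frozen=True)
class ScoringConfig:
    """All tunable constants of the four component scores and size filter.

    Attributes
    ----------
    contig_penalty_bp:
        Denominator penalty added per contig after the first (draft
        assemblies only). Calibrated so that an assembly capturing ~99%
        of its genes per contig-break still loses visible score.
    gap_penalty_bp:
        Denominator penalty per run of N of length >= ``gap_min_run``;
        a gap counts the same as a contig break.
    gap_min_run:
        Minimum N-run length treated as an assembly gap.
    min_retained_size / max_retained_size:
        Assemblies strictly smaller are classified plasmid-too-small;
        strictly larger, eukaryote-too-large. The bounds themselves are
        retained.
    rrna_ranges:
        Per-molecule ideal length windows.
    rrna_base / rrna_tier_increments:
        Base score 0.1 plus, per molecule type, 0.3 (ideal length) /
        0.2 (> half the ideal minimum) / 0.1 (any prediction).
    trna_decrement / trna_floor:
        0.1 subtracted per standard amino acid with no non-pseudo tRNA,
        floored at 0.1.
    essential_decrement / essential_floor:
        0.01 subtracted per missing essential domain, floored at 0.1.
    essential_domains:
        The marker-domain accession panel (default: bundled 102-entry list).
    """

    contig_penalty_bp: int = 10_000
    gap_penalty_bp: int = 10_000
    gap_min_run: int = 10
    min_retained_size: int = 138_500
    max_retained_size: int = 18_000_000
    rrna_ranges: Mapping[str, RRNARange] = field(default_factory=_default_rrna_ranges)
    rrna_base: float = 0.1
    rrna_tier_increments: tuple[float, float, float] = (0.3, 0.2, 0.1)
    trna_decrement: float = 0.1
    trna_floor: float = 0.1
    essential_decrement: float = 0.01
    essential_floor: float = 0.1
    essential_domains: tuple[str, ...] = field(
        default_factory=default_essential_domains
    )

    def __post_init__(self) -> None:
        for name in ("contig_penalty_bp", "gap_penalty_bp", "gap_min_run"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("trna_floor", "essential_floor", "rrna_base"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.min_retained_size >= self.max_retained_size:
            raise ValueError("min_retained_size must be < max_retained_size")
        if not self.essential_domains:
            raise ValueError("essential_domains must be non-empty")
        if len(set(self.essential_domains)) != len(self.essential_domains):
            raise ValueError("essential_domains entries must be unique")
        object.__setattr__(
            self,
            "essential_domains",
            tuple(strip_version(a) for a in self.essential_domains),
        )

    def replace(self, **changes) -> "ScoringConfig":
        return dataclasses.replace(self, **changes)


def load_config(path: str | Path) -> ScoringConfig:
    """Build a :class:`ScoringConfig` from a YAML file.

    Recognized keys mirror the dataclass fields; ``rrna_ranges`` maps
    molecule -> [min_ideal, max_ideal]; ``essential_domains_file`` points at
    an accession list file (overrides ``essential_domains``). Unknown keys
    raise, so typos never silently fall back to defaults.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(ScoringConfig)}
    changes: dict = {}
    for key, value in raw.items():
        if key == "essential_domains_file":
            changes["essential_domains"] = load_essential_domains(value)
        elif key == "rrna_ranges":
            changes["rrna_ranges"] = {
                mol: RRNARange(int(lo), int(hi)) for mol, (lo, hi) in value.items()
            }
        elif key == "rrna_tier_increments":
            changes["rrna_tier_increments"] = tuple(float(v) for v in value)
        elif key == "essential_domains":
            changes["essential_domains"] = tuple(value)
        elif key in known:
            changes[key] = value
        else:
            raise ValueError(f"unknown config key: {key!r}")
    return ScoringConfig(**changes)
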