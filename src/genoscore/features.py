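"""Canonical per-genome feature sets and adapters for predictor outputs.

The scorers never look at raw tool output; they consume a ``FeatureSet``
holding tRNA, rRNA, protein-gene and domain-hit records in canonical form.
Adapters are provided for the tool formats the scoring scheme was built on —
tRNAscan-SE tabular output, RNAmmer GFF2, Prodigal GFF3 and HMMER3
``--domtblout`` tables — plus a native plain-text feature-table format so a
genome can be scored with no external predictors at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .config import strip_version

logger = logging.getLogger(__name__)

__all__ = [
    "STANDARD_AMINO_ACIDS",
    "TRNAGene",
    "RRNAGene",
    "ProteinGene",
    "DomainHit",
    "FeatureSet",
    "parse_trnascan",
    "parse_rnammer_gff",
    "parse_prodigal_genes",
    "parse_hmmer_domtbl",
    "read_feature_table",
    "write_feature_table",
]

#: The 20 standard amino acids, in tRNAscan-SE three-letter spelling.
STANDARD_AMINO_ACIDS: tuple[str, ...] = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)

_AA_ALIASES = {aa.lower(): aa for aa in STANDARD_AMINO_ACIDS}
_AA_ALIASES.update({"sec": "SeC", "sec(p)": "SeC", "selcys": "SeC"})

RRNA_MOLECULES = ("5S", "16S", "23S")


def _canonical_amino_acid(raw: str) -> tuple[str, bool]:
    """Map a predictor's tRNA type call to (amino_acid, pseudo_flag).

    "Undet"/"Sup"/unknown calls become "other": an unknown identity cannot
    demonstrate presence of any of the 20 standard amino acids.
    """
    key = raw.strip().lower()
    if key == "pseudo":
        return "other", True
    return _AA_ALIASES.get(key, "other" if key else "other"), False


@dataclass(frozen=True)
class TRNAGene:
    """A predicted tRNA: amino-acid call, anticodon (DNA alphabet), pseudo flag."""

    amino_acid: str
    anticodon: str | None = None
    pseudo: bool = False

    def __post_init__(self) -> None:
        if not self.amino_acid:
            raise ValueError("amino_acid must be set")
        if self.anticodon is not None and (
            len(self.anticodon) != 3 or set(self.anticodon) - set("ACGT")
        ):
            raise ValueError(f"anticodon must be a 3-mer over ACGT, got {self.anticodon!r}")


@dataclass(frozen=True)
class RRNAGene:
    """A predicted rRNA gene of one molecule type with its length in bases."""

    molecule: str
    length: int

    def __post_init__(self) -> None:
        if self.molecule not in RRNA_MOLECULES:
            raise ValueError(f"molecule must be one of {RRNA_MOLECULES}, got {self.molecule!r}")
        if self.length < 1:
            raise ValueError("rRNA length must be >= 1")


@dataclass(frozen=True)
class ProteinGene:
    """A predicted protein-coding gene with its nucleotide length."""

    id: str
    length_nt: int

    def __post_init__(self) -> None:
        if self.length_nt < 3:
            raise ValueError(f"gene {self.id!r}: length_nt must be >= 3")


@dataclass(frozen=True)
class DomainHit:
    """One protein-domain hit: family accession (version-stripped) and gene id."""

    domain_accession: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not self.domain_accession:
            raise ValueError("domain_accession must be non-empty")
        object.__setattr__(self, "domain_accession", strip_version(self.domain_accession))


@dataclass
class FeatureSet:
    """All predicted features of one genome, in canonical form."""

    genome_name: str
    trnas: list[TRNAGene] = field(default_factory=list)
    rrnas: list[RRNAGene] = field(default_factory=list)
    genes: list[ProteinGene] = field(default_factory=list)
    domains: list[DomainHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genome_name:
            raise ValueError("genome_name must be non-empty")


# ---------------------------------------------------------------------------
# tRNAscan-SE tabular output
# ---------------------------------------------------------------------------

def parse_trnascan(path: str | Path) -> list[TRNAGene]:
    """Parse tRNAscan-SE tabular output (``-o`` file).

    Expects the standard 3-line header followed by whitespace-delimited rows
    with columns: sequence name, tRNA number, begin, end, type, anticodon,
    intron begin, intron end, score[, note]. Rows typed "Pseudo", or whose
    trailing note contains "pseudo", are flagged pseudo. Anticodons of
    "???"/"NNN" are recorded as unknown.
    """
    path = Path(path)
    out: list[TRNAGene] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            # header: first three lines of the format (title, subtitle, dashes)
            if lineno <= 3 and (
                "----" in stripped
                or stripped.lower().startswith(("sequence", "name"))
            ):
                continue
            fields = stripped.split()
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: malformed tRNAscan-SE row: {stripped!r}")
            raw_type, raw_anticodon = fields[4], fields[5]
            amino_acid, pseudo = _canonical_amino_acid(raw_type)
            note = " ".join(fields[9:]).lower()
            if "pseudo" in note:
                pseudo = True
            anticodon = raw_anticodon.upper()
            if len(anticodon) != 3 or set(anticodon) - set("ACGT"):
                out.append(TRNAGene(amino_acid, None, pseudo))
            else:
                out.append(TRNAGene(amino_acid, anticodon, pseudo))
    return out


# ---------------------------------------------------------------------------
# RNAmmer GFF2 output
# ---------------------------------------------------------------------------

_RNAMMER_MOLECULES = {
    "5s_rrna": "5S",
    "16s_rrna": "16S",
    "23s_rrna": "23S",
    "8s_rrna": None,  # eukaryotic 5.8S-style calls: not scored
}


def parse_rnammer_gff(path: str | Path) -> list[RRNAGene]:
    """Parse RNAmmer GFF2 output into rRNA gene records.

    Length is derived from the 1-based inclusive coordinates
    (end - start + 1), never read from attributes. Lines whose attribute
    names an unrecognized molecule are skipped with a warning.
    """
    path = Path(path)
    out: list[RRNAGene] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) < 9:
                fields = stripped.split()
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GFF row: {stripped!r}")
            start, end, attribute = int(fields[3]), int(fields[4]), fields[8]
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start ({end} < {start})")
            molecule = _RNAMMER_MOLECULES.get(attribute.strip().lower(), None)
            if molecule is None:
                logger.warning("%s:%d: skipping unknown rRNA molecule %r", path, lineno, attribute)
                continue
            out.append(RRNAGene(molecule, end - start + 1))
    return out


# ---------------------------------------------------------------------------
# Prodigal GFF3 output
# ---------------------------------------------------------------------------

def parse_prodigal_genes(path: str | Path) -> list[ProteinGene]:
    """Parse Prodigal GFF3 CDS records into protein-gene records.

    length_nt = end - start + 1 (1-based inclusive). A CDS with no ID
    attribute gets a synthesized "<contig>_<ordinal>" id.
    """
    path = Path(path)
    out: list[ProteinGene] = []
    per_contig: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: malformed GFF row: {stripped!r}")
            if fields[2] != "CDS":
                continue
            contig, start, end = fields[0], int(fields[3]), int(fields[4])
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start ({end} < {start})")
            per_contig[contig] = per_contig.get(contig, 0) + 1
            gene_id = ""
            if len(fields) >= 9:
                for item in fields[8].split(";"):
                    key, _, value = item.partition("=")
                    if key.strip() == "ID" and value:
                        gene_id = value.strip()
                        break
            if not gene_id:
                gene_id = f"{contig}_{per_contig[contig]}"
            out.append(ProteinGene(gene_id, end - start + 1))
    return out


# ---------------------------------------------------------------------------
# HMMER3 --domtblout output
# ---------------------------------------------------------------------------

def parse_hmmer_domtbl(
    path: str | Path,
    essential_domains: Sequence[str],
    max_evalue: float | None = None,
) -> list[DomainHit]:
    """Parse HMMER3 per-domain tabular output, keeping essential-panel hits.

    Accessions are compared version-stripped. The Pfam accession may appear
    in the target-accession column (hmmscan: models are targets) or the
    query-accession column (hmmsearch: models are queries); either is
    accepted and the opposite record's name becomes the gene id. Rows whose
    accession is not in ``essential_domains`` are ignored; duplicate hits
    for one domain are all returned (presence, not copy number, is scored).

    By default no E-value threshold is applied — whatever the producer of
    the file considered a hit counts as one. Pass ``max_evalue`` to filter
    on the full-sequence E-value (column 7) independently.
    """
    path = Path(path)
    wanted = {strip_version(a) for a in essential_domains}
    out: list[DomainHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) < 13:
                raise ValueError(f"{path}:{lineno}: malformed domtblout row: {stripped!r}")
            target_name, target_acc = fields[0], strip_version(fields[1])
            query_name, query_acc = fields[3], strip_version(fields[4])
            if max_evalue is not None:
                try:
                    evalue = float(fields[6])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad E-value field {fields[6]!r}") from exc
                if evalue > max_evalue:
                    continue
            if target_acc in wanted:
                out.append(DomainHit(target_acc, query_name))
            elif query_acc in wanted:
                out.append(DomainHit(query_acc, target_name))
    return out


# ---------------------------------------------------------------------------
# Native feature-table format
# ---------------------------------------------------------------------------
#
# A versioned plain-text format with four sections mirroring the four
# feature lists:
#
#   #genoscore-features v1
#   genome <name>
#   [trna]
#   amino_acid<TAB>anticodon<TAB>pseudo
#   Met<TAB>CAT<TAB>0
#   [rrna]
#   molecule<TAB>length
#   16S<TAB>1550
#   [gene]
#   id<TAB>length_nt
#   [domain]
#   accession<TAB>gene_id
#
# Sections may be empty or omitted; '-' encodes an unknown anticodon.

_FEATURE_MAGIC = "#genoscore-features v1"
_SECTION_HEADERS = {
    "trna": "amino_acid\tanticodon\tpseudo",
    "rrna": "molecule\tlength",
    "gene": "id\tlength_nt",
    "domain": "accession\tgene_id",
}


def write_feature_table(features: FeatureSet, path: str | Path) -> None:
    """Write a FeatureSet in the native plain-text format (lossless)."""
    lines = [_FEATURE_MAGIC, f"genome\t{features.genome_name}"]
    lines.append("[trna]")
    lines.append(_SECTION_HEADERS["trna"])
    for t in features.trnas:
        lines.append(f"{t.amino_acid}\t{t.anticodon or '-'}\t{int(t.pseudo)}")
    lines.append("[rrna]")
    lines.append(_SECTION_HEADERS["rrna"])
    for r in features.rrnas:
        lines.append(f"{r.molecule}\t{r.length}")
    lines.append("[gene]")
    lines.append(_SECTION_HEADERS["gene"])
    for g in features.genes:
        lines.append(f"{g.id}\t{g.length_nt}")
    lines.append("[domain]")
    lines.append(_SECTION_HEADERS["domain"])
    for d in features.domains:
        lines.append(f"{d.domain_accession}\t{d.gene_id}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_feature_table(path: str | Path) -> FeatureSet:
    """Read the native feature-table format written by write_feature_table."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].strip() != _FEATURE_MAGIC:
        raise ValueError(f"{path}: not a genoscore feature table (missing {_FEATURE_MAGIC!r})")
    genome_name = ""
    section: str | None = None
    trnas: list[TRNAGene] = []
    rrnas: list[RRNAGene] = []
    genes: list[ProteinGene] = []
    domains: list[DomainHit] = []
    for lineno, line in enumerate(lines[1:], 2):
        stripped = line.rstrip("\n")
        if not stripped.strip() or stripped.startswith("#"):
            continue
        if stripped.startswith("[") and stripped.endswith("]"):
            section = stripped[1:-1]
            if section not in _SECTION_HEADERS:
                raise ValueError(f"{path}:{lineno}: unknown section {section!r}")
            continue
        fields = stripped.split("\t")
        if section is None:
            if fields[0] == "genome" and len(fields) == 2:
                genome_name = fields[1]
                continue
            raise ValueError(f"{path}:{lineno}: unknown field {fields[0]!r}")
        if stripped == _SECTION_HEADERS[section]:
            continue
        try:
            if section == "trna":
                aa, anticodon, pseudo = fields
                trnas.append(TRNAGene(aa, None if anticodon == "-" else anticodon, bool(int(pseudo))))
            elif section == "rrna":
                molecule, length = fields
                rrnas.append(RRNAGene(molecule, int(length)))
            elif section == "gene":
                gene_id, length_nt = fields
                genes.append(ProteinGene(gene_id, int(length_nt)))
            elif section == "domain":
                accession, gene_id = fields
                domains.append(DomainHit(accession, gene_id))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}:{lineno}: bad {section} row {stripped!r}: {exc}") from exc
    if not genome_name:
        raise ValueError(f"{path}: missing genome_name ('genome <name>' line)")
    return FeatureSet(genome_name, trnas, rrnas, genes, domains)
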