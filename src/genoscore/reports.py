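"""Report writers: score cards, dedupe tables, cohort analytics exports.

All outputs are plain TSV (plus a JSON mirror of the score cards). Scores
are displayed rounded to two decimals; the underlying tables keep full
precision and rounding never feeds back into any computation.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .assembly import GenomeAssembly, classify_by_size, genome_fingerprint
from .cohort import AnticodonTable, CohortScoreTable, format_percent
from .config import ScoringConfig

__all__ = [
    "SCORE_CARD_COLUMNS",
    "score_card_frame",
    "write_score_cards",
    "write_dedupe_report",
    "write_distribution_table",
    "write_anticodon_table",
    "write_rare_anticodon_table",
]

#: Versioned score-card schema (v1). Changing this set is a breaking change.
SCORE_CARD_COLUMNS: tuple[str, ...] = (
    "genome_name",
    "status",
    "genus",
    "source",
    "sequence_quality",
    "rrna",
    "trna",
    "essential",
    "raw_combined",
    "total",
    "combine_mode",
)

_SCORE_COLUMNS = ("sequence_quality", "rrna", "trna", "essential", "raw_combined", "total")


def score_card_frame(
    table: CohortScoreTable,
    metadata: Sequence[dict] | None = None,
    combine_mode: str = "auto",
) -> pd.DataFrame:
    """Assemble the score-card table (one row per genome, schema v1).

    ``combine_mode`` picks the ``total`` column: "raw" reports the raw
    combined mean, "standardized" the cohort-standardized total, "auto"
    standardized for cohorts of two or more and raw otherwise.
    """
    rows = table.rows.copy()
    n = len(rows)
    if combine_mode == "auto":
        combine_mode = "standardized" if n >= 2 else "raw"
    if combine_mode == "standardized" and "standardized_total" in rows.columns:
        rows["total"] = rows["standardized_total"]
    elif combine_mode == "raw":
        rows["total"] = rows["raw_combined"]
    else:
        raise ValueError(f"unknown combine mode {combine_mode!r}")
    rows["combine_mode"] = combine_mode
    meta = metadata or [{}] * n
    for key in ("status", "genus", "source"):
        rows[key] = [m.get(key, "") for m in meta]
    return rows[list(SCORE_CARD_COLUMNS)]


def write_score_cards(frame: pd.DataFrame, outdir: str | Path) -> tuple[Path, Path]:
    """Write score cards as TSV and JSON (2-decimal display rounding)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    shown = frame.copy()
    for column in _SCORE_COLUMNS:
        shown[column] = shown[column].map(lambda v: f"{v:.2f}")
    tsv = outdir / "score_cards.tsv"
    shown.to_csv(tsv, sep="\t", index=False)
    js = outdir / "score_cards.json"
    records = []
    for _, row in frame.iterrows():
        record = {k: row[k] for k in SCORE_CARD_COLUMNS}
        for column in _SCORE_COLUMNS:
            record[column] = round(float(record[column]), 2)
        records.append(record)
    js.write_text(json.dumps(records, indent=2) + "\n", encoding="utf-8")
    return tsv, js


def write_dedupe_report(
    assemblies: Iterable[GenomeAssembly],
    path: str | Path,
    config: ScoringConfig | None = None,
) -> pd.DataFrame:
    """TSV of name, fingerprint, total_size, size_class, duplicate_of.

    ``duplicate_of`` is empty for the first assembly carrying a fingerprint
    and names that representative for every later copy.
    """
    config = config or ScoringConfig()
    representative: dict[str, str] = {}
    rows = []
    for asm in assemblies:
        fp = genome_fingerprint(asm)
        rows.append(
            {
                "name": asm.name,
                "fingerprint": fp,
                "total_size": asm.total_size,
                "size_class": classify_by_size(asm.total_size, config).value,
                "duplicate_of": representative.get(fp, ""),
            }
        )
        representative.setdefault(fp, asm.name)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, sep="\t", index=False)
    return frame


def write_distribution_table(distribution: pd.DataFrame, path: str | Path) -> None:
    shown = distribution.copy()
    shown["percent"] = shown["percent"].map(lambda v: f"{v:.1f}")
    shown.to_csv(path, sep="\t", index=False)


def write_anticodon_table(table: AnticodonTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def write_rare_anticodon_table(rare: pd.DataFrame, path: str | Path) -> None:
    shown = rare.copy()
    shown["percent"] = shown["percent"].map(format_percent)
    shown.to_csv(path, sep="\t", index=False)
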