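"""Summary statistics over an nrEVE catalogue.

Aggregates a catalogue (the shape of the published 64-nrEVE table) into
per-species, per-family, per-genome-sense and per-functional-region tallies
with percentages, the transcription summary (actively transcribed / rows
with transcriptome data), and the circulating-virus similarity summary.
Percentages are integer, rounded half-up, so printed counts reproduce the
printed percentages (21/64 -> 33%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import pandas as pd

from .formats_io import EveCatalogue

#: family -> genome-sense class
DEFAULT_SENSE_MAP: dict[str, str] = {
    "Rhabdoviridae": "negative_ssRNA",
    "Phasmaviridae": "negative_ssRNA",
    "Orthomyxoviridae": "negative_ssRNA",
    "Phenuiviridae": "negative_ssRNA",
    "Xinmoviridae": "negative_ssRNA",
    "Virgaviridae": "positive_ssRNA",
    "Tombusviridae": "positive_ssRNA",
    "Narnaviridae": "positive_ssRNA",
    "Tymoviridae": "positive_ssRNA",
    "Partitiviridae": "dsRNA",
    "Totiviridae": "dsRNA",
}

SENSE_CLASSES = ("negative_ssRNA", "positive_ssRNA", "dsRNA", "unclassified")


def percent(count: int, total: int) -> int:
    """Integer percentage, rounded half-up (the printed-table convention:
    12.5% -> 13)."""
    if total == 0:
        return 0
    return int(
        (Decimal(count) * 100 / Decimal(total)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )


@dataclass
class SummaryReport:
    total: int
    per_species: pd.DataFrame  # species, count, pct
    per_family: pd.DataFrame
    per_sense: pd.DataFrame
    per_function: pd.DataFrame
    transcribed: int
    analysed: int
    warnings: list[str] = field(default_factory=list)


def _tally(series: pd.Series, label: str, total: int) -> pd.DataFrame:
    counts = series.value_counts()
    df = pd.DataFrame({label: counts.index, "count": counts.values})
    df["pct"] = [percent(c, total) for c in df["count"]]
    # deterministic: count desc, then name
    return df.sort_values(["count", label], ascending=[False, True], ignore_index=True)


def summarize(
    catalogue: EveCatalogue, sense_map: Optional[dict[str, str]] = None
) -> SummaryReport:
    """All catalogue tallies.  A family missing from the sense map counts
    as unclassified, with a warning recorded in the report."""
    sense_map = sense_map if sense_map is not None else DEFAULT_SENSE_MAP
    df = catalogue.table
    total = len(df)
    warnings = []

    def sense_of(family: str) -> str:
        if family == "unclassified":
            return "unclassified"
        if family not in sense_map:
            warnings.append(f"family {family!r} not in sense map; counted as unclassified")
            return "unclassified"
        return sense_map[family]

    sense = df["family"].map(sense_of) if total else pd.Series(dtype=str)
    k, n = transcription_summary(catalogue)
    return SummaryReport(
        total=total,
        per_species=_tally(df["species"], "species", total) if total else _empty("species"),
        per_family=_tally(df["family"], "family", total) if total else _empty("family"),
        per_sense=_tally(sense, "sense_class", total) if total else _empty("sense_class"),
        per_function=_tally(df["region"], "function", total) if total else _empty("function"),
        transcribed=k,
        analysed=n,
        warnings=warnings,
    )


def _empty(label: str) -> pd.DataFrame:
    return pd.DataFrame(columns=[label, "count", "pct"])


def transcription_summary(catalogue: EveCatalogue) -> tuple[int, int]:
    """(actively transcribed, analysed): analysed = rows carrying a
    detection fraction; transcribed = rows detected in >= 1 dataset."""
    df = catalogue.table
    if len(df) == 0:
        return 0, 0
    has = df["transcript_k"].notna()
    analysed = int(has.sum())
    transcribed = int((df.loc[has, "transcript_k"] >= 1).sum())
    return transcribed, analysed


def similarity_summary(
    pairs: pd.DataFrame,
    min_query_cover: float = 0.5,
    min_identity: float = 0.5,
) -> tuple[int, pd.DataFrame, pd.DataFrame]:
    """Summary of nucleotide similarity between nrEVEs and circulating
    viruses: (number of distinct nrEVEs with a retained match, retained
    pairs, rejected sub-threshold pairs).

    ``pairs`` columns: name, query_cover, identity (proportions), plus any
    carry-through columns.
    """
    required = {"name", "query_cover", "identity"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"similarity table missing columns {sorted(missing)}")
    ok = (pairs["query_cover"] >= min_query_cover) & (pairs["identity"] >= min_identity)
    retained = pairs[ok].reset_index(drop=True)
    rejected = pairs[~ok].reset_index(drop=True)
    return retained["name"].nunique(), retained, rejected


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def report_markdown(report: SummaryReport, similarity_count: Optional[int] = None) -> str:
    lines = [
        "# nrEVE catalogue summary",
        "",
        f"Total nrEVEs: {report.total}",
        "",
        "## Per species",
        report.per_species.to_string(index=False),
        "",
        "## Per viral family",
        report.per_family.to_string(index=False),
        "",
        "## Per genome-sense class",
        report.per_sense.to_string(index=False),
        "",
        "## Per functional region",
        report.per_function.to_string(index=False),
        "",
        f"Transcription: {report.transcribed} of {report.analysed} nrEVEs with "
        "transcriptome data were detected in at least one dataset.",
    ]
    if similarity_count is not None:
        lines.append(
            f"Circulating-virus similarity: {similarity_count} distinct nrEVEs "
            "retained at the 50% cover / 50% identity thresholds."
        )
    if report.warnings:
        lines += ["", "## Warnings"] + [f"- {w}" for w in report.warnings]
    lines += [
        "",
        "Counts are taken from the catalogue table itself; where a narrative "
        "tally disagrees with the table, the table wins.",
    ]
    return "\n".join(lines) + "\n"


def write_report_tables(report: SummaryReport, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.per_species.to_csv(outdir / "per_species.tsv", sep="\t", index=False)
    report.per_family.to_csv(outdir / "per_family.tsv", sep="\t", index=False)
    report.per_sense.to_csv(outdir / "per_sense_class.tsv", sep="\t", index=False)
    report.per_function.to_csv(outdir / "per_function.tsv", sep="\t", index=False)
    (outdir / "summary.md").write_text(report_markdown(report))
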