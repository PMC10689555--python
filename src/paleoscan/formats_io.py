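"""Readers and writers for every external representation the pipeline touches.

All other modules operate on the in-memory types defined here (sequence
records, reads, protein-database entries, ORF interval tables, nrEVE
catalogues).  Coordinates in files are 1-based fully-closed intervals, as in
the published catalogue tables; all internal arithmetic is 0-based half-open
and the conversion happens only at this I/O boundary.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: canonical viral functional-region labels
FUNCTION_LABELS = ("Capsid", "Glycoprotein", "RdRp", "PolymerasePB1", "Hypothetical")

_REGION_ALIASES = {
    "polymerase pbi": "PolymerasePB1",
    "polymerase pb1": "PolymerasePB1",
    "polymerasepb1": "PolymerasePB1",
    "rdrp": "RdRp",
    "capsid": "Capsid",
    "glycoprotein": "Glycoprotein",
    "hypothetical": "Hypothetical",
}

#: viral family inferred from the root token used in nrEVE names
FAMILY_ROOTS = {
    "Rhabdo": "Rhabdoviridae",
    "Partiti": "Partitiviridae",
    "Parititi": "Partitiviridae",  # spelling variant present in the catalogue
    "Phasma": "Phasmaviridae",
    "Phenui": "Phenuiviridae",
    "Orthomyxo": "Orthomyxoviridae",
    "Xinmo": "Xinmoviridae",
    "Virga": "Virgaviridae",
    "Tombus": "Tombusviridae",
    "Narna": "Narnaviridae",
    "Tymo": "Tymoviridae",
    "Toti": "Totiviridae",
}

NAME_RE = re.compile(r"^nrEVE_([A-Z][a-z]{3})([A-Za-z]+)_([0-9]+)$")

DB_CATEGORIES = ("viral", "host", "TE", "retroviral")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class SequenceRecord:
    """One FASTA record: a genome contig, read, or protein."""

    id: str
    description: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FastqRead:
    """One FASTQ read with Phred+33 qualities."""

    id: str
    sequence: str
    qualities: list[int]


@dataclass
class ProteinDbEntry:
    """A database protein with its sidecar annotation."""

    id: str
    sequence: str
    category: str  # viral | host | TE | retroviral
    family: str = "unclassified"
    function: str = "Hypothetical"
    sense_class: str = "unclassified"


@dataclass
class OrfInterval:
    name: str
    function: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "+"


@dataclass
class OrfIntervalTable:
    """ORF annotation of one reference viral genome."""

    virus_id: str
    orfs: list[OrfInterval] = field(default_factory=list)

    def validate(self, virus_length: int, overlap_slack: int = 30) -> None:
        for orf in self.orfs:
            if not (1 <= orf.start <= orf.end <= virus_length):
                raise FormatError(
                    f"ORF {orf.name}: interval {orf.start}-{orf.end} outside "
                    f"1-{virus_length}"
                )
        by_strand: dict[str, list[OrfInterval]] = {}
        for orf in self.orfs:
            by_strand.setdefault(orf.strand, []).append(orf)
        for strand, orfs in by_strand.items():
            orfs = sorted(orfs, key=lambda o: o.start)
            for a, b in zip(orfs, orfs[1:]):
                overlap = a.end - b.start + 1
                if overlap > overlap_slack:
                    raise FormatError(
                        f"ORFs {a.name} and {b.name} overlap by {overlap} nt "
                        f"on strand {strand} (slack {overlap_slack})"
                    )


@dataclass
class EveCatalogue:
    """Catalogue of nrEVE records in the shape of the published Table 1.

    ``table`` columns: name, species, accession, start, length, region,
    family, transcript_k, transcript_n (the latter two are pandas nullable
    integers; missing when no transcriptome data was analysed).
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _find_illegal_line(path, bad_id: str, alphabet: frozenset) -> int:
    """Locate the first line of the offending record containing an illegal
    character, for error reporting."""
    in_record = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                in_record = line[1:].split()[0] == bad_id if line[1:].split() else False
                continue
            if in_record and set(line.strip().upper()) - alphabet:
                return lineno
    return -1


def read_fasta(path, moltype: str) -> list[SequenceRecord]:
    """Read a (possibly gzipped) multi-record FASTA file.

    ``moltype`` is ``"dna"`` (alphabet ACGTN) or ``"protein"`` (20 amino
    acids + X).  Duplicate ids and illegal characters are hard errors.
    """
    if moltype not in ("dna", "protein"):
        raise ValueError(f"moltype must be 'dna' or 'protein', got {moltype!r}")
    alphabet = DNA_ALPHABET if moltype == "dna" else PROTEIN_ALPHABET
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
            seen.add(rec.id)
            seq = str(rec.seq).upper()
            if not seq:
                raise FormatError(f"empty sequence for id {rec.id!r} in {path}")
            bad = set(seq) - alphabet
            if bad:
                lineno = _find_illegal_line(path, rec.id, alphabet)
                raise FormatError(
                    f"illegal character(s) {sorted(bad)} for moltype {moltype} "
                    f"in record {rec.id!r} ({path}, line {lineno})"
                )
            records.append(SequenceRecord(rec.id, rec.description, seq))
    return records


def write_fasta(path, records: Iterable[SequenceRecord], width: int = 70) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=_strip_id(r.description, r.id))
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def _strip_id(description: str, rec_id: str) -> str:
    # Biopython stores "id rest" in description; keep only the rest.
    if description == rec_id:
        return ""
    if description.startswith(rec_id + " "):
        return description[len(rec_id) + 1 :]
    return description


def read_fastq(path) -> list[FastqRead]:
    """Read Sanger (Phred+33) FASTQ.  Truncated records and length
    mismatches between sequence and quality strings are hard errors."""
    reads: list[FastqRead] = []
    try:
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                reads.append(
                    FastqRead(
                        rec.id,
                        str(rec.seq).upper(),
                        list(rec.letter_annotations["phred_quality"]),
                    )
                )
    except ValueError as exc:
        raise FormatError(f"malformed FASTQ {path}: {exc}") from exc
    return reads


def write_fastq(path, reads: Iterable[FastqRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            if len(r.qualities) != len(r.sequence):
                raise FormatError(f"read {r.id!r}: quality/sequence length mismatch")
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Protein database sidecar
# ---------------------------------------------------------------------------


def read_protein_db(fasta_path, sidecar_path) -> list[ProteinDbEntry]:
    """Read a protein FASTA together with its category sidecar TSV
    (columns: id, category, family, function, sense_class).

    Every FASTA id must be annotated in the sidecar; a missing id is a hard
    error raised before any search can run.
    """
    records = read_fasta(fasta_path, "protein")
    side = pd.read_csv(sidecar_path, sep="\t", dtype=str).fillna("")
    required = {"id", "category", "family", "function", "sense_class"}
    if not required.issubset(side.columns):
        raise FormatError(
            f"sidecar {sidecar_path} missing columns {sorted(required - set(side.columns))}"
        )
    meta = {row["id"]: row for _, row in side.iterrows()}
    entries = []
    for rec in records:
        if rec.id not in meta:
            raise FormatError(f"sidecar missing annotation for db entry {rec.id!r}")
        row = meta[rec.id]
        if row["category"] not in DB_CATEGORIES:
            raise FormatError(
                f"db entry {rec.id!r}: unknown category {row['category']!r}"
            )
        entries.append(
            ProteinDbEntry(
                id=rec.id,
                sequence=rec.sequence,
                category=row["category"],
                family=row["family"] or "unclassified",
                function=normalize_region(row["function"]) if row["function"] else "Hypothetical",
                sense_class=row["sense_class"] or "unclassified",
            )
        )
    return entries


def write_protein_db(fasta_path, sidecar_path, entries: Sequence[ProteinDbEntry]) -> None:
    write_fasta(fasta_path, [SequenceRecord(e.id, "", e.sequence) for e in entries])
    pd.DataFrame(
        {
            "id": [e.id for e in entries],
            "category": [e.category for e in entries],
            "family": [e.family for e in entries],
            "function": [e.function for e in entries],
            "sense_class": [e.sense_class for e in entries],
        }
    ).to_csv(sidecar_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# nrEVE catalogue (Table-1 shape)
# ---------------------------------------------------------------------------


def normalize_region(label: str) -> str:
    key = label.strip().lower()
    if key in _REGION_ALIASES:
        return _REGION_ALIASES[key]
    raise FormatError(f"unknown viral region label {label!r}")


def family_from_name(name: str) -> str:
    """Infer the viral family from an nrEVE name per the naming convention:
    four-letter host abbreviation, family root, ordinal."""
    m = NAME_RE.match(name)
    if not m:
        raise FormatError(f"nrEVE name {name!r} does not match the naming convention")
    root = m.group(2)
    if root.lower().startswith("unc"):
        return "unclassified"
    if root in FAMILY_ROOTS:
        return FAMILY_ROOTS[root]
    return root + "viridae"


def parse_transcript_fraction(text: str) -> tuple[Optional[int], Optional[int]]:
    """Parse a detection fraction like ``"3/4"``; ``""`` or ``"-"`` means no
    transcriptome data."""
    text = (text or "").strip()
    if text in ("", "-"):
        return None, None
    m = re.match(r"^([0-9]+)/([0-9]+)$", text)
    if not m:
        raise FormatError(f"malformed transcript fraction {text!r}")
    k, n = int(m.group(1)), int(m.group(2))
    if k > n:
        raise FormatError(f"transcript fraction {text!r} has numerator > denominator")
    return k, n


CATALOGUE_COLUMNS = [
    "name",
    "species",
    "accession",
    "start",
    "length",
    "region",
    "transcript_detection",
]


def read_catalogue(path) -> EveCatalogue:
    """Read a tab-separated nrEVE catalogue (Table-1 schema)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(CATALOGUE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"catalogue {path} missing columns {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        start, length = int(r["start"]), int(r["length"])
        if start < 1 or length < 1:
            raise FormatError(
                f"catalogue row {r['name']}: start and length must be >= 1"
            )
        k, n = parse_transcript_fraction(r["transcript_detection"])
        rows.append(
            {
                "name": r["name"],
                "species": r["species"],
                "accession": r["accession"],
                "start": start,
                "length": length,
                "region": normalize_region(r["region"]),
                "family": family_from_name(r["name"]),
                "transcript_k": k,
                "transcript_n": n,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "name",
            "species",
            "accession",
            "start",
            "length",
            "region",
            "family",
            "transcript_k",
            "transcript_n",
        ],
    )
    if len(table):
        table["transcript_k"] = table["transcript_k"].astype("Int64")
        table["transcript_n"] = table["transcript_n"].astype("Int64")
        dup = table["name"][table["name"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate nrEVE names in catalogue: {sorted(set(dup))}")
    return EveCatalogue(table)


def write_catalogue(path, catalogue: EveCatalogue) -> None:
    df = catalogue.table.copy()
    frac = []
    for k, n in zip(df["transcript_k"], df["transcript_n"]):
        frac.append("-" if pd.isna(k) else f"{int(k)}/{int(n)}")
    out = pd.DataFrame(
        {
            "name": df["name"],
            "species": df["species"],
            "accession": df["accession"],
            "start": df["start"],
            "length": df["length"],
            "region": df["region"],
            "transcript_detection": frac,
        }
    )
    out.to_csv(path, sep="\t", index=False)


def packaged_table1() -> EveCatalogue:
    """The catalogue of 64 tephritid nrEVEs shipped with the package."""
    return read_catalogue(_data_path("table1_tephritid_nreves.tsv"))


def packaged_table2() -> pd.DataFrame:
    """Nucleotide-similarity records between nrEVEs and circulating viruses
    shipped with the package (columns: name, accession, length, query_cover,
    evalue, identity, virus; fractions as proportions in [0, 1])."""
    df = pd.read_csv(_data_path("table2_circulating_similarity.tsv"), sep="\t")
    df["query_cover"] = df["query_cover"].str.rstrip("%").astype(float) / 100.0
    df["identity"] = df["identity"].str.rstrip("%").astype(float) / 100.0
    df["evalue"] = df["evalue"].astype(float)
    return df


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


# ---------------------------------------------------------------------------
# ORF interval tables and GFF3
# ---------------------------------------------------------------------------


def read_orf_table(path) -> OrfIntervalTable:
    """Read an ORF interval TSV (columns: virus_id, orf, function, start,
    end, strand)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"virus_id", "orf", "function", "start", "end", "strand"}
    if not required.issubset(df.columns):
        raise FormatError(f"ORF table {path} missing columns {sorted(required - set(df.columns))}")
    virus_ids = set(df["virus_id"])
    if len(virus_ids) != 1:
        raise FormatError(f"ORF table {path} must describe exactly one virus, got {sorted(virus_ids)}")
    orfs = [
        OrfInterval(
            name=r["orf"],
            function=normalize_region(r["function"]),
            start=int(r["start"]),
            end=int(r["end"]),
            strand=r["strand"],
        )
        for _, r in df.iterrows()
    ]
    return OrfIntervalTable(virus_id=virus_ids.pop(), orfs=orfs)


def write_orf_table(path, table: OrfIntervalTable) -> None:
    pd.DataFrame(
        {
            "virus_id": [table.virus_id] * len(table.orfs),
            "orf": [o.name for o in table.orfs],
            "function": [o.function for o in table.orfs],
            "start": [o.start for o in table.orfs],
            "end": [o.end for o in table.orfs],
            "strand": [o.strand for o in table.orfs],
        }
    ).to_csv(path, sep="\t", index=False)


def write_gff3(path, features: Iterable[dict]) -> None:
    """Write nrEVE loci as GFF3.  Each feature dict carries: seqid, start
    (1-based), end (inclusive), strand, name, plus optional attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = [f"ID={f['name']}", f"Name={f['name']}"]
            for key in ("family", "region", "top_hit"):
                if f.get(key):
                    attrs.append(f"{key}={f[key]}")
            fh.write(
                "\t".join(
                    [
                        f["seqid"],
                        "paleoscan",
                        "nrEVE",
                        str(f["start"]),
                        str(f["end"]),
                        str(f.get("score", ".")),
                        f.get("strand", "."),
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
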