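"""Synthetic inputs with known ground truth.

This module emulates the study's real inputs at desk scale: host genome
assemblies carrying integrated fragments of viral proteins (nrEVEs) at a
configurable amino-acid divergence, decoy integrations derived from host,
transposable-element and retroviral proteins, a categorized protein
database, RNA-seq libraries over a transcribed subset of the integrations,
and small-RNA libraries with the piRNA hallmarks (25-30 nt length peak,
5'-uridine bias, single-strand origin).  Every planted feature is recorded
in a truth table so downstream recall/precision is computable without any
external data.

Background genome sequence is i.i.d. with configurable GC and no repeat
structure; integrations are reverse-translations of protein fragments with
uniform random synonymous codons.  Both choices keep the mapping between
planted truth and detected signal exact.  Identical seeds give identical
outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .formats_io import (
    FastqRead,
    OrfInterval,
    OrfIntervalTable,
    ProteinDbEntry,
    SequenceRecord,
    write_fasta,
    write_fastq,
    write_protein_db,
)
from .homology_search import reverse_complement

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_standard = CodonTable.unambiguous_dna_by_id[1]
CODONS_FOR_AA: dict[str, list[str]] = {}
for codon, aa in _standard.forward_table.items():
    CODONS_FOR_AA.setdefault(aa, []).append(codon)
for codons in CODONS_FOR_AA.values():
    codons.sort()

#: (family, function) palette cycled over when generating viral db entries
VIRAL_PALETTE = [
    ("Rhabdoviridae", "Capsid"),
    ("Rhabdoviridae", "Glycoprotein"),
    ("Rhabdoviridae", "RdRp"),
    ("Partitiviridae", "Capsid"),
    ("Partitiviridae", "RdRp"),
    ("Phasmaviridae", "Glycoprotein"),
    ("Phenuiviridae", "Capsid"),
    ("Orthomyxoviridae", "PolymerasePB1"),
    ("Xinmoviridae", "Glycoprotein"),
    ("Virgaviridae", "RdRp"),
    ("Tombusviridae", "RdRp"),
    ("Narnaviridae", "RdRp"),
    ("Tymoviridae", "Capsid"),
    ("Totiviridae", "Capsid"),
]

#: genome-sense class of each viral family
FAMILY_SENSE = {
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

TRUTH_COLUMNS = [
    "planted_id",
    "contig",
    "start",
    "length",
    "source_protein",
    "category",
    "family",
    "function",
    "divergence",
    "strand",
    "transcribed",
]


@dataclass
class InsertionSpec:
    """One planted integration: a fragment of a database protein,
    substituted at amino-acid rate ``divergence`` and reverse-translated."""

    source_protein: str
    divergence: float = 0.1
    fragment_aa: Optional[int] = None  # None = whole protein
    contig: Optional[str] = None
    position: Optional[int] = None  # 0-based; None = random non-overlapping
    strand: Optional[str] = None
    transcribed: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must lie in [0, 1]")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic genome."""

    seed: int = 0
    contig_count: int = 4
    contig_length: int = 500_000
    gc: float = 0.40
    n_viral_insertions: int = 20
    divergence: float = 0.1
    fragment_aa_range: tuple[int, int] = (50, 150)
    decoys_per_category: dict = field(
        default_factory=lambda: {"host": 5, "TE": 5, "retroviral": 5}
    )
    n_viral_proteins: int = 20
    n_decoy_proteins_per_category: int = 8
    protein_aa_range: tuple[int, int] = (150, 400)
    transcribed_fraction: float = 0.5
    insertions: Optional[list[InsertionSpec]] = None  # overrides the counts
    extra_db_entries: Optional[list[ProteinDbEntry]] = None

    def __post_init__(self) -> None:
        if self.contig_length <= 0 or self.contig_count <= 0:
            raise ValueError("contig count and length must be positive")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must lie in [0, 1]")


@dataclass
class SrnaLibrarySpec:
    """Composition of one synthetic small-RNA library.

    Planted piRNA-like reads are substrings of designated loci; the length
    distribution defaults to a 25-30 nt peak; the 5' base is uridine with
    probability exactly ``p1U``; reads originate from the locus plus strand
    with probability ``p_strand``.  Background reads are random sequence
    (21-22 nt) mapping nowhere; the planted filter-violating categories
    exercise the cleaning stages.
    """

    total_reads: int = 5000
    pirna_fraction: float = 0.8
    length_weights: Optional[dict[int, float]] = None  # None = 25-30 peak
    p1U: float = 0.9
    p_strand: float = 1.0
    background_lengths: tuple[int, ...] = (21, 22)
    n_low_quality: int = 0
    n_low_complexity: int = 0
    n_out_of_range: int = 0
    adapter: Optional[str] = None

    def __post_init__(self) -> None:
        for p in (self.pirna_fraction, self.p1U, self.p_strand):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.length_weights:
            if any(not 18 <= l <= 32 for l in self.length_weights):
                raise ValueError("planted piRNA lengths must lie in [18, 32]")

    def resolved_lengths(self) -> tuple[np.ndarray, np.ndarray]:
        if self.length_weights:
            lengths = np.array(sorted(self.length_weights), dtype=int)
            w = np.array([self.length_weights[l] for l in lengths], dtype=float)
        else:
            lengths = np.arange(25, 31)
            w = np.ones(len(lengths))
        return lengths, w / w.sum()


@dataclass
class SimulatedGenome:
    contigs: list[SequenceRecord]
    db: list[ProteinDbEntry]
    truth: pd.DataFrame

    def contig(self, name: str) -> SequenceRecord:
        for c in self.contigs:
            if c.id == name:
                return c
        raise KeyError(name)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "genome.fa", self.contigs)
        write_protein_db(outdir / "proteins.fa", outdir / "proteins.tsv", self.db)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sequence primitives
# ---------------------------------------------------------------------------


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def diverge_protein(rng: np.random.Generator, protein: str, rate: float) -> str:
    """Substitute each residue with probability ``rate`` to a uniformly
    random different residue (protein-space divergence)."""
    out = list(protein)
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        choices = AMINO_ACIDS.replace(out[i], "") if out[i] in AMINO_ACIDS else AMINO_ACIDS
        out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def reverse_translate(rng: np.random.Generator, protein: str) -> str:
    """DNA encoding of ``protein`` with uniform random synonymous codons."""
    parts = []
    for aa in protein:
        codons = CODONS_FOR_AA.get(aa)
        if codons is None:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        parts.append(codons[rng.integers(0, len(codons))])
    return "".join(parts)


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------


def _default_db(rng: np.random.Generator, config: SimulationConfig) -> list[ProteinDbEntry]:
    entries = []
    lo, hi = config.protein_aa_range
    for i in range(config.n_viral_proteins):
        family, function = VIRAL_PALETTE[i % len(VIRAL_PALETTE)]
        entries.append(
            ProteinDbEntry(
                id=f"viral_{i:03d}",
                sequence=random_protein(rng, int(rng.integers(lo, hi + 1))),
                category="viral",
                family=family,
                function=function,
                sense_class=FAMILY_SENSE[family],
            )
        )
    for category in ("host", "TE", "retroviral"):
        for i in range(config.n_decoy_proteins_per_category):
            entries.append(
                ProteinDbEntry(
                    id=f"{category}_{i:03d}",
                    sequence=random_protein(rng, int(rng.integers(lo, hi + 1))),
                    category=category,
                )
            )
    if config.extra_db_entries:
        entries.extend(config.extra_db_entries)
    return entries


def _auto_insertions(
    rng: np.random.Generator, config: SimulationConfig, db: Sequence[ProteinDbEntry]
) -> list[InsertionSpec]:
    lo, hi = config.fragment_aa_range
    specs: list[InsertionSpec] = []
    viral = [e for e in db if e.category == "viral"]
    n_transcribed = int(round(config.transcribed_fraction * config.n_viral_insertions))
    for i in range(config.n_viral_insertions):
        src = viral[int(rng.integers(0, len(viral)))]
        frag = int(rng.integers(lo, min(hi, len(src.sequence)) + 1))
        specs.append(
            InsertionSpec(
                source_protein=src.id,
                divergence=config.divergence,
                fragment_aa=frag,
                transcribed=i < n_transcribed,
            )
        )
    for category, count in config.decoys_per_category.items():
        pool = [e for e in db if e.category == category]
        for _ in range(count):
            if not pool:
                break
            src = pool[int(rng.integers(0, len(pool)))]
            frag = int(rng.integers(lo, min(hi, len(src.sequence)) + 1))
            specs.append(
                InsertionSpec(source_protein=src.id, divergence=config.divergence, fragment_aa=frag)
            )
    return specs


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Generate host contigs with planted integrations, the categorized
    protein database, and the truth table describing exactly what was
    planted."""
    rng = np.random.default_rng(config.seed)
    db = _default_db(rng, config)
    db_by_id = {e.id: e for e in db}
    specs = config.insertions if config.insertions is not None else _auto_insertions(rng, config, db)

    contig_names = [f"contig_{i+1}" for i in range(config.contig_count)]
    backgrounds = {
        name: list(random_dna(rng, config.contig_length, config.gc)) for name in contig_names
    }
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in contig_names}

    truth_rows = []
    for idx, spec in enumerate(specs):
        src = db_by_id.get(spec.source_protein)
        if src is None:
            raise ValueError(f"insertion source {spec.source_protein!r} not in database")
        frag_aa = spec.fragment_aa or len(src.sequence)
        frag_aa = min(frag_aa, len(src.sequence))
        frag_start = int(rng.integers(0, len(src.sequence) - frag_aa + 1))
        fragment = src.sequence[frag_start : frag_start + frag_aa]
        diverged = diverge_protein(rng, fragment, spec.divergence)
        dna = reverse_translate(rng, diverged)
        strand = spec.strand or ("+" if rng.random() < 0.5 else "-")
        planted = dna if strand == "+" else reverse_complement(dna)

        contig = spec.contig or contig_names[int(rng.integers(0, len(contig_names)))]
        if contig not in backgrounds:
            raise ValueError(f"unknown contig {contig!r}")
        pos = spec.position
        if pos is None:
            pos = _place(rng, occupied[contig], config.contig_length, len(planted))
        else:
            if _overlaps(occupied[contig], pos, len(planted)):
                raise ValueError(f"explicit position {pos} overlaps a prior insertion")
        occupied[contig].append((pos, pos + len(planted)))
        backgrounds[contig][pos : pos + len(planted)] = planted
        truth_rows.append(
            {
                "planted_id": f"planted_{idx:03d}",
                "contig": contig,
                "start": pos,
                "length": len(planted),
                "source_protein": src.id,
                "category": src.category,
                "family": src.family,
                "function": src.function,
                "divergence": spec.divergence,
                "strand": strand,
                "transcribed": spec.transcribed,
            }
        )

    contigs = [SequenceRecord(name, "", "".join(backgrounds[name])) for name in contig_names]
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return SimulatedGenome(contigs=contigs, db=db, truth=truth)


def _overlaps(intervals: list[tuple[int, int]], start: int, length: int) -> bool:
    end = start + length
    return any(start < b and a < end for a, b in intervals)


def _place(
    rng: np.random.Generator,
    intervals: list[tuple[int, int]],
    contig_len: int,
    length: int,
    max_tries: int = 200,
) -> int:
    if length > contig_len:
        raise ValueError("insertion longer than contig")
    for _ in range(max_tries):
        pos = int(rng.integers(0, contig_len - length + 1))
        if not _overlaps(intervals, pos, length):
            return pos
    raise ValueError("could not place insertion without overlap")


# ---------------------------------------------------------------------------
# RNA-seq simulation
# ---------------------------------------------------------------------------


def simulate_rnaseq(
    genome: SimulatedGenome,
    depth: float,
    read_len: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
    background_reads: int = 0,
) -> list[FastqRead]:
    """Uniform reads over the transcribed planted loci (plus optional
    genomic background reads), with substitution errors at ``error_rate``.
    Read ids encode the source locus so mapping tests can check assignments
    against truth."""
    if read_len < 30:
        raise ValueError("read_len must be >= 30")
    rng = np.random.default_rng(seed)
    reads: list[FastqRead] = []
    loci = genome.truth[genome.truth["transcribed"]]
    if depth > 0:
        for _, row in loci.iterrows():
            locus_seq = genome.contig(row["contig"]).sequence[
                row["start"] : row["start"] + row["length"]
            ]
            if read_len > len(locus_seq):
                raise ValueError(
                    f"read_len {read_len} exceeds locus {row['planted_id']} length {len(locus_seq)}"
                )
            n_reads = int(round(depth * len(locus_seq) / read_len))
            for i in range(n_reads):
                start = int(rng.integers(0, len(locus_seq) - read_len + 1))
                seq = locus_seq[start : start + read_len]
                if rng.random() < 0.5:
                    seq = reverse_complement(seq)
                seq = _add_errors(rng, seq, error_rate)
                reads.append(
                    FastqRead(f"{row['planted_id']}_read_{i}", seq, [40] * read_len)
                )
    for i in range(background_reads):
        contig = genome.contigs[int(rng.integers(0, len(genome.contigs)))]
        start = int(rng.integers(0, len(contig.sequence) - read_len + 1))
        seq = _add_errors(rng, contig.sequence[start : start + read_len], error_rate)
        reads.append(FastqRead(f"background_read_{i}", seq, [40] * read_len))
    return reads


def _add_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(out)) < rate)[0]
    for i in hits:
        choices = "ACGT".replace(out[i], "")
        out[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Small RNA simulation
# ---------------------------------------------------------------------------


def simulate_srna(
    genome: SimulatedGenome,
    spec: SrnaLibrarySpec,
    seed: int = 0,
    source_loci: Optional[pd.DataFrame] = None,
) -> tuple[list[FastqRead], dict[str, int]]:
    """One synthetic small-RNA library.

    Returns the reads and the per-category planted counts (pirna,
    background, low_quality, low_complexity, out_of_range, adapter_only)
    against which a cleaning attrition report can be compared exactly.
    """
    rng = np.random.default_rng(seed)
    loci = source_loci if source_loci is not None else genome.truth
    loci = loci[loci["category"] == "viral"] if "category" in loci.columns else loci
    if len(loci) == 0:
        raise ValueError("no source loci for piRNA reads")
    lengths, weights = spec.resolved_lengths()
    max_len = int(lengths.max())
    for _, row in loci.iterrows():
        if row["length"] < max_len:
            raise ValueError(f"locus {row['planted_id']} shorter than max read length")

    n_pirna = int(round(spec.total_reads * spec.pirna_fraction))
    n_background = spec.total_reads - n_pirna
    reads: list[FastqRead] = []
    counts = {
        "pirna": n_pirna,
        "background": n_background,
        "low_quality": spec.n_low_quality,
        "low_complexity": spec.n_low_complexity,
        "out_of_range": spec.n_out_of_range,
    }

    rows = list(loci.iterrows())
    for i in range(n_pirna):
        _, row = rows[int(rng.integers(0, len(rows)))]
        locus_seq = genome.contig(row["contig"]).sequence[
            row["start"] : row["start"] + row["length"]
        ]
        length = int(rng.choice(lengths, p=weights))
        plus = rng.random() < spec.p_strand
        want_u = rng.random() < spec.p1U
        seq = _draw_pirna(rng, locus_seq, length, plus, want_u)
        reads.append(FastqRead(f"pirna_{i}", seq, [40] * len(seq)))

    for i in range(n_background):
        length = int(rng.choice(np.asarray(spec.background_lengths)))
        reads.append(
            FastqRead(f"bg_{i}", random_dna(rng, length, 0.5), [40] * length)
        )
    for i in range(spec.n_low_quality):
        length = 26
        seq = random_dna(rng, length, 0.5)
        n_bad = int(math.floor(0.2 * length)) + 1  # just over the 20% rule
        quals = [40] * length
        for j in rng.choice(length, size=n_bad, replace=False):
            quals[j] = 5
        reads.append(FastqRead(f"lowq_{i}", seq, quals))
    for i in range(spec.n_low_complexity):
        base = "ACGT"[int(rng.integers(0, 4))]
        reads.append(FastqRead(f"lowc_{i}", base * 25, [40] * 25))
    for i in range(spec.n_out_of_range):
        length = 17 if i % 2 == 0 else 33
        reads.append(FastqRead(f"oor_{i}", random_dna(rng, length, 0.5), [40] * length))

    if spec.adapter:
        for r in reads:
            r.sequence = r.sequence + spec.adapter
            r.qualities = r.qualities + [40] * len(spec.adapter)
    return reads, counts


def _draw_pirna(
    rng: np.random.Generator, locus_seq: str, length: int, plus: bool, want_u: bool
) -> str:
    """A substring of the locus on the chosen strand whose 5' base is T iff
    ``want_u``, chosen among matching start positions (substitution only
    when no position qualifies)."""
    template = locus_seq if plus else reverse_complement(locus_seq)
    n_starts = len(template) - length + 1
    starts = np.arange(n_starts)
    first = np.frombuffer(template.encode("ascii"), dtype=np.uint8)[:n_starts]
    is_t = first == ord("T")
    pool = starts[is_t] if want_u else starts[~is_t]
    if len(pool) == 0:
        start = int(rng.integers(0, n_starts))
        seq = template[start : start + length]
        head = "T" if want_u else "ACG"[int(rng.integers(0, 3))]
        return head + seq[1:]
    start = int(pool[int(rng.integers(0, len(pool)))])
    return template[start : start + length]


# ---------------------------------------------------------------------------
# Reference viral genome
# ---------------------------------------------------------------------------


def simulate_reference_virus(
    seed: int,
    orf_specs: Sequence[tuple[str, str, int]],
    intergenic: int = 200,
    virus_id: str = "refvirus",
) -> tuple[SequenceRecord, OrfIntervalTable, dict[str, str]]:
    """A reference viral genome laid out as alternating intergenic spacers
    and ORFs.  ``orf_specs`` rows are (orf name, function label, protein
    length aa).  Returns the genome, its ORF interval table (1-based
    inclusive) and the ORF proteins (usable as viral db entries)."""
    rng = np.random.default_rng(seed)
    parts = []
    orfs = []
    proteins = {}
    cursor = 0
    for name, function, aa_len in orf_specs:
        spacer = random_dna(rng, intergenic, 0.45)
        parts.append(spacer)
        cursor += len(spacer)
        protein = random_protein(rng, aa_len)
        dna = reverse_translate(rng, protein)
        orfs.append(
            OrfInterval(name=name, function=function, start=cursor + 1, end=cursor + len(dna))
        )
        proteins[name] = protein
        parts.append(dna)
        cursor += len(dna)
    parts.append(random_dna(rng, intergenic, 0.45))
    genome = SequenceRecord(virus_id, "synthetic reference viral genome", "".join(parts))
    table = OrfIntervalTable(virus_id=virus_id, orfs=orfs)
    table.validate(len(genome.sequence))
    return genome, table, proteins


def write_reads(path, reads: Sequence[FastqRead]) -> None:
    write_fastq(path, reads)
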