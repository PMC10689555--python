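"""From translated-search hits to a validated nrEVE catalogue.

The discovery procedure mirrors a two-stage homology screen: a forward
translated search of the host genome against viral proteins (stringent
cutoff, default 1e-6) proposes candidate loci; each candidate's genomic
sequence is then re-searched against the full categorized database (viral +
host + transposable-element + retroviral entries, looser cutoff, default
1e-4) and kept only when its top hit is viral.  Kept candidates are named
(host abbreviation + viral family root + ordinal), classified by the top
viral hit's annotation, and can be clustered by genomic proximity or mapped
onto an annotated reference viral genome to assign the functional region
they derive from.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .formats_io import (
    DB_CATEGORIES,
    EveCatalogue,
    OrfIntervalTable,
    ProteinDbEntry,
    SequenceRecord,
)
from .homology_search import (
    Hsp,
    SearchConfig,
    reverse_complement,
    search_translated,
    translate_six_frames,
    _frame_to_contig,
)

FORWARD_EVALUE = 1e-6
VALIDATION_EVALUE = 1e-4
#: HSPs for the same (contig, strand, subject) merge into one locus when
#: their genomic footprints overlap or sit within this many nucleotides
MERGE_GAP_NT = 10


@dataclass
class NrEve:
    """One validated non-retroviral endogenous viral element."""

    name: str
    host_species: str
    contig: str
    start: int  # 1-based on the contig
    length: int
    genomic_strand: str
    family: str
    sense_class: str
    function: str
    top_hit_id: str
    top_identity: float
    top_evalue: float
    sequence: str  # oriented to the sense of the viral hit

    def __post_init__(self) -> None:
        if self.length != len(self.sequence):
            raise ValueError(f"{self.name}: length != len(sequence)")


@dataclass
class ValidationVerdict:
    candidate_id: str
    best_hit_id: str
    best_hit_category: str
    decision: str  # keep | discard
    reason: str


@dataclass
class EveCluster:
    contig: str
    members: list[str]
    gaps: list[int]
    threshold: int


@dataclass
class RegionAssignment:
    nreve: str
    virus_id: str
    ref_start: Optional[int]  # 1-based on the reference genome
    ref_end: Optional[int]
    function: str
    evalue: Optional[float]
    mapped: bool


@dataclass
class CandidateLocus:
    """A merged forward-screen locus, before validation."""

    candidate_id: str
    contig: str
    start: int  # 0-based half-open
    end: int
    genomic_strand: str
    best_hsp: Hsp
    sequence: str = ""


# ---------------------------------------------------------------------------
# Naming
# ---------------------------------------------------------------------------

_BINOMIAL_RE = re.compile(r"^([A-Z][A-Za-z]+) ([a-z][a-z]+)$")


def species_abbreviation(host_species: str) -> str:
    m = _BINOMIAL_RE.match(host_species.strip())
    if not m:
        raise ValueError(f"host species must be a binomial 'Genus species', got {host_species!r}")
    genus, epithet = m.groups()
    return genus[0].upper() + epithet[:3]


def family_root(family: str) -> str:
    if family == "unclassified":
        return "Unc"
    if family.endswith("viridae"):
        return family[: -len("viridae")]
    return family


def name_nreve(host_species: str, family: str, ordinal: int) -> str:
    """Catalogue name: nrEVE_ + host abbreviation + family root + ordinal,
    e.g. ("Ceratitis capitata", "Rhabdoviridae", 1) -> nrEVE_CcapRhabdo_1."""
    if ordinal < 1:
        raise ValueError("ordinal must be >= 1")
    return f"nrEVE_{species_abbreviation(host_species)}{family_root(family)}_{ordinal}"


# ---------------------------------------------------------------------------
# Candidate extraction: merge HSPs into loci
# ---------------------------------------------------------------------------


def merge_hsps_to_loci(hsps: Sequence[Hsp], flank: int = 0) -> list[CandidateLocus]:
    """Merge HSPs into candidate loci.

    HSPs on the same (contig, genomic strand) hitting the same subject merge
    when their genomic intervals overlap or lie within MERGE_GAP_NT and are
    collinear on the subject; loci from different subjects that overlap
    genomically collapse to the best-scoring one, so one genomic region
    yields one candidate.
    """
    groups: dict[tuple, list[Hsp]] = {}
    for h in hsps:
        groups.setdefault((h.query_id, h.strand, h.subject_id), []).append(h)

    loci: list[CandidateLocus] = []
    for (contig, strand, _subject), members in groups.items():
        members.sort(key=lambda h: (h.query_start, h.query_end))
        chains: list[list[Hsp]] = []
        for h in members:
            merged = False
            if chains:
                prev = chains[-1]
                gap = h.query_start - max(x.query_end for x in prev)
                if gap <= MERGE_GAP_NT and _collinear(prev[-1], h, strand):
                    prev.append(h)
                    merged = True
            if not merged:
                chains.append([h])
        for chain in chains:
            best = min(chain, key=Hsp.sort_key)
            loci.append(
                CandidateLocus(
                    candidate_id="",
                    contig=contig,
                    start=min(x.query_start for x in chain) - flank,
                    end=max(x.query_end for x in chain) + flank,
                    genomic_strand=strand,
                    best_hsp=best,
                )
            )

    # collapse genomically overlapping loci (different subjects / strands)
    loci.sort(key=lambda l: (l.contig, l.start, l.end))
    collapsed: list[CandidateLocus] = []
    for locus in loci:
        if (
            collapsed
            and collapsed[-1].contig == locus.contig
            and locus.start < collapsed[-1].end
        ):
            if locus.best_hsp.sort_key() < collapsed[-1].best_hsp.sort_key():
                collapsed[-1] = locus
            continue
        collapsed.append(locus)
    for i, locus in enumerate(collapsed):
        locus.candidate_id = f"candidate_{i:03d}"
    return collapsed


def _collinear(a: Hsp, b: Hsp, strand: str) -> bool:
    if strand == "+":
        return b.subject_start >= a.subject_start
    return b.subject_start <= a.subject_start


# ---------------------------------------------------------------------------
# Discovery
# ---------------------------------------------------------------------------


def discover(
    contigs: Sequence[SequenceRecord],
    db: Sequence[ProteinDbEntry],
    host_species: str,
    forward_config: Optional[SearchConfig] = None,
    validation_config: Optional[SearchConfig] = None,
    flank: int = 0,
) -> tuple[list[NrEve], list[ValidationVerdict]]:
    """Run the full discovery procedure on one host genome.

    Returns the validated nrEVE records (named, classified) and one verdict
    per forward-screen candidate, so every candidate lands in exactly one of
    catalogue / discard list.
    """
    for e in db:
        if e.category not in DB_CATEGORIES:
            raise ValueError(f"db entry {e.id!r} has unknown category {e.category!r}")
    viral = [e for e in db if e.category == "viral"]
    if not viral:
        raise ValueError("database contains no viral entries")
    forward_config = forward_config or SearchConfig.translated(evalue_cutoff=FORWARD_EVALUE)
    validation_config = validation_config or SearchConfig.translated(
        evalue_cutoff=VALIDATION_EVALUE
    )
    by_id = {e.id: e for e in db}
    contig_by_id = {c.id: c for c in contigs}

    forward_hits = search_translated(contigs, viral, forward_config)
    loci = merge_hsps_to_loci(forward_hits, flank=flank)

    verdicts: list[ValidationVerdict] = []
    kept: list[tuple[CandidateLocus, Hsp]] = []
    for locus in loci:
        contig = contig_by_id[locus.contig]
        start = max(locus.start, 0)
        end = min(locus.end, len(contig.sequence))
        genomic = contig.sequence[start:end]
        locus.start, locus.end = start, end
        locus.sequence = genomic if locus.genomic_strand == "+" else reverse_complement(genomic)

        candidate = SequenceRecord(locus.candidate_id, "", locus.sequence)
        val_hits = search_translated([candidate], db, validation_config)
        if not val_hits:
            verdicts.append(
                ValidationVerdict(
                    locus.candidate_id, "", "", "discard", "no validation hit at cutoff"
                )
            )
            continue
        top = min(val_hits, key=Hsp.sort_key)
        category = by_id[top.subject_id].category
        if category == "viral":
            verdicts.append(
                ValidationVerdict(
                    locus.candidate_id,
                    top.subject_id,
                    category,
                    "keep",
                    f"top hit {top.subject_id} is viral (E={top.evalue:.2e})",
                )
            )
            kept.append((locus, top))
        else:
            verdicts.append(
                ValidationVerdict(
                    locus.candidate_id,
                    top.subject_id,
                    category,
                    "discard",
                    f"top hit {top.subject_id} is {category} (E={top.evalue:.2e})",
                )
            )

    eves = _build_records(kept, by_id, host_species)
    return eves, verdicts


def _build_records(
    kept: list[tuple[CandidateLocus, Hsp]],
    by_id: dict[str, ProteinDbEntry],
    host_species: str,
) -> list[NrEve]:
    # ordinals per (host, family) in (contig, start) order
    kept = sorted(kept, key=lambda pair: (pair[0].contig, pair[0].start))
    counters: dict[str, int] = {}
    eves = []
    for locus, top in kept:
        entry = by_id[top.subject_id]
        family = entry.family or "unclassified"
        counters[family] = counters.get(family, 0) + 1
        eves.append(
            NrEve(
                name=name_nreve(host_species, family, counters[family]),
                host_species=host_species,
                contig=locus.contig,
                start=locus.start + 1,
                length=locus.end - locus.start,
                genomic_strand=locus.genomic_strand,
                family=family,
                sense_class=entry.sense_class if family != "unclassified" else "unclassified",
                function=entry.function,
                top_hit_id=top.subject_id,
                top_identity=top.identity,
                top_evalue=top.evalue,
                sequence=locus.sequence,
            )
        )
    return eves


def catalogue_from_eves(eves: Sequence[NrEve]) -> EveCatalogue:
    """Shape discovered records into the Table-1 catalogue schema."""
    table = pd.DataFrame(
        {
            "name": [e.name for e in eves],
            "species": [e.host_species for e in eves],
            "accession": [e.contig for e in eves],
            "start": [e.start for e in eves],
            "length": [e.length for e in eves],
            "region": [e.function for e in eves],
            "family": [e.family for e in eves],
            "transcript_k": pd.array([None] * len(eves), dtype="Int64"),
            "transcript_n": pd.array([None] * len(eves), dtype="Int64"),
        }
    )
    return EveCatalogue(table)


# ---------------------------------------------------------------------------
# Proximity clustering
# ---------------------------------------------------------------------------


def cluster_by_distance(catalogue: EveCatalogue, threshold: int) -> list[EveCluster]:
    """Single-linkage clustering of catalogue intervals per contig; the gap
    between consecutive records is next.start - (prev.start + prev.length),
    floored at 0; clusters of size >= 2 are reported."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    clusters: list[EveCluster] = []
    df = catalogue.table.sort_values(["accession", "start", "length"], kind="stable")
    for contig, group in df.groupby("accession", sort=True):
        rows = group.to_dict("records")
        current = [rows[0]]
        gaps: list[int] = []
        for prev, nxt in zip(rows, rows[1:]):
            gap = max(nxt["start"] - (prev["start"] + prev["length"]), 0)
            if gap <= threshold:
                current.append(nxt)
                gaps.append(gap)
            else:
                if len(current) >= 2:
                    clusters.append(
                        EveCluster(contig, [r["name"] for r in current], gaps, threshold)
                    )
                current, gaps = [nxt], []
        if len(current) >= 2:
            clusters.append(EveCluster(contig, [r["name"] for r in current], gaps, threshold))
    return clusters


def clusters_to_table(clusters: Sequence[EveCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": [c.contig for c in clusters],
            "members": [",".join(c.members) for c in clusters],
            "gaps": [",".join(map(str, c.gaps)) for c in clusters],
            "threshold": [c.threshold for c in clusters],
        }
    )


# ---------------------------------------------------------------------------
# Functional-region assignment on a reference viral genome
# ---------------------------------------------------------------------------


def assign_function_region(
    eve: NrEve,
    reference: SequenceRecord,
    orf_table: OrfIntervalTable,
    evalue_cutoff: float = 1e-4,
    min_overlap: float = 0.30,
) -> RegionAssignment:
    """Map one nrEVE onto an annotated reference viral genome and label it
    with the ORF of maximal overlap.

    The nrEVE is aligned in protein space (its six-frame translation against
    the reference's six-frame translation); the best alignment's footprint
    on the reference is compared with the ORF intervals.  "Hypothetical"
    when no ORF covers >= ``min_overlap`` of the mapped interval or no
    alignment reaches ``evalue_cutoff``.
    """
    ref_frames = translate_six_frames(reference.sequence)
    subjects = [
        SequenceRecord(f"{reference.id}|frame{f:+d}", "", prot)
        for f, prot in ref_frames.items()
        if prot
    ]
    config = SearchConfig.translated(evalue_cutoff=evalue_cutoff)
    hits = search_translated([SequenceRecord(eve.name, "", eve.sequence)], subjects, config)
    if not hits:
        return RegionAssignment(eve.name, reference.id, None, None, "Hypothetical", None, False)
    top = min(hits, key=Hsp.sort_key)
    sub_frame = int(top.subject_id.rsplit("frame", 1)[1])
    ref_lo, ref_hi = _frame_to_contig(
        sub_frame, len(reference.sequence), top.subject_start, top.subject_end
    )
    function = "Hypothetical"
    best_overlap = 0
    span = ref_hi - ref_lo
    for orf in orf_table.orfs:
        o_lo, o_hi = orf.start - 1, orf.end  # to 0-based half-open
        overlap = min(ref_hi, o_hi) - max(ref_lo, o_lo)
        if overlap > best_overlap and overlap >= min_overlap * span:
            best_overlap = overlap
            function = orf.function
    return RegionAssignment(
        eve.name, reference.id, ref_lo + 1, ref_hi, function, top.evalue, True
    )


def assign_function_regions(
    eves: Sequence[NrEve],
    references: dict[str, tuple[SequenceRecord, OrfIntervalTable]],
    **kw,
) -> list[RegionAssignment]:
    """Per-family reference mapping; families without a configured
    reference yield an explicit unmapped result."""
    out = []
    for eve in eves:
        ref = references.get(eve.family)
        if ref is None:
            out.append(
                RegionAssignment(eve.name, "", None, None, "Hypothetical", None, False)
            )
        else:
            out.append(assign_function_region(eve, ref[0], ref[1], **kw))
    return out


def region_assignments_to_table(assignments: Sequence[RegionAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "nreve": [a.nreve for a in assignments],
            "virus": [a.virus_id for a in assignments],
            "ref_start": [a.ref_start for a in assignments],
            "ref_end": [a.ref_end for a in assignments],
            "function": [a.function for a in assignments],
            "evalue": [a.evalue for a in assignments],
            "mapped": [a.mapped for a in assignments],
        }
    )
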