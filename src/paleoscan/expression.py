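"""Transcription of nrEVEs from RNA-seq libraries.

Detection is by direct read mapping: a read is assigned to an nrEVE (or the
housekeeping gene) when an ungapped end-to-end alignment with at most the
configured number of mismatches exists on either strand.  An nrEVE counts
as detected in a dataset when covered over at least the breadth threshold
(default half its length at depth >= 1); detection frequency across
datasets is reported as "k/n" as in the published catalogue.  Relative
abundance is the length-normalized read-count ratio to the housekeeping
gene (ribosomal protein L23a by default).  ORFs are maximal stop-free
translated segments, with no start-codon requirement, because endogenized
fragments are internal pieces of viral ORFs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .formats_io import FastqRead, SequenceRecord
from .homology_search import reverse_complement, translate_frame


@dataclass
class ExpressionConfig:
    min_breadth: float = 0.50  # fraction of nrEVE length covered
    min_depth: int = 1
    max_mismatches: int = 2
    housekeeping_id: str = "L23a"
    min_orf_aa: int = 100
    #: require an ATG at the ORF 5' end instead of stop-to-stop segments
    require_start_codon: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.min_breadth <= 1.0:
            raise ValueError("min_breadth must lie in (0, 1]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass
class TranscriptionProfile:
    nreve: str
    dataset: str
    mapped_reads: float
    breadth: float
    detected: bool
    relative_abundance: Optional[float]  # None when housekeeping count is 0


@dataclass
class OrfAnnotation:
    nreve: str
    frame: int
    strand: str
    aa_length: int
    aa_sequence: str
    nt_start: int  # 0-based half-open on the nrEVE forward strand
    nt_end: int


@dataclass
class MappingResult:
    """Per-target fractional read counts and per-base depth."""

    counts: dict[str, float]
    coverage: dict[str, np.ndarray]
    mapped: float
    unmapped: float
    total: int


# ---------------------------------------------------------------------------
# Read mapping
# ---------------------------------------------------------------------------


def _candidate_alignments(seq: str, target: str, max_mm: int) -> list[tuple[int, int]]:
    """(start, mismatches) of every end-to-end ungapped alignment of
    ``seq`` inside ``target`` with <= max_mm mismatches.

    Pigeonhole seeding: split the read into max_mm + 1 segments; any
    qualifying alignment contains at least one exact segment.
    """
    L = len(seq)
    if L > len(target):
        return []
    n_seg = max_mm + 1
    seg_len = L // n_seg
    if seg_len == 0:
        return []
    starts_checked: set[int] = set()
    out = []
    tarr = np.frombuffer(target.encode("ascii"), dtype=np.uint8)
    rarr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    for i in range(n_seg):
        off = i * seg_len
        seg = seq[off : off + seg_len]
        pos = target.find(seg)
        while pos != -1:
            start = pos - off
            if 0 <= start <= len(target) - L and start not in starts_checked:
                starts_checked.add(start)
                mm = int(np.count_nonzero(tarr[start : start + L] != rarr))
                if mm <= max_mm:
                    out.append((start, mm))
            pos = target.find(seg, pos + 1)
    return out


def map_reads(
    reads: Sequence[FastqRead],
    targets: Sequence[SequenceRecord],
    config: Optional[ExpressionConfig] = None,
) -> MappingResult:
    """Assign reads to targets (either strand); multi-target reads go to
    the target with fewest mismatches, ties split evenly as fractional
    counts.  Depth vectors accumulate the same fractions."""
    if not targets:
        raise ValueError("targets must be non-empty")
    config = config or ExpressionConfig()
    counts = {t.id: 0.0 for t in targets}
    coverage = {t.id: np.zeros(len(t.sequence)) for t in targets}
    mapped = 0.0
    for read in reads:
        best_mm = config.max_mismatches + 1
        # best alignment per target, over both strands
        per_target: dict[str, tuple[int, int]] = {}
        for t in targets:
            cands = []
            for seq in (read.sequence, reverse_complement(read.sequence)):
                cands.extend(_candidate_alignments(seq, t.sequence, config.max_mismatches))
            if cands:
                per_target[t.id] = min(cands, key=lambda c: c[1])
        if not per_target:
            continue
        best_mm = min(mm for _, mm in per_target.values())
        winners = [(tid, s) for tid, (s, mm) in per_target.items() if mm == best_mm]
        share = 1.0 / len(winners)
        for tid, start in winners:
            counts[tid] += share
            coverage[tid][start : start + len(read.sequence)] += share
        mapped += 1.0
    return MappingResult(
        counts=counts,
        coverage=coverage,
        mapped=mapped,
        unmapped=len(reads) - mapped,
        total=len(reads),
    )


# ---------------------------------------------------------------------------
# Transcription detection
# ---------------------------------------------------------------------------


def profile_dataset(
    reads: Sequence[FastqRead],
    eves: Sequence[SequenceRecord],
    housekeeping: SequenceRecord,
    dataset: str,
    config: Optional[ExpressionConfig] = None,
) -> list[TranscriptionProfile]:
    """Map one RNA-seq dataset against the nrEVEs plus the housekeeping
    gene and compute per-nrEVE detection and relative abundance."""
    config = config or ExpressionConfig()
    result = map_reads(reads, list(eves) + [housekeeping], config)
    hk_count = result.counts[housekeeping.id]
    hk_rate = hk_count / len(housekeeping.sequence) if hk_count > 0 else None
    profiles = []
    for eve in eves:
        depth = result.coverage[eve.id]
        breadth = float(np.mean(depth >= config.min_depth))
        count = result.counts[eve.id]
        rel = (count / len(eve.sequence)) / hk_rate if hk_rate else None
        profiles.append(
            TranscriptionProfile(
                nreve=eve.id,
                dataset=dataset,
                mapped_reads=count,
                breadth=breadth,
                detected=breadth >= config.min_breadth,
                relative_abundance=rel,
            )
        )
    return profiles


def detect_transcription(
    profiles: Iterable[TranscriptionProfile],
) -> pd.DataFrame:
    """Detection frequency per nrEVE across datasets.

    Returns a table (nreve, detected_in, datasets, fraction,
    actively_transcribed); an nrEVE is actively transcribed iff detected in
    at least one dataset.
    """
    rows: dict[str, list[TranscriptionProfile]] = {}
    for p in profiles:
        rows.setdefault(p.nreve, []).append(p)
    if not rows:
        raise ValueError("no profiles supplied")
    out = []
    for nreve, plist in rows.items():
        k = sum(1 for p in plist if p.detected)
        n = len(plist)
        out.append(
            {
                "nreve": nreve,
                "detected_in": k,
                "datasets": n,
                "fraction": f"{k}/{n}",
                "actively_transcribed": k >= 1,
            }
        )
    return pd.DataFrame(out)


def profiles_to_table(profiles: Iterable[TranscriptionProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "nreve": [p.nreve for p in profiles],
            "dataset": [p.dataset for p in profiles],
            "reads": [p.mapped_reads for p in profiles],
            "breadth": [p.breadth for p in profiles],
            "detected": [p.detected for p in profiles],
            "rel_abundance": [p.relative_abundance for p in profiles],
        }
    )


# ---------------------------------------------------------------------------
# ORF finding
# ---------------------------------------------------------------------------


def find_orfs(
    sequence: str,
    min_aa: int = 100,
    name: str = "",
    require_start_codon: bool = False,
) -> list[OrfAnnotation]:
    """Maximal stop-free translated segments >= ``min_aa`` in all six
    frames, longest first.  Segment boundaries are stop-to-stop (or the
    sequence edge); with ``require_start_codon`` each segment is trimmed to
    its first methionine."""
    L = len(sequence)
    out: list[OrfAnnotation] = []
    for frame in (1, 2, 3, -1, -2, -3):
        prot = translate_frame(sequence, frame)
        off = abs(frame) - 1
        pos = 0
        for segment in prot.split("*"):
            seg_start = pos
            pos += len(segment) + 1
            if require_start_codon:
                m = segment.find("M")
                if m == -1:
                    continue
                seg_start += m
                segment = segment[m:]
            if len(segment) < min_aa:
                continue
            aa_lo, aa_hi = seg_start, seg_start + len(segment)
            lo = off + 3 * aa_lo
            hi = off + 3 * aa_hi
            if frame > 0:
                nt_start, nt_end = lo, hi
            else:
                nt_start, nt_end = L - hi, L - lo
            out.append(
                OrfAnnotation(
                    nreve=name,
                    frame=frame,
                    strand="+" if frame > 0 else "-",
                    aa_length=len(segment),
                    aa_sequence=segment,
                    nt_start=nt_start,
                    nt_end=nt_end,
                )
            )
    out.sort(key=lambda o: (-o.aa_length, o.frame, o.nt_start))
    return out


def orfs_to_table(orfs: Iterable[OrfAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "nreve": [o.nreve for o in orfs],
            "frame": [o.frame for o in orfs],
            "strand": [o.strand for o in orfs],
            "aa_length": [o.aa_length for o in orfs],
            "nt_start": [o.nt_start + 1 for o in orfs],
            "nt_end": [o.nt_end for o in orfs],
            "aa_sequence": [o.aa_sequence for o in orfs],
        }
    )
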