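"""Translated (blastx-like) and nucleotide (blastn-like) local similarity
search.

The translated search is the pipeline's screening engine: host contigs are
translated in all six frames and scanned against a protein database with
exact k-mer seeding, ungapped x-drop extension and gapped refinement; hit
significance uses Karlin-Altschul statistics, E = K * m' * n' * exp(-lambda*S),
with a length-adjusted effective search space.  For problems small enough
that heuristics buy nothing (a few kb of query against a few hundred
residues) the search runs exact local alignment over every frame/subject
pair, so reported scores equal the full Smith-Waterman optimum there.

The nucleotide search reports, per (query, subject) pair, query cover (the
union of query positions in retained alignments over the query length) and
the identity of the best alignment, the two quantities used to relate nrEVEs
to circulating viral genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .formats_io import ProteinDbEntry, SequenceRecord

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_PROT_ALPHABET = str(_BLOSUM62.alphabet)  # 'ARNDCQEGHILKMFPSTWYVBZX*'
_SENTINEL = len(_PROT_ALPHABET)  # padding code; never matches anything

_PROT_CODE = np.full(128, _SENTINEL, dtype=np.int8)
for _i, _c in enumerate(_PROT_ALPHABET):
    _PROT_CODE[ord(_c)] = _i

# substitution matrix with an extra sentinel row/column at -10000 so that
# extensions crossing a sequence boundary collapse immediately
_SUBMAT = np.full((_SENTINEL + 1, _SENTINEL + 1), -10000, dtype=np.int32)
_SUBMAT[:_SENTINEL, :_SENTINEL] = np.asarray(_BLOSUM62, dtype=np.int32)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FRAMES = (1, 2, 3, -1, -2, -3)


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def translate_frame(dna: str, frame: int) -> str:
    """Translate one frame (+1..+3 forward, -1..-3 on the reverse
    complement) with the standard genetic code; codons containing N give X,
    stop codons are rendered '*' and retained."""
    if frame < 0:
        dna = reverse_complement(dna)
    off = abs(frame) - 1
    usable = (len(dna) - off) // 3 * 3
    if usable <= 0:
        return ""
    segment = dna[off : off + usable]
    prot = str(Seq(segment).translate())
    if "N" in segment:
        # any codon containing N is undetermined, even when the ambiguity
        # would resolve to a single residue
        arr = np.frombuffer(segment.encode("ascii"), dtype=np.uint8).reshape(-1, 3)
        undetermined = (arr == ord("N")).any(axis=1)
        if undetermined.any():
            chars = np.frombuffer(prot.encode("ascii"), dtype=np.uint8).copy()
            chars[undetermined] = ord("X")
            prot = chars.tobytes().decode("ascii")
    return prot


def translate_six_frames(dna: str) -> dict[int, str]:
    """All six frame translations, keyed by frame label."""
    return {f: translate_frame(dna, f) for f in FRAMES}


# ---------------------------------------------------------------------------
# Configuration and statistics
# ---------------------------------------------------------------------------


@dataclass
class SearchConfig:
    """Scoring and statistics parameters for a search.

    Karlin-Altschul lambda/K/H default to the gapped BLOSUM62 11/1 values
    for translated mode and to the +2/-3, 5/2 values for nucleotide mode.
    """

    mode: str = "translated"  # translated | nucleotide
    matrix: str = "BLOSUM62"
    match: int = 2
    mismatch: int = -3
    gap_open: int = 11
    gap_extend: int = 1
    word_size: int = 3
    xdrop_bits: float = 20.0
    evalue_cutoff: float = 1e-6
    la_lambda: float = 0.267
    la_k: float = 0.041
    la_h: float = 0.14
    #: ungapped score gate (as an E-value) deciding which seeds reach the
    #: gapped stage; generous so that borderline hits are never lost
    gate_evalue: float = 10.0
    max_extension: int = 200
    #: below this many DP cells (total translated query x db residues) the
    #: search is exact over every frame/subject pair
    exact_cell_limit: int = 40_000_000

    def __post_init__(self) -> None:
        if self.word_size < 2:
            raise ValueError("word size must be >= 2")
        if self.evalue_cutoff <= 0 or self.la_lambda <= 0 or self.la_k <= 0:
            raise ValueError("cutoff, lambda and K must be positive")

    @classmethod
    def translated(cls, **kw) -> "SearchConfig":
        return cls(mode="translated", **kw)

    @classmethod
    def nucleotide(cls, **kw) -> "SearchConfig":
        defaults = dict(
            mode="nucleotide",
            gap_open=5,
            gap_extend=2,
            word_size=11,
            la_lambda=0.625,
            la_k=0.41,
            la_h=0.78,
            evalue_cutoff=1e-4,
        )
        defaults.update(kw)
        return cls(**defaults)

    @property
    def xdrop_raw(self) -> float:
        return self.xdrop_bits * math.log(2.0) / self.la_lambda


@dataclass
class NtSearchConfig:
    """Retention thresholds for nucleotide similarity pairs."""

    min_query_cover: float = 0.50
    min_identity: float = 0.50

    def __post_init__(self) -> None:
        for v in (self.min_query_cover, self.min_identity):
            if not 0.0 <= v <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")


@dataclass
class Hsp:
    """One local alignment between a query and a database subject.

    Query coordinates are 0-based half-open nucleotides on the query contig;
    subject coordinates are 0-based half-open (residues for translated mode,
    nucleotides otherwise).
    """

    query_id: str
    subject_id: str
    frame: int  # +-1..3 translated; +1/-1 = strand for nucleotide
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    raw_score: float
    bit_score: float
    evalue: float
    identity: float
    length: int  # aligned columns
    n_identities: int = 0
    n_mismatches: int = 0
    n_gap_opens: int = 0

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"

    def sort_key(self):
        return (self.evalue, -self.bit_score, self.subject_id)


def evalue(raw_score: float, m_eff: float, n_eff: float, lam: float, k: float) -> float:
    """Karlin-Altschul expectation E = K * m' * n' * exp(-lambda * S)."""
    if m_eff <= 0 or n_eff <= 0:
        raise ValueError("effective search space must be positive")
    return k * m_eff * n_eff * math.exp(-lam * raw_score)


def bit_score(raw_score: float, lam: float, k: float) -> float:
    return (lam * raw_score - math.log(k)) / math.log(2.0)


def effective_lengths(
    m: int, n: int, n_subjects: int, lam: float, k: float, h: float
) -> tuple[float, float]:
    """Expected-HSP-length adjustment: l = ln(K m n)/H subtracted from the
    query and once per subject from the database, floored at 1."""
    if m <= 0 or n <= 0:
        return 1.0, 1.0
    ell = math.log(max(k * m * n, math.e)) / h
    return max(m - ell, 1.0), max(n - n_subjects * ell, 1.0)


# ---------------------------------------------------------------------------
# Seeding and ungapped extension (vectorized)
# ---------------------------------------------------------------------------


def _encode_protein(seq: str) -> np.ndarray:
    return _PROT_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].astype(np.int32)


def _kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling base-32 hash of every k-window; windows touching a sentinel
    get -1 (never matched)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    h = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        win = codes[j : j + n]
        h = (h << 5) | win.astype(np.int64)
        bad |= win >= _SENTINEL
    h[bad] = -1
    return h


def _join_seeds(qh: np.ndarray, sh: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All (query position, subject position) pairs with equal k-mer hash."""
    order = np.argsort(sh, kind="stable")
    sh_sorted = sh[order]
    valid = qh >= 0
    qpos_all = np.nonzero(valid)[0]
    qh_v = qh[valid]
    left = np.searchsorted(sh_sorted, qh_v, side="left")
    right = np.searchsorted(sh_sorted, qh_v, side="right")
    counts = right - left
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    qpos = np.repeat(qpos_all, counts)
    offsets = np.concatenate(([0], np.cumsum(counts)))[:-1]
    flat = np.arange(total, dtype=np.int64) - np.repeat(offsets, counts) + np.repeat(left, counts)
    spos = order[flat]
    return qpos, spos


def _extend_batch(
    qcodes: np.ndarray,
    scodes: np.ndarray,
    qi: np.ndarray,
    si: np.ndarray,
    direction: int,
    xdrop_raw: float,
    max_ext: int,
) -> np.ndarray:
    """Best ungapped extension score from each (qi, si) anchor moving in
    ``direction`` (excluding the anchor itself), with x-drop termination.
    Sentinel padding in the code arrays stops extensions at boundaries."""
    n = len(qi)
    best = np.zeros(n, dtype=np.float64)
    run = np.zeros(n, dtype=np.float64)
    idx = np.arange(n)
    for t in range(1, max_ext + 1):
        if len(idx) == 0:
            break
        step = _SUBMAT[qcodes[qi[idx] + direction * t], scodes[si[idx] + direction * t]]
        run[idx] += step
        better = run[idx] > best[idx]
        best[idx[better]] = run[idx[better]]
        keep = run[idx] > best[idx] - xdrop_raw
        idx = idx[keep]
    return best


# ---------------------------------------------------------------------------
# Gapped refinement
# ---------------------------------------------------------------------------


def _protein_aligner(config: SearchConfig) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(config.matrix)
    aligner.open_gap_score = -(config.gap_open + config.gap_extend)
    aligner.extend_gap_score = -config.gap_extend
    return aligner


def _nucleotide_aligner(config: SearchConfig) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = config.match
    aligner.mismatch_score = config.mismatch
    aligner.open_gap_score = -(config.gap_open + config.gap_extend)
    aligner.extend_gap_score = -config.gap_extend
    return aligner


def _alignment_stats(alignment) -> tuple[int, int, int, int, int, int, int, int]:
    """(qstart, qend, sstart, send, columns, identities, mismatches,
    gap opens) of one Bio.Align alignment (local mode)."""
    blocks_q, blocks_s = alignment.aligned
    qs, qe = int(blocks_q[0][0]), int(blocks_q[-1][1])
    ss, se = int(blocks_s[0][0]), int(blocks_s[-1][1])
    counts = alignment.counts()
    identities = int(counts.identities)
    mismatches = int(counts.mismatches)
    gap_opens = max(len(blocks_q) - 1, 0) + 0
    # columns include gap columns
    columns = int(alignment.length)
    return qs, qe, ss, se, columns, identities, mismatches, gap_opens


def _frame_to_contig(frame: int, contig_len: int, aa_start: int, aa_end: int) -> tuple[int, int]:
    """Map an aa interval on a frame translation to 0-based half-open
    nucleotide coordinates on the forward strand of the contig."""
    off = abs(frame) - 1
    lo = off + 3 * aa_start
    hi = off + 3 * aa_end
    if frame > 0:
        return lo, hi
    return contig_len - hi, contig_len - lo


# ---------------------------------------------------------------------------
# Translated search
# ---------------------------------------------------------------------------


def search_translated(
    contigs: Sequence[SequenceRecord],
    db: Sequence[ProteinDbEntry] | Sequence[SequenceRecord],
    config: Optional[SearchConfig] = None,
) -> list[Hsp]:
    """Six-frame translated search of ``contigs`` against a protein
    database.  Returns E-value-filtered HSPs, best first."""
    config = config or SearchConfig.translated()
    if not db:
        raise ValueError("protein database is empty")
    aligner = _protein_aligner(config)

    subjects = [(e.id, e.sequence) for e in db]
    n_total = sum(len(s) for _, s in subjects)
    hsps: list[Hsp] = []
    for contig in contigs:
        frames = translate_six_frames(contig.sequence)
        frames = {f: p for f, p in frames.items() if len(p) >= config.word_size}
        if not frames:
            continue
        m_total = sum(len(p) for p in frames.values())
        m_eff, n_eff = effective_lengths(
            m_total, n_total, len(subjects), config.la_lambda, config.la_k, config.la_h
        )
        if m_total * n_total <= config.exact_cell_limit:
            contig_hsps = _search_contig_exact(
                contig, frames, subjects, aligner, config, m_eff, n_eff
            )
        else:
            contig_hsps = _search_contig_seeded(
                contig, frames, subjects, aligner, config, m_eff, n_eff
            )
        hsps.extend(contig_hsps)
    hsps.sort(key=Hsp.sort_key)
    return hsps


def _make_hsp(
    contig: SequenceRecord,
    subject_id: str,
    frame: int,
    qwin_offset: int,
    alignment,
    config: SearchConfig,
    m_eff: float,
    n_eff: float,
) -> Optional[Hsp]:
    score = float(alignment.score)
    if score <= 0:
        return None
    e = evalue(score, m_eff, n_eff, config.la_lambda, config.la_k)
    if e > config.evalue_cutoff:
        return None
    qs, qe, ss, se, columns, ident, mism, gapo = _alignment_stats(alignment)
    aa_start, aa_end = qwin_offset + qs, qwin_offset + qe
    nt_start, nt_end = _frame_to_contig(frame, len(contig.sequence), aa_start, aa_end)
    return Hsp(
        query_id=contig.id,
        subject_id=subject_id,
        frame=frame,
        query_start=nt_start,
        query_end=nt_end,
        subject_start=ss,
        subject_end=se,
        raw_score=score,
        bit_score=bit_score(score, config.la_lambda, config.la_k),
        evalue=e,
        identity=ident / columns if columns else 0.0,
        length=columns,
        n_identities=ident,
        n_mismatches=mism,
        n_gap_opens=gapo,
    )


def _search_contig_exact(contig, frames, subjects, aligner, config, m_eff, n_eff):
    out = []
    for frame, prot in frames.items():
        for sid, sseq in subjects:
            try:
                alignments = aligner.align(prot, sseq)
                if len(alignments) == 0:
                    continue
                alignment = alignments[0]
            except (ValueError, OverflowError):
                continue
            hsp = _make_hsp(contig, sid, frame, 0, alignment, config, m_eff, n_eff)
            if hsp:
                out.append(hsp)
    return out


def _search_contig_seeded(contig, frames, subjects, aligner, config, m_eff, n_eff):
    k = config.word_size
    pad = config.max_extension + k + 2
    sentinel_pad = np.full(pad, _SENTINEL, dtype=np.int32)

    # concatenated query frames with sentinel padding between and around
    frame_list = list(frames.items())
    q_parts = [sentinel_pad]
    q_offsets = []  # (frame, global offset of local position 0, length)
    cursor = pad
    for frame, prot in frame_list:
        q_offsets.append((frame, cursor, len(prot)))
        q_parts.append(_encode_protein(prot))
        q_parts.append(sentinel_pad)
        cursor += len(prot) + pad
    qcodes = np.concatenate(q_parts)

    s_parts = [sentinel_pad]
    s_offsets = []
    cursor = pad
    for sid, sseq in subjects:
        s_offsets.append((sid, cursor, len(sseq)))
        s_parts.append(_encode_protein(sseq))
        s_parts.append(sentinel_pad)
        cursor += len(sseq) + pad
    scodes = np.concatenate(s_parts)

    qpos, spos = _join_seeds(_kmer_hashes(qcodes, k), _kmer_hashes(scodes, k))
    if len(qpos) == 0:
        return []

    # ungapped x-drop extension around every seed
    seed_score = np.zeros(len(qpos), dtype=np.float64)
    for j in range(k):
        seed_score += _SUBMAT[qcodes[qpos + j], scodes[spos + j]]
    right = _extend_batch(
        qcodes, scodes, qpos + k - 1, spos + k - 1, +1, config.xdrop_raw, config.max_extension
    )
    left = _extend_batch(qcodes, scodes, qpos, spos, -1, config.xdrop_raw, config.max_extension)
    total = seed_score + right + left

    gate = (
        math.log(config.la_k * m_eff * n_eff) - math.log(config.gate_evalue)
    ) / config.la_lambda
    keep = total >= gate
    if not keep.any():
        return []
    qpos, spos = qpos[keep], spos[keep]

    # map survivors back to (frame, subject) and merge nearby anchors into
    # gapped-refinement windows
    q_starts = np.array([o for _, o, _ in q_offsets])
    s_starts = np.array([o for _, o, _ in s_offsets])
    qidx = np.searchsorted(q_starts, qpos, side="right") - 1
    sidx = np.searchsorted(s_starts, spos, side="right") - 1

    windows: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for qp, sp, qi, si in zip(qpos, spos, qidx, sidx):
        local_q = int(qp - q_offsets[qi][1])
        local_s = int(sp - s_offsets[si][1])
        windows.setdefault((int(qi), int(si)), []).append((local_q, local_s))

    out = []
    seen: set[tuple] = set()
    merge_gap = 40  # aa between anchors merged into one refinement window
    for (qi, si), anchors in windows.items():
        frame, _, flen = q_offsets[qi]
        sid, _, slen = s_offsets[si]
        prot = frames[frame]
        sseq = subjects[si][1]
        anchors.sort()
        groups: list[list[int]] = []
        for a, _ in anchors:
            if groups and a - groups[-1][-1] <= merge_gap:
                groups[-1].append(a)
            else:
                groups.append([a])
        pad_aa = slen + 60
        for grp in groups:
            lo = max(grp[0] - pad_aa, 0)
            hi = min(grp[-1] + k + pad_aa, flen)
            key = (qi, si, lo, hi)
            if key in seen:
                continue
            seen.add(key)
            alignments = aligner.align(prot[lo:hi], sseq)
            if len(alignments) == 0:
                continue
            hsp = _make_hsp(contig, sid, frame, lo, alignments[0], config, m_eff, n_eff)
            if hsp:
                out.append(hsp)
    # identical alignments may be reached from several windows
    unique = {}
    for h in out:
        key = (h.subject_id, h.frame, h.query_start, h.query_end, h.subject_start, h.subject_end)
        if key not in unique or h.raw_score > unique[key].raw_score:
            unique[key] = h
    return list(unique.values())


# ---------------------------------------------------------------------------
# Nucleotide search
# ---------------------------------------------------------------------------


@dataclass
class NtPair:
    """Per (query, subject) summary of a nucleotide search."""

    query_id: str
    subject_id: str
    query_cover: float
    best_identity: float
    best_evalue: float
    retained: bool
    hsps: list[Hsp] = field(default_factory=list)


def _has_seed(query: str, subject: str, k: int) -> bool:
    if len(query) < k or len(subject) < k:
        return False
    qmers = {query[i : i + k] for i in range(len(query) - k + 1)}
    return any(subject[i : i + k] in qmers for i in range(len(subject) - k + 1))


def search_nucleotide(
    queries: Sequence[SequenceRecord],
    subjects: Sequence[SequenceRecord],
    config: Optional[SearchConfig] = None,
    nt_config: Optional[NtSearchConfig] = None,
) -> tuple[list[Hsp], list[NtPair]]:
    """Nucleotide search on both strands with per-pair query cover.

    A pair is retained iff query cover >= min_query_cover and the identity
    of its best HSP >= min_identity.
    """
    if not queries or not subjects:
        raise ValueError("queries and subjects must be non-empty")
    config = config or SearchConfig.nucleotide()
    nt_config = nt_config or NtSearchConfig()
    aligner = _nucleotide_aligner(config)

    n_total = sum(len(s.sequence) for s in subjects)
    hsps_all: list[Hsp] = []
    pairs: list[NtPair] = []
    for q in queries:
        m = len(q.sequence)
        m_eff, n_eff = effective_lengths(
            m, n_total, len(subjects), config.la_lambda, config.la_k, config.la_h
        )
        for s in subjects:
            pair_hsps: list[Hsp] = []
            for strand, qseq in ((1, q.sequence), (-1, reverse_complement(q.sequence))):
                if not _has_seed(qseq, s.sequence, config.word_size):
                    continue
                pair_hsps.extend(
                    _greedy_nt_hsps(
                        q, s, qseq, strand, aligner, config, m_eff, n_eff
                    )
                )
            if not pair_hsps:
                continue
            covered = np.zeros(m, dtype=bool)
            for h in pair_hsps:
                covered[h.query_start : h.query_end] = True
            cover = float(covered.mean())
            best = min(pair_hsps, key=Hsp.sort_key)
            retained = cover >= nt_config.min_query_cover and best.identity >= nt_config.min_identity
            pair_hsps.sort(key=Hsp.sort_key)
            pairs.append(
                NtPair(
                    query_id=q.id,
                    subject_id=s.id,
                    query_cover=cover,
                    best_identity=best.identity,
                    best_evalue=best.evalue,
                    retained=retained,
                    hsps=pair_hsps,
                )
            )
            hsps_all.extend(pair_hsps)
    hsps_all.sort(key=Hsp.sort_key)
    return hsps_all, pairs


def _greedy_nt_hsps(q, s, qseq, strand, aligner, config, m_eff, n_eff, max_rounds=10):
    """Repeated best local alignment with masking of the already-aligned
    query interval, yielding up to ``max_rounds`` non-overlapping HSPs."""
    out = []
    work = qseq
    qlen = len(qseq)
    for _ in range(max_rounds):
        alignments = aligner.align(work, s.sequence)
        if len(alignments) == 0:
            break
        alignment = alignments[0]
        score = float(alignment.score)
        if score <= 0:
            break
        e = evalue(score, m_eff, n_eff, config.la_lambda, config.la_k)
        if e > config.evalue_cutoff:
            break
        qs, qe, ss, se, columns, ident, mism, gapo = _alignment_stats(alignment)
        if strand > 0:
            nt_start, nt_end = qs, qe
        else:
            nt_start, nt_end = qlen - qe, qlen - qs
        out.append(
            Hsp(
                query_id=q.id,
                subject_id=s.id,
                frame=strand,
                query_start=nt_start,
                query_end=nt_end,
                subject_start=ss,
                subject_end=se,
                raw_score=score,
                bit_score=bit_score(score, config.la_lambda, config.la_k),
                evalue=e,
                identity=ident / columns if columns else 0.0,
                length=columns,
                n_identities=ident,
                n_mismatches=mism,
                n_gap_opens=gapo,
            )
        )
        work = work[:qs] + "N" * (qe - qs) + work[qe:]
    return out


# ---------------------------------------------------------------------------
# Tabular output (blast outfmt-6 shape)
# ---------------------------------------------------------------------------

OUTFMT6_COLUMNS = [
    "query",
    "subject",
    "pident",
    "length",
    "mismatches",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def hsps_to_table(hsps: Iterable[Hsp]) -> pd.DataFrame:
    """HSPs as a blast outfmt-6-shaped table (1-based inclusive
    coordinates)."""
    rows = []
    for h in hsps:
        rows.append(
            {
                "query": h.query_id,
                "subject": h.subject_id,
                "pident": round(100.0 * h.identity, 2),
                "length": h.length,
                "mismatches": h.n_mismatches,
                "gapopen": h.n_gap_opens,
                "qstart": h.query_start + 1,
                "qend": h.query_end,
                "sstart": h.subject_start + 1,
                "send": h.subject_end,
                "evalue": h.evalue,
                "bitscore": round(h.bit_score, 1),
            }
        )
    return pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)
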