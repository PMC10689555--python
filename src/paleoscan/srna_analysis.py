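"""Small-RNA processing and piRNA-signature analysis of nrEVE loci.

Libraries are cleaned (adapter trim, empty / low-quality / low-complexity
removal, 18-32 nt length window, collapse to unique sequences), mapped
end-to-end against nrEVE sequences, and profiled per locus: length
histogram, 5' nucleotide composition (reported in RNA space, so T counts as
U), and strand split, all on unique reads.  A locus is called piRNA-like
when the mapped population shows the three hallmarks together: a 25-30 nt
length majority, a 5'-uridine majority, and near-single-strand origin.
Positional hotspots and seed-aware complementarity of the piRNAs to a viral
genome (mismatches inside positions 2-8 or 14-22 abolish targeting) are
computed from the same assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .formats_io import FastqRead, SequenceRecord
from .homology_search import reverse_complement


@dataclass
class SrnaConfig:
    min_len: int = 18
    max_len: int = 32
    low_quality_phred: int = 20
    max_low_quality_fraction: float = 0.20
    max_mono_fraction: float = 0.8
    mismatches: int = 0
    pi_length_range: tuple[int, int] = (25, 30)
    min_pi_length_fraction: float = 0.5
    min_first_u_fraction: float = 0.5
    min_dominant_strand_fraction: float = 0.9
    hotspot_sd: float = 3.0
    min_hotspot_reads: int = 10
    seed_windows: tuple[tuple[int, int], ...] = ((2, 8), (14, 22))
    min_adapter_overlap: int = 8

    def __post_init__(self) -> None:
        if self.min_len > self.max_len or self.min_len < 1:
            raise ValueError("invalid length window")
        for v in (
            self.max_low_quality_fraction,
            self.max_mono_fraction,
            self.min_pi_length_fraction,
            self.min_first_u_fraction,
            self.min_dominant_strand_fraction,
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class SrnaProfile:
    """Per (nrEVE, library) small-RNA statistics on unique reads."""

    nreve: str
    library: str
    unique_mapped: int
    pct_of_library: float
    length_histogram: dict[int, int]
    first_nucleotide: dict[str, int]  # RNA space: U/A/C/G
    plus_count: int
    minus_count: int
    pirna_like: bool
    verdicts: dict[str, bool]
    detail: pd.DataFrame = field(repr=False, default=None)


@dataclass
class SeedMatch:
    pirna: str
    target_id: str
    target_position: int  # 0-based start on the virus forward strand
    target_strand: str
    identities: int
    alignment_length: int
    mismatch_positions: list[int]  # 1-based from the piRNA 5' end
    seed_clean: bool


@dataclass
class HotspotResult:
    nreve: str
    positions: list[int]  # 0-based 5'-end positions exceeding the threshold
    threshold: Optional[float]
    insufficient_data: bool


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------


def _trim_adapter(seq: str, adapter: str, min_overlap: int) -> str:
    """Remove the adapter by exact match: a full internal occurrence, or a
    read 3' suffix equal to an adapter prefix with >= min_overlap nt."""
    idx = seq.find(adapter)
    if idx != -1:
        return seq[:idx]
    max_ov = min(len(adapter), len(seq))
    for ov in range(max_ov, min_overlap - 1, -1):
        if seq.endswith(adapter[:ov]):
            return seq[: len(seq) - ov]
    return seq


def clean_reads(
    reads: Sequence[FastqRead],
    config: Optional[SrnaConfig] = None,
    adapter: Optional[str] = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Clean one library and collapse to unique sequences.

    Stage order: adapter trim -> drop empty -> drop low-quality (more than
    20% of bases below Phred 20) -> drop low-complexity (mononucleotide
    fraction above threshold) -> keep lengths inside the inclusive
    [min_len, max_len] window -> merge identical sequences with summed
    counts.  Returns (unique table with columns sequence/count, attrition
    report); input count always equals kept + per-stage drops.
    """
    config = config or SrnaConfig()
    report = {
        "input": len(reads),
        "adapter_trimmed": 0,
        "dropped_empty": 0,
        "dropped_low_quality": 0,
        "dropped_low_complexity": 0,
        "dropped_length": 0,
        "kept": 0,
    }
    counts: dict[str, int] = {}
    for read in reads:
        seq = read.sequence
        if adapter:
            trimmed = _trim_adapter(seq, adapter, config.min_adapter_overlap)
            if len(trimmed) != len(seq):
                report["adapter_trimmed"] += 1
            seq = trimmed
        quals = read.qualities[: len(seq)]
        if not seq:
            report["dropped_empty"] += 1
            continue
        low = sum(1 for q in quals if q < config.low_quality_phred)
        if low / len(seq) > config.max_low_quality_fraction:
            report["dropped_low_quality"] += 1
            continue
        mono = max(seq.count(b) for b in "ACGT") / len(seq)
        if mono > config.max_mono_fraction:
            report["dropped_low_complexity"] += 1
            continue
        if not config.min_len <= len(seq) <= config.max_len:
            report["dropped_length"] += 1
            continue
        report["kept"] += 1
        counts[seq] = counts.get(seq, 0) + 1
    unique = pd.DataFrame(
        {"sequence": list(counts), "count": list(counts.values())}
    ).sort_values(["count", "sequence"], ascending=[False, True], ignore_index=True)
    report["unique_sequences"] = len(unique)
    return unique, report


# ---------------------------------------------------------------------------
# Mapping
# ---------------------------------------------------------------------------


def _occurrences(needle: str, haystack: str) -> list[int]:
    out, pos = [], haystack.find(needle)
    while pos != -1:
        out.append(pos)
        pos = haystack.find(needle, pos + 1)
    return out


def map_srna(
    unique_reads: pd.DataFrame,
    eves: Sequence[SequenceRecord],
    config: Optional[SrnaConfig] = None,
) -> pd.DataFrame:
    """Assign unique reads to every nrEVE where they match end-to-end
    (default zero mismatches) on either strand.

    Returns a table with one row per (sequence, nrEVE, strand): sequence,
    count, eve, strand, five_prime (0-based position of the read's 5' end
    in nrEVE coordinates), length, first_nt (RNA space).
    """
    config = config or SrnaConfig()
    if config.mismatches != 0:
        raise NotImplementedError("only exact (0-mismatch) small-RNA mapping is supported")
    rows = []
    for _, rec in unique_reads.iterrows():
        seq, count = rec["sequence"], int(rec["count"])
        rc = reverse_complement(seq)
        for eve in eves:
            plus_hits = _occurrences(seq, eve.sequence)
            if plus_hits:
                rows.append(
                    {
                        "sequence": seq,
                        "count": count,
                        "eve": eve.id,
                        "strand": "+",
                        "five_prime": plus_hits[0],
                        "length": len(seq),
                        "first_nt": _rna(seq[0]),
                    }
                )
            minus_hits = _occurrences(rc, eve.sequence)
            if minus_hits:
                # the read's 5' end sits at the 3' end of the genomic match
                rows.append(
                    {
                        "sequence": seq,
                        "count": count,
                        "eve": eve.id,
                        "strand": "-",
                        "five_prime": minus_hits[0] + len(seq) - 1,
                        "length": len(seq),
                        "first_nt": _rna(seq[0]),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["sequence", "count", "eve", "strand", "five_prime", "length", "first_nt"],
    )


def _rna(base: str) -> str:
    return "U" if base == "T" else base


# ---------------------------------------------------------------------------
# Profiles and the piRNA call
# ---------------------------------------------------------------------------


def profile_and_call(
    assignments: pd.DataFrame,
    library: str,
    total_unique_reads: int,
    config: Optional[SrnaConfig] = None,
) -> list[SrnaProfile]:
    """One profile per nrEVE present in ``assignments``.

    The piRNA-like verdict is the conjunction of three sub-verdicts, each
    reported: length (fraction of unique reads in the 25-30 nt window),
    first-nucleotide (5'-U fraction) and strand (dominant-strand fraction).
    """
    config = config or SrnaConfig()
    profiles = []
    for eve, group in assignments.groupby("eve", sort=True):
        dedup = group.drop_duplicates(subset=["sequence", "strand", "five_prime"])
        n = len(dedup)
        hist = {l: 0 for l in range(config.min_len, config.max_len + 1)}
        for l, c in dedup.groupby("length").size().items():
            hist[int(l)] = int(c)
        first = {b: 0 for b in "UACG"}
        for b, c in dedup.groupby("first_nt").size().items():
            first[str(b)] = int(c)
        plus = int((dedup["strand"] == "+").sum())
        minus = n - plus
        lo, hi = config.pi_length_range
        in_window = int(dedup["length"].between(lo, hi).sum())
        verdicts = {
            "no_data": n == 0,
            "length": n > 0 and in_window / n >= config.min_pi_length_fraction,
            "first_u": n > 0 and first["U"] / n >= config.min_first_u_fraction,
            "strand": n > 0 and max(plus, minus) / n >= config.min_dominant_strand_fraction,
        }
        profiles.append(
            SrnaProfile(
                nreve=eve,
                library=library,
                unique_mapped=n,
                pct_of_library=100.0 * n / total_unique_reads if total_unique_reads else 0.0,
                length_histogram=hist,
                first_nucleotide=first,
                plus_count=plus,
                minus_count=minus,
                pirna_like=verdicts["length"] and verdicts["first_u"] and verdicts["strand"],
                verdicts=verdicts,
                detail=dedup.reset_index(drop=True),
            )
        )
    return profiles


def profiles_to_table(profiles: Iterable[SrnaProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {
            "nreve": p.nreve,
            "library": p.library,
            "unique_mapped": p.unique_mapped,
            "pct_of_library": round(p.pct_of_library, 4),
            "plus": p.plus_count,
            "minus": p.minus_count,
            "pirna_like": p.pirna_like,
        }
        row.update({f"len_{l}": c for l, c in p.length_histogram.items()})
        row.update({f"first_{b}": c for b, c in p.first_nucleotide.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hotspots
# ---------------------------------------------------------------------------


def hotspots(
    assignments: pd.DataFrame,
    nreve: str,
    nreve_length: int,
    config: Optional[SrnaConfig] = None,
    weight_by_count: bool = False,
) -> HotspotResult:
    """Positions whose unique-read 5'-end start counts exceed
    mean + hotspot_sd * SD over the per-position distribution."""
    config = config or SrnaConfig()
    group = assignments[assignments["eve"] == nreve]
    dedup = group.drop_duplicates(subset=["sequence", "strand", "five_prime"])
    if len(dedup) < config.min_hotspot_reads:
        return HotspotResult(nreve, [], None, True)
    starts = np.zeros(nreve_length)
    weights = dedup["count"] if weight_by_count else np.ones(len(dedup))
    for pos, w in zip(dedup["five_prime"], weights):
        starts[int(pos)] += w
    threshold = float(starts.mean() + config.hotspot_sd * starts.std())
    # strict exceedance, with an epsilon so counts exactly at the threshold
    # are not flagged through rounding error
    positions = np.nonzero(starts > threshold * (1 + 1e-9) + 1e-9)[0].tolist()
    return HotspotResult(nreve, positions, threshold, False)


# ---------------------------------------------------------------------------
# Seed-aware complementarity to a viral genome
# ---------------------------------------------------------------------------


def seed_complementarity(
    pirnas: Sequence[str],
    virus: SequenceRecord,
    min_identities: int = 22,
    config: Optional[SrnaConfig] = None,
) -> list[SeedMatch]:
    """Best ungapped full-length alignment of each piRNA to either strand
    of the virus (exhaustive over all offsets); matches with >= the
    identity floor are reported with their mismatch positions (1-based on
    the piRNA) and whether both seed windows are mismatch-free."""
    config = config or SrnaConfig()
    varr = np.frombuffer(virus.sequence.encode("ascii"), dtype=np.uint8)
    rc_arr = np.frombuffer(
        reverse_complement(virus.sequence).encode("ascii"), dtype=np.uint8
    )
    N = len(varr)
    out = []
    for pirna in pirnas:
        L = len(pirna)
        if L > N:
            raise ValueError(f"virus {virus.id} shorter than piRNA ({L} nt)")
        parr = np.frombuffer(pirna.encode("ascii"), dtype=np.uint8)
        best = None  # (identities, strand, offset_on_template)
        for strand, template in (("+", varr), ("-", rc_arr)):
            windows = np.lib.stride_tricks.sliding_window_view(template, L)
            idents = (windows == parr).sum(axis=1)
            off = int(np.argmax(idents))
            cand = (int(idents[off]), strand, off)
            if best is None or cand[0] > best[0]:
                best = cand
        identities, strand, off = best
        if identities < min_identities:
            continue
        template = varr if strand == "+" else rc_arr
        mismatches = (np.nonzero(template[off : off + L] != parr)[0] + 1).tolist()
        seed_clean = not any(
            lo <= p <= hi for p in mismatches for lo, hi in config.seed_windows
        )
        target_pos = off if strand == "+" else N - off - L
        out.append(
            SeedMatch(
                pirna=pirna,
                target_id=virus.id,
                target_position=target_pos,
                target_strand=strand,
                identities=identities,
                alignment_length=L,
                mismatch_positions=mismatches,
                seed_clean=seed_clean,
            )
        )
    return out


def seed_matches_to_table(matches: Iterable[SeedMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pirna": [m.pirna for m in matches],
            "target": [m.target_id for m in matches],
            "position": [m.target_position + 1 for m in matches],
            "strand": [m.target_strand for m in matches],
            "identities": [m.identities for m in matches],
            "length": [m.alignment_length for m in matches],
            "mismatch_positions": [
                ",".join(map(str, m.mismatch_positions)) for m in matches
            ],
            "seed_clean": [m.seed_clean for m in matches],
        }
    )


# ---------------------------------------------------------------------------
# Coverage track and plot
# ---------------------------------------------------------------------------


def coverage_track(assignments: pd.DataFrame, nreve: str, nreve_length: int) -> np.ndarray:
    depth = np.zeros(nreve_length)
    group = assignments[assignments["eve"] == nreve]
    dedup = group.drop_duplicates(subset=["sequence", "strand", "five_prime"])
    for _, r in dedup.iterrows():
        if r["strand"] == "+":
            lo = int(r["five_prime"])
            depth[lo : lo + int(r["length"])] += 1
        else:
            hi = int(r["five_prime"]) + 1
            depth[max(hi - int(r["length"]), 0) : hi] += 1
    return depth


def write_bedgraph(path, nreve: str, depth: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{nreve} sRNA coverage"\n')
        start = 0
        for i in range(1, len(depth) + 1):
            if i == len(depth) or depth[i] != depth[start]:
                if depth[start] > 0:
                    fh.write(f"{nreve}\t{start}\t{i}\t{depth[start]:g}\n")
                start = i


def plot_profile(profile: SrnaProfile, path) -> None:
    """Length histogram colored by 5' nucleotide, plus strand above the
    axis and minus strand below."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"U": "tab:red", "A": "tab:green", "C": "tab:blue", "G": "tab:orange"}
    lengths = sorted(profile.length_histogram)
    fig, ax = plt.subplots(figsize=(6, 4))
    detail = profile.detail
    for strand, sign in (("+", 1), ("-", -1)):
        bottom = np.zeros(len(lengths))
        for base in "UACG":
            sub = detail[(detail["strand"] == strand) & (detail["first_nt"] == base)]
            counts = np.array(
                [int((sub["length"] == l).sum()) for l in lengths], dtype=float
            )
            ax.bar(
                lengths,
                sign * counts,
                bottom=sign * bottom,
                color=colors[base],
                label=base if strand == "+" else None,
                width=0.8,
            )
            bottom += counts
    ax.axhline(0.0, color="black", linewidth=1)
    ax.set_xlabel("read length (nt)")
    ax.set_ylabel("unique reads (+ above, - below)")
    ax.set_title(f"{profile.nreve} / {profile.library}")
    ax.legend(title="5' nt", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
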