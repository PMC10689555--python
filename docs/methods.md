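# Methods

This note documents the models and conventions implemented in `paleoscan`,
the parameters that matter, what the synthetic data does and does not
emulate, and the numerical choices a maintainer should know about.

## Discovery model

An nrEVE is detected as a genomic interval whose translation is
significantly similar to a viral protein.  Discovery is a two-stage
screen:

1. **Forward screen.** Host contigs are translated in all six frames and
   searched against the *viral* entries of a categorized protein database
   at E ≤ 10⁻⁶.  HSPs on the same contig and strand hitting the same
   subject are merged into one candidate locus when their genomic
   footprints overlap or lie within 10 nt and are collinear on the
   subject; candidate loci from different subjects that overlap
   genomically collapse to the best-scoring one.  Candidates are extracted
   with zero flank (a `flank` parameter exists for exploration), stored in
   the orientation of the viral hit, with the genomic strand kept as a
   separate field.
2. **Validation.** Each candidate's genomic sequence is re-searched, again
   in translated space, against the *full* database — viral entries plus
   host proteins, transposable elements and retroviral pol — at the looser
   E ≤ 10⁻⁴.  The candidate is kept if and only if its single top hit
   (lowest E, then highest bit score, then lexicographic subject id) is
   viral.  Every candidate receives a recorded verdict, so catalogue plus
   discard list always partition the forward-screen output.  The
   categorized decoy entries play the role that a comprehensive
   non-redundant protein database plays in an online analysis; a
   margin-based variant of the verdict is deliberately not the default
   because the simplest top-hit rule is the most predictable.

Kept candidates become catalogue records.  The name is
`nrEVE_` + (uppercase genus initial + first three letters of the species
epithet) + (viral family minus the terminal "viridae", or `Unc` for
unclassifiable elements) + `_` + an ordinal assigned per (host, family) in
(contig, start) order.  Family, genome-sense class and functional region
come from the top viral hit's sidecar annotation.

## Alignment statistics

The translated search scores with BLOSUM62, gap open 11 / extend 1
(a gap of length g costs 11 + g); the nucleotide search uses +2/−3 with
gaps 5/2.  Significance uses the Karlin–Altschul expectation
E = K·m′·n′·e^(−λS) with gapped parameters λ = 0.267, K = 0.041
(BLOSUM62 11/1) and λ = 0.625, K = 0.41 (+2/−3, 5/2).  The effective
lengths subtract the standard expected-HSP-length correction
ℓ = ln(K·m·n)/H (H = 0.14 translated, 0.78 nucleotide), applied once to
the query and once per database sequence, floored so both stay ≥ 1.
The query length m is the summed length of all six frame translations of
a contig.

Two search regimes share this scoring:

- **Exact regime** (m·n ≤ 4×10⁷ DP cells): every frame/subject pair is
  aligned with a full local Gotoh alignment, so the best reported HSP
  score *is* the Smith–Waterman optimum.  All validation searches and
  reference-genome mappings run here.
- **Seeded regime** (genome scale): exact k-mer seeds (k = 3 aa / 11 nt)
  are joined by hashing, extended ungapped in both directions with an
  x-drop of 20 bits, gated at an ungapped E ≤ 10 and refined with a
  windowed gapped alignment (window padding = subject length + 60
  residues, wide enough that the local optimum cannot escape it).
  Neighborhood words and two-hit seeding are deliberately omitted;
  sensitivity is guaranteed empirically by planted-truth recall rather
  than by parity with any particular search tool.

Translation follows the standard genetic code; stop codons are rendered
`*` and retained (BLOSUM62's `*` row scores −4 against everything), and a
codon containing N translates to X even when the ambiguity would resolve
to a single residue.

For nucleotide similarity to circulating viruses, each (query, subject)
pair is aligned greedily — best local alignment, mask the aligned query
interval, realign, up to ten rounds — and summarized by *query cover*
(union of query positions in retained HSPs over query length) and the
identity of the best HSP.  Pairs are retained at cover ≥ 0.50 and identity
≥ 0.50.

## Proximity clustering and region assignment

Catalogue intervals on one contig are clustered by single linkage on the
gap `next.start − (prev.start + prev.length)` (1-based starts; negative
gaps, i.e. overlaps, count as 0); clusters of two or more members are
reported with their gaps.  Thresholds of interest in practice are 5000,
1000 and 200 nt.

To assign the viral ORF an element derives from, the element is aligned in
protein space against the six-frame translation of an annotated reference
viral genome (E ≤ 10⁻⁴); the best alignment's footprint on the reference
is labeled with the ORF of maximal overlap, requiring at least 30% of the
mapped interval; otherwise, or when nothing aligns, the label is
Hypothetical.  A family with no configured reference yields an explicit
unmapped record rather than an error.  When a multi-HSP element spans two
ORFs, maximal overlap decides — the choice is this package's own.

## Transcription

Detection works by direct read mapping rather than assembly: a read is
assigned to an element (or the housekeeping gene) when an ungapped
end-to-end alignment with ≤ 2 mismatches exists on either strand;
multi-target reads go to the fewest-mismatch target, ties split evenly as
fractional counts.  An element is *detected* in a dataset when covered
over ≥ 50% of its length at depth ≥ 1, and *actively transcribed* when
detected in at least one dataset; frequencies are reported as `k/n`.
Relative abundance is (element reads / element length) ÷ (L23a reads /
L23a length), flagged undefined when the housekeeping count is zero.  This
deterministic breadth criterion replaces de novo assembly plus re-search,
and the length-normalized ratio replaces a model-based estimator; both
substitutions are intentional and documented here because they trade
fidelity to a specific toolchain for testability.

ORFs inside elements are maximal stop-free translated segments of ≥ 100 aa
in any of the six frames, with *no* start-codon requirement — endogenized
fragments are internal pieces of viral ORFs and generally lack an ATG.  An
ATG-anchored mode is available as a switch.

## Small RNAs

Cleaning order: adapter trim (exact match of an adapter prefix to the read
3′ end, ≥ 8 nt overlap) → drop empty → drop reads with > 20% of bases
below Phred 20 → drop low-complexity reads (mononucleotide fraction
> 0.8 — the specific rule is this package's choice) → keep lengths in the
inclusive 18–32 nt window → collapse to unique sequences with summed
counts.  A per-stage attrition report is always produced and input =
kept + Σ dropped holds by construction.

Mapping is exact (zero mismatches) end-to-end on either strand; all
profile statistics are computed on *unique* reads, with copy counts
retained but used only in the optional weighted hotspot mode.  A locus is
**piRNA-like** when three sub-verdicts hold simultaneously on its mapped
unique reads:

| hallmark | statistic | threshold |
|---|---|---|
| length peak | fraction with length in 25–30 nt | ≥ 0.5 |
| 1U bias | fraction with 5′ U (T in DNA space) | ≥ 0.5 |
| strand origin | dominant-strand fraction | ≥ 0.9 |

The thresholds operationalize a qualitative description (a "distinctive"
25–30 peak, uracil bias, single-strand origin); all three are
configuration values and the sub-verdicts are always reported so users can
re-threshold.

Hotspots are positions whose unique-read 5′-end counts exceed
mean + 3·SD of the per-position distribution, computed only when ≥ 10
unique reads map ("insufficient data" otherwise).  A three-sigma rule on
per-position counts flags the natural Poisson tail when starts are sparse
and random; it is calibrated for the question actually asked — is any
position grossly over-represented relative to an even layout — and the
exceedance test carries a small epsilon so counts exactly at the threshold
never flag through floating-point rounding.

Seed-aware complementarity aligns each piRNA ungapped against both strands
of a viral genome, exhaustively over all offsets (adequate for viral
genomes of tens of kb), reports matches at ≥ 22 identities with mismatch
positions in piRNA coordinates, and marks a match `seed_clean` when
neither window 2–8 nor 14–22 (1-based from the 5′ end) contains a
mismatch — mismatches there are considered to abolish target recognition.

## Synthetic data

The simulator generates the study conditions the pipeline is tested
under: host contigs of i.i.d. background sequence at GC 0.40 (tephritid-
like) carrying planted integrations; a protein database of uniform-random
proteins annotated as viral (with family, function, genome-sense) or as
host/TE/retroviral decoys; RNA-seq reads drawn uniformly over transcribed
loci; and small-RNA libraries mixing locus-derived piRNA-like reads with
random background.

An integration is built by substituting a fragment of a database protein
at amino-acid rate *d* (each hit residue replaced by a uniformly random
different residue), then reverse-translating with uniform random
synonymous codons, and planting on a random strand without overlap.
Defaults: 4 contigs × 500 kb, 20 viral integrations of 50–150 aa
(catalogue elements are mostly a few hundred nt of coding sequence, so
50–150 aa is the realistic fragment range), 5 decoys per category, d =
0.1–0.2.  Small-RNA reads default to a 25–30 nt length peak; the 5′ base
is uridine with probability *exactly* p1U because starts are drawn from
the matching-base position pool (substitution is a fallback only when a
locus has no usable start), which keeps threshold-grid tests unambiguous.

What the simulator does **not** emulate — and what passing tests therefore
do not show about real data: repeat structure and segmental duplication
(a planted-TE mode exercises the decoy filter, but there is no repeat
landscape), codon usage bias, indel sequencing errors, PCR duplicates,
degraded or fragmented assemblies, and real viral protein families with
shared domains.  Recall and false-positive numbers on synthetic genomes
bound the idealized behaviour of the method, not its performance on any
particular assembly.

## Problem sizes and determinism

The test suite and the acceptance script use these sizes, chosen to make
each property measurable in seconds to a minute on one CPU: discovery
recall on a 2-Mb genome (4 × 500 kb) with 20 integrations and 15 decoys at
d = 0.2 and d = 0.4; aligner-oracle equivalence on 200 random pairs
(contigs ≤ 2 kb, proteins ≤ 500 aa) against a from-scratch quadratic
Gotoh dynamic program; a 100-trial null calibration (10-kb contig vs 100 ×
300-aa proteins, expecting no hits at E ≤ 10⁻⁶); a 12-cell piRNA-signature
grid (p1U ∈ {0.3, 0.75, 0.95} × strand ∈ {0.5, 1.0} × peaked/flat lengths,
2500 reads per cell); and 200 × 1-kb ORF-oracle comparisons.  All
randomness flows from explicit seeds; the same seed gives byte-identical
simulator output.

## Known limitations

- Discovered element boundaries are alignment footprints; at high
  divergence the extracted interval can be slightly shorter or longer
  than the historically inserted fragment.
- The validation verdict is a top-hit rule; a decoy and a viral protein
  with near-identical scores resolve by E-value order, not by a margin.
- Multi-copy elements (paralogs) on one contig merge only if within 10 nt;
  orthology across species is out of scope — no decision rule is
  implemented because none is defensible from coordinates alone.
- The nucleotide search reports at most ten HSPs per pair (greedy
  masking), which is ample for element-vs-virus comparisons but would
  undercount cover for long, highly repetitive queries.
- First-nucleotide statistics are reported in RNA space (U, not T);
  percentages of mapped reads use unique reads in the denominator
  throughout.
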