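# Methods

## The measurement model

Each sequenced molecule reports one reporter mRNA from one cell carrying one
hgRNA. Read 1 (210 nt) is an amplicon of the guide cassette:

```
leader | Cas9 spacer (20) | tracrRNA | Cas12a DR | Cas12a spacer (23)
       | flank | CBC (12) | flank | UMI (10, configurable) | backbone
```

Read 2 (104 nt) covers the reporter's splice junction. The package treats
this architecture as data: a `VectorLayout` lists the anchor sequences and
element lengths, and all extraction is anchor search plus fixed offsets. The
default layout (used by the simulator) takes the published Cas9 tracrRNA and
AsCas12a direct-repeat sequences as internal anchors and package-defined
constants for the flanks; analyses of real vectors must supply their own
layout, since the deposited plasmid's exact flanking sequence is
configuration, not something the package guesses.

### Parsing

Anchors are located allowing at most `max_anchor_mismatches` substitutions
(default 1); there is no indel tolerance, so element offsets are fixed once
anchors are found. A read fails with `anchor_missing` if any anchor is absent.
Spacer pairs are matched against the library by exact dictionary lookup with
an optional Hamming-1 rescue per spacer; both spacers must point at the same
library record — recombined (chimeric) pairs fail as `guide_unmatched`,
pairs compatible with several records as `multi_match`. Read 2 is classified
by searching for each outcome class's junction signature — the
`2·min_overhang` window centred on the junction point — with at most one
substitution; exactly one matching class is required, otherwise the read is
`ambiguous` and excluded from both IE and EE (it informs neither junction).

### Deduplication

PCR duplicates share CBC and UMI up to sequencing error. CBCs are clustered
per hgRNA and UMIs within each (hgRNA, CBC cluster) by directional greedy
clustering: sequences sorted by (count descending, lexicographic ascending)
join the first accepted representative within Hamming distance 1, else found
a new cluster. Sorting by count makes the assignment independent of input
order; the lexicographic tie-break makes it fully deterministic. Nesting the
UMI clustering inside the CBC cluster prevents molecules from different cells
merging on a shared UMI. Conflicting outcomes inside a duplicate group are
resolved by strict majority; ties are dropped — a molecule whose reads split
evenly between junctions identifies neither.

### Quantification

For guide g, `PSI_g = 100 · IE_g / (IE_g + EE_g)` over deduplicated
molecules, where IE counts the outcome classes configured as
*inclusion-like*. Which junction is inclusion-like is reporter configuration:
for a progerin-style mutant reporter the aberrant junction is the numerator,
for a mutually-exclusive-exon reporter one exon is designated. The reference
is the *pooled* intergenic PSI — counts summed over all intergenic control
guides, i.e. a count-weighted cumulative PSI rather than a mean of per-guide
PSIs — computed separately per pseudo-replicate, and
`ΔPSI_g = PSI_g − PSI_intergenic`. PSI is reported only when
`IE + EE ≥ min_reads` (default 20): the screen design controls coverage at
the cell level, but a molecule-count floor is needed to keep percentile
cutoffs stable, and it is exposed as a parameter.

### Hit calling

Pseudo-replicates: each guide's distinct CBCs are randomly halved (extra CBC
to R1; single-CBC guides flagged), so every guide appears in both replicates
and the halves are biologically independent cells. Per replicate, cutoffs are
the 5th/95th percentiles (linear interpolation) of the intergenic PSI
distribution — flagging both 5% tails gives the empirical 10% FDR design
point. Significance is strict (`PSI > high` or `PSI < low`): a value exactly
at the cutoff is not "beyond the extremes", and strict inequalities avoid
hit inflation in degenerate (tied) distributions; with `tail_fraction = 0`
the cutoffs are ±∞ and nothing is flagged. A gene is a hit in a replicate iff

1. its gene-level PSI — pooled IE/EE over the gene's quantified guides
   (count-weighted; an unweighted-mean alternative sits behind
   `gene_stat="mean"`) — is beyond the same cutoff pair,
2. strictly more than half of its quantified guides are significant in the
   gene's direction (3 of 4, 2 of 3, 2 of 2), and
3. at least two guides are significant in that direction.

Final hits must pass in both replicates with the same direction. Paralog-pair
hgRNAs (two target genes) are excluded from single-gene aggregation and
reported as their own class.

## Base-editor tiling

Guide ΔPSI is the arithmetic mean of the adenine- and cytosine-editor screen
scores; a guide present in only one screen keeps its single score (the
averaging rule is silent on missing editors, so the fallback is the package's
choice). Gene-level scores pool IE/EE per editor, subtract that editor's
pooled intergenic PSI, then average editors; output is sorted ascending by
ΔPSI with lexicographic tie-break. Protospacers lying completely within exons
map to protein coordinates through the transcript CDS: each base inside the
CDS belongs to codon `index // 3 + 1` in transcription order; '+'-strand genes
report the first mapped index, '−'-strand genes the last. Profiles use
non-overlapping decade windows ([1–10], [11–20], …) rather than sliding
windows — exact, testable semantics with an unambiguous x-axis — and the
window mean is the unweighted mean of guide scores; empty windows are absent,
never zero. Guides within 3 nt (configurable) of an internal exon edge are
flagged as splice-site-overlapping: they stay in gene-level scores but are
excluded from protein tiling, where their effect confounds the
amino-acid-level interpretation.

## Library design rules

Design operates on precomputed candidate tables (on-target scores, GuideScan
off-target scores, genomic Hamming-neighbour counts, transcript-coverage and
CDS-position annotations); computing those scores is out of scope.

- **KO filters**: hamming0 = 1, hamming1 = 0 (Cas12a also hamming2 ≤ 2),
  GuideScan > 0.16 (strict), on-target > 0.1 (strict), no BveI (ACCTGC /
  GCAGGT) or Eco47III (AGCGCT) site in the spacer, cut site inside the CDS.
- **Ranking**: six rounds with thresholds relaxed by fifths. Round r
  requires transcript fraction ≥ 1 − 0.2(r−1), cut ≥ 10% − 2%(r−1)
  downstream of the start, ≥ 50% − 10%(r−1) upstream of the stop, and
  genomic spacer overlap with already-accepted guides ≤ r − 1 (capped at 4);
  round 6 accepts everything left. Only the first relaxation step is stated
  explicitly in the source procedure (1 → 0.8, 10% → 8%, 50% → 40%,
  overlap 0 → 4); the linear schedule here is the one consistent reading of
  those deltas and is isolated in `rank_round_thresholds`. Within a round
  candidates are ordered by on-target descending (ties: spacer
  lexicographic); the top 25 get labels a1…a25 / b1…b25.
- **Pairing**: all a×b combinations are assigned the smallest tier whose
  criteria they meet; tier 1 requires cut distance ≥ 150 bp, no spacer
  overlap, full transcript coverage and upstream-middle CDS position, with
  distance relaxing 150 → 120 → 90 → 60 → 30 → 0 over tiers. Pairs are taken
  best tier first, each guide used once, until 4 pairs; an anti-diagonal
  reshuffle (a1-b4, a2-b3, …) is applied when it lowers no pair's tier, to
  spread guide quality across the gene's hgRNAs.
- **Sparse genes**: an explicit composition table maps the available
  (Cas9, Cas12a) counts to dual / single-enzyme (intergenic-partnered)
  hgRNAs; (3,3) → 3 duals, (1,1) → one dual plus one single per enzyme,
  (1,0)/(0,1) → nothing. Combinations the source rules do not enumerate
  ((4,3), (4,2), (4,1)) follow the same leftover-as-single logic.
- **Paralogs**: with ≥2 guides per enzyme per gene, the orientation-balanced
  set {A1-B1, A2-B2, B1-A1, B2-A2}; a gene lacking Cas9 guides contributes
  Cas12a guides to the other gene's Cas9 partners (B1-A1 … B4-A4); two genes
  covered by only one enzyme yield nothing.
- **BE filters**: no homopolymer (AAAAAA/TTTTT/CCCCCC/GGGGGG) or restriction
  motif (GATATC/GCAGGT/ACCTGC), no CAGGT/ATATC prefix or GCAG suffix, ≥1 nt
  exonic overlap, an A or C within spacer positions 1–12 (the editing
  window), GuideScan > 0.16 and ≤ 2 sites within two genomic mismatches
  (the two-mismatch constraint is read as a neighbour-count bound and is
  configurable, since a distance bound is the other defensible reading).

All tie-breaks are score-descending then lexicographic, so identical
candidate tables give byte-identical libraries.

## Simulator

The generator emulates the screen's statistical structure, not its
biochemistry. Defaults are the study conditions: 4 targeting guides per
gene, baseline reporter PSI 50, 250 cells (CBCs) per guide mirroring the
screening coverage floor, depth 500 molecules per guide, PCR duplication
1 + Poisson(0.5) copies per molecule (mean 1.5), substitution rate 10⁻³ per
base. Per molecule: CBC uniform over the guide's pool, isoform ~
Bernoulli(PSI_true/100), fresh UMI. UMIs are rejection-sampled to be mutually
beyond Hamming distance 1 within a (guide, CBC) group so deduplication
recovers the ground-truth molecule count exactly; at a 10-nt UMI the rejected
mass is negligible, so this does not distort the statistics. Reads are
assembled from the default `VectorLayout` and a synthetic two-outcome
cassette reporter (shared upstream exon, distinct alternative/downstream
exons); quality strings are constant because quality is unused downstream.

What the simulator does **not** model: cell fitness and guide dropout over
time, reporter-independent transcriptome effects, indels or adapter
artefacts in reads, UMI saturation, and chimeric PCR between constructs.
Passing tests therefore demonstrate the correctness of the readout
arithmetic and the calibration of the empirical-FDR procedure under the
declared noise model — not robustness to every artefact of real screens.

## Numerical and testing choices

- Percentiles use NumPy's linear-interpolation definition; on PSIs 1…100 the
  5%/95% cutoffs are 5.95 and 95.05 (frozen in a test).
- PSI values at finite depth are discrete; combined with strict cutoff
  inequalities this makes the realised null flagged fraction land slightly
  below the nominal 10% (≈9.5% at depth 500), which the calibration
  experiment reports honestly rather than adjusting.
- Coordinates are 0-based half-open internally; 1-based only in reports
  (amino-acid positions are 1-based).
- Problem sizes in tests: the FDR calibration uses 1,000 guides × 20
  repetitions at depth 500; parameter recovery uses 500 genes × 4 guides
  (20 true regulators at ΔPSI ±30, depth 300, 20 CBCs per guide, molecule
  level). These sizes make the Monte-Carlo error small relative to the
  asserted tolerances while keeping the default suite fast.
- Dedup clustering is quadratic in distinct barcodes per group; fine for
  per-cell UMI counts, and the brute-force oracle in the tests is the same
  algorithm restated naively.

## Known limitations

- No indel tolerance anywhere in read parsing (v1 scope).
- No p-value model for hits — the procedure is purely empirical-percentile
  by design.
- Single-CBC guides cannot form two pseudo-replicates and are flagged rather
  than rescued.
- The design engine consumes candidate tables; it neither scans genomes for
  PAM sites nor computes on/off-target scores.
- No cross-sample normalisation (time-point comparisons are a study-design
  question, not a formula in this package).
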