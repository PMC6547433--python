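# Methods

`ribote` implements a translation-efficiency (TE) analysis for ribosome
profiling together with a synthetic-data generator that encodes a specific
failure mode of the standard protocol: cycloheximide (CHX) pretreatment of
starved yeast cultures re-activates TORC1-dependent transcription of
ribosome-biogenesis ("ribi") genes during the minutes between drug addition
and harvest. The new transcripts cannot be translated (elongation is
blocked), so measured ribi mRNA rises while ribi footprints do not — and the
apparent TE of the whole regulon collapses with no translational regulation
having occurred. The package exists to make that artifact, and the analysis
that exposes it, reproducible end to end on desk-scale synthetic data.

## Quantification model

**Single-position reduction.** Every aligned read is collapsed to one
genomic position before any mask or CDS test. Footprints are assigned to the
ribosomal P-site, `5' end + offset(length)` with a length-dependent offset;
mRNA reads to their 5'-most aligned base after strandedness correction
(reverse-stranded chemistry flips the read strand first). A read counts for
gene *g* iff that position lies in *g*'s CDS on the matching strand and is
not masked; otherwise it is discarded. Masks therefore test a single base,
not the whole read footprint.

**Masks.**
- *Mappability (crossmap):* position *p* is masked when the 26-mer starting
  at *p* matches a window at any other genomic location, on either strand,
  within 2 substitutions. The production algorithm is pigeonhole
  seed-and-verify (split the k-mer into `max_mismatches + 1` parts; a pair
  within budget must agree exactly on one part; bucket by part, verify
  candidates with exact Hamming distance). It is definitionally equal to
  all-vs-all enumeration, and the test suite checks bit-exact agreement
  against an independent brute-force enumerator on dozens of genomes with
  engineered duplications. Indels are out of scope. A per-gene exemption
  (`crossmap_exempt_genes`) re-quantifies designated genes (e.g.
  near-identical paralog families) with the edge mask only.
- *CDS edges:* the first 30 and last 5 codons of every CDS are masked,
  strand-aware, removing the initiation pile-up (which CHX exaggerates) and
  termination effects. Effective length = CDS length − masked overlap; a CDS
  with no codons left is a hard error naming the gene.

**P-site offsets.** Per read length, a metagene histogram of 5'-end
positions at distances 0..L−1 upstream of annotated start codons; the offset
is the argmax (ties break toward the smaller offset). A length is estimated
only from ≥ 50 upstream-window reads with a peak ≥ 2× the histogram median
*and* ≥ 15% of the window's reads — sparse uniform histograms can beat the
median rule by chance, hence the second guard. Failing lengths fall back to
the depth-weighted mode of the successful offsets and are flagged, never
silent. If no length succeeds the estimator raises.

**RPKM and filters.** RPKM = count / (effective length/10³) / (assigned
reads/10⁶). The denominator is the library's total CDS-assigned reads (the
definition leaves this open; a CDS-assigned total keeps footprint and mRNA
RPKM internally consistent and cancels in all ratios). Genes enter an
analysis only with ≥ 128 mRNA counts and ≥ 1 footprint count in *every*
sample under comparison (the strictest reading of the per-sample rule) and
only if not blacklisted as dubious ORFs. TE = footprint RPKM / mRNA RPKM.

**Fold changes and statistics.** Fold changes between samples are computed
on RPKM and normalized so the median over passing genes is exactly 1
(numpy median convention; even-length inputs use the midpoint mean).
Time-course variability is the per-gene fold-range, max TE / min TE across
timepoints, complete-case over timepoints where the gene passes filters (≥ 2
required). "Switchers" are genes with fold-range ≥ 8 (inclusive). Gene-set
overlap enrichment is an upper-tail hypergeometric probability of the
flagged count in the intersection. Grouped ±CHX comparisons take per-gene
log2 normalized RPKM ratios and run two-sided t-tests — a one-sample test
per gene set (mean vs 0) and a Welch two-sample test of set vs complement;
significance tiers are NS / * / ** / *** / **** at p < 10⁻², 10⁻⁵, 10⁻¹⁰,
10⁻²⁵ (the outer anchors are the conventional printed ones; the interior two
are interpolated design choices). **No multiple-testing correction is
applied anywhere**; all probabilities are raw per-test values.

**ddCt.** ΔCt = mean Ct(target) − mean Ct(reference) per sample, ΔΔCt
relative to a calibrator sample, fold = 2^−ΔΔCt with amplification
efficiency fixed at 2. Technical-replicate SDs combine in quadrature; the
reported interval is [2^−(ΔΔCt+SD), 2^−(ΔΔCt−SD)] — an interval transform of
the Ct uncertainty, not an SD of folds.

**Localization scoring.** Nuclei: Otsu threshold on the RFP channel,
connected components, size filter; touching nuclei are not declumped (a
merged pair is one label, documented behavior). Cells: foreground is GFP
strictly above a robust-background threshold (mean + 2·SD of the dimmest 75%
of pixels — the "robust background" shape with its parameters stated as the
contract), opened with a 3×3 structuring element to drop speckle, restricted
to components connected to a nucleus, and partitioned by nearest-nucleus
propagation; every cell contains its nucleus. Score = (mean nuclear GFP) /
(mean cytoplasmic GFP), equal to the ratio of whole-cell-normalized
compartment intensities; invariant to gain, not to offset — background
subtraction is available but off by default. Per-group aggregation reports
mean ± 1.96·SD/√n (normal approximation; at the n ≥ 200 cells the protocol
calls for, t vs normal is immaterial), flagging smaller groups.

## The synthetic model

Defaults (the study conditions the generator emulates):

| parameter | default | meaning |
|---|---|---|
| `n_genes` / `frac_ribi` | 200 / 0.05 | toy genome size; ribi fraction (the real regulon is ~200 of ~6600 genes, ~3%; 5% is the desk-scale analogue — see *Compositional effects*) |
| `cds_length_range` | 300–1500 nt | whole codons; must exceed the 105 nt edge mask |
| `mean_mrna_abundance`, `te_true` | logN(3, 1), logN(0, 0.5) | per-gene base abundance and true TE, drawn once per seed so paired conditions differ only by multipliers |
| `chx_mrna_multiplier` / `chx_footprint_multiplier` | 3.0 / 0.5 | the artifact: applied to ribi genes in starved+CHX states only |
| `starvation_ribi_mrna_multiplier` | 0.5 | starvation represses ribi transcription (footprints track mRNA, so true TE is unchanged) |
| `gcn4_te_multiplier` | 4.0 | starvation-induced translational activation of one GCN4-like gene |
| `dek_codon_bias` / `background_dek_frequency` | 0.40 / 0.17 | Asp/Glu/Lys codon fraction in ribi vs other CDSs |
| `read_length_distribution` / `true_psite_offsets` | 26–34 nt, mode 28 | footprint lengths and their true offsets (12–16 nt) |
| `oscillation_amplitude` / `n_timepoints` | log2 8 / 16 | time-course mode: sinusoidal log2 TE oscillation of ribi genes, shared phase chosen so the 16-point grid hits both extrema |
| `start_peak_fraction` | 0.10 | footprints with P-site on the start codon (initiating ribosomes; CHX is known to pile ribosomes at starts) — without it the metagene offset estimator would have no signal |
| `luti_uorf_fraction` | 0.70 | starved-state footprints of the LUTI-like gene diverted to its upstream-ORF, outside the CDS |

The genome is one chromosome of head-to-tail single-exon genes (yeast-like;
no splicing) with ≥ 300 nt random flanks, one exactly duplicated non-ribi
paralog pair (so the crossmap mask is exercised), one GCN4-like gene, one
LUTI-like gene whose starved isoform is 5'-extended by 240 nt and carries a
real 45 nt uORF, and two dubious ORFs for the blacklist. Reads are allocated
multinomially (abundance × transcript length for mRNA; footprint density ×
CDS length for footprints), placed exactly (no sequencing errors, no
indels), and emitted with the mRNA strand flipped to mimic reverse-stranded
chemistry. Simulated alignments carry their source gene as ground truth;
BED/SAM writers drop it. Everything is deterministic under the configured
seed, and byte-identical FASTA/GFF3 across runs.

The CHX multipliers apply only in starved+CHX states. The real effect also
exists in replete cells at a much smaller magnitude; modeling it would blur
the clean factorization (starved-vs-replete with CHX shows the artifact,
without CHX shows none) that the validation checks rely on, so it is
deliberately not simulated.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: sequencing error and mapping ambiguity beyond
exact duplication, UMI/duplicate structure, rRNA contamination, nucleotide-
level biases of nuclease digestion and ligation, codon-level pausing (the
DEK codon bias affects sequence composition only; the footprint multiplier
is a free parameter, not a mechanistic model of why CHX depletes footprints
from DEK-rich messages, which remains an open question), isoform-resolved
quantification (the LUTI gene differs only in footprint placement), and
optical realism (cells are noiseless-geometry disks; segmentation results on
real micrographs will be worse).

## Compositional effects in RPKM time courses

Per-million normalization makes RPKM compositional: if a regulon carrying a
weight fraction *w* of the footprint mass oscillates 8-fold in synchrony,
library totals oscillate too, compressing the regulon's own measured
fold-range by ≈ (1−w+2.83w)/(1−w+w/2.83) and pushing every other gene into
antiphase. At w ≈ 0.15 that compression is ~40% — no per-library
normalization can recover the true amplitude — while at w ≈ 0.05 it is a few
percent. The time-course pipeline divides each timepoint's TE by its
across-gene median, which removes the *common* compositional factor exactly;
a residual bias (~5–10% at 5% ribi mass) remains because the oscillating
genes shift the all-gene median itself. This is why the default ribi
fraction is 5%: it is simultaneously the more realistic value and small
enough that the recovered median ribi fold-range sits within ~8% of the true
8-fold amplitude at the depths used.

## Problem sizes and numerical choices

Validation runs at desk scale, chosen by power analysis: 10⁶ reads/library
for the four-condition artifact experiment (per-gene log2 ratio noise
≈ 0.05, so the median ribi TE fold change estimates 1/6 to within a few
percent), 10⁵ reads/library × 100 replicate null runs for type-I control,
3×10⁵ reads/library for the 16-point course (max/min noise inflation ≈
2^(2·1.5σ) ≈ 10%), 10⁵ reads for exact P-site recovery. The acceptance
script uses 5×10⁵ and 2×10⁵ respectively. Degenerate inputs fail loudly:
empty universes, zero totals, CDSs shorter than the mask, missing
references, sub-duplicate qPCR replicates and nucleus-fills-cell cells all
raise or are excluded with a log entry. Metagene argmax ties break toward
the smaller offset; switcher and filter thresholds are inclusive
(fold-range ≥ 8; mRNA ≥ 128; footprints ≥ 1).

## Known limitations

Counting assumes CDS annotations are disjoint per (chromosome, strand) and
validates this at load; overlapping-gene resolution is not implemented. The
hypergeometric overlap test is a generic stand-in for external GO-enrichment
tooling and is not expected to reproduce any particular published constant.
Whether the grouped comparisons should be one- or two-sample is genuinely
ambiguous in the field's figures; both are computed and reported. Crossmap
is substitution-only at a single read length (26 nt default). The qPCR model
fixes amplification efficiency at 2; no efficiency calibration is provided.
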