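# Methods

This note documents the models and decision rules `njatlas` implements,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Junction model and coordinates

A splice junction is identified by `(chrom, intron_start, intron_end,
strand)` with 1-based inclusive *intron* coordinates — `intron_start` is
the first intronic base, `intron_end` the last (the STAR `SJ.out.tab`
convention). GTF coordinates are likewise 1-based inclusive; conversions
happen only at I/O boundaries. Junctions with unknown strand (STAR strand
code 0) inherit the strand of the unique overlapping gene; junctions
overlapping zero or more than one gene are classified `other` and excluded
from peptide generation, because neoantigen calls need unambiguous
transcript provenance.

### Splice-type classification

For a non-annotated junction within a single gene, classification follows
a fixed precedence against the gene's representative transcript (the
coding transcript with the highest median TPM):

1. both splice sites annotated for the gene and at least one full exon
   strictly inside the junction → **exon skip**;
2. exactly one site annotated → an alternative 3′ or 5′ splice site,
   labelled by the transcription-strand orientation of the deviant end
   (donor side → A5, acceptor side → A3) and by where that end falls:
   inside an annotated exon → **loss** of exonic sequence; inside an
   annotated intron → **gain** of intronic sequence;
3. both ends inside one exon → **in_exon**; both inside one intron →
   **in_intron**;
4. anything else → **other**.

The field's figure legends name these categories but do not define the
residual ones formally; the precedence above is this package's declared,
deterministic resolution.

### nt_delta and mutant transcripts — one primitive

Both the classifier's `nt_delta` and the neoantigen module's mutant
transcript come from a single edit rule: the mutant exon set is
`(exon union ∪ {annotated introns of the transcript overlapping the
junction}) − junction interval`, and `nt_delta` is the resulting change in
spliced-transcript length (exonic loss < 0, intronic gain > 0). Restoring
overlapped introns first is what makes splice-site shifts *into* an intron
and intron-internal junctions correctly retain flanking intronic sequence
as exonic. Frame status is `in_frame` iff `|nt_delta| mod 3 = 0` and the
junction overlaps the CDS; `frameshift` otherwise within the CDS;
`noncoding` outside it.

### Canonical partner

The spliced-frequency denominator partner is the annotated intron of the
same gene sharing the donor site, else the acceptor site; ties go to the
highest summed tumour-cohort read count, then the shortest intron. For
junctions sharing no site, the annotated intron fully containing the
junction is used, else the nearest-overlapping one, else none (an
`in_exon` junction typically has no partner and its frequency is 1 when
expressed). The containment rule for site-free junctions is a declared
choice; published methods do not specify this case.

## Cohort gates and calls

Defaults (all overridable via `ThresholdConfig`):

| parameter | default | meaning |
| --- | --- | --- |
| `purity_min` | 0.60 | tumour purity gate (inclusive); normals exempt |
| `tpm_min` | 10 | median TPM in ≥1 subtype, coding, non-mitochondrial |
| `count_min` | 10 | target spliced reads per sample |
| `depth_min` | 20 | target+canonical spliced reads per sample |
| `freq_min` | 0.01 | spliced frequency *f* = t/(t+c); 0 when t=c=0 |
| `freq_inclusive` | True | ≥ vs > at the frequency boundary |
| `psr_public_min` | 0.10 | public: tumour PSR ≥ 10% (inclusive) |
| `psr_normal_max` | 0.01 | cancer-specific: normal PSR < 1% (exclusive) |

Two readings of the count/depth filter circulate (per sample vs summed
over the cohort); both are applied — a cohort-sum pre-filter (Σ target ≥
`count_min`, Σ depth ≥ `depth_min`) before per-sample evaluation. The
frequency boundary is likewise stated both as ≥1% and >1% in different
places; the inclusive reading is the default and the strict one is a
config flag. PSR denominators use gated samples only, and junctions seen
only in normals are never emitted (the catalogue is tumour-seeded).

## Intron retention

IR ratio = intronic / (intronic + spliced), defined 0 at 0/0. The
two-group comparison is a two-sided rank-sum test (exact for groups ≤ 8,
normal approximation otherwise) with Benjamini–Hochberg adjustment across
introns — a deliberate, documented stand-in for the GLM used by dedicated
IR software; the decision criteria (|ΔIR| ≥ 0.10, adjusted p < 0.05, PSR ≥
0.10 / < 0.01) are unchanged. Published methods do not fully specify the
per-sample IR positivity rule; here a sample is flagged when its ratio
deviates from the normal-cohort mean by ≥ 0.10, and IR PSRs are flagged
fractions. Intronic read counting from alignments is out of scope: the
module consumes per-intron count tables, which the generator emits.

## Conservation tiers

Tier boundaries follow the published legend exactly: tumour-wide = 100%
of regions, highly = (70%, 100%), moderately = (30%, 70%], weakly =
(0, 30%], absent = 0. Fractions 0.7 and 0.3 therefore fall to moderately
and weakly. Tiers are driven by the *putative* rule (≥ 10 spliced reads);
the *detectable* rule (CPM > 0) is computed alongside but does not drive
tiers. The CPM denominator is the region's total unique junction reads —
library size is not recoverable from junction tables alone, and this
self-contained choice is stated in output metadata. Downsampling curves
use nested seeded subsets (a shuffled region order per draw, prefixes as
subsets), which makes each draw's curve exactly non-increasing rather
than only in expectation — testable without tolerance.

## Neoantigen candidates

Mutant transcripts are rebuilt with the edit primitive above, the CDS is
re-extracted from the annotated start codon (if the start codon is spliced
out the product is noncoding and yields nothing), and translation runs to
the first stop codon, translating frameshift tails in the new frame; if no
stop occurs before the transcript end the product is truncated there and
flagged. The junction-affected residue span is the set of codons
overlapping edited nucleotides (computed by longest common prefix/suffix
of reference and mutant CDS; a pure deletion spans its two flanking
residues), extended to the new C terminus for frameshifts.

Tiling enumerates all 8–11-mers overlapping that span, deduplicated by
sequence, each with up to 30 flanking residues per side; windows containing
an ambiguous `X` are disqualified. Tumour specificity is exact substring
absence from the reference proteome. Presentation uses two pluggable
scorer tables (peptide, allele, score) over the five prevalent HLA-A
alleles (A*01:01, A*02:01, A*03:01, A*11:01, A*24:02); percentile ranks
are computed *within the submitted tumour-specific candidate set* per
allele and scorer (scorer-internal reference distributions are out of
scope), with competition ranking so ties share the better rank. A
candidate is selected when some allele puts it in the top `q` with both
scorers. The sources conflict on `q` (top 1% in one place, top 10
percentile in another); the default is `q = 0.01` and the knob is exposed.
An MS-detected peptide confirms a junction when it matches the mutant
protein at a position overlapping the affected span and is absent from the
reference proteome.

## Subtype statistics

Burden is the count of public NJs a sample expresses under the per-sample
expression rule. Group comparisons use the same rank-sum machinery as the
IR module, BH-adjusted across subtype pairs. NJ–gene correlations are
Pearson on log2(CPM+1) vs log2(TPM+1) (the log/pseudocount choice is
declared; sources plot log2 units without stating it), averaged unweighted
across subtypes and classified positive at mean r ≥ 0.10, negative at
≤ −0.10. Differential NJs require |log2 fold change| > 1.5 (strict, on
pseudocount-1 means) and BH-adjusted rank-sum p < 0.05.

## Synthetic data: what it emulates, and what it does not

The generator emulates the *structure* of the real study inputs: STAR
junction tables for a tumour cohort, a normal cohort, and multi-region
cases; an Ensembl-style GTF with CDS records; genome and proteome FASTA;
purity/subtype metadata; TPM matrices; scorer tables; IR count tables.
Genes are random-sequence, GC≈0.5, 3–6 exons, CDS built by
back-translating a random protein so reference translation is guaranteed;
GT..AG motifs are written at intron boundaries for realism but are not
validated downstream.

Planted junctions are realized from `(splice_type, nt_delta)` against the
gene model (for exon skips the realized nt_delta is minus the skipped
exon's length). Canonical-junction reads are Poisson with mean
`read_depth_scale` (default 1000, so the depth gate is never binding by
accident); planted reads are set to hit the target frequency in
expectation and clamped to the count/depth gates, so planted truth is a
property of the emitted files, not of sampling luck. Expressing tumour
samples are a seeded shuffled prefix of ⌈PSR·n⌉ gated samples — PSR targets
are hit exactly, separating threshold logic from binomial noise. Normal
samples leak each planted junction with probability `normal_leak_rate`
(default 0). Multi-region cases express each junction in all regions
(tumour-wide) or in a ⌈fraction·regions⌉ subset (subclonal). Truth flags
are recomputed from the emitted counts with the package's own gate rules,
so the truth table is exact by construction whenever margins are ≥2× the
thresholds (the default plant specs guarantee this).

Deliberately **not** emulated: read-level data (no FASTQ/BAM), sequencing
error, mapping ambiguity, overlapping genes, multi-isoform genes, fusion
or trans-splicing, batch effects, and realistic expression covariance.
Passing tests therefore demonstrate the correctness of the decision rules
and their composition, not robustness to alignment artefacts or annotation
ambiguity in real cohorts.

## Problem sizes and numerics

The demonstration cohort used throughout the tests and the acceptance
script is 20 tumour + 50 normal samples, 30 genes, 30 planted junctions,
with 2 five-region cases; classification and translation oracles run on
1,000 and 150 random planted events respectively, and tiling oracles on
proteins ≤ 50 residues — sizes chosen so the whole suite completes in
seconds while exercising every rule at its boundaries. Exact rank-sum
p-values are used for groups ≤ 8; percentile ranks use competition
ranking; BH adjustment comes from statsmodels; translation uses the
standard nuclear codon table (ambiguous codons → `X`). Headline cohort
counts from TCGA/GTEx-scale analyses (hundreds of public NJs per tumour
type, etc.) are functions of cohort composition and are not reproduced at
this scale by design.

## Known limitations

* One transcript per gene is generated synthetically; multi-isoform
  behaviour (representative-transcript choice by median TPM) is
  implemented but only lightly exercised.
* The canonical-partner rule for site-free junctions and the per-sample
  IR positivity rule are declared choices where the sources are silent.
* External presentation scorers are consumed as score tables; adapters
  that shell out to real predictors are intentionally absent.
* The IR module's test statistic differs from GLM-based tools; borderline
  p-values will not match those tools numerically.
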