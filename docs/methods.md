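# Methods

## Coordinate and sequence conventions

All coordinates are 0-based, half-open, on the forward strand of the subject
sequence; cut positions are inter-base integers (BED-compatible). Spacer
sequences and PAMs are reported 5′→3′ on the protospacer strand; for
minus-strand sites every interval is the mirror `len − x` of the plus-strand
computation, and all strand-symmetry claims are property-tested.

IUPAC matching is strict about ambiguity in the *subject*: an `N` base in
the scanned sequence satisfies only an `N` pattern position, never a
concrete or degenerate one, and windows whose spacer or PAM contains `N` are
not reported at all. This is deliberately conservative site calling — a
dubious base should not nominate a target site.

## Nuclease models

Five built-in profiles are shipped as a YAML table (`data/nucleases.yaml`)
and can be extended with custom enzymes using the same schema:

| enzyme | PAM | side | cut model | optimal spacer |
|---|---|---|---|---|
| SpCas9 | NGG | 3′ | blunt, −3 bp | 17–22 nt |
| SaCas9 | NNGRRT | 3′ | blunt, −3 bp | ≥ 21 nt |
| NmCas9 | NNNNGATT | 3′ | blunt, −3 bp | ≥ 19 nt |
| AsCpf1 | TTTN | 5′ | staggered 18/23 nt | ≥ 19 nt |
| LbCpf1 | TTTN | 5′ | staggered 18/23 nt | ≥ 19 nt |

The Cas9 blunt offset of 3 bp is stated generically for the family; applying
it to SaCas9 and NmCas9 is a convention here, kept configurable. Likewise the
Cpf1 target-strand nick at 23 nt (hence the 5-nt 5′ overhang) follows the
standard staggered-cut literature rather than a measured value, and is a
parameter, not a constant. The upper bound (25 nt) of the open-ended optimal
ranges matches the scanner's maximum spacer length.

## Matched-site scanning

`scan_matched_sites` slides every spacer length in the requested range
(17–25 nt; 24–25 for the long-NmCas9 combo) over both strands, requiring
`TTTN` immediately 5′ and the combo's combined Cas9 motif immediately 3′ of
the spacer. Matching is vectorised per pattern position with numpy boolean
masks; results are deduplicated by (start, end, strand) — overlapping hits
of different spacer lengths at one locus are all reported, since different
lengths of the same protospacer are distinct guides — and sorted
deterministically. An invalid or too-short sequence logs a warning and
returns an empty list rather than raising, so batch scans survive malformed
records.

Seed-overlap pairing scans single-nuclease sites at one representative
spacer length (the seed depends only on the PAM position), takes the
PAM-proximal `seed_len` (7 nt) interval of each site, and reports Cas9/Cpf1
pairs whose seed intervals intersect as genomic intervals. "Overlap" is not
quantified further in the source framing, so the minimum overlap defaults to
1 nt and is configurable.

## Donor design

The donor insertion point between a Cas9 and a Cpf1 cut is the midpoint of
the Cas9 blunt cut and the Cpf1 *non-target-strand* nick (the only Cpf1 cut
annotated on locus maps), rounded toward the Cas9 cut to break half-integer
ties deterministically.

`design_ssodn` copies homology arms directly from the reference around the
insertion point and reverse-complements the assembled oligo when the
requested strand identity (NT vs T) calls for the other physical strand;
arm labels always refer to the emitted oligo's own 5′/3′ ends, so the NT and
T versions of one edit are exact reverse complements with swapped arm
lengths. PAM-proximal/-distal arm labels are resolved against an explicit
anchor nuclease recorded in the design, avoiding Cas9/Cpf1 orientation
confusion. Donors are emitted as-is: silent PAM-disrupting mutations to
prevent re-cutting are not introduced (the benchmarked oligos carried none);
an opt-in would be a straightforward extension but is intentionally not a
default behaviour.

The recommended asymmetric designs are 37/77: for SpCas9 a T-strand donor
with the 77-nt arm PAM-distal, for the Cpf1 enzymes an NT-strand donor with
the 77-nt arm PAM-proximal. SaCas9 and NmCas9 raise an explicit error — they
showed too little HDR activity for any donor recommendation to be supported.

In-silico digestion cuts at every exact occurrence of the recognition
sequence with a configurable top-strand cut offset (1 for both XbaI
`T^CTAGA` and HindIII `A^AGCTT`); fragment lengths always sum to the
amplicon length.

## Read alignment and outcome classification

Reads are aligned semi-globally (global over the read, free end gaps where
the reference overhangs) with affine scores match +2 / mismatch −2 / gap
open −6 / gap extend −1, a gap of length k costing `open + (k−1)·extend`.
The engine is Biopython's `PairwiseAligner`; an independent hand-written
Gotoh dynamic program serves as the test oracle for score optimality.
Indels in the resulting M/I/D CIGAR are shifted to their leftmost equivalent
position so CIGARs are canonical, and per-read identity is matches over
aligned columns (M+I+D). Reads below the identity threshold (default 0.75)
or shorter than the minimum length (default 30 nt) are `Unaligned` and
excluded from every denominator — this replaces a read-mapper's
mapping-quality filter, which has no analogue in direct pairwise alignment
to a short local reference.

Classification inspects only events intersecting the window spacer ± 40 bp
(clipped to the reference; in HDR mode coordinates are shifted past the
insert). A deletion intersects the window as an interval; an insertion at
inter-base position p counts when `window_start ≤ p ≤ window_end`.
Substitution-only reads are `Match`. Reads with both insertion and deletion
events in the window — a case the three-way scheme leaves open — are
labelled by the longest event, ties going to `Deletion`; any deterministic
rule would do, this one favours the event type that dominates real NHEJ
spectra. The HDR site-presence test searches for the exact recognition
sequence within the read segment aligned to the window, not genome-wide in
the read, anchoring the call to the edit locus while tolerating distant
errors. FASTQ base qualities are parsed but not used.

Incorrect-integration style ratios can be formed from the summary under
either denominator (all aligned reads, or HDR-positive reads only) since all
raw counts are reported.

## Statistics

The rank-sum test uses an exhaustive permutation null of the midrank-sum
statistic for combined n ≤ 20 (≈ 184k assignments at worst, enumerated
directly), which handles ties exactly — identical groups give p = 1 by
construction; larger samples use the normal approximation with tie
correction. The t-test is Welch's by default (paired on request; which
figures of the source benchmark were paired is not stated, so the caller
decides), and zero variance in both groups raises an explicit degenerate
error rather than returning p = NaN. Raw p-values are reported;
Benjamini–Hochberg adjustment is offered as a helper but not applied by
default, matching the source analyses. FPKM values are user-supplied
metadata; the 25-FPKM split uses strict `<` for the low group.

## Synthetic data

The simulator is the package's test harness for the classifier, not a read
simulator with platform realism. A 240-nt reference (minimum: spacer + PAMs
+ two 40-bp windows) embeds exactly one matched site; backgrounds producing
extra sites or containing the recognition sequence are resampled, so the
locus is unambiguous by construction. The default mixture (wt 0.6, indel
0.3, HDR-correct 0.07, HDR-wrong 0.03) reflects the regime the assays
measure: NHEJ dominating editing, HDR in the low percent range, erroneous
incorporation several-fold rarer than correct. Indel lengths are geometric
(p = 0.3, truncated at 25 nt) with a 50/50 insertion/deletion split — a
simplicity choice, no indel-spectrum realism is claimed. Indel positions are
sampled within ±5 nt of the Cas9 cut (intersected with the spacer),
mimicking repair locality and guaranteeing window containment; HDR-wrong
indels land anywhere in the window but clear of the inserted site.
Sequencing error is substitution-only at 0.001/base by default (bounded at
0.05), so at error 0 every truth label is exactly recoverable; candidate
indels that could left-shift under gap normalisation, or that would create
or delete a recognition-sequence occurrence, are rejected and resampled to
preserve that exactness. Simulated sequencing indels are deliberately
excluded — adding them would make truth recovery approximate.

Consequences for interpretation: passing tests show the classifier is exact
on unambiguous molecules and calibrated under substitution noise; they do
not exercise homopolymer sequencing indels, quality decay, PCR duplicates,
chimeric reads, or large structural outcomes, all of which real amplicon
data contain.

All randomness flows through `numpy.random.default_rng` seeded from one
mandatory integer (fixture and read generation use distinct child streams),
so outputs are byte-identical across runs and platforms.

## Problem sizes

The shipped verification runs use sizes chosen to make the checks decisive
while staying lightweight: 500 random pairs (≤ 60 nt) for the
aligner-vs-oracle comparison, 100 × 2-kb sequences per combo in the test
suite (30 × 1-kb in the acceptance script, where the naive oracle dominates
the cost) for scanner equivalence, 10,000 reads for mixture recovery, and
1,000 replicates for t-test calibration.

## Known limitations

* Scanning is naive-window based and meant for amplicon/locus-scale input,
  not genome-scale search; no uniqueness/off-target filtering is applied.
* The recommender encodes the benchmark's qualitative conclusions as fixed
  rules; it does not re-derive them from user data.
* The paired-end merging, UMI, and variant-calling layers of production
  amplicon pipelines are out of scope, as is subtyping of deletions by
  microhomology.
* SaCas9/NmCas9 cut offsets and the Cpf1 target-strand nick offset are
  conventions (see above), configurable but not experimentally anchored
  here.
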