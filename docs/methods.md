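# Methods

This note records the models, parameter choices and numerical conventions
behind `tdnascope`, and what the synthetic data generator does and does
not emulate.

## Coordinates and conventions

All genomic intervals are 1-based inclusive; BED export converts to
0-based half-open. A blunt insertion is encoded as `del_end = del_start -
1`. The canonical T-DNA is written 5'→3' with LB starting at position 1
and RB ending at position L; "forward" insertion places this sequence on
the host + strand. The source study never defines its forward/reverse
labels relative to a reference; any consistent convention reproduces a
"one forward, one reverse" pair, and this one makes the orientation truth
table (side, relative strand, LB/RB-proximal end) self-evident.

Border truncations are measured from the extremes of vector coverage, not
from the 25-bp border-repeat annotation, so losses larger than the repeat
(26, 34, 35 bp in the emulated line) are representable. A consequence
visible in reports: a truncation ≥ 25 bp removes the entire border repeat
and the LB/RB *feature* is then reported absent — this is bookkeeping,
not information loss, since the truncation lengths are reported
separately.

The junction coordinate of a read is the retained host base adjacent to
the T-DNA. The removed host interval of a call is
`[left_junction + 1, right_junction - 1]`, which matches the inclusive
interval style in which insertion sites are reported in this literature
(width = end − start + 1; 33 and 27 bp for the emulated line).

Neighbor-gene distance is the plain boundary difference between the
insertion interval and the nearest gene boundary (no ±1): this convention
reproduces all five published distances (9,466 / 8,137 / 15,621 / 1,543 /
11,914 bp) exactly from the published coordinates. Both a site-relative
label (gene upstream/downstream of the insertion) and a gene-frame label
(insertion upstream/downstream of the gene 5'→3') are emitted, because
published tables and prose use the two perspectives inconsistently.

## The mapper

A deliberately small seed–chain–extend split-read aligner keeps the
package self-contained at desk scale (references up to a few Mb); SAM
import is the escape hatch for real-scale data mapped externally.

- Seeds: exact k-mers, both strands; k = 15 for short reads, 13 for long
  reads; k-mers with > 64 occurrences are dropped. Long reads sample
  seeds at stride 5 and chains with < 3 seeds are discarded as noise.
- Chains: seeds grouped per (target, strand), split where the diagonal
  jumps by more than the band (50 bp). A chain with ≥ 90% of seeds on one
  diagonal is verified gapless in numpy (exact for the substitution-only
  short-read model and error-free long reads); drifting chains are
  extended with an edit-distance path (edlib) and rescored.
- Scoring: match +1, mismatch −2, gap open −4, gap extend −1; a gap of
  length g costs 4 + g (open charged once plus per-base extension). The
  exact Smith–Waterman oracle used in tests implements the same scheme
  with a row-vectorized Gotoh DP whose horizontal-gap state is a prefix
  maximum (exact, because re-opening inside an existing gap is never
  optimal).
- X-drop segmentation: a candidate segment is split wherever its running
  score falls more than 30 below its running maximum. Without this,
  Kadane-style trimming happily bridges a multi-kb inverted or foreign
  block as a mismatch valley between two strong flanks — real local
  aligners terminate extension instead, and split-read SV signatures
  depend on that behavior.
- Ties are broken toward the shortest segment and ordered by (score,
  target, position), so output is deterministic.

## Junction logic and microhomology

A junction read must carry host and vector segments adjacent on the read:
query overlap ≤ 5 bp (microhomology allowance) and query gap < 50 bp
(room for short filler DNA). The gap bound matters: a long carrier read
can also cross an unrelated structural variant, and without an adjacency
requirement its distal host segments would fabricate junction evidence at
the SV boundary.

Junction microhomology is treated as a property of the *data*, not the
caller: when the first inserted base equals the host base it replaced, no
aligner can place the breakpoint uniquely. The generator therefore plants
events whose junctions carry no score-gaining extension (a prefix-sum
condition on the match/mismatch scores across each junction, checked over
a 50-bp window), and the preset scans forward from the nominal midpoint
position until all junctions are clean. This is why exact (0-bp) recovery
is a fair test. Real data does not offer this guarantee; on real reads
breakpoints are accurate only up to microhomology, as with any caller.

## Long-read resolution and consensus

Spanning reads need ≥ 200 bp of host alignment on each flank (guards
against spurious short host hits inside filler DNA) on the same strand
and chromosome as the call; reads whose flanks disagree with the call
chromosome are left to the SV screen as translocation evidence. The
deletion interval is the coordinate-wise lower median of per-read gaps.
The consensus is a star alignment: the medoid insert (minimum total edit
distance) is the column frame; per-column votes (bases, deletions, and
majority insertions) decide the sequence, ties broken A < C < G < T.
Medoid-star was chosen over partial-order alignment as adequate,
deterministic and testable at ≤ a few dozen reads per site; with ~8
spanning reads at 5% combined error it recovers a 6-kb insert to > 99.5%
identity (tested), which keeps truncation and filler measurements within
±2 bp.

## SV screen

Split-read signatures per adjacent host-segment pair: DEL (reference gap
≥ 50 bp, small query gap), INS (query gap ≥ 50 bp; any small reference
gap alongside is the target-site deletion accompanying an insertion), DUP
(reference overlap > 50 bp), TRA (different chromosomes). INV requires
the minority-strand segment to be flanked by majority-strand segments on
both sides within one read: single-boundary reads yield half-open
intervals that cannot be clustered reproducibly across samples and are
discarded (full-spanning coverage is plentiful at 40×; this trades a
little sensitivity for a subtraction that actually cancels).
Signatures cluster per type when both breakpoints agree within 100 bp;
events need ≥ 3 supporting reads. Subtraction removes a transgenic event
when a same-type wild-type event has both breakpoints within 500 bp
("same position" is undefined in the source study; 500 bp is configurable
and logged). The rearrangement rule keeps events strictly longer than
1 kb outside the insertion sites ± 1 kb; translocations are flagged
regardless of length (the length rule is unstated for them; flagging
unconditionally is the conservative reading and is noted in the report).

## In-silico PCR and the verification scheme

PCR is combinatorial, not thermodynamic: a primer binds at exact matches
(a mismatch budget is available; the 3'-terminal base must always match)
and every convergent site pair within 5 kb yields a product. Per site the
designer emits host-left/host-right 20-mers (GC 40–60%, unique in the
locus ± 5 kb) and two T-DNA internal primers, giving five combinations:
two junction combinations consistent with the called orientation
(transgenic-only bands), the two opposite-orientation controls (silent),
and one locus-spanning combination. For a hemizygous insertion the
spanning product amplifies the wild-type allele present in both samples,
while the transgenic allele's product exceeds the size limit — hence the
4 / 4 / 2 partition across two sites.

## Zygosity

The reference-allele fraction is computed over long reads covering the
site ± 200 bp: contiguous single-segment coverage is the reference
allele, split coverage the insertion allele. Verdict thresholds 0.1/0.9
are wide enough to be stable at 30–40× (a triploid single-carrier site
has expectation 2/3 with binomial noise ~0.08 at this depth).

## The generator and what passing tests mean

The generator emulates: hemizygous single-copy insertions with border
truncations, target-site deletions, fillers engineered to share no
15-mer with host or vector (so "unknown origin" is decidable), an
internally deleted cassette, configurable ploidy via weighted haplotype
sampling, shared background SVs present in both samples, 150-bp
paired-end reads (substitution-only errors, constant quality encoding the
error rate) and log-normal long reads with substitution+indel errors and
a 500-bp emitted-length floor. Long-read lengths default to median 20 kb
(σ_log 0.4): at 40× this yields ~8–14 reads fully spanning an ~6-kb
insert per site, enough for a stable consensus under any seed.

It does not emulate: empirical quality profiles, chimeric reads, PCR
duplicates, homopolymer-biased Nanopore errors, repeat-rich host
sequence, or vector-backbone integration. Passing tests therefore show
the *logic* is correct under a clean but faithfully structured model;
they do not bound performance on repeat-dense real genomes, where
multi-mapping and microhomology dominate the error budget.

Problem sizes in the test suite — two 150-kb chromosome analogs, 30×
short reads, 40× long reads, a 3-kb construct for the randomized
recovery suite — were chosen as the smallest sizes at which every
quantity of interest (five neighbor distances within 20 kb, multi-kb
background SVs, ~6-kb inserts) fits with realistic margins.

## Known limitations

- The randomized exact-recovery suite covers single-copy events; tandem
  arrangements are exercised with constructed alignments (truncation
  semantics inside tandem arrays are ambiguous without per-copy
  phasing).
- Background translocations can be detected but not planted by the
  generator.
- The consensus is unweighted by base quality; at error rates well above
  ~10% the medoid-star approach will degrade before a quality-aware
  polisher would.
- `run_pipeline` currently sources data from the built-in preset (or its
  wild-type negative control); real data enters through the per-stage
  CLI (`map` onward) and SAM import instead.
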