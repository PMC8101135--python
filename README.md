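# tdnascope

Molecular characterization of T-DNA integration in transgenic plant
genomes from whole-genome resequencing data.

When an *Agrobacterium* binary vector delivers its T-DNA into a plant
genome, the integration event is messy: the left and right border (LB/RB)
ends of the transferred unit are usually truncated, a few dozen host bases
at the target site are deleted, short "filler" DNA of unknown origin can
appear at a junction, cassette features may be missing, and — rarely —
integration triggers larger chromosomal rearrangements. Regulators and
molecular biologists characterizing a transgenic line need all of these
quantities: the insertion sites and orientations, the target-site
deletions, the border truncations, the copy number and arrangement, the
zygosity, and the genes near or disrupted by each insertion.

`tdnascope` implements this characterization as a reusable pipeline over
short paired-end reads (junction detection) and long Nanopore-style reads
(full insert reconstruction and structural-variant screening), together
with a synthetic transgenic-genome and read generator so that every stage
is testable without external data.

## What the pipeline computes

For a host genome $H$, a canonical T-DNA unit $T[1..L]$ (LB starting at
position 1, RB ending at $L$), and read sets from a wild-type and a
transgenic sample:

- **Junction calling (short reads).** A junction read aligns partly to
  the host and partly to the vector; its host-segment boundary pins one
  side of an insertion. Junctions are clustered per (chromosome, flank
  side, vector end); paired left/right clusters become an insertion call
  with removed host interval $[\ell+1, r-1]$ where $\ell, r$ are the last
  and first retained host bases. Orientation follows a truth table over
  (flank side, relative strand, LB/RB-proximal vector end).
- **Insert resolution (long reads).** Reads whose host alignments flank a
  site on both sides localize the target-site deletion (coordinate-wise
  median of per-read gaps) and carry the complete insert, which is
  extracted, strand-normalized, and collapsed to a consensus by star
  alignment against the medoid insert with per-column majority vote.
- **Insert characterization.** The consensus is locally aligned back to
  $T$; border truncations are `min(covered) - 1` and `L - max(covered)`,
  feature presence is coverage of each feature interval (threshold 0.5),
  uncovered sub-intervals ≥ 10 bp are fillers (re-mapped to the host to
  decide known vs unknown origin), and unit traversals give the copy
  count and arrangement (single / tandem-direct / tandem-inverted).
- **Differential SV screen.** Split-read signatures (DEL/INS/INV/DUP/TRA)
  are clustered per sample; transgenic events matched by a same-type
  wild-type event within 500 bp are subtracted, and remaining events
  longer than 1 kb (plus any translocation) outside the insertion sites
  are flagged as putative insertion-induced rearrangements.
- **Verification and context.** An in-silico PCR engine predicts the band
  pattern of the junction / wrong-orientation / locus-spanning primer
  scheme; zygosity is the reference-allele fraction among site-spanning
  long reads; neighbor genes within 20 kb and disrupted genes (with the
  exon/intron hit) come from the GFF3 annotation.

The internal mapper is a seed–chain–extend split-read aligner (exact
k-mer seeds, diagonal chaining, gapless or edit-distance extension with
X-drop segmentation, scoring match +1 / mismatch −2 / gap open −4 /
extend −1) and is validated against an exact Smith–Waterman oracle. SAM
import/export provides an escape hatch for alignments from external
mappers.

## The built-in study design (`pb29` preset)

The preset plants a triploid, hemizygous design with two single-copy
insertions on two 150-kb chromosome analogs: site A (reverse orientation,
33-bp target-site deletion, LB/RB truncations 26/3 bp, a 24-bp unknown
filler on the right junction) and site B (forward, 27-bp deletion,
truncations 35/34 bp), both with the 2-kb "35S-API-Nos" cassette missing
from the inserted unit. Neighbor genes sit at boundary distances 9,466 /
8,137 / 15,621 / 1,543 / 11,914 bp and one gene's first exon spans site
A. Three >1-kb background SVs are shared by the wild-type and transgenic
samples, so a correct differential screen flags nothing.

## Worked example

```
$ tdnascope run --outdir out --seed 42
```

runs simulate → filter → map → call → resolve → characterize → SV screen
→ zygosity → annotate → in-silico PCR and writes `report.json`,
`insertions.bed`, `inserts.fasta`, `rearrangements.vcf` and
`summary.txt`. The summary for seed 42 reads:

```
tdnascope 0.1.0 integration report
config hash e68346f8f1622fd1, seed 42
insertion sites: 2
  Chr03:75001-75033 orientation=reverse deletion=33 bp
    LB/RB truncation 26/3 bp, 1 copy (single), absent features: LB, 35S-API-Nos, fillers: 24 bp (right)
    zygosity: heterozygous (reference allele fraction 0.7174)
  Chr10:75002-75028 orientation=forward deletion=27 bp
    LB/RB truncation 35/34 bp, 1 copy (single), absent features: LB, 35S-API-Nos, RB, fillers: none
    zygosity: heterozygous (reference allele fraction 0.7179)
flagged rearrangements: 0
```

Reading: the Chr03 insertion removed host bases 75,001–75,033 (33 bp) and
carries a reverse-oriented single T-DNA copy missing 26 bp from the LB
end and 3 bp from the RB end, with a 24-bp right-side filler that does
not map to the host; a reference-allele fraction near 2/3 is exactly what
one carrier haplotype in a triploid predicts; no rearrangement survives
the wild-type subtraction and >1 kb rule. (The LB feature is reported
absent at both sites because the truncations remove the whole 25-bp
border repeat — the RB likewise at site B.)

Per-stage subcommands (`simulate`, `map`, `call-ngs`, `resolve`,
`characterize`, `svdiff`, `pcr`, `annotate`) expose the same operations
over files; `tdnascope map` writes SAM, `call-ngs` consumes SAM from this
or an external mapper.

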