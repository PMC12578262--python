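# Methods

This note documents the models and procedures implemented in `circorf`,
their assumptions, the parameters that matter, and what the synthetic
fixtures do and do not demonstrate.

## Back-splice detection

Detection is self-contained and deterministic: an exact k-mer index of the
genome replaces a short-read aligner. From each read, the first and last
20 nt are looked up (both strands, via reverse complement of the query);
a pair of same-chromosome hits in inverted order — the read prefix mapping
*downstream* of the read suffix — is the head-to-tail geometry of a
back-splice. Both anchors are extended toward each other and the read is
accepted only if some breakpoint reconstructs it exactly (zero mismatches)
as two genomic segments.

Numerical choices:

* **Splice signal.** The genomic dinucleotides flanking the junction must
  read GT immediately after the donor and AG immediately before the
  acceptor, in gene orientation (strand-aware). A policy switch
  `{enforce, report, ignore}` controls whether non-canonical junctions are
  dropped, flagged, or passed.
* **Breakpoint ties.** When the bases flanking both junction sides repeat,
  several breakpoints reconstruct the read, each implying coordinates
  shifted by the repeat length. These junction-shift variants all come from
  the same anchor-hit pair and are canonicalized by preferring
  splice-signal-consistent breakpoints, then the 5′-most breakpoint in read
  coordinates. Reads with placements on several distinct anchor-hit pairs
  (or on both strands) are genuinely ambiguous and yield no call, with a
  logged reason.
* **Support.** Candidates are grouped by (chromosome, strand, acceptor,
  donor); "unique back-spliced reads" counts distinct read *sequences*, so
  PCR duplicates contribute one unit of support. The default threshold is
  2 unique reads.
* **Spliced sequence.** When a call's span coincides with an annotated exon
  run on the same strand, its sequence is the exon join (the exonic-circle
  case); otherwise the genomic span. Minus-strand sequence is
  reverse-complemented at extraction, so all downstream code sees the
  circle 5′→3′. Calls whose spliced sequence contains N are dropped with a
  logged reason — translation of an undefined base is never attempted.
* **Origin classes.** Precedence when several labels apply: exact
  exon-boundary join (with UTR/CDS sub-labels by base overlap of the
  circle's transcript-coordinate span) > exon–intron > intron > antisense >
  intergenic. Gene-derived labels require same-strand overlap.

Known limitation: the detector reconstructs a read as exactly **two**
genomic segments, so a back-splice read whose half additionally crosses an
internal linear splice junction of the circle is not recovered. Anchor
matching is exact; mismatch-tolerant alignment is out of scope.

## Circular ORF prediction

The circle is linearized as four concatenated copies — enough for an ORF to
wrap the junction three times, which distinguishes terminating from
non-terminating frames at any length. Per frame, ORFs start at ATG (a
near-cognate policy reusing the smORF codon list is available as a config
switch; ATG-only is the default because initiator-mutation controls in this
field use ATG→ACG) and run to the first in-frame stop, or to the end of the
concatenation with `has_stop=False`. Only ORFs whose codon span covers a
junction boundary (a multiple of L strictly inside the span, the stop codon
included) qualify; the longest per frame is kept, ties to the 5′-most
start.

* **MOEBIUS.** A circle is a rolling-circle template iff L ≡ 0 (mod 3) and
  at least one frame has no stop codon anywhere around the circle (checked
  on one period of the doubled sequence; rotation-invariant by
  construction). A stop-free frame with no start codon is still reported,
  anchored at the frame offset with no start codon — the non-terminating
  frame exists regardless of initiation.
* **Score.** S = 100·K + 1000·H + (len(aa)/1,010,000)·M, read
  left-to-right so the length term contributes only for MOEBIUS ORFs and
  stays below the flag terms; the alternative parse (standalone length term
  plus a bare MOEBIUS flag) is available as `score_variant=additive_len`.
  Among equal scores, longer ORFs rank first, then 5′-most start.
* **KNOWN_START** maps the ORF's first base through the circle's exon
  blocks back to genomic coordinates and compares it with the host
  transcript's annotated start-codon base, strand-aware.
* **Junction residue.** The amino acid whose codon contains the first
  junction boundary inside the ORF. When the ORF start is codon-aligned
  with the circle length (every MOEBIUS fixture: start at circle position
  0, L ≡ 0 mod 3) no codon straddles the boundary and the first residue of
  the next period is used. If the boundary codon is the stop codon, no
  junction residue exists and the ORF contributes no peptide.

## Ribosome footprints

Footprints of 27–32 nt are retained (the mononucleosome-protected length
range). Per circle, a junction window of the last 31 + first 31 nt
(wrapping circles shorter than the flank) centers the back-splice point; a
footprint is assigned iff exactly one circle's window admits an exact
placement covering the center with ≥ 6 nt on each side, and the read does
not occur exactly in the linear transcriptome or genome. The latter check
is a desk-scale stand-in for cross-referencing genomic rearrangements and
repeat annotations; no repeat database is consulted, a documented
simplification. Unique-footprint support is deduplicated by read sequence;
the ribo-circRNA threshold defaults to 1 unique junction footprint (the
stricter ≥ 20 criterion is a configuration choice).

Translation efficiency is TE = (ribo + c)/(circ + c) on counts-per-million
junction reads per library (`norm="cpm"`, invariant to joint library
rescaling; raw counts available), pseudocount c = 0.5 everywhere a ratio
could divide by zero. The conjoint GM/DM classification calls a level "up"
at fold change ≥ 2 and "down" at ≤ 0.5 on GM/DM-oriented ratios; any level
in between collapses the pair to "unchanged". Only the raw fold-change
arithmetic is implemented; dispersion-based significance testing is out of
scope. P-site offsets and 3-nt periodicity are not modelled — junction
coverage, not codon phasing, is the evidence used here.

## Junction peptide databases and smORFs

Proteins of junction-crossing cORFs are combined with the reference
proteome; metadata (circle id, junction residue, frame, repeat-unit flag)
round-trips through FASTA headers. A MOEBIUS product is theoretically
infinite, so its database entry is one repeat unit plus 40 residues of
junction-overlapping context, flagged as a repeat unit. In-silico trypsin
cleaves after K/R except before P; fragments tile the protein, and with m
missed cleavages every concatenation of ≤ m+1 adjacent fragments is
emitted (the pipeline enumerates junction peptides with the usual MS search
allowance of 2). Novelty is exact substring search against the proteome;
an I/L-equivalence switch exists for the MS-realistic match but is off by
default, matching a plain string-search contract.

smORF annotation locates an identified peptide by exact match in the
3-frame translations of the supplied RNA records (the pipeline supplies the
4× circle sequences; mismatch-tolerant homology search is not
implemented). Scanning upstream in frame — capped at 1,000 codons so
stop-free circular frames terminate — the start is the 5′-most in-frame
ATG above the upstream stop, else the 5′-most near-cognate codon
(GTG/ACG/CTG/AGG/AAG/ATT/ATC) passing the minimal strong Kozak test
(purine at −3, G at +4; a truncated context fails), else the codon after
the upstream in-frame stop. The stop-to-stop span counts codons strictly
between the flanking in-frame stops (sequence edges bound the count);
under 150 codons marks a smORF.

## Synthetic fixtures

The generator emulates the structure of a paired myoblast (GM) / myotube
(DM) circRNA-seq + ribosome-profiling study: by default 20 single-transcript
genes (alternating strand, one per chromosome, 4–6 exons of 100–160 nt,
introns of 60–120 nt with forced GT/AG signals over a uniform-ACGT
background), 10 planted exonic circles spanning internal exon runs, of
which 2 are MOEBIUS, 3 GM + 3 DM samples with 5 back-spliced reads of
100 nt per junction per sample, 8 junction footprints per translated circle
per sample, and footprints on the first 5 circles. Each circle-hosting
gene's CDS starts at the first base of the circle's first exon, so the
circle reads ATG + stop-free codons across one period: every planted circle
carries a junction-crossing ORF with an annotated start, MOEBIUS circles
get a run length divisible by three, others explicitly not. Decoys cover
both false-positive classes the stringency rules guard against: contiguous
mature-mRNA fragments (linear reads), point-mutated junction reads and
footprints (the zero-mismatch rule), and out-of-window footprint lengths.

Two constructive guarantees keep the planted truth honest rather than
tuned: (i) a gene hosting a *translated* circle is resampled from its own
seed substream until the circle's junction-spanning tryptic peptide (up to
2 missed cleavages) is at least 7 residues and absent from the linear
proteome — shorter or host-matching peptides are exactly the ones an MS
search could never attribute to the circle; (ii) a planted footprint whose
short overhang happens to continue identically into the host mRNA past the
junction is linear-indistinguishable and is redrawn, because the
linear-decoy rule would rightly reject it. Back-splice read offsets keep
each read half within the circle's terminal exon so the read reconstructs
as exactly two genomic segments (see the detection limitation above).

What passing fixture tests show — and what they do not: recovery is
demonstrated on noise-free, uniquely-mappable, single-isoform toy genomes
with exact reads. Real data add sequencing errors, multi-mapping and
repeats, isoform complexity, rRNA contamination and coverage biases, none
of which are modelled; error models, GC bias and expression effect sizes
beyond per-group depth are explicit non-goals. The fixture scale (10
circles, ~40 kb genome) was chosen so the full pipeline and test suite run
in seconds on one CPU; all counts and thresholds are configurable.

## Determinism

Every source of randomness derives from a single integer seed through
per-stage, per-sample, per-gene substreams; reruns are bit-identical, and
the serialized configuration plus its hash are written into every run
directory so any output can be audited against the thresholds that
produced it. Every discarded item (short read, ambiguous placement,
non-canonical junction, under-supported candidate, rejected footprint)
emits one structured log line with its reason.
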