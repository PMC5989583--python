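# Methods

## Scope and model

The package operationalises a comparative-genomics workflow for bacterial
carotenogenesis: identify *crt* orthologues in an annotated genome, read
the chromosomal organisation of the hits, corroborate them with family
motifs, and translate gene presence/absence into a pigmentation group and
a set of producible carotenoids.  It deliberately stops short of de novo
gene prediction, multiple alignment, phylogenetics and structure
prediction; annotations are taken as given.

## Coordinates and genome I/O

Internal coordinates are 0-based half-open throughout; the 1-based
inclusive convention of GenBank/GFF3 is converted exactly once at the
parse/write boundary.  This makes overlap and gap arithmetic pure interval
arithmetic (`overlap = max(0, min(ends) − max(starts))`).  GenBank I/O goes
through Biopython; GFF3 is the package's own small dialect (CDS rows with
`locus_tag`, `product` and `translation` attributes plus a paired FASTA),
chosen so that write∘parse∘write is byte-stable and unknown-strand
features (seen in draft genomes) can be expressed with `.`.  When a CDS
lacks a stored translation it is derived from the nucleotide sequence
under translation table 11; compound (join) locations are flagged and
their protein taken from the annotation only.  A CDS with neither
translation nor sequence is skipped with a warning rather than failing the
whole parse.

An optional curation pass re-assigns CDS starts to an in-frame upstream
candidate (preferring ATG > GTG > TTG > CTG, nearest first, never crossing
an in-frame stop, 90 bp window by default).  It is off by default: it is a
reproducible stand-in for the manual start-codon curation that annotation
pipelines often require, and should only be enabled deliberately.

Multi-record files are treated as draft genomes (contigs as replicons);
adjacency is never asserted across contigs.

## Orthologue calling

The search is an exhaustive blastp-style screen without heuristic seeding:
every annotated protein is aligned to every panel query with full
Smith–Waterman dynamic programming, affine gaps (open 11, extend 1, i.e. a
gap of length L costs 11 + L) and BLOSUM62.  `X` is accepted and scores 0
against everything.  Traceback is deterministic with ties resolved
diagonal > up > left.  Raw scores convert to bit scores and E-values via
the Karlin–Altschul relations, `bit = (λS − ln K)/ln 2` and
`E = mn·2^(−bit)`, with the published gapped BLOSUM62 constants λ = 0.267
and K = 0.041 by default.  The search space *n* is the summed proteome
length, mirroring a database search over one proteome; agreement with any
particular search tool's E-values is explicitly not a goal — the criteria
are thresholds and the package's own tests operate far from them.

A candidate is accepted iff all four criteria hold: identity ≥ 0.30
(identical columns over *all* alignment columns, gaps included in the
denominator — the common BLAST convention, chosen because the source
criteria do not fix a denominator), length difference < 0.20 of the query
length, bit ≥ 50 (inclusive) and E < 10⁻¹⁰ (exclusive).  Among accepted
candidates the highest identity wins; ties break by bit score, then by
smallest locus tag.  Synteny is never used to discard a hit — locus
context is reported downstream as annotation, not applied as a filter.

The DP fill is numba-compiled (with an equivalent pure-Python fallback),
which keeps an exhaustive screen of a full proteome against a ten-query
panel in the sub-second range.

## Locus architecture

A locus is a maximal run of accepted hits on one replicon in which
consecutive members are separated by ≤ 3 intervening CDS **and** ≤ 10 kb;
both knobs are configurable.  The numbers operationalise "adjacent" and
"1–3 separating ORFs" as observed in the cohort; no bp bound is stated in
the source material, so 10 kb was fixed once as a generous same-locus
distance.  Accessory orthologues (LOG, DUF2141) count as locus members,
never as separating ORFs.

Pattern labels are a pure function of membership, order, strand and decoy
counts: `P1_contiguous` (crtY/I/B/G in one locus, zero decoys between
consecutive members), `P2_crtG_separated` (Y/I/B contiguous, G in the same
locus 1–3 ORFs away), `P3_atypical` (all four in one locus but the Y/I/B
trio on mixed strands — the translocated-prototype case),
`P4_YIB_together` (Y/I/B co-located, G elsewhere or absent),
`P5_YIG_together` (Y/I/G co-located, B elsewhere), `scattered`, and
`partial` when fewer than three of B/I/Y/G are present at all.

"Immediately upstream/downstream" flags (crtW vs crtZ, crtX vs crtW) are
reported strand-aware — read along the reference gene's direction of
transcription — with the plain coordinate-order convention available via
`relative_position(..., strand_aware=False)`.  The crtY–crtI record
(`co_located`, `co_oriented`, overlap or gap in bp) feeds a cohort summary
with the count of overlapping strains, the modal overlap and the gap
range.

PGC (photosynthesis gene cluster) detection is an explicitly labelled
heuristic: ≥ 6 accepted hits from an optional photosynthesis panel within
one 50 kb window.  It only ever adds a caveat.

## Motifs

Motif patterns use the compact literature notation (fixed letters, `x`,
`(x)n`/`(x)_n` runs); no alternations or ranges — this is intentionally
smaller than the PROSITE grammar.  "Near the N-/C-terminus" is a 60-residue
window (configurable; the sources give no number).  CrtW is motif-complete
only with HDxxH plus at least two HxxHH occurrences — their spacing is not
constrained, only the count.  Motif presence corroborates a call; it never
rejects one.

## Pathway reachability

The default graph has 16 reactions from the IPP/DMAPP precursor pool
through GGPP, phytoene, lycopene and β-carotene to the xanthophylls, the
IPP↔DMAPP isomerisation being the single reversible edge; DMAPP also feeds
cytokinin via MiaA + LOG.  The astaxanthin route is modelled from
zeaxanthin through adonixanthin under CrtW alone — an interpretation of
the branchpoint scheme, since full stoichiometry is not given.  CrtG
acting on astaxanthin (2-hydroxyastaxanthin, known from *Brevundimonas*)
is left out of the defaults but can be declared in the TSV edge-list
override, as can the spirilloxanthin branch (CrtC/CrtD/CrtF).

A compound is producible iff reachable from the precursors using only
edges whose full enzyme set is present (fixed-point closure); terminals —
producible non-precursors with no applicable outgoing edge — approximate
accumulation, since transient-vs-accumulating kinetics are not modelled.
IDI is treated as housekeeping and always supplied by the classifier.

## Genotype groups

With core = {crtE, crtB, crtI, crtY, crtZ}: group IV iff the core is
incomplete; I = core + crtG; II = core + crtG + crtW; III = core + crtW;
a complete core alone is "unassigned" with a `zeaxanthin_only` caveat
(zeaxanthin producers can look yellow, orange or in between).  crtX never
changes the group — it only extends products with glycosides — and the
hypothetical core+G+W+X genotype is therefore group II.  Any non-IV strain
carries a `possible_cryptic_colourless` caveat: strains with a full colour
genotype but a dysfunctional or repressed crtB/crtI are known.  Predicted
carotenoids are the coloured terminals plus the co-accumulating
intermediates reported for the cohort (caloxanthin alongside nostoxanthin,
adonixanthin alongside astaxanthin).

Consistency between the group label and the pathway output is enforced at
run time (group I must reach nostoxanthin, II/III astaxanthin).  One
boundary is deliberately looser: a *hypothetical* core-incomplete genotype
such as {E,B,I,Y} still reaches coloured intermediates (β-carotene), so
"group IV implies nothing coloured" cannot hold over all 2⁸ genotypes; it
does hold for every genotype lacking crtE, crtB or crtI, which covers all
attested non-pigmented strains.  The hypothetical case is flagged with a
`coloured_intermediates_possible` caveat instead.

## Synthetic data

The generator is the package's study-condition definition, not a tuning
dial.  The reference panel is itself synthetic — random proteins of
family-typical lengths (CrtE 300 aa, LOG 193 aa, CrtI 490 aa, …) with the
family motifs stamped at fixed positions — so no real sequence is ever
bundled or downloaded.  Planted orthologues are diverged to a target
local-alignment identity (default 0.60, the realistic middle of reported
orthologue identities; the package aligner is the defining oracle, ±0.02)
by BLOSUM-plausible substitutions plus a few single-residue indels, with
motifs re-stamped afterwards.  Decoy ORFs are unrelated random proteins.
Intergenic spacers are uniform 50–300 bp except where an exact crtY–crtI
overlap (1–8 bp; multiples of 3 are rejected because they would place the
upstream stop codon in frame inside the downstream ORF) or gap (6–25 bp)
is planted; separate regions are isolated by > 3 decoys and > 10 kb.  For
overlapped pairs the downstream ORF's first bases are taken from the
upstream ORF's tail and its protein re-derived from the genome, so DNA and
annotation stay mutually consistent.  Default genome: one 60 kb replicon
at G+C 0.62 (within the cohort's 0.56–0.68 range).  Same seed ⇒
byte-identical output.

What the generator does *not* emulate: realistic codon usage, genuine
evolutionary divergence along a phylogeny, paralogous gene families,
annotation errors.  Passing recovery tests therefore demonstrates the
pipeline's correctness on clean annotations with controlled divergence,
not robustness to mis-annotation.

The packaged 41-strain cohort table (strain, species, genome status, crt
genotype, group, colour, PGC flag) is checksum-verified at load; it
supports the genotype-level cohort statistics exactly and deterministically.

## Problem sizes and numerical choices

Recovery tests run all six architecture templates × 20 seeds (120 genomes,
~28 CDS each) — small enough to screen exhaustively in well under a
minute of alignment time while exercising every template and both
crtY–crtI junction types.  Aligner equivalence against the exponential
enumeration oracle is exhaustive over all peptide pairs up to length 2–3
on a 4-letter alphabet plus a seeded random sample up to length 6 (the
full ≤ 6 cross-product is astronomically large for an exponential oracle);
an independent library implementation provides a second cross-check at
realistic lengths.  Pathway closure is verified against brute-force BFS
for all 2⁸ enzyme subsets.  All randomness in tests and in the acceptance
script derives from fixed or supplied seeds.

## Known limitations

* Identity/length-difference denominators are conventions (alignment
  columns; query length); other choices shift borderline calls.
* E-values are analytic Karlin–Altschul values, not composition-adjusted;
  they are used only against a generous threshold.
* Terminal compounds are a coarse proxy for accumulation; colour intensity
  and carotenoid quantities are out of scope.
* The PGC window heuristic and the 3-ORF/10-kb locus bounds are pragmatic
  defaults, all configurable.
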