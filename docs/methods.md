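# Methods

This note documents the models and procedures implemented in `paleoerv`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## The system being modeled

SERV-K/MER11 is a clade of HML-2-related endogenous retroviruses found in
Old World monkeys (and, by interspecies transmission, gibbons). Its
members share a diagnostic architecture: short (~588 bp) LTRs with large
U3 deletions, an *env* gene whose C-terminal region derives from an
HML-8-like virus, and a ~726-bp non-coding region between *env* and the
3′ LTR derived from an HML-8 LTR (annotated MER11A by RepeatMasker),
followed by a short *env*-derived remnant containing the polypurine tract.
The toolkit implements the genome-scale procedures used to characterize
such a clade: locus discovery from repeat annotations, structural
annotation, LTR-divergence dating, cross-species orthology, splice-form
detection, and reporter-assay quantification.

## Mining

Repeat tracks report one provirus as several records. Loci are rebuilt by
merging whitelisted records (`LTR5_RM`, `LTR5B`, `HERVK-int`, `MER11A`)
whose gap (`next.start − prev.end`) is ≤ `max_gap` (default 1000, taken
inclusive to match `bedtools merge -d 1000`); the merge is a transitive
closure, so it is idempotent and independent of input order.
Classification precedence is off_target → solo_ltr → short_fragment →
provirus: solo LTRs are recognized before the 2-kb length filter because a
single detached LTR (588–968 bp) is a solo LTR, not a fragment. Manual
curation of misannotations is replaced by the whitelist plus a reportable
`off_target` class — nothing is silently dropped. Loci containing an N-run
of ≥50 bases are flagged `gapped` and excluded from structural annotation,
since assembly gaps make structure calls unreliable. Merged-locus strand
is the strand of the longest member (fragments of one element share
strand, so ties are immaterial on clean tracks).

## Alignment substrate

All structure calls run on global affine-gap pairwise alignments
(match +2, mismatch −3, gap open −8, gap extend −1, Biopython
PairwiseAligner; the first optimal alignment is taken, which makes
tie-breaking deterministic). Terminal LTRs are located by *infix*
alignment (free end gaps on the locus window), which keeps terminal
mismatches inside the reported interval — a local alignment would shave
mutated LTR termini and misplace the TSD search. The TSD is the longest
exact duplication of 4–8 bases immediately flanking the element; exact
boundaries are tried first and small (±3) offsets only as a fallback for
boundary jitter. A detected duplication can extend the true TSD when
adjacent bases match by chance; mismatched duplications (as in
translocation-derived loci) are reported with `tsd_match = False`.

## ORF calling

A gene is *absent* when ≥50% of its reference span has no aligned query
base. Otherwise the caller walks the reference codons: a stop codon in the
query (in the reference frame, checked only where the cumulative
insertion−deletion offset is a multiple of 3) or the first codon at which
the net offset becomes non-zero is a disruption event. A gene is *intact*
— "full length or nearly full length" — iff no event occurs before 90% of
its reference codon count (`completeness_fraction`, default 0.90). The
90% rule is measured in codon space from the start codon; the wording
("nonsense or frameshift") refers to codon-level events, and in-frame
indels within the first 90% are tolerated but flagged
(`inframe_indels`). The pro–pol programmed frameshift is modeled as a
reference feature: nonsense codons at or after the slip site (default
codon 290 of the 300-codon *pro*) do not disrupt *pro*, so a *pro*
truncated by a few terminal codons still counts as intact.

## Deletions and the recombinant region

Internal deletions are maximal query-gap runs ≥50 bases, reported in
consensus coordinates and matched against the shared catalog (pro-pol
3384–5639, pol-env 6233–8152, 1-based inclusive as conventionally printed;
stored 0-based half-open internally). Catalog matching requires both
endpoints within `match_tolerance` (default 20 bases — alignment placement
jitters around repeats); unmatched intervals are reported as novel. The
MER11 region is detected by local alignment of the MER11 reference to the
env → 3′-LTR tail; the locus is recombinant iff the best hit covers ≥200
bases at ≥70% identity (real MER11A matches run ~85%). Deletion detection
is restricted to the coding span (5′ UTR through *env*), because the
region 3′ of *env* legitimately differs between recombinant and
non-recombinant architectures and would otherwise produce spurious
"deletions". LTR typing runs the same machinery against the full-length
LTR reference and labels the sorted combination of matched U3 deletions
(Δ1–Δ7), `full`, or `novel`.

### Breakpoint scanning

Crossovers between two parents are detected from per-window (100 bp,
step 10) identity tracks projected onto query coordinates; the majority
parent must switch and persist for ≥3 windows. Each coarse switch is then
refined by maximizing, over candidate split points within one window, the
matches to the outgoing parent on the left plus the incoming parent on the
right — the maximum-likelihood boundary under a symmetric substitution
model. Positions still carry ±window/2 uncertainty in the contract: only
sites where the parents differ carry information, so at 10% parent
divergence (~1 informative site per 10 bp) single-crossover error has an
irreducible tail even for the ML estimator; at the ~50% divergence typical
of the actual parental *env* pair, localization is within a few bases. A
query more than 40% diverged from both parents is declared `unalignable`.

## Molecular dating

Integration age is `p / r`, with `p` the 5′–3′ LTR p-distance over
gap-excluded aligned columns and `r` the **pairwise** divergence rate
between cognate LTRs (default 0.0034 per site per Myr; each LTR accrues
half). This interpretation is fixed by the anchor 1 difference / 588 bases
/ 0.0034 ≈ 0.5 Myr — the conventional "single-difference" resolution of
588-bp LTR pairs. Identical pairs yield only an upper bound,
`T_res = (1/compared_sites)/r`; both the interval `[0, T_res]` and its
midpoint (the conventional plotting position, 250 kyr for 588-bp LTRs) are
reported. For diverged pairs the interval is the exact Poisson CI on the
substitution count, rescaled. No multiple-hit correction is applied — the
normalization is linear in divergence — which biases ages low above ~15
Myr; this is a documented limitation, alongside host-lineage rate
variation and gene conversion, which no LTR clock escapes.

Distance trees use neighbor joining (scikit-bio) on the p-distance matrix
with labels canonically sorted, negative branches clamped to zero; they
stand in for maximum-likelihood trees, which users export to external
tools. Discordance — the signature of inter-provirus recombination — is
declared when a provirus's two LTRs are not a cherry **and** at least one
of them has a foreign leaf strictly closer (patristic) than its own
partner; the strictness means identical pairs are never flagged. This
patristic criterion replaces bootstrap clade membership because the
stand-in tree is NJ; it is configurable and flagged proviruses are
excluded from dating.

## Orthology

A junction query is genomic flank on one side of an element boundary plus
element sequence on the other. Queries are searched by exact 12-mer
seeding (numpy-indexed), diagonal clustering, and per-diagonal identity
scoring; a junction is intact iff the best placement covers ≥50 bases on
*both* sides of the junction point at ≥90% identity (identity is measured
over up to 200 bases per side, which damps the binomial noise of diverged
flanks while the 50-base coverage requirement stands), with a unique best
hit (second-best score <90% of best, otherwise `unresolved` — a
first-class state, never coerced). The element-side span of a junction
query is capped at 500 bases: the junction neighborhood carries the
information, while longer element stretches match paralogous proviruses
elsewhere in the target genome and defeat the uniqueness test. The identity threshold is a declared
proxy: "intact" has no published numeric definition, and 0.90 over 50
bases tolerates Old-World-monkey-scale flank divergence while rejecting
paralogous hits. Presence requires ≥1 intact junction; proviral sequence
at a locus without intact junctions is not counted (such hits are often
assembly artifacts). If the 1000-bp flank resolves nothing the search
escalates to 5000 bp; species with cleanly absent junctions are tested
with a flank–flank empty-site query that skips the downstream TSD copy.
The OCA of an insertion is the rooted-tree MRCA of the focal species and
all present species; empty-site species inside the OCA clade trigger a
coherence warning (loss or incomplete lineage sorting) rather than an
error.

Allele frequency from 3-primer PCR genotype tables is
`(2·n(+/+) + n(+/−)) / (2·n(non-failed))` — failed reactions leave the
denominator, two alleles per scored individual, which is the arithmetic
that reproduces screen frequencies like 3/28 = 10.7% and 17/24 = 70.8%.
Hemizygous genotypes are not modeled; the 3-primer design yields the
diploid vocabulary.

## Transcripts and assays

Splice junctions are read directly from SAM CIGAR N operations
(donor = 1-based last exonic base, acceptor = 1-based first exonic base,
so N length = acceptor − donor − 1), aggregated by site pair and filtered
at `min_support` (default 2 — thresholded aggregation replaces manual
browser inspection). The sRec ORF is the spliced transcript translated
from the annotated start through the first stop; with 261 + 189 nt coding
exons that is 450/3 − 1 = 149 residues, split 87 + 62 at the junction
codon. Transport activity is the ratio of eGFP to mCherry MFI over
scatter-gated, non-double-negative events; MFI is the arithmetic mean
("mean fluorescent intensity"), with geometric mean and median exposed as
options. Infectivity is %GFP+ among scatter-gated events, with the
threshold optionally set at the 99.9th percentile of a negative control.
Gate boundaries are config-supplied; no compensation or gate learning is
attempted, and only CSV event exports are read (no FCS parsing).

## The synthetic-data generator

The generator is first-class, tested code; its defaults define the study
conditions. The element library is built once per seed: a 968-bp
full-length LTR whose Δ1+Δ2 form is exactly the 588-bp short LTR; a
9,488-bp short-LTR consensus provirus whose gag/pro/pol/env ORFs translate
cleanly and sit at coordinates compatible with the printed deletion
coordinates (pro-pol 3384–5639 spans the pro/pol boundary, pol-env
6233–8152 the pol/env boundary); a recombinant tail of 283 (HML-8 env,
carrying the 189-nt sRec second exon in frame) + 726 (MER11) + 42
(purine-only PPT remnant) bases; U3R of the short LTR is 494 bp, so the
four reporter-insert segments total 1545. Seven U3 deletions (Δ1–Δ7, at
generator-defined endpoints since only approximate lengths are printed;
user-supplied endpoints are accepted for real data) combine into the
observed LTR variants.

LTR aging is substitution-only: each copy draws Poisson(L·r/2·age)
substitutions at distinct uniform positions, so expected pairwise
divergence is r·age; same-site collisions bias the clock low by <3% at 25
Myr. Implantation duplicates the `tsd_len` target-site bases (default 6,
range 4–8 — typical betaretroviral TSDs; the clade's true TSD length is
not asserted anywhere, so it is a parameter). Fragmented tracks split
internal records with gaps uniform on [50, 900] bases — exercising but
never violating the 1-kb merge rule — and jitter outer record edges by up
to 3 bases. Speciation removes absent elements back to a single-TSD empty
site and mutates background at `flank_divergence` per unit patristic
distance from the focal species, leaving retained elements unmutated so
presence truth is exact. For LTR-tree work, `simulate_ltr_pair_set` gives
each provirus private pre-integration lineage divergence (default 8–15 Myr
equivalent) so cognate pairs form cherries, as they do in a real LTR
phylogeny — without it every pair radiates from one ancestor and cherry
structure is undefined.

The standard study (`simulate_study`) implants 60 elements in 5 Mb of
41%-GC i.i.d. background: 12 full recombinants across all LTR variants
(a third with identical LTRs), 8 pro-pol, 10 pol-env and 6 double-deletion
carriers, 6 non-recombinant relatives, 10 solo LTRs, and 8 decoy-family
elements, ages uniform on [0, 12] Myr, both strands, with premature stops
implanted in some ORFs so status recovery is informative. Orthology runs
on a four-taxon tree (two macaques, a baboon, a colobine) with ~1–4%
flank divergence. These sizes keep a full validation run around a minute
while every rule (merge gap, 2-kb filter, whitelist, 90% boundary,
deletion tolerance) is exercised near its boundary.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: realistic base composition (no isochores or
repeat landscape beyond the implants; k-mer junction search faces far more
paralogy in a real genome), indels outside deletions (the dating alignment
sees no indel noise), sequencing error or quality structure in reads,
assembly artifacts other than N-gap flags, gene conversion between LTRs
(which corrupts real LTR clocks), and population structure beyond
Hardy–Weinberg.

## Numerical choices and degenerate inputs

Coordinates are 0-based half-open internally; `.out` files and locus names
are 1-based (UCSC convention); deletion catalogs print 1-based inclusive.
Ties in the consensus caller break A<C<G<T; columns with ≥50% gaps are
dropped. `estimate_age` refuses zero compared sites; `transport_activity`
returns an explicit `empty_gate` status instead of dividing by zero;
junction queries must span the 50-base window on both sides; empty
sequences, non-positive lengths, frequencies outside [0,1], overlapping
deletions, and unknown catalog names all raise errors rather than
degrading. Every generator is byte-reproducible given its seed, and the
pipeline derives all stage seeds from one global seed.
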