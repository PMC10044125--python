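# Methods

This note documents the conventions, parameter choices and known
limitations behind `mitochar`'s computations.

## Coordinates and annotation arithmetic

Coordinates are 1-based inclusive (GenBank convention). A feature with
`end < start` wraps the circular origin and has length
`L − start + 1 + end` for genome length `L`. The intergenic spacer
attached to feature *i* is `start(i+1) − end(i) − 1`; negative spacers
denote overlap, and the last feature pairs with the first across the
origin, so for features tiling the circle
`Σ lengths + Σ spacers = L` holds exactly, overlaps entering as negative
terms. The feature-table parser accepts both en-dash and hyphen range
delimiters and strips thousands separators; a declared Size column is
cross-checked against the computed length and mismatches are *warnings*
with both values reported, because published tables contain arithmetic
slips that should not abort parsing. Gene-name aliases are normalized on
parse (16S→rrnL, 12S→rrnS, "A + T-rich"→control_region); anticodons are
stored in the DNA alphabet because published tables mix RNA and DNA
spellings. The strand census counts gene features only — the control
region is non-coding and carries no meaningful strand.

## Composition and skew

AT-skew = (A − T)/(A + T), GC-skew = (G − C)/(G + C), computed on the
majority strand. Both are scale-invariant, so percentage inputs are as
valid as raw counts. A zero denominator raises an explicit error in the
scalar functions but is flagged as "undefined" (None) in region tables,
so one degenerate region cannot abort a report. Per-region sequences are
the concatenation of strand-corrected member-feature sequences, counting
bases shared by overlapping features once per feature: region sizes are
then plain sums of feature lengths, which is how published per-region
size tables are constructed. (On the bundled reference layout this gives
a PCG region of 11,209 bp where the corresponding published table prints
11,202; the published figure is not reconstructible from its own
coordinate table under any single overlap convention we tried, so the
plain-sum value is reported as computed.) Internally all values are
double precision; display rounding is round-half-up at the printed
precision of each column (percentages 1 dp, skews 3 dp), which is the
convention that reproduces printed skew tables exactly.

For the reference control-region row, note the published skews are
positive although its printed base percentages have T > A and C > G; the
implementation always reports the formula's signed value.

## Codon usage

The genetic code is injected (default: NCBI translation table 5, built
from Biopython's codon tables) rather than hardcoded. Synonymous families
group sense codons by amino acid — under table 5 this yields the 6-codon
Leu family, the 8-codon Ser family including AGA/AGG, 4-codon Arg (CGN),
Met {ATA, ATG} and Trp {TGA, TGG} — and the stops {TAA, TAG} form their
own 2-codon family so terminal-stop usage can be expressed on the RSCU
scale (a published stop-row RSCU of 2 = 11/(11/2) is only reproducible
this way). Stop-family values are excluded from codon-bias plots/tables
by default.

Decomposition reads codons in frame from position 1 of the
strand-corrected sequence; the length-mod-3 remainder becomes trailing
bases. Stop classification: trailing "T"/"TA" ⇒ incomplete stop
(completed to TAA by polyadenylation); no remainder with terminal
TAA/TAG ⇒ complete; anything else ⇒ `non_canonical`, deliberately
flagged rather than guessed — reference annotations list several
minority-strand genes with stop "T" yet lengths divisible by three, and
the flag surfaces exactly that tension. `count_codons` excludes terminal
complete stops by default but counts internal in-frame TAA/TAG, and a
separate terminal-stop tally is exposed, since published stop counts mix
the two accountings.

RSCU is count divided by family mean; families never observed give
flagged zeros. Display rounding is round-half-up at 2 dp.

## Gene order

Orders are extracted by start coordinate on the majority strand, control
region excluded, aliases normalized. Two circular orders over the same
gene set are compared by linearizing both at a shared anchor (default
cox1, syntenic in observed and ancestral arrangements; configurable) and
taking the complement of a longest common subsequence of the name
sequences: `n − LCS` is exactly the minimum number of genes whose removal
reconciles the orders, i.e. a minimal moved-gene set (verified against
exhaustive search for small n in the test suite). The default comparison
ignores strand — the canonical lepidopteran trnM event is a
translocation, not an inversion — while `strict_strand=True` also flags
strand flips. The built-in ancestral insect order is the Drosophila-like
arrangement with trnI-trnQ-trnM preceding nad2; its strand signs follow
the conventional majority/minority assignment. No
tandem-duplication–random-loss event reconstruction is attempted.

## Control-region scanning

All scanners are exact (no mismatches):

- **Motif**: all, possibly overlapping, occurrences; N is a wildcard.
  The default report motif is ATAGG with an optional trailing A reported
  when present ("ATAGG(A)-like"); no fuzzy matching, as the landmark is
  a single exact occurrence in practice.
- **Homopolymers**: maximal single-base runs ≥ a minimum length.
  Defaults poly-T ≥ 10 and poly-A ≥ 8 sit below the typical observed
  17 bp and 10 bp stretches so both are detectable with margin.
- **Microsatellites**: maximal perfect arrays of a given 1–6 bp unit
  with ≥ min copies (default unit AT, ≥ 5 copies); a trailing partial
  unit extends the reported end but not the copy count.
- **Tandem repeats**: maximal periodicity runs with period ≥ `min_unit`
  and ≥ `min_copies` copies, reported once at their smallest period; an
  array whose primitive period falls below `min_unit` (homopolymers,
  dinucleotide arrays) is not reported, keeping the three repeat
  families disjoint. Defaults `min_unit=5, min_copies=2` reflect the
  field's practice of treating (AT)n arrays as microsatellites rather
  than tandem repeats; repeat-finder settings differ between published
  reports, so all thresholds are configurable.

Only the annotated strand is scanned by default (reverse-strand scanning
is an option); every emitted hit is re-extracted from the sequence and
checked against its own description before being returned.

## Synthetic mitogenomes

The generator samples sequence i.i.d. per region-class base distribution
and then overwrites the discrete plan at fixed positions: planned start
codons and (possibly incomplete) stop codons as strand-aware base
constraints, overlaps realized exactly through negative spacers, and
control-region elements planted at fixed offsets. Conflicting planned
bases (e.g. a stop codon colliding with an overlapping gene's start) or
infeasible layouts raise errors naming the constraint. The control
region is assembled with a seeded repair loop: filler positions inside
any scanner hit that is not part of the plan are resampled until the
scanners report exactly the planted set — an AT-rich 288 bp region
produces chance unit-5 duplications often enough that plain rejection of
whole regions would rarely terminate, while local repair converges in a
few dozen iterations. All randomness flows through a single
`numpy.random.default_rng(seed)`; identical configs give byte-identical
artifacts.

The bundled profile mirrors the reference mitogenome: the published
37-gene + control-region layout (lengths, strands, overlaps, anticodons,
start codons, stop plans), per-region base probabilities matching the
published percentages (full genome ≈ 81% A+T, control region ≈ 96%), and
the four control-region landmarks (ATAGGA motif at offset 10 followed
immediately by 17×T; (AT)₁₄ mid-region; 10×A flush with the downstream
trnM boundary).

What the generator does *not* emulate: codon-level selection (PCG
interiors are i.i.d., so synthetic RSCU profiles are flat apart from
composition bias), tRNA secondary structure, transcription-driven
compositional gradients, and indel/substitution evolution. Pipeline
tests on generator output therefore demonstrate bookkeeping correctness
— coordinates, strand handling, tallies, scanner coordinates — not the
biological realism of any statistic.

The ground-truth manifest is computed at generation time by direct,
deliberately simple tallies over the emitted sequence (character counts,
stepping in threes) and verified against the sequence before return; the
test suite then requires the analysis modules to reproduce it exactly.

## Problem sizes and tolerances

The scanner-vs-oracle property battery runs 1000 random sequences of
50–2000 bp over three alphabets (uniform and AT-rich) with the
brute-force tandem oracle capped at unit length 10; the scanners
themselves have no such cap. Composition-target recovery on the 288 bp
control region is asserted within ±2.5 percentage points, the binomial
sampling width at that length. Exhaustive moved-set minimality is
checked for orders of 6 genes (subset enumeration is exponential);
larger instances rely on the LCS argument above. Published-table
reproductions are asserted at the tables' own printed precision.
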