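# Methods

## Model and coordinate conventions

All analysis runs in transcript space: PHAS loci are searched on cDNA
(and promoter) sequences, not on the genome. Coordinates are 1-based,
fully closed intervals throughout, so a 21-nt binding site printed as
424–444 spans exactly 21 nucleotides and can be used verbatim. Matching
is done in a single DNA alphabet (U→T on input); small RNAs are rendered
back as RNA for display.

A phase grid with cycle length k ∈ {21, 24} anchored at position *a*
consists of duplexes *i* = 1, 2, … whose top (sense) strands occupy
`[a + (i−1)k, a + ik − 1]`. Dicer products carry 2-nt 3′ overhangs at
both ends, which places the bottom strand of duplex *i* at sense
coordinates `[top_start − 2, top_end − 2]` and its 5′ nucleotide at
`top_end − 2`. Hence the in-phase rules: a plus-strand read is in phase
iff its 5′ end ≡ *a* (mod k); a minus-strand read iff its 5′ end ≡
*a* + k − 3 (mod k). The k − 3 offset is not a free parameter — it is
forced by the overhang geometry — and the classification is invariant
under shifting the anchor by multiples of k (property-tested).

## Region detection

Reads of length exactly k (a config flag can admit k ± 1) occupy a
duplex when their mapped RPM on either strand exceeds `min_rpm`
(default 0, i.e. any detectable read; no abundance floor is imposed
because the screen's own criteria never state one). For each of the k
anchor residue classes, maximal runs of consecutive occupied duplexes
are enumerated; runs of ≥ `min_duplexes` (default 5, the boundary is
inclusive) become candidate regions, deduplicated by (phase class,
span). Published locus tables often print one long region per locus even
when occupancy is gapped, so `merged_hull` additionally reports, per
phase class, the hull from first to last occupied duplex; the primary
output remains the maximal runs, which are the objects the ≥ 5-tandem
criterion actually constrains.

## Phasing score

Within a window of five consecutive registers (5k nt),

    score = (n − 2) · ln(1 + 10 · Σp / (1 + ΣU))

where n is the number of the five registers occupied by ≥ 1 unique
in-phase k-nt read (both strands, via the phase rules), Σp the **total
read count** of in-phase k-nt reads in the window, and ΣU the number of
**unique** out-of-phase k-nt reads. The p/U asymmetry (counts vs unique
sequences) is deliberate and kept exactly as defined; one consequence,
asserted as a property, is that doubling all read counts never lowers a
passing window's score. Windows slide register by register across the
candidate span; a region passes iff its best window scores **strictly**
above 1. By construction n = 2 gives score 0 and n < 2 negative scores,
so sparsely occupied windows can never pass. By default ΣU counts only
k-nt reads; a flag admits all lengths (the choice only hardens the
filter).

## Degradome validation and trigger search

Degradome (PARE) tags are 5′ ends of uncapped cleavage fragments and are
therefore mapped sense-strand only; a profile accumulates tag RPM at
each 5′ coordinate. A cleavage signal is *dominant* when its RPM ≥
`min_rpm` (default 1.0 RPM) and stands ≥ `min_dominance` (default
2.0-fold) over the strongest other signal within ±50 nt (background
floored at ε = 0.1 RPM so isolated peaks are always dominant). These
thresholds are package decisions — "dominant" is never quantified in
the screens this follows — and are config-exposed. Libraries are kept
separate; any single supporting library validates a site.

Trigger complementarity uses a miRU-style penalty: Watson–Crick 0, G:U
wobble 0.5, mismatch 1.0, doubled at sRNA positions 2–7, ungapped,
cutoff 3.0. The search space is the union of a supplied known-miRNA set
and all 18–24-nt library reads. The predicted cleavage site is the
target base paired to sRNA position 10, i.e. `binding_end − 9`; this
single rule reproduces every published (binding, cleavage) pair we use
as fixtures, for 21- and 22-nt guides alike, whereas a literal
"10–11 nt from the binding site's 5′ flank" reading does not.
Validation demands a dominant degradome signal at exactly the predicted
position (`jitter` widens this; default 0). A candidate trigger must
also pass the flank check: its predicted cleavage lies within ±2 nt of
the region's 5′ boundary or on the region's register — both facets
("at the flank" vs "register-concordant") are accepted because the
cleavage that sets the phase necessarily defines a register.

## phasiRNA naming, targets, DCL dependence

Mature phasiRNAs are read off the grid anchored at the trigger cleavage
site and named `Locus(anchor)k 3'D<i>(±)`; the parser tolerates the
typographic drift of published tables (curly primes, stray spaces,
unicode minus). The 5′-side grid (`5'D<i>`) mirrors the 3′ arithmetic,
duplex *i* at `[anchor − ik, anchor − ik + k − 1]`; published tables
print 5′-side names but never the arithmetic, so the mirrored grid is
this package's convention. Multiple anchors per locus are supported
(each grid reported separately) because published loci do list several.
Target prediction reuses the miRU scorer across a transcript set with
`cut = miru_end − 9`, validated exactly as triggers are.

DCL dependence compares summed in-phase k-nt RPM inside a region between
wild-type and dcl-mutant libraries, each normalised to its own total;
fold = wt / max(mutant, 0.1 RPM), dependent at ≥ 2.0-fold (both
config-exposed; the underlying claim is only "relatively higher", so
the 2-fold default is deliberately mild). The call is scale-invariant by
construction.

## RdDM promoter analysis

24-nt phasiRNA binding sites on promoters are exact, zero-mismatch
occurrences of the phasiRNA's reverse complement (a full-length exact
24-mer search needs no heuristic seeding at promoter scale); same-strand
verbatim occurrences are reported too, flagged `identical`. Cytosine
context follows the standard trinucleotide rule (CG, CHG, CHH with
H ∈ {A,C,T}), on the reverse complement for bottom-strand cytosines,
with truncated 3′-end triplets defaulting to CHH; contexts partition all
cytosines on both strands (property-tested). Bisulfite reads map by
three-letter matching — C→T collapse on read and reference for the
forward strand, G→A in sense coordinates for reverse-strand reads — and
only reads with exactly one placement across all supplied promoters are
retained. Per cytosine we emit methylated coverage in RPM of the whole
bisulfite library **and** the conventional methylated fraction:
"per-cytosine coverage in RPM" admits both readings, so both columns
are produced and neither is privileged. The RdDM consistency call uses
CHH only (the RdDM-characteristic context): consistent iff total CHH
methylated RPM is strictly higher in the phasiRNA-expressing tissue and
target expression (total RPM of exactly matching RNA-seq reads) is
strictly lower there; CG/CHG are reported but not gated on.

## Synthetic scenarios

`make_phas_scenario` plants one PHAS locus in a 1-kb i.i.d.-uniform
transcript among three 800-nt background transcripts: per-duplex,
per-strand read counts are Poisson with mean `depth` (default 20; eight
duplexes), the trigger is embedded so that its position 10 faces the
anchor (cleavage site = region start), the degradome carries a
Poisson-20 tag pileup at the cleavage site over 20 scattered unit tags,
and out-of-phase noise adds unique count-1 k-mers at off-register
positions, 10% of the phased read total by default. The noise-only
control runs the identical noise process without the locus. Defaults
are the study conditions used by the tests and the acceptance script;
at these depths the planted anchor, trigger and cleavage site are
recovered exactly in every seeded replicate we test (20 seeds), and
noise-only seeds yield no candidate region. `make_mutant_library` thins
planted phased reads binomially with retention = `depletion` (0.05
emulates a dcl mutant), leaving background untouched. `make_rddm_scenario`
derives 24-nt phasiRNAs from a planted precursor, plants their reverse
complements in a 200-nt promoter, draws 60 bisulfite reads per tissue
with per-context methylation rates (defaults CHH 0.6 vs 0.05 between
tissues, CG 0.3 / CHG 0.2 shared; conversion 1.0) and gives the target
gene lower RNA-seq depth in the high-methylation tissue (5 vs 40 reads
over a 60-read decoy background).

What the generator does **not** emulate: sequencing error, mismatch
mapping, length heterogeneity of real sRNA libraries, genome-scale
multi-mapping, RNA secondary structure, partial bisulfite conversion
bias, or realistic rice sequence composition. Passing tests therefore
demonstrate the correctness of the algorithms and thresholds under the
stated model, not performance on real libraries — headline locus counts
from real data are explicitly out of scope.

## Numerical and degenerate-input choices

`log1p` is used for the score; ties in cleavage detection break toward
the smaller position; trigger candidates order by (penalty, −RPM,
position). RPM always normalises by the pre-filter library total, so
Σ RPM = 10⁶ exactly even when reads are length-excluded from analysis.
Empty libraries, zero-length FASTA records, duplicate record ids,
non-integer counts, anchors off the transcript, spans shorter than one
window and k ∉ {21, 24} all raise immediately with named errors rather
than propagating silently. Scenario generation, library thinning and all
tests are seeded (`numpy.random.default_rng`); identical seeds reproduce
byte-identical scenario files.

## Known limitations

Exact-match mapping only (by design: degradome chemistry and the
zero-mismatch promoter rule make this faithful, but SNPs or sequencing
errors in real data would need an upstream aligner); 22-nt phasiRNA
enumeration is not implemented (no published arithmetic to follow);
genome-resident (intronic/intergenic) PHAS loci are out of scope, as is
whole-genome bisulfite alignment — promoter-local profiles only; the
promoter→gene association is supplied via configuration rather than
inferred by aligning the promoter's trailing partial mRNA.
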