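# Methods

This note documents the models and decision rules implemented in `utrlens`,
the defaults they ship with, what the synthetic-data generator does and does
not emulate, and the numerical choices that affect results.

## Coordinates, alphabets, catalogs

Sequences are stored as uppercase DNA (`U` → `T` on input); `N` is accepted
and excluded from composition denominators.  All internal coordinates are
0-based half-open; every reported coordinate is 1-based inclusive, matching
the convention of published PAS-position tables.  A catalog key is the
quadruple (gene, variant, species, region); variant suffixes such as `b(2)`
are opaque labels and never parsed.  Report tables are sorted by
(gene, variant, species) so identical inputs give byte-identical outputs.

## Composition

G+C is (G+C)/(A+C+G+T).  Codon-position G+C partitions an in-frame CDS by
position; a trailing partial codon is dropped with a warning.  The UTR–CDS
correlation is plain Pearson r with a two-sided p and an OLS line; the 95%
band uses the t-quantile confidence interval of the fitted mean,
half-width `t·s·sqrt(1/n + (x−x̄)²/Sxx)`.  Inputs with zero variance on
either axis are rejected rather than returning r = NaN.

## uORF scanning and the translation-class surrogate

Every ATG in the 5′ UTR is a uAUG; a uORF follows its frame to the first
in-frame stop inside the UTR (default `min_codons=1`, so AUG-stop counts).
ORFs that run into the CDS are excluded by default and only reported,
flagged, when `require_stop_in_utr=False` — published per-variant uORF
counts are consistent with stop-containing ORFs only.

Initiation context uses the two most informative Kozak positions: optimal
when the −3 base is a purine **and** +4 is G, adequate when exactly one
holds, weak otherwise; a −3 position that does not exist (cap distance < 3)
counts as unsatisfied.  Cap-distance classes are optimal > 19 nt,
weak < 12 nt, and an explicit *intermediate* band for 12–19 nt, which the
published two-letter scheme leaves undefined; when emitting `O`/`W` summary
strings, intermediate and adequate collapse to `O` so that only outright
weak prints as `W`.

The translation class (I = low, III = efficient) is a deliberate surrogate
for the original regression-tree classifier, whose fitted splits were never
published: class III iff no uORF, length ≤ 100 nt, and MFE density ≥ −0.45
kcal/mol/nt when structure information is supplied; otherwise class I.  All
three thresholds are configuration (`TranslationThresholds`).  This rule
reproduces the published class for the catalog rows whose features are
printed, with one documented exception: the published table assigns the
72-nt human and 89-nt mouse RBP4_d leaders (both uORF-free) to different
classes, so no feature-based rule can match both; the surrogate classes
both as III.

## PAS typing and efficiency

Canonical AAUAAA (C), non-canonical AUUAAA (NC), and a configurable NC\*
set defaulting to eleven rare single-base AAUAAA variants
(TATAAA, AGTAAA, AAGAAA, AATATA, AATACA, CATAAA, GATAAA, AATGAA, TTTAAA,
ACTAAA, AATAGA).  Scanning is sense-strand only (PAS function is
strand-specific), overlaps allowed.  Efficiency uses the distance from
hexamer start to the annotated 3′ end: inside [10, 45] nt (inclusive) a
canonical signal is VE and any other type E; outside, LE.  The window was
chosen to cover the published VE distances (17–45 nt, with one call at
exactly 45).  Benchmarked against all 42 published (length, position,
type, label) rows, the rule reproduces 40 calls; the two misses are
exactly the two published-in-parentheses mouse labels (canonical at
distance 20 and non-canonical at distance 14 called LE), which contradict
any distance rule and are flagged as known exceptions rather than fitted.
Usable (non-LE) signals nominate alternative 3′ ends 20 nt after the
hexamer end, capped at the UTR end.

## k-mer enrichment

Occurrences are counted with overlaps across the set; two-strand mode (the
default) pools a word with its reverse complement under the
lexicographically smaller key, the convention under which reverse-
complement pairs like CTGGCA/TGCCAG are reported with a single count.
The background is a Markov chain of order 0–2 (default 2) estimated from
the input set itself with pseudo-count 0.01 — species-calibrated background
tables can be supplied but are not bundled.  Significance is the upper-tail
binomial P(X ≥ obs) with n = window count and p = expected/n (Poisson
approximation above 10⁴ positions), Bonferroni-corrected over the words
actually observed (RSAT-style; `4^k` is available by option);
`sig_index = −log₁₀(E)` is computed in log space so extreme enrichment does
not overflow.  Published significance indices depend on the tool-internal
test count and background calibration, so they are comparison points, not
exact targets.

## miRNA site accessibility

Seed matching pairs miRNA positions 1..`min_seed` (default 8) antiparallel
against the UTR, allowing at most one G:U and one mismatch, with position 1
required to pair Watson–Crick.  Scoring follows the accessibility-energy
logic: `ΔG_open` is the unconstrained minus the site-forced-unpaired
ensemble free energy of a window extending 70 nt on each side of the site
(≤ 0 by construction — constraining can only raise the free energy), and
`ΔΔG = ΔG_duplex − ΔG_open`.  A site is accessible iff ΔΔG < −10 kcal/mol
and very accessible iff additionally ΔG_open > −10 kcal/mol, so very
accessible ⊆ accessible always.  The engine is a contract: `StubEngine`
(deterministic lookups) backs the tests; `ViennaEngine` computes duplex
energies with `duplexfold` and opening energies with constrained partition
functions.  Absolute site counts for a real transcriptome depend on the
miRNA catalog snapshot used, so catalogs are user-supplied inputs and
published per-gene counts are not asserted.

## Structure ensembles and shapes

The toy engine does exhaustive enumeration under base-pair maximization
(−1 kcal/mol per pair, Watson–Crick plus G:U), with the standard minimum
hairpin loop of 3 nt, pruned by a Nussinov-style bound so only structures
within the energy window are generated; results are sorted by (energy,
dot-bracket) for determinism.  It is exact, which is what makes the census
properties verifiable; its cost is exponential, so it is capped at 40 nt by
default and ViennaRNA (`mfe` + `subopt`) serves for realistic lengths and
energies.  The suboptimal window defaults to +5 kcal/mol, the conventional
band within which native structures of structural RNAs fall.

Abstract shapes drop unpaired positions, collapse each maximal helix to one
bracket pair, and merge helices separated only by bulges/internal loops;
multiloop branching is preserved, and a fully open chain maps to `_`
(examples: `((...))` → `[]`, `..((..))..((...)).` → `[][]`,
`((.((...)).((...)).))` → `[[][]]`).  A helix (maximal stack) of the MFE
structure is *conserved* when its exact base-pair set occurs in ≥ 60% of
the suboptimal structures (threshold configurable).  Thermodynamic MFE
values depend on the energy-parameter version, so published MFEs are only
ever compared within ±10%.

## Conservation and Ka/Ks

Pairwise identity: global alignment, match +1 / mismatch −1 / gap open −10
/ gap extend −0.5, free end gaps.  Identity is matches over alignment
columns excluding terminal-gap overhangs, because UTR variants genuinely
differ at their ends; internal gaps count as differences.  Two sequences
with no alignable region (a fully staggered optimal alignment) score 0.
Homology calls are inclusive: identity ≥ 60% (the conventional cutoff for
orthologous mammalian non-coding sequence).  MSA construction is delegated
to external aligners; the package only computes column-wise identities of
pre-aligned rows.  Published identity values from generic alignment tools
with unpublished parameters are tolerance comparisons, not exact targets.

Ka/Ks implements Nei–Gojobori (1986) with the SNAP stop-codon convention:
per-position synonymous-site fractions exclude mutations to stop codons
from the denominator; codons differing at several positions average
substitution counts over all shortest mutational pathways, discarding
pathways that pass through a stop (all retained if every one is blocked);
gap- or N-containing and stop codons are excluded pairwise.  Jukes–Cantor
`d = −¾·ln(1 − 4p/3)` corrects both proportions; p ≥ ¾ yields NaN (flagged,
not thrown), and the ratio is undefined when Ks = 0.  Site counts satisfy
S + N = 3 × codons compared, and the statistic is symmetric in its
arguments.  Note that Biopython's NG86 counts stop neighbors as
nonsynonymous sites and keeps stop-crossing pathways; the test suite
cross-checks against it only where the conventions provably coincide, and
against an exhaustive pathway-enumeration oracle everywhere.

## Synthetic data: what it emulates, what it does not

The generator emulates the statistical structure the analyses assume: gene
families with lettered UTR variants; i.i.d. background sequence at a target
G+C (55% by default in the presets, typical of mammalian UTRs); planted
uORFs with exact cap distances, context classes and peptide lengths;
planted PAS hexamers at exact distances from the 3′ end; planted enriched
k-mers and perfect-complement miRNA seed sites; and ortholog families
diverged from a root with per-site substitution rates by codon position
(defaults 0.05/0.05/0.15, third position fastest) and a flat UTR rate.
After planting, stray ATGs (5′ UTRs) and stray PAS hexamers (3′ UTRs) are
scrubbed outside protected intervals, so truth tables are exhaustive and
scanner recovery can be asserted exactly.  CDSs are generated and kept as
open reading frames, including under divergence (mutations creating
internal stops are re-drawn).

It does **not** emulate: isochore/genomic G+C context, repetitive elements,
indel evolution (substitutions only), splicing or exon structure,
transcription-start heterogeneity, or realistic miRNA target ensembles.
Passing recovery tests therefore demonstrates correctness of the scanners
and classifiers under the stated model, not performance on real transcript
annotations, where feature density, composition bias and indels differ.

Two presets mirror the headline biological contrast for end-to-end tests:
the ED-like preset (long multi-uORF leaders, multiple PAS, slow UTR
divergence) whose variants all classify as translation class I, and the
LD-like preset (short uORF-free leaders, single proximal PAS, fast UTR
divergence) whose variants classify as III.

Reproducibility: one global seed; each gene/variant and each
(record, species) divergence draws from a `SeedSequence`-spawned substream,
so output is byte-identical for a fixed plan and independent of generation
order.

## Problem sizes used in the shipped checks

The self-contained verification suite uses: 500 random ≤3-codon pairs for
the Ka/Ks oracle; a fixed 50-sequence panel of 8–25-nt sequences for
exhaustive structure enumeration; ≥200 planted features for scanner
recovery; 100 replicates for the codon-position-ordering and motif-recovery
rates; 40 replicates of 600-nt UTRs for the Jukes–Cantor identity check.
These sizes were chosen to make the checks statistically meaningful while
keeping the whole suite fast on a single CPU.

## Known limitations

* The translation-class rule is a surrogate, not the original fitted tree.
* PAS efficiency is a pure distance rule; downstream U/GU-rich elements and
  cleavage-site evidence are out of scope.
* The NC\* variant list and the 10–45 nt window are defaults, not claims of
  optimality; both are parameters.
* Enrichment E-values depend on the background choice; input-trained
  backgrounds make small catalogs self-referential.
* The toy folding engine ignores stacking thermodynamics by design; use the
  ViennaRNA engine for energy-faithful results.
* Checks that compare against the published per-variant tables need the
  original sequence catalog supplied by the user (see README); without it
  they report the catalog as unavailable.
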