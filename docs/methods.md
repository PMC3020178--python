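# Methods

## Background and model

A BAC (bacterial artificial chromosome) library arrays ~100–250 kb genomic
inserts in 384-well plates (rows A–P × columns 1–24); a clone's name encodes
its plate, row and column (e.g. `CH243-341E5`). Each clone is end-sequenced
with the two vector primers, SP6 and T7, giving up to two BAC-end sequences
(BES) per clone. When both end-reads of an intact clone are aligned to a
reference genome they land on the same chromosome, on opposite strands,
facing inward ("tail-to-tail"), with an implied span — the interval from the
outermost coordinate of one read to the outermost coordinate of the other —
consistent with the insert size. Every departure from that geometry carries
information about what went wrong between library construction and data
deposition, and because the defects are introduced by *plate-level* handling
(sequencing a whole plate with one primer, replicating plates, re-picking
clones), their signatures are plate-structured. bacqc turns each documented
failure mode into a detector and validates all of them by recovery of
defects injected into a simulated library with exact truth labels.

## Concordance classification

`classify_mappings(a, b, bounds)` assigns exactly one class:

* `NO_END_POSITIONED` / `ONE_END_ONLY` — zero or one end mapped;
* `DIFFERENT_CHROMOSOME` — ends on different chromosomes;
* otherwise orientation is read off strand + coordinate order: the
  leftmost-mapped read on `+` and the rightmost on `-` is inward-facing;
  both reads on one strand is `TAIL_TO_HEAD`; the reverse arrangement is
  `HEAD_TO_HEAD`;
* an inward-facing pair is `TAIL_TO_TAIL` when the implied span lies in the
  insert-size window, else `TAIL_TO_TAIL_OUTSIZE`. Degenerate geometry
  (non-positive span) is classified outsize, never raised.

The insert-size window defaults to **[50 kb, 350 kb]**, generous around the
~150–250 kb insert range of CHORI-style libraries so that only clearly
aberrant spans are called outsize; it is configurable everywhere. All
coordinates are 0-based half-open internally (BED-native); a 1-based
inclusive TSV dialect is converted on read.

Classification is symmetric in its two arguments (which primer carries
which mapping cannot change the geometry), a property the suite checks; an
independent oracle in the test suite re-derives the class from midpoint
direction vectors and agrees with the implementation on an exhaustive
strand × order × span × chromosome × missing-end grid.

## Per-plate statistics and outlier flagging

For each plate we count reads attempted/positioned and clones by end
status, and derive four proportions: positioned reads of all reads;
tail-to-tail clones of clones positioned at all (both-ends-positioned +
one-end-only; "all clones" is available as an option); one-end-only clones
of clones positioned at all; and tail-to-tail clones of clones with both
ends *sequenced*. Proportions with empty denominators are reported absent,
not zero. Counts are conservative: summed over plates they reproduce the
library totals.

Outlier plates are flagged per metric with an exact two-sided binomial
test of the plate's numerator against a robust library rate — the
**leave-one-plate-out median** of the other plates' proportions — followed
by Benjamini–Hochberg adjustment across plates at α = 0.05. The median was
chosen over a count-weighted pooled mean deliberately: one or two grossly
defective plates (a swapped pair has *zero* tail-to-tail clones) drag a
pooled mean down far enough that every healthy plate tests as a
significant excess, while the median is untouched. With the median rate,
simulated recovery runs flag exactly the injected plates, and the
clean-library false-flag rate measured over 20 seeds × 50 plates is at the
nominal level (0 of 1000 plate-tests at α = 0.05).

Detection power: a defect must displace a plate's proportion by a few
binomial standard errors (≈ 0.03 at 384 clones). A contamination episode
touching ~15 % of one primer's reads sits at the edge of that test's power
— though the hotspot detector still finds it — while the documented
real-world episode (~200 of 768 reads) is unmistakable.

## Swap detection

A plate swap attributes one primer's reactions for a whole plate (or part
of one) to another plate. `test_plate_swap` evaluates the what-if
well-for-well (E5 ↔ E5, the physically plausible exchange): for every well
address present on both plates, the pair is classified as-is and with the
suspect primer's mappings exchanged, and the well is assigned `swapped`,
`original`, or `neither` according to which configuration yields (more)
tail-to-tail clones; `neither` wells — typically an unmapped end on one
side — carry no evidence and do not vote. The *gain* is the change in the
two plates' combined tail-to-tail count. `scan_swap_candidates` tests
every unordered candidate pair × both primers and ranks by gain (default
`min_gain` 10 suppresses coincidental gains); `apply_plate_swap` performs
the straight swap for repair. On a simulated 50 % partial swap the
per-well assignment recovers > 95 % of truth-labelled wells among those
that vote.

One identifiability caveat: exchanging *either* primer's mappings
restores a crossed pairing equally well — swapping SP6 re-unites each
well's true pair just as swapping T7 does — so mappings alone cannot say
which primer's reactions physically moved. The scanner reports both
what-ifs with identical gain and ranks them by a deterministic tie-break
(SP6 first); resolving the physical event needs laboratory records.

## Overlap redundancy and well adjacency

Overlapping clone pairs are found per chromosome by a sweep over
start-sorted implied spans (never an all-pairs scan; the suite checks the
sweep against brute force). Percent overlap is normalised by the
**shorter** span, so a re-picked clone whose end-reads differ slightly in
length still scores ~100 %. Histograms use right-closed 2 % bins over
(0, 100], modal ties resolving to the higher bin.

One consequence of the shorter-span denominator is worth recording: in a
*random* (defect-free) placement, a shorter span fully contained in a
longer one also scores exactly 100 %, and with insert lengths ~N(184 kb,
30 kb) containment happens for ≈ 9 % of intersecting pairs — an atom at
the 100 % bin that dominates the otherwise flat random-overlap histogram.
The diagnostic contrast between the same-plate peak at 100 % (re-picked
clones) and a different-plate peak well below 100 % therefore only emerges
when genuine cross-plate redundancy outweighs the containment atom, which
is exactly the situation in a real library; the validation scenarios
inject `cross_plate_duplicate` defects (target overlap 0.87, mid-bin —
a target sitting exactly on a bin edge splits between neighbouring bins
by rounding parity) alongside same-plate duplicates to reproduce it.

Well-adjacency analysis counts same-plate clone pairs with ≥ 1 bp of
BES-mapping intersection whose wells share a row or column with 0, 1 or 2
intervening wells — the footprint of localised cross-contamination during
plate handling. A pair counts once in its single stratum. The per-plate
count of *all* BES-overlapping clone pairs is also reported: on a
contaminated plate it can exceed the plate's clone count, a hallmark that
distinguishes a contamination pileup from genuine redundancy.

## Contamination hotspots and the k-mer screen

A contamination hotspot is many distinct clones' same-primer reads mapping
to one tiny region (classically a eubacterial 16S rRNA fragment that
happens to align somewhere in the reference). Detection is single-linkage
clustering of mapped-read start coordinates per chromosome with linkage
distance `max_span` (default 500 bp), keeping clusters whose mapping
envelope is ≤ 2 × `max_span` (a safety factor against chained pileups) and
that contain ≥ `min_clones` distinct clones (default 5). Documented
real clusters span 33–106 bp with 13–59 members; the defaults sit far
below those signals and far above random pileup at realistic mapping
density. Results are sorted by member count and are invariant to input
order. Single linkage is applied to starts rather than midpoints: simpler,
order-invariant, and indistinguishable at these scales.

The independent screen compares read sequences against a user-supplied
contaminant FASTA by canonical k-mer sharing (k = 21; canonical = the
lexicographically smaller of a k-mer and its reverse complement, so both
strands match). Per read, the fraction of its k-mers present in the
reference set yields a verdict: ≥ 0.8 contaminant, ≥ 0.2 chimera
(part insert, part contaminant), else clean; reads shorter than k are
clean with a warning. A read built as 300 bp random + 300 bp reference
has an analytically exact fraction of (300−k+1)/(600−k+1) = 280/580,
which the suite asserts to the digit. Identifying *what* the contaminant
is (database search) is out of scope — the user supplies the reference.

## The synthetic library

`simulate_library` emulates the post-alignment data of an end-sequencing
project. Defaults: insert length ~ Normal(184 kb, 30 kb) truncated to the
insert window by rejection (no boundary atoms); read length ~ Normal(600,
100) bp clipped to [50, insert/2]; per-end unmapped probability 0.25;
per-clone discordant probability 0.05 (the discordant clone gets one of
four geometries: tail-to-head, head-to-head, outsize, different
chromosome); SP6/T7 terminus assignment randomised per clone; uniform
placement on a configurable genome, default 3 × 30 Mb. Everything flows
from one seeded generator: identical configs give byte-identical output.

The default toy genome is dense (a 2-plate library is already ~3×
coverage), which exercises the overlap machinery cheaply but overstates
coincidental read collisions ~20-fold relative to a real mammalian-scale
reference. Scenarios that assert the *absence* of signals (clean-library
hotspots, clean adjacency, exact cluster membership) therefore simulate on
a sparser 3 × 200 Mb genome, and the full-library scale run uses
26 × 100 Mb so that 528 plates give ~14× coverage — the real
library-to-genome ratio. These are scenario configurations; the defaults
are unchanged.

Defect injection overwrites mappings in place — a cross-contaminated well
contains the wrong clone's DNA but its reads keep the well's name — so the
record count is always conserved. Two consistency rules matter for truth
labels: (i) a clone touched by one defect is never re-targeted by a later
one, so every label refers to the final record set; (ii) duplication
sources must be concordant clones (a re-picked clone is physically an
ordinary clone; a different-chromosome "source" has no meaningful span to
copy). Duplicate copies are jittered by ±min(250 bp, half the read
length): the duplicate's reads come from the same physical DNA and align
at nearly the same positions, and the bound guarantees the copy shares
mapped bases with its source.

What the simulator does **not** model: base-level sequences (alignment is
presumed done; the k-mer screen has its own sequence fixtures), mapping
ambiguity and repeat-induced mismapping, chromosome-scale coverage biases,
correlated failures across neighbouring wells other than the explicit
defect kinds, and partial-plate sequencing. Passing recovery tests
therefore demonstrate the detectors' correctness on idealised geometry and
their null behaviour at realistic density — not robustness to alignment
artefacts of any particular mapping pipeline.

## Pipeline and reproducibility

`run_pipeline` chains read → pair → classify → plate statistics → flags →
swap scan (over flagged plates) → overlaps → adjacency → hotspots →
optional screen, writing one TSV per stage plus a JSON summary; all
writers emit fixed column order and sorted rows, so identical inputs give
byte-identical files. The CLI exits 0 on a clean library, 2 when any
plate is flagged (for gating automated release pipelines), 1 on error.
Thresholds actually used are logged to stderr and recorded in the summary.
The full overlap-pair list is written only on request (`write_pairs`);
at full-library scale it runs to millions of rows, while the histograms
and counts that downstream decisions use are always written.

`scripts/acceptance.py --seed N --out results/acceptance.json` re-runs
the whole validation from scratch — clean-library metrics and false-flag
rate, full- and partial-swap recovery, the 59-read/33 bp hotspot
reproduction, the overlap contrast, exact adjacency recovery, the
analytic chimera fixture, and pipeline byte-determinism — deriving every
sub-simulation seed from `--seed`. Problem sizes (20–30 plates per
scenario, 5 repeat seeds for the false-flag rate) were chosen to give
stable statistics at interactive runtimes; the 528-plate full-scale run
lives in the test suite.

## Known limitations

* The plate-proportion test assumes clone outcomes are independent within
  a plate; a defect that *raises* concordance uniformly would be invisible.
* Single-linkage hotspot clustering can discard a genuine cluster whose
  envelope is inflated past 2 × `max_span` by an adjacent background read;
  at realistic density this is rare but not impossible.
* The swap detector considers pairwise well-for-well exchanges only; a
  three-plate rotation or cross-well scrambling is reported as partial
  swaps with reduced gain rather than resolved.
* Percent-overlap containment (the 100 % atom) means the same-plate 100 %
  peak alone does not prove duplication on sparse data; the well-adjacency
  and per-plate pair-count signals disambiguate.
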