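# Methods

This note documents the models, parameter choices and numerical
conventions behind mirberry, and what the synthetic-data tests do and do
not demonstrate about real libraries.

## Read cleaning

Qualities are Phred+64 (Q = ASCII − 64); a `phred_offset=33` switch
handles modern encodings. "Low quality" is not uniquely defined by a
per-character quality formula alone, so both readings are implemented:
the default fails a read if *any* base has Q < 10 (the strictest reading
consistent with a per-character definition), and `low_quality_mode="mean"`
uses the mean. The filter order is fixed and observable: quality → 3′
adapter → insert-null → 5′ contaminant → length < 18 → length > 30 →
poly-A; a read failing several filters is counted once, at the first.
Adapter matching uses an 8 nt anchor with ≤ 1 mismatch (common small-RNA
practice; both knobs are configurable), and "poly-A" means ≥ 80% adenine
in the insert. Percentages in the accounting table are count/raw × 100 at
3 decimals.

The gel in this kind of protocol isolates ~18–28 nt fragments while the
analysis window is 18–30 nt; the length bounds are therefore parameters
(`min_len`, `max_len`), not constants.

## Tag classification

The original workflow used permissive BLASTN searches (E = 0.1). At tag
lengths of 18–30 nt such searches behave like (near-)exact matching, so
mirberry substitutes deterministic rules: exact substring on either strand
for cDNA/EST/ncRNA references, and ungapped ≤ 2-mismatch matching with a
± 2 nt end shift for known mature miRNAs (overlap must cover at least
min(len) − 2 positions). This is a deliberate deviation chosen for
auditability; a real BLAST mode is out of scope. Family labels come from
the best hit (fewest mismatches, ties by reference id). The family
member-vs-reads correlation is the product-moment r with the p-value from
the t transform on n − 2 degrees of freedom; it requires ≥ 3 families.
Positional nucleotide statistics denominate each position by the
sequences long enough to have it.

## The bundled folding engine

Minimum-free-energy folding over pseudoknot-free structures with hairpin
loops ≥ 3 nt. The energy model is intentionally small and lives in a
versioned table (`data/energy_params.tsv`) shared verbatim by the dynamic
program and the exhaustive-enumeration oracle:

* admissible pairs: Watson-Crick plus G:U wobble;
* stacking energy for adjacent pairs p, q:
  −0.5·(bond(p) + bond(q)) kcal/mol with bond(A:U) = 2, bond(C:G) = 3,
  bond(G:U) = 1 — so a C:G/C:G stack contributes −3.0 kcal/mol, close to
  the Turner-model magnitude;
* hairpin-loop closing penalty min(3.0 + 0.1·(L − 3), 5.0);
* interior loops, bulges and multiloops are free.

Isolated pairs are never favourable (they earn no stack but pay the
hairpin penalty), which keeps structures clean without an explicit
lone-pair ban. The DP is O(n³) (numba-accelerated when available, pure
NumPy/Python otherwise) with deterministic tie-breaking: ties prefer
unpaired bases, then the hairpin > stack > interior case order. The
traceback's structure energy is asserted against the shared energy
function in tests, and DP = enumeration is property-tested on hundreds of
random sequences ≤ 22 nt.

Two caveats are intrinsic to the model. First, absolute MFE values are
not comparable to Turner-model folders; the −18 kcal/mol precursor rule is
applied to whichever engine produced the structure, and ViennaRNA can be
swapped in (`engine="vienna"`) where published-scale energies matter.
Second, reverse-complement symmetry of the energy tables holds only for
the Watson-Crick-only configuration — under revcomp a G:U pair maps to
C:A, which cannot pair — so that invariant is tested with
`EnergyModel(allow_gu=False)`.

## Duplex metrics and the star strand

The miRNA\* is defined from the fold: the interval of positions paired to
the mature region, extended 2 nt past its 3′ edge (the canonical Dicer
2-nt overhang). Between consecutive paired mature positions with gaps
(gap_m, gap_s) on the two strands, min(gap_m, gap_s) counts as an
adjacent-mismatch run and |gap_m − gap_s| as a bulge; the rule thresholds
apply to the maxima. "Bulge" is thus read as a nucleotide run, not an
event count (the event count is also reported). Terminal unpaired mature
bases lie outside the duplex; instead, a mature region with < 50% of its
bases paired (or pairing with itself) is treated as having no star on
this EST, which fails rule 6 and leaves the duplex rules 4–5 vacuously
true. This makes "exactly one rule fails" well defined for every planted
fixture.

## Novel-miRNA rules

The seven acceptance rules use inclusive bounds (GC exactly 30% passes;
MFE exactly −18 passes). The precursor window is mature ± 150 nt clipped
to the EST (whole-EST mode available) — folding whole multi-kilobase ESTs
adds nothing for typical precursor sizes and cubically inflates runtime.
The ≥ 10-read cutoff is applied before EST mapping. Cross-species
uniqueness is exact-substring search (both strands) against the five
other-species cDNA sets. miPEP ORFs are scanned in the three forward
frames of up to 500 nt of pri-miRNA sequence 5′ of the mature start
(orientation is fixed by the mature hit strand, so reverse frames are
excluded); every AUG is paired with its first in-frame stop and peptides
of 4–75 aa are reported.

## Target prediction

The scoring scheme is the miRU/psRNATarget-lineage penalty set — mismatch
1.0, G:U 0.5, gap 2.0, doubled at seed positions 2–8 — which is the
published scheme consistent with an "expectation ≤ 3" cap; the values are
exposed in `TargetParams`. The alignment is ungapped over
min(20, miRNA length) positions. The seed must be perfect Watson-Crick
(wobble configurable), and positions 9–11 all paired calls cleavage,
anything else translational repression (a binary rule; partial central
matches are not graded). Site accessibility (UPE) is defined against the
bundled engine: the energy forfeited when the site ± 17 nt context is
refolded with the site forced unpaired. Because this is not the
partition-function accessibility a web server computes, UPE filtering is
off by default and the 25 kcal/mol cap is honoured when enabled.

## GO enrichment

Counts are term-assignment counts (a gene contributes once per assigned
term), matching definitions phrased over "GO terms" rather than genes.
The test statistic is the standard hypergeometric upper tail; the
sometimes-printed form "1 − f(k)" is not a valid tail probability and is
available only as an explicitly labelled `paper_literal` audit mode.
Biological-process and molecular-function namespaces are tested
separately by default (`joint_namespaces=True` merges them); d in the BH
step-up is the number of distinct terms present in the target set of that
namespace. The BH implementation is order-preserving and cross-checked
against statsmodels.

## Synthetic libraries and what they show

The generator emulates the gross structure of a ripening-fruit small-RNA
library: a read-length profile peaked at 24 nt (51.6%) with 21 nt (16.7%)
and 23 nt (13.6%) side modes; planted conserved-miRNA reads with
0/1/2/3-mismatch rates 0.70/0.15/0.10/0.05; hairpin-derived novel reads;
rRNA/tRNA/cDNA fragments; poly-A, low-quality and adapter-artifact
classes (fractions 0.35/0.08/0.06/0.04/0.30/0.03/0.07/0.07). Reads are 44
nt: insert + full 3′ adapter + random fill, so a 30-nt insert still
leaves the 8-nt adapter anchor visible. One seeded NumPy generator drives
all sampling; identical configs are byte-identical.

Clean-class inserts are rejection-resampled so their category is
deterministic from the manifest: no ≥ 75% adenine content, no internal
3′-adapter anchor (including across the insert/adapter junction), no 5′
end that mimics a 5′-adapter suffix. Planted hairpin designs are verified
by running the actual rule evaluator and resampled until exactly the
intended rule-flag vector is realized; the weak-MFE and no-star designs
use constrained alphabets ({A,U} stems with C-only loops/spacers, {A,C}
matures without AA runs) chosen so the intended fold is forced rather
than probable. Planted target sites are reverse complements of a miRNA
with one non-seed mismatch (at position 13 for cleavage-mode sites, 10
for repression-mode), inserted into cDNA genes by segment replacement;
one GO term is concentrated on the site-carrying genes to give the
enrichment stage a planted positive.

What passing these tests shows: the bookkeeping is exact (category
partitions, count conservation), every rule and threshold triggers
precisely where specified, and the discovery machinery recovers planted
signal without false positives under the stated matching rules. What it
does not show: robustness to sequencing-error models, degradome-scale
reference complexity, paralogous reference sequences that differ by a few
mismatches, or the judgement calls of manual curation — real libraries
contain all of these. One visible interaction even in synthetic data: a
1-mismatch conserved read occasionally coincides with the reverse
complement of a planted target site inside a cDNA and is classified cDNA
by cascade order, so conserved recovery is ~99.9% rather than 100%.

## Problem sizes and numerics

Default test/verification sizes: a 5,000-read library for unit tests, a
50,000-read library for the recovery checks, 400 reads for the golden
run, 500 random sequences ≤ 22 nt for the folding-oracle sweep, 100
random parameter sets (N ≤ 30) for the enrichment oracle — sizes chosen
so the planted classes are well populated while the whole suite stays
quick on one core. Floats in machine-readable summaries are rounded to 6
significant digits and table percentages to fixed decimals, which makes
golden outputs portable across platforms. All orderings (tags, hits,
enrichment rows) have documented deterministic sort keys, so identical
inputs and seeds give identical files.
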