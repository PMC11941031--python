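# Methods

This note documents the models, parameters and numerical choices behind
`smmiptools`, and what the synthetic-data tests do and do not demonstrate.

## The assay being modeled

A single-molecule molecular inversion probe (smMIP) is a single-stranded
oligo whose two terminal arms hybridize to the same template strand,
flanking a target region. Gap-fill polymerization from the elongation arm
across the insert, followed by ligation to the hybridization arm,
circularizes the probe around a copy of the target; circles are amplified
with universal backbone primers and sequenced. A 9-nt fully degenerate UMI
inside the probe tags each capture event, so PCR duplicates can be
collapsed. On bisulfite-converted DNA the template is C-depleted
(unmethylated C reads as T; methylated CpG C stays C), which both collapses
sequence complexity and leaves CpGs under the arms with an unknown base
(template Y = C/T, probe R = A/G).

Coordinates are 0-based half-open everywhere internally; only file
boundaries convert (BED native, VCF −1 on input, Bismark coverage +1 on
output). Minus-strand target CpGs are normalized to the plus-strand
cytosine (a CpG site is its own reverse complement); strand is kept as
metadata only. Probes are designed against the original-top (OT) converted
strand by default; the original-bottom (OB) conversion is implemented and
selectable.

## Thermodynamics

Arm melting temperatures use the stacked nearest-neighbor model,
`Tm = ΔH / (ΔS + R·ln(C_T/x)) − 273.15`, with the SantaLucia unified
ΔH/ΔS table, duplex initiation terms and the entropic monovalent-salt
correction (0.368·(N−1)·ln[Na⁺]), evaluated by Biopython's `Tm_NN`.
Defaults: 50 mM Na⁺, 25 nM oligo (each strand). An independent flat
per-dinucleotide lookup oracle in the test suite pins the parameterization
to 0.01 °C. Degenerate positions are resolved to the unmethylated expansion
(template Y→T, probe R→A) before Tm/GC computation — the majority state
genome-wide; the resolution is a configuration choice, not a claim about
any particular locus.

Hairpin and dimer screening is deliberately **not** a partition-function
fold: it finds the best *ungapped* antiparallel complementary stretch
(within one oligo, with a ≥ 3-nt loop, stem ≥ 4 bp; between oligos,
stem ≥ 5 bp), scores every sub-stem of each maximal complementary run by
its nearest-neighbor stem Tm (Tm is not monotone under stem extension), and
reports hits above a 20 °C stem-Tm threshold. This model is reproducible,
exactly checkable against an O(n³) brute-force oracle, and strong enough to
enforce a dimer-free pool. Degenerate Y/R pair optimistically (any
expansion that pairs counts) so ambiguity codes never hide a conflict; N
never pairs, because the only N runs in an assembled probe are the random
UMI, which would otherwise make every probe pair trivially "complementary".

## Probe design

Hard windows (the stringent profile): insert length 90–100 bp, arm length
25–30 bp, arm GC 0–60 %, arm ΔTm ≤ 5 °C; the panel-wide arm-Tm spread is
capped at 10 °C. Soft penalties, combined linearly with unit default
weights: CpGs overlapped by the arms (counted on the pre-conversion genomic
sequence), common SNP positions under the arms, arm ΔTm, and hairpin stem
Tm in excess of the 20 °C threshold. CpGs *inside* the captured insert are
not penalized — only arm annealing is disturbed by unknown methylation —
though the insert interval is reported for coverage analyses. The linear
combiner is the simplest monotone choice; selection depends only on the
induced ordering.

Enumeration considers every (insert placement, arm length pair)
combination; arms shared by many candidates are featurized once. A region
yielding more than 50 000 surviving candidates keeps the 50 000 with
smallest ΔTm (configurable; never triggered at the default windows).
Candidate-level hairpin screening covers the two arms; the assembled probe
(arms + UMI + backbone) is screened at selection time on sampled
candidates, treated exactly like a dimer conflict. Screening ~40 000
assembled sequences per target would dominate runtime while almost all of
them are never sampled; the final pool is still guaranteed clean.

Selection is round-based per constraint stage: one candidate per target is
drawn with probability ∝ 1/(1+penalty) (a softmax transform is available);
the tentative pool is screened for probe–probe dimers, assembled hairpins
and the Tm-spread cap (the probe farthest from the panel median Tm is
flagged when the cap is exceeded); every conflicted candidate's penalty is
incremented by 5.0 and its target resampled. After 50 rounds a maximal
conflict-free subset is fixed (so a mutually dimerizing pair loses only one
member) and the remainder re-enumerates under the next loosened stage:
insert 90–100 → 85–105 → 80–110 bp, arms 25–30 → 24–32 → 22–34 bp, GC cap
60 → 70 → 80 %, arm ΔTm 5 → 7 → 10 °C. Penalties reset on re-enumeration.
Targets failing all stages are recorded with a reason
(`no_candidates` / `unresolved_conflicts` / `window_out_of_bounds`) rather
than silently dropped. With a fixed seed the whole pipeline, including CSV
output, is byte-reproducible; all iteration orders are sorted.

The default backbone is the widely used 30-nt MIP backbone compatible with
common sequencing-adapter priming; it is a pure configuration value. The
specificity scan counts exact occurrences of each arm's binding site in the
converted genome with degenerate-aware matching — converted-space
collisions (two loci identical only after C→T) are exactly the failure mode
that matters here — and flags multi-mappers as warnings, not rejections.

## Capture simulation

The simulator is the toolkit's study-condition generator, not a sequencer
model. Per capture event it draws a category — with insert (remainder),
self-circularized (0.30), unrelated artifact (0.10), chimeric arm join
(0.05) — then a probe proportional to its log-normal capture efficiency
(σ = 1.6, chosen so the 1st–99th percentile efficiency ratio exceeds
1000-fold, matching the observed coverage heterogeneity of probe-dependent
capture), the target CpG state ~ Bernoulli(β), a fresh 9-nt UMI, and a
geometric PCR duplicate count (mean 3; optionally biased by methylation
state to exercise UMI correction). Non-CpG cytosines of the insert convert
with probability 0.98; non-target insert CpGs are emitted unmethylated.
Read layout (fixed by this artifact and mirrored by the classifier):
`M = UMI(9) ∥ hyb-site ∥ insert ∥ elong-site ∥ backbone`,
R1 = M (adapter-filled) truncated to 150 bp, R2 = reverse complement of M
likewise. Arm regions derive from the synthetic probe (R positions resolve
uniformly at random per event, no conversion noise); the insert derives
from the captured template. Sequencing substitutions are applied per emitted
read at 0.001/base with constant quality.

What this does **not** emulate: instrument error profiles and quality
decay, indels, adapter read-through chemistry, DNA fragmentation and input
titration, genuine off-target genomic capture (unrelated reads are random
sequence), and methylation haplotype structure. Passing the round-trip
tests therefore shows the analysis is correct *given* the modeled failure
modes, not that real libraries will reach the same accuracy.

## Read classification and methylation calling

Arms are located by a seeded k-mer search (seed length
`max(6, min_arm_len // (max_mismatches + 1))`, so the pigeonhole principle
guarantees equivalence with a full sliding Hamming scan) with IUPAC-aware
verification: a site Y matches read C or T; mismatches are capped at 10 %
of the arm length, rounded down. Categories follow the three-group scheme;
the gap between arm matches on read 1 decides no-insert (< 5 bp) versus
with-insert (≥ 5 bp); a hybridization arm on R1 paired with an elongation
arm on R2 in consistent orientation is with-insert, with the insert merged
from both mates (R1 wins where they overlap) — necessary because a 90+ bp
insert usually pushes the elongation arm off a 150 bp read. Two arms from
different probes mark a chimera, reported under the off-target tally rather
than as a fourth category; single-arm reads are not-probe-related with the
found probe recorded.

Insert reads align gaplessly at offset 0 (arm-anchored) to the expected
converted amplicon, with the bisulfite-aware rule: read T matches reference
Y or T; read C matches reference Y, C, or a reference T that derives from a
genomic C (incomplete conversion); cap 10 % mismatches. Reads sharing
(probe, UMI) collapse to one capture event by per-CpG majority; exact ties
are *missing* (unbiased under symmetric error, unlike defaulting to
unmethylated). Beta values and coverage are reported both raw and
UMI-collapsed; the 20× minimum-coverage filter applies to the counting unit
in force (events when collapsing — stated in the report), and the Bismark
coverage output is 1-based, tab-delimited, sorted. A non-directional mode
additionally tries the reverse-complement orientation; on the simulator's
fixed orientation it changes nothing, which the tests assert.

## Problem sizes

The test suite and the acceptance script run at desk scale: panels of 2–20
probes on 8–50 kb synthetic contigs, 200–4000 read pairs per simulation
(the parameter-recovery run uses 10 probes × 300 read pairs/probe). These
sizes keep every check exact or tightly seeded while exercising all code
paths; the library itself has no size-dependent switches.

## Known limitations

* The dimer/hairpin model ignores gapped and G·T wobble pairings and loop
  entropy; a full secondary-structure model would score differently near
  the 20 °C threshold.
* Specificity is an exact-occurrence scan in converted space, not an
  alignment: near-exact repeats with a single mismatch are not flagged.
* UMIs are compared exactly; an edit-distance-1 merge is deliberately out
  of scope, so UMI sequencing errors can split one event in two.
* The gapless arm-anchored aligner cannot rescue reads with indels in the
  insert.
* Panel Tm-spread enforcement is greedy (flag the worst outlier per round);
  it can fail targets that a combinatorial reassignment would keep.
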