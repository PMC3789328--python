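# Methods

`sharkmir` re-implements, as an open and tested pipeline, a miRNA
discovery workflow for a species without a sequenced genome: small-RNA
reads are cleaned and collapsed, mapped in a fixed cascade against known
miRNA references and a proxy genome of a related species, and genome-only
reads are promoted to putative candidate (PC) miRNAs when their genomic
context folds into a hairpin satisfying twelve numeric criteria.  This
note records the models, the defaults, and the judgement calls.

## Read cleaning

A read is kept when its 3' adapter is found and the insert in front of it
is 15–30 nt without an ambiguous base.  The adapter is located at the
leftmost exact occurrence of its first 8 nt; one mismatch is tolerated
when the full adapter fits in the read (`TrimPolicy`).  An adapter at
position 0 is an adapter-dimer and is dropped, as are inserts shorter
than 15 nt and reads whose adapter is absent.  N-containing inserts count
as junk.  Quality strings are parsed but otherwise ignored: the workflow
defines no quality threshold beyond N-removal.  Collapsing orders tags by
descending count, then lexicographically, so output files are
byte-identical across runs.

## Group classification

Every unique tag receives exactly one group; per-library group read
counts therefore sum exactly to the clean-read total (the additivity the
published distribution table exhibits).  The cascade is: focal-species
precursors (1a) → known precursors/matures of related species (1b if the
matched precursor itself occurs in the proxy genome; otherwise 2a when
the tag's own genomic flank yields a qualifying hairpin, else 2b) →
other-RNA references (3a genome-mappable / 3b not) → genome only (4a
criteria-passing hairpin, 4b folds but fails criteria, 5 no credible
fold) → nothing (6).

Defaults: 1 mismatch against known-miRNA and other-RNA references, 0
against the genome; tags may overhang a mature reference by up to 2 nt
per end; genome hits are extended by 80 nt on each side for hairpin
screening, which keeps candidate precursors inside the typical 60–100 nt
pre-miRNA range.  The genome is searched on both strands; minus-strand
flanks are reverse-complemented so the tag always reads sense.

Two boundaries in the cascade are genuinely underdetermined and are
explicit knobs:

* **4b vs 5** — "folds but fails" is defined as: some candidate window
  forms a stem-loop of ≥ 10 bp with surrogate dG ≤ −10 kcal/mol
  (`HairpinScreen.fold_min_bp`, `fold_max_dg`).
* **Which genome hit to screen** — a read excised from one arm of a
  perfect-stem precursor also maps, reverse-complemented, onto the other
  arm, and the screen can legitimately succeed at only one of the mapped
  positions.  `classify` therefore screens the flanks of up to the top 4
  genome hits and accepts if any passes; reported evidence still lists
  every hit, best first (mismatches, then chromosome, then position).

## Hairpin model

The built-in fold is a Nussinov-style dynamic program maximizing
stacking-weighted base pairs — GC = 3, AU = 2, GU = 1 — with a minimum
hairpin loop of 3 nt.  Traceback ties are broken toward pairing the
leftmost candidate, making structures deterministic.  The free energy is
a surrogate, not a nearest-neighbour thermodynamic model:

    dG = −(total pair weight) + 0.5 × (number of enclosed unpaired runs),

clamped at 0.  Loops and bulges destabilize, which fixes the sign of the
penalty term.  This surrogate is deliberately simple: the criteria logic,
not the thermodynamics, is the subject here, and externally computed
folds (RNAfold/Mfold dot-bracket with a trailing energy) are accepted via
`read_fold_file` and evaluated by the identical criteria code.

Structure bookkeeping on the chosen stem-loop (multi-branch structures
are flagged and judged on the stem-loop with most pairs):

* an **error** is an unpaired position inside a region;
* a **bulge** is a maximal run of consecutive unpaired positions in the
  stem;
* a **biased error** is the asymmetric excess of an internal loop —
  |unpaired on the 5' side − unpaired on the 3' side| between two
  consecutive stem pairs; a bulge is biased when that excess is nonzero.

The twelve criteria are applied verbatim: dG ≤ −15 kcal/mol; hairpin
(up + down stem + terminal loop) ≥ 50 nt; stem ≥ 16 bp; terminal loop
≤ 20 nt; mature-region pairs ≥ 12; ≥ 80% of the small RNA inside the stem
arms (pm, denominated by mature length); mature errors ≤ 7; largest stem
bulge ≤ 12; largest mature bulge ≤ 8; biased errors in the worst mature
bulge ≤ 4; biased mature bulges ≤ 2; MFEI ≥ 0.7 with
MFEI = −dG·100/precursor length/GC%.  The stem-bulge bound (≤ 12) being
looser than the mature bound (≤ 8) is kept as printed.  A GC% of zero
leaves MFEI undefined and fails criterion 12.  The precursor length in
MFEI is the full folded candidate window.

Because the precursor boundaries around a mapped read are unknown, the
screen folds a grid of windows (lengths 60–110 nt, anchored at either end
of the read with 2 or 8 nt margins, read taken as 5p arm and as 3p arm)
and accepts the first window passing all twelve criteria.

## Variant nomenclature

A detected mature sequence is related to a known reference by an ungapped
alignment searched over ±5 nt end offsets with ≤ 3 substitutions — bounds
chosen to cover every name shape the workflow emits (largest observed:
R+5, 2ss).  Minimal substitution count wins; ties break by smaller total
end displacement, then smaller left offset.  Names render as
`known[_L±n][R±n][_<k>ss(<pos><from><to>)+]`, substitution positions
1-based in the detected sequence, DNA alphabet; an exact copy is the bare
known name.  Decoding is the exact inverse; positive offsets draw bases
from the supplied genomic flank of the reference, and
`decode(encode(describe(d)))` = d is property-tested across the full
descriptor space.  One published token of the form `13TA` described as a
substitution "at position 1" is treated as position 13 (an evident typo).
PC miRNAs are named `PC-{arm}-{rank}_{count}` with rank by descending
read abundance per arm.

## Clusters

Loci on one chromosome join a cluster when their distance is ≤ 10,000 bp,
transitively (single linkage).  Distance is the inter-locus gap (end of
the left locus to start of the right one, boundary inclusive, overlap =
0); start-to-start is available as a config option.  Strand is ignored
for clustering and retained in output.  Clusters are numbered by
(chromosome, leftmost start); singletons are reported and labelled.  Loci
sharing a precursor are 5p/3p duplex partners; a two-member cluster that
is exactly one duplex is flagged duplex-only.

## Quantification

Sequencing counts are normalized to reads per million and compared as
log2((a + c)/(b + c)) with pseudocount c = 0.25 (the workflow states no
zero-handling; 0.25 is a conventional choice).  A miRNA is differential
when |log2 ratio| is strictly greater than 1.

qPCR tables use the comparative-Ct method on replicate means:
ΔCt = Ct(target) − Ct(reference gene), ΔΔCt = ΔCt(group) − ΔCt(control
group), relative expression 2^−ΔΔCt.  The control group is exactly 1 by
construction.  The reported SE is that of ΔΔCt in cycles, combining the
four mean-Ct standard errors in quadrature; per-replicate ΔCt is
available but the mean-first formulation matches the usual
"average Ct ± SE" presentation.  The implementation follows the stated
formula only — it makes no attempt to fit any particular published
fold-change table, since relative quantification is fully determined by
the Ct values.  No efficiency correction (Pfaffl) and no significance
testing are performed.

## Target scanning

The miRNA, read 3'→5', is locally aligned against each target with
complementarity scoring: Watson–Crick +5, G:U wobble +1, mismatch −3,
affine gaps −8 open / −2 extend; substitution scores at miRNA positions
2–8 from the 5' end (the seed) are doubled (scaling 2.0).  Sites must
reach score ≥ 50 and duplex energy ≤ −20 kcal/mol.  The energy is again a
surrogate: per helix stack GC −2.2, AU −1.1, GU −0.5 kcal/mol, +4.1 per
interior loop/bulge opening; externally computed energies can be injected
through `energy_fn`.  Candidate sites are score peaks along the target;
sites overlapping a kept site by ≥ 50% are dropped in favour of the
higher score.  The seed window bounds are configurable, as seed
conventions differ between tools.

## Synthetic fixtures

The generator is a pure function of (seed, config).  It emulates a
size-selected small-RNA library from a genome carrying hairpin-encoded
miRNAs: precursors are perfect stems (default 28 bp, GC fraction 0.55)
with an all-A terminal loop (default 10 nt) — non-pairing both in the
precursor (A·A) and in its reverse complement (U·U), so no spurious
in-loop helices arise on either strand — planted in random sequence with
12–20 kb spacers, except for a configured number of precursors dropped
2–5 kb after their predecessor to create known clusters (expected
clusters = precursors − close pairs).  Hairpin validity is certified
constructively: the closed-form surrogate energy of a perfect stem,
−(3·n_GC + 2·n_AU) + 0.5, and the trivially known pairing geometry are
checked against the criterion bounds arithmetically, independent of the
evaluator under test.  Reads are the mature sequence plus adapter, padded
to 40 nt; per-miRNA counts are Poisson around the configured depth
(default 100); background reads are random 15–30-mers rejection-sampled
against the genome and references, guaranteeing their group-6 truth
label.  Adapter-seed 8-mers are excluded from planted precursors so
trimming cannot truncate a planted tag.

What the fixtures do **not** emulate: sequencing errors, ligation bias,
length heterogeneity of real isomiRs, imperfect (bulged) precursor stems,
repeat families, or cross-mapping tags.  Passing the end-to-end recovery
tests therefore demonstrates the pipeline's bookkeeping and decision
logic, not robustness to the noise structure of real libraries.

## Problem sizes and numerical choices

The test and reproduction workloads use 20 planted novel + 5 known
precursors at depth 100 (end-to-end), 200 random sequences ≤ 30 nt for
fold/oracle agreement, 1,000 seeded variant pairs for nomenclature
round-trips, and 100 seeded locus sets for cluster/union-find
equivalence — sizes at which every independent oracle is exact and the
whole suite runs in seconds.  Percentages in report tables are rounded
half-up to one decimal.  Coordinates are 0-based half-open internally and
1-based inclusive in reports (GFF convention).  All randomness flows
through `numpy.random.default_rng` seeded from explicit integers.

## Known limitations

The surrogate fold is not Mfold/RNAfold-equivalent; criteria verdicts on
real candidates should use imported folds for fidelity.  The brute-force
mapper is adequate for desk-scale genomes (hundreds of kb to a few Mb)
but is no replacement for an indexed aligner at whole-genome scale.
Group 1b requires the matched reference precursor to occur exactly in the
proxy genome, which is strict when the proxy is a related species rather
than the focal one.  The 4b/5 boundary is a heuristic with no ground
truth; it is surfaced as configuration rather than buried.
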