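# sharkmir

Discovery and annotation of microRNAs from small-RNA sequencing in a
species **without a sequenced genome**, using the genome of a related
species as a proxy.  The package re-implements, as an open and tested
library, the workflow used to characterize liver miRNAs of the
whitespotted bamboo shark against the elephant-shark genome: read
cleaning, a fixed mapping cascade into ten groups, hairpin-criteria
evaluation with the minimal folding energy index, isomiR-style variant
naming, 10-kb genomic cluster detection, and expression quantification.
It is aimed at small-RNA bioinformaticians who need the whole decision
chain to be inspectable and reproducible offline — every stage is driven
by a seeded synthetic-fixture generator with known ground truth.

## The method in brief

* **Cleaning.** Reads keep the insert before the leftmost 3'-adapter
  occurrence; inserts of 15–30 nt without N are collapsed into unique
  counted tags per library.
* **Classification.** Each tag lands in exactly one group: focal-species
  precursor (1a); known precursor/mature of a related species, with the
  precursor genome-mappable (1b) or the tag's own flank hairpin-positive
  (2a) or not (2b); other RNA, genome-mappable or not (3a/3b); genome
  only with a criteria-passing hairpin (4a — a putative candidate, PC,
  miRNA), a failing fold (4b), or no fold (5); unmappable (6).  Group
  read counts add up exactly to the library total.
* **Hairpin criteria.** A candidate precursor must satisfy twelve bounds,
  among them dG ≤ −15 kcal/mol, stem ≥ 16 bp, terminal loop ≤ 20 nt,
  ≥ 80% of the small RNA inside the stem, and

      MFEI = −dG · 100 / mirLen / CG% ≥ 0.7 ,

  the index that separates miRNA precursors from other folded RNA.
* **Nomenclature.** A detected sequence is named after its closest known
  miRNA plus end-offset and substitution tokens, e.g.
  `ola-miR-144_L-1R+2_1ss12TA` (one base fewer on the left, two more on
  the right, T→A at position 12); novel candidates become
  `PC-{5p|3p}-{rank}_{count}`.
* **Clusters.** Loci within 10,000 bp on one chromosome form a cluster
  (single linkage); two matures cleaved from one precursor are a 5p/3p
  duplex pair.
* **Expression.** Reads-per-million with log2 ratios (|log2| > 1 =
  differential) and qPCR 2^−ΔΔCt on replicate means, with
  ΔCt = Ct(target) − Ct(reference), ΔΔCt = ΔCt(group) − ΔCt(control).
* **Targets.** miRanda-style complementarity scan of miRNAs against
  3'-UTR/EST sequences (gap open −8.0, extend −2.0, score ≥ 50.0, energy
  ≤ −20.0 kcal/mol, 5'-seed scaling 2.0).

The built-in fold is a documented surrogate (max-weight Nussinov-style
DP); externally computed Vienna/Mfold folds are accepted for fidelity.
See `docs/methods.md` for every model, default, and judgement call.

## Worked example

Each capability has a narrative script under `examples/`.  The core one,
hairpin evaluation (`examples/02_hairpin_criteria.py`):

```text
GUCUAAUAUCGUCCGGGCGCAAUCGAAAAAAAAAAAUCGAUUGCGCCCGGACGAUAUUAGAC
((((((((((((((((((((((((((..........))))))))))))))))))))))))))
dG = -65.5 kcal/mol   MFEI = 2.34   stem = 26 bp   loop = 10 nt
  [x] dG <= -15 kcal/mol
  [x] hairpin length >= 50 nt
  [x] stem base pairs >= 16
  ...
  [x] MFEI >= 0.7
qualifies as a pre-miRNA hairpin: True
```

A 62-nt candidate folds into a 26-bp stem with a 10-nt loop; its
surrogate free energy and MFEI clear all twelve bounds, so a read mapping
to one of its arms would be promoted to a PC miRNA.  The full pipeline on
a simulated two-library study (`examples/08_full_pipeline.py`) prints:

```text
sharkmir run report
===================
library LN: 504 clean reads
library LR24: 505 clean reads
known miRNAs (groups 1b/2a): 3
PC miRNAs (group 4a): 10
clusters: 9
duplex (5p/3p) pairs: 2
```

— the 3 planted known-miRNA copies surface in group 1b under their
reference names, the 8 planted novel hairpins (2 expressing both arms,
hence 10 mature PC miRNAs) in group 4a, and the genomic layout is
recovered as 9 clusters with 2 duplex pairs, exactly the planting plan.

There is also a thin CLI mirroring the library
(`sharkmir trim|classify|hairpin|annotate|cluster|diffexpr|ddct|scan|simulate|run`).

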