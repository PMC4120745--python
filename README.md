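# lineorf1

Analysis of the modular, reticulate evolution of ORF1 proteins in
Jockey-superfamily LINE retrotransposons (the CR1, L2 and Jockey lineages).

Most LINEs carry two open reading frames. ORF2 — apurinic endonuclease (APE)
plus reverse transcriptase (RT) — is structurally conserved and evolves
tree-like, so a neighbor-joining phylogeny of the concatenated APE+RT
domains defines lineages and subgroups. ORF1, a nucleic-acid-binding
protein, is built from interchangeable modules — RRM (RNA recognition
motif), CCHC zinc knuckle, PHD finger, the composite transposase-22 module
(coiled-coil + RRM + CTD), esterase, zinc finger / leucine zipper — and its
evolution is reticulate: domains are gained, lost and occasionally whole
ORF1s move between lineages. `lineorf1` provides the complete toolchain for
studying this:

* **Domain annotation** (`lineorf1.domain_scan`): ungapped PSSM scans of a
  seven-profile library, with hit probabilities calibrated as empirical
  percentiles of shuffle-null maxima and the 85% acceptance rule; heptad
  coiled-coil detection.
* **Architecture typing** (`lineorf1.architecture`): the five-type /
  three-subtype ORF1 grammar. Precedence V (coverage < 10%) → IV (esterase)
  → II (Tnp22) → I (RRM immediately upstream of a CCHC) → III (PHD) → V,
  with subtypes encoding PHD position, RRM/CCHC multiplicity and zf/lz
  presence.
* **Phylogenetics** (`lineorf1.phylo`): pairwise-deletion identities,
  p/Poisson/Kimura amino-acid distances, Saitou–Nei neighbor joining with
  fixed tie-breaking, column-bootstrap bipartition supports, Fitch/Hartigan
  parsimony, and support-plus-structure subgroup delineation.
* **RRM clustering** (`lineorf1.clustering`): all-vs-all Smith–Waterman
  z-scores of extracted RNP2→RNP1 RRM cores, thresholded connected
  components and a force-directed layout.
* **Transfer detection** (`lineorf1.congruence`): a lineage monophyletic in
  the ORF2 tree whose ORF1s nest strictly inside another lineage's clade of
  the ORF1 tree is reported as a horizontal-acquisition candidate, with a
  permutation p-value.
* **Simulator** (`lineorf1.synthetic`): Yule lineage trees, Poisson protein
  evolution, modular ORF1 events (PHD gain/loss, esterase gain) and
  explicit whole-ORF1 transfers, with a replayable event log — full ground
  truth for every pipeline stage.

A transcription of the published 20-subgroup domain table (448 elements)
ships as a regression fixture (`lineorf1.io_formats.load_table1_fixture`;
see `src/lineorf1/data/README.md`).

## Worked example

Classify a freshly built Jockey-style ORF1
(`python examples/01_annotate_and_classify.py`):

```
ORF1 length: 292 aa
  RRM       [ 20,  95)  score=  225.4  prob=100.0%  accepted=True
  RRM       [107, 182)  score=  225.4  prob=100.0%  accepted=True
  CCHC      [194, 212)  score=   53.8  prob=100.0%  accepted=True
  CCHC      [224, 242)  score=   53.8  prob=100.0%  accepted=True
  CCHC      [254, 272)  score=   53.8  prob=100.0%  accepted=True
architecture: RRMx2-CCHCx3  coverage=0.70
ORF1 type: IB  (type I = RRM immediately upstream of CCHC; subtype B = >=2 RRMs with >=3 CCHCs)
```

Each line is one accepted profile hit: coordinates are 0-based half-open,
the score is the log-odds sum of the best window, and the probability is
the percentile of that score among null-scan maxima (hits at or above 85%
are accepted). Two RRMs directly upstream of three CCHC knuckles with 70%
of the ORF covered is the canonical Jockey-lineage architecture, type IB.

Detect a simulated horizontal ORF1 acquisition
(`python examples/05_horizontal_transfer.py`):

```
injected transfer: L2 ORF1 -> CR1 clade ['CR1-03', 'CR1-04', 'CR1-05', 'CR1-06']
elements carrying the RRM+CCHC block: 11
candidate: CR1 ORF1s embedded in L2
  recipients: CR1-03,CR1-04,CR1-05,CR1-06
  embedding positions: 1
  delta Fitch (ORF1 vs ORF2 label changes): 0
  permutation p: 0.003
ground-truth recipient set recovered exactly: True
```

The four CR1 recipients stay inside the CR1 lineage on the ORF2 tree but
their ORF1s cluster inside the L2 clade of the RRM+CCHC-block tree — the
embedding pattern that diagnoses horizontal ORF1 acquisition. The
permutation p-value (an invented quantification, flagged as such in
reports) measures how unusually clustered the recipients' ORF1s are.

The other examples cover the reference-table statistics (`02`), bootstrap
trees and subgroup delineation (`03`), and RRM clustering (`04`).

## Command line

A thin CLI wraps the library:

```bash
lineorf1 simulate --n-taxa 20 --seed 7 --ht --outdir sim/
lineorf1 run-all --orf1-fasta sim/orf1.fasta --ape-fasta sim/ape.fasta \
    --rt-fasta sim/rt.fasta --lineage-tsv sim/true_lineages.tsv \
    --seed 7 --outdir out/
lineorf1 fixture-stats
```

`run-all` writes annotation, classification, subgroup, cluster, layout and
transfer tables plus both newick trees; every file carries the tool version
and a config hash, and a rerun with the same inputs and seed is
byte-identical.

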