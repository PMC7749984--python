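# cladetrace

Progressive phylogenetic analysis, calibrated molecular-clock dating and
mitochondrial-introgression discordance — exercised end-to-end on simulated
hominin mtDNA scenarios.

## The problem

Arguments about the deep geography of modern-human origins often rest on a
small set of phylogenetic observations made on mitochondrial genomes:

* whether a labelled group of populations (e.g. "the Africans") is
  **monophyletic or paraphyletic** on the mtDNA tree, tracked step by step as
  taxa are added to the sampling (*progressive phylogenetic analysis*, PPA);
* a **divergence-time chain** obtained from a strict clock and a single
  external calibration (here the chimpanzee/human split, fixed at 8 MYBP);
* a **gene-tree/species-tree conflict**: an mtDNA capture event moves the
  recipient lineage across the tree, and the *direction* of the transfer is
  read off the displaced taxon's new sister group.

`cladetrace` implements this whole chain as tested, reusable code.  Because
such claims are typically published without deposited alignments, the package
ships a synthetic-scenario module that is a first-class citizen: a dated
species tree for chimpanzee (`Pan`), Denisovan (`Hsnd`), the Sima de los
Huesos and classic Neanderthal lineages (`SH_Hsnn`, `Hsnn_star`) and six
modern humans (`Mbuti`, `San`, `Yoruba1`, `Yoruba2`, `Lund`, `French`), with
one mitochondrial capture from the modern-human stem into `Hsnn_star` at
500,000 YBP.  Everything downstream is validated against this generative
truth.

## The model

Sequences evolve site-independently under JC69 or K2P (Kimura 1980,
transition/transversion rate ratio κ, default 4) along a dated tree with a
strict clock *r* (default 1.5 × 10⁻⁸ substitutions/site/year, 16,500 sites).
Distances are corrected observed proportions — JC69
`d = -(3/4) ln(1 - 4p/3)` or K2P
`d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)` — with pairwise deletion of
ambiguous sites.  Trees come from neighbor joining (exact on additive
matrices) or exhaustive Fitch parsimony at toy scale; rooting places the root
at the midpoint of the outgroup's pendant edge.  Node ages follow from mean
root-to-leaf depths and linear scaling through the calibration node:
`age(v) = cal_age · depth(v) / depth(cal)`.  Group status is classified as
monophyletic (group = a complete clade), paraphyletic (group = a clade minus
one nested clade) or polyphyletic, and discordance between a reference and a
test topology is resolved into a minimal set of displaced taxa plus a
donor/recipient call per displaced taxon.

## Worked example

```python
import cladetrace as ct

spec = ct.build_scenario_preset("fig1_fig3")
model = ct.MtdnaPhylogenyModel.from_scenario(
    spec, seed=1,
    ppa_core=["Pan", "Hsnd", "SH_Hsnn", "Hsnn_star", "Mbuti", "Lund"],
    ppa_additions=["San", "Yoruba1", "Yoruba2"],
)
res = model.fit()
print(res.summary())
```

prints

```
MtdnaPhylogenyModel results
===========================
taxa: 10  sites: 16500
inference: nj (distance model K2P)
outgroup: Pan
calibration: MRCA(Pan,Hsnd) = 8,000,000 YBP

Group classification (paraphyly = clade minus one nested clade):
  african      paraphyletic
  archaic      paraphyletic
  non_african  monophyletic

Calibrated node ages (rounded to 25,000 yr in this table):
     8,000,000 YBP  MRCA[root]
       775,000 YBP  MRCA[French,Hsnd,Hsnn_star,Lund,Mbuti,SH_Hsnn,San,Yoruba1,...]
       400,000 YBP  MRCA[French,Hsnn_star,Lund,Mbuti,San,Yoruba1,Yoruba2]
       250,000 YBP  MRCA[French,Lund,Mbuti,San,Yoruba1,Yoruba2]
       225,000 YBP  MRCA[French,Lund,Yoruba1,Yoruba2]
       175,000 YBP  MRCA[French,Lund,Yoruba2]
       125,000 YBP  MRCA[French,Lund]
       650,000 YBP  MRCA[Hsnd,SH_Hsnn]
       150,000 YBP  MRCA[Mbuti,San]

PPA placements:
  step 1: +San on edge [Mbuti]
  step 2: +Yoruba1 on edge [Lund]
  step 3: +Yoruba2 on edge [Lund]

Discordance vs reference topology:
  shared bipartitions:      5
  conflicting bipartitions: 4 (RF distance)
  displaced taxa: {Hsnn_star}
  direction: donor lineage {French,Lund,Mbuti,San,Yoruba1,Yoruba2} -> recipient Hsnn_star (forward configuration)
  note: direction is inferred from topology alone; branch lengths and alternative discordance processes are not tested
```

Reading the output: on this replicate the mtDNA tree nests the single
non-African core lineage (`Lund`) *inside* the span of the African taxa, so
the African group is paraphyletic; the rooted ingroup splits
`(Hsnd, SH_Hsnn)` from `(Hsnn_star + modern humans)` near 800,000 YBP; and
the displaced-taxon analysis recovers `Hsnn_star` as the recipient of an
mtDNA transfer from the modern-human stem — the generating scenario.  The
`400,000 YBP` row is this replicate's (noisy) estimate of the 500,000 YBP
capture node; medians over replicates recover it (see below).

The same run is available from the shell:

```sh
cladetrace run-all --preset fig1_fig3 --seed 1 --out run1/
cladetrace simulate --preset fig1_fig3 --seed 1 --out sim/   # stage by stage
cladetrace distances --fasta sim/alignment.fasta --out sim/d.phy
cladetrace infer --matrix sim/d.phy --outgroup Pan --out sim/tree.nwk
```

## Layout

| module | contents |
| --- | --- |
| `scenarios`, `simulate` | dated scenario presets, introgression events, locus trees, clock simulation |
| `distances` | p/JC69/K2P distances, PHYLIP matrix I/O |
| `treebuild`, `treeutils` | neighbor joining, UPGMA, rooting, bipartitions |
| `parsimony` | Fitch scoring, topology enumeration, exhaustive search |
| `ppa` | monophyly classification, attachment edges, progressive runs |
| `chronology` | node depths, single-calibration dating |
| `discordance` | topology comparison, displaced taxa, direction inference |
| `model`, `pipeline`, `cli` | Model/Results interface, one-command runs, CLI |

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
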