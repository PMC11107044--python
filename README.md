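# pulkit

Analysis toolkit for polysaccharide utilization locus (PUL) induction and
substrate preference in glycan-degrading gut and rumen *Bacteroidota*
(e.g. *Segatella bryantii*, *Xylanibacter ruminicola*).

Bacteria of this phylum sense, bind, import and depolymerize dietary
polysaccharides through PULs — co-regulated gene clusters whose hallmark is
a *susC/susD*-like transporter/binding-protein pair.  Which glycan a
predicted PUL actually targets, and which substrate a generalist strain
prefers when several are available, are questions answered experimentally
by (i) growth phenotyping on pure glycans, (ii) RNA-seq induction profiling
against a glucose reference, and (iii) qRT-PCR time courses of *susC*
markers in two-substrate mixtures.  `pulkit` implements that full analysis
chain, plus a synthetic-data generator with known ground truth so every
stage is testable end to end.

## What it computes

**Growth phenotyping** (`pulkit.growth`).  Dilution-corrected OD600 curves
are stitched (`OD = measured x dilution factor`), the exponential phase is
located by sliding-window log-linear fits, and the specific growth rate is
the two-point formula

    mu = (ln A_max - ln A_min) / (T_max - T_min)

over that phase, with `maxOD` the highest corrected OD.  Growth on a
substrate is *excellent* (mu >= 0.5/h and maxOD >= 3), *poor* (mu < 0.5/h
and maxOD <= 1.5) or *good* (otherwise).  Expected growth on a
polysaccharide is the monosaccharide-composition-weighted sum of the rates
(or maxODs) measured on its component sugars.

**Induction profiling** (`pulkit.expression`).  From a gene x sample count
matrix: CPM/TPM within-sample normalization, TMM (trimmed mean of M-values)
between-sample scaling factors implemented from first principles (verified
to 1e-6 against edgeR's `calcNormFactors`), CPM-based expression filtering,
and per-gene induction

    log2FC(g, s) = log2( (mean normalized CPM on substrate s + c) /
                         (mean normalized CPM on glucose + c) )

with pseudocount c = 0.5 CPM.  Genes with |log2FC| > 3 on at least one
substrate are selected; per PUL, the mean log2FC of its susC/susD markers
is summarized and each substrate is called **confirmed** (maximal marker
induction, > 3), **cross_activated** (> 3 but not maximal), **moderate**
(1–3) or **not_induced**.

**Substrate preference** (`pulkit.preference`).  qPCR marker induction is
quantified as 2^-ddCt (16S rRNA reference gene, glucose culture as
calibrator).  Each marker time course in a two-substrate mixture is classed
*inactive* (mean induction <= 5 over all time points; 0 points), *active*
(induction > 5 at every considered time point, the final point exempted for
rapidly depleted substrates such as starch; 1 point) or *delayed*
(gradual activation; 0.5 points).  A substrate's preference score is its
summed points divided by its number of assays, yielding a [0, 1] ranking.

**Synthetic data** (`pulkit.synthetic`).  Negative-binomial count
experiments with PUL-structured induction (strong marker effects, weaker
effector effects, optional cross-activation), lag/exponential/plateau
growth curves with dilution events, and qPCR series realizing the three
dynamic classes — all seeded and bit-reproducible, with truth tables for
recovery testing.

## Worked example

Simulate a small experiment (3 PULs, glucose + 3 substrates, triplicate),
profile induction and call targets:

```
$ pulkit --seed 7 simulate --scenario minimal --outdir demo
INFO pulkit: simulated 52 genes x 12 samples (minimal)
$ pulkit induce --counts demo/counts.tsv --samples demo/samples.tsv \
    --annotation demo/pul_annotation.tsv --outdir demo/out
INFO pulkit: expression filter kept 52/52 genes
INFO pulkit: 9 genes pass |log2FC| > 3
INFO pulkit: 3 PULs confirmed on >= 1 substrate
$ head -3 demo/out/pul_calls.tsv
pul_id      substrate  marker_log2fc       status     near_tie
pul_starch  starch     6.0495501714468904  confirmed  False
pul_starch  xylan      0.12015898729607147 not_induced False
```

The starch PUL's susC/susD markers were simulated with a 6 log2-unit
induction on starch; the pipeline recovers ~6.05 and confirms starch as the
target while the other substrates stay below the gate.  Each of the three
encoded PULs is confirmed on exactly its true substrate.

Genome-level CAZyme density, as tabulated per strain:

```
$ pulkit summarize --n-cazymes 198 --genome-size-mb 3.41
58.1
```

## Layout

```
src/pulkit/
  synthetic.py    scenario fixtures and the three simulators
  growth.py       stitching, rate estimation, classification, expected growth
  expression.py   CPM/TPM/TMM, log2FC, PUL aggregation and target calls
  preference.py   ddCt, dynamic classification, preference scoring
  io.py           TSV/CSV formats, config, CAZyme density summaries
  cli.py          simulate | growth | induce | prefer | summarize | report
docs/methods.md   model assumptions, parameter defaults, design choices
```
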