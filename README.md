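# capture-kit

Tools for **Cas9-nickase paired-gRNA clonal barcoding**: design of
targetable barcode cassettes and combinatorial libraries, barcode counting
from amplicon reads, enrichment and clonal-origin statistics, editing
outcome / reporter-state QC, a multi-evidence variant priority score, and a
clonal-evolution simulator that generates realistic synthetic inputs with
ground truth.

## The problem

Cellular DNA barcoding tags every founder cell of a population (for
example, a drug-naive tumor cell line) with a heritable DNA barcode, so the
clonal composition of the population can be tracked through an experiment
by amplicon sequencing. In a paired-nickase barcoding design each barcode
is a fixed-flank cassette carrying two fully designed 20-nt gRNA target
sites separated by a 15-nt linker:

```
CGTCCG (N20, site_a) GCCACCATGGTCGAC (N20, site_b) CGGTAG     (67 nt)
```

The two PAMs sit in the fixed flanks in PAM-out orientation, so delivering
Cas9^D10A and the two cognate gRNAs cuts *only* the targeted barcode,
switching a fluorescent reporter (~2/3 of repair outcomes shift the
reading frame) and letting the clone carrying that barcode be isolated
live from the pool. Two pools of a few thousand oligos give millions of
distinct barcodes combinatorially (6,000 × 6,000 → 36 million).

After a drug-selection experiment (one vehicle control, R treated
replicates), the questions this package answers are:

* **Which barcodes are enriched?** Counts per barcode are compared with a
  conservative posterior log2 fold change for unreplicated count data: the
  read rate of a barcode has a Gamma(k + α)/N posterior, and the statistic
  is the c-quantile (default c = 0.01) of the posterior of
  log2(λ_trt/λ_ctl). Barcodes with a value above a threshold (default 4)
  are called enriched.
* **Did resistance preexist or emerge?** A barcode enriched in all R
  independent replicates is a preexistence candidate; one enriched in a
  single replicate likely acquired resistance during treatment. The chance
  probability of recurrence in r of R replicates is binomial,
  C(R, r)·P^r·(1−P)^(R−r), with P estimated as
  (enriched union)/(detected complexity), optionally multiplied by the
  complexity as a Bonferroni-style adjustment.
* **Which somatic variants explain resistance?** Each variant gets a
  priority score PS = mean(AS, DS, CS, GS, MS) of five 0–100 components
  (allele frequency, deleteriousness, CRISPR-screen fold change, clinical
  gene and mutation membership), zeroed for genes not expressed
  (FPKM < 0.1 everywhere).

## Worked example

```python
from capture_kit import clonal_stats, clone_sim
from capture_kit.clonal_stats import (
    estimate_selection_probability, preexistence_probability,
)

# simulate a 40-day drug-selection experiment: 20,000 founders barcoded at
# MOI 0.3 from a 200,000-barcode library, 1 control + 5 treated replicates
sim = clone_sim.simulate(clone_sim.SimConfig(seed=1))
summary = clonal_stats.call_enriched(
    sim.table, "control", ["R1", "R2", "R3", "R4", "R5"], threshold=4.0
)
print(summary.n_enriched_per_replicate, summary.n_enriched_union)

complexity = len(sim.table.counts)
p, pct = estimate_selection_probability(summary.n_enriched_union, complexity)
print(f"P={p:.2g} -> {pct:.2g}% of founder clones drive resistance")
print("chance of all-5 recurrence:",
      preexistence_probability(p, 5, 5, complexity, adjust=True))
```

prints (seed 1):

```
{'R1': 4, 'R2': 8, 'R3': 4, 'R4': 5, 'R5': 8} 11
P=0.002 -> 0.2% of founder clones drive resistance
chance of all-5 recurrence: 1.75e-10
```

Each treated replicate ends up dominated by a handful of clones: 4–8
barcodes clear the enrichment threshold per replicate, 11 distinct ones in
total, i.e. ~0.2% of the ~5,500 detected founder clones. The adjusted
binomial model says a *non-preexisting* barcode recurring in all five
replicates by chance is essentially impossible (~2e-10), so the barcodes
that do recur in all five replicates carried resistance before treatment.
At the study's own scale (157 enriched barcodes of 0.23 million detected,
P ≈ 0.0007) the same model gives 1.68e-16 unadjusted and 3.86e-11 adjusted.

The same workflow is available from the shell:

```sh
capture-kit simulate --seed 1 --out simdir --fastq
capture-kit count --fastq R1=simdir/R1.fastq --reference ref.tsv --out counts.tsv
capture-kit enrich --counts simdir/counts.tsv --control control \
    --treated R1,R2,R3,R4,R5 --out enriched.tsv
```

plus `capture-kit design / assemble / prioritize` for library design and
variant ranking.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the core computation from scratch: it simulates the default
experiment with the given seed, counts barcodes, calls enrichment against
the control, estimates the selection probability and the preexistence
chance model from the run's own detected complexity, scores the calls
against the planted ground truth, logs the numbers to stderr and writes
the results JSON to `--out`.
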