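# Methods

This note documents the models implemented in `capture_kit`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data generator does and does not establish.

## Cassette model and design rules (`cassette_design`)

A cassette is `five_flank + site_a + linker + site_b + three_flank`
(defaults `CGTCCG`, 15-nt `GCCACCATGGTCGAC`, `CGGTAG`; 67 nt total). The
barcode identity (`barcode_key`) is the 40-nt concatenation
`site_a + site_b`. PAM-out geometry is a spec invariant: the 3' flank must
start with NGG (plus-strand PAM for `site_b`) and the 5' flank must end
with CCN (minus-strand PAM for `site_a`); `capture_guides_for` therefore
returns `(revcomp(site_a), site_b)` as the spacer pair.

Candidate filtering enforces, in order: length 20 over A/C/G/T; no stop
codon (TAA/TAG/TGA) in any in-frame codon overlapping the candidate,
*including* junction codons completed by the fixed flank or linker; no
forbidden motif (defaults MluI `ACGCGT` and BamHI `GGATCC`, the cloning
sites — SalI is deliberately not forbidden because the linker itself
contains `GTCGAC`), again scanning across junctions; optionally a minimum
on-target score.

Open choices and how they were resolved:

* **Reading-frame phase.** The insert sits inside a fluorophore fusion
  whose codon phase at the start of the cassette depends on vector context
  not captured by the motif alone. Default `frame_phase = 0` (the 5' flank
  starts a codon); configurable, with a `strict_all_frames` mode that
  excludes stops in all three forward frames.
* **On-target scoring.** Published on-target models are not re-implemented;
  scores are accepted as an external column. The built-in fallback is a
  transparent heuristic (GC in [0.3, 0.8], no homopolymer ≥ 5, each
  violation costs 50 of 100) meant for tests and filtering sanity, not for
  real library design.
* **Oligo pools.** `emit_oligos` splits each cassette into a top oligo
  (5' flank + site + 5' part of the linker) and a bottom oligo (reverse
  complement of the rest), sharing a complementary 3' overlap of
  configurable length centered in the linker; annealing + extension of any
  top/bottom pair reconstructs the cassette exactly (tested exhaustively on
  small pools). The even n/n pool split is a parameter, not an assumption.
* **v2 frame safety.** `check_frames_v2` verifies that a coding region has
  no stop in the design frame, no stop in the −1 frame, and no canonical
  −1 programmed-frameshift slippery heptamer `X₁X₁X₁ X₂X₂X₂ N` (X₂ ∈
  {A, T}); the pattern is configurable because slippery-site definitions
  vary.

## Barcode extraction and counting (`amplicon_io`)

Reads are searched for the full fixed-flank motif at every offset (the
library uses a 0–8 nt stagger, and upstream trimming can shift reads
further), on the plus strand first, then the reverse complement; the
leftmost plus-strand hit wins when a read contains several (concatemer
artifacts). Matching is exact by default — mirroring a grep-style
pipeline — with an optional per-segment mismatch tolerance
(`max_flank_mismatch` counted separately in the 5' flank, linker and 3'
flank). N20 segments must be unambiguous A/C/G/T.

Counting keeps only keys equal to a reference key (100%-match counting).
`hamming_rescue = d` optionally rescues keys within Hamming distance d of a
*unique* reference key; ties stay unassigned. Per-sample accounting is
conservative: assigned + unassigned(no_motif, no_reference_match) equals
the reads processed, asserted in tests.

Quality trimming is reduced to nothing by default: motif matching already
rejects corrupt reads, and wrapping an external trimmer would add a
dependency without changing the exact-match contract.

## Enrichment statistic and origin model (`clonal_stats`)

For a barcode with counts `k_trt`, `k_ctl` in samples with assigned totals
`N_trt`, `N_ctl`, the posterior of the read rate is
`λ ~ Gamma(k + α) / N` (α = 1 by default). The enrichment statistic is the
c-quantile (c = 0.01) of the posterior of `log2(λ_trt/λ_ctl)` — a
conservative single-replicate generalized fold change. Two routes are
implemented: Monte-Carlo sampling of the two Gammas, and a closed form via
the Beta representation (`G_t/(G_t+G_c) ~ Beta(k_t+α, k_c+α)`, so the ratio
quantile is `q/(1−q) · N_ctl/N_trt` at the Beta quantile `q`). The closed
form is exact and is the default; the Monte-Carlo route is retained as the
independent cross-check (agreement within 0.05 over a count grid is an
acceptance property). This is a faithful-by-construction substitute for
the published tool, not a byte-identical port; its normalization uses
per-sample assigned totals rather than median-of-ratios size factors,
because barcode pools are dominated by a few clones after selection.

Enrichment is one-sided (treatment over control, threshold 4 by default);
depletion calling exists behind a flag. The "top n most enriched" ranking
is statistic-descending with ties broken by treated count then key.

The preexistence chance model is binomial: the probability that a
non-preexisting barcode is enriched in r of R replicates is
`C(R, r)·P^r·(1−P)^(R−r)`, with P = (enriched union)/(detected
complexity). The complexity adjustment is a plain multiplication as the
source model specifies (a min(·, 1)-capped variant is available behind a
flag). Origin labels follow the recurrence rule: all R replicates →
preexisting candidate, exactly one → late-emerging, otherwise
intermediate.

## Editing outcomes and purity (`editing_qc`)

Reads are aligned globally to the reference cassette (Needleman–Wunsch,
affine gaps; defaults match +1, mismatch −1, open −4, extend −1 — chosen
for short, indel-dominated amplicons). Tie-breaking is deterministic and
gaps are left-aligned, so indel placement in repeats is reproducible. The
net indel length inside a cut window — by default the 15-nt inter-nick
offset plus 3 nt into each protospacer, since nickase double-nicks fall
between the PAM-distal ends of the two sites — determines the frame class
(net mod 3: 0 in-frame, 1 "+1", 2 "−1"). Reporter prediction: v1 silences
eGFP for any frameshift; v2 frames the puromycin marker in for the −1
class only.

Reads whose motif is intact are assigned by exact key match; edited reads
are assigned by best alignment across the library, accepted only if both
N20 remnants *outside* the cut window match the assigned cassette exactly
(the flank/linker anchors and PAM-distal protospacer parts survive
editing). Composition purity = target-assigned / assignable; targeted
fraction = edited among target-assigned. Both statistics are reported
because "targeted percentage" can mean either.

The ~2/3 frameshift expectation is treated as a model prediction: under a
uniform indel-size model on 1..30 nt, exactly 20/30 sizes are
non-multiples of 3. The model is swappable (`{net_size: probability}`).

## The simulator (`clone_sim`)

What it emulates: lentiviral transduction at MOI 0.3 (Poisson integrations;
zero-integration cells removed; multi-integration cells kept and tracked),
skewed library representation (lognormal weights, σ = 1), Galton–Watson
expansion to >100× coverage per group, multinomial splitting into one
control + 5 replicates, 40 days of daily dynamics, and multinomial
sequencing sampling with per-base substitution errors, optionally as
FASTQ with a 0–8 nt stagger.

Daily dynamics per treated replicate:

* sensitive cells die with probability 0.35/day;
* persisters (1% of sensitive cells at treatment start) are a *maintained*
  slow-cycling pool: they divide at 0.2/day as turnover (the compartment
  does not expand) and each division converts to stable resistance with
  probability 2e-4;
* resistant cells (preexisting clones — a 7e-4 fraction of founders — or
  converted persisters) grow by `Poisson(n · f)` per day with clone
  fitness f drawn once per clone from a lognormal with median 1.3/day and
  spread 0.15. The fitness spread is deliberate: between-clone fitness
  heterogeneity is what lets a late-emerging clone outgrow a preexisting
  one in a single replicate.

The default scale (20,000 founders, 200,000-barcode library, depth 1e5) is
a ~150× scale-down of the emulated experiment that preserves the ordering
`library ≫ founders` (rare barcode collisions), coverage per clone, and
the qualitative endpoint regime: treated pools dominated by a few clones,
a mix of shared (preexisting) and private (acquired) enriched barcodes,
control pools flat. The vehicle control holds the baseline distribution
static rather than simulating neutral drift; control-side sampling noise
still enters through sequencing.

What it does **not** emulate — and hence what a green test does not
establish: PCR amplification bias and chimeras, persister reversibility
and cell-cycle structure, spatial competition, drug pharmacokinetics,
barcode-independent fitness differences among sensitive clones, and indel
generation in unedited pools. Conclusions from simulation are about the
statistical pipeline (extraction, counting, enrichment, origin inference),
not about the biology of any particular cell line.

Determinism: every stochastic step draws from one `numpy` generator seeded
from `SimConfig.seed`; identical config + seed reproduce byte-identical
outputs (tested). A per-day audit (births − deaths = Δtotal) is recorded
and asserted.

## Variant priority score (`variant_priority`)

Components are scaled per analysis run: min–max over the tool-scored
candidate set after orientation normalization (CADD: higher = deleterious;
SIFT and PROVEAN: lower = deleterious; screen log2FC: positive = enriched
under drug — all configurable, since published pipelines rarely state
orientations). Frameshift deletions, stop gains and splicing variants are
unscorable by the tools and receive 100; other unscored variants receive
the median of the scaled scored set, with the median fixed *before*
imputation so imputed values cannot shift it. Degenerate spread (max =
min) maps all scored values to 50 with a warning. Per-run scaling was
chosen over global theoretical ranges because no finite global range
exists for PROVEAN-like scores.

## Numerical and degenerate-input choices

* Beta quantiles come from `scipy.stats.beta.ppf`; k = 0 is handled by the
  prior pseudocount (α = 1 ⇒ Beta(1, ·)), so no special-casing is needed.
* The binomial preexistence term uses exact integer `math.comb`.
* Alignment traceback uses an absolute tolerance of 1e-9 when matching
  predecessor scores (scores are small sums of the integer-valued
  parameters, so this is far below the score granularity).
* Empty inputs raise; degraded inputs that a run should survive (short
  region in the slippery scan, fewer enriched barcodes than `top_n`,
  extinct replicates, genes missing from the FPKM table) warn and
  continue.

## Known limitations

* The enrichment statistic is a reconstruction of the generalized
  fold-change idea from its definition, not a port; numerical values can
  differ from the published tool at the second decimal.
* Edited-read assignment in `purity_report` is O(reads × library) in
  alignment calls and is intended for small captured-pool QC, not for
  library-scale data.
* The simulator's persister compartment is a deliberate simplification
  (constant-size, memoryless conversion); it reproduces the *rate* regime
  of late-emerging resistance, not persister biology.
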