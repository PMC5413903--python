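# Methods

## The question and the measurement

Lentiviral barcoding tags each transduced cell with a random 30-bp DNA
sequence that is copied to every descendant. After a short expansion window
the population is split into four dishes and reprogrammed; barcodes are then
recovered from the successfully reprogrammed cells of each dish. A barcode
recovered from two or more dishes ("shared") means that sister cells —
progeny of one tagged founder — reprogrammed in parallel. The *heritability
level* `h` is the probability that a sibling of a reprogrammed cell is
itself reprogrammed within the experimental window; `h = 0` is the purely
stochastic limit.

Under the stochastic null with one population doubling, the expected number
of shared barcodes is `T = N · C · E²`, with `N` transduced cells,
`C = 1 − 1/n_dishes` the chance two sisters split apart (0.75 for four
dishes) and `E` the reprogramming efficiency. Everything beyond this closed
form is estimated by simulation.

## The stochastic model (`clonetrace.sim`)

Each replicate simulates the experiment forward:

1. **Seeding/infection.** `N0 = round(N_seeded · (1 − e^(−m)))` cells are
   tracked — only cells that received at least one barcoded virus are
   visible to the assay. Each founder draws an integration count from a
   zero-truncated Poisson(m) and each integration a barcode id uniformly
   from the library (default diversity 8 × 10⁶). Finite diversity produces
   birthday-type barcode collisions between unrelated clones, and
   multi-integration founders inflate barcode-level sharing; both effects
   are therefore represented mechanistically rather than corrected post
   hoc. A `single_integration` switch forces one integration per cell, and
   `multi_integration_correction` optionally divides overlap counts by the
   mean integration count `m / (1 − e^(−m))` as an approximate post-hoc
   alternative.
2. **Division.** Each founder produces `k ∈ 0..8` progenies with
   probabilities `P(k)`; progeny inherit all barcode ids and record `k` as
   their *progeny class* (a proxy for cycling speed).
3. **Plating.** Dish labels are i.i.d. uniform on the four dishes.
4. **Loss of material.** Each dish loses `round(d · size)` uniformly chosen
   cells; `d` pools cell death, uneven splitting and PCR/sequencing
   dropout, and is scanned over 0.1–0.9 because it cannot be measured
   directly.
5. **Reprogramming.** Per-dish barcode quotas `BA_1..BA_4` are drawn from a
   Gaussian `(mu, si)` — matching the dish-to-dish variation of observed
   barcode counts — rounded, clamped to be non-negative, and capped by the
   dish's available distinct barcodes (a truncation is flagged as
   *clamped*). Cells are drawn uniformly without replacement until the
   dish's reprogrammed cells carry at least `BA_i` distinct barcodes. With
   multiple integrations a single draw can overshoot the quota by up to
   `k_int − 1` barcodes, so "at least" is the sharpest attainable reading
   of an exact quota.
6. **Heritable sharing.** Every not-yet-reprogrammed sibling of a stage-5
   cell — in any dish, including the same one — is reprogrammed with
   probability `h`, either a single level or a per-progeny-class map
   (proliferation-dependent heritability).

Overlaps are counted at the **barcode level**: for each barcode, the set of
dishes in which at least one reprogrammed carrier sits, tabulated into
exactly-2/3/4-dish counts. Each exactly-2 barcode is attributed to the
progeny class of (a representative of) its carrying clone, giving the
per-class contribution decomposition.

The paper's rendering of the Gaussian parameters calls `si` a "variance";
it is used here as the standard deviation, the parameter a Gaussian is
naturally specified by.

### Default progeny distribution

The cycling behaviour of the starting fibroblasts enters through `P(k)`.
Live-imaging class frequencies are not published numerically, so the
default `P(0..8) = (0.05, 0.10, 0.35, 0.20, 0.15, 0.06, 0.05, 0.02, 0.02)`
was fixed once on qualitative grounds: most cells divide once or twice
within the window, a small fraction dies or rests, and a 15% minority of
fast cyclers produces more than four progenies (below the reported 25%
ceiling for that subpopulation). With this default the fast classes
contribute disproportionately to double overlaps relative to their cell
fraction, as the decomposition analysis expects. `P(k)` is ordinary
configuration; any distribution over 0..8 progenies may be supplied.

## Fitting the heritability level (`clonetrace.fit`)

For each loss value `d` and heritability `h` on a grid (defaults 0.1–0.9
and 0–1, step 0.1) the model is executed `R = 100` times and the simulated
shared-barcode counts are compared with the observed count using a
Kruskal–Wallis rank test. The observation is a single number, so the
default comparison treats it as a singleton group and computes an **exact
permutation p-value** over the `R + 1` equally likely placements of the
singleton label; the chi-square approximation is unreliable at `n = 1`.
Two consequences are worth noting:

- the smallest attainable p-value is `2/(R + 1)`, so at least ~40
  replicates are needed before any grid point can be rejected at
  `alpha = 0.05` (`R = 100` gives a floor of ~0.02);
- compatibility (`p ≥ 0.05`, i.e. failure to reject) defines the accepted
  set, and the **best fit** is the accepted level whose median simulated
  count is closest to the observation (ties resolved toward the smaller
  level). When no level is accepted at a given `d`, the result is an
  explicit no-fit with the closest-median level reported separately
  (`best_or_closest`), never a silent imputation.

A joint mode (`compare="classes"`) tests the double/triple/quadruple
overlap classes jointly via a Bonferroni-combined min-p, and
`acceptance="reject"` flips the acceptance direction; both exist because
the published description leaves the grouping and direction open, and the
defaults are the readings that reproduce the described behaviour.

The quota parameters `mu`/`si` for the fit are taken from the observed
per-dish distinct-barcode counts. When the data were generated at `h > 0`,
those observed counts already include sister-induced barcodes, so the fit
simulations (quota plus heritability on top) run slightly rich; the
recovered level can land one grid step below the generating value at high
`h`. This bias is intrinsic to the procedure being modelled, not a defect
of the implementation, and parameter-recovery tests bound it at one grid
step.

## Barcode recovery (`clonetrace.extract`)

Reads are `signature (10 bp) + left flank + barcode + right flank`.
Demultiplexing assigns a read to the unique nearest signature within one
mismatch (configurable); flanks are located exactly, then with a
one-substitution fallback. A candidate barcode is discarded when more than
20% of its bases fall below Q20 (exactly 20% is retained — the boundary is
read strictly), or when its trimmed length is outside 26–34 bp. Variants
are collapsed by greedy abundance-ordered centroid clustering with
normalized identity `1 − levenshtein/max(len)` and threshold 0.8, the
plateau of the cluster-count-versus-threshold sweep on random 30-mers.
Single-read clusters are removed as noise. A dish counts as containing a
barcode only when it holds ≥ 0.1% of the barcode's expected per-dish share
(total reads / 4). The singleton filter operates on the pooled (cross-dish)
read count, since the published order of those two steps is not stated.

Distances come from a bit-parallel Myers kernel (patterns ≤ 64 bases fit
one machine word), which makes the 8 × 10⁸ pairwise comparisons of a
40,000-sequence threshold sweep tractable; the sweep computes the bounded
edge list once at the loosest threshold and replays the greedy assignment
per threshold, which is exactly equivalent to direct clustering because
pairwise identities do not depend on the threshold.

## Synthetic data (`clonetrace.synth`)

The generator emulates: clonal barcode inheritance, four-dish splitting,
configurable heritability, multi-integration, log-normal PCR amplification
bias per (barcode, dish), i.i.d. per-base substitution errors (optional
indels, default 0), constant Q30 qualities with an optional low-quality
read fraction, and the two spike-in control barcodes
(`TGCTGACC…` / `GGACGCGC…`) at configurable per-dish cell numbers
(100/400, 20/80 or 10/50 for the three barcoded experiments). It does
**not** model Ion-Torrent-specific homopolymer errors, chimeric PCR
products, quality-score degradation along the read, or FACS gating, so
passing round-trip tests demonstrate correctness of the pipeline's logic
under the stated noise model, not robustness to every artefact of real
sequencing data.

## Problem sizes and numerical choices

Simulation-based tests run scaled-down experiments — 20,000 seeded cells at
MOI 0.63 with a 10⁶-barcode library and per-dish quotas of ~75 barcodes —
chosen so that the reprogramming efficiency (~3–4%) matches the real
experiments' few-percent scale at this population size; the analytic-limit
check uses 20,000 single-integration clones with `P(2) = 1` and a 10¹⁰
library so the closed form applies. All randomness flows through
`numpy.random.SeedSequence` spawning, making every result reproducible
from one integer seed, and FASTQ output is byte-identical for a fixed
seed. Gaussian quota draws are rounded to integers and clamped at zero;
quota truncation is reported per replicate as a clamped fraction rather
than silently absorbed.

## Known limitations

- The heritability grid has the resolution of its step (0.1 by default);
  finer structure requires a finer grid and proportionally more runs.
- The mark–recapture diversity estimate is a point estimate; no interval
  is attached.
- The post-hoc multi-integration correction is a mean-field approximation
  provided for comparison only; the forward simulation is the primary
  treatment.
- Reverse-complement flank search is available but off by default, since
  the amplicon design fixes the read orientation.
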