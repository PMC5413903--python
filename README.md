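# clonetrace

Cellular-barcoding analysis of reprogramming heritability: is the ability of
a somatic cell to become an induced pluripotent stem cell (iPSC) a heritable,
lineage-level trait, or a purely stochastic event?

In the underlying experimental design, fibroblasts are tagged with lentiviral
DNA barcodes (30 random bases integrated into the genome, inherited by all
progeny), allowed to divide a few times, split across four culture dishes,
and then reprogrammed. Barcodes recovered by amplicon sequencing from the
successfully reprogrammed (GFP+) cells of each dish identify clonal lineages:
a barcode found in **two or more dishes** means sister cells reprogrammed in
parallel. If reprogramming were purely stochastic, the expected number of
shared barcodes would be

```
T_expected = N · C · E²
```

where `N` is the number of transduced cells, `C = 1 − 1/4 = 0.75` the chance
that two sisters are split into different dishes, and `E` the reprogramming
efficiency. Observing far more sharing than `T_expected` indicates that the
fate is pre-established in particular lineages. `clonetrace` implements the
full analysis chain:

- **`clonetrace.synth`** — synthetic barcode libraries, ground-truth clonal
  experiments and noisy FASTQ reads (signature + flank + barcode + flank),
  including the two printed spike-in control barcodes;
- **`clonetrace.extract`** — demultiplexing by 10-bp dish signatures, flank
  trimming, quality/length filters, greedy identity clustering of sequencing
  variants (`BarcodeClusterer`, scikit-learn style), singleton and cross-dish
  noise filters, and the dish-overlap table;
- **`clonetrace.stats`** — Poisson MOI arithmetic, library-complexity and
  mark-recapture diversity estimates, reprogramming efficiency, `T_expected`;
- **`clonetrace.sim`** — a stochastic agent-based model of the experiment:
  seeding and infection (zero-truncated-Poisson multi-integration), clonal
  division (0–8 progenies per founder), four-dish plating, loss of material,
  quota-driven reprogramming and heritable sister reprogramming with
  probability `h` (the *heritability level*);
- **`clonetrace.fit`** — `HeritabilityGridSearch`: for each loss value `d`
  and heritability `h` on a grid, simulated shared-barcode counts are
  compared with the observed count by a Kruskal–Wallis test; levels the test
  cannot reject form the accepted set, and the best fit is the accepted level
  whose median simulated count is closest to the observation.

## Worked example

Recover the heritability level from a synthetic experiment generated at a
known truth of `h* = 0.2` (20,000 seeded cells, MOI 0.63, 10⁶-barcode
library, 30% loss of material):

```python
from dataclasses import replace
import clonetrace as ct
from clonetrace.fit import ObservedOverlaps, grid_fit
from clonetrace import stats

print("MOI:", round(stats.moi_from_fraction(0.591), 2))
print("Expected shared (stochastic):",
      round(stats.expected_shared(170_000, 0.75, 0.0167), 1))

base = ct.SimParams(n_seeded=20_000, moi=0.63, diversity=1_000_000,
                    loss=0.3, mu=75.0, si=8.0)
observed = ObservedOverlaps.from_overlap_counts(
    ct.run(replace(base, heritability=0.2, n_replicates=1), seed=11).replicates[0]
)
print("Observed shared barcodes:", observed.shared)
print("Observed per-dish barcode counts:", observed.per_dish_distinct)

result = grid_fit(observed, base, d_grid=[0.3],
                  h_grid=[round(0.1 * i, 1) for i in range(11)],
                  n_replicates=100, seed=12)
f = result.per_d[0.3]
print("Accepted heritability levels:", f.accepted_h)
print("Best-fit heritability:", f.best_h)
```

Output:

```
MOI: 0.89
Expected shared (stochastic): 35.6
Observed shared barcodes: 89
Observed per-dish barcode counts: (106, 90, 98, 102)
Accepted heritability levels: [0.2]
Best-fit heritability: 0.2
```

Reading the numbers: a GFP+ control fraction of 59.1% corresponds to MOI
0.89; purely stochastic reprogramming of the pilot experiment would produce
about 36 shared barcodes; the synthetic experiment produced 89 shared
barcodes across its four dishes (around 100 distinct barcodes each), and the
grid fit identifies 20% sister-cell heritability — the generating value — as
the only level statistically compatible with that observation.

The same pipeline runs from the shell:

```bash
clonetrace synth   --config cfg.yaml --out run/
clonetrace extract --fastq run/dish1.fastq --fastq run/dish2.fastq \
                   --fastq run/dish3.fastq --fastq run/dish4.fastq --out out/
clonetrace fit     --observed obs.json --config sim.yaml \
                   --grid-h 0:1:0.1 --grid-d 0.1:0.9:0.1 --reps 100
```

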