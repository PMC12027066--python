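# midtrace

Metabolite identification from parallel ¹³C isotope tracing, using
convolution distances between mass isotopomer distributions (MIDs).

When cells grow on a ¹³C-labeled nutrient, each metabolite acquires an MID
— the vector x = (x₀, …, x_n) of fractional abundances of its n+1 mass
isotopomers — that reflects its biosynthetic origin. Biochemically related
compounds have similar MIDs in every labeling experiment, and a compound
assembled from two carbon skeletons carries approximately the convolution
of its precursors' MIDs. For peaks A (m carbons) and B (n ≥ m carbons) the
MID distance searches all measured peaks C with n−m carbons ("convolutants")
for the moiety that best explains B as A plus C, summed over experiments e:

    d(A,B) = min_C Σ_e ‖ x^{A,e} ⊛ x^{C,e} − x^{B,e} ‖₂,
    (x ⊛ y)_k = Σ_{i+j=k} x_i y_j

Small d(A,B) suggests a biosynthetic relationship and, for unknown peaks,
nearby previously identified metabolites constrain the unknown's identity.
The package is aimed at mass-spectrometry metabolomics groups running
parallel tracer panels, and at anyone evaluating isotope-based annotation
strategies in silico.

It provides:

- **`midtrace.mid`** — MID vectors, peak tables (TSV), convolution,
  enrichment, the multi-experiment convolutant-search distance, nearest
  neighbors and distance-threshold networks;
- **`midtrace.preprocess`** — natural-¹³C correction (binomial model,
  p₁₃ = 0.0107), the ≥10% enrichment filter, the false-isotopomer filter
  (>0.03 in >10 experiments), co-elution artefact grouping;
- **`midtrace.network` / `emu` / `simulate`** — atom-mapped reaction
  networks from a plain-text format, elementary-metabolite-unit (EMU)
  decomposition, isotopically nonstationary ODE simulation and steady-state
  solves, pre-steady-state sampling, multi-tracer panel simulation with
  seeded noise;
- **`midtrace.relatedness`** — the carbon-contribution gold standard f
  (fraction of one metabolite's carbon derived from another; related
  defined as f > 1/2);
- **`midtrace.evaluate`** — precision-recall/AUPR against f, noise and
  dropout robustness, discoverability, greedy tracer-subset selection;
- **`midtrace.annotate`** — candidate matching by m/z over the M+H, M−H,
  M+NH₄, M+H−H₂O and M−H−H₂O adducts at 10 ppm, with labeling-consistency
  checks and neighbor-guided candidate selection;
- **`midtrace.fixtures`** — synthetic networks and simulated tracer panels
  so the entire pipeline runs without any external data;
- a **`midtrace`** command-line interface (`fixtures`, `simulate`,
  `preprocess`, `distance`, `neighbors`, `network-export`, `relatedness`,
  `evaluate`, `annotate`) writing TSV/JSON outputs plus a run manifest.

## Worked example

Simulate the bundled evaluation network (five U-¹³C tracer experiments,
sampled before isotopic steady state), compute all pairwise MID distances,
and look at the neighborhood of `ace`, a two-carbon cleavage product of the
three-carbon intermediate `p2`:

```python
from midtrace.fixtures import FixtureSpec, make_peak_table
from midtrace.mid import pairwise_distances, nearest_neighbors
from midtrace.evaluate import precision_recall

table, truth, labels = make_peak_table(FixtureSpec())
matrix = pairwise_distances(table)
for pid, d, conv in nearest_neighbors("ace", matrix, 5):
    print(f"{pid:<4s} d={d:.4f} convolutant={conv}")
curve = precision_recall(matrix, labels)
print(f"AUPR={curve.auc:.3f} prevalence={curve.prevalence:.3f}")
```

prints

```
p2   d=0.3032 convolutant=fmt
p1   d=0.3654 convolutant=fmt
fmt  d=0.3705 convolutant=fmt
x1   d=0.3930 convolutant=direct
ala  d=0.4007 convolutant=fmt
AUPR=0.964 prevalence=0.159
```

The nearest neighbor of `ace` is its true precursor `p2`, reached by
convolving `ace` with the one-carbon peak `fmt` — i.e. the distance has
reconstructed the cleavage p2 → ace + fmt from labeling patterns alone.
The remaining neighbors are the upstream pathway (`p1`, `ala`), the other
cleavage fragment and its condensation product. Across all pairs, ranking
by MID distance separates biochemically related pairs (carbon-contribution
f > 1/2) from unrelated ones with an area under the precision-recall curve
of 0.96, against a prevalence of 0.16.

The same workflow from the shell:

```sh
midtrace fixtures --template eval_default --seed 7 --out demo
midtrace distance --table demo/mid_table.tsv --cutoff 0.7 --export-network --out demo
midtrace evaluate --table demo/mid_table.tsv --pairs demo/related_pairs.tsv --out demo
```

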