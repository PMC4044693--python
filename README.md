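# cytofingerprint

Cytometric fingerprinting for microbial community monitoring: four
fingerprint-comparison methods — **Dalmatian Plot**, **CHIC**, **CyBar** and
**FlowFP-style probability binning** — plus cytometric diversity indices and
ordination statistics, in one Python library with a CLI.

## The problem

A flow cytometer measures every cell of a microbial community individually;
with a DNA stain such as DAPI, the 2D histogram of forward scatter (FSC,
cell-size related) against DNA fluorescence is a *cytometric fingerprint* of
the community's structure — cluster positions are cell types/states, cluster
intensities their abundances. Fingerprints can be acquired in minutes, which
makes them attractive for near-real-time monitoring of bioreactors,
wastewater communities or environmental samples, long before sequencing
results would arrive. What is needed — and what this package provides — is
the downstream quantitative machinery: turning pairs of fingerprints into
dissimilarities, dissimilarity matrices into ordinations and diversity
indices, and gate abundances into testable correlations with process
parameters.

## Methods implemented

| Method | Input | Dissimilarity |
|---|---|---|
| Dalmatian Plot | per-sample operator gate sets, rasterized to black/white (or gray) masks | Jaccard distance on black-pixel sets; Ruzicka (weighted Jaccard) in gray mode |
| CHIC | gray-scale histogram images, no gating | `P_sim = sum(XOR image) / #{informative pixels of the overlap image}`, in gray-level units 0–255 |
| CyBar | experiment-wide gate template | Bray–Curtis on relative gate abundances; plus a log2-fold-change barcode heat map and gate-vs-parameter Spearman correlations |
| FlowFP | recursive equal-count binning (2^r bins fitted on training samples) | ½ · L1 distance on bin fractions |

Diversity indices (from the gray fingerprint image with `N_all` pixels of
which `N_i` are informative, i.e. non-white):

- **range-weighted richness** `Rr = N_i / N_all`
- **structural organization** `So = (1/N_i) Σ |P_ij − P_average|`, with
  `P_average` the mean intensity over informative pixels
- **dynamics** `Dy` (mean dissimilarity of consecutive samples) and `Da`
  (mean over all pairs), computed from any method's matrix

Statistics: non-metric multidimensional scaling (Kruskal stress-1, isotonic
regression, multi-start), environmental vector fitting and Procrustes
comparison of ordinations, both with 999-permutation add-one p-values.

Because real event data are rarely shareable, the package ships a
synthetic-community generator (`cytofingerprint.synth`): Gaussian-mixture
communities in transformed (FSC, DNA) space with known abundances, a
proliferation satellite at doubled DNA signal, a diffuse debris background,
abundance drift/changepoint series, and replicate group designs — every
downstream stage is testable against ground truth.

## Worked example

Two "inocula" (communities with shifted cluster positions), four replicate
samples each, 20 000 events per sample, all four methods on identical data:

```python
from cytofingerprint import *
from cytofingerprint.synth import two_group_specs
from cytofingerprint.workflows import four_method_matrices
from cytofingerprint.stats import within_between

spec_a, spec_b = two_group_specs()
groups = simulate_groups(spec_a, spec_b, reps=4, n_events=20_000, seed=1)
specs = [spec_a if g == "A" else spec_b for g in groups.labels]
mats = four_method_matrices(groups.tables, specs, training=(0, 4))
labels = dict(zip([t.sample_id for t in groups.tables], groups.labels))
for name, m in mats.items():
    w, b = within_between(m, labels)
    print(f"{name:10s} within={w:7.4f}  between={b:7.4f}")

o = nmds(mats["chic"], n_starts=20, seed=1)
print(f"CHIC NMDS stress = {o.stress:.4f}")
pr = procrustes(o, nmds(mats["flowfp"], n_starts=20, seed=1), n_perm=999, seed=1)
print(f"Procrustes CHIC vs FlowFP: correlation={pr.correlation:.3f} p={pr.p_value}")
```

prints

```
chic       within= 3.9506  between=23.1241
dalmatian  within= 0.0127  between= 0.9089
cybar      within= 0.0068  between= 0.6250
flowfp     within= 0.0197  between= 0.8619
CHIC NMDS stress = 0.0002
Procrustes CHIC vs FlowFP: correlation=0.831 p=0.004
```

Every method sees the two groups as far more dissimilar between than within
(CHIC's values are gray-level units, the other three live in [0, 1]); the
CHIC and FlowFP ordinations agree (Procrustes correlation 0.83, p = 0.004 at
999 permutations) — the methods tell one consistent story about the same
data, each with its own resolution and operating requirements.

The same pipeline is available from the shell:

```bash
cytofingerprint simulate groups --spec-a a.json --spec-b b.json \
    --reps 4 --n 20000 --seed 1 --out events/
cytofingerprint chic --events events/ --resolution 128 --out chic.tsv
cytofingerprint nmds --matrix chic.tsv --k 2 --starts 20 --seed 1 --out ord.tsv
cytofingerprint run --config config.json --out results/   # all stages at once
```

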