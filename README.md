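# fconn

Functional-connectivity graph classification for resting-state fMRI-style
data: linear and non-linear dependence measures between brain regions,
graph embedding, and one-shot neural-network classification of diagnostic
groups (cognitively normal CN, mild cognitive impairment MCI, Alzheimer's
disease AD).

## The problem

Pairwise *functional connectivity* (FC) between parcellated brain regions
is the standard feature substrate for fMRI-based diagnosis. Pearson
correlation only sees linear coupling; genuinely non-linear interregional
dependence is invisible to it. This package implements and compares three
dependence measures as classification features:

* **PCC** — Pearson correlation, `rho = cov(A,B) / (sigma_A * sigma_B)`,
  in [-1, 1];
* **MIC** — the maximal information coefficient,
  `MIC = max_{nA*nB < B(n)} I*(A,B; nA, nB) / log2 min(nA, nB)`,
  the grid-optimized, normalized mutual information, in [0, 1] — sensitive
  to any functional relationship;
* **eMIC** — the extended MIC, `eMIC = MIC - rho^2`, an index of *purely
  non-linear* dependence: near zero for linear or independent pairs.

Each subject's R×R FC matrix becomes either a flattened feature vector or a
weighted graph embedded with node2vec (biased random walks + skip-gram).
Classification uses a multilayer **extreme learning machine** (ELM):
random frozen hidden layers `H_l = g([X,1] W_l)`, concatenated to `H`, and
output weights solved in closed form, `beta = pinv(H) Y` (Moore–Penrose
pseudoinverse; ridge-regularized variant available). Evaluation is
stratified 10-fold cross-validation with top-k Welch-t feature selection
inside each training fold, reporting accuracy, sensitivity and specificity.

Because clinical rs-fMRI cohorts are access-restricted, the package ships a
first-class synthetic-cohort generator: band-limited (0.01–0.08 Hz)
BOLD-like ROI signals with controllable linear couplings and non-linear
couplings (`x^2`, `sin(2*pi*x)`, `|x|`) whose strength can differ between
diagnostic groups. It is the test bed for every claim the package makes.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic cohort (3 groups × 20 subjects, 30 ROIs, 140 time points; groups
differ **only** in non-linear coupling strength — CN 0.4, MCI 1.0, AD 1.6):

```bash
python analysis/01_simulate_cohort.py   # cohort -> results/cohort/
python analysis/02_fc_matrices.py       # PCC/MIC/eMIC -> results/fc/
python analysis/03_embed_graphs.py      # feature matrices -> results/features/
python analysis/04_classify_cv.py       # 10-fold CV -> results/reports/
python analysis/05_feature_count_sweep.py
```

`02` prints the mean |FC| on the ten non-linearly coupled edges — PCC
cannot see them, MIC/eMIC grade with severity:

```
group      PCC     MIC    eMIC
CN       0.106   0.209   0.191
MCI      0.119   0.268   0.245
AD       0.137   0.318   0.288
noise    0.090   0.196   0.183
```

`04` prints the cross-validated classification table (64 selected
features, multilayer ELM with 1000 hidden neurons):

```
     task measure  accuracy  sensitivity  specificity
 CN_vs_AD     PCC     0.400         0.35         0.45
 CN_vs_AD     MIC     0.950         0.95         0.95
 CN_vs_AD    eMIC     0.975         1.00         0.95
CN_vs_MCI     MIC     0.875         0.90         0.85
MCI_vs_AD    eMIC     0.825         0.85         0.80
...
```

On a contrast that is purely non-linear by construction, the non-linear
measures separate the groups almost perfectly while Pearson-based features
stay at chance — the qualitative ordering the measures are designed to
expose. `05` shows the ordering is stable across the whole
feature-count sweep (8–435 features).

A config-driven CLI wraps the same stages end to end
(`fconn example-config`, `fconn run --config cfg.ini --out out/`), with
subcommands `generate`, `fc`, `embed`, `classify` that consume each
other's output directories, so real ROI-time-series TSVs can replace the
synthetic cohort at any point.

## Layout

```
src/fconn/        library: cohort, fc, embedding, melm, evaluation, pipeline, cli
analysis/         numbered study drivers (thin wrappers over the library)
scripts/          acceptance.py
tests/            pytest suite (unit, property and end-to-end tests)
docs/methods.md   modelling and algorithmic details
```
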