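# Methods

## The problem and the method

Breast ultrasonography (BU) images can be classified as benign, malignant or
normal using *deep features*: activation vectors tapped from the layer that
feeds the final classification layer of an ImageNet-pretrained CNN. Those
vectors are long (512–2048 values per image) and most coordinates carry
little class information; keeping all of them both slows training and hurts
accuracy. `budl` implements the wrapper approach to pruning them: a
population-based metaheuristic proposes binary feature masks, each mask is
scored by actually training a support vector machine on the masked training
features and measuring holdout accuracy, and the search minimizes the
blended cost

    M(mask) = φ · (1 − Accuracy) + γ · n_selected / n_total

with φ = 0.99 and γ = 0.01 by default, so accuracy dominates and the
feature-ratio term breaks ties toward smaller subsets. With φ + γ = 1 the
cost lies in [0, 1]. An empty mask is never scored: binarized all-zero
positions are repaired to a single uniformly chosen feature.

A final *network selection* stage keeps only the backbones whose optimized
holdout accuracy exceeds 94% (strictly), concatenates their selected
columns sample-wise, and trains a final SVM on the combined descriptor —
optionally after a second wrapper pass over the concatenated columns
(default is the plain concatenated fit).

## Search space and binarization

All ten optimizers search the continuous box [0, 1]^d. A position is mapped
to a mask by a fixed threshold: bit j is set iff coordinate j is strictly
above 0.5. The threshold rule is the simplest mapping consistent with the
box bounds; S/V-shaped transfer functions are a known alternative but are
deliberately not the default, and the threshold is exposed in
`OptimizerConfig.binarize_threshold`. Positions are clipped to the box
after every update.

Elitism is enforced outside the schemes: the best (cost, mask) ever
evaluated is tracked by the objective and can only improve, so the
convergence trace is non-increasing for every algorithm regardless of
whether its population update is greedy (MPA, GNDO, MRFO, PFA, PRO, parts
of HHO) or replace-unconditionally (SMA, EO, ASO, HGSO, parts of HHO).
Equal-cost masks never displace the incumbent (first-found tie-break), so
the reported best is stable under reruns.

## The ten schemes and their parameters

Each scheme follows the canonical update equations of its original
publication, with the parameter values used throughout:

| scheme | role of parameters |
|---|---|
| MPA  | three predation phases (Brownian, mixed, Lévy) over thirds of the run; FADs effect 0.2; step constant P = 0.5; per-agent memory saving |
| GNDO | generalized-normal sampling around (agent, best, population mean); exploration by random pairwise difference jumps; greedy acceptance |
| SMA  | fitness-ranked weights W; oscillation amplitude arctanh(1 − t/T); contraction amplitude 1 − t/T; restart probability 0.03 |
| EO   | equilibrium pool of the 4 best-ever states plus their mean; exponential decay with a₁ = 2, a₂ = 1; generation probability 0.5 |
| MRFO | chain/cyclone foraging alternating random- and best-anchored spirals; somersault factor S = 2 |
| ASO  | fitness-derived masses; Lennard-Jones window h ∈ [1.1, 1.24] over a K-best neighbourhood shrinking with √(t/T); depth weight 50; constraint (multiplier) weight 0.2; velocity integration |
| HHO  | escape energy E = 2E₀(1 − t/T) switching exploration, soft/hard besiege and Lévy-flight rapid dives (β = 1.5, Mantegna sampling) |
| HGSO | 2 gas clusters with Henry constants updated by the temperature term exp(−t/T); solubility-driven pull toward cluster and global bests; 1 worst agent re-initialized per iteration |
| PFA  | pathfinder perturbed by its own displacement plus a vibration term u₂·e^(−2t/T); followers attracted to a random neighbour and the pathfinder with decaying noise |
| PRO  | population halves; rich agents repelled from the best poor agent; poor agents pulled toward the mid-point of the best and mean rich positions; per-coordinate reset mutation 0.06 |

Numerical choices worth noting:

* **ASO stabilization.** The interaction force uses the physical
  Lennard-Jones sign (repulsive below the equilibrium ratio, attractive
  above), and per-coordinate accelerations are clamped to the box width.
  Without the clamp the 1/mass scaling produces accelerations of order 10²
  on a unit box in the first iterations, slamming every atom onto the box
  faces before the force schedule decays.
* **Lévy steps** use Mantegna's algorithm with β = 1.5.
* **Degenerate inputs**: log/ratio terms are guarded with tiny epsilons;
  constant feature columns standardize to zeros rather than dividing by a
  zero standard deviation.

Search budget defaults are population 10 and 100 iterations; the holdout is
a stratified 80/20 split (per class, round(count·0.2) samples to the test
side, never emptying the training side). The SVM inside the loop is a
linear-kernel, one-vs-one multiclass SVC with C = 1 and train-split
standardization — plain on purpose, since it is fitted ~10³ times per run.
Fitness results are cached by mask bits; caching changes timing only, never
results.

## What the synthetic generator emulates

`make_synthetic_features` stands in for deep-feature tables: k informative
columns are drawn from class-conditional Gaussians whose means are 0, s,
2s (unit SD) for the three classes — s is the `separation` in SD units —
and the remaining columns are class-independent noise. `label_noise`
optionally reassigns a fraction of labels to a different class, emulating
annotation error and capping attainable accuracy at a level fixed by the
fixture. The generator is deterministic given its spec.

What it does *not* emulate: correlated features (real deep features are
strongly correlated), heavy-tailed activations, class imbalance unless
requested, and any image-level nuisance structure. Passing tests therefore
demonstrate that the search machinery finds planted low-dimensional signal
under the stated budgets — not that the pipeline reaches any particular
accuracy on real ultrasound data.

The toy image generator writes speckle-textured grayscale PNGs with a
smooth dark ellipse (benign), an irregular star-shaped blob with a darker
fill (malignant), or speckle only (normal). The speckle floor sits above
both lesion fills so dark-pixel fractions are exact lesion-area statistics.
These images exercise the folder-per-class loading and extraction plumbing;
they make no claim to ultrasound physics.

## Study fixtures used by the acceptance checks

* **Exhaustive-oracle equivalence (d = 12).** All 4095 non-empty masks are
  enumerated to find the true cost optimum, and each algorithm (population
  10, 100 iterations) must come within 5% relative cost on at least 4 of 5
  seeded fixtures. The fixture is designed so that the exhaustive optimum
  is *structurally determined*: two strongly separated informative columns
  (s = 4), ten inert padding columns (zero variance, standardized away),
  and 15% label noise. With stochastic padding columns the 4095-mask
  maximum is instead an extreme-value artifact of the particular holdout —
  roughly one test sample above the structural plateau — which no budgeted
  search can be expected to match; inert padding removes that artifact
  while label noise keeps the optimum accuracy-dominated, so the check
  measures search quality rather than holdout luck. Fixture size is
  60 per class so the holdout has 36 samples.
* **Benchmark convergence.** Sphere on [0, 1]^10 (optimum at the origin
  corner) and a shifted Rastrigin with its optimum at 0.375 per coordinate.
  The equilibrium optimizer reaches median best values far below 1e-3;
  every scheme must beat the best of 1000 uniform random samples.
* **Planted-feature recovery (d = 200).** 50 samples per class, 10
  informative columns at separation 2. Every algorithm's selected mask must
  reach at least the full-feature holdout accuracy on the same split and
  recall informative columns above the equal-size random-mask expectation
  (n_selected/d).
* **Scheme invariants.** Non-increasing traces, in-box positions, non-empty
  masks and bit-identical reruns, for all ten schemes across seeds.

Problem sizes were chosen so the whole suite and the acceptance script each
run in minutes on one CPU; they are desk-scale stand-ins, not replicas of
the 780-image clinical dataset.

## Backbone registry and extraction backends

The registry pins the 16 supported backbone names to the pre-softmax
feature widths of record (e.g. ResNet-18 → 512, ResNet-50 → 2048,
DenseNet-201 → 1920, Inception-ResNet-v2 → 1536, ShuffleNet → 544,
NASNet-Mobile → 1056). Several of these widths correspond to the MATLAB
model-zoo variants and differ from other frameworks' homonyms; the registry
is therefore authoritative, and a backend that cannot produce the exact
registered width for a name must refuse rather than substitute. The
torchvision backend (optional `realnets` extra) maps the eight names
torchvision can serve at the registered width and taps the flattened
pooled activation feeding the classifier; preprocessing is the standard
resize plus ImageNet normalization, with grayscale replicated to three
channels. The mock backend produces seeded hash noise offset by coarse
intensity statistics of the decoded image — a pure function of (image
bytes, backbone spec, seed) — so tests exercise the full extraction
contract deterministically and without downloads.

## Experiment protocol

`run_benchmark` repeats the whole comparison: for each of `repeats`
(default 10) a fresh stratified split is drawn and shared by every feature
table and algorithm in that repeat, so summary columns are comparable; the
all-ones mask supplies the full-features baseline. Cells are aggregated as
mean ± sample SD (n − 1 denominator; accuracy to one decimal, feature
counts as integers), every cell being recomputable from the persisted
per-run JSON. Wall-clock timings are reported but never asserted on —
they are hardware-dependent.

## Known limitations

* Fitness accuracy is measured on the same 20% holdout that the search
  optimizes, following the protocol this framework replicates; the selected
  subset's accuracy is therefore an optimistically biased estimate. An
  unbiased assessment needs a third, untouched partition.
* The binary landscape is evaluated through a single split; no inner
  cross-validation is offered.
* The ten schemes are faithful at the level of their canonical update
  equations, but metaheuristic behaviour is sensitive to implementation
  minutiae; relative rankings on real data may differ from published ones.
* The real-backbone path covers only the torchvision-servable subset of the
  registry; the remaining names require a framework with the matching
  model-zoo variants.
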