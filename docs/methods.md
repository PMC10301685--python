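# Methods

## The benchmarking problem

A drug-response model maps (cell-line features, drug features) to a scalar
sensitivity label (log IC50 here; AUC supported as an alternative measure).
Three properties make honest benchmarking of pathway-informed models
delicate, and this package is organized around them.

First, models must be compared on one *uniform dataset*: pathway-based
architectures require every input gene to carry pathway annotation, and
enrichment-based models additionally require targets to sit in the
protein-interaction network, so the assembly cascade intersects gene sets
across omics modalities, drops genes outside every pathway, filters drug
targets to the common set (and network), and keeps only drugs with both
targets and measured responses. A provenance report records counts at each
stage.

Second, the prediction task depends on what is held out. Leave-pairs-out
(LPO) tests interpolation to unseen (cell line, drug) combinations;
leave-cell-lines-out (LCO) tests transfer to new samples;
leave-drugs-out (LDO) tests transfer to new compounds. Each scheme
partitions its unit (pairs, cell lines, drugs) into five blocks after a
seeded shuffle; fold k takes block k as test and block k+1 (mod 5) as
validation, giving the 3:1:1 ratio, every unit tested exactly once, and —
for LCO/LDO — no unit shared between roles within a fold. The rotation (as
opposed to independent re-randomization per fold) is a design choice made
for exact single-coverage of test units.

Third, absolute per-cell-line metrics mislead. Scoring is per cell line:
predictions across a cell line's test drugs are compared with its measured
values (Spearman and Pearson correlation, RMSE, MSE, R², concordance
index), then averaged across cell lines (SD with the n−1 denominator).
When drug identity dominates response variance, a predictor that only
ranks drugs by their global potency already attains a high per-cell-line
rank correlation. The package therefore centres its comparisons on
*improvement*: against scheme-specific naive group-mean predictors,
against the same architecture with size-matched random pathway
collections, and with paired two-sided Wilcoxon signed-rank tests across
cell lines.

## Model families

All trained models are scalar-output regression networks on a small
reverse-mode autodiff core (float64, CPU), optimized with Adam on mean
squared error, mini-batches of 64, up to 300 epochs with early stopping on
validation RMSE (patience 30) and restoration of the best-validation
weights. Continuous input columns (expression, copy number, enrichment
scores) are z-scored with train-fold statistics only; binary target and
fingerprint bits pass through; labels are used raw so RMSE stays in label
units.

**Explicit family.** The first variant concatenates a binary drug-target
vector and the expression vector (length 2G) and connects them to one node
per pathway through the stacked membership mask, so a pathway node sees
only its member genes' inputs from both blocks. The second variant first
collapses each gene's features (target bit, expression, optionally copy
number) into a per-gene node through a block-diagonal feature-to-gene mask,
then applies the gene-to-pathway mask. Masked layers are sparse by
construction: weights are drawn densely, multiplied by the mask, and the
mask re-applied after every optimizer step, so off-mask weights are exactly
zero at all times (the forward pass uses the masked weight, hence off-mask
gradients vanish identically). Two numerical choices matter and were made
after observing validation-loss behaviour on synthetic training folds:

* masked layers use *identity activation*. Pathway activity in the
  generative model (and plausibly in real data) is signed; a rectifier at
  the m-wide bottleneck discards half of each node's range and measurably
  degraded the leave-cell-line-out fit. All nonlinearity lives in the ReLU
  dense head (default widths 128, 64, dropout 0.1).
* initialization is He-uniform scaled by each unit's *effective* fan-in
  (its unmasked in-degree), not the dense fan-in. A pathway node with 20
  member genes otherwise starts with weights an order of magnitude too
  small. With an all-ones mask the draw is numerically identical to the
  dense layer's, which keeps the masked/dense equivalence testable.

Explicit models reject fingerprint input at construction: their drug
features must be gene-indexed for the membership wiring to mean anything.

**Implicit family.** The attention network dedicates a subnetwork to each
pathway: member-gene expression plus a learned drug embedding produce
per-gene attention weights (softmax over tanh-scored hidden units), the
attention-weighted expression and the embedding yield a scalar pathway
activation, and the activation vector — re-weighted by a pathway-level
softmax attention — is concatenated with the drug embedding and fed to the
dense head. The exact operator shapes are this package's decision; the
published diagrams of such models are schematic. Raw pathway activations
(before the global re-weighting) depend only on member-gene inputs and the
drug embedding, which is the tested isolation property.

The enrichment-feature model converts profiles into per-pathway permutation
z-scores: for a continuous profile the observed statistic is the mean value
over member genes, for a set-valued profile the overlap count; the null
permutes gene labels (default 1000 permutations, seeded) and the score is
(S_obs − mean)/SD, with 0 for a degenerate null. Expression and copy
number are treated as continuous, mutations as set-valued. Drug targets
are first diffused over the protein-interaction network with a random walk
with restart (restart probability 0.5, column-normalized weights, L1
tolerance 1e−8); the choice of restart probability is a standard default
and exposed in configuration. Fingerprint bits are not gene-indexed, so
the structural block enters through a learned linear projection of the 512
bits to m values rather than through enrichment. The blocks for a chosen
variant are concatenated per (cell line, drug) pair and fed to a dense
network.

**Baselines.** The naive predictor uses only entity identity: per-drug
train means under LCO, per-cell-line means under LDO, and under LPO the
average of the two component means with the global mean substituting for
an unseen component. Its means are computed by sequential sum/count
accumulation in record order so that an independent group-by recomputation
reproduces them bit for bit. The five-layer MLP (four hidden layers,
default 128/64/32/16) and a 500-tree randomized-forest regressor (which
consumes train+validation data, since it does not early-stop) complete the
baseline set. Random-pathway controls resample each pathway's membership
uniformly without replacement at its original size, independently across
pathways — sizes are matched exactly, overlap structure is not.

## Synthetic study conditions

The generator is linear-Gaussian for analyzability. Defaults (and the
reasoning where a value was free): 120 cell lines, 30 drugs, 300 genes, 20
pathways of 5–30 genes — large enough for five-fold splits per scheme and
per-cell-line rank metrics over ~30 test drugs, small enough that a full
benchmark runs in minutes on one CPU. Pathway effect β = 1.5, drug-offset
SD τ = 2, cell-line-offset SD 0.5, noise SD σ = 0.5, all in label (log
IC50) units: τ ≫ β puts the data in the drug-identity-dominated regime
(the between-drug share of response variance exceeds 50%, and the naive
LCO predictor scores SCC ≈ 0.8), while β/σ = 3 keeps the pathway signal
recoverable. Expression loads on pathway activities with SD-1 Gaussian
loadings plus SD-0.3 gene noise, is shifted positive and emitted on the
FPKM scale so the real preprocessing path (log2(FPKM+1), variance filter)
runs end to end; mutation rate 0.1; fingerprints derive from per-pathway
512-bit prototypes with 5% bit flips so structural similarity tracks
target-pathway identity; the interaction network contains a spanning path
plus random edges within each pathway and 200 background edges, which
guarantees every target gene a network node.

What the generator does *not* emulate: empirical response distributions,
drug-class structure, tissue covariates, missing measurements, or
correlated multi-pathway drug action (one target pathway per drug by
default). Passing tests therefore demonstrate that the pipeline measures
what it claims under a known ground truth — not that any architecture wins
on real data.

The ground truth exposes the noise-free regression surface
μ + b_d + γ_c + β·a_{c,p(d)}; its RMSE converges to σ and no trained model
should beat it beyond stochastic tolerance.

## Statistics

Wilcoxon signed-rank contrasts drop zero differences (the common
convention), use the exact sign-flip null for n ≤ 25 — computed by
convolution over doubled midranks, so ties are handled exactly — and a
tie-corrected normal approximation without continuity correction above.
Percent improvement over random collections is computed on aggregate means
(100·(real − mean)/|mean| for correlations, sign-flipped for errors, so
positive always favours the biological collection). Concordance counts
measured ties as non-comparable and prediction ties as half-concordant.
The specificity analysis tests each drug's (each cell line's) responses
against the pool of all *other* responses — excluding the entity's own
values avoids self-comparison bias — with two-sided Mann–Whitney U and
Benjamini–Hochberg FDR within each family.

## Degenerate inputs and tie-breaks

Cell lines with fewer than two test pairs, or a constant measured or
predicted vector, have undefined correlations and concordance; RMSE/MSE
are still computed, and aggregates count exclusions. Duplicate drugs
across experimental batches resolve to the batch measured on most cell
lines, ties to the lexicographically smallest label. Enrichment scores are
0 when the permutation null is degenerate or a pathway has no member in
the profile support. Experiment orchestration derives every child seed by
stable hashing of (master seed, stage, index), making full runs
reproducible and resumable cell by cell.

## Known limitations

Training is single-threaded NumPy: adequate at the synthetic scale
(seconds per fold), not at the scale of public drug screens. The
enrichment pipeline is the cost hot-spot by design (one permutation null
per profile), which is why randomized-collection replicates default to 20
for directly-masked models but 3 for the enrichment model. Hyperparameter
search is out of scope; defaults are documented above and overridable per
experiment. Pathway topology, gene-identifier harmonization, and
dose–response curve fitting are explicitly not modelled.
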