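# Methods

## Scope and data model

granulekit analyzes three related label-free DIA experiments on stimulated
neutrophils, all carried as `QuantTable` objects (protein × sample intensity
matrix + per-sample metadata):

* **cell proteome** — control + three stimuli (LPS, TNF-α, PMA) × six time
  points (0, 15, 30, 60, 120, 240 min) × 3 replicates;
* **secretome** — control + three stimuli × six time points
  (0, 5, 15, 30, 60, 120 min), one sample per point, with a constant-amount
  protein A spike-in;
* **shedding experiment** — per stimulus, stimulus vs stimulus+GM6001 arms
  × 3 replicates at a single time point.

Long DIA-NN-style reports (`Protein.Group`, `Run`, `PG.MaxLFQ`) are pivoted
to wide tables; conflicting duplicate (protein, run) rows and unknown runs
are hard errors. Annotation tables (granule subsets, exclusion classes,
membrane topology, secretion-route predictions) are inputs, never
recomputed; unlisted accessions default to empty annotations.

## Normalization

Secretome samples are first median-normalized (each sample's log2 median is
shifted to the grand median of sample medians), then divided by the relative
spike-in abundance `spike_i / geomean(spike)`. The geometric mean is the
reference because it is scale-free; the choice only fixes the table's
overall unit and cancels in every downstream ratio. Both steps are
idempotent, preserve missingness, and the spike-in row has zero CV
afterwards. Cell tables are assumed normalized upstream (the usual
variance-stabilizing pipelines); `median_normalize` is available as a
fallback. Missing values are never imputed.

## Release screen

FC(t) = mean(stimulated)/mean(control) at each shared time point
(ratio of replicate means — stable under dropout). The trend is an OLS slope
of raw FC versus time in hours; a log-FC fit is available by flag but raw FC
is the default. The rule is strict: slope > 0 AND max observed FC > 1.5 at
t > 0 (the 0-min point carries no stimulation signal and is excluded from
the max, though it enters the fit). Exclusion (mitochondrial / ribosomal /
histone) is applied after the threshold rule, and calls carry their reason.
Raising the FC threshold can only shrink the released set (tested property).

**Classifier operating characteristics.** With a single secretome sample per
point, FC noise is the ratio of two log-normals: at measurement CV = 0.2 the
log-FC standard deviation is ≈ 0.28, so a flat background trajectory exceeds
FC 1.5 at one of five post-baseline points with probability ≈ 0.3, and about
a fifth of background proteins pass the joint rule per condition. The
3-condition union therefore has high recall (≈ 1.0 on planted data) but
limited precision (≈ 0.4 at CV 0.2; ≈ 1.0 at CV ≤ 0.05). This is a property
of the rule itself, not of the implementation — a single-replicate
design with strict per-point thresholds cannot control the false-positive
rate at high measurement noise. Tests report it honestly rather than
papering over it.

## Differential testing

Welch's two-tailed t on log2 intensities with BH adjustment across the
tested proteins of one (condition, time) stratum; significance means
adjusted p ≤ 0.01 and |FC| ≥ 1.5. The variance moderation used by dedicated
proteomics packages is deliberately **not** reimplemented — the screens here
are driven by the thresholds, not the moderation — so at 3 replicates and
CV 0.2 the stand-in test is conservative (measured type-I ≈ 0.037 at nominal
0.05) and noticeably less powerful than a moderated test. One visible
consequence: on default-noise synthetic runs the clustering stage may
receive very few (or zero) differential proteins and is then skipped for
that condition; the clustering code itself is exercised independently.

## Fuzzy c-means

Hand-implemented alternating optimization: memberships
u_ij = 1/Σ_k (d_ij/d_ik)^(2/(m−1)) (a point coincident with a centroid takes
membership 1 there), centroids v_j = Σ u_ij^m x_i / Σ u_ij^m, Euclidean
distance, stop at max |Δu| < 1e−5 or 300 iterations. The objective
J = Σ u^m d² is asserted non-increasing every run. Initialization is seeded
sampling of input rows (explicit centroids can be passed), so results are
deterministic given the seed. Profiles are z-scored per protein (population
SD; zero-variance profiles dropped). Default fuzzifier m = 2; a
dimension/size heuristic estimate is available but flagged as such. The
cluster number is chosen by mean silhouette of the hardened assignment over
a candidate range, ties toward smaller c; a minimum inter-centroid-distance
criterion is available as an alternative. As m → 1 the hardened partition
coincides with Lloyd's k-means from the same initialization — verified on
well-separated data; on structureless data the two algorithms may settle
into different (equally arbitrary) fixed points, so that equivalence is only
claimed when separation ≫ spread.

## Pattern integration

Cellular "relative percentage" is 100 × mean LFQ(t) / mean LFQ(0); zero or
missing baselines mark the trajectory undefined rather than raising. Judging
cellular "decrease"/"increase" by eye is not reproducible; here the criteria
are explicit and configurable: depletion = negative OLS slope AND
minimum ≤ 80% (depletion_delta = 20 points); induction = positive slope AND
maximum ≥ 150% (induction_delta = 50 points). The decision table
(release flag × depletion/induction/neither) yields exhaustive, mutually
exclusive labels; undefined trajectories are "unscored". Kinetic subtype
assignment z-scores each supernatant trajectory (making it invariant to
affine rescaling), builds a subset consensus as the mean of its markers'
z-scored trajectories, and assigns the best subset when Pearson r ≥ 0.8.
The default marker table (AG: AZU1, MPO, ELANE, PRTN3; SG: LCN2, LTF, MMP8,
CHI3L1, CRISP3, TCN1, LRG1, OLFM4; GG: FCN1, FGL2, MMP9, CAMP, CHIT1, CD93,
PGLYRP1; SV: FCGR3B, CD14, CD11b) is editable. Similarity alone does not
establish subcellular localization; assignments are candidates.

## Shedding and topology

Substrate rule: two-tailed Welch t on log2 intensities, p < 0.05, and
*signed* log2(stimulus / stimulus+inhibitor) > 0.6 — the direction
(reduction under the inhibitor) is part of the rule even though the
threshold is conventionally quoted as an absolute value. No multiplicity
adjustment by default (BH by flag). Zero-variance identical arms give p = 1.
With the 0.6 effect gate the null false-substrate rate is ≤ 1% at CV 0.1
while 2-fold reductions are detected with power > 0.9.

Peptide topology: a single- or multi-pass model holds 1-based inclusive TM
spans; type I puts the N terminus extracellular, type II the C terminus. A
peptide fully inside one region takes its label; peptides overlapping a TM
boundary — or lying in an ambiguous interior loop of a multi-pass model —
are "spanning". The ectodomain fraction is computed over non-spanning
peptides; "majority extracellular" means fraction > 0.5, and all-spanning
proteins are unscored. The interval logic is checked against a per-residue
brute-force classifier.

## Synthetic world

The generator plants one class per protein: released with depletion,
released without depletion (azurophilic-marker-like), induced cellular
(cytokine-like), shed membrane, background. Default fractions
0.10/0.05/0.05/0.05/0.75.

* Released supernatant FC follows a saturating curve with half-rise at
  30 min, normalized so the **last sampled time point reaches
  `release_amplitude`** (default 3 — a mid-range value for granule cargo at
  2 h). The normalization makes the noise-free maximum observed FC equal the
  amplitude exactly, which the tests rely on.
* Cellular depletion is linear from 100% to `depletion_floor` (default 40%,
  a strong but not exhaustive discharge); induction is linear to
  `induction_peak` (default 300%, comfortably past the induction threshold).
* Noise is multiplicative log-normal with CV = `noise_cv` (default 0.2,
  typical of single-sample label-free intensities); missingness is
  completely at random at `dropout_rate` (default 0.1). Intensity-dependent
  missingness is deliberately not modeled.
* The spike-in row is a fixed amount; every run is multiplied by a scale
  drawn uniformly from `run_scale_range` (default 0.5–2), so spike-in
  normalization is testable and exact in the noise-free limit.
* Shed membrane proteins get a single 21-residue TM span at a random
  position in a 100–800-residue chain, random type I/II orientation, and are
  substrates in all three stimuli; the inhibitor reduces their supernatant
  level `inhibitor_effect`-fold (default 2).
* Route-prediction flags for non-canonical released proteins are drawn
  independently at prevalences typical of neutrophil secretome annotation
  (20.4% signal peptide, 33.1% nonclassical, 10.7% transmembrane, 59.1%
  vesicle). Real route predictions are correlated, so the synthetic
  "any route" share (~80%) exceeds what correlated flags would give.

What a green test on this world establishes: the pipeline recovers planted
structure under log-normal noise and MCAR missingness at the stated rates.
What it does not establish: behavior under intensity-dependent missingness,
batch structure, correlated noise across time points, protein-inference
ambiguity, or real biological kinetics — the class templates are stand-ins,
not kinetic estimates.

## Numerical conventions

* Strict inequalities in the release and shedding rules (the conventional thresholds are
  strict ">" rules).
* OLS slopes via `scipy.stats.linregress`, checked against the closed form
  to 1e−12; BH via statsmodels, checked against a brute-force step-up oracle
  (agreement to one ulp; the two implementations order the arithmetic
  differently).
* TSV floats are written with 17 significant digits so write → read is a
  bit-exact round trip; rewriting a table twice yields identical bytes.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; generator substreams are keyed per experiment
  so cell/secretome/shedding tables from one config describe the same
  planted truth.
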