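# Methods

## The classification model

Subtyping degraded FFPE expression data runs in four stages.

**Transcript integrity.** For a transcript covered at `k` sampled positions
with depths `c_1..c_k`, the coverage distribution `p_i = c_i / Σc_j` has
Shannon entropy `H = −Σ_{p_i>0} p_i ln p_i` (natural log, with
`0·ln 0 := 0`), and `TIN = 100·e^H/k`. `e^H` is the effective number of
uniformly covered positions, so TIN is the percentage of the transcript
with effectively uniform coverage: 100 for perfectly even coverage, `100/k`
for a single spike, 0 for no coverage. TIN is invariant to overall
sequencing depth (scaling all depths cancels). Positions are sampled every
10 nt along the spliced mRNA with both endpoints always included
(configurable); transcripts with mean depth < 10 are excluded from a
sample's median TIN (medTIN). Gene-level TIN defaults to the TIN of the
gene's most-covered transcript per sample (`max_coverage`); a `mean` mode
averages transcript TINs instead. Both are offered because transcript→gene
aggregation is a genuine modeling choice; `max_coverage` follows the
transcript that actually dominates the gene's quantification. Background
(intergenic) coverage subtraction is not implemented.

**Feature-gene selection.** From a user-supplied candidate list (the union
of published CMS signature-gene lists in real use; the simulator's module
genes in the synthetic setting), genes are kept when their median TIN
across the cohort's samples is **strictly greater than 20**. The strict
inequality matters at the boundary and is part of the contract. Candidates
absent from the TIN table are dropped with a warning; an empty selection is
an error. The published signature lists themselves are inputs, not shipped
resources: they are external artifacts maintained elsewhere, and baking in
a copy would silently pin their version.

**Pair encoding.** Expression is log2(x+1)-transformed (on by default;
disable for data already on log scale, e.g. microarray intensities), then
z-normalized **per gene across the samples of the cohort being encoded**
(sample sd, n−1). Each ordered pair (a, b) with a < b lexicographically
yields the binary feature `1[z_a > z_b]`; ties encode 0, so constant or
zero-padded genes behave deterministically. Column order is the
lexicographic pair order and is part of the persisted model contract.
Cohort-internal normalization is what buys cross-protocol robustness: any
per-gene positive affine distortion of the input (platform, labeling
chemistry, scanner) leaves the encoding bit-identical. The price is that a
single sample cannot be encoded alone; cohort-mode input (≥ 2 samples,
realistically dozens) is required, and the package refuses single-sample
matrices rather than silently producing unstable calls. All m(m−1)/2 pairs
are used; no pruning.

Genes expected by a trained model but absent from a new cohort are injected
as constant rows (z = 0) up to a missing fraction of 0.2, and reported;
beyond that alignment fails. Zero is the natural neutral value: the padded
gene loses, exactly, its information content.

**Classifier.** `sklearn.ensemble.RandomForestClassifier` with the
classical defaults of the original random-forest implementation: 500 fully
grown trees, `mtry = ⌊√P⌋` features per split, minimum leaf size 1, fixed
seed. Class probabilities are averaged per-tree leaf distributions; with
fully grown trees on binary features leaves are almost always pure, so this
equals the fraction of trees voting each class (the test suite checks the
vote-tally equivalence). Calls are argmax with ties broken toward the
lower-numbered CMS — deterministic and documented, since any tie rule is
arbitrary. There is no reject option; confidence lives in the probability
vector, and filtering calls by `max prob ≥ 0.5` can only raise accuracy
(checked as a property). Out-of-bag accuracy is recorded in the model
manifest. Models persist as a zip of JSON manifest (genes, pair order,
classes, hyperparameters, seed, format version, forest checksum) plus the
joblib-serialized forest; the loader verifies the checksum, the
gene/pair-order consistency and the major format version.

**Evaluation.** Accuracy is the fraction of jointly labeled samples whose
call equals the benchmark core CMS label; benchmark samples without a core
call (`NOLBL`) are excluded and the denominator used is always reported.
The 4×4 contingency table (predicted × benchmark) has trace/total equal to
accuracy by construction. Per-class one-vs-rest sensitivity and specificity
return NaN when a denominator is zero. Concordance significance is the
one-sided exact binomial tail `P = Σ_{j≥k} C(n,j) p0^j (1−p0)^(n−j)` with
`p0 = 0.25` — uniform chance agreement among four subtypes — as the default
null; the null is a parameter and is printed with the result, because the
appropriate chance level depends on the marginal label distribution and a
user may prefer a cohort-specific `p0`.

## The synthetic cohort generator

The simulator emulates the situation the pipeline must survive, not any
particular dataset.

**Fresh-frozen layer.** Five gene modules — immune, epithelial, metabolic,
stromal (50 genes each) and 300 background genes. Each sample draws a
subtype from proportions (0.15, 0.40, 0.15, 0.30), roughly the mix seen in
colorectal cohorts with CMS2 dominant. Log2 abundance is
`x_gs ~ N(mu_g + delta·1[module(g) active in subtype(s)], sigma)` with
per-gene baselines `mu_g ~ U(3, 8)` (≈ 8–256 TPM), `delta = 1.5`,
`sigma = 1`; linear expression is `2^x − 1`. The subtype↔module map is
CMS1→immune, CMS2→epithelial, CMS3→metabolic, CMS4→stromal. `delta = 1.5`
(≈ 2.8-fold) keeps held-out fresh-frozen accuracy high but below
saturation, matching the regime where real FF cohorts classify in the
nineties rather than perfectly; a larger effect would make every model
perfect and mask any degradation effect, a smaller one would make the
planted structure unrealistically hard.

**Degradation layer.** Degradation acts multiplicatively on linear
expression (transcript loss is proportional to molecule counts), in three
mean-preserving steps:

1. *Gene-level* typical retention `r_g ~ Beta(mean = 1 − severity(module),
   concentration = 10)` — module severities default to immune 0.8,
   epithelial 0.3, stromal 0.3, metabolic 0.5, background 0.5, encoding the
   observation that immune marker transcripts degrade far more than
   epithelial and stromal markers while other pathways spread in between.
   Concentration 10 gives gene-to-gene spread without heavy tails.
2. *Sample-level* quality `q_s ~ U(0.5, 1)` — block-to-block variation.
3. *Realized* retention `r_gs ~ Beta(mean = r_g·q_s, concentration = 2)`,
   then Poisson counting noise at an effective depth of
   `counts_per_tpm = 0.5` expected usable reads per TPM unit:
   `ffpe = Poisson(ff·r_gs·counts_per_tpm)/counts_per_tpm`.

Step 3 is the scientifically load-bearing choice. A purely deterministic
attenuation (`ff·r_g·q_s`) is a per-gene scale factor plus a per-sample
factor, and the pair encoding is constructed to be invariant to exactly
that — deterministic loss would leave rank features untouched and make
degradation consequence-free, which contradicts what degradation does to
real classifiers. Fixation damage varies unpredictably per block and per
transcript, so the retention realized in one sample scatters widely around
its expectation (concentration 2 ⇒ strongly variable), and the few reads
surviving from a badly degraded transcript add counting noise and
dropouts. Both layers preserve `E[ffpe] = ff·r_g·q_s ≤ ff` elementwise.
Setting `counts_per_tpm = None` disables counting noise for users who want
the attenuation model in isolation.

The matching TIN table tracks realized integrity:
`TIN = clip(100·r_gs + N(0, 5), 0, 100)` — a gene's measured TIN in a
sample reflects how degraded that sample's copy actually is, with 5 TIN
units of measurement noise (visible spread while keeping module ordering
reliable).

**What the simulator does not emulate:** read-level artifacts (adapters,
insert-size, rRNA content), transcript-length and GC dependence of
degradation, correlated gene-gene expression within modules, tumor purity,
platform-specific probe effects, and batch structure. Passing tests
therefore show that the pipeline behaves correctly under module-structured
expression with module-specific, sample-variable degradation — not that it
attains any particular accuracy on real archival cohorts.

## Desk-scale validation experiments

`cmsffpe.benchmark.degradation_benchmark` runs, per seed: simulate 400
samples (defaults), split 200/200, select feature genes with the TIN
filter, train on fresh-frozen pair features, and score on held-out
fresh-frozen and FFPE expression; a second model trained identically on
*all* candidate genes serves as the comparator. Twenty seeds keep the
medians stable while finishing in about two minutes on one CPU; 400-sample
cohorts match the scale of the discovery-type cohorts the method targets.
Under the defaults the filtered model's held-out FF accuracy sits around
0.98–1.0 and its degraded-FFPE accuracy above the all-candidate model's —
the directional effect that motivates preservation-aware selection.

## Numerical and design notes

* TIN is clipped at 100 to absorb float overshoot at exact uniformity;
  `Σc = 0` returns 0 by definition.
* z-normalization uses the n−1 sample standard deviation; constant genes
  map to all-zero rows with a logged warning.
* All simulator randomness derives from a single integer seed through
  separate spawned streams for the FF and degradation layers, so
  `degrade` is reproducible independently of how many draws `simulate_ff`
  consumed.
* Training labels (benchmark core calls) are an explicit input file and are
  never inferred or bundled: which benchmark labeling to train against is a
  scientific decision the user must make visibly.
* The coverage-ingestion path reads pre-sampled per-transcript depth
  vectors from TSV; alignment-file ingestion was left out of scope to keep
  the package free of alignment-stack dependencies — upstream tools already
  produce per-base coverage.
* File formats are TSV (UTF-8, Unix newlines, `NA` for missing) and
  round-trip exactly; model archives and every CLI output carry a manifest
  with input checksums, seed and package version.

## Known limitations

* Not a single-sample predictor: calls depend (weakly, through cohort
  z-scores) on the composition of the cohort being classified.
* The TIN>20 threshold is the published operating point, exposed as a
  parameter but not re-derived here.
* With the immune module filtered out, CMS1 is recognized largely by
  elimination; its sensitivity is the first casualty of aggressive
  filtering (visible in the worked example).
* The binomial concordance test treats calls as independent Bernoulli
  trials, ignoring per-sample difficulty correlation.
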