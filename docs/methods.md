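# Methods

`rootedit` quantifies CRISPR/Cas9 editing outcomes in cohorts of transgenic
hairy roots, where each root is genotyped by Sanger-sequencing a short
amplicon around the guide target and comparing the edited trace with an
unedited control. This note describes the models, the synthetic-data
generator that stands in for wet-lab cohorts, the numerical choices, and
the limits of what the tests demonstrate.

## Coordinate and cut-site model

All coordinates are 0-based, half-open, on the amplicon forward strand.
SpCas9 is modelled as cutting bluntly between the −4 and −3 positions
relative to the NGG PAM; `cut_pos` is the first base 3′ of the cut. The
staggered-end biology that SpCas9 can also produce (1-nt 5′ overhangs) is
represented only through the templated-insertion predictor, not through
cut geometry: fill-in of a 1-nt overhang duplicates the base at the −4
position (protospacer base 17), which is the package's prediction for the
identity of 1-bp insertions. Guides on the minus strand keep protospacer
and PAM in their own orientation, with `cut_pos` in forward coordinates.

## Guide design filters

Candidates are every 20-mer adjacent to an NGG PAM on either strand.
Filters (all hard): the cut site must fall within the 5–65% window of the
CDS (measured at the cut, not the protospacer start — the choice when the
window's reference point is ambiguous); the protospacer must begin with G
(U6-driven transcription initiates on guanine; no G-appending fallback);
and the protospacer+PAM must not contain a BbsI site (GAAGAC/GTCTTC),
which would break cut-ligation cloning. Off-target hits are PAM-adjacent
20-mers in a user-supplied background FASTA, compared by Hamming distance;
hits with more than 4 mismatches including at least one in the PAM-proximal
seed (default 12 nt, the Cas-OFFinder convention; configurable) are
dismissed as non-cleavable. Exact (0-mismatch) hits are treated as the
on-target site and excluded from the risk count. Ranking is lexicographic:
fewest surviving off-targets, then highest efficiency score, then 5′-most
cut.

## Trace model and decomposition

A chromatogram is modelled as a `TraceMatrix`: one row per template
position with the fractional signal of A, C, G, T, each row summing to 1.
This is exactly the information the decomposition consumes, so no AB1
parsing, quality values, or dye artifacts are modelled.

The edited trace downstream of the cut is a non-negative mixture of
templates, one per indel size in {−30..+30} (0 = wild type): deletion
templates shift the control left, insertion templates shift it right with
the inserted rows set to uniform 0.25 (a mixed trace cannot resolve
inserted bases). The fit window runs from `cut + max_indel` to
`read_length − max_indel`, so every template inside the window is fully
determined by control rows; this deterministic rule replaces an
interactively chosen window for reproducibility, and it is why amplicons
must extend ≥ ~65 bp past the cut. The mixture is solved by non-negative
least squares (`scipy.optimize.nnls`) over the flattened window (rows ×
4 channels); coefficients are normalized to percentages summing to 100.

Per-size significance: the active (non-zero) coefficients are refit by
ordinary least squares and each is given a two-sided t-test p-value
against zero. Inference on the non-negativity boundary is more subtle
than this (the constrained estimator's distribution is not the OLS one);
the OLS recipe is a deliberate, testable stand-in that behaves correctly
in the two regimes that matter here — near-zero p for truly present
alleles, large p for noise-level coefficients. Fit quality is
R² = 1 − SS_res/SS_tot over the window, clamped to [0, 1].

QC follows the study rules: a root is rejected outright when R² ≤ 0.7;
surviving spectra drop indels with p ≥ 0.01. Percentages are written to
one decimal place in reports; full precision is kept internally.

## Scores and group statistics

Per root, INDEL score = Σ percentages of significant indels (editing
efficiency) and KO score = Σ percentages of likely-null indels:
frameshifts (size mod 3 ≠ 0) plus in-frame indels with |size| ≥ 21 bp.
The ≥21-bp rule is applied to either sign; no insertion that large has
been observed, but the symmetric rule is the natural reading. KO ≤ INDEL
always. Groups (guide × construct) report mean ± SE (sample SD/√n, n−1
denominator); groups with fewer than 15 roots are computed but flagged
non-reportable. Promoter contrasts use Welch's two-sample t-test
(unequal variances, Welch–Satterthwaite df, two-sided p) via
`scipy.stats.ttest_ind(equal_var=False)`; no multiple-testing correction
is applied across contrasts by default, matching how such screens are
usually reported (a Holm step can be layered on by the caller).

Dominance is judged per root: an indel qualifies as dominant when it
exceeds 20% of the sequence population in at least one root, and the
pooled per-guide listing orders keys by the maximum percentage observed.
(Whether published pooled listings used per-root or pooled-sample
thresholds is ambiguous; per-root is the default and the threshold is
config-switchable.) The pooled mutation-spectrum summary counts event
occurrences across roots and reports the deletion:insertion event ratio,
flagged undefined when no insertions occurred.

## Microhomology scoring and repair prediction

Microhomology patterns are maximal repeated blocks flanking the cut: left
copy entirely 5′ of the cut, right copy starting at or after it, both
within the search window, with nested sub-patterns of a longer repeat at
the same offset suppressed (left-maximality). Collapsing a pattern
deletes `right_start − left_start` bp. Pattern weight is
`100 · exp(−ΔL/20) · (2·GC + AT)` — exponential decay in the implied
deletion length (length constant 20 bp) with GC pairs counted double;
these constants follow the established microhomology scoring convention
and are config-exposed. The out-of-frame score is the weight fraction of
patterns whose ΔL is not a multiple of 3, in percent. Deletion scoring
uses a 30-bp window on each side so implied deletions respect the
decomposition's reporting cap (the window length was an open choice;
30 bp keeps the two stages coherent).

Microhomology *strength* summarises a locus over 100-bp flanks: the sum
of pattern weights, each further decayed by `exp(−d/20)` where d is the
pattern's gap distance to the cut, divided by a fixed normalization
constant (3400) chosen once so that a typical random locus scores ≈ 0.5.
Classes: low < 0.3 ≤ average ≤ 0.8 < high. The value is a package-defined
proxy — published strength values come from a trained model that is not
reproduced here — so only the class labels and the monotonicities
(longer/GC-richer/closer ⇒ stronger) are contract-bound.

The combined predicted spectrum mixes microhomology deletions (pooled by
size, weighted by pattern score) with the templated +1 insertion at a
configurable insertion mass, default 0.25 to reflect the ≈3:1
deletion:insertion ratio. Top-k extraction breaks weight ties by smaller
|size|, then deletions before insertions.

Concordance with observed dominant indels is by signed size (published
top-5 lists carry no base identity; duplicate sizes in a list collapse);
a strict mode also matching insertion bases exists for synthetic ground
truth. Insertion concordance asks whether the most frequent pooled 1-bp
insertion base equals the −4 template base and reports the template
base's share of insertion mass.

## The synthetic cohort generator

The generator emulates the statistical structure of the study cohort, not
its sequences:

* **Indel-size distribution** — the shipped fixture
  (`data/pooled_size_weights.tsv`) anchors P(−1) = 0.226 and
  P(+1) = 0.191 (the observed pooled 1-bp frequencies), fixes total
  deletion mass at 0.75 vs insertion mass 0.25 (the ≈3:1 ratio), and
  spreads the remaining mass geometrically over −2..−30 (ratio 0.82) and
  +2..+4 (ratio 0.5). Only the anchors and support bounds are observed;
  the tail shape is a documented modeling choice.
* **Per-root structure** — each root carries k dominant indels, k uniform
  on 1–4, every dominant event > 20% of the population, the wild-type
  fraction uniform on a configurable range (default 0.10–0.30, i.e. a
  mean editing level of ≈80%, typical of an efficient guide). k is capped
  at ⌊edited%/(20.5)⌋ so the dominance constraint stays satisfiable:
  biologically, a weakly edited (or chimeric, mostly-unedited) root cannot
  carry four >20% indels. Roots whose edited fraction falls below the
  dominance cutoff (e.g. a seed-mismatched guide) carry at most one minor
  event — this is how the seed-SNP negative control produces near-zero
  INDEL scores without a special case downstream.
* **Distinct sizes with exact marginals** — sizes within a root are
  distinct, drawn by Madow systematic probability-proportional-to-size
  sampling with inclusion probability k·p(s). Unlike redraw-on-collision,
  this keeps the pooled event-size frequencies equal to the fixture
  weights in expectation (a naive scheme depresses the −1 share by
  several points because it is the most collision-prone size).
* **Templated insertions** — a +1 insertion copies the −4 template base
  with probability 0.75 (the generator's template bias, chosen to mirror
  the observed preponderance of template-matching insertions), else a
  uniform other base. Larger insertions get uniform random bases.
* **Chimerism** — represented implicitly: allele percentages are
  arbitrary, with no diploid 50/50 constraint.
* **Traces** — control = one-hot of the reference; edited = the
  percentage-weighted mixture of indel-shifted allele signals downstream
  of the cut. Noise is independent Gaussian per signal fraction
  (default SD 0.01), truncated at zero, rows renormalized — the simplest
  model that exercises the significance machinery. The synthesis bound
  `max_shift` is deliberately independent of the decomposition window so
  stress scenarios can inject oversized (e.g. 40-bp) deletions.
* **Study layout** — `simulate_study` assigns each guide label one
  amplicon (random sequence with an in-frame CDS and a usable filtered
  guide) and each guide × construct group a configured mean INDEL level
  via the wild-type fraction range, so promoter contrasts are recoverable
  downstream. Everything is seeded and byte-reproducible.

What the generator does **not** emulate: real chromatogram artifacts
(mobility shifts, dye blobs, basecall quality), sequence-dependent repair
preferences (sizes are drawn from a global distribution, not from the
locus's microhomologies), amplification bias, and heteroduplex effects.
Passing tests therefore demonstrate that the decomposition and statistics
recover what this model generates — not that the pipeline is robust to
every failure mode of real Sanger data.

## Problem sizes and defaults

Default amplicons are 300 nt (a cut needs ≥20 nt upstream and ≥65 nt
downstream); the demo study runs 2 guides × 2 constructs × 15 roots in
well under a minute on one CPU. Generator calibration checks draw ≥10,000
events; the decomposition stress scenario uses 200 roots; noiseless
recovery is verified over 100 seeded roots. These sizes give sampling
errors well inside the tolerances being checked (e.g. binomial SE ≈ 0.4
points at n = 10,000 for a 22.6% share).

## Degenerate inputs and tie-breaks

Zero indel size is always an error; a trace with no signal variance in
the fit window raises an undefined-fit error rather than reporting R²;
an all-zero NNLS solution likewise. The all-deletion pooled-spectrum
ratio is reported as undefined, not infinity. Welch's test requires n ≥ 2
per group and variance in at least one group. Guide ranking and top-k
extraction have total, documented orderings so outputs are deterministic.

## Known limitations

* Insertion base identity is never inferred from traces — only synthetic
  ground truth (and the real study's cloning-based tables) carries it.
* The OLS p-value recipe ignores constrained-inference subtleties (see
  above); with 61 templates and short windows the active-set refit can be
  ill-conditioned for reads much shorter than ~130 nt.
* The microhomology strength scale is a proxy; absolute values are not
  comparable with trained-model outputs, only classes and orderings.
* Efficiency-score ranking defaults to the out-of-frame proxy; trained
  third-party efficiency models are out of scope and enter only as
  user-supplied score tables.
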