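# Methods

`etchnet` re-implements, as a tested library, the computational core of a
proximity-labeling (BioID) and affinity-purification (AP-MS) interactomics
analysis of nuclear transcription factors: building a contaminant
repository from GFP control purifications, scoring bait–prey spectral
counts against that background, applying a compound high-confidence
filter, and running the downstream network, localization, motif and
genomic-interval analyses. This note documents the models, the defaults
and why they were chosen, and what the synthetic-data generators do and
do not emulate.

## Contaminant repository

GFP control purifications carrying different localization tags (untagged,
myristoylated/MYR, nuclear-export/NES, nuclear/NLS) define the
nonspecific-binder background. A control run enters the repository only
if it detects at least `qc_min_proteins` preys with PSM > 0 — 1000 for
BioID and 300 for AP-MS by default, both boundary-inclusive and
configurable. For each prey the repository records, per stratum:

* `pct` — 100 × (runs detecting the prey) / (runs in the stratum),
* `avg_spec` — mean PSM over the runs **where the prey was detected**
  (not over all runs; a rare but abundant binder keeps a high AvgSpec),
* `max_spec` — the maximum PSM.

Strata are `All` (every passing run), `NLS` and `MYR`. NES-tagged and
untagged runs contribute to `All` only; a stratum with zero runs is
marked absent rather than reported as zero.

## Interaction scoring

The scorer is a two-component count mixture in the spirit of the SAINT
family, fully specified so it can be checked against direct likelihood
evaluation:

* PSM counts are negative binomial with mean μ and dispersion α
  (var = μ + αμ²; α = 0 degenerates to Poisson). One α is shared across
  preys, estimated from the control compendium by pooled method of
  moments: α̂ = Σᵢ(s²ᵢ − m̄ᵢ) / Σᵢ m̄ᵢ², clamped at 0.
* Background component: mean = the prey's average count over **all**
  control runs (zeros included), floored at a pseudocount of 0.1.
* True-interaction component: mean = max(bait replicate mean,
  2 × background mean). The floor of 2× encodes the minimal assumption
  that a true interactor is enriched over background; without it the two
  components collapse when the bait signal equals background.
* Each replicate count gets a posterior probability of the true
  component under equal priors; the pair's probability is the mean of
  its replicate posteriors. Baits are scored independently.

The Bayesian FDR at rank k of the probability-sorted list is the
cumulative mean of (1 − p) over the top k pairs. Ties share the value of
the last tied rank; tie-breaking in the sort is by prey identifier, so
the output is order-invariant and deterministic. The cumulative mean of
a non-increasing probability sequence is automatically non-decreasing,
which the tests assert as an invariant.

The scorer is not, and does not try to be, bit-compatible with any
external implementation; the on-disk scoring table uses a SAINT-list
compatible layout so an externally produced scoring file can be injected
into the pipeline in its place.

## Compound high-confidence filter

A scored pair is retained iff BFDR < 0.01 (strict) **and** the prey is
seen in < 10% of control runs (strict) **or** is rescued by a bait
AvgSpec ≥ 3× the repository AvgSpec (inclusive). For BioID, a prey that
is a frequent contaminant without rescue in **either** the `All` or the
`NLS` stratum is eliminated outright. Readings of the three boundaries
(strict, strict, inclusive) are configurable. Two open choices were made
here: the main frequency/rescue clause is anchored on the `All` stratum,
and the per-stratum elimination check applies the rescue comparison
against that stratum's own AvgSpec. Bait self-detections are excluded
from HCI counts. Every record's decision log names the first failing
clause in the order BFDR → elimination strata → frequency/rescue, which
makes the filter auditable and idempotent: re-filtering a retained set
changes nothing.

## Downstream analytics

* **Correlation clustering** — Pearson correlation between bait AvgSpec
  profiles (raw by default, log1p optional) and Ward linkage on
  Euclidean distances between profiles (the variance-increase criterion,
  Ward.D2-equivalent; heights are √(2·|A||B|/(|A|+|B|)) × centroid
  distance). Constant profiles have undefined correlations and are
  excluded from clustering with a warning. Dendrograms serialize to
  Newick.
* **Method overlap / hubs / novelty** — set arithmetic over per-bait
  unique-prey sets; hub ranking reports every prey at the maximal
  shared-bait count, ties ordered lexicographically.
* **Fisher enrichment vs a reference set** — per prey, the 2×2 table of
  (baits detecting vs not) × (study vs reference collection), two-sided
  Fisher exact p (all tables with probability ≤ the observed), BH
  adjustment across all tested preys, direction signed by the detection
  fractions. The per-prey formulation was chosen because results are
  naturally a list of differentially detected preys.
* **Expression cross-referencing** — a prey is retained iff its maximum
  RPKM over the requested stage window exceeds the threshold (strict
  `> 1` by default, switchable to `≥`). Preys missing from the table
  count as not expressed and are reported separately.
* **Localization profiling** — per compartment, the score is
  max(0, Pearson r) between log1p bait and marker profiles over the
  union of their preys (absent = 0), then max-normalized so the best
  compartment scores 1 whenever any correlation is positive. This
  honors a [0, 1] score scale and the correlation-of-profiles idea; it
  is this package's own formula, a stand-in for external services whose
  normalization steps are unpublished, and is not meant to reproduce
  their numeric scores. Under a global rescaling of the bait profile
  the log1p transform makes scores only asymptotically invariant; the
  argmax compartment is stable in practice and the tests assert
  approximate score stability (±0.05).

## 9aaTAD motif scanning

Every 9-residue window is scored against per-position residue classes
with optional flanking constraints (disallowed residues immediately
outside the window; vacuously satisfied at sequence boundaries).
`percent_match` = 100 × satisfied / total constraints. Two stringencies
ship as an editable plain-text config; the low-stringency classes are
positionwise supersets of the moderate ones, and the moderate pattern
additionally disallows basic flanks. The shipped classes are
reconstructed from the published 9aaTAD prediction tool's position
rules — the exact classes that tool uses are not recoverable, so the
pattern file is data, not code, and can be replaced wholesale. All
overlapping windows are reported; `X` never satisfies a constraint; no
reverse-strand scanning.

## Genomic intervals

BED semantics throughout: 0-based, half-open. Peak–TSS distance is
measured from the peak midpoint (configurable to a summit column) to the
nearest TSS, signed negative upstream relative to the gene's strand.
Categories are assigned by the first |distance| window that applies —
proximal promoter at 0–1 kb, distal promoter at 1–3 kb — then by
gene-body overlap if a feature annotation is supplied, else intergenic;
proportions sum to 100%. Enhancer overlap and peak-set comparison both
use the ≥1-shared-base rule; abutting half-open intervals do not
overlap, and a peak overlapping several partners counts once on its own
side (so the two sides of a comparison may report different shared
counts, and both are reported).

## Synthetic data: what it emulates, and what it does not

The generators produce every input the pipeline consumes, each with a
ground-truth table sufficient to score the pipeline without reaching
into generator internals.

* **Control runs** — per-prey detection probabilities drawn once from
  Beta(0.6, 3) (mean ≈ 0.17, most contaminants rare, a few frequent);
  a configurable fraction of contaminants (default 20%) is detectable
  in a single tag class only, which exercises the All/NLS elimination
  rule. Detected counts are zero-truncated negative binomial with mean
  `lambda_bg`.
* **Bait runs** — 2 biological × 2 technical replicates. Planted
  interactors draw a latent abundance per biological replicate
  (gamma with mean `lambda_true`, dispersion 0.25) shared by its
  technical replicates, which add independent Poisson noise — technical
  variation nested inside biological variation. Baits also see the
  class-independent and NLS-specific background (the baits are nuclear
  proteins), and their own construct is spiked in to exercise
  self-detection exclusion.
* **Defaults** — 21 baits, 2000 preys, control compendium of 64
  untagged + 24 MYR + 4 NES + 26 NLS runs, 50 planted interactors per
  bait, `lambda_true` = 20, `lambda_bg` = 1, dispersion 0.25. The
  replicate-level dropout knob defaults to 0: at a mean of 20 PSMs,
  total non-detection of a true interactor in a replicate is not a
  realistic feature of spectral counting, and the negative-binomial
  sampling already produces stochastic non-detection at low means. The
  knob exists to stress-test sensitivity under weaker signals.
* **Other fixtures** — marker/bait localization profiles built from
  disjoint compartment-specific prey blocks with log-normal abundance
  and multiplicative noise; protein sequences with motifs planted at
  recorded positions over human-proteome-like residue frequencies;
  genome fixtures with genes on a widely spaced grid (50 kb) so each
  planted peak's intended category is unambiguous; stage-resolved
  expression tables where a configurable fraction of expressed genes
  peaks at the 8-cell stage.

What the generators do **not** emulate: peptide-level identification,
protein length and detectability biases, correlated contaminant
structure across runs (batch effects), shared true interactors between
baits, or realistic genome annotation density. Passing recovery tests
therefore demonstrates that the statistical machinery is correct and
well calibrated under the stated noise model — not that the pipeline's
operating characteristics transfer unchanged to real purifications.

## Problem sizes and numerical choices

The recovery experiments run at 100 baits × 2000 preys (the package's
standard benchmark size, ~62k table rows, seconds of compute); unit
fixtures are smaller. Tolerances: Fisher p is checked against an
exhaustive hypergeometric enumeration to 1e-10 (with the conventional
(1 + 1e-7) relative slack when comparing table probabilities); Ward
heights against a brute-force agglomeration to 1e-9 relative; interval
operations against all-pairs scans exactly. Degenerate inputs are
errors, not silent zeros: empty control sets, all-QC-failing runs, empty
peak sets for overlap proportions, zero-size Fisher references, and
motifs longer than their sequence all raise.

## Known limitations

* The scorer shares one dispersion across preys; strongly prey-specific
  overdispersion would mis-calibrate per-replicate posteriors.
* The localization formula is a documented stand-in (see above).
* The shipped 9aaTAD pattern classes are a reconstruction; users with
  the original tool's definitions should supply them as a config file.
* Peak annotation uses midpoints unless a summit column is provided.
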