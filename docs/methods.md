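# Methods

## Problem setting

The package analyzes sulfur-metabolism gene content in collections of
metagenome-assembled genomes (MAGs) binned from stool shotgun metagenomes of
case-control colorectal-cancer cohorts. The unit of detection is a protein
hit (a MAG protein matching a gene-family HMM); the unit of inference is the
participant. All downstream statistics are presence-based: abundance,
coverage, and copy number beyond presence are deliberately not modeled,
because MAG recovery depth confounds them.

## Gene catalog

The catalog is the controlled vocabulary: 79 gene families, each with a
substrate class (`inorganic`, `organic_cys_met`, `organic_taurine`,
`accessory`), a sulfidogenic flag (the encoded reaction directly yields
H₂S), an HMM profile id, and an optional trusted bit-score cutoff. The
shipped default covers the gene families named in the primary gut
sulfur-cycle literature (dsrABC and the DsrMKJOP complex, asrABC, sqr, sat,
apr/qmo, assimilatory cys genes, thiosulfate/tetrathionate reduction, the
cysteine/methionine degradation enzymes mgl, metBC, malY, dcyD, lcd, CBS,
mccB, 3MST, the taurine pathway genes bsh, tauD, tpa, toa, xsc, isfD,
islAB, and sulfonate transport/utilization); entries beyond the named set
are representative members of standard sulfur-cycle families with
placeholder HMM ids and cutoffs. Production annotation should supply its
own catalog TSV (same columns); everything downstream is driven by the file,
not by hard-coded symbols. Multi-subunit requirements (dsrAB, asrABC,
islAB) are deliberately *not* catalog entries: detection happens per subunit
profile, and complexes are expressed as AND-sets in the pathway grammar.

Symbol case follows field convention (operon genes lowercase; CBS, 3MST
uppercase); `GeneCatalog.resolve` maps case-insensitive queries onto the
canonical spelling so profile names and catalog symbols cannot silently
diverge.

## Hit filtering

* **Trusted cutoffs** — a hit is retained iff its full-sequence bit score is
  ≥ the profile's trusted cutoff. The comparison is inclusive, following
  HMMER's own trusted-cutoff semantics. Profiles without a cutoff (typical
  for custom-built HMMs) have their hits retained and flagged, so callers
  can report them separately rather than silently losing or keeping them.
* **BLAST survey filter** — identity strictly greater than 60% and
  alignment length ≥ 40 amino acids. "Coverage of 40 amino acids" is read
  as alignment length because the 12-column tabular format carries
  alignment length, not percent coverage.
* **MAG quality** — high tier: completeness > 90%, contamination < 5%,
  strain heterogeneity < 0.5% (records without a strain-heterogeneity value
  cannot reach the high tier); medium tier: completeness > 50%,
  contamination < 5%. All inequalities strict. Filters on hits and on MAGs
  act on disjoint attributes and therefore commute; both are idempotent.
* **TNM → stage** — samples with TNM but no stage are mapped via a shipped,
  editable lookup (simplified AJCC colorectal convention: any M1 → IV;
  N1/N2 with M0 → III; T1/T2 N0 M0 → I; T3/T4 N0 M0 → II). Tokens are
  normalized (p/c/y prefixes and a/b/c subletters stripped). Unmatched
  triples are reported as `unstaged`, never guessed, and unstaged
  participants are excluded from stage denominators.

## Participant binarization and summaries

A participant carries a gene iff at least one of their MAGs has at least one
retained hit. `mags_with_gene` counts carrier MAGs, not hit copies.
Participants whose MAGs all fail quality filtering stay in denominators as
non-carriers: disease-state proportions are normalized to the total number
of participants in the state. Dot-plot cells report the carrier proportion
per gene × state and the mean carrier-MAG count over carriers only
(undefined, not zero, when a state has no carriers). Genus summaries take
genus labels verbatim from the metadata's closest-genus designator; missing
labels go to an `unclassified` bucket.

## Pathway grammar and completeness

Pathways are data (YAML), not code: an ordered list of steps, each with
alternative gene requirements, each requirement an AND-set of subunit
symbols. The shipped grammar encodes the two taurine-reduction families:

* 3-step: deamination {tpa}|{toa} → sulfoacetaldehyde acetyl transfer
  {xsc} → terminal sulfite reduction {dsrA,dsrB}|{asrA,asrB,asrC}
  (4 variants);
* 4-step: deamination {tpa}|{toa} → sulfoacetaldehyde reduction {isfD} →
  isethionate cleavage {islA,islB} → terminal reduction as above
  (4 variants).

Additional alternatives are added by editing the config. A step is
satisfied iff some alternative's AND-set is a subset of the unit's pooled
gene set. Status vocabulary: `complete` (no step missing), `near_complete`
(exactly one missing), `first_and_last_only` (first and last satisfied,
≥1 interior missing), `absent` (otherwise). For 3-step grammars the single
interior step makes the two non-complete labels coincide;
`first_and_last_only` takes precedence there because it is the signature of
potential cross-organism cooperation, while for 4-step grammars a single
missing interior step reports `near_complete`. With the completion order
absent < first_and_last_only < near_complete < complete, adding a gene can
never demote a unit (property-tested).

Pooling levels: single MAG; genus (union of gene sets over all MAGs with
that label across the cohort); participant (union over the participant's
MAGs). A participant-complete pathway with no single complete MAG is
flagged a cooperation candidate. The reported variant is the one satisfying
the most steps, ties broken lexicographically, so dsrAB-terminated and
asrABC-terminated completions are distinguishable in output.

## Association statistics

* **State test** — per gene, a 2×3 table of carrier/non-carrier counts over
  healthy/adenoma/carcinoma; Pearson chi-squared with df 2, no continuity
  correction and no small-count exclusion — instead the smallest expected
  cell count is surfaced (`expected_min`) so users can judge the
  approximation. A zero row margin (gene carried by everyone or no one)
  yields statistic 0, p 1, and a degenerate flag rather than an error. The
  tail probability comes from the χ² survival function (at df 2 this equals
  exp(−χ²/2), used as a cross-check in tests).
* **Multiplicity** — Benjamini–Hochberg step-up adjustment across all
  features tested in a run (genes plus any pathway-level features) as a
  single family, returned in input order.
* **Stage trend** — Rao score test of slope 0 in
  logit P(carrier) = β₀ + β₁·stage, evaluated at the intercept-only fit:
  U = Σxᵢ(yᵢ−ȳ), V = ȳ(1−ȳ)Σ(xᵢ−x̄)², statistic U²/V, p from χ²₁. Stage is
  coded as equally spaced 1–4 — the minimal reading of a logistic
  regression against stage; any other coding can be passed as integers. The
  default cohort for stage profiles is staged carcinoma participants; the
  caller chooses which profiles enter the test. The closed form is verified
  against statsmodels' likelihood-based GLM score test to 1e-6 in tests.
* **Direction** — the state with maximal carrier proportion; ties break
  toward the more advanced state. Reporting convenience only; it carries no
  inferential weight.

## Synthetic cohorts

The generator samples participants per state, a MAG count per participant
(negative binomial by default; mean ≈ 25.4 matches the published scale of
16,936 MAGs over 667 participants, with 265/112/290 participants per
state), a genus per MAG from a weighted pool, and per-MAG gene presence
from the genus carriage profile. Disease-state effects multiply carriage
odds: p′ = p·o/(1−p+p·o), so a planted odds ratio is exactly the logistic
alternative the stage test targets, and `planted_effect_truth` returns the
implied per-state carriage probabilities in closed form. Copy numbers are
1 + Poisson(0.25) where present — only presence matters downstream.
Carcinoma stages are drawn from a configurable distribution (default
0.2/0.3/0.3/0.2 over I–IV).

The default genus pool is class-structured — cysteine/methionine genes
common across genera, inorganic reduction genes rare, taurine genes
intermediate, mirroring observed prevalence structure — and is built with a
fixed internal generator so it is a stable study condition, not a random
variable. `independent_genus_pool` collapses to independent per-MAG coin
flips, the exchangeable setting used for calibration studies. Synthetic
quality metrics are drawn inside the medium-quality region so quality
filtering is a pass-through unless a test arranges otherwise.

The tblout writer emits present genes at cutoff + 5 bits (100 bits for
cutoff-less profiles) and optional decoys at cutoff − 0.1, so parse + filter
must reproduce the generating matrix exactly; this round-trip is asserted
in tests and recomputed by the acceptance script.

What passing on synthetic cohorts does *not* show: robustness to taxonomy
errors, to study batch effects, to uneven MAG recovery between states, or
to HMM cross-matching between paralogous families — none of which the
generator emulates.

## Simulation-study sizes and numerical choices

Calibration uses 2,000 null cohorts of 60 participants/state with 20 genes
(carriage probabilities spread over [0.08, 0.35] to keep expected cell
counts moderate) and checks that the raw type-I error at α = 0.05 lies in
[0.03, 0.07]; power uses 200 cohorts of 200/state with one gene's carriage
odds tripled in carcinoma and requires the planted gene to attain the
minimum adjusted p with the correct direction in >90% of runs. These sizes
were chosen as the smallest at which the binomial Monte-Carlo error is well
inside the asserted bands. The permutation oracle for the chi-squared test
uses 100,000 label shuffles at 100 participants/state; near the discrete
floor of the permutation distribution (statistics ≈ 0) the asymptotic and
permutation tails legitimately diverge, so oracle comparisons are made on
tables with mid-range statistics.

All randomness flows from integer seeds through `numpy.random.default_rng`;
generated files are byte-stable given a seed. Chi-squared and BH
computations delegate tail and step-up mechanics to scipy/statsmodels; the
contingency construction, degenerate handling, score-test closed form, and
pathway logic are implemented here and cross-checked against independent
implementations (scipy's `chi2_contingency`, statsmodels' GLM score test,
brute-force enumeration) in the test suite.

## Known limitations

* Presence-based inference cannot distinguish active pathways from silent
  gene content, nor resolve species within a genus label.
* The shipped catalog's non-named entries and all trusted cutoffs are
  representative defaults, not curated values; real annotation runs should
  supply their own catalog.
* The chi-squared test pools studies; no stratified or mixed-effects model
  is offered.
* The 2×3 test treats adenoma as an unordered category; a trend test across
  disease states (as opposed to stages) is not implemented.
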