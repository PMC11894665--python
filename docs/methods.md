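# Methods

This note documents the statistical model, the numeric choices, and what
the synthetic data generator does and does not emulate.

## Model and procedure

**Mass error.** The quantity modelled throughout is the precursor mass
error in neutral-mass Da space: observed minus theoretical neutral mass.
A correctly identified phosphopeptide has an error near 0; a sulfopeptide
misidentified as phosphorylated is offset by −(HPO₃ − SO₃) =
−0.009516 Da per misassigned site (−0.019032 Da for two sites). A third
systematic population sits near +0.0193 Da: when the instrument isolates
the +1 isotope peak (+1.003355 Da) and the search engine wrongly adds a
deamidation (+0.984016 Da), the residual error is
+1.003355 − 0.984016 = +0.019339 Da. All constants are computed from
atomic compositions via pyteomics, never typed in by hand.

**Recalibration.** Raw errors carry a per-raw-file calibration offset.
The pipeline subtracts the per-run *median* error from every PSM of that
run, after FDR filtering (q < 0.01, strict) and before the phospho
filter, so the median is taken over all confident PSMs of the run. The
median is the right location estimator here because the error
distribution is a mixture: a mean would be dragged by the artifact
populations, whereas the median sits inside the dominant near-zero
component as long as that component holds the 50% quantile. The
subtraction is idempotent, preserves within-run differences, and leaves
singleton runs at exactly 0 (logged).

**Peptidoform identity.** PSMs are pooled by *nonstrict* peptidoform:
`SEQUENCE|Name@Residue:count|...` with the terms sorted — modification
residue type and count are kept, site positions and charge are dropped.
Position-level identities would split the PSM support of exactly the
peptides we care about, because a labile sulfate yields no localisation
evidence. Robustness filters (≥ 3 experiments AND ≥ 90 PSMs, both
inclusive, applied as one conjunction) keep only peptidoforms whose
error distribution can support a mixture fit.

**Mixture fitting.** For each robust peptidoform, univariate Gaussian
mixtures with k = 1, 2, 3 are fit by EM. Details the procedure fixes:

- k = 1 uses the closed-form MLE (sample mean, population-style sd); EM
  would converge to the same point, so no iteration is run.
- k ≥ 2: means initialised at k evenly spaced sample quantiles; 5
  restarts with means jittered by 0.5·sd of the data; convergence when
  the mean log-likelihood changes by < 1e-8; cap at 500 iterations
  (flagged, not fatal); variance floor 1e-8 Da² (sd floor 1e-4 Da)
  against point-mass collapse; log-likelihood is asserted nondecreasing
  at every iteration. Deterministic given the seed.
- Model selection: BIC = p·ln(n) − 2·lnL with p = 3k − 1 free
  parameters (k means, k variances, k − 1 weights). Selection is
  sequential — 2 replaces 1 only if BIC drops by ≥ 10, then 3 replaces
  the winner under the same rule — so the smallest adequate model wins.
  The ΔBIC ≥ 10 threshold is the conventional "very strong evidence"
  cut-off.

**Bins and assignment.** Nine contiguous half-open bins of width
0.005 Da partition [−0.0225, 0.0225): BOI3 [−0.0225, −0.0175), BOI2
[−0.0175, −0.0125), BOI1 [−0.0125, −0.0075) cover the sulfation shifts;
TRUEp1–3 cover (−0.0075, +0.0075); DECOY1–3 mirror the BOIs on the
positive side as shift controls. Half-open intervals make the bins a
true partition (the interval notation used in the field does not state
endpoint ownership). Bin AUC is the closed-form probability mass of the
fitted mixture over the bin (weighted normal CDF differences); the
denominator is the model's total mass (1.0), not the mass inside the
binned span — "total AUC for the model" reads most naturally as the
whole density, and the choice only matters for pathologically broad
fits. Assignment threshold: AUC ≥ 15%; multiple and empty assignments
are both legitimate outcomes.

**Calling.** Component classes: ss if |mean + 0.019032| ≤ 0.002, s if
|mean + 0.009516| ≤ 0.002, p if |mean| ≤ 0.004, else other. The
0.002 Da "centered near" tolerance is roughly the BOI half-width minus
typical fit jitter; it is configurable. The histogram type is the
slash-joined set of classes present, fixed order ss/s/p. Labels:
Convincing if any component is s or ss; otherwise Undetermined if a
component mean lies in (−0.006, −0.004) Da (these always sit between an
s and a p profile and are typed "s/p"); otherwise Not Convincing. The
ambiguous band is stated inconsistently across its sources (−0.06/−0.04
vs −0.006/−0.004); the pipeline adopts (−0.006, −0.004) Da — the only
reading compatible with the ±0.0225 Da bin span — and exposes it in the
configuration. A "widely distributed" sd gate is exposed (`wide_sd`) but
off by default, since no width criterion is quantified anywhere.
Deamidated peptidoforms are never candidates. Candidacy optionally
requires biological context beyond "No prior knowledge".

**Enrichment.** Foregrounds are deduplicated protein accession sets
behind bin-assigned peptidoforms; the background is every protein with a
fitted model. One-sided hypergeometric upper tails (scipy) with BH
adjustment *within each term category* (GO-BP/GO-CC/GO-MF/custom),
mirroring separate per-category analyses. BH-adjusted p doubles as the
q-value cutoff; minimum background set size 1 so the small known-sY term
survives. GMT term maps are consumed as-is; no ontology propagation.

**MS² assessment.** Theoretical b/y ions at charges 1..min(2, precursor
charge); square-bracket modifications shift every fragment containing
the site, curly-brace (Sulfo) modifications shift none (full neutral
loss) while the precursor retains the mass. No phospho neutral-loss
series is generated, since its −79.96 Da would mimic sulfate loss.
Matching takes the most intense peak within ±0.05 Th of each ion (ties:
smallest |Δm/z|); metrics are the annotated fraction of total ion
current (each peak counted once) and the fraction of inter-residue bonds
covered by ≥ 1 matched ion. Verdict: a hypothesis wins when it is ≥ the
other on both metrics and strictly better on at least one. Strictness on
both cannot be required: complementary b/y ions cover the same bond, so
on a near-complete spectrum sequence support ties at 1.0 under both
hypotheses while the TIC fraction still separates them. Alternative
interpretations rewrite one phosphorylation to a sulfation (preferring
Y[Phospho]→Y{Sulfo}; a phospho parked on a non-Y residue is removed and
the lowest-index free tyrosine sulfated — a seeded-random mode
reproduces random placement), and a second rewrite yields the
double-sulfation variant when ≥ 2 phosphorylations and ≥ 2 tyrosines
allow it. The %TIC denominator is all peaks; a noise floor is exposed
but defaults to 0.

## Synthetic data generator

The generator emulates the statistical structure of a large
multi-experiment phosphoproteome build with planted truth. Defaults
(the study conditions; one build = 200 peptidoforms):

| parameter | default | rationale |
| --- | --- | --- |
| PSM count / peptidoform | Uniform(90, 500) | spans the robustness threshold up to well-covered peptidoforms |
| per-run offset | Uniform(−0.01, 0.01) Da | severe but realistic per-file miscalibration |
| error sd σ | 0.002 Da | a well-calibrated Orbitrap (~1 ppm at 2000 Da) |
| runs / experiments | 40 / 8 | every peptidoform spread over ≥ 3 experiments |
| class proportions | p 0.60, s 0.08, ss 0.04, s/p 0.06, ss/s/p 0.03, deam_artifact 0.12, decoy_shift 0.07 | phosphorylation dominates; positive-shift artifacts outnumber sulfation (as observed in real builds, where DECOY bins are far fuller than BOIs); the near-balanced tails keep the per-run error median — and hence recalibration — essentially unbiased |
| q-fail fraction | 0.1 | a visible FDR-filter effect without dominating |
| acidic flank bias | 0.3 | raises foreground flank acidity to ~19–20% vs ~13% background, the contrast scale reported for real sulfation sites |
| annotation probabilities | known_sY 0.6 / Secreted 0.4 / Golgi 0.4 / Transmembrane 0.15 on sulfated proteins; 0.05 background | strong but imperfect annotation coverage |
| pT misassignment | 0.1 | occasionally parks the phospho on a T in a sulfated peptide, emulating search-engine site ambiguity |

Class mean shifts are mechanistic, not sampled: s = −δ, ss = −2δ
(δ = 0.009516 Da), p = 0, deamidation artifact = +1.003355 − 0.984016,
decoy_shift = +δ. Class counts are apportioned exactly
(largest-remainder), so a 10% class in a 100-peptidoform build yields
exactly 10 truth entries. Peptides are tryptic-like (K/R terminus, no
internal arginine), 7–30 residues, uniform composition; each peptidoform
gets its own synthetic protein with ±10-residue flanks, acidity-biased
within ±7 of planted sY sites. Synthetic spectra place b/y peaks under a
stated hypothesis (full neutral loss vs retained) with log-normal
intensities and a configurable fraction of uniform noise peaks.

**What it does not emulate** — and therefore what passing tests do not
show about real data: retention time, chimeric spectra and co-isolation,
isotope envelope errors beyond the +1 artifact, instrument-specific
noise and intensity models, peptides shared between proteins (one
peptidoform per protein by default), q-value/score correlation
structure, and site-localisation ambiguity beyond the simple pT
misassignment. Recovery rates on the synthetic build are upper bounds
on real-data performance, not estimates of it.

## Numerical and degenerate-input choices

- All-identical mass errors: one component at that value with floored
  variance.
- Empty bins in composition tables: fractions reported NA, never 0.
- Peptide sequences absent from the protein map: peptidoform retained
  with an empty accession set; such peptidoforms contribute no
  enrichment foreground.
- Impossible hypergeometric configurations (k > K): p = 0 with a
  warning rather than an exception, since they can only arise from
  inconsistent inputs.
- Flank windows are truncated (not padded) at protein termini; the
  central Y is excluded from composition counts (configurable), and
  sites are deduplicated by (accession, position) in both foreground and
  background — sites, not detections, carry the biology.

## Scale of the shipped analyses

The default build (200 peptidoforms, ~60k passing PSMs) was chosen as
the package's standard demonstration scale: large enough for every
planted class to have double-digit membership and for enrichment tests
to be decisive, small enough that the full pipeline fits in ~1.5 minutes
on one CPU. The acceptance script regenerates this build from its seed
argument at every run.

## Known limitations

- Only b/y ions at ≤ 2+ are modelled; a/c/z series and internal
  fragments are out of scope.
- The nonstrict peptidoform identity deliberately discards site
  localisation; distinct site isoforms pool together.
- BH-adjusted p-values stand in for Storey q-values wherever a q-value
  cutoff is configured; with few terms the difference is immaterial but
  the naming is kept honest in the code.
- GO term maps must be pre-propagated; the package performs no DAG
  traversal.
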