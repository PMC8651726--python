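# Methods

This note documents the models, statistical procedure, simulator design and
numerical choices behind `hdxdiff`, and what its synthetic benchmarks do and
do not demonstrate about real data.

## Exchange model and pH correction

Backbone amide exchange is modelled in the EX2 limit of Linderstrøm-Lang
kinetics: each residue `i` exchanges independently with observed rate
`k_obs,i = k_int,i / PF_i`, where `k_int,i` is the intrinsic (random-coil)
rate and `PF_i ≥ 1` the protection factor. Expected peptide uptake after
exposure `t` in a buffer with deuterium fraction `D` is

    uptake(t) = D · Σ_i (1 − exp(−k_obs,i · t))

summed over the peptide's exchangeable residues: all residues except
prolines (no backbone NH), the protein's first residue, and the peptide's
own N-terminal residue, whose amide loses label too quickly to measure.
This matches the amide-counting rule used for back exchange
(`N = length − prolines − 1`).

Intrinsic rates are treated as purely base-catalysed:
`k_int(pH) = k_int,ref · 10^(pH − pH_ref)`, valid roughly for pH 5–10
(a warning is raised outside). Sequence-context corrections of the
Bai–Englander type are deliberately omitted: every quantity the analysis
consumes is a rate *ratio* or a normalized uptake, and absolute intrinsic
rates cancel throughout. The same single-exponent law gives the cross-pH
time conversion `factor = 10^(pH₁ − pH₂)`, and the simulator is exactly
consistent with it: labelling for `t·factor` at the low pH equals labelling
for `t` at the high pH to floating-point precision (a property test
enforces < 1e-9 relative error).

Two conversion factors between pH 7.4 and 5.3 coexist on purpose. The
two-decimal meter readings 7.36/5.38 give `10^1.98 = 95.50`; the published
time maps for this buffer pair were produced with 96.38, which corresponds
to unrounded readings (ΔpH ≈ 1.984). The package computes the former from
supplied conditions and ships the latter as a preset
(`PH74_TO_PH53_FACTOR`); it never silently reconciles them. Duration
renderings round half-up to whole seconds, which reproduces the published
5 s–2 min conversions exactly; the published 5 min and 10 min renderings
differ from 96.38-based arithmetic by 1–2 s (consistent with a slightly
different unrounded factor) and are not reproduced.

The glass-electrode correction `pD = pH_read + 0.4·D_frac` scales the
standard +0.4 offset linearly with the deuterium fraction of the buffer.
Buffer readings more than 0.050 units from the aimed pH trigger QC
warnings, mirroring common buffer-acceptance practice.

## Significance procedure

One global confidence interval is derived per state pair, not per peptide:

1. per-(peptide, timepoint) sample SDs (ddof = 1) are collected from
   timepoints measured in at least 3 replicates — singleton timepoints
   contribute differences but no variance information;
2. within each state the SDs are averaged as a root mean square, the
   divisor being the number of pooled SDs (peptides × triplicated
   timepoints);
3. the two state SDs pool in quadrature, and the CI half-width is
   `t · SD_pool/√n` with `t` the two-tailed Student-t critical value at 98%
   confidence and `n − 1 = 2` degrees of freedom (6.965; computed via
   `scipy.stats.t.ppf` and cross-checked against the published constant in
   tests).

A difference `ΔD = mean(test) − mean(ref)` is significant when
`|ΔD| > CI`; negative ΔD is protection (the test state exchanges less).
Swapping the states negates every ΔD and leaves the significance set
unchanged. No multiple-testing correction is applied — the fixed 98% CI is
the procedure, and it is conservative: under the null (identical states,
Gaussian noise) the CI sits at ≈5.7 single-measurement SDs while the
difference of means scatters with ≈0.8–1.4 SDs, so empirical null coverage
is essentially 100%, comfortably above the 98% nominal level. The flip side
is limited sensitivity: a true shift equal to 5 single-measurement SDs is
*below* the threshold in expectation. The power property tested is
therefore stated against the pooled SD: a shift of 5×SD_pool is detected at
at least one affected timepoint in >99% of peptides. Users should read
non-significance accordingly.

Peptides observed in only one state are reported in a side list rather than
dropped — disappearance of a peptide in a bound state can itself indicate
strong association.

## Classification logic

Three pairwise comparisons (apo vs LUV−BMP, apo vs LUV+BMP, LUV−BMP vs
LUV+BMP, each first-listed state as reference) reduce per peptide to a
triple of directional calls in {protection, deprotection, none}. The
decision table is total over all 27 triples:

| apo vs −BMP | apo vs +BMP | −BMP vs +BMP | category |
|---|---|---|---|
| none | protection | significant (either) | bmp_specific |
| protection | protection | none | zwitterionic |
| protection | protection | protection | bmp_enhanced |
| none | deprotection | significant (either) | destabilized_by_bmp |
| anything else | | | none |

`bmp_enhanced` requires the direct −/+BMP comparison to confirm the deeper
protection; when that comparison is underpowered the call degrades to
`zwitterionic` (row 2), which is visible in the evidence triple attached to
every call. A second layer compares categories between untagged and tagged
constructs: effects present in both are `constitutive`, only in the tagged
form `tag_induced`, only in the untagged form `tag_abolished`.

Peptides significant at ≥ `min_timepoints` (default 1 — a deliberate,
permissive choice; raise it to demand reproducibility across exposures)
merge by interval union into maximal regions. A region's painting value is
the maximum |ΔRFU| (or |ΔD| when no control is available) over its peptides
and timepoints, recording the timepoint where the maximum occurred. Painting
propagates peptide calls to all covered residues — no sub-peptide
localization — except that a region fully nested inside a longer one
overrides it for its own residues, the localization a shorter peptide
legitimately provides. Partial overlaps with conflicting categories resolve
by priority (bmp_specific > bmp_enhanced > zwitterionic > others) with a
logged warning. Residues with no covering peptide are `no_data`, kept
distinct from "covered but unchanged".

## Synthetic data generator

The generator emulates the structure of vendor state-data exports: one row
per (peptide, state, exposure, replicate), plus maximally labelled control
tables. Defaults mirror the motivating study design: triplicates at a
designated subset of timepoints (the rest singletons), uniform back
exchange applied as a multiplicative factor `1 − BE`, and homoscedastic
Gaussian noise per measurement. The noise SD defaults to 0.05 Da — the
study reports no replicate noise magnitude, and 0.03–0.08 Da is the
replicate-SD range typical of peptide-level HDX-MS; the value is
configurable and not calibrated to any dataset. Peptide maps tile the
sequence with length jitter around a mean (default 12 residues, overlap 5),
absorbing terminal fragments shorter than the overlap; achieved coverage
below the target raises a warning rather than an error. Protein sequences
used in tests and demos are seeded-random stand-ins (5% proline), never
real sequences.

What passing tests show — and don't. The generator satisfies the analysis'
own assumptions exactly: independent-site EX2, homoscedastic noise, uniform
back exchange, no carryover, no peptide-level intensity effects,
no EX1 contribution to centroid uptake tables. Recovery of injected regions
at 5× effect-to-noise therefore demonstrates internal consistency of the
pipeline, not robustness to the correlated noise, heteroscedasticity,
variable back exchange or envelope distortions of real instruments.

## Envelope simulation and bimodality detection

Envelopes live on an integer-Da grid. The natural envelope comes from an
averagine-style elemental approximation (composition scaled to the
peptide's average mass from `pyteomics`; exact formulas are an extension
point that unit-mass grids would not resolve). Deuteration convolves the
natural envelope with the exact Poisson-binomial distribution of per-site
incorporation probabilities — centroid shift equals Σpᵢ to machine
precision, verified against exhaustive enumeration for N ≤ 10. Two-state
unfolding mixes folded and open envelopes with weights
`(e^{−k_open·t}, 1 − e^{−k_open·t})`; unfolding is irreversible, with no
refolding term.

Bimodality detection compares one- and two-component binomial mixtures
fitted by maximum likelihood under a Gaussian intensity-noise model (least
squares; the two-component optimum is located by EM on the intensity
weights). Two numerical choices matter:

- the single component fits **both n and p** (discrete search over n,
  moment-matched p), so one binomial can absorb the overdispersion that the
  natural envelope and Poisson-binomial heterogeneity add; without this,
  merely wide unimodal envelopes reward a spurious second component;
- fits are scored with a BIC-style criterion on residual sum of squares,
  with a noise floor of 1% of the base peak (typical MS intensity
  uncertainty) so noiseless synthetic envelopes do not produce unbounded
  score ratios.

Bimodality is declared when the two-component score improves by more than
`ic_margin` (default 60; calibrated so that, at 6 Da separation and 1%
noise, overdispersed unimodal envelopes score gains ≤ ~35 and genuine
mixtures ≥ ~95) **and** the component centroids separate by more than 1 Da.
At those conditions the detector achieves ≥95% true-positive and ≤5%
false-positive rates over 500 simulated envelopes (tested). In
pulse-labelling series the open-population fraction is the high-mass
component weight when bimodality is declared; otherwise it falls back to
centroid interpolation between the known endpoint envelopes (exact in
expectation, since the mixture centroid is linear in the weight). Opening
rates recovered from weight-vs-time fits land within 20% of truth at 1%
intensity noise.

## Determinism, degenerate inputs, limitations

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical config + seed reproduces
byte-identical tables, and the pipeline manifest records versions, seed and
applied correction factors. Degenerate inputs are handled explicitly:
empty sequences, zero exchangeable amides, non-positive exposure times and
unknown residues raise; negative uptake (noise) and RFU outside [0, 1.05]
warn without clipping; envelopes with fewer than 3 nonzero points report
unimodal with a warning.

Known limitations: no acid-catalysed or sequence-dependent intrinsic-rate
model (cross-pH conversion degrades below pH ~5); no temperature or
ionic-strength dependence; one global CI rather than per-peptide testing,
and no multiple-testing correction; RFU-based comparison is required when
experiments differ in deuterium fraction — raw-uptake comparison across
such designs is invalid and the package does not attempt it; no charge
states, ion mobility or fits to real spectra in the envelope module.
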