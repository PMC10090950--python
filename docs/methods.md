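# Methods

## Kinetic model

`trail` models the loss of unlabeled (light-nitrogen) signal during a
continuous ¹⁵N labeling time course as a first-order process.  Protein
synthesis is assumed zero-order at steady state, so the unlabeled
fraction of a protein pool decays exponentially with the observed
clearance rate `k_t`.  Because a fraction of the measured signal may
never label (e.g. slowly exchanging extracellular material contaminating
a dissected tissue), fits carry a constant plateau:

    y(t) = baseline + (1 − baseline) · exp(−k_t · t)

The clearance rate decomposes additively into proteolytic degradation
and dilution by cell division, `k_t = k_deg + k_div`; cell death is
assumed balanced by division at tissue steady state and is not modeled.
All times are in days and all rates in 1/day — the natural units of the
6-timepoint (0, 2, 4, 8, 16, 32 day) design the package targets.

Fitting uses a bounded trust-region nonlinear least-squares solver
(`scipy.optimize.curve_fit`, method `trf`) with `k ∈ (1e−6, 10]`/day and
`baseline ∈ [0, 0.95]`, initialized from a log-linear regression of the
baseline-subtracted signal.  The standard error of `k_t` comes from the
Jacobian-based covariance at the optimum with residual-variance scaling —
standard NLS practice.  The t-statistic is `k_t / se`, and the p-value is
the upper tail of a Student-t reference with `n − 2` degrees of freedom
(two fitted parameters), one-sided because the question is whether the
rate is meaningfully above zero.  Singular or non-convergent fits are
flagged (`converged=False`) rather than raised, so batch runs over
thousands of proteins complete.

Degenerate inputs: series with fewer than three distinct timepoints are
rejected; normalized values outside `[−0.1, 1.5]` (beyond plausible noise
overshoot) are rejected at the single-fit level and skipped with a
warning in batch runs.

## Proteome processing

Within each replicate, a protein is retained only if every channel of
that replicate carries at least 3 peptide spectral matches; replicates
missing a channel are dropped with a warning.  Signals are normalized by
the replicate's t=0 reporter value, after which all replicates are
pooled into a single kinetic curve per protein (not averaged per
replicate).  A fit passes quality control when it converged with
t-statistic > 3, pools ≥ 2 replicates, and carries ≥ 4 PSMs in total.
The replicate threshold defaults to 2 but is configurable — designs with
three replicates can demand all three.

Decile assignment ranks rates ascending (decile 1 = slowest 10%,
decile 10 = fastest) with near-equal decile sizes and stable-order tie
breaking, so any strictly monotone transform of the rates yields the
same assignment.

Relative abundance from unlabeled channels: per-channel column sums are
equalized within each biological replicate (the simplest defensible
reading of "channel normalization"), channels are combined by geometric
mean, intensities are divided by protein length in residues, each
replicate is rescaled by its maximum, and replicates are combined by a
final geometric mean.

## Division-rate estimation from DNA isotopologues

A newly replicated strand draws nucleotides from a precursor pool that
mixes fully and partially ¹⁵N-labeled species with recycled, fully
unlabeled nucleotides (fraction `r`).  The per-position precursor
distribution for a base with `N` nitrogen atoms (dA and dG 5, dC 3,
dT 2; the deoxyribose carries none) is `π(0) = r`,
`π(m) = (1 − r)·p_lab(m)` for `m ≥ 1`.  Observed normalized spectra are

    mono(m) = (1 − f_new)·δ₀ + f_new·π
    di(m)   = (1 − f_new)·δ₀ + f_new·(π ⊛ π)

where `f_new` is the new-strand fraction and the self-convolution
follows from adjacent nucleotides being incorporated together.  Only
homodimeric dinucleotides (dAdA, TT, dCdC, dGdG) are modeled, matching
the acquisition.

Natural-isotope correction deconvolves the binomial natural-¹⁵N envelope
(each light site independently heavy with probability 0.00364) by
solving the exact lower-triangular mixing system; negative artifacts
from noise are clamped and the spectrum renormalized.  ¹³C isotopes are
taken as resolved away by high-resolution acquisition and are ignored.

`p_lab` is read off the renormalized labeled mononucleoside peaks, then
`(r, f_new)` are estimated by least squares on the full dinucleotide
envelope.  Because the model is linear in `f_new`, the optimal `f_new`
for a given `r` has a closed form; the search is a dense scan over `r`
(step 0.01) followed by bounded scalar refinement, which recovers both
parameters to better than 0.01 at 1% bin noise.  `r` is estimated
independently per timepoint (precursor enrichment rises during
labeling); samples without labeled signal return `f_new = 0` with `r`
flagged unidentifiable.  Each (base, unit, timepoint, replicate)
observation contributes one new-strand fraction — from the mono labeled
fraction `L/(1 − r̂)` and from the di fit — and all enter a single
equally weighted exponential fit `f_new(t) = 1 − exp(−k_div·t)`.
Doubling time is `ln2 / k_div`.

## Cell-cycle correction and comparative statistics

`k_deg = k_t − k_div` per tissue.  Proteins with `k_t ≤ k_div` are
flagged division-dominated: their clearance is explained by dilution and
a corrected degradative half-life is undefined (NaN).

Dispersion is the index of dispersion, population variance (÷ n)
divided by the mean, per the verbal definition used in cross-tissue
work; a sample-variance variant is available by flag.  Note that
`dispersion(c·x) = c·dispersion(x)`: the statistic is invariant to
which protein is faster, not to an overall rescaling of rates.
Cross-tissue dispersion D is computed on `k_deg`; intracomplex
dispersion d on the within-tissue rates of complexes with ≥ 5 detected
subunits.  Complex coherence is assessed against a null of equally
sized uniform random proteome subsets (default 1,000 seeded draws) by a
one-sided Mann–Whitney test; a single observed complex falls back to an
empirical percentile.  Per-protein cross-tissue rate comparisons use a
Welch-type test on the fitted rates and their standard errors with
Welch–Satterthwaite degrees of freedom.  Subset-versus-proteome
comparisons use a two-sided Mann–Whitney of the subset against its
complement.  Complex median deciles are tested against the proteome
median decile (5.5) by a one-sample t-test.  Mann–Whitney tests use the
asymptotic method for speed and uniform behavior across sample sizes.

The goodness-of-fit p-value attached to each turnover fit is a quality
metric thresholded through the t-statistic gate, not a selection test at
a fixed level, and is therefore not part of the type-I-error calibration
suite; the four comparison tests above are all calibrated under
simulated nulls.

## Sequence features

GRAVY is the mean Kyte–Doolittle hydropathy.  Isoelectric point solves
the Henderson–Hasselbalch net-charge equation over the termini and the
D, E, C, Y, H, K, R side chains with the EMBOSS pKa set, by bisection to
pH-interval convergence (charge residual far below 1e−4); a different
pKa table would shift pI values in the second decimal.  The polar class
is {D, E, H, K, N, Q, R, S, T}, acidic {D, E}, basic {K, R, H}.
Intrinsically disordered regions are maximal runs of ≥ 40 residues with
disorder score strictly > 0.5; per-residue scores are an input (the
package does not implement a disorder predictor).  Non-canonical
residues (X, B, Z, U) are excluded from numerators and denominators
with a logged count.  Feature–rate association uses Spearman's
tie-corrected rank correlation, two-sided.

## Synthetic data

The generators emulate the study design, not raw spectra.  The proteome
generator draws per-protein rates log-normally (default median
0.2/day, log-SD 0.55, spanning half-lives of roughly 1–10 days — the
range covered by mammalian tissue proteomes), baselines uniform on
[0, 0.1], per-protein abundances log-normally, and applies
multiplicative log-normal reporter noise (signal-to-noise-based reporter
quantification has roughly constant CV).  PSM counts are Poisson (mean
10), so occasional low-coverage channels exercise the filters.  The
log-normal can describe either `k_deg` (with `k_t = k_deg + k_div`) or
the observed `k_t` directly; the latter permits truly
division-dominated proteins (`k_t ≤ k_div`) such as the long-lived
extracellular proteins of proliferative tissue.

The DNA generator forms `f_new(t) = 1 − exp(−k_div t)`, builds mono and
di spectra from `(r, p_lab)` as above, forward-convolves the
natural-abundance envelope, and adds multiplicative bin noise.  The
default labeled-species distribution concentrates on the fully labeled
species (0.70/0.22/0.08 on the top three shifts), reflecting a highly
enriched dietary precursor pool.  The multi-tissue generator draws
correlated per-tissue degradation rates with a configurable
cross-tissue log-spread and plants "coherent complexes" whose members
share a complex-level rate within each tissue.

What the generators do not emulate: peptide-level quantification and
isolation interference, chromatographic effects, heterodimeric
dinucleotides, missing-channel structure beyond dropout through PSM
draws, and any correlation between abundance and turnover.  Passing
closed-loop tests therefore demonstrates correctness of the estimation
chain under the stated model, not robustness to every artifact of real
acquisitions.

A caveat the test suite quantifies: t0 normalization divides every
channel by a noisy reference, which correlates errors within a replicate
and degrades the nominal coverage of `k̂ ± 3·se` from ~99% (independent
additive noise) to ~89% at 2% multiplicative noise on the full pipeline.
Standard errors from pooled fits should be read with this in mind.

## Problem sizes and determinism

The acceptance script simulates 1,000 proteins per tissue at 2% reporter
noise and DNA time courses with three samples per timepoint at 1% bin
noise — sizes chosen so the whole recomputation completes in about a
minute while leaving median estimates stable to a few percent.  All
randomness flows from explicit seeds (`numpy.random.default_rng`);
rerunning any generator, test, or script with the same seed reproduces
its output bit for bit.

## Known limitations

- Single-pool, steady-state kinetics only: no precursor lag, no
  multi-compartment models, no non-steady-state labeling.
- Bulk-tissue rates are abundance-weighted averages over cell types.
- The recycled fraction `r` is assumed shared across positions within a
  timepoint and estimated per timepoint; strong recycling combined with
  very low labeling is weakly identified.
- The dispersion statistic scales with the overall rate magnitude;
  comparisons across groups implicitly assume comparable mean rates.
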