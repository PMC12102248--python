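# Methods

## Sorption model and K_ads estimation

Co-precipitation experiments are modelled with a linear (Henry-type)
isotherm: the sorbed-P/sorbed-Fe molar ratio equals `K_ads · [P]_d`, with
`[P]_d` the dissolved concentration at equilibrium in µM and `K_ads` in
µM⁻¹.  No Langmuir saturation or surface-complexation term is included:
over the experimental range (0–28 µM P against 0.2 mM Fe) the data are
treated as linear, which is also what makes the rock-record inversion
well-posed.

Raw records hold aliquot concentrations as measured; the pH of each vessel
was held by NaOH/HCl additions, so aliquot values are multiplied by a
per-vessel dilution factor (≥ 1) to recover in-vessel concentrations before
mass balance.  Sorbed amounts are `initial − in-vessel final`.  A vessel
with no Fe precipitate (sorbed Fe ≤ 0) is an error, not a point.  Mildly
negative sorbed-P values arising from measurement noise are retained in
fits and flagged — dropping them would bias `K_ads` upward.

Fits are unweighted OLS (no weighting is justified by the replicate
structure), either free-intercept or forced through the origin
(`slope = Σxy/Σx²`).  Trend lines used for seawater estimation are
forced-origin; free-intercept fits are retained for displaying raw
phosphite data.  Replicates are fitted raw by default; a flag pre-averages
replicate points at the same dissolved concentration.  The standard error
of the slope uses the usual linear-regression formulas with `n−1` or `n−2`
degrees of freedom.

## Chromatographic quantification

Each species is quantified from a 3-minute trace: one minute of pre-peak
background, one minute containing the peak, one minute of post-peak
background.  The trace is smoothed by a frequency-domain low-pass filter
(real FFT, components above `1/(window_points·Δt)` zeroed, default window
5 points).  The original acquisition software's FFT filter has an
unpublished transfer function; only relative smoothing matters for area
stability, so a hard cutoff was chosen and is documented here as this
package's definition.  The baseline is the mean of the pre- and post-peak
windows (a robust median variant is available by flag; the baseline rule is
a package choice, as no rule is standard).  The area is the
baseline-subtracted sum over the peak window times Δt; negative computed
areas are floored at zero and flagged, with a small round-off tolerance
(10⁻⁹ of trace scale) so that an exactly flat trace is not flagged.

Calibration is OLS of area on concentration over ≥ 3 standards spanning
0.2–100 ppb.  Detection limits are configured per species (0.1 ppb for
hypophosphite, phosphite and phosphate; 0.2 ppb for pyrophosphate); values
below the limit are censored, reported as "< DL", and excluded from
extraction-yield sums.  Rock-basis conversion multiplies extract ppb by the
solid:solution ratio (default 10 mL/g, i.e. 1:10) over 1000.  Extraction
yield is the percentage of bulk total P recovered as the sum of uncensored
species; pyrophosphate counts one P equivalent by default (all inputs are
taken as ppm P), with a flag to count two when inputs are molecular.
Instrument drift is corrected by piecewise-linear interpolation of the
measured/expected factor of check standards over run order.

## Seawater reconstruction

The inversion is `[P]_d = (1/K_ads)·(P_ads/Fe_ads)` with the molar ratio
computed from rock analyses as `(p_ppm·10⁻⁶/30.974)/(fe_wt%·10⁻²/55.845)`.
Two uncertainty axes are bracketed by scenarios:

* **Extraction representativeness.**  `ratio`: bulk P is partitioned by the
  extract's species proportions, with pyrophosphate in the denominator (it
  is measured dissolved P) but not itself projected to seawater;
  hypophosphite is excluded by default (never observed above detection).
  `complete`: the leach recovered all rock phosphite, so the phosphite pool
  equals the extract value and the entire remainder of bulk P is treated as
  phosphate — this is the minimal-phosphite reading, and makes the
  complete-extraction phosphate pool slightly exceed the ratio-based one,
  as the published scenario tables show.
* **Metamorphic phosphite.**  Secondary phosphite produced during
  diagenesis/metamorphism is modelled as `yield × coexisting phosphate
  pool`, subtracted and floored at zero with an explicit flag.  Yields: 0
  (scenarios 1, 3); 0.00075 — the 0.075% experimental reduction yield at
  350 °C — (scenarios 2b, 4b); a second cited experimental yield (scenarios
  2a, 4a) is not printed in the source and is therefore a required config
  input with no default, so the default scenario set is {1, 2b, 3, 4b, 5}.
  Scenario 5 (all phosphite metamorphic) yields identically zero dissolved
  phosphite and is rendered "ENP" (estimation not possible).

The default coefficient pair is `K_ads(P(V)) = 0.026`,
`K_ads(P(III)) = 0.0005` µM⁻¹ — the pH 6.75 values in Si-bearing artificial
seawater, the pH considered representative of Archean seawater.  The exact
pair behind the published scenario tables is not printed as a pair; this
default is an explicit assumption and fully configurable.

Formation ranges are the (min, max) over per-sample estimates, not over
range endpoints of the input quantities, since extremes of different
quantities occur in different samples.  Rendering rounds to three decimals
in µM and prints `0.000*` for values below 0.5 nM, distinguishing floored
zeros from sub-precision values via the flag columns in the tidy output.

## Parsimony and rooting

Fitch small parsimony runs a post-order intersection/union pass with unit
change cost on the rooted, fully labelled tree; multifurcations — which
consensus trees can contain — are treated as soft, resolved arbitrarily
with zero-length branches and logged, so the reported count is that of the
chosen resolution (an upper bound on the best resolution's count).  A
root-state constraint is scored as an ancestral-state observation
attached at the root (equivalently: a zero-length pseudo-tip of that
state), so the constrained count exceeds the free count by exactly one when
the constrained state is outside the root's optimal set — this is the
quantity behind the one-switch (APO-first) vs two-switch (DPO-first)
comparison, and for a monophyletic DPO clade away from the root it
coincides with the hard fixed-root minimum.

MAD rooting evaluates, for every branch and the continuous root position on
it, the root-mean-square relative ancestor deviation `|2·d(anc,b)/d(b,c) −
1|` over all tip pairs, where the ancestor is the point on the b–c path
nearest the candidate root (the root itself for pairs spanning it, their
meeting node otherwise).  The position minimising the spanning-pair sum has
a closed form and is clamped to the branch; ties across branches go to the
first branch in preorder traversal and are logged.

## Synthetic data: what it emulates, and what it does not

* **Sorption series** follow the isotherm exactly, with multiplicative
  lognormal noise (unit median) on the sorbed ratio — concentrations are
  positive and ICP-MS error is relative, and the unit-median choice keeps
  the median fitted slope unbiased.  Default grid 0.5–28 µM (7 points),
  0.2 mM initial Fe, 99% of Fe sorbed, 5% relative noise, 3 replicates,
  dilution factors uniform in [1, 1.1].  Records are constructed backwards
  from the model, so the measurement chain inverts them exactly at zero
  noise.
* **Chromatograms** are Gaussian peaks (σ = 5 s default) over a linearly
  drifting baseline with white noise, amplitudes set so integrated area
  equals response factor × concentration; peaks closer than 6σ log a
  warning.
* **BIF tables** draw each quantity independently and uniformly within
  published per-formation ranges, resampling until extract phosphite is
  below extract phosphate (as observed in every measured sample) and
  raising bulk P to at least the extract sum.  Because the draws are
  independent, extreme combinations (high phosphite share with high total
  P) occur that real, correlated samples do not show; synthetic
  formation-level estimate ranges are therefore wider than ranges computed
  from the real per-sample data, and no published concentration range is
  asserted against synthetic tables.
* **Trees** use random sequential attachment with exponential branch
  lengths; the DPO clade is grown from a single anchor tip of an APO
  backbone, so monophyly — and, for intermediate clade sizes, a root
  outside the clade — holds by construction.

Consequently the passing tests demonstrate correctness of the inference
chain (exact inversion at zero noise, calibrated behaviour under the stated
noise models, agreement with independent oracles), not the empirical values
obtainable only from the deposited per-sample datasets; when those files
are supplied as CSVs the same pipeline computes the corresponding fitted
coefficients, concentration ranges and fractions from them.

## Numerical choices and limitations

* Singular fits (all x identical, free intercept) and inverted calibrations
  (slope ≤ 0) raise errors rather than returning NaN.
* The through-origin fit reports uncentred R².
* Problem sizes in tests and the acceptance script (21-point experiment
  series, 21-sample formation suite, 24-tip trees, 50-seed noise studies)
  were chosen to characterise the estimators well while keeping the full
  suite in the order of seconds.
* Out of scope: HFO precipitation kinetics and Fe speciation chemistry,
  deep-water (greenalite-precursor) settings, ocean circulation or
  source–sink fluxes, column chemistry of the ion chromatograph, and any
  tree inference — the rooted, labelled gene tree is an input.
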