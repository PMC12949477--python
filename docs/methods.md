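# Methods

This note documents the models behind `sfsim`, the parameter choices that
matter, and what the simulator does and does not capture about real
clinical data.

## The data model

Each eye carries two linked longitudinal measurements:

- a 24-2 visual field: 52 locations on a 6° grid (the two blind-spot
  locations at (15, ±3) are excluded), each with a sensitivity threshold
  in dB and a total deviation (TD = threshold − age-normal threshold);
- cpRNFL thickness in the six Garway-Heath-style sectors T, TS, NS, N,
  NI, TI, in microns.

Truth is defined at the final visit: measured values plus one accepted
linear progression rate per location (dB/y ≤ 0) and per sector (µm/y ≤ 0).
The nine earlier noise-free visits are built by **anti-progression**:
visit v takes value(v+1) − slope·Δt with Δt = 183/365.25 years. For TD,
a location that would rise above 0 dB is set to 0 and frozen for all
earlier visits, and a location already above 0 at the final visit is
frozen at that value — sensitivities do not become supra-normal going back
in time. Thresholds move in lockstep with TD via the per-location
normative offset frozen at the final visit (no aging across synthetic
visits, consistent with the aging reversal below). OCT sectors
anti-progress without a cap. Stable twins repeat the final visit ten
times with all rates set to zero; they are the specificity arm of any
benchmark.

The resulting true series is piecewise linear per channel: a fixed rate,
with floors. Mean summaries can therefore be nonlinear even though every
channel is linear.

## Ground-truth progression criteria

Given a clinical-like series (4–14 visual-field visits, ≥3 OCT visits),
the criteria decide which channels carry a genuine progression rate.

**Slope fitting.** Ordinary least squares on raw dB (so floor effects are
visible), with residual-based outlier removal for series of length ≥ 5:
points whose residual from the initial fit falls outside
median ± 1.5·IQR are dropped and the line refit. Removal is skipped below
5 points (removing from n=4 leaves nothing fittable). When the IQR
degenerates to 0, any point whose residual differs from the median is an
outlier, but never more than ⌊n/3⌋ points (most deviant first) so the
refit stays defined.

**Permutation slope test.** One-sided toward deterioration:
p = (1 + #{permuted slopes ≤ observed}) / (1 + #permutations), permuting
the (outlier-removed) values over their visit times. All n! orderings are
enumerated for n ≤ 7; otherwise 5000 seeded random permutations. Ties
count toward the numerator, so heavily quantised series are conservative.

**Visual field.** Fitted slopes get +0.1 dB/y added to reverse normal
aging, and the criteria act on the corrected slopes (the published rule
notes aging has been removed before its negativity check). Criterion 1:
corrected slope below the series-length cutoff
{4: −1.6, 5: −1.1, 6: −0.9, 7: −0.7, 8: −0.5, ≥9: −0.4} dB/y **and**
permutation p < 0.5. The permissive p-gate deliberately admits "event"
like collapses that a t-test would reject; the slope cutoffs do the work
of holding specificity near 99%. Criterion 2: corrected slope < 0,
p < 0.5, and at least one 8-connected neighbour that passed either
criterion — iterated to a fixed point so chains of weakly declining
locations bridging definite progression are captured. Accepted locations
keep their corrected slope (clamped ≤ 0); everything else gets rate 0.

**OCT.** A sector progresses iff its outlier-removed slope is below
−0.1 µm/y and either the two-sided regression t-test or the permutation
test rejects at 0.05. No aging correction (sector-level aging is ~0.2 µm/y
globally over 5 years, below the noise floor).

**Measured operating points** (recomputed by `scripts/acceptance.py`;
2000 Monte-Carlo series per condition, stable truth 30 dB, annual visits,
Reliable staircase noise): criterion-1 specificity ≈ 98% pooled over
lengths 4–10; sensitivity to a true −0.5 dB/y decline ≈ 7–11% at lengths
4–6 — slow progression in short series is deliberately excluded from the
truth rather than risk false rates. For the neighbour rule on fully
stable fields, the pair mechanism (a stable location falsely added next
to a false criterion-1 flag, probability ≈ P(false flag) × P(own p < 0.5)
≈ 0.01 × 0.5) yields ≈ 97% specificity. The *iterated* rule is weaker:
because P(negative slope and p < 0.5) ≈ 0.4 per stable location sits near
the site-percolation threshold of the 8-connected grid, a single false
flag can seed a chain of additions, and the chain-inclusive specificity
is ≈ 88–90%. Both figures are reported by the validation harness; users
deriving truth from noisy short series should treat criterion-2-only
locations with caution.

## Measurement-noise models

**Visual field.** Noise is not additive: every visit is re-measured by
simulating the Full Threshold 4–2 staircase at each location. The
responder sees a stimulus at x dB (higher = dimmer) with probability
fp + (1 − fp − fn)·(1 − Φ((x − t)/σ(t))), where the Henson-type spread
σ(t) = min(6, exp(−0.081·t + 3.27)) dB grows as sensitivity t falls. The
staircase steps 4 dB (dimmer after seen, brighter after not) until the
first response reversal, then 2 dB to a second reversal; the estimate is
the last seen level, clamped to the 0–40 dB instrument range (a run with
no seen response floors at 0). A single staircase is run per location
(the instrument's re-test when the estimate strays > 4 dB from the start
is omitted for simplicity). Starting values follow a growth pattern: the
four primary points (±9°, ±9°) start at their age-normal values, every
other location at the mean of its completed 8-neighbours — so errors
propagate spatially, as on the instrument. Measured behaviour at the
Reliable rates (fp 3%, fn 1%): test–retest SD ≈ 1.9 dB at 30 dB truth,
≈ 3.5 dB at 20 dB, ≈ 5 dB with a positive floor bias at 10 dB.

Four shipped conditions: Reliable (3%/1%), Unreliable (15%/3%), and
`_gve` variants that first pick one visit uniformly and add ±2 dB (equal
chance) to all 52 true thresholds of that visit — a session-level
general-height shift.

The age-normal surface is a smooth eccentricity-decreasing surrogate
(≈34 dB centrally to ≈31 dB at the edge, `normative_thresholds()`). It
only sets the staircase operating point and the threshold↔TD offset and
is replaceable by the user.

**OCT.** Independent Gaussian noise per sector and visit, SD from the
published sector table (first visit: 4.18/5.18/4.56/5.53/5.97/3.23 µm for
T/TS/NS/N/NI/TI; subsequent visits: 3.11/3.50/3.03/3.55/3.81/2.43),
clamped at 0 µm and rounded to integer microns. The two SD rows are read
literally as per-visit SDs; a nested within/between-visit random-effects
alternative would induce between-visit correlation this model does not
have.

**Randomness.** Every eye-visit draws from its own stream keyed by
(dataset seed, eye index, visit index), so eyes are reproducible
independently of iteration order. Seeds 1–8 are the canonical release
pairing (progressing: Reliable/Unreliable/Reliable_gve/Unreliable_gve =
1/2/3/4; stable twins 5/6/7/8); any seed below 103 triggers a
reserved-seed warning so user variants cannot collide with released
noise realisations.

## Synthetic seed population

The seed generator emulates the published marginal summaries of the
curated clinical population so every stage is testable without clinical
data:

- Final-visit mean deviation: ceiling − Gamma with mean −2.6 dB and SD
  4.0 dB (left-skewed, hard cap at +2 dB, matching the skewed clinical
  histogram). Undamaged locations have true TD exactly 0 (truth is
  deviation from normal); damage is a connected focal cluster (depths ~
  Gamma, mean ≈ 8 dB) plus a uniform diffuse component that lands the
  field mean exactly on target, clipped to the 0 dB threshold floor.
- Progressing locations per eye: round(N(20.8, 12.3)) clipped to [0, 52],
  grown as a connected cluster by neighbour accretion (the neighbour
  criterion presumes spatial clustering). Pointwise rates are exponential
  with mean 0.6 dB/y (left-skewed; bounded to [0.001, 6.6] dB/y). An
  alternative published summary puts the mean pointwise rate at 0.2 dB/y;
  `SeedConfig.vf_slope_mean` exposes it.
- Sector thicknesses: per-sector Gaussians with the published final-visit
  means/SDs, clipped to the published ranges and rounded to microns; a
  latent eye factor coupled to the MD draw (ρ = 0.5) gives the
  structure–function correlation real eyes show. Sector rates:
  min(0, N(published mean, SD)) per sector, so a realistic fraction of
  sectors is non-progressing.
- person.csv: one synthetic person per eye, sex ≈ 52% female, age at
  final visit ~ N(67.7, 11.5).

What this does **not** emulate: the joint spatial covariance of real
glaucomatous fields beyond single-cluster defects, correlation between
the location of field damage and which sectors thin (only the global
severity link is modelled), bilateral eyes, and any nonlinearity of true
progression (all truth is linear with floors). Tests passing on this
population therefore validate the machinery and its operating points,
not clinical realism of any individual field.

## PoPLR benchmarking

Per location, a one-sided (deterioration) p-value from the
regression-slope t statistic, truncated to [10⁻⁶, 1]; constant series get
p = 1; a perfectly monotone series gets the floor. The Fisher statistic
S = −Σ ln pᵢ is calibrated by permuting the visit order — the same
permutation across all locations, preserving spatial correlation — with
p = (1 + #{S_perm ≥ S_obs}) / (1 + n_perm); n_perm defaults to 1000 plus
the identity (exhaustive when n! ≤ n_perm). OCT uses the same machinery
over its 6 sector series. On stable staircase-measured bundles the PoPLR
p-value is verified super-uniform (never anti-conservative).

ROC curves sweep the PoPLR p cutoff over a progressing/stable bundle
pair; AUC by trapezoid. The partial AUC integrates over false-positive
rate ∈ [0, 0.1] and is reported as a percentage of its 0.1 maximum
(chance level 5%). The source table this mirrors captions its pAUC
"specificity ≤ 90%", but "percentage of 0.1" forces the FPR ≤ 0.1
(specificity ≥ 90%) reading, which is what is implemented. No McClish
correction.

## Numerical and design choices

- Right-eye orientation throughout; location order `vf.1..vf.52` is
  row-major, superior-left to inferior-right (`grid_table()` documents
  it). Neighbourhood is 8-connectivity on the 6° grid.
- Mean deviation is the unweighted mean of the 52 TD values (the derived
  data's summary), not the instrument's variance-weighted MD.
- Permutation tests permute the outlier-removed values (the alternative —
  permuting raw values — is not implemented).
- The criterion-1 cutoff indexes the *original* series length even when
  outlier removal shortens the fit.
- Problem sizes in the shipped tests and the acceptance script (2000
  Monte-Carlo series per length, 2000 stable fields, bundles of 12–250
  eyes, 150–1000 PoPLR permutations) were chosen to put Monte-Carlo error
  comfortably below the effect sizes being checked while keeping a full
  run in the minutes range on one CPU.

## Known limitations

- The staircase model omits the Full Threshold re-test pass and fixation
  -loss/short-term-fluctuation modelling; SITA-style Bayesian
  thresholding is out of scope (FT noise is similar by design).
- OCT noise has no between-visit correlation and no scan-quality model.
- The neighbour rule's chain behaviour (above) means criterion-2
  specificity on very noisy stable fields is materially below the pair
  bound; this is a property of the published rule itself, reproduced
  faithfully.
- Bit-compatibility with any released dataset's RNG stream is a
  non-goal; reproducibility is guaranteed only within this package.
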