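# Methods

## Model structure and assumptions

The model treats bud cold-hardiness (LT10, °C) as a single daily state
driven entirely by mean air temperature and photoperiod. Its distinctive
ingredient is the cold-stress memory

CSM_t = Σ_{n=onset}^{t} min(T_a,n − T_th,ac, 0) · w(t−n+1),
w(r) = k / ((log10 r)^c + k),

a thermal-time sum in which each past day's temperature deficit is
discounted by a forgetting curve of its age. Key assumptions:

* **Daily resolution.** Sub-daily temperature excursions are invisible;
  rapid (hours-scale) cold responses are outside the model.
* **Base-10 logarithm.** With the published cultivar parameters the weight
  retained 170 days back is 0.55–0.59, i.e. "about half", which is the
  behaviour the curve is meant to capture; a natural-log reading would
  collapse long-term memory to below 0.15 and was rejected.
* **Warm-day clipping.** Days at/above T_th,ac contribute exactly zero to
  CSM rather than a positive term; forgetting under warmth is carried
  entirely by the weight decay. The alternative unclipped reading is
  switchable (`clip_warm_days=False`) for comparison but is not the
  default.
* **Rank convention.** The current day has elapsed rank 1 (weight exactly
  1); the onset day carries the largest rank. Accumulation starts at the
  first autumn day *strictly* below T_th,ac; a day exactly at the
  threshold neither triggers onset nor contributes deficit.
* **One-way phase sequence.** pre-acclimation → acclimation →
  deacclimation within a season. The transition fires when CSM_{t−1} ≤
  CSM_de or the photoperiod condition holds (OR semantics; AND available
  via `transition_rule="and"`), and is permanent: spring reacclimation is
  represented inside the deacclimation phase through the CSM term of
  σT_de = CSM + GDD, never by re-entering acclimation.
* **Baseline cap.** LT10 never rises above LT10_ini (−2 °C), the hardiness
  of unacclimated buds; deacclimation increments are clipped at that
  ceiling. No lower bound is imposed — the slowdown factor S, not a hard
  floor, limits midwinter hardening.
* **Seasons are independent.** Multi-year series are split at 1 July
  (configurable); each season restarts from LT10_ini with empty memory.

On the transition day the previous σT_de is taken as CSM_{t−1} with
GDD = 0, so the first deacclimation increment reflects only that day's
change. GDD contributions below T_th,de are clipped at zero, making GDD
non-decreasing.

## Photoperiod

Day length is geometric sunrise-to-sunset duration (solar centre at zero
altitude; no refraction, twilight or elevation correction), computed from
the Spencer Fourier-series solar declination. That series is accurate to
about 0.2°, keeping day length within ~1 min of a full astronomical
calculation at the latitudes of interest — the simpler single-cosine
declination approximation can err by ~2° (≈10 min of day length at 31° N),
too coarse against critical day lengths that differ between cultivars by
only 7 min, and was therefore not used. The trigger requires the critical
day length to be met *while day length is increasing* (between winter and
summer solstice); without that guard the ~11 h threshold would also be
crossed in late October, starting deacclimation in autumn, which
contradicts the intended seasonality. Latitudes are restricted to ±66° so
sunrise/sunset exist year-round.

## Freezing-test scoring

Percent dead is the class-weighted bud fraction
P = (0·n0 + 0.25·n0.25 + 0.5·n0.5 + 1·n1)/n × 100; LT10 for a sampling
date is the most negative target temperature with P ≤ 10 % (inclusive
threshold, no interpolation between the 1 °C-spaced targets). Non-monotone
damage profiles — a deeper freeze scoring less damage, which sampling noise
can produce — still return the most negative qualifying temperature, with a
logged warning. Dates where every subsample exceeds the threshold raise a
censored-observation error; batch conversion skips them with a warning.

## Calibration

Nine parameters (all but LT10_ini) are fitted by differential evolution
(scipy's implementation, best/1/bin with immediate updating and L-BFGS-B
polish) minimising the RMSE between simulated and observed LT10 at the
observation dates (exact-date matching, no interpolation). Default bounds
are generous envelopes around both published cultivar sets: T_th,ac ∈ [5,
25] °C, H_ac/H_de ∈ [0.001, 0.2] °C °C⁻¹, k ∈ [1, 50], c ∈ [0.5, 6],
CSM_ac/CSM_de ∈ [−1500, −50] °C, T_th,de ∈ [−25, 15] °C, P_de ∈ [540, 780]
min. Any subset of parameters can instead be held fixed.

The forward model inside the objective is fully vectorised (CSM by
discrete convolution of the deficit series with the weight sequence; the
baseline cap via a running-maximum identity on the cumulative increments),
evaluating a five-season objective in about a millisecond; a literal
day-by-day recursion is kept in the test suite as the correctness oracle,
with agreement required to 1e−9.

The differential-evolution population is 15 per free parameter by default
(up to 300 generations). The package's acceptance-scale recovery
experiments use population 12 per parameter, ≤ 150 generations and
convergence tolerance 0.003, sizes at which refits on five synthetic
seasons reliably reach the ~0.3 °C observation-noise floor; smaller
populations (8 per parameter) occasionally stall in a local optimum about
0.35 °C above it.

2-fold cross-validation randomly halves the observations (seeded,
reproducible), calibrates on each half and validates on the other,
reporting per-fold RMSE and squared Pearson correlation. Observation-level
splitting follows the stated validation design; because it leaks
within-season autocorrelation between folds, season-level splitting is
offered as an option (`partition_by="season"`).

Identifiability caveat: CSM_de and P_de can each trigger the transition,
so they trade off when one trigger dominates the data; the simulation
result records the transition date so degenerate fits are visible.

## Sensitivity analysis

Each fitted parameter is perturbed by −5 % … +5 % in 1 % steps (ten
non-zero perturbations; 0 % is excluded as it gives 0/0) around the
supplied optimum, others held fixed, and
NSC = (ΔRMSE/RMSE_opt)/(ΔP/P_opt) is computed per step. Signed
coefficients are stored; the headline NSC_mean is the mean of absolute
values (magnitude ranking), with the signed mean reported alongside. A
parameter that cannot influence any observed day (e.g. T_th,de when all
observations precede the transition) has NSC_mean exactly 0. The analysis
requires RMSE_opt > 0 and raises otherwise.

## Synthetic data

The weather generator produces T(d) = mean + amplitude ·
cos(2π(doy − warmest_doy)/365.25) + AR(1) noise (stationary
initialisation) plus optional additive spells (overlaps sum). The
"kagoshima-like" preset — mean 16 °C, amplitude 9 °C, warmest day 218,
φ = 0.7, innovation SD 1.5 °C, latitude 31.37° N — yields winters whose
temperatures regularly cross both cultivars' acclimation thresholds and
memory depths comparable to the critical CSM values, so every phase of the
model is exercised. Observations are the simulated LT10 sampled every 7
days inside 1 November–30 April with homoscedastic Gaussian noise
(default SD 0.3 °C).

What the generator does **not** emulate: skewed/heteroscedastic
measurement error, within-week observation clustering, multi-day weather
regimes beyond AR(1) persistence, elevation or cold-air-drainage effects,
and minimum (as opposed to mean) temperatures. Passing the recovery tests
therefore shows the estimation machinery is sound under the model's own
assumptions, not that the model generalises to any real site.

## Problem sizes used in the test suite

Simulator-vs-oracle equivalence uses 50 random 200-day series (both
cultivar parameter sets); memory-oracle equivalence uses 200 random
120-day series. The parameter-recovery experiment uses 5 synthetic seasons
(~130 weekly observations), 0.3 °C noise and 10 independent
noise/optimiser seeds, requiring the refit trajectory to match the
noise-free truth within 0.5 °C RMSE over the daily November–April window
in at least 8 of 10 replicates; in the shipped configuration all 10
replicates pass with trajectory RMSEs of 0.05–0.11 °C.

## Known limitations

* Daily mean temperature only; no sub-daily memory, no frost-event
  modelling against minimum temperatures (beyond comparing LT10 with any
  series the user supplies).
* Parameters are cultivar- and site-specific; CSM_de in particular likely
  varies with cold-stress climate and should be refit for new fields.
* The photoperiod increasing-branch guard is a modelling choice the
  seasonality argument forces but that the transition rule itself does not
  state; it only matters for autumn threshold crossings.
* The CSM formulation is empirical: the forgetting curve imitates, rather
  than mechanistically represents, the molecular machinery of stress
  memory.
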