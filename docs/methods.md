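# Methods

`doapred` predicts the bispectral index (BIS, a 0–100 processed-EEG depth-of-
anesthesia score) of a patient under propofol/remifentanil total intravenous
anesthesia, from the drug infusion history alone. Two difficulties shape the
design: the statistics of anesthesia time series change across the case
(induction, maintenance, recovery — *temporal covariate shift*), and patients
with different physiology respond differently to the same doses (cross-patient
distribution shift). The package counters the first with temporal distribution
characterization and matching (an AdaRNN-style recurrent regularizer) and the
second with feature-based knowledge distillation from a teacher network that
additionally observes the recent BIS itself.

## Data model and preprocessing

The unit of input is a per-case 1-Hz record of cumulative propofol (mg),
cumulative remifentanil (µg) and BIS, plus static covariates (age, sex,
height, weight), in a CSV dialect mirroring infusion-pump track exports
(missing samples are empty cells). Cleaning applies, in order:

1. **Eligibility.** A case is discarded when (a) the BIS at the start of drug
   infusion is below 80 (the patient was not awake), (b) any channel is
   missing for more than 300 s inside the span from infusion start to the end
   of the BIS measurement, or (c) the first recorded BIS occurs when the
   cumulative infused dose is already nonzero. The filter reports the first
   violated rule as a reason code.
2. **Linear interpolation** of the remaining missing values (boundary gaps are
   an error, not silently extrapolated).
3. **Monotone repair** of cumulative-dose channels: a sample lower than its
   predecessor is replaced by the mean of its two neighbours; the pass
   iterates to a fixed point because one repair can expose another decrease.
4. **LOWESS smoothing** of the BIS with `frac = 0.03` — *training cases only*;
   validation and test BIS stay raw.
5. **10-s resampling**: infusion pumps update their cumulative record every
   10 s, so one sample per 10 s is kept. The dynamic feature is the
   *incremental* dose per 10-s bin (difference of the cumulative channel);
   increments are nonnegative after repair and sum exactly to the infused
   total. We read "cumulative usage over 10 s" as this increment rather than
   the running total, which would be unbounded and confounded with case
   length.
6. **Windowing**: sliding windows of 120 bins (20 min) at stride 1. The
   target is the BIS at the window's final bin. The teacher receives a third
   channel, the BIS of the *previous* bin at every step, so the first
   admissible window starts at bin 1 and a case of N bins yields N − 120
   windows.

Dose increments, statics and BIS targets are z-scored with statistics fitted
on the training split only; the previous-BIS channel shares the target's
scaling.

## Temporal distribution characterization (TDC)

Training data are split along normalized case time into K maximally
*dissimilar* periods: maximize `(1/K) Σ_{i≠j} d(D_i, D_j)` over segmentations
whose period lengths lie in `[Δ1, Δ2]`, where a period's summary is the mean
feature vector of the windows whose end falls in it (window features: mean and
final dose increments of both drugs) and `d` is cosine distance. Training
against the most-dissimilar periods prepares the model for the worst
distribution shift the data contain. Boundaries live on a candidate grid of
tenths of the timeline; the greedy solver inserts one boundary at a time
(lowest-index tie-break, deterministic), and an exhaustive solver over the
same grid serves as the test oracle. Greedy optimality is not guaranteed in
general; on two-regime series it attains the exhaustive optimum in ≳90 % of
instances and in our studies never fell below the grid-aligned equal split.
Defaults: K = 5, Δ1 = 1/10, Δ2 = 1, ten candidate chunks.

Because training pools many cases, the segmented axis is *relative* position
within each case's span of admissible window ends, aligning periods with
anesthesia phases — the shift this component targets — rather than absolute
clock time.

## Networks

Teacher and student share one architecture: a GRU over the 120-step window, a
two-layer fully connected bottleneck (ReLU) that consumes the final hidden
state concatenated with the four static covariates, and a linear scalar head.
The only difference is the input width — the teacher's extra previous-BIS
channel. Library defaults are GRU width 64 and bottleneck 64→32; the bundled
experiments use width 32, sized so a 5-seed comparison runs on one desktop
CPU core in minutes. Widths are configuration, never hard-coded.

The networks are built on a small reverse-mode autodiff engine written for
this package (`doapred.autodiff`): numpy arrays on a define-by-run tape, with
the GRU recurrence fused into a single tape node whose hand-written
backpropagation-through-time backward is JIT-compiled with numba (a pure
numpy fallback keeps parity; both are gradient-checked against central finite
differences).

## Losses

With periods fixed by TDC, each training batch is stratified so every period
is represented proportionally. Per batch:

* **Prediction loss** `L_pred`: mean over periods of the period's MSE on the
  normalized target scale, so sparse periods count equally.
* **TDM regularizer**: for each unordered period pair (i, j),
  `L_tdm(i,j) = Σ_t α_t · d(h̄_i^t, h̄_j^t)` where `h̄^t` is the period's
  batch-mean hidden state at step t and `d` is cosine distance (the same
  metric as TDC; the choice is shared deliberately). The importance vector α
  lies on the V-simplex. The combined objective is
  `L = L_pred + λ · mean_{i<j} L_tdm(i,j)` with λ = 0.05. The printed
  normalization of the pairwise sum is ambiguous up to a constant absorbed in
  λ; we use the mean over unordered pairs.
* **Importance evaluation**: α starts uniform (1/V). In the default *neural*
  mode a per-pair linear evaluator reads the concatenated period summaries
  and emits softmax weights; it is trained adversarially (gradient ascent on
  the weighted distance) while the network descends, so α concentrates on the
  worst-matched states — the same direction the alternative *boosting* rule
  takes, which multiplicatively boosts states whose distance grew between
  epochs and renormalizes. The boosting mode ships for ablation comparisons.
  The evaluator's inputs are detached so the network's own gradient flows
  only through the distance term.
* **Distillation** (student only): `L_g`, the squared Euclidean distance
  between teacher and student per-step hidden states (averaged over windows
  and steps), and `L_b`, the same for bottleneck features (averaged over
  windows). `‖·‖²` is read as the squared norm, for smooth gradients; the
  averaging convention only rescales the (unit) weights. Teacher features are
  detached by default, so distillation shapes the student alone and the
  teacher keeps its own objective: teacher minimizes `L_pred + λ·TDM`,
  student minimizes `L_pred + λ·TDM + L_g + L_b`.

## Optimization

Both networks are updated simultaneously from the same batch by separate Adam
optimizers: initial learning rate 0.005, decayed ×0.1 every 10 epochs, batch
256 for training and 128 for evaluation, 30 epochs. Gradient explosion is
prevented by global gradient-norm clipping, the reading we take of "weight
clipping"; literal weight-value clipping is available behind a flag. The
default threshold (10.0) sits well above the typical per-step gradient norms
(2–4 at these loss scales), so clipping engages only on genuine spikes — a
threshold below the typical norm would silently rescale every step and,
because the student's extra loss terms enlarge its gradient, would rescale
the full model differently from its ablations. All randomness (patient sampling, corruption, splits, initialization,
batch order) derives from one root seed through named substreams; runs are
bitwise reproducible, and the pipeline manifest records SHA-256 digests of
every artifact so reproducibility is checkable byte for byte (checkpoints use
a timestamp-free container for this reason).

## Synthetic cohort

No public data ship with the package; a simulator generates cohorts with the
statistical structure the method assumes. Drug disposition is a standard
three-compartment mammillary model with an effect-site compartment, advanced
by the exact zero-order-hold discretization (matrix exponential of the
augmented linear system, including eliminated mass) at 1-s steps — chosen
over explicit stepping because it is exact to machine precision, which makes
mass balance and the one-compartment closed form testable at 1e-6 rather than
at an integrator-dependent tolerance. Effect is a sigmoid-Emax surface on the
potency-normalized combined effect-site concentration
`U = Ce_p/EC50_p + Ce_r/EC50_r`:

    BIS = E0 − Emax · U^γ / (1 + U^γ)

Population constants are arbitrary fixture values in plausible ranges, not
clinical parameter sets (no Schnider/Minto covariate models). Cross-patient
shift enters as deterministic age trends on EC50s and propofol ke0 (defaults:
−0.015 µg/mL, −0.06 ng/mL and −0.003 min⁻¹ per year around age 50) times
unit-mean lognormal inter-individual variability (σ = 0.12), so a declared
trend is recoverable by regression — the generator's shift is the knob the
acceptance studies turn. Each case runs three phases: a long awake baseline
(so every prediction window has a fully recorded history and predictions span
all phases), a 2 mg/kg induction bolus, a jittered maintenance infusion, and
recovery after the propofol stop a few minutes before the record ends.
Recording defects are planted on demand — Gaussian BIS noise, missing
stretches, non-monotone cumulative-dose glitches, a depressed starting BIS, a
delayed first BIS sample — and each planted defect travels with the case as
ground-truth metadata, so preprocessing tests are exact rather than
statistical.

What the simulator does *not* emulate: surgical stimulation and artifacts,
signal-quality dropouts, drug interactions beyond the single Emax surface,
pump latency, or non-stationary measurement noise. Passing tests therefore
demonstrate that the implementation realizes the method and that the method
behaves as claimed *under its own assumptions*; they are not evidence about
clinical data.

## Evaluation

Performance error per prediction is `PE = 100·(measured − predicted) /
predicted` (the reference is the prediction, exactly as defined for
computer-controlled infusion pumps); per case we report MDPE (median PE,
signed bias), MDAPE (median |PE|, inaccuracy), RMSE and MAE, each for the
whole case and per phase: induction is the 10 min from propofol start,
recovery runs from propofol stop to the end, maintenance is the remainder
(induction is truncated, with a warning, if the stop comes first). Cohort
tables give across-case mean ± sample SD (ddof 1; a single case reports SD 0
with a flag). Even-length medians are the mean of the central pair.
Evaluation always uses unsmoothed BIS.

## Bundled experiments and problem sizes

`doapred.experiments` drives the desk-scale studies: cohorts of 40 patients
(20/10/10 case split), 2 400-s cases, GRU width 32, 30 epochs, five seeds.
One seed of the full-vs-ablation comparison takes roughly two minutes on one
CPU core. The comparison trains (i) the full model — TDM with neural
importance plus both distillation terms — and (ii) a plain dose-only GRU
student (no TDM, no KD), then evaluates per-case RMSE on the held-out test
cases. Reported outcomes: training-loss decrease for every seed, the median
teacher-vs-student ordering (the teacher sees the previous-bin BIS and wins
by a wide margin), and the full-vs-ablation ordering. The last comparison
is the fragile one at this scale: in our runs the full model improves the
paired per-cohort RMSE on a majority of cohorts, but the improvement is
smaller than cohort-to-cohort variation, so a comparison of per-arm medians
over five seeds can go either way. Two mechanisms limit the benefit at desk
scale: with only twenty training patients the student overfits, and the
distillation signal is misleading in the first epochs (the teacher is
itself untrained) while the steep learning-rate decay leaves few
high-learning-rate steps to recover — a transient that vanishes at
hundreds-of-patients scale, where epochs contain orders of magnitude more
optimizer steps.

## Known limitations

* The greedy segmentation solver is heuristic; only grid-restricted
  optimality is checked, and only empirically.
* The neural importance evaluator is linear per pair; richer evaluators fit
  behind the same interface but are untested.
* The simulator's fixture constants are not clinically validated; absolute
  RMSE values on synthetic cohorts do not transfer to patient data.
* Case records must be regular 1-Hz grids; irregular sampling is out of
  scope.
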