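# Methods

## Setting and notation

Families of RNA-seq experiments arrive sequentially. Family t yields a
gene-p-value matrix: Nₜ per-gene p-values **P**ₜ = {P_{t,1}, …, P_{t,Nₜ}}
from a two-group differential expression analysis. Decisions on batch t
are final once made. Writing V₍s₎ and R₍s₎ for the false and total
rejections in batch s, the target of control is the global FDR

FDR(t) = 𝔼[FDP(t)] = 𝔼[ Σ_{s≤t} V₍s₎ / max(Σ_{s≤t} R₍s₎, 1) ],

required to stay ≤ α at every time t.

## Offline procedures

**BH.** Order p₍₁₎ ≤ … ≤ p₍N₎, take the maximal i\* with
p₍ᵢ\*₎ ≤ i\*α/N (i\* = 0 if none) and reject every hypothesis with
pⱼ ≤ p₍ᵢ\*₎. Ties are rejected or retained together, so the decision set
never depends on sort stability, and |{pⱼ ≤ p₍ᵢ\*₎}| = i\* exactly.

**Storey-BH.** π̂₀ = min{1, (1 + #{pᵢ > λ}) / (N(1−λ))} with λ ∈ (0,1)
(default 0.5), then BH with per-rank thresholds iα/(Nπ̂₀). The raw
estimator can exceed 1; it is clamped because a null proportion above one
is meaningless and would only make the procedure more conservative than
BH. When π̂₀ = 1 the adaptive procedure is bitwise identical to BH.

**Validation.** p-values must be finite and in [0,1]; 0 and 1 are legal,
NaN or out-of-range values raise. Silently dropping bad values would
change N and therefore every threshold, which is why validation is a hard
error.

**R⁺.** Rₛ⁺ is the maximum rejection count of batch s when one p-value is
set to zero, the maximum over the choice of replaced p-value, rerunning
the full procedure (for Storey-BH including the π̂₀ recomputation, since
the replacement changes #{p > λ}). The implementation replaces the single
largest p-value and reruns once: the post-replacement multiset
{0} ∪ P∖{pⱼ} has every order statistic weakly smallest when pⱼ is the
maximum, which weakly maximises any step-up rejection count, and for
Storey-BH the same choice maximally reduces #{p > λ} and hence π̂₀, so
both effects point the same way. The literal N-rerun definition is kept
behind `exhaustive=True` and the two paths are asserted equal on random
vectors in the test suite. Rₛ⁺ ≥ max(Rₛ, 1) always (for α > 0 the planted
zero is itself rejected).

## Online batch procedures

All three procedures start at α₁ = γ₁α for a non-negative sequence {γₛ}
with Σγₛ = 1. The built-in default is the power law γ(s) = s^(−2)/ζ(2) =
(6/π²)s^(−2), chosen for its closed-form normaliser; any exponent > 1 or
an explicit weight list is accepted, and the choice is recorded in the
serialized state so runs are reproducible.

**onlineBH** updates

α_{t+1} = [ Σ_{s≤t+1} γₛα − Σ_{s≤t} αₛRₛ⁺ / (Rₛ⁺ + Σ_{r≤t, r≠s} Rᵣ) ]
· (N_{t+1} + Σ_{s≤t} Rₛ) / N_{t+1}.

The bracket is the remaining alpha-wealth: the budget released through
time t+1 minus what each past batch "spent", where a batch's spend shrinks
as other batches accumulate rejections (the denominator is recomputed at
the current time with all Rᵣ up to t). The trailing factor converts pooled
wealth into a per-batch test level, inflated by past discoveries. Two
consequences pin the algebra down and are asserted in tests: with zero
rejections everywhere (Rₛ = 0, Rₛ⁺ = 1) the update telescopes to
αₜ = γₜα exactly, and the cumulative spend never exceeds the released
budget Σ_{s≤t} γₛα (to 10⁻¹²).

**onlineStBH** runs Storey-BH per batch and discounts each spent term by
an adaptive constant kₛ ∈ (0,1]. The exact constant is a pluggable
function; the default is the batch's own Storey π̂₀ at the configured λ —
a natural discount (a batch estimated to be mostly signal spends less),
stored per batch in the ledger so the accounting is fully replayable. Any
alternative definition can be swapped in via `process_batch(k_fn=...)`
without touching recorded history.

**onlinePRDS** needs no R⁺:
α_{t+1} = α·γ_{t+1}·(N_{t+1} + Σ_{s≤t} Rₛ)/N_{t+1}. It retains FDR
control when p-values within a batch are positively dependent (PRDS) yet
independent across batches, and is noticeably more conservative.

Levels are clamped to [0,1]; a depleted wealth yields αₜ = 0 — the batch
is still processed (nothing can be rejected) rather than erroring, keeping
the ledger contiguous.

**State.** The ledger (method, α, γ spec, λ, per-batch records s, Nₛ, αₛ,
Rₛ, Rₛ⁺, kₛ, π̂₀ₛ) is append-only and serialized as versioned JSON with
full-precision floats; round-trips are bit-exact and a configuration
mismatch on reload is an error, never a silent merge. File replacement is
write-temp-then-rename, so a killed process cannot corrupt the state.

## Count simulator

Each batch draws, per gene i: a relative abundance aᵢ from a log-normal
(sdlog 1.5) renormalised to sum to one within the batch, and a dispersion
φᵢ from log-normal(log 0.1, 0.7). A fraction π of genes is flagged DE,
a proportion `prop_up` (default 0.5) up-regulated; group-2 means are
multiplied by the effect size f (default 1.5) for up genes and divided by
f for down genes (symmetric on the log scale). Per sample j the depth is
dⱼ = D·Uniform(0.9, 1.1) with D = 10⁷, and counts follow a negative
binomial with mean m_ij = aᵢdⱼ·fold_ij and variance m_ij + φᵢm_ij²
(so the NB shape parameter is 1/φᵢ — the size/dispersion convention is
fixed here to avoid the reciprocal ambiguity). Defaults are a 5 vs 5
two-group design with 10,000 genes per batch.

Reference simulators of this kind resample (μ, φ) pairs estimated from
real datasets; shipping those is not possible here, so the log-normal
stand-ins above are an *emulation* of that design, not a reproduction.
Two consequences: the marginal abundance distribution is unimodally
log-normal rather than empirical (after renormalisation the median
expected count is (D/N)·exp(−sdlog²/2) ≈ 325 rather than D/N = 1,000),
and any mild (μ, φ) dependence present in real data is absent, so the
simulated batches are exactly independent. Passing tests therefore
demonstrate the procedures' behaviour under clean NB sampling with
independent batches — not robustness to real-data artefacts such as
outliers, batch effects or correlated genes.

Seeding: every (master_seed, batch, replicate) triple is hashed through
`numpy.random.SeedSequence` into an independent 31-bit stream, so batches
and replicate runs are reproducible independently and in any order.

## DE engines

The published workflow this stands in for is voom/limma; full parity is
out of scope, and two engines are provided.

* **welch** — per-gene Welch t-test on log-CPM values
  y = log₂((c + 0.5)/(L + 1)·10⁶), Satterthwaite df.
* **voom_lite** — group-mean fit on log-CPM; lowess trend (span 0.5,
  3 robustness iterations) of √sd against average log-count; per-
  observation precision weights = predicted⁻⁴ (clipped to [10⁻⁶, 10⁶]),
  evaluated at each observation's fitted log-count; weighted group-
  difference t-statistic with empirical-Bayes variance moderation:
  the prior (d₀, s₀²) is estimated by moment matching on log s² via
  digamma/trigamma inversion, posterior variances
  (d₀s₀² + df·s²)/(d₀ + df), moderated df = d₀ + df. When the between-
  gene spread of log s² does not exceed the χ² sampling wobble the prior
  df is reported as ∞ and all variances shrink to the common value.

Genes with zero within-group variability on the log-CPM scale get p = 1
and a `degenerate` flag rather than NaN — keeping Nₜ fixed matters for
the online ledger. Both engines are calibrated under the simulator's
null (fraction of p < 0.05 within 0.04–0.06; KS statistic < 0.05 on
10⁴ null genes). No low-count pre-filtering is applied in simulation, so
Nₜ equals the configured gene count; a mean-count filter
(`mean_count_filter`) is available for real-data tables.

The FDR-control results are bounds that hold for any valid p-value engine
under the null, which insulates the study-level conclusions from this
substitution; power figures, by contrast, are engine-dependent and should
be read as relative comparisons between procedures, not as voom/limma
reproductions.

## Simulation studies

The unordered study simulates `n_batches` independent families at a
constant π, computes p-values once per batch, and feeds the identical
stream to every procedure (offline procedures at level α per batch;
online procedures through the state machine). Per run the final
cumulative FDP and two power summaries are recorded:

* `power_standard` = TP / #truly-DE — conventional power (headline);
* `power_as_printed` = TP / max(#declared-DE, 1) — the true-discovery
  proportion, exposed separately because some studies print this
  quantity under the name power; neither is silently substituted for the
  other.

"Empirical FDR" is the mean over replicate runs of the *final-time*
global FDP, consistent with evaluating FDR(t) at the last batch;
per-time FDP trajectories are available on `RunMetrics` for plotting.

The ordered study replaces the constant π with a two-block schedule —
high-π "super" matrices tested before low-π "regular" matrices. The five
built-in 50-batch designs are (count @ π): (10 @ 0.3, 40 @ 0.05),
(10 @ 0.3, 40 @ 0.175), (10 @ 0.5, 40 @ 0.25), (10 @ 0.5, 40 @ 0.375),
(10 @ 0.5, 40 @ 0.5), giving overall π of 0.1–0.5; the overall-π identity
is validated to 10⁻¹² at construction. For other batch counts the 1:4
super:regular ratio can be re-solved via `make_ordered_schedule`.

**Problem sizes.** The package's default study scale is 20 batches ×
2,000 genes × 100 replicate runs with the welch engine — chosen so a full
comparison runs in minutes on a laptop while leaving Monte-Carlo SEs
small relative to α. The full-scale design (50 × 10,000 × 1,000,
voom-style engine) is a configuration change, not different code.

## Numerical choices and edge cases

* Step-up scans are vectorised sorts; ties share the fate of p₍ᵢ\*₎.
* Trigamma inversion: Newton iteration from x₀ = 0.5 + 1/y, 50-iteration
  cap, relative tolerance 10⁻¹⁰; y ≤ 0 maps to d₀ = ∞.
* Lowess predictions are linearly interpolated between fitted points and
  flat-extrapolated beyond the fitted range.
* `compute_fdp` guards the empty-rejection case with max(ΣR, 1).
* Custom gamma weights may sum to < 1 (the remainder is simply never
  released); a sum exceeding 1 + 10⁻¹² is rejected.

## Known limitations

* The voom_lite engine approximates, but does not reproduce, voom/limma
  (no contrast matrices, single two-group design, lowess rather than
  limma's exact trend machinery).
* The simulator does not model outliers, gene-length effects, batch
  effects across families, single-cell zero inflation, or empirical
  (μ, φ) dependence.
* The kₛ constant in onlineStBH is a documented default, deliberately
  pluggable; with aggressive orderings and high π the procedure can spend
  greedily (its FDR inflation in that regime is expected behaviour, not a
  bug).
* Real-data ingestion is limited to generic gene-p-value tables plus the
  unique-gene overlap filter; ortholog mapping and enrichment analyses
  are out of scope.
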