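# Methods

This note records the models, statistical procedures, numerical
choices and known limitations behind `codakit`.

## Data model and conventions

A coda is an ordered vector of strictly positive inter-click intervals
(ICIs), in seconds; a k-click coda has k−1 ICIs and duration
D = Σ tᵢ.  Ordered (exchange-style) datasets carry a speaker id and the
onset time of the first click for every coda and are sorted by onset.
I/O accepts 2-click codas with a warning; analysis operations treat
3 clicks as the minimum and, following standard practice, exclude rare
codas with more than 10 clicks.  Rejected rows are always logged with
their reason, never silently dropped, so sample sizes are auditable.

Segmentation constants: a single whale's **call sequence** joins
consecutive codas no more than 8 s apart (twice the ~4 s response
period); the gap is measured onset-to-onset by default
(termination-to-onset is available) because the 8 s figure derives from
response-time periodicity, which is an onset process.  A later coda is
**overlapping** when its onset falls strictly inside the earlier coda,
and **adjacent** (turn-taking) when its onset falls within 2 s after
the earlier coda's termination; both boundaries are closed (onset
exactly at termination → adjacent with gap 0; gap exactly 2 s →
adjacent).  **Choruses** are connected components of the cross-whale
link graph (adjacent or overlapping links between different whales
only); within each linked pair the earlier-onset whale leads, pairs
with onsets within 1 ms are excluded from role assignment, and a
whale's chorus role is its majority pairwise role.

## Discrete typing

**Tempo.**  Durations are modelled by Gaussian-kernel density
estimation on a 2048-point grid spanning [0, max + 3·bandwidth].
Modes (tempo types) are the local maxima and class boundaries the
interleaving minima; a duration exactly on a boundary goes to the lower
class.  Bandwidth defaults to Silverman's rule with an explicit
override, and the CLI exposes a bandwidth sweep because the mode count
is the scientifically meaningful output and must be stable across a
bandwidth range before it is trusted.  Two pruning rules suppress
estimation artefacts: maxima below 5% of the global peak are dropped
(they are tails, not modes), and two maxima whose separating valley
exceeds 95% of the lower peak are merged (such dips are sampling
wiggles; genuine bimodality produces much deeper valleys).  Boundary
positions use the centre of the low-density basin rather than the raw
argmin, which wanders on flat valleys.

**Rhythm.**  Rhythm centroids are unit-sum standardised-ICI vectors,
one set per click count, fit by k-means with a fixed seed (default
20240507) or loaded from a centroid table.  Assignment minimises the
mean squared distance between the coda's standardised absolute ICI
vector and centroids of the same click count; a standardised-cumulative
variant is available (the literature's 18 reference clusters could have
been defined either way).  Rhythm assignment is invariant to uniform
time scaling; tempo assignment is not — the two features are
orthogonal by construction.  A bundled table
(`data/reference_rhythms_synthetic.csv`) carries 18 synthetic centroids
over 3–10 clicks with the reference configuration's cardinality; it
exercises the loading path and must be replaced by centroids fit on
real data for empirical work.

**Ornaments precede typing.**  An ornament is the final click of a coda
containing exactly one more click than the nearest preceding or nearest
following coda (either side) of the same whale within a 10 s window.
The rule is iterated to a fixed point using flagged neighbours'
de-ornamented click counts, so runs of ornamented codas are still
recognised from their far sides.  Because ornaments do not determine
discrete type, the pipeline detects them first, fits tempo and rhythm
models on de-ornamented codas, and types every coda on its
de-ornamented form.  Skipping this step biases every downstream
duration statistic: an undetected ornament inflates a coda's apparent
duration by ~50% of one ICI spacing and drags it into the wrong class.

## Context-sensitivity statistics

All bespoke tests are permutation tests with the add-one convention
p = (#{null ≥/≤ observed} + 1)/(N + 1), which bounds p below by
1/(N+1); the default N = 10 000 resamples makes the smallest
reportable p ≈ 0.0001.  Resampling is *without replacement*: each
resample permutes coda durations within exchangeability pools and
re-evaluates the observed pair structure, rather than drawing
independent pairs.  This choice is deliberate — matched-count random
pair draws do not mirror the observed pairing structure (observed
pairs chain through shared codas) and measurably distort the null;
within-pool permutation is exactly calibrated when durations are
exchangeable within pools.

* **Adjacent-drift test** (one-sided): observed mean |ΔD| over
  consecutive same-whale, same-type coda pairs inside call sequences;
  pools are each whale's codas of one discrete type (an any-whale pool
  variant exists).  Small observed drift ⇒ duration varies smoothly.
* **Triple correlation**: Spearman rank correlation (two-sided) between
  drift(c₁,c₂) and drift(c₂,c₃) over consecutive same-whale, same-type
  triples.  Note the null landmark: for i.i.d. durations consecutive
  drifts share the middle coda with opposite signs, so their
  correlation is −½, not 0.  Positive values therefore indicate
  strongly sustained trends.
* **Chorus-matching test** (one-sided): observed mean |D_a − D_b| over
  overlapping cross-whale pairs; pools are all codas of one discrete
  type across whales, embodying the null that chorusing whales match
  only discrete type.
* When ornament annotations are supplied, all drift statistics use
  de-ornamented durations: the ornament click is an independent feature
  and including its ICI would attribute ornamentation effects to tempo.

**Ornamentation statistics.**  The centroid test compares, per
ornamented coda, A = MSE(standardised full coda, centroid of the rhythm
assigned at its raw click count) with B = MSE(standardised
ornament-removed coda, centroids of its same-whale adjacent codas'
types); the one-sided p randomly swaps A/B labels within pairs.  The
final-ICI statistic (t_{k−1} − t_{k−2})/t_{k−2} (defined for ≥ 4
clicks, scale-invariant) is compared between ornamented and
unornamented codas of the same click counts by a two-sample KS test
(asymptotic p).  Positional enrichment uses Fisher's exact tests on
2×2 tables of ornamented × sequence-initial and × sequence-final
(singleton sequences excluded by default); degenerate tables report the
Haldane–Anscombe-corrected odds ratio, flagged in the method name, with
the exact p unaffected.

**Chorus-change test.**  Link-choruses separated by less than the
sequence gap are merged into *exchanges*, and every leader coda with
onset inside the exchange window (extended one gap beyond the end) is
scored — restricting to link-connected codas would let a coda that
silences its interlocutor select itself out of the analysis.  A
"change in chorusing behaviour" after a leader coda is: the follower
answers it after more than 8 s of silence (begins), the follower's next
coda comes more than 8 s after the coda's termination but it vocalises
again later (pauses), or no further follower codas occur in the
recording (ceases).  Fisher's exact test compares ornamented vs plain
leader codas.  No multiple-testing correction is applied anywhere.

## Synthetic exchange generator

The generator emulates a tagged multi-whale recording: a leader whale
produces call sequences (mean length 8 codas, one coda per ~4 ± 0.3 s,
14–30 s pauses between sequences), each sequence drawing one rhythm
template and one tempo mode; followers answer each leader coda with
probability 0.9, overlapping with probability 0.4 and otherwise
turn-taking within 2 s.  Defaults: five unit-sum templates over 4–8
clicks; five tempo modes at 0.35/0.55/0.80/1.10/1.50 s (sd 0.04–0.05 s,
support truncated at ±2 sd so classes have genuine density gaps);
per-ICI jitter 0.002 s; ornament rate 4% with 2× enrichment at sequence
boundaries and a 1.5× final-ICI multiplier; follower duration imitation
with 0.01 s noise; ornamented leader codas silence the follower for
three responses with probability 0.15 (baseline 0.05).

Rubato is a damped stochastic oscillator on duration: the drift
velocity carries AR(1) momentum (persistence 0.8) plus a pull back to
the mode (reversion 0.2), innovation scaled so the stationary step sd
equals `rubato_step_sd` (default 0.03 s).  A plain bounded random walk
fails on both counts that matter here: its increments are serially
uncorrelated (no sustained trends — consecutive-drift correlation ≈ 0)
and its stationary distribution is nearly uniform over the bounds
(flattening the very duration modes tempo typing relies on).  The
oscillator produces consecutive-drift correlations around +0.5 and
mode-peaked durations.  Duration draws are truncated by redraw rather
than hard-clipped: clipping creates point masses at class edges that
are assigned across the class boundary and violate within-class
exchangeability.

The matched null world (`null_exchange`) makes durations i.i.d. within
type, disables imitation (followers draw from the leader's mode),
places ornaments uniformly, and equalises the pause probabilities.
Every generated coda carries truth labels (rhythm, tempo, ornament,
per-sequence rubato class, imitated coda), and one integer seed drives
a single `numpy` generator, so outputs are bit-reproducible.

What the generator does *not* emulate: inter-clan repertoire
differences, more than one concurrent conversation, click-level
amplitude/spectral structure, coda types with click-count-sharing
rhythm variants, behavioural-state modulation of calling rate, and
annotation error beyond small ICI jitter.  Passing recovery tests shows
the pipeline recovers the features this model injects, not that real
recordings satisfy the model.

## Calibration and problem sizes

Type-I calibration runs the two duration permutation tests on 200
independent null-world hours (3600 s recordings, ~950 codas each,
199 resamples per test, α = 0.05), supplying the generator's
ground-truth labels so the statistical procedure is isolated from model
estimation; measured rejection rates fall within 0.05 ± 0.02.  Running
the same calibration through the full estimation pipeline (KDE tempo
fitting, k-means rhythms, ornament detection) adds roughly 1–4
percentage points of anti-conservativeness, traceable to rare ornament
detection misses whose inflated durations contaminate type pools —
worth remembering when interpreting borderline p-values on real data,
where type estimation error is unavoidable.  Recovery analyses use one
to three simulated hours; the acceptance script uses a two-hour
exchange for feature statistics and the 200-replicate calibration, and
verifies the Spearman/KS/Fisher/permutation kernels against exhaustive
or brute-force oracles on 1000+ random small instances.

## Known limitations

* Tempo-mode counts depend on the KDE bandwidth; the 5-mode recovery
  uses 0.05 s (between the within-mode sd and the mode spacing), and
  any substantive claim about mode counts should be checked across the
  CLI's bandwidth sweep.
* The permutation tests condition on estimated discrete types; their
  exactness degrades gracefully with typing error but is not guaranteed
  under gross model misspecification.
* The ornament detector only represents final-click ornaments, and a
  fully isolated run of ornamented codas (no plain coda within the
  window on either side) is undetectable under the definition.
* "Pauses/ceases chorusing" are operationalised with the 8 s sequence
  gap and recording-level follower timelines; other reasonable
  operationalisations exist and the constants are exposed as
  parameters.
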