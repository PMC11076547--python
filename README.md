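# codakit

Tools for analysing the combinatorial and conversational structure of
sperm whale (*Physeter macrocephalus*) codas.

Sperm whales communicate with **codas** — short stereotyped bursts of
3–40 clicks.  A coda of *k* clicks is fully described by its vector of
inter-click intervals (ICIs) `t = (t₁, …, t_{k−1})`, `tᵢ > 0`.  Its
**duration** is `D = Σ tᵢ`, and its **standardised ICI** vector
`t / D` (unit sum) captures the click pattern independent of speed.
`codakit` decomposes codas produced in multi-whale exchanges into four
features:

* **rhythm** — the discrete category of the standardised ICI vector
  (nearest centroid by mean squared distance, within click count);
* **tempo** — the discrete category of the duration, one class per
  mode of a Gaussian-kernel density estimate over durations;
* **rubato** — smooth, sustained modulation of duration across a
  single whale's consecutive codas, imitated by interlocutors;
* **ornamentation** — an extra final click appended to a coda whose
  remaining clicks match its neighbours.

The package provides the data model and CSV I/O for annotated coda
tables, exchange segmentation (call sequences under an 8 s gap rule,
turn-taking/overlap classification with a 2 s window, choruses,
leader/follower roles), the statistics that establish rubato and
ornamentation as controlled features (within-type permutation tests of
adjacent-pair drift `|D_{i+1} − D_i|` and of overlapping-pair duration
matching, Spearman correlation of consecutive drifts over coda triples,
a paired permutation test of centroid distances with the ornament
retained vs removed, a two-sample Kolmogorov–Smirnov test of the
final-ICI statistic `(t_{k−1} − t_{k−2})/t_{k−2}`, and Fisher's exact
tests of positional and behavioural coupling), the rhythm × tempo
"phonetic alphabet" with per-cell rubato/ornament tallies and
information capacities (`log₂` of the realisable inventory), time–time
exchange plots, and a synthetic multi-whale exchange generator whose
ground-truth labels make every stage testable without field data.

It is intended for bioacousticians and quantitative ethologists working
from annotated click tables; audio-level click detection is out of
scope.

## Worked example

Generate a synthetic two-whale exchange, type it, and run the rubato
tests:

```sh
$ coda simulate --seed 5 --out sim/
475 codas over 1784 s -> sim

$ coda fit tempo sim/codas.csv --bandwidth 0.05 --out tempo.yaml
5 tempo modes at [0.335, 0.545, 0.83, 1.106, 1.492] (bandwidth 0.0500 s) -> tempo.yaml

$ coda ornaments detect sim/codas.csv
11 ornaments in 475 codas (2.3%)

$ coda rubato test sim/codas.csv --resamples 300 --seed 2 --bandwidth 0.05 --report text
method=adjacent_drift_permutation  observed=0.0349...  null_value=0.0592...  p_value=0.00332  n=386 ...
method=triple_drift_spearman       observed=0.3482...  p_value=2.9e-10      n=310 ...
method=chorus_matching_permutation observed=0.0180...  null_value=0.0740...  p_value=0.00332  n=103 ...
```

Reading: the five duration modes are the tempo types; adjacent codas of
the same discrete type drift by 0.035 s on average while random
same-type codas of the same whale differ by 0.059 s (one-sided
permutation p = 0.0033 at 300 resamples), consecutive drifts correlate
positively (r = 0.35: drift trends are sustained), and overlapping
codas from different whales match durations far more closely than
same-type chance (0.018 s vs 0.074 s): duration is being controlled and
imitated.

The same analyses run on real annotated coda tables via the canonical
CSV schema (`coda_id, recording_id, whale_id, onset_time_s,
ici_1..ici_9`); `coda io convert` adapts wide ICI tables as they
circulate in the coda literature.

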