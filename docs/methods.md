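# Methods

`eogdeco` models the recognition side of an EOG-driven text entry
system: a user spells Kana characters with sequences of five eye
motions (up, down, left, right, center), six skin electrodes measure
the corneoretinal potential, and a continuous decoder converts the
multi-channel signal into characters.  This note describes the models,
the synthetic data the package is validated on, the numerical choices,
and what the desk-scale experiments do and do not show.

## Signal model and synthetic EOG

The generator renders a motion sequence through a latent 2-D gaze
state.  Each motion is a logistic saccade from the current gaze
position toward the motion's target on the unit circle (up=(0,1),
down=(0,−1), left=(1,0), right=(−1,0), center=origin), followed by a
hold; optional motionless "sil" padding (default 500 ms) frames the
recording.  Because every transition starts from wherever the gaze
currently is, the rendered waveform of a motion depends on its
neighbours — the property context-dependent units exist to model.  When
the rise time is comparable to or longer than the motion duration, the
gaze undershoots its target and adjacent motions fuse, which is the
regime of fast continuous input.

The gaze is projected to six channels by a fixed geometry matrix
(CH1/CH6 above the eyes respond positively to "up", CH3/CH4 below to
"down", CH2 at the left temple to "left", CH5 at the right temple to
"right", with deliberate asymmetries between paired electrodes), then
scaled by the user's amplitude (uV per unit deflection; physiological
range roughly 290–1100 uV/rad).  Additive terms:

* band-limited noise — white Gaussian noise low-pass filtered with a
  zero-phase 101-tap FIR at 27 Hz, so >99% of the noise power lies
  below 30 Hz, matching the EOG band; `noise_std` is the broadband
  standard deviation before filtering and stands in for measurement
  noise plus myoelectric and electrode artifacts;
* drift — an integrated Gaussian random walk whose standard deviation
  grows as `drift_rate·sqrt(t)`, per channel;
* per-motion gain jitter — multiplicative trial-to-trial variation of
  saccade extent (default 10%);
* per-user electrode geometry — a seeded perturbation of the channel
  matrix (`geometry_jitter`), fixed within a user, emulating individual
  electrode placement and skin contact.  This is what makes pooled
  (user-independent) models genuinely degrade on a new user: amplitude
  scaling alone shifts all hypotheses' likelihoods equally and barely
  changes their ranking.

Library defaults describe deliberate input (400±100 ms motions, 100 ms
rise).  The *experiment* population instead emulates practised fast
input: ~0.25 s motions with 0.40 s rise (strong undershoot/fusion),
150–220 uV artifact noise, 25% geometry jitter.  Under slow, clean
conditions every recognizer in the package is essentially perfect and
there is nothing to compare.

What the generator does **not** emulate: blinks and other discrete
artifacts, session-to-session electrode re-attachment within a user,
nonstationary noise, EOG saturation, and the kinematics of real
saccades (main-sequence velocity profiles).  Passing tests on this data
therefore show the *pipeline* behaves as designed under the stated
degradations, not that the absolute error rates transfer to human
recordings.

## Input protocol

48 basic Kana characters and 2 modification marks are each a fixed
4-motion code; a voiced/semi-voiced character is its mark code followed
by the base character's code (8 motions).  Codes never repeat a motion
(a repeated motion has no boundary in the signal), start off-center and
end in "center"; there are exactly 52 such codes over five motions, so
the inventory fits.  Five published table entries are fixed verbatim;
the remaining codes are assigned by a seeded permutation.  Greedy
4-motion framing with a one-frame mark lookahead makes any code
concatenation uniquely decodable, which the tests verify on random
words.

## Acoustic-style models

Every modelling unit — an eye motion with optional left/right context
("p−t+s" naming, analogous to triphones), or the boundary silence — is
a 4-state strict left-to-right HMM (no skips) with diagonal-covariance
Gaussian-mixture emissions and an explicit exit probability per unit.
Features are the raw channel samples at 100 Hz (6-dim, or the 2-dim
horizontal/vertical projection CH2−CH5 and mean(CH1,CH6)−mean(CH3,CH4));
no windowing, deltas or normalisation by default.

Training is embedded Baum–Welch: each labelled recording's unit
sequence is composed into a linear chain, forward–backward occupancies
are accumulated for states, mixture components and transitions, and all
parameters are re-estimated jointly.  Numerical choices:

* all computation in the log domain; `-inf` marks impossible events;
* variance floor `1e-4` of the per-dimension global data variance;
* mixtures grown by binary splitting (means ±0.2 sigma, weights
  halved) along a schedule ending at 16 components by default; the
  experiments use (1, 2) at desk scale;
* a state whose total occupancy falls below 0.5 frames keeps its
  previous parameters (with a warning) instead of being re-estimated;
* flat start from global moments; for the 2-state recovery tests the
  start symmetry must be broken explicitly.

State tying is expressed by object identity: logical unit states that
share one emission object are accumulated and updated as one physical
state, so the same Baum–Welch code trains tied and untied systems.

## Decision-tree state tying

Tri-unit inventories grow cubically (4·5·4 tri + 4·5 + 5·4 one-sided
boundary models = 120 models, 480 states for five motions and four
states), far beyond what desk-scale data can estimate.  For each
(target motion, state position) all context variants are pooled at a
tree root and split greedily by yes/no context questions — identity
questions per motion and side, plus horizontal {left,right} and
vertical {up,down} groups; an absent context answers "no" to every
question, which routes the one-sided boundary units through the same
trees.  Split gain is evaluated on pooled single-Gaussian sufficient
statistics (the exact mixture likelihood under re-clustering is not
tractable); splitting stops when the best gain drops below a threshold.
Unseen context combinations resolve through the trees at decode time,
so any valid unit can be synthesised.  Transition matrices are shared
per target motion (occupancy-weighted average of the variants).

The threshold trades complexity against data volume.  The default
(1000 nats) yields ~30–50 tied states on the default two-unit training
corpus; matching the full-scale system's tied/untied ratio (~0.32)
would need a much larger corpus, and forcing it at desk scale
demonstrably overfits (tiny leaf occupancies, worse error).  The
threshold is a config parameter.

Bi-unit systems are tied with the same machinery (only left-context
questions can produce a valid split).  Untied bi systems were markedly
worse than mono at desk scale from sheer parameter count, which says
nothing about context modelling; tying restores the expected
mono > bi > tri error ordering.

## Character N-grams

Backoff character models of order 1–3 with interpolated Witten–Bell
smoothing (`lambda(h) = c(h)/(c(h)+T(h))`, unigrams interpolated with
the uniform distribution), stored and exchanged in ARPA format.
Order-1 models are plain distributions over character tokens (no
boundary symbols); higher orders use `<s>`/`</s>`.  Perplexity is the
exponentiated mean negative log-probability per scored character
(end-of-sequence excluded by default).

The licensed 12M-character corpus such models are normally trained on
is replaced by a synthetic character source: Zipf-distributed unigram
frequencies with a per-predecessor successor emphasis (first-order
Markov), so higher orders have structure to learn.  Test words are
drawn from the *same* source instance as the LM training text —
mirroring real usage, where both the LM corpus and the things users
type are natural language.  Absolute perplexities of the original
corpus are not reproducible and are not asserted.

## Decoding

The decoder composes, for every character, the chain of its unit HMMs.
With context-dependent units the first unit depends on the preceding
character's last motion and (for tri units) the last unit on the
following character's first motion, so characters are expanded into
entry variants per predecessor context and exit variants per successor
first-motion; an exit variant for motion f connects only to characters
starting with f.  This makes cross-character context exact; a config
switch (`cross_char_context`) restricts to word-internal contexts.
Optional silence models frame the utterance.

Search is time-synchronous Viterbi over (graph node, LM history)
pairs.  Character arcs add `lm_weight`·log P(char|history) plus the
insertion penalty (log-domain, per character — the recognized output
units are characters).  With `beam=None` the search is exact and equals
exhaustive hypothesis enumeration (tested); the default beam of 40
reproduced the exact scores on every decode it was compared against
while cutting trigram decoding severalfold.  LM histories are compiled
to a deterministic automaton; only histories holding a live token are
propagated.  Ties between equal-scoring candidates are broken
deterministically by graph order (stay over advance, earlier arcs
first), so decoding is reproducible; exact lexicographic tie-breaking
among equal-scoring hypotheses would require n-best bookkeeping and is
not implemented.

## User adaptation

* **MLLR** — mean-only maximum likelihood linear regression,
  `mu' = A mu + b`, one global regression class by default (k-means on
  component means for more classes; a class with occupancy below the
  feature dimension merges into the global class).  For diagonal
  covariances the transform solves one (d+1)-dimensional normal
  equation per output dimension.  Estimation is iterated twice:
  re-aligning with the adapted models removes most of the occupancy
  bias of the first pass (a single pass misses a known mean shift by
  ~2× the documented tolerance).
* **MAP** — per-component `mu' = (tau mu0 + sum gamma x)/(tau + sum
  gamma)`, default tau = 10 frames; weights and variances keep their
  priors.  The update is exact in both limits (tau→0 gives the ML
  means, tau→∞ the priors) and component means move monotonically
  between them.
* **Insertion-penalty tuning** — grid search minimising development
  CER; ties prefer the value closest to zero.  In the adaptation
  experiment the penalty is tuned on the adaptation sequences
  themselves (scored at the motion level, since they are not protocol
  words), keeping the test words untouched.

## Threshold baseline

Per-sample classification of the 2-D feature (norm below threshold →
"center", otherwise nearest direction by inner product, ties broken
left/up/right/down), a sliding majority vote, and run-length merging.
The stock 1000 ms vote window corresponds to roughly one motion at a
deliberate input rate; the baseline experiment scales the window to one
motion duration of the profile under test.  The default center
threshold is half the profile amplitude.

## Scoring

Minimum-edit-distance alignment with unit costs yields substitution,
deletion and insertion counts; the error rate is 100·(S+D+I)/N (N the
reference length) at either the character (CER) or the motion level.
Tie preference in the traceback: substitution over deletion over
insertion.  Corpus rates pool counts across utterances rather than
averaging per-utterance rates.  Insertion-heavy output can exceed
100%.

## Desk-scale experiments

Problem sizes were chosen so a full default run completes in minutes on
one core: 5 synthetic users, 2 units of training data each (one unit =
22 sequences of 4–8 motions, ≈136 motions), a seeded 16-character
decoding vocabulary, 8 test words of 2–4 characters, mixture schedule
(1, 2).  The three drivers:

* `run_unit_comparison` — user-dependent mono/bi/tri × 0–3-gram CER
  grid, pooled over users, plus a relative-reduction report.
* `run_adaptation_curve` — a tri system pooled over the population is
  evaluated on a deliberately mismatched target (fast input, weak
  300–340 uV amplitude, own electrode geometry) without adaptation and
  with MLLR, MAP, and MAP + insertion-penalty tuning at several
  adaptation amounts, averaged over repeats.
* `run_baseline_comparison` — motion error rate of the threshold
  recognizer versus mono-unit HMMs on 2-channel and 6-channel features.

Observed qualitative behaviour at the defaults: tri < bi < mono at
every LM order; CER non-increasing in LM order; threshold ≫ HMM; the
unadapted pooled model far worse than adapted ones, with MAP improving
as adaptation data grows and penalty tuning helping at the larger
amounts.  One deviation from the full-scale system is expected and
accepted: with only two units of training data the 2-channel HMM can
edge out the 6-channel HMM, because the extra channels' information is
outweighed by the extra parameters' estimation noise; the threshold
baseline remains far worse than either.

## Known limitations

* Absolute error rates depend on undeposited human recordings and are
  not reproduced; only orderings and arithmetic identities are
  asserted.
* No streaming/partial-output decoding, lattices or n-best lists.
* MLLR is mean-only; MAP updates means only.
* The decoder's dense LM-history representation is sized for the
  desk-scale vocabularies; order-3 decoding over the full 73-character
  protocol would want a sparser token store.
* Blink events and other non-gaze artifacts are outside the model.
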