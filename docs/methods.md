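# Methods

## Model

`crfalign` scores a pairwise alignment of a template (structure) profile HMM
*s* and a target profile HMM *t* as a conditional random field over lattice
paths.  Path states either align two columns (M / MM), consume a target
column only (I; five-state MI, DG) or a template column only (D; five-state
IM, GD).  The five-state scheme follows the HHalign pair-state machine, whose
transition set is restricted to self-transitions plus transitions between MM
and each gap state; the three-state scheme reduces it (MM→M; MI, DG→I;
IM, GD→D) and by default allows all nine ordered transitions.  Pair-state
letters are written target-first: this is forced by the reduction — MI and DG
consume a target column, and their reduced state I is an insertion in the
target.

The edge score is `F = T0 + sum_k mu_k T_k`.

### Base model T0

Per aligned column: `Saa + Str + S2`, all in bits, converted to natural log
(× ln 2) when the lattice table is built.

* `Saa(i, j) = log2 sum_a q_i(a) p_j(a) / f(a)` — profile co-emission
  log-odds against the background `f` (the mean of the two profiles'
  backgrounds; identical files share one).  This is the standard HMM-HMM
  column score.  It is floored at `saa_floor = −10` bits: two one-hot columns
  on different residues would otherwise contribute −∞ and delete lattice
  edges.
* `Str` factorises over the two HMMs: a pair transition `X1Y1 → X2Y2`
  scores `log2[ tr_target(X1→X2) · tr_template(Y1→Y2) ]`, with the G (gap)
  letter contributing factor 1 and with transition probabilities read from
  the most recently consumed column of each HMM (no factor before the first
  column — end transitions are unscored, as are BEGIN/END edges generally).
  Letter pairs with no stored HMM transition (I→D, D→I) are undefined; they
  can only occur among reduction candidates and are skipped there.
  Transition probabilities are floored at 1e−6 inside `Str` so a zero
  probability cannot disconnect the lattice.
* `S2(i, j) = w_ss · sum_c P_target(c|j) · ss_matrix[ss_template(i), c]` —
  the template's assigned 3-class secondary structure against the target's
  predicted class probabilities.  Defaults: diagonal +1, H↔E −2, other
  off-diagonals −0.5, `w_ss = 0.3`.  These values are config-visible and
  serialized with every model; no test depends on their particular values
  beyond fixtures where they are known.

In the three-state scheme, every reduced edge takes the larger of its
candidate five-state scores; this max-reduction is applied uniformly to gap
state *and* gap transition scores (the alternative — re-maximising states
only — was open; uniformity keeps the reduced table a true upper envelope of
five-state path scores, which is also asserted as a test invariant).

### Boosting stages Tk

Each stage holds, per alignment state, exactly six regression trees of depth
at most five; the stage output is their sum, and stages enter `F` with
weight `mu_k = 0.2`.  Within a stage the six trees are fitted by residual
(gradient) boosting with unit inner shrinkage: the stage weight is the only
learning rate.  Trees split by exact greedy variance reduction over all
midpoints of consecutive distinct feature values, with ties broken by lowest
feature index then lowest threshold, and `min_leaf = 20` by default (the
pooled training sets run to ~10^5 rows; tiny leaves fit sampling noise).
Zero-gain splits are admitted — an XOR-type interaction has no first-split
gain yet is separable at depth 2, and the depth cap bounds the added
variance.  Trees serialize to nested JSON; loading validates the format
version and per-state coverage.

### Features

Six match features for an edge aligning template column i with target column
j: the Saa score; the Pearson correlation of the two emission vectors
(defined as 0 for a zero-variance column); secondary-structure agreement
(unit weight); −|ΔRSA|; mean secondary-structure agreement over window
offsets −w..+w (w = 2, truncated at chain ends); and min(neff)/20.  Six gap
features of the consumed residue: a secondary-structure class score (H = 1,
E = −1, C = 0); RSA; emission entropy / ln 20; neff/20; normalised distance
to the nearer terminus (in [0, 0.5]); and a gap-continuation flag (previous
edge in the same state).  The schema is versioned and serialized with the
model, so replacing the feature lists is a localised change.  In the
five-state scheme MI/DG share the target-consuming gap geometry and IM/GD
the template-consuming one, but every state owns its own trees.

## Inference

All dynamic programming runs in natural-log space with log-sum-exp.  The
forward/backward recursions give the log partition function, per-edge
posteriors `exp(α + F + β − log Z)` and match posteriors `P(s_i, t_j)`;
they are verified against exhaustive path enumeration to ~1e−15 on small
lattices.  Viterbi decoding supports global, glocal (start on the top/left
lattice boundary, end on the bottom/right; end gaps unscored) and local
(free start/end) modes.  Ties are broken by the fixed preference order
M > D > I (five-state MM > IM > GD > MI > DG), then smaller template then
target coordinate, making output bit-reproducible.

MAP (maximum accuracy) decoding maximises the sum of match posteriors over
co-linear pair sets.  Global mode uses zero gap cost.  Local and glocal
modes subtract a threshold `mth` from every match and charge `0.5·mth` once
per *internal* gap opening — per maximal gap run, not per residue: the
penalty exists to discourage unnatural numbers of internal gaps, which is a
count of runs.  Local/glocal MAP reuses the global-ensemble posteriors; the
threshold is applied to already-computed `P(s_i, t_j)`.  A local alignment
whose best adjusted total is ≤ 0 is empty by convention.

## Training

Stage k: compute posteriors for every training pair under the current model;
take every reference-path edge as a positive sample labelled
`1 − P(edge)` and draw `Nf·La = 16·La` off-path edges uniformly without
replacement (duplicates add no information) as negatives labelled
`−P(edge)`, allocated evenly across states with the remainder handed out in
the fixed order M, I, D; pool samples across pairs per state (one global
ensemble per state per stage); fit the stage; append it with weight mu; then
redraw fresh samples under the updated model for the next stage.  For
five-state training the reference path's gap columns are first given unique
five-state labels by a dynamic program that maximises the base score along
the fixed path (ties prefer MI over DG and IM over GD).  Note that the
five-state transition set makes a reference path with directly adjacent I
and D columns unlabelable; such pairs are rejected (the synthetic generator
never emits them).  Training is bit-reproducible: per-pair, per-stage RNG
streams are derived from the seed, and the serialized model is
byte-identical across reruns.

## Synthetic benchmark

The generator emulates what a curated reference-alignment benchmark
provides, at controllable difficulty.  A first-order walk with `gap_open`
and `gap_extend` produces the reference path (gap runs never switch
directly between I and D).  Matched columns draw both profiles'
emission vectors from a Dirichlet centred on a shared latent composition
with concentration `profile_concentration` — one knob playing the role of
sequence identity; unmatched columns use independent latents.
Secondary-structure classes are segmental (runs of 3–9) on the template and
agree at matched positions with probability `ss_agreement` (deliberately
independent per position so the rate is binomially calibrated; unmatched
target residues extend local runs instead).  Predicted class probabilities
are Dirichlet-noised with the argmax preserved; RSA of matched targets is
the template value plus N(0, `rsa_noise`), clamped to [0, 1]; HMM transition
probabilities mirror the local gap structure; neff ~ U[1, 10].

Presets: *easy* (concentration 50, agreement 0.95, gap_open 0.08) and
*twilight* (concentration 3, agreement 0.65, gap_open 0.15).  What the
generator does **not** model: substitution-matrix evolution, domain
architecture, alignment-block conservation structure, or correlated errors
in predicted features.  Passing tests therefore demonstrate that the
machinery learns and decodes correctly when the features carry signal — not
that any particular accuracy transfers to real protein pairs.

The benchmark used by the tests and the acceptance script is 200 pairs of
length 30–60 (150 train / 50 test), five stages, trivial (zero) base model —
sizes chosen so a full train-and-evaluate cycle completes in about a minute
on one CPU while still pooling ~10^5 samples per state.

## Observed decoding behavior and limitations

On the easy benchmark with a zero base model, five stages of weight 0.2
leave the learned edge-score contrast at roughly one natural-log unit, so
path posteriors remain diffuse even when Viterbi accuracy is already near
its ceiling (> 0.99).  In that regime MAP decoding — which is optimal for
the *model's* posteriors and provably attains at least Viterbi's posterior
total (asserted as a test property) — recovers one to two fewer true matches
per pair than Viterbi, because summing diffuse posteriors rewards spurious
chain extensions.  MAP's advantage reappears where posteriors express
genuine ambiguity (e.g. the twilight preset under the base model) and the
two decoders converge as stages accumulate.  Other known limitations: the
exact HHalign `Str`/`S2` parameterisations are not published alongside the
pair-state machine, so the factored transition product and the
secondary-structure matrix here are this package's documented choices; the
six-plus-six feature lists are likewise this package's reconstruction from
the named ingredients (profile similarity, secondary structure, solvent
accessibility, environment) and are schema-versioned so they can be swapped
without touching other modules; no banding or heuristic acceleration is
implemented — cost is O(S²·Ls·Lt) per pair.
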