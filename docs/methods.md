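# Methods

This package implements a smooth, differentiable relaxation of
Smith–Waterman / Needleman–Wunsch pairwise alignment, a learned alignment
module (LAM) built on it, and SMURF: joint learning of a multiple sequence
alignment and a GREMLIN-style Markov Random Field (MRF) whose couplings
predict residue–residue contacts from unaligned homologous sequences.

## Smooth alignment

Classic alignment DP computes the maximum of `path_score` over monotone
lattice paths, where a path earns the match score `a_ij` for every aligned
residue pair and pays gap penalties for unaligned residues.  Replacing max
with logsumexp yields the log-partition function of the Gibbs distribution

    p(path) ∝ exp(path_score(path) / T),

and `smooth_score(a, T) = T · log Σ_paths exp(path_score/T)`.  The
probability that residues (i, j) are matched — the posterior alignment —
equals `∂ smooth_score / ∂ a_ij`.  We compute it directly with a
forward–backward pass over the same three-state machine (match, x-gap,
y-gap), which makes the posterior itself an explicit differentiable
function: training losses that consume the posterior need only first-order
automatic differentiation.  The identity with the derivative is verified by
finite differences in the test suite.

Conventions:

* **Path space.** The distribution is over lattice *move* paths, so with
  `restrict_turns` off, opposite gap runs in different orders are distinct
  paths.  `restrict_turns` forbids the y-gap → x-gap transition, leaving one
  canonical ordering — this removes the double counting that biases the
  smooth alignment toward the diagonal.
* **Local mode.** A nonempty path begins and ends with a match; the empty
  path is valid with score 0 (the Smith–Waterman floor).  Global mode runs
  corner to corner and charges terminal gaps like internal ones.
* **Affine gaps.** Three-state machine; the first position of a maximal gap
  streak costs `open`, later ones `extend`.  Linear mode is the
  `open == extend` special case of the same machine (the path distribution
  is identical, and `restrict_turns` still applies).
* **Numerics.** All recursions run in log space on `score/T` with the final
  value rescaled by `T`; disallowed states carry a −10⁹ sentinel rather than
  −∞ so every gradient stays finite.  Scores up to ±10³ and temperatures
  down to 10⁻² are exercised in tests.
* **Batching.** The batched DP sweeps anti-diagonals, vectorized over batch
  and diagonal.  Items carry their true lengths; invalid lattice nodes are
  pinned to the sentinel and per-item terminal nodes are addressed exactly,
  so padding can never leak into a result.
* **Hard alignment.** The max/argmax version of the same machine with
  deterministic tie-breaking (match > x-gap > y-gap; earliest cell in
  row-major order for local endpoints).

Brute-force oracles (`enumerate_paths`, `brute_force_smooth_score`,
`brute_force_posterior`) enumerate every path for sequences up to length 7
and anchor the DP implementations in the tests at 10⁻⁸ agreement.

## Learned Alignment Module

Each residue is embedded by a single linear convolution (window `2w+1`,
default `w = 9`; zero padding keeps positions aligned) applied to the
one-hot sequence; unknown residues (X/N) are all-zero rows.  The alignment
score between query position i and sequence position j is the dot product of
their embeddings.  Running the smooth alignment on each similarity matrix
gives one posterior per sequence, all in query coordinates; contracting with
the one-hot sequences yields the *soft MSA*: per-sequence expected residue
distributions per query column plus leftover gap mass (the two always sum to
one).  The number of filters follows the original 512 by default; the
synthetic studies in the tests use 64, which loses nothing measurable at
query length 30 and keeps runtimes small.  Whether the original encoder had
depth or nonlinearities is not documented in the text available to us; the
single linear layer is the minimal faithful reading and is isolated behind
`EncoderParams`.

## MRF and masked language modeling

The MRF has site fields `v_i[a]` and symmetric pairwise couplings
`W_ij[a,b]` with zero diagonal blocks (symmetry is enforced by
parameterization, never by projection after the fact).  For a masked
(sequence, column) entry the model predicts

    softmax_a ( v_i[a] + Σ_{j unmasked} Σ_b W_ij[a,b] · profile[s,j,b] ),

masked entries contributing nothing to their neighbours (the mask token is
the all-zero profile).  The loss is the mean cross entropy at masked entries
against the pre-mask profile, with gap mass spread uniformly over the
alphabet — the model has no gap state, so an insertion can never be guessed
better than uniformly — plus L2 penalties.  The coupling penalty follows the
GREMLIN convention `λ_w (L−1)(A−1) ‖W‖²` rescaled by `1/(B·L)` because our
cross entropy is a mean per masked entry rather than a sum over all
(sequence, site) terms; without the rescaling the penalty crushes the
couplings and contact recovery collapses (measured in the synthetic study).
Defaults: mask rate 0.15, λ_v = λ_w = 0.01.

Contact scores are Frobenius norms of the coupling blocks with the standard
average-product correction (APC); pairs closer than 6 positions along the
chain are excluded at evaluation time.  APC annihilates rank-one background
exactly, which the tests verify.

## Synthetic families (the study conditions)

Real protein families cannot ship with the package, so every experiment runs
on generated families with complete ground truth:

1. `plant_mrf` places `n_contacts` column pairs at separation ≥ 6 and gives
   each a coupling block `W[a, σ(a)] = strength` for a random permutation σ;
   fields are `N(0, 1.5²)`, giving dominant-residue column frequencies
   around 0.3–0.5 — the conservation level of a reasonably conserved
   protein-family alignment.  Weaker fields make the *alignment* problem
   under-determined (no column signal to align to), stronger ones make it
   trivial.
2. `gibbs_sample` draws sequences by single-site Gibbs sampling
   (independent chains — a star phylogeny; no tree correlation).
3. `corrupt_with_indels` deletes each position with rate 0.05 and inserts
   geometric(0.5)-length runs with rate 0.05 per slot, recording the exact
   residue-level alignment of every corrupted sequence to the uncorrupted
   query.

Default study conditions: L = 30 columns, alphabet 20, 20 planted contacts,
400 sequences, 30 Gibbs sweeps, indel rates 0.05.  The coupling magnitude
1.775 was fixed once by `calibrate_strength`: bisection until the
fixed-alignment MLM baseline recovers 90% of planted pairs in the top-20.
Against this family, aligning each corrupted sequence to the *true* column
profile (log-odds scores, affine gaps) recovers ≈ 0.91 of ground-truth match
pairs — the practical ceiling any learned aligner can approach under these
conditions.

What the generator does **not** emulate: phylogenetic correlation between
sequences, indel hotspots or length-dependent gap costs, biased amino-acid
composition, and alignment depth heterogeneity.  Passing the synthetic
recovery tests therefore shows the machinery is sound and self-consistent,
not that it matches tool performance on real Pfam/Rfam families.

## Training

* **BasicAlign** fits only the encoder by gradient descent on the squared
  difference between each sequence's soft profile and the column-average
  profile (columns become residue-pure when sequences agree).  The raw
  objective has a degenerate optimum — drive all alignment mass into gaps
  and every profile equals the all-zero mean — so the implementation adds a
  linear gap-mass penalty (default weight 2.0) that removes the collapse
  direction without touching the purity signal.  Defaults: 300 steps,
  learning rate 0.01, minibatches of 100 sequences.
* **TrainMRF** jointly descends the MLM loss in encoder and MRF parameters,
  starting the MRF at zero and the encoder from BasicAlign's output.
  The joint phase is deliberately *stochastic*: minibatches of 100 sequences
  and a raised mask rate (0.35).  Full-batch joint training freezes in a
  register-jitter local optimum (alignments off by one or two columns for a
  fifth of the residues, and confidently so); minibatch noise lets the
  register escape it — on the default study family, ground-truth match
  recovery goes from ~0.64 (full batch) to ~0.85 (minibatched).  200 steps
  at learning rate 0.01 by default.
* **MRF refit.**  After the joint phase the encoder is frozen and the MRF is
  refit from zero on the settled alignment (150 steps, learning rate 0.1,
  mask rate 0.15) — the MRF that co-evolved with a still-moving alignment
  systematically underestimates couplings.  Because a single refit endpoint
  is mask-stream noisy (contact-AUC spread of ~0.1 across refit seeds), the
  reported contact scores average the APC matrices of a small refit ensemble
  (`refit_mrf_ensemble`, n = 3–5); the averaging helps the fixed-alignment
  baseline just as much, so comparisons stay fair.  `run_smurf` can also
  alternate joint adjustment and refit (`cycles`), warm-starting each joint
  phase from the previous refit.
* **MLM-GREMLIN** is the fixed-alignment baseline: the same loss and
  optimizer on hard one-hot profiles of a given MSA, MRF parameters only.
  TrainMRF with a frozen encoder and fixed profiles reproduces it loss-for-
  loss (a test asserts ≤ 10⁻⁸ divergence), which pins both loops to the same
  semantics.

All loops use plain Adam at a fixed learning rate; masks (and minibatches)
come from a per-step seed stream derived from the config seed, so runs are
bit-reproducible.  Alignment parameters during training default to local
mode with affine gaps (open −6, extend −2) at temperature 1.0; the hardened
alignment is insensitive to the hardening gap penalties over a wide range
(open −2 … −8, measured).  For 30-column study families the encoder is run
with half-window w = 5 and 64 filters (the package defaults of w = 9 /
512 filters are sized for real protein-family lengths).

## Known limitations

* The smooth DP is O(n·m) per pair with a Python-level wavefront loop;
  fine for family sizes used here (hundreds of sequences, lengths ≤ ~100),
  not for proteome-scale work.
* The alignment learned jointly on shallow, weakly conserved synthetic
  families plateaus below the oracle ceiling: ground-truth match recovery
  reaches 0.82–0.86 against the ≈ 0.91 of an alignment to the true column
  profile.  Consequently the contact AUC from the learned alignment sits
  below the fixed-true-alignment baseline, and the size of that gap varies
  between family realizations (from ≈ 0.03 on easier draws to ≈ 0.2 on
  low-conservation draws).  The acceptance study reports both numbers; runs
  on real, deeper, more conserved families should not be extrapolated from
  these synthetic figures in either direction.
* No GPU path and no banded/linear-memory DP; local-mode conventions follow
  the package's own definition where the original formulation is
  unavailable, and are isolated behind `AlignParams`.
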