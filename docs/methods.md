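# Methods

## Channel model

A stored composite letter σ = (σ_A, σ_C, σ_G, σ_T), Σσ_i = k, is read back
as base counts X summing to the sequencing depth N. Reads are modelled as
i.i.d. draws from

    q_i(σ) = (σ_i / k)(1 − p) + (p / 3)(1 − σ_i / k),

i.e. the mixture proportions with a lumped per-base error rate p that moves
probability mass uniformly onto the other three bases, followed by
multinomial sampling at depth N. Assumptions baked in:

- **Positions are independent.** No neighbour effects, no per-read
  correlation between positions.
- **One error rate.** Substitutions, insertions and deletions are not
  distinguished; p (default 0.01) absorbs them all as an effective
  substitution-style rate. There is consequently no alignment step: counts
  correspond to positions exactly.
- **No amplification bias** beyond what multinomial sampling produces.

Even at p = 0 the channel is noisy: multinomial sampling alone mis-ranks
letters at shallow depth. Any statement of the form "recovery is perfect"
is therefore depth-qualified.

## MAP letter inference

With a uniform prior over the alphabet, the posterior argmax equals the
likelihood argmax; letter-independent terms cancel, leaving the multinomial
score Σ_i X_i log q_i(σ). A finite-copy variant Σ_i log C(F_i, X_i) with
per-base copy numbers F_i = f·q_i (f = `copy_scale_f`, default 10⁶) is kept
as a configurable cross-check; the two argmaxes agree in the large-f limit,
which the tests verify empirically, and the physical copy number is not
knowable from the data anyway, so the multinomial form is primary.

For alphabets of 128+ letters, exhaustive scoring is replaced by default
with an extremum search: the unconstrained maximiser of the score over
mixture fractions is the error-floor-corrected observed frequency
max(0, (X/N − p/3)/(1 − 4p/3)), renormalised; the handful of lattice
letters nearest that point are scored exactly. Exhaustive scoring remains
available and is the oracle in the equivalence tests (10³ random draws per
configuration, zero mismatches required). Batch decoding always uses the
vectorised exhaustive score matrix, which is fast enough at these sizes.

Call reliability is the Euclidean distance ‖X/N − σ*/k‖₂ between the
normalised observation and the called letter. Ties in the score break by
smaller distance, then by alphabet order; all orderings in the package are
deterministic so archives and reports reproduce bit-for-bit under a seed.

## Transition library

For a fixed (alphabet, N, p) the library tabulates
T[i, j] = P(inferred = σ_j | stored = σ_i). Two builders:

- **Exact**: enumerate all C(N+3, 3) observable count vectors, infer each
  once, and accumulate multinomial probabilities per (source, target).
  Guarded to ≤ 10⁸ scored (observation, letter) pairs; beyond that the
  builder refuses and points to Monte Carlo.
- **Monte Carlo**: per source letter, `n_draws` seeded channel draws
  (default 2 × 10⁴) inferred in batch. The library feeds rankings, not
  precise probabilities, so moderate sampling suffices; exact-vs-MC
  agreement is tested to < 0.01 row-wise at small N.

The diagonal complement 1 − T[i, i] is the letter error rate used to select
code alphabets: the 64/128/256 lowest-error letters of Φ_6/Φ_8/Φ_10, with
the selection library built at the experiment's target depth (error rates
are depth-dependent). Selection sorts by (error rate, descending
lexicographic ratio), so the size-s subset is a prefix of the size-(s+1)
subset and the choice is reproducible. Which subset the original
simulation study used is not recorded anywhere; this deterministic
lowest-error rule is this package's own reading of the selection principle.

Libraries are cached in-process by (alphabet hash, N, p, method, draws,
seed) and serialize to JSON.

## Alternative letter sets

When inference gets a position wrong, the correction candidates for that
position are ranked by the posterior of the stored letter given everything
observed there:

    score(t) = log P(X | t) + log T[t, inferred]

— the multinomial observation likelihood times the transition probability
*into* the inferred letter. Both factors matter and the direction of the
second is load-bearing. Ranking by the inferred letter's outgoing
transition row covers the true letter only ~80% of the time (top-2, 64
letters at 190×): given that we *saw* σ*, the question is which letters
plausibly transition into σ*, weighted by how well they explain the actual
counts. The combined ranking covers the truth in its top-2 in ≈ 99.7% of
natural inference errors and ≥ 99.88% of the boundary-like errors that
reliability ranking actually selects, which is what makes two-alternative
substitution sets sufficient. The letter-level library view
(`TransitionLibrary.alternatives`) ranks by the into-letter column alone
and serves analytics; the decoder, validator and metrics all use the
per-position posterior sets.

## Soft-decision decoding

Per RS block (45 letters, 41 information symbols, t = 2):

1. Hard-decode the MAP calls. Success returns immediately — the soft path
   never degrades a hard-decodable block — and is *not* second-guessed at
   block level (see decoder errors below).
2. Otherwise, for s = 1, 2, …: take the d least-reliable positions as the
   candidate set, where d starts at max(4, t + 2) and grows by one per
   failed level, capped at `max_positions` (default 8); try every size-s
   combination of candidates in reliability-rank order; for each
   combination, substitute every assignment of top-m alternatives
   (m = `max_alternatives`, default 2) in descending joint posterior,
   ties broken by position rank; hard-decode each substituted word.
3. One RS decode attempt = one iteration; the budget (`max_iterations`,
   default 10⁵) bounds the search, after which the block is given up as
   `exhausted`.

The start size d₀ = max(4, t + 2) and the growth-by-one schedule are this
package's choices; the method's description fixes the growth but not the
start. With m = 2 and the cap at 8, a full search costs at most ~5,600 RS
attempts, a few tenths of a second — in practice blocks at working depths
decode within the first levels.

### RS decoder errors

Beyond t errors the RS decoder can return a valid but wrong codeword. Two
defences, in the order the algorithm applies them:

- **Membership check**: every position where the decoded letter differs
  from the inferred letter must carry a letter from that position's top-m
  alternative set. Solutions found by the substitution search are checked
  in-line; failures are excluded and the search continues. If the search
  then exhausts, the first rejected solution is returned *flagged* rather
  than discarded — the flag, not the rejection, is the durable signal.
  An immediate hard-decision success is only flagged, never rejected, at
  block level: the membership test has a real false-alarm rate (the truth
  sits outside the top-2 set in ~0.3% of corrections), and rejecting a
  correct codeword strands the block.
- **CRC32**: each matrix of 10 blocks carries a 32-bit checksum over its
  payload bits. Only a CRC failure triggers re-decoding, and only of
  flagged / soft-searched blocks, with their accepted codewords excluded,
  for up to `max_block_passes` (default 3) rounds. The CRC thus arbitrates
  the membership check's false alarms. An exhausted block short-circuits
  the passes (re-running an identical search cannot improve).

Standalone block decoding (no CRC available) exposes the same loop as
`decode_block_validated`, with membership as the only arbiter.

## Archive layout

A matrix = 10 consecutive RS(45, 41) blocks = 410 information symbols of
m = log₂|Σ| bits each. The byte stream (4-byte big-endian length prefix +
payload, zero-padded) is cut into chunks of 410·m − 32 bits per matrix;
each chunk's CRC-32/ISO-HDLC (the zlib polynomial 0x04C11DB7, reflected,
init/xorout 0xFFFFFFFF) occupies the last 32 information bits. Bits map to
symbols big-endian, left to right; positions are 0-based everywhere. For
|Σ| = 256 this gives 406 payload bytes per matrix; for 64 and 128 the
per-matrix payload is not byte-aligned and the stream is treated as a bit
stream (CRCs are computed over the chunk packed MSB-first with zero pad).
Where the CRC lives is not specified by the method description; this
placement is a compatible reconstruction. Non-power-of-two alphabets (the
full Φ_6 of 84 letters, the six-letter in vitro set) are first-class for
inference, libraries and letter-level experiments but are excluded from
the byte codec: RS with symbol = letter over a 6-letter alphabet cannot
reach block length 45.

Failed matrices are counted and zero-filled in the output stream.

## Report metrics

With ground truth supplied, `DecodeReport` carries three ratios (the
method names them without formulas; these are the definitions used here):

- **letter inference accuracy** — fraction of all positions whose MAP call
  equals the stored letter;
- **position prediction accuracy** — among truly erroneous positions in
  blocks that entered the soft search, the fraction present in the final
  candidate position set;
- **true-letter prediction accuracy** — among those covered positions, the
  fraction whose alternative set contains the stored letter.

## Constructed error fixtures

Capability probes need blocks with exactly e letter errors that the soft
decoder is *supposed* to handle: erroneous positions ranked worst by
reliability and true letters inside the alternative sets. A fixture takes
a random codeword, samples clean counts for every position (re-drawing any
that mis-infer), then at e chosen positions replaces the counts with a
blend (1 − λ)q(truth) + λq(w) rounded to integers, where w is a letter
whose top alternative is the truth and λ is the smallest grid value that
flips inference to w. Sitting just past the decision boundary maximises
the reliability distance subject to inferring w. Clean positions that
still out-rank a constructed error are re-drawn (the ranking is the
fixture's defining property, not any particular clean realisation), and
the construction asserts all three properties before returning.

## Synthetic data: what it does and does not show

The generator *is* the study condition: multinomial sampling at depth N
from the per-letter base distributions with p = 0.01, the depths 490×/190×
for the 256-/64-letter codes, RS(45, 41), 10 blocks + CRC32 per matrix.
Passing tests show the codec and decoder behave as designed under that
channel. They do not show robustness to what real sequencing adds:
indels that desynchronise positions, neighbour-dependent error rates,
non-uniform read coverage, PCR amplification bias, or synthesis-ratio
drift. Measured letter-error rates here are accordingly lower than the
in vitro tables of the original study at equal depth; comparisons against
those in vitro numbers are out of scope (the underlying reads are not
bundled or fetched).

## Problem sizes and numerical choices

- Depth sweeps: 50 matrices per configuration in the acceptance script,
  20 in the test suite (≈ 0.9 and 2.3 MB-scale archives respectively,
  standing in for the original 20.8 MB corpus); payloads are seeded
  pseudo-random bytes.
- Capability probes: 50 fixtures per error count, e scanned up to the
  candidate-set cap of 8.
- Monte-Carlo libraries: 2 × 10⁴ draws/letter for decoding, 4 × 10³ for
  subset selection (a ranking needs less precision than a probability).
- Exact-build guard: 10⁸ scored pairs. Score-matrix chunking keeps peak
  memory modest on large enumerations.
- log q underflow is clamped (−10³⁰ stands in for log 0) so p = 0 channels
  stay finite; zero-probability observations still score −∞ in the scalar
  path where that is the mathematically right answer.
- All randomness flows through seeded numpy Generators; every CLI command
  and experiment takes a seed and reproduces byte-identical outputs.

## Known limitations

- No indel modelling or alignment; the channel is strictly positional.
- The byte codec requires power-of-two alphabets; 84- and 6-letter systems
  are letter-level only.
- The membership check's false-alarm handling relies on the matrix CRC;
  a standalone block decode can still discard a correct codeword in the
  ~0.3% of corrections whose truth falls outside the top-m set (raising m
  trades search breadth for that risk).
- Transition libraries are built per exact depth; there is no
  interpolation across depths.
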