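# Methods

## Problem setting

Automated model building in cryo-EM maps produces, per traced residue, a
probability distribution over amino-acid identities and a confidence
score. When the map contains chains of unknown identity, those
predictions can identify the protein: the per-chain predictions are
compiled into a profile HMM and searched against a proteome. `densid`
implements that identification path, the post-processing that turns raw
traces plus search results into a finished model, and the metric suite
used to judge built models. The neural networks that produce the
predictions are out of scope; a synthetic generator with a controlled
noise model stands in for them.

## Profile HMMs from predictions

A profile HMM normally comes from a multiple sequence alignment; here the
match emission of node i is the predicted probability row P(i) directly,
and the transitions are a fixed function of the predicted confidence
c(i) ∈ [0, 1]:

- M→M(i) = max(c(i) − d, m_min); M→I(i) = M→D(i) share the remainder
  equally;
- I→M(i) = D→M(i) = 1 − d; I→I(i) = D→D(i) = d; I→D = D→I = 0.

Defaults are d = 0.5 and m_min = 0.5. As printed, max(c − 0.5, 0.5) = 0.5
for every c ∈ [0, 1], so at the defaults M→M is constant and the profile
ignores confidence; this is implemented literally and flagged in the API
docs, and both parameters are exposed (d = 0.2, m_min = 0 restores
c-dependence). Insert emissions are the background distribution —
standard profile-HMM practice; the predictions specify match emissions
only. The background defaults to uniform (1/20), which keeps closed-form
test values exact; a Swiss-Prot-like composition is selectable.

Boundary nodes: the begin state reuses node 1's transition values (the
serialized node-0 line), and the final node's match state exits to the
end state with probability 1, which is also what the HMMER3 file format
expects on its last node row (its M→D and D→D fields are `*`).

Serialization uses the HMMER3/f text dialect: scores are negative natural
logs of probabilities, probability 0 is `*`, probability 1 is `0.00000`.
Files round-trip within 1e-5 on every probability and are accepted by
stock HMMER 3.4 and by pyhmmer's parser (both used as independent
cross-checks in the tests; neither is used by the implementation).

## Search engine

Scoring follows the local-alignment "implicit probabilistic model" used
by HMMER-style tools: an alignment may enter the profile at any node
(uniform entry probability 1/L) at any sequence position, exits freely
from any match state, and flanking residues are emitted at background so
they cancel exactly against the i.i.d. background null. Scores are
log2-odds (bits); Forward sums over all paths, Viterbi takes the best
path with ties broken by state priority M > D > I for reproducibility.
All arithmetic is in log space with −inf as the zero-probability
sentinel; the dynamic programming kernels are numba-compiled. The engine
is verified against an exhaustive path-enumeration oracle (pure Python,
independent of the kernels) on all profiles with L ≤ 3 and sequences of
length ≤ 4, to 1e-9 bits. Ambiguous residues (X) emit background in all
states, scoring zero bits.

E-values come from a Gumbel fit (`scipy.stats.gumbel_r`) to Forward
scores of n seeded random background sequences (default n = 1000,
length 100); E = |database| × survival(bit score). Ranking is invariant
to the calibration curve, so the seeded recovery benchmarks use the
minimum n = 100 to keep 100-trial runs near two minutes. No
length-dependent null correction is applied; decoys of similar length to
the host sequences make the benchmarks fair, but E-values for databases
with very heterogeneous lengths are approximate. Cross-referencing of
pseudo-symmetric copies groups chains by best-hit target and sums bit
scores, so several individually marginal hits to one target reinforce
each other.

## Post-processing

- Matched residues (M states of the winning hit's Viterbi alignment) are
  mutated to the target letter and keep the aligned position; unmatched
  residues keep their argmax-probability identity (a flag converts them
  to UNK instead).
- Chain connection merges fragments assigned to the same target when
  their matched ranges are disjoint and in order with gap g ≥ 0 and the
  upstream-to-downstream terminal anchor distance is ≤ 3.8 Å × (g + 1) —
  3.8 Å being the Cα virtual bond. Merging is greedy by ascending gap,
  then distance, until stable; the ordering is a determinism choice, the
  distance rule an interpretation of "proximity". Note an ideal helix's
  virtual bond is 3.83 Å, so gap-0 connection of perfectly ideal
  fragments wants a slightly larger allowance; the parameter is exposed.
- Pruning removes chains shorter than 4 residues and runs after
  connection so connectable short fragments survive.
- The predicted backbone RMSD maps to the stored confidence as
  clamp((1.2 − r) / 0.7, 0, 1): 1 at 0.5 Å, 0 at 1.2 Å, linear between,
  saturating outside. The score is written into the B-factor column
  (identity mapping, 2 decimals in PDB).
- The residue k-NN graph links each residue to its 20 nearest anchor
  atoms (Cα/P), ties broken by lower index; systems with n ≤ k get n − 1
  neighbours.

## Metrics

Residue correspondence is mutual-nearest-neighbour pairing of anchor
atoms under a 3 Å cutoff (the cutoff is stated by convention; the
assignment scheme is a design choice — mutual NN is symmetric and needs
no global optimizer). RMSDs pool squared per-atom distances over all
pairs with no superposition, since compared models share the map frame.
Recall, precision, amino-acid accuracy and completeness follow the
definitions above; identical formulas apply to nucleotides with P
anchors, the (OP1, P, OP2, O5') backbone set and base identity.

Q-score: for each atom, map values are trilinearly interpolated at
deterministic points (Fibonacci sphere, 8 per shell) on concentric
shells of radius 0 … 2.0 Å in 0.1 Å steps, excluding points closer to
another atom than to the evaluated one, and Pearson-correlated with the
ideal falloff exp(−r²/2σ²), σ = 0.6 Å by default. All numeric details
are exposed as parameters. Atoms within r_max of the map edge are
skipped and counted. Pearson correlation makes the score invariant to
affine rescaling of map values.

FSC: the normalized cross-correlation of two maps' Fourier transforms in
radial frequency shells (default width one reciprocal box length),
reported with the 0.5-crossing frequency when present. Model-to-map FSC
uses the Gaussian renderer below for the model map — an admitted
simplification of scattering-factor rendering.

## Synthetic data

The generator defines the conditions under which everything is tested:

- **Structures** are ideal α-helices (rise 1.5 Å, twist 100°, Cα radius
  2.3 Å, idealized N/C/O offsets), giving the 3.8 Å Cα spacing real
  chains have, laid out on a grid with seeded axial rotations.
- **Profiles** mix the one-hot true identity with uniform noise:
  P(i) = (1 − η)·onehot + η/20, confidences Uniform(lo, hi). η is the
  single noise knob: 0 is a perfect predictor, 1 carries no information.
  Benchmarks run at η = 0.5 (identification, 200 residues, 100 decoys)
  and η = 0.3 (33-residue fragment of a 400-residue target), with 100
  seeded trials each.
- **Proteomes** embed each true sequence inside a longer random host
  (20–100 extra residues) among i.i.d. decoys; ids and descriptions
  record the ground truth.
- **Maps** are sums of unit Gaussians at atom positions, truncated at
  4σ.
- **Perturbations** add i.i.d. Gaussian coordinate jitter (RMSD recovers
  σ√3) and resample identities at a given error rate.

Every generator is a pure function of its seed. What this does *not*
emulate: realistic cryo-EM noise spectra and resolution gradients,
correlated prediction errors between neighbouring residues, homologous
(rather than random) decoys, and nucleic-acid probability profiles.
Passing benchmarks therefore demonstrate the correctness and statistical
behaviour of the machinery, not identification rates on real maps —
E-values on real proteomes additionally depend on the search tool's own
calibration.

## Numerical choices and problem sizes

Exact algebraic identities (transition row sums) are asserted to 1e-12;
serialization round-trips to 1e-5 (5-decimal score quantization);
DP-vs-oracle agreement to 1e-9 bits. The test suite and benchmarks use
deliberately modest sizes — 100-trial benchmarks, ≤ 200-residue
profiles, ≤ 64³ maps — chosen so a full run stays within minutes on one
CPU while keeping binomial error bars well inside the asserted margins.

## Known limitations

- At default d = m_min = 0.5 the transition table is
  confidence-independent (implemented as printed; see above).
- Single-hit local alignment only: no multi-domain (multihit) model, no
  biased-composition correction.
- E-value calibration is per-profile Monte Carlo, not a fitted analytic
  relation; very short profiles (L ≤ 2) can have coarse tails.
- Chain connection uses Euclidean termini distance, not path-through-
  density.
- Q-score parameters follow common practice but are not fitted to any
  experimental resolvability scale.
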