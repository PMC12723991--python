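# Methods

This note records the models implemented by `structland`, the parameter
choices that matter, and what the synthetic study conditions do and do not
establish.

## Alphabets and encoding

Both built-in alphabets (amino-acid and 3Di) carry 20 residue-like states
plus a gap, `q = 21`, with the gap at the last index.  Aligned sequences
necessarily contain gaps, so the gap is a first-class state everywhere: in
the one-hot input (`q × L` per sequence, exactly one 1 per column), in the
decoder's softmax output, and in the Potts model.  Amino-acid input is
upper-cased and 3Di input lower-cased before validation; the
unknown-residue character `X` is remapped to the gap with a logged warning
count rather than rejected, since real alignments contain it.

Unaligned 3Di strings produced by an external amino-acid→3Di translator
are brought into MSA coordinates by `project_onto_alignment`: each 3Di
symbol is placed at the corresponding amino-acid row's non-gap columns and
gaps are copied from the amino-acid row, so the projected alignment shares
the source alignment's exact gap mask.

## Pairwise identity

Percent identity uses a global Needleman–Wunsch alignment with match = 1,
mismatch = 0, linear gap = −1 (configurable), and identity =
100 × matches / alignment length, gap columns included in the denominator.
Among co-optimal alignments the tie-break maximizes score, then matches,
then minimizes alignment length — implemented as a lexicographic dynamic
programme, which is exact because every transition adds a constant tuple
and lexicographic order is translation-invariant.  Because that objective
is symmetric in the two sequences, identity is guaranteed symmetric, which
a fixed-traceback aligner does not provide.  Identity values in this
package are used comparatively (reweighting, cluster statistics), so the
simple scoring convention is sufficient.

## Mean-field DCA

Sequences are reweighted by `w_n = 1/|{m : identity(n,m) ≥ θ}|` with
θ = 0.8 (standard DCA practice; configurable), giving the effective depth
`Meff = Σ w`.  Single-site and pair frequencies get a uniform pseudocount
λ = 0.5 (the canonical mean-field default; λ > 0 is required for
invertibility): `f_i = λ/q + (1−λ)·f̂_i`, `f_ij = λ/q² + (1−λ)·f̂_ij`,
with diagonal blocks forced to `f_ii(a,b) = f_i(a)·[a = b]`.

Couplings come from inverting the connected-correlation matrix
`C_ij(a,b) = f_ij(a,b) − f_i(a) f_j(b)` restricted to the q−1 non-reference
states per site (the gap is the excluded reference; any choice is
gauge-equivalent): `e_ij = −(C⁻¹)_ij`, zero-padded on the reference state,
symmetrized, with `e_ii = 0`.  Fields are set self-consistently from the
single-site frequencies, `h_i(a) = ln f_i(a)/f_i(ref) − Σ_j e_ij(a,·)·f_j`.
Models are returned in zero-sum gauge (couplings with vanishing row and
column sums, fields zero-mean), which leaves all Hamiltonian differences
invariant and makes energies comparable across models.

Mean-field inversion is accurate in the small-coupling regime; the unit
tests validate it against an exhaustively enumerated two-site distribution
at coupling 0.1, where the relative error is at the percent level.  It is
not expected to recover strong couplings quantitatively — only their
ranking, which is what contact prediction uses.

Direct information for a pair (i, j) is the mutual information of the
two-site direct distribution `P_dir(a,b) ∝ exp(e_ij(a,b)) ĥ_i(a) ĥ_j(b)`,
with auxiliary fields fitted by alternating marginal matching (a
Sinkhorn-style fixed point; tolerance 1e-6 on the worst marginal mismatch,
maximum 500 iterations, which converges in a handful of iterations for all
models exercised here).  DI ranking is used as-is — no average-product
correction — and the long-range filter keeps pairs with |i−j| > 4.

## VAE

The architecture is deliberately minimal: encoder
`q·L → 3L ReLU → (μ, log σ)` and decoder `2 → 3L ReLU → q×L logits` with a
position-wise softmax.  The latent prior is N(0, I); sampling uses
`z = μ + σ⊙ε`.  The log-σ head is exponentiated for positivity and clipped
to ±10 for numerical stability.  Initialization is seeded Glorot-uniform.

The minimized loss is categorical cross-entropy of the input states under
the decoder, summed over positions and averaged over the batch, plus the
closed-form Gaussian KL averaged over the batch.  This reduction (sum over
positions, mean over batch) makes reported magnitudes proportional to L.
Optimization is Adam (β₁ = 0.9, β₂ = 0.999) with learning rate 1e-4 and L2
weight penalty 1e-4 by default, batch size 64.  The L2 penalty enters the
gradients but not the reported loss components, so the report's
`total = reconstruction + kl` identity holds exactly.  Early stopping
monitors the epoch-mean training loss (no validation split), halts after
50 epochs without improvement, and restores the best-loss parameters.
Training is bit-reproducible given (seed, config, data) on a fixed numpy
build.  Since the network is a single hidden layer per side, the forward
and backward passes are plain numpy matrix algebra with a hand-written
Adam step; no deep-learning framework is involved.

Per-position argmax decoding breaks ties toward the lowest state index,
deterministically.

## Landscapes

The grid spans the bounding box of the embedded μ coordinates plus a 10 %
margin, 100×100 by default (50×50 in the test suite for speed); a
degenerate zero-range dimension falls back to a unit box with a warning.
At each node the decoder distribution is computed, the argmax sequence
extracted and scored by the Potts Hamiltonian, and the mean per-position
Shannon entropy recorded using the natural log over all q = 21 states
(0 ≤ Ĥ ≤ ln q), with 0·ln 0 = 0.

The radial-exclusion analysis pairs each training sequence's own
Hamiltonian with the Hamiltonian of the sequence decoded at its μ, then
recomputes Pearson R after excluding sequences within radius r of the
latent centre.  The centre defaults to the origin — the prior mean, where
decoder entropy peaks — with the entropy-surface argmax available as an
alternative.  R is reported as undefined when fewer than 3 sequences
remain (or when either Hamiltonian set is constant).  In the packaged
experiments the radius grid spans from 0 to the 90th percentile of
μ-distances, so every evaluated radius retains a meaningful sample for the
correlation estimate.

Low-energy selection returns the grid cells in the lowest Hamiltonian
quantile, ascending by H (stable order on ties), as (latent coordinate,
decoded sequence) pairs; translating decoded 3Di sequences back to amino
acids is left to an external adapter.

## Contacts

A contact is a residue pair whose Cβ atoms (Cα for glycine) lie within an
inclusive 8.0 Å cutoff and whose separation exceeds 4 positions.  The
first model and first chain are used unless told otherwise; residues
missing the representative atom fall back to Cα or are skipped with a
warning.  Structure residue numbers are taken as the 1-based MSA/model
coordinates; an explicit mapping can be layered on top when the two
numbering systems differ.  Performance is TPR = true positives / pairs
taken over the top `round(x·L)` DI-ranked long-range pairs for
x = 0.1 … 3.0 in steps of 0.1, capped by the number of available ranked
pairs.  The subsampling evaluation redraws sequences without replacement
at each requested depth and re-runs the whole weights → statistics →
inversion → DI pipeline per replicate.

## Synthetic study conditions

The generator defaults define the packaged experiments:

- Planted family: L = 30, q = 4, 10 planted pairs with |i−j| > 4, coupling
  strength 1.0 concentrated on one preferred state pair per coupling (in
  zero-sum gauge), field scale 0.3, M = 2000 Gibbs samples.  The reduced
  q = 4 keeps enumeration oracles and repeated fits fast while preserving
  the structure of the inference problem; q = 21 runs through the same
  code paths.
- Gibbs sampler: one independent chain per output sequence, uniform random
  initialization, 500 burn-in sweeps by default with a fixed site order and
  exact full conditionals.  Thinning is accepted for interface
  compatibility but is irrelevant across independent chains.  The kernel
  is numba-compiled; exactness is verified against exhaustively enumerated
  distributions on all (L ≤ 3, q ≤ 3) fixtures.
- Two-cluster family: shared planted-coupling topology, per-cluster field
  displacement of scale 2.0 ("high" divergence), 150 sequences per
  cluster.  This yields within-cluster identity well above between-cluster
  identity and a VAE latent space in which the clusters are linearly
  separable.
- Toy structures: Cα chains relaxed by gradient descent from an extended
  conformation so that requested long-range pairs come inside the contact
  cutoff and all other long-range pairs stay outside it; Cβ atoms are
  placed 1.53 Å from Cα away from the local chain axis; requested glycine
  positions omit Cβ to exercise the Cα fallback.  Requests the geometry
  cannot satisfy raise an error listing the offending pairs.

What these fixtures do **not** emulate: real 3Di state statistics,
phylogenetic correlation between sequences (samples are i.i.d. from the
Potts distribution, so reweighting is nearly inert), alignment errors, or
realistic fold geometry.  Passing tests therefore demonstrate correctness
of the machinery and recoverability of planted signal — not field
performance on natural families, which depends on MSA depth, diversity and
alignment quality.

## Numerical choices and degenerate inputs

- Pseudocount λ > 0 is required by the inversion; a singular correlation
  matrix raises an error advising a larger λ.
- DI values are clipped at 0 against −1e-12-scale floating-point noise.
- Argmax ties (decoder, DI ranking) break deterministically (lowest index,
  lexicographic pair order).
- Empty alignments, ragged rows, out-of-alphabet characters, and
  projection length mismatches raise errors naming the offending record
  and column.
- Pearson R is undefined (NaN) for fewer than 3 points or zero variance.

## Known limitations

- Mean-field inversion underestimates strong couplings; only DI *ranking*
  should be interpreted.
- The VAE trains full-batch epochs in numpy on one CPU; it is sized for
  alignments of hundreds-to-thousands of rows and L up to a few hundred,
  not for very deep families.
- The landscape Hamiltonian and the contact-prediction DCA share one
  reweighting/pseudocount configuration.
- Generated sequences are 3Di (or amino-acid) argmax decodes; no
  back-translation or structure prediction is performed here.
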