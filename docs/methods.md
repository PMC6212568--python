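# Methods

## Model

The generator is a conditional variational autoencoder over fixed-width
one-hot protein sequences. A sequence of up to `max_length` residues
(default 140) is encoded over a 22-symbol alphabet — the 20 standard
amino acids in alphabetical one-letter order, a wildcard `X` for any
non-standard residue (selenocysteine and friends map here), and a
padding symbol `-` that right-pads to the maximum length — and flattened
to a vector of `22 × max_length` entries (3080 at the default length).
The conditioning attribute `a` is concatenated to the input: 8 binary
metal flags in the fixed order Fe, Zn, Ca, Na, Cu, Mg, Cd, Ni, or the
1265-entry one-hot rule encoding of a fold topology (below).

Both networks are built from linear blocks `LB(x) = ReLU(BN(Wx + b))`.
The encoder stacks three blocks of 512, 256 and 128 units and ends in
two affine heads over a 16-dimensional latent space: `μ = Lin(h)` and
`σ² = softplus(Lin(h))` (a floor of 1e-8 keeps `1/σ²` finite). The
decoder mirrors the widths (128, 256, 512) on the concatenation `[z, a]`
and ends in an affine layer with a sigmoid, giving a soft reconstruction
in (0, 1)^3080. Batch normalization uses batch statistics during
training and accumulated running statistics at inference, so encoding or
generating a single sequence is always well defined.

Training minimizes the negative single-sample ELBO per datum:
summed elementwise binary cross-entropy between the sigmoid output and
the one-hot target (the Bernoulli likelihood matching the sigmoid
output; a per-position categorical likelihood would be the natural
alternative but would not match the stated sigmoid architecture), plus
the closed-form Gaussian KL to the standard-normal prior,
`Σ_d ½(μ_d² + σ_d² − 1 − ln σ_d²)`. The KL term is multiplied by a
burn-in factor that ramps linearly from 0 to 1 per optimizer step over
`kl_burnin_epochs` worth of steps (default 100 epochs), preventing the
KL penalty from switching latent units off before the reconstruction
has taken shape. The optimizer is Adam with learning rate 5e-4, batch
size 512 and both moment-decay constants set to 0.9 — the second moment
decay is deliberately nonstandard and kept configurable. Convergence is
declared when no epoch improves the best epoch-mean loss by more than
`tol = 1e-4` (relative) within a 10-epoch patience window, counted only
once the burn-in has reached 1 so the ramp-induced loss increase never
triggers a stop. Weights are initialized fan-in-scaled normal from a
seeded generator; initialization, shuffling and reparameterization noise
all derive from `random_state`, so runs replay exactly.

Decoding takes the argmax of each 22-wide block (ties break to the
lowest symbol index), strips the trailing padding run, and maps any
interior padding argmax to the wildcard so that positional
correspondence with the input frame survives for motif analysis.

## Topology grammar

Fold topologies follow the "periodic table" description of protein
structure: an ordered list of secondary-structure elements, each with an
orientation sign, a layer letter A–D and a signed position token (+0 to
+6, −1 to −6; −0 does not exist). The context-free grammar has five
nonterminals and exactly 22 productions — 2 topology rules
(recurse/terminate), 1 element rule, 2 orientation rules, 4 layer rules
and 13 position rules — frozen in that order, so every rule has a fixed
index. The canonical derivation is leftmost and expands each element
fully (topology rule, element rule, orientation, layer, position —
five rules per element) before moving right; it is unique given the
string, and a k-element topology always derives in exactly 5k rules.
With a capacity of 55 rule slots, topologies of up to 11 elements are
encodable; longer ones are rejected. Each slot is one-hot over 23
options (22 productions plus a blank padding rule), giving the
55 × 23 = 1265 conditioning vector. Parsing ignores whitespace and
accepts typographic minus signs, emitting ASCII on output, because
topology strings in print mix both typographies.

## Dataset construction rules

`data_prep` operates on already-provided records (a FASTA file plus a
TSV manifest); querying structure or sequence databases is out of scope.
Three construction rules for metal-binding corpora are implemented:

- **Negative examples.** For every metal-binding sequence a twin is
  added whose annotated binding residues are resampled from the
  training set's overall amino-acid composition and whose flags are
  zeroed. The draw is a plain background sample with no exclusion of
  the original residue, so a resampled site can retain its native
  identity by chance; the identity-matching propagation rule below is
  consistent with that choice.
- **Homologue propagation.** A homologue aligned to a mutated native
  position receives the same replacement residue if and only if it
  currently carries the same amino acid as the native sequence at that
  column.
- **Length filter.** Homologue hits are kept when their length is
  within 80–120 % of the query and at most 140 residues.

Residue indexing is 0-based throughout; only the PDB reader converts at
its boundary.

## Discriminator

The candidate-ranking classifier maps the same 3080-entry input through
six layers of 1024, 512, 256, 128, 64 and 8 units — the first five are
linear blocks, the last is affine with a sigmoid — and predicts the
8-metal flag vector. The loss is binary cross-entropy with per-metal
weights proportional to the inverse of each metal's positive count,
normalized to average 1 so the loss scale is unchanged (the
normalization is a package choice; only "inverse ratio" is prescribed).
Predictions are clamped at 1e-7 for stability. Validation is
family-disjoint: families are atomic in the 90/10 split, packed
greedily largest-first to approach the requested fraction, and
designated hold-out sequences drag their whole family into validation.
Early stopping saves a checkpoint every epoch and restores the one with
the lowest validation loss.

## Sampling procedures

*Metalloprotein task*: the input sequence is encoded once with the
(possibly modified) attribute; 1,000 latent vectors are drawn from the
posterior by reparameterization (`z = μ + σ·ε`) and decoded with the
same attribute. The discriminator then ranks the pool for the requested
metal, descending, with stable ties.

*Structure task*: round 1 draws 1,000 latent vectors from the
standard-normal prior, conditioned on the topology encoding. (The
first round could equally sample the posteriors of training sequences;
the prior is the design choice here because it surveys the whole latent
space and needs no training data at hand.) A
pluggable scorer — lower is better — ranks the pool; the external
threading/relaxation/fold-comparison stages of a full pipeline sit
behind this interface (`CommandScorer` adapts any executable reading
FASTA and writing a TSV of scores), and a Hamming-distance mock is
provided for testing. Each later round encodes the incumbent best
sequence and samples its posterior neighbourhood. The incumbent is
always added to the round's candidate pool (elitism); this is implied
rather than stated by the iterative protocol, and making it explicit
turns "the best score never worsens" into an invariant the code
asserts. The shortlist of the top 5 candidates per round is recorded
for multi-candidate hand-off. Scorer failures skip the candidate with a
warning rather than aborting a multi-hour search.

## Analysis metrics

- **His-x3-His scan**: all pairs (i, i+4) of histidines; with a
  secondary-structure string, both positions must be helical (H/G/I).
  Either predicted or template-derived annotations are accepted.
- **Close histidines**: histidine pairs with sequence separation ≥ 2
  whose representative coordinates on a template structure are within a
  cutoff. The cutoff defaults to 7 Å — a typical metal-coordination
  screening distance — and is configurable, as is unavoidable for a
  quantity with no canonical definition. The representative coordinate
  is the side-chain centroid (heavy atoms), falling back to the
  alpha-carbon for glycine or stripped residues.
- **Conservation**: per alignment column, Jensen–Shannon divergence
  (half-mixture form, log base 2, hence values in [0, 1]) between the
  column's amino-acid distribution and a background — the training-set
  composition by default, uniform on request. Gaps are excluded from
  the column distribution; columns over 50 % gaps are flagged rather
  than dropped.
- **Sequence identity**: position-wise for equal lengths; otherwise
  identical pairs over alignment columns of a global Needleman–Wunsch
  alignment (match +1, mismatch 0, gap open −1, extend −0.5).

## Synthetic data

The generator emulates the statistical structure of a PDB-plus-homologue
harvest without any download: each family has a uniform-random consensus,
up to 50 homologues (the per-structure cap used when harvesting real
homologues) that keep each position with probability `conservation`
(default 0.8, a plausible within-family identity for significant
sequence hits) and otherwise redraw it uniformly, a planted three-residue
coordination motif tied to the family's metal flag (for copper:
His-x3-His plus cysteine; anchors are distinct per metal so signals never
collide), topology labels drawn from the grammar — optionally from a
pool smaller than the family count, so several families share a fold as
real fold space does — and negative twins built by the real
dataset rule. Homologue mutations are independent per position:
residue covariation is deliberately absent, since the modelling approach
itself does not reproduce covariation and planting it would test nothing
the model can learn. Consequently, passing tests demonstrate recovery of
independent per-position and attribute-linked signals, not of epistatic
structure in real families.

## Problem sizes and numerical choices

Tests and examples run reduced configurations chosen to exercise every
mechanism at desk scale: 60-residue sequences, hidden widths
(128, 64, 32), ~500–2,000 records, a few hundred epochs of full-batch or
near-full-batch Adam. At this scale the metal-conditioned model reaches
near-perfect reconstruction of its training families and a
planted-motif frequency gap above 0.3 between flag-on and flag-off
generation; the discriminator reaches held-out per-metal AUROC ≥ 0.9 on
family-disjoint splits. Degenerate inputs are handled explicitly:
decoding is total on arbitrary real vectors, argmax ties break low,
empty derivations and over-capacity topologies are rejected, σ² is
floored, BCE inputs are clamped, and non-finite losses abort training
with the epoch index.

## Known limitations

The NumPy implementation is single-threaded BLAS-bound and is not meant
for the 148,000-record scale of a full PDB-derived corpus; interfaces
(checkpoints, manifests, scorer adapters) are designed so a GPU
implementation could be swapped in behind the same estimator surface.
Structure-based scoring, molecular dynamics, secondary-structure
prediction and homology search are out of scope; the scorer interface
and the secondary-structure argument of the motif scan are the points
where external tools plug in. Generated sequences inherit the i.i.d.
assumptions of the training corpus — no covariation — and the
conditioning vector must come from the same frozen alphabet, metal order
and rule order recorded in each checkpoint.
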