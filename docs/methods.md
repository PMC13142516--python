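# Methods

## Model

`pairsite` predicts, for every residue of a query protein, the probability
that it participates in the interface with a given partner protein.  Inputs
are per-residue embedding matrices `E_A` (query, L_A × d) and `E_B`
(partner, L_B × d).  One unilateral multi-head cross-attention layer
computes per-head attention `softmax(Q_h K_h^T / scale)` with queries
projected from `E_A` and keys/values from `E_B`; the per-head contexts are
concatenated and passed through a learned output projection, LayerNorm, and
a two-layer MLP (linear → ReLU → dropout → linear) ending in a sigmoid.

Design choices where the architecture description leaves freedom:

- **Head realisation.** The attention equations are written single-matrix
  but the head count is fixed at 16; we implement the standard head split
  (head_dim = d/16) with a learned d × d output projection, consistent with
  the parameter accounting that places "output projections" inside the
  attention block.
- **Attention scale.** Default `per_head_sqrt` (√head_dim, standard
  multi-head practice); `full_dim_sqrt` (√d, the form in which the
  equations are usually printed) is selectable.  The choice affects neither
  parameter counts nor any invariant.
- **No residual connection** by default: the equations route query
  information only through the attention weights, which is also what makes
  the scrambled-partner control meaningful.  An optional residual flag
  exists but is off.
- **MLP hidden width = d.** This is the only width that reproduces the
  published totals: 4(d²+d) + 2d attention parameters plus
  (d·d + d) + (d + 1) MLP parameters give 8,202,241 ≈ 8.20 M at d = 1280,
  with an 80.0 : 20.0 attention:MLP split.
- **Initialisation**: scaled-uniform fan-in weights, zero biases, unit
  LayerNorm gain, explicit seed.  The output (logit) bias is configurable;
  initialising it to the imbalance logit log(π/(1−π)) is used in the
  reduced-scale studies (and is consistent with the strongly negative
  output biases reported for trained full-scale models).
- **Dropout** 0.10 by default, applied to the MLP hidden activations,
  training only.
- **Numerics**: softmax with max-subtraction; LayerNorm ε = 1e-5; BCE
  probability clamp 1e-7.  The forward pass is verified against an
  independent dense-loop implementation to ≤1e-6 and the analytic gradients
  against central finite differences.

The implementation is pure NumPy, including backpropagation and Adam; at
the scales this package trains (d ≤ 64, hundreds of pairs) a deep-learning
framework is unnecessary and exact reproducibility is easier to guarantee.

## Training

Binary cross-entropy over residues, one pair per optimisation step
(variable lengths, no padding), Adam (default lr 1e-4, config-exposed) with
optional decoupled weight decay on weight matrices only.  Validation loss
is evaluated each epoch; strict improvement resets the patience counter;
training stops after 10 epochs without improvement or 50 epochs total, and
the parameters of the best validation epoch are returned.  Class imbalance
is *not* reweighted by default (plain BCE); an optional positive-weight
flag exists.

## Chunked inference

Embedder context is bounded (1,022 residues for the ESM-2 checkpoint the
adapter targets).  Sequences longer than the window are cut into
overlapping windows with stride 512; the final window is end-aligned at
max(0, L − window) so no residue is dropped and no padding is fabricated.
Every query window is run against every partner window and per-residue
probabilities are combined by max pooling over all covering combinations —
the minimal rule that degenerates bit-exactly to direct prediction for
single-window inputs and is monotone in added windows.  Max pooling over
partner windows before or after query aggregation is equivalent under max.
`predict_long_pair` slices chunk views from full embedding matrices; for
the synthetic and file backends (position-local embeddings) this is
identical to re-embedding each chunk, which is what a PLM backend would do
through the same `ChunkPlan`.

## Interface labeling

A focal-chain residue is an interface residue when
RSA_isolated − RSA_in_complex > 4 (percentage points, strict).  SASA uses
the Shrake–Rupley method: 960 deterministic Fibonacci-lattice sphere points
per atom, probe 1.4 Å, per-element van der Waals radii
(C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å), hydrogens, waters and hetero
records excluded, highest-occupancy alternate conformers retained.  RSA
normalises per-residue SASA by the Tien et al. (2013) theoretical maximum
accessible areas (generic 200 Å² fallback for unknown residue types, with a
warning).  The normalisation table is configurable because published
RSA-based labeling protocols do not always state their reference.
Structure-derived labels transfer to full-length parent sequences by global
pairwise alignment; labels aligned to gaps are dropped (counted and
warned), and mappings below 90% identity over the structural residues are
rejected, mirroring the curation filter.

## Dataset curation

Pair records are kept when they reference exactly one parent accession,
match it at ≥90% identity, are not antibody–epitope complexes (an input
metadata flag, not computed), and have peptide ligands of ≤30 residues.
Focal proteins are clustered greedily longest-first (CD-HIT style): a
sequence joins the first cluster whose representative exceeds 25% pairwise
identity, else founds a new cluster.  Pairwise identity is identities on
the best Smith–Waterman alignment (BLOSUM62, gap open 11 / extend 1)
normalised by the shorter sequence length — the CD-HIT convention.
Normalising by local-alignment length instead is degenerate: two unrelated
proteins sharing a single high-scoring residue pair (e.g. W–W) align over
one column at 100% identity and everything merges.  The alignment recipe
behind the published 25% threshold is unstated, so this is a documented
stand-in chosen to be inclusive toward locally similar regions.

Whole clusters are assigned to train/validation/blind subsets at 60:10:30
(largest-remainder apportionment over clusters, seeded shuffle), so all
pairs of a focal protein — and all of its >25%-identity relatives — land in
one subset.  Grouped 5-fold cross-validation deals clusters round-robin
into five blind folds and splits the remainder 70:10, giving 70:10:20 per
fold.  Leakage-freedom is asserted programmatically.  Peptide disorder
classification consumes a 3-state (H/E/C) secondary-structure string and
flags ≥75% coil (inclusive); no secondary structure is computed from
coordinates.

## Evaluation

Residue-level metrics at an inclusive 0.5 probability cutoff: accuracy,
recall, precision (percent), F1, MCC, plus rank-based AUROC (ties one
half) and PRAUC by stepwise interpolation over recall.  Metrics are
micro-averaged (residues pooled across pairs), which is the convention
under which published dataset-level rows close internally: printed
recall/precision plus dataset totals reconstruct confusion counts whose
recomputed accuracy and MCC match the printed values to the printed
precision.  Degenerate denominators report 0 with a flag rather than NaN.
The scrambled-partner control is a pure composition of a seeded uniform
permutation of the partner sequence with the ordinary prediction path.

## Synthetic data

The generator emulates SLiM-mediated, partner-conditioned interfaces with
coupled k-mer pairs (default one couple of 3-mers): every query receives
its motif (so the query side is marginally uninformative), the partner
receives the coupled motif with a probability derived from the target
positive rate (default 3%, within the 1.7–3.5% range typical of
residue-level interface data), and a query residue is positive iff it lies
in a query-motif occurrence *and* the partner contains the coupled motif —
recomputable by plain string matching.  Sequences are uniform over the
20-letter alphabet; datasets whose realised positive fraction misses the
target by more than ±30% relative are redrawn.  The synthetic embedder
hashes each residue's k-mer context (k = 3, replicate padding at the
termini) to a deterministic unit vector plus a small smooth positional
component, making motifs linearly separable in embedding space.

What the generator does *not* emulate: real PLM embedding geometry
(contextual, anisotropic, long-range), structural interfaces that are
dispersed rather than contiguous, homology between pairs, and label noise
from crystal-contact artifacts.  Passing the synthetic studies therefore
demonstrates that the architecture, training loop and evaluation stack
work and that predictions are genuinely partner-conditioned — not that
full-scale benchmark performance is reproduced.

Toy complexes for the labeler place one carbon sphere per residue on a
10 Å-spaced line (chain A) and partner atoms 4 Å from exactly the requested
contact positions — inside the occlusion radius 2(r + probe) = 6.2 Å, which
buries ≈18% of the contact residue's surface (ΔRSA ≈ 17 points) — with all
remaining partner atoms 500 Å away.  Expected labels are therefore known
exactly.

## Reduced-scale learnability study

`studies.run_learnability_study` is the desk-scale analogue of a blind-set
benchmark with a scrambled-partner control: 200 pairs (queries 40–60
residues, partners 20–40) split 140/20/40 train/val/test, d = 32 synthetic
embeddings, 4 heads, Adam lr 3e-3 with weight decay 0.01 and dropout 0.10,
output bias at the imbalance logit, ≤50 epochs with patience 10.  These
problem sizes keep the whole study under ~10 s on one CPU.  At seed 1 the
held-out AUROC is 0.955 (MCC 0.555) and drops to 0.477 (MCC 0.0) with
scrambled partners.

Across seeds 1–10 the held-out AUROC is stable (0.91–0.96) and the
scrambled MCC always collapses (≤0.23, usually 0.0), but the scrambled
AUROC is noisy (≈0.48–0.81).  The reason is instructive: under scrambled
partners the predicted probabilities collapse by 2–3 orders of magnitude
(to ~10⁻³), yet rank-based AUROC still detects residual micro-ordering —
sharp attention from query-motif residues over random partner keys passes
through the rectifying MLP and inflates expected scores slightly.  This
rectification bias is architectural, shrinks with regularisation, and is
invisible to thresholded metrics, which is exactly why the control's
published signature is an MCC collapse.

## Known limitations

- No PLM weights are shipped; full-scale training and the published blind
  benchmarks require an embedding backend registered through the adapter
  interface and corresponding compute.
- The clustering identity recipe and the RSA normalisation table are
  documented stand-ins for unstated upstream choices.
- SASA is estimated on heavy atoms with a fixed element-radius table; no
  implicit-hydrogen radius corrections.
- The training loop is single-process, one pair per step; it is not meant
  for datasets beyond a few thousand pairs.
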