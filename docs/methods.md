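# Methods

## Model

The package predicts properties of molecules, molecule sets, and reactions
from SMILES with a directed message-passing neural network (D-MPNN).

**Featurization.** A molecule is a directed multigraph over heavy atoms;
every bond contributes two directed edges. Atom feature vectors x_v are
ordered one-hot blocks — atomic number (1–100), heavy-atom degree (0–5),
formal charge (−2…+2), chirality tag, hydrogen count (0–4), hybridization
(sp…sp3d2) — each with a trailing "other" slot, plus an aromaticity bit
and the atomic mass divided by 100. Total width 133. Bond vectors carry a
leading null-bond bit, a bond-type one-hot (single/double/triple/aromatic +
other), conjugation and ring bits, and a stereo-tag one-hot (width 15).
The directed-edge feature is e_vw = cat(x_v, bond), so the two twins of a
bond differ only in the atom block. Hydrogens are implicit: they enter
only through the H-count block. Chirality and bond stereo use the parser's
native tags (CW/CCW, cis/trans) rather than CIP labels — a dialect choice,
recorded here.

**Encoder.** Edge states initialize as h⁰_vw = τ(W_i e_vw) and are refined
by

    h^{t+1}_vw = τ( h⁰_vw + W_h · Σ_{k ∈ N(v)\w} h^t_kv ),

i.e. the message into edge v→w sums the states of edges entering v
*excluding the reverse twin w→v* (the exclusion is what makes the walk
non-backtracking and numerically stable), with a skip connection to the
initial state at every step. The depth T (default 3) counts initialization
as the first step, so T−1 refinement updates run — the counting convention
of the original D-MPNN implementations. Atomic embeddings are
h_v = τ(W_o · cat(x_v, Σ_incoming h^T)); molecular embeddings aggregate
atoms by mean (default), sum, or sum divided by a fixed norm scaler
(default 100 — the option has no canonical default, so a round constant is
used). MPNN layers have no bias by default; τ defaults to ReLU
(leakyrelu/tanh available). Optional molecule-level features x_m are
concatenated to the embedding, or can replace the graph path entirely
(fixed-embedding bypass).

**Readout.** A feed-forward network (default 2 layers × 300 hidden, bias
on, same τ) maps embeddings to targets: identity for regression, sigmoid
for binary targets, a per-task softmax for multiclass, and for spectra a
softplus positivity head followed by normalization to unit sum over valid
bins (chosen so masking and normalization commute). Multiclass outputs are
laid out as contiguous per-task blocks. With multiple molecule columns
(solute + solvent, reaction + solvent) each column gets its own encoder
unless shared; embeddings concatenate in column order, so the model is
deliberately *not* permutation-invariant across columns.

**Reactions.** Atom-mapped `reactants>>products` pairs condense into a
single pseudomolecule (condensed graph of reaction): vertices and edges
are the unions over both sides keyed by map number. Features combine the
sides as reactant ⊕ (product − reactant) by default (prod_diff and
reac_prod modes are available); a bond missing on one side contributes the
null-bond encoding there, and an atom missing on one side imputes that
side's features from the other, so identity reactions have exactly zero
difference blocks. Unmapped atoms raise by default (silent mis-mapping
corrupts training); a lenient mode assigns leftover map numbers in
canonical order.

**Atom/bond-level heads.** A shared encoder feeds one FFN per property
(properties do not share readouts). Bond readouts use the symmetrized sum
of the two directed edge states. An optional attention constraint makes
per-atom (or per-bond) predictions sum exactly to a supplied molecular
value c: softmax weights a_i from a learned score head redistribute the
residual, pred_i = raw_i + a_i (c − Σ raw). Exactness of the sum is the
contract; the weighting is the learned, pluggable part.

## Training

Adam with a piecewise schedule: linear warmup in optimizer steps from
init_lr 1e-4 to max_lr 1e-3 over 2 warmup epochs, then exponential decay
parameterized to hit final_lr 1e-4 exactly at the final step (the
endpoints are the schedule's definition; warmup-in-steps and the
exact-endpoint decay are this package's concretization). Batch size 50,
30 epochs by default; the CLI warns that small datasets need many more
epochs. Regression targets are standardized per task on the training
split and predictions are returned in original units (round trip exact to
machine precision). Early stopping (patience in epochs) retains the
best-validation weights. Ensembles are independent weight seeds on the
shared split; each cross-validation fold re-splits with seed+fold and
ensemble members within a fold vary only the weight seed. Prediction is
the ensemble mean. Dropout, when enabled, applies after each activation
in both MPNN and FFN and is disabled at inference unless Monte Carlo
dropout uncertainty is requested.

The network runs on a small float64 reverse-mode automatic-differentiation
engine over NumPy arrays written for this package; gradient correctness is
enforced by finite-difference tests on every learnable tensor. Training is
bit-deterministic under a fixed seed on one device.

Transfer learning loads a checkpoint and freezes the message-passing
weights, optionally plus the first k readout layers; frozen tensors are
excluded from the optimizer and remain bit-identical. Checkpoints are
single `.npz` files holding all weights plus the full configuration and
target-scaler state, version-stamped.

Hyperparameter search is native random search over a discrete space with
an append-only JSON-lines trial log (O_APPEND writes, safe for parallel
workers); a targeted sampler such as a Tree-structured Parzen Estimator
can be plugged in as a callable but is not bundled.

## Losses and metrics

- Regression: MSE; bounded MSE, in which an inequality target like
  ">5.0" incurs zero loss once satisfied (plain MSE is used for "=",
  including satisfied equalities); Gaussian NLL for mean-variance (MVE)
  heads; evidential normal-inverse-gamma NLL with regularizer
  λ·|error|·(2ν+α), λ default 0.2 (exposed flag). The NIG head reports
  aleatoric β/(α−1) and epistemic β/(ν(α−1)) variances.
- Classification: binary/multiclass cross entropy; a differentiable soft
  Matthews correlation surrogate built from expected confusion counts
  (Gorodkin's R_K for multiclass) so hard predictions recover the usual
  MCC; Dirichlet evidential loss (Bayes-risk squared error plus a KL
  penalty on misleading evidence).
- Spectra: spectral information divergence, Σ p ln(p/q) + q ln(q/p) over
  valid bins after renormalization and flooring at 1e-8 (configurable;
  no canonical value exists), and the 1-D first-order Wasserstein
  distance — the L1 gap between cumulative sums, in bin-width units.
  Masked bins (exclusion regions, missing values) carry no mass, receive
  provably zero gradient, and are skipped in both divergences.
- Evaluation-only metrics: RMSE, MAE, R², AUROC, AUPRC, accuracy, hard
  MCC, cross entropy, SID, Wasserstein. Metrics undefined on the data
  (single-class AUROC, constant-uncertainty rank correlation) raise a
  dedicated signal rather than crashing or returning a silent number.

## Uncertainty

Sources: ensemble variance across members (plus the mean of member
variances when members carry MVE heads — the law-of-total-variance
combination, chosen because the split into between- and within-model
terms is exact); Monte Carlo dropout over K=30 passes (default);
the MVE and evidential heads directly; mean pairwise spectral divergence
between ensemble members for spectra; predicted probabilities for
classifiers.

Regression calibrations rescale the variance on a held-out set (≥10
points enforced): z-scaling fits the single NLL-optimal variance factor;
t-scaling fits a Student-t scale (df = n−1) to standardized residuals;
CRUDE keeps the empirical residual distribution (linear-interpolated
quantiles) for intervals; MVE weighting reweights member variances by
held-out NLL through softmax weights. Classification offers
single-parameter Platt scaling (a temperature on the logits, fit by 1-D
NLL minimization) and isotonic regression. Calibration never changes
predicted means, and classification maps are monotone, so rankings and
AUROC are preserved. Evaluation: Gaussian NLL, Spearman correlation of
|error| with uncertainty, expected normalized calibration error (default
10 equal-count bins), and miscalibration area (area between the empirical
central-interval coverage curve and the diagonal).

## Synthetic data

The fixture generator emulates the input formats, not chemistry: random
acyclic C/O/N trees plus substituted benzene/pyridine rings, capped at 12
heavy atoms so the full suite runs in minutes on one CPU. Targets follow
stated closed-form rules — heavy-atom count with N(0, 0.1) noise (small
relative to one atom), ring indicator, element-based class labels, a
two-Gaussian synthetic spectrum whose centers shift with composition,
per-atom degrees (whose molecular sum, twice the bond count, provides a
natural constraint value), and a heteroscedastic variant with noise
σ = 0.05 × heavy atoms for uncertainty-recovery tests. Reactions are
mapped identity pairs (zero-change controls) and single-bond cleavages,
with a fully mapped Diels–Alder fixture (6-atom union graph, 2 formed
bonds, 4 order changes) always first. All randomness flows through seeded
generators passed as arguments; regeneration is byte-identical.

What passing these fixtures shows: the graph construction, encoder,
losses, optimizer and uncertainty machinery compose into a system that
learns relationships that are genuinely graph-computable. What it does not
show: performance on real assays, spectra with physical line shapes,
tautomer/charge standardization, 3-D conformational effects — real
chemistry is out of the generator's scope by design.

## Problem sizes used in the shipped checks

Oracle equivalence uses 20 molecules of ≤6 atoms × 20 weight draws at
hidden size 24 (the loop reference is quadratic in edges); permutation
invariance, 50 molecules × 10 renderings; parameter recovery, the
300-molecule atom-count fixture at the default architecture (300 hidden,
depth 3, 50 epochs); heteroscedastic MVE recovery, 600 molecules at 96
hidden; calibration recovery, five simulated sets of n = 5000 summarized
by their median so one Monte Carlo draw cannot dominate.

## Known limitations

- CPU-only, float64; fine at fixture scale, not tuned for 10⁵-molecule
  datasets.
- Bond-level targets support the symmetrized-state readout only; no
  directed per-edge targets.
- Multiclass column counts must be declared (class labels are not
  inferred from the CSV).
- The Wasserstein loss treats masked bins as zero-mass positions: mass
  transported across an exclusion region still pays the distance through
  it.
- No conformal prediction, no Bayesian layers beyond MC dropout, no 3-D
  or attention-based encoders.
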