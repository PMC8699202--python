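# Methods

## Problem and model

`pepccs` predicts the collision cross section (CCS, Å²) of a tryptic peptide
ion from its sequence and charge state (z ∈ {2, 3, 4}).  CCS is the
charge-state-specific effective area governing an ion's mobility in buffer
gas; accurate predictions let a proteomics search reject candidate
identifications whose observed ion-mobility behaviour does not match.

The regressor is a two-branch neural network:

* **Convolutional branch** — the sequence is laid out as a fixed-length
  (L = 96 positions by default) multi-channel 1D signal with 323 channels
  per position and passed through six valid 1D convolutions (kernel 6,
  stride 1; 150 output channels each, 50 in the last) with one subsampling
  layer (kernel = stride = 2) between convolutions 3 and 4, then flattened.
* **Dense branch** — a global feature vector (peptide length, charge as an
  integer and one-hot, N-terminal acetylation flag, plus windowed
  composition features, 1626 entries in total) through two 250-node layers.
* Both branches are concatenated and fed through a 600-node hidden layer to
  a single linear output.  All hidden activations are ReLU; weights use He
  initialization.

In the **reduced variant** the windowed features are dropped, only the six
global scalars remain, and they are concatenated directly to the flatten
output (the two dense-branch layers are removed).

Training uses Adam (learning rate 3·10⁻⁴), batch size 256, mean absolute
error on CCS/1000, validation MAE recorded every 1000 iterations and at
each epoch end, and the best-validation checkpoint is returned.  The
network, backpropagation and Adam are implemented directly in numpy
(float32, im2col convolutions); the package has no deep-learning framework
dependency, which keeps it installable in minimal environments and makes
every numerical step inspectable.

## Featurization

Each residue is described by 45 features: 21 one-hot identity slots
(oxidized methionine is a dedicated 21st symbol), H/C/N/O/S element counts
of the residue, ten side-chain class flags, two dyad flags ({N,D}, {E,Q}),
six float descriptor scales, and a padding flag that is 1 only for padding
positions.  The chemistry table ships as a versioned CSV
(`data/residue_chemistry_v1.csv`) and can be replaced by the user.

Two deliberate choices in the shipped table:

* The non-polar class is G, A, V, L, I, P, M, F, **W**.  (Published
  versions of this class sometimes list V twice where W is plainly meant;
  the class table is data, so users can disagree.)
* The six descriptor scales are Kyte–Doolittle hydropathy (shifted by +4.5
  so the scale is non-negative), Zimmerman bulkiness, Grantham polarity,
  Zamyatnin residue volume, isoelectric point and Chou–Fasman helix
  propensity, with oxidized Met inheriting Met's values.  Non-negativity
  matters because the fraction-type cumulative feature C² (below) is only
  bounded in [0, 1] when features are non-negative.

Cumulative features over a residue window [j_start, j_end]:
C¹ = (window sum)/100, C² = window sum / whole-peptide sum (defined as 0
when the whole-peptide sum is 0), C³ = window mean.  The C³ denominator is
the window length j_end − j_start + 1 — the only reading that yields a
well-defined average.  C¹ additivity, the C² bound and the C³ min/max
bracket are enforced by property tests against an independent brute-force
implementation.

The spatial encoding gives every one of the L positions 323 channels:
residue indicator; N-terminus / acetylated-N-terminus / C-terminus flags;
the 315-feature block {F, C¹/C²/C³ of the prefix [0, j], C¹/C²/C³ of the
suffix [j, n−1]} (seven 45-wide sub-blocks); relative position j/(n−1)
(0 for n = 1); raw residue distances from either terminus (unscaled — the
/100 scaling applies only to C¹); and the charge state replicated across
all positions including padding, so convolution kernels see the charge
everywhere.  Padding rows carry the padding symbol in the F block and zero
elsewhere (except the charge channel).  L must be at least n + 41; the
default 96 accommodates the generator's longest peptide (45 residues) with
the required margin.

The dense-branch vector appends, to the six scalars, the C¹ vector of each
window in a fixed layout: for each fixed length k ∈ {5, 10, 20} an
N-terminal and a C-terminal window (clamped when n < k; terminal anchoring
reflects the strong terminal dependence of CCS), then tilings of the
peptide into 2, 4, 8 and 16 consecutive windows.  Fractional borders are
rounded half-up and repaired left-to-right so every window keeps at least
one residue; when n is smaller than the number of windows in a tiling,
windows degenerate to single residues and may overlap.  The layout gives
36 windows for every peptide, hence 6 + 45·36 = 1626 dense-branch features.

Other open points were resolved as follows: subsampling is max-pooling
(average pooling is a config option); convolutions are valid (no zero
padding — padding positions already carry an explicit padding feature); no
learning-rate schedule, weight decay, dropout or input normalization.

## Accuracy measures and drift calibration

`evaluate` reports RMSE and MAE (Å²), the mean / median / 90th-percentile
absolute percentage errors (MPE, MdPE, Δ90; percentile by linear
interpolation), R² and Pearson's r.  Percentage errors are magnitudes;
signed variants are out of scope.  For a constant reference vector the
error measures are still computed but R² and r are NaN (with a warning).

Drift times relate to CCS through t_d = A·Ω·√μ/z + B with μ = mM/(M+m) the
ion/gas reduced mass (default gas N₂, m = 28.006 Da).  The √μ form follows
the Mason–Schamp proportionality; a literal linear-μ variant is selectable,
and since A and B are refitted by ordinary least squares against reference
drift times either way, the choice only changes the mass weighting.
Per-charge drift reports fit A/B globally and evaluate R²/MSE within each
charge group.

## Synthetic data

The generator emulates the composition of a timsTOF tryptic data set:
lengths uniform on 7–45, residues drawn with rough proteome frequencies,
C-terminal K/R with probability 0.9, per-Met oxidation probability 0.1,
N-terminal acetylation probability 0.05, and a length-dependent charge rule
(longer peptides carry more protons).  Labels come from a constructed
ground truth — per-charge affine in (neutral mass)^(2/3) (globular-ion
surface scaling), plus small per-residue offsets and a positional term
(+15 Å² × relative position for each proline/histidine) — with Gaussian
noise of σ = 5 Å² by default.  Slopes/intercepts are chosen so default CCS
values span roughly 250–1100 Å², matching the strata used for
range-resolved reports.

This function is a stand-in, not a physical model.  It reproduces the
features that matter for exercising the method — charge-state branches,
mass scaling, composition and position dependence, realistic noise — but
none of the conformational physics of real peptide ions.  Tests passing on
it demonstrate that the featurization is faithful, the network trains and
the contracts hold; they do not certify accuracy on experimental data.

## Problem sizes and the desk-scale configuration

The published layer widths (150-channel convolutions) are intended for
GPU-scale training on ~450k peptides.  The package's experiments and test
suite instead run a **desk-scale** configuration
(`NetworkConfig.desk_scale()`: channels 16×5 + 8, dense 32/32, head 64 —
same topology, narrower layers), which trains in minutes on one CPU core
and, at these data sizes, converges faster per Adam iteration than the wide
network.  Problem sizes used by the test suite and acceptance script:

* overfit check: 200 noiseless peptides, full batch, ≤2000 iterations;
* generalization check: 5000 train / 500 validation / 1000 test at
  σ = 5 Å², 700 iterations — the trained model's test MAE is compared to a
  charge-stratified mean-CCS baseline;
* feature-ablation check: 1500/300/500, 250 iterations, 3 seeds per
  variant, comparing the full against the reduced feature set;
* ensemble: 3 members differing only in the training seed.

All randomness (weights, shuffling, batch order, generator, label noise)
flows from explicit integer seeds; identical seeds give bit-identical
histories and artifacts.

## Known limitations

* No PTMs beyond N-terminal acetylation and Met oxidation; charges outside
  2–4 are rejected, not extrapolated.
* The exact window layout of the dense-branch features is a documented
  reconstruction (terminal anchoring + fractional tilings); alternative
  layouts are configurable but untested against experimental data.
* Masses are monoisotopic; no isotope distributions.
* The numpy implementation is single-threaded BLAS-bound; it is intended
  for desk-scale experiments, not for retraining on ~10⁵-peptide corpora.
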