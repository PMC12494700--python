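# Methods

This note records the modeling choices behind `geneopocket`: the procedure,
its assumptions, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical details needed to
reproduce results exactly.

## Pipeline

1. **Structure preparation.** Fixed-column PDB, first model only, waters
   dropped, alternate locations collapsed to the highest-occupancy variant.
   Input structures are assumed prepared (protonation and tautomer
   assignment are out of scope).  The ligand is either named explicitly or
   auto-selected as the HETATM residue with the most heavy atoms outside a
   fixed ion/buffer exclusion list.  Optionally, only protein chains with at
   least one atom within 10 Å of the ligand are kept (per-chain minimum
   atom distance), which avoids duplicated symmetry copies of the true
   pocket in multi-chain crystals.

2. **Channels.** A cubic voxel grid (spacing 1.0 Å, padding 5.0 Å beyond
   the protein's vdW envelope; cells half-open, centers at
   origin + (i+½)·spacing) carries eight scalar potentials.  The
   inverse-distance sums run over a spherical neighborhood of 10 Å — beyond
   that, 1/d contributions are negligible against the min-max normalization
   — and the distance is clamped below at spacing/2 so values inside atoms
   stay bounded (the potentials are evaluated everywhere, including inside
   the protein, and an unclamped 1/d would let interior singularities
   dominate the normalization).  Each channel is independently min-max
   rescaled to [0,1] per protein; a constant channel maps to 0.5.  The
   empty-space mask is where the raw signed-distance channel is
   non-negative.

3. **Hydrogen-bond channels.** Both use the well-type radial term
   −ε_a(R⁶ − 2R⁴) with R = R_min/d + 0.96.  The constant 0.96 is treated as
   a fixed empirical offset of the potential's parameterization and
   implemented literally; with it, the term peaks at R = √(4/3) (value
   32/27·ε) and crosses zero at R = √2.  The donor channel multiplies the
   radial term by cos²(ang₁)·cos²(ang₂), where ang₁ is the angle between
   the donor→hydrogen bond direction and the hydrogen→probe direction
   (contribution zeroed past 90°) and ang₂ the angle between the
   antecedent→donor and donor→probe directions (factor 1 when the donor has
   no heavy-atom neighbor).  With several hydrogens on one donor, the most
   favorable hydrogen counts.  This geometry yields the full radial value
   on an ideal linear H-bond and decays smoothly off-axis.

4. **Atom parameters.**  Magnitudes are largely conventional because the
   per-protein normalization removes global scales; what matters are signs
   and relative orderings.  Defaults: vdW radii and masses from standard
   element tables; charges O −0.4, N −0.3, H +0.15, C 0.0 (overridable per
   atom from a PQR sidecar); lipophilic coefficients C/S/halogens −1,
   N/O +1, P +0.5, hydrogens inheriting their heavy neighbor's sign (the
   lipophilic channel sums only negative coefficients, the hydrophilic one
   only positive ones — a sign split of one scalar, not two tables);
   polarity 1 for N and O, and for S bearing a hydrogen; H-bond well depth
   ε = 1 with R_min 1.9 Å (O) / 2.0 Å (N).  Bonds are inferred by
   covalent-radius sums + 0.4 Å tolerance; donors without a bonded
   hydrogen are demoted.  All tables are replaceable via YAML.

5. **Operator layer.**  One convolution operator per channel,
   ψ_i = φ_i ∗ K_i, with kernels sampled from radial profiles on the voxel
   lattice, truncated at 3σ_i, and L1-normalized.  Radial construction
   makes central symmetry exact on the lattice, hence equivariance under
   the grid's 24 proper rotations and integer translations; ‖K‖₁ = 1 plus
   convex combination weights gives sup-norm non-expansivity (Young's
   inequality).  Default families: a signed difference-of-Gaussians
   (unit-mass Gaussian at σ minus one at 2σ, renormalized) for the distance
   channel — a center-surround profile that responds to cavity-scale
   contrast — and plain Gaussians for the seven potential channels.
   Boundaries are zero-padded; the 5 Å grid padding keeps pockets away
   from boundary artifacts.  σ has a floor of 0.25·spacing (below which
   the sampled kernel degenerates to the identity tap).

6. **Combination, thresholding, pockets.**  ψ = the convex combination of
   the ψ_i, min-max normalized over empty-space voxels only and clamped to
   [0,1] (keeping ψ smooth everywhere for scoring while the mask is
   enforced at thresholding).  The binary field is ψ > θ (strictly; ties go
   to background) intersected with the empty-space mask, labeled by
   26-connectivity (most permissive — avoids fragmenting thin pocket necks;
   configurable to 6/18).  Pockets are scored by
   mean ψ · (1 − exp(−V/V_ref)) with V_ref = 30 voxels: bounded, monotone
   in volume, order-preserving at equal volume, and damping one-voxel
   specks.  Ties break by larger volume, then lower label.  Descriptors per
   pocket: centroid (unweighted voxel-center mean), equal-volume-sphere
   radius, counts of acceptor/donor protein atoms within 4 Å of any pocket
   voxel center, mean lipophilic/hydrophilic composite and mean polar
   channel over pocket voxels, and a `small` flag below 100 Å³.

## Training

The loss is maximized with Adam (β₁ = 0.9, β₂ = 0.999, learning rate 0.01)
for 50 epochs of per-example updates with seeded shuffling (batch size 1;
grids of different proteins have different shapes, and determinism is part
of the test contract).  Constraints hold by construction: α = softmax(a),
θ = logistic(t), σ = floor + softplus(u), with σ additionally projected
below the largest value whose truncated kernel still fits the smallest
training grid.  k defaults to 0.02, the center of the range in which the
loss produces a small number of appropriately sized pockets; initialization
is σ = 2 Å, α uniform, θ = 0.5.

The hard threshold is not differentiable, so optimization runs through a
logistic surrogate logistic((ψ − θ)/T) with T annealed linearly from 0.1 to
0.01 over the epochs; every reported loss is recomputed with the hard
threshold.  Gradients are analytic for α, θ and (in the ablation variants)
the free kernel taps — including the exact subgradient of the min-max
output normalization through its argmin/argmax voxels — while σ is
differentiated by a central finite difference on the sampled kernel only
(step 10⁻³ Å), which sidesteps the non-smooth truncation/renormalization of
the tap grid.  The optimizer is plain numpy; grids are small enough that a
dense-framework autograd would buy nothing.

Ablation variants replace the radial kernels with fully learnable taps of
the same size, either re-normalized to unit L1 norm at every evaluation
(NE-NE: non-expansive, not equivariant) or unconstrained (NE-E: neither).
Multi-restart selection trains one model per training set and keeps the one
with the highest H₁ on a validation set (ties to the earlier restart).

## Synthetic data

Two generators provide all test inputs; both are deterministic per seed.

**Shell complexes** place C/N/O atoms (70/15/15) quasi-uniformly (Fibonacci
lattice, 0.15 Å jitter, ~1.8 Å spacing) on a 10 Å sphere with a 30° opening
cap removed, a 5-heavy-atom ligand cluster at the center, and a hydrogen on
each N/O pointing into the cavity so the donor channel is non-degenerate.
They exercise every parsing and channel code path and give a geometrically
known cavity, but emulate none of real proteins' residue chemistry, packing
density, surface texture, or multiple competing cavities.  A model that
ranks these cavities first demonstrates that the pipeline's geometry,
learning and ranking machinery compose correctly — not performance on
crystal structures.

**Phantoms** are pure channel stacks: per-channel signal × ball indicator
plus i.i.d. Gaussian voxel noise (default σ 0.1, 16³ grids), normalized
like real channels, with the ball (or a sub-ball) as truth.  They give full
control of signal and noise for the non-expansivity and recovery suites.
`generate_from_model` runs a known parameter vector on phantom stacks and
takes its top-scoring pocket as the truth, yielding datasets whose
attainable loss is known — the oracle for parameter recovery.

## Problem sizes

The shipped suites use desk-scale sizes chosen to keep the full test run in
a few minutes: 6 training + 20 evaluation shell complexes (~460 atoms,
~34³ voxels each, 12 epochs), 24 + 12 recovery phantoms (16³, 50 epochs),
100-pair non-expansivity and 200-pair loss-oracle checks.  The training
machinery itself is size-agnostic.

## Numerical details

- Convolution: direct (scipy.ndimage) below ~1500 taps, FFT above; both are
  true convolutions and agree with a triple-loop oracle to 1e-12.
- Min-max normalizations map a constant field to 0.5; output normalization
  requires a non-empty empty-space mask.
- Sphere–voxel truth test: exact closed-box/sphere distance with strict
  inequality, so tangential (zero-volume) contact does not mark a voxel;
  zero-radius atoms mark exactly their half-open owning voxel.
- Ranking ties: equal scores → larger volume → lower label; equal overlap
  in matching → best (lowest) rank.
- Success curves use strict `value < threshold`; failures never count.
- Equivariance holds bit-tight on the lattice; under off-lattice rigid
  rotation of the atoms the channels are re-sampled, so system-level tests
  assert stable detection (match rank, mean ψ) rather than identical
  component counts — re-sampling can split or merge speck-sized components.

## Limitations

- Charges, lipophilicity and H-bond well parameters are conventional
  defaults, not a fitted force field; results on real proteins will depend
  on supplying better tables (YAML/PQR hooks exist).
- One connected component = one pocket: adjacent subcavities separated by
  thin necks merge at permissive connectivity.
- The convex combination cannot invert a channel's polarity; per-channel
  orientation flips exist in the normalization config if a channel's
  convention needs reversing.
- mmCIF, biological-assembly expansion, and protonation are out of scope;
  inputs are assumed prepared.
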