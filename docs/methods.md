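# Methods

## Model

`dfscan` predicts candidate rescue sites — residues where a second-site
mutation can compensate a deleterious first-site mutation — from a single
native structure, using only backbone elasticity.

The protein is coarse-grained to one node per residue at the Cα position
and modelled as an anisotropic network model (ANM): nodes i, j are joined
by a Hookean spring of constant γ whenever their distance is below a
cutoff r_c. The 3N×3N hessian **H** of this network has, for each
connected pair, the off-diagonal block −γ·ê_ij ê_ijᵀ (ê_ij the unit
inter-node vector) and diagonal blocks that cancel each super-row, so
rigid translations and rotations are exact zero modes. The first-order
displacement under an external force **F** follows linear response
theory,

    ΔR = H⁺ F,

with H⁺ the Moore-Penrose inverse over the non-rigid modes. A connected,
non-planar network must show exactly six near-zero eigenvalues; the
pseudo-inverse refuses to proceed otherwise, because a seventh soft mode
signals a disconnected or floppy network and a count below six a broken
hessian.

A mutation at residue i is mimicked by a point force **F**_i applied at
node i. For a pathogenic site i and a candidate rescue site j, the
rescuability index

    ρ_ij = (d(u, p_i) − d(u, p_ij)) / d(u, p_i)

compares the deformation of the singly perturbed structure p_i with the
doubly perturbed p_ij; d is the root-mean-square of the per-residue
displacement magnitudes of the linear-response field. No rigid-body
superposition is applied before measuring d: pseudo-inverse responses are
orthogonal to the rigid subspace by construction, so a refit would be a
first-order no-op while costing determinism and time. ρ ∈ (0, 1]
indicates compensation, ρ = 1 exact cancellation, ρ < 0 aggravation.

Because ρ depends on force orientation, each site carries a deterministic
set of unit vectors from the spherical Fibonacci lattice (z uniformly
spaced in (−1, 1), azimuth advancing by the golden angle 2π/φ²). The pair
score

    S_ij = mean over F_i orientations of ( max over F_j orientations of ρ )

is collected for all ordered pairs i ≠ j into rescuability matrices, one
per magnitude scheme: **S**^FF (Fixed Force — both sites receive the base
magnitude) and **S**^FR (Fixed RMSD — the second-site magnitude is
rescaled by d(u, p_i)/d(u, p_j) so that each force alone deforms the
structure equally). Within linear response the double-force displacement
is the superposition of the two single-force responses, so the engine
precomputes the three unit-force response columns per site and reduces
each pair to a small Gram-matrix update; this is algebraically identical
to rebuilding every response from scratch, which the test suite verifies
against a naive reference implementation at 1e-10.

Per residue j and per scheme, the number of first sites with S_ij > 0 is
divided by j's contact degree (its ANM neighbour count — the model's own
contact graph, keeping the method self-contained), min-max rescaled to
[0, 1] across residues, and the two scheme components are averaged into
the compensatory power P_j. Residues with P strictly above the
top-fraction quantile (default: top 28%) are classified as rescue sites;
ties at the threshold are excluded, so a flat profile predicts nothing.
If a scheme's ratio vector is constant, its component is set to zero — a
flat signal carries no compensatory information.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| r_c | 15.0 | Å | canonical ANM cutoff for Cα networks |
| γ | 1.0 | energy/Å² | cancels exactly out of ρ, S and P (verified numerically) |
| orientations/site | 12 | — | near-icosahedral coverage; 144 ρ evaluations per pair |
| base magnitude | 1.0 | arbitrary | ρ is invariant to uniform force scaling within LRT |
| zero_tol | 1e-6·λ_max | — | separates rigid from soft modes in double precision up to N ≈ 10³ |
| classification percentile | top 0.28 | — | reference operating point of the compensatory-power threshold |
| pocket threshold | 0.20 (inclusive) | — | a pocket is a rescue pocket when ≥ 20% of members are rescue sites |
| proximity cutoff | 4.0 | Å | minimum heavy-atom distance for "in contact with a prediction" |

The orientation count is deliberately configurable and the `converge`
utility reports max |ΔS| between scans at doubled counts, so sampling
adequacy is measured rather than assumed.

## Evaluation layer

Predictions are compared with reference pathogenic (PS) and rescue (RS)
site tables by exact residue matching on author numbering (chain, residue
number, insertion code — never renumbered). Reported statistics:
sensitivity, specificity, accuracy; enrichment = (TP/(TP+FP)) /
((TP+FN)/nres); and the threshold minimising
D = (1 − sensitivity)² + (1 − specificity)², searched exactly over the
observed score values (ties resolve to the threshold predicting fewer
positives). Missed reference rescue sites are re-examined for contact
(< 4 Å minimum heavy-atom distance) with predicted sites; Cα-only inputs
fall back to Cα distances and are flagged. Pair-specific rescue sets for
a PS i collect residues j with S_ij > 0 under either scheme, intersected
by default with the globally classified rescue sites; a flag exposes the
looser S-only variant, since either reading of "a predicted rescue site
rescuing i" is defensible. Compensatory motions — the double-force
displacement at the ρ-maximising orientation pair, ties to the lowest
indices — are decomposed onto the first k non-rigid normal modes via the
root mean square inner product (RMSIP), and each mode carries the
exponential-entropy collectivity κ = (1/N)·exp(−Σ u_i² ln u_i²) (this is
the standard involvement-entropy form; κ ranges from 1/N for a localised
mode to 1 for a uniform one). Divergent positions between a human
sequence and a close homologue are read from a 2-record aligned FASTA:
columns with two differing standard amino acids, reported at the human
ungapped position; gap columns are never divergences, since indels are
not point compensations.

## Synthetic fixtures

All development and testing runs on generated geometries: a regular
tetrahedron (edge 3.8 Å; the smallest non-planar network), an ideal
α-helix Cα trace (rise 1.5 Å, 100° turn, radius 2.3 Å — consecutive
spacing ≈ 3.83 Å, matching the real Cα virtual bond), a jittered cubic
lattice and a self-avoiding random globule (minimum spacing 3.5 Å). All
randomness is seeded and bit-reproducible. These fixtures exercise every
code path and the elastic model exactly, but they carry no side chains,
no sequence signal and no real mutation data, so green tests demonstrate
the correctness of the mechanics and arithmetic — not predictive accuracy
on real proteins, which requires real structures and curated mutation
tables supplied by the user.

## Numerical choices and limitations

- Dense `scipy.linalg.eigh` for the spectrum: at target sizes (N ≲ 10³)
  dense routines beat iterative ones and are exactly reproducible.
- Altloc handling: highest occupancy, ties to first in file. Residues
  without a Cα are skipped and counted; a chain or model that does not
  exist is a hard error.
- Scan matrices are ordered (row = pathogenic site, column = rescue
  candidate), never symmetrised; the diagonal is masked NaN.
- The full-scan cost is dominated by one n_or×n_or Gram product per pair;
  a 60-residue scan at 12 orientations with both schemes takes well under
  a second on one CPU, and the acceptance run (scan + evaluation + mode
  analysis + convergence check) about two seconds. The sizes used there —
  60 residues, 12 orientations — were chosen as comfortable desk-scale
  defaults, not limits; N ≈ 10³ remains tractable.
- Convergence caveat: max |ΔS| between doubled orientation counts decays
  on compact (globular, lattice) fixtures and short helices, but on the
  bare 60-residue helix the FF metric is dominated by pairs involving the
  floppy termini, whose strongly negative scores converge slowly and
  non-monotonically (drift 2.28 at 6→12 vs 2.29 at 12→24, while the
  median drift falls from 0.075 to 0.061). The max-drift diagnostic is
  therefore a worst-case indicator; inspect the per-entry drift on
  elongated structures.
- FF scores are unbounded below: when the second site responds much more
  strongly than the first, every second-site orientation aggravates the
  deformation. This is genuine physics of the fixed-force scheme, and one
  reason the FR scheme exists.
- The method predicts positions of candidate rescue mutations, not
  amino-acid identities, and cannot see compensation via side-chain
  mimicking or direct partner interactions — mechanisms with little
  backbone signature.
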