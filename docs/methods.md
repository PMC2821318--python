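# Methods

This note records the model, the numerical choices, and the design
decisions behind `contactpot`, including what the synthetic generators do
and do not emulate.

## Structure model

A structure is an ordered list of standard residues grouped by chain, each
residue an ordered list of heavy atoms. Parsing (Bio.PDB underneath) keeps
the first MODEL only, resolves alternate locations to the
highest-occupancy conformer (ties toward altloc `A`), and drops hydrogens,
waters, HETATM ligands and non-standard residues (MSE and friends are
excluded rather than remapped — curation-grade training sets rarely need
them, and remapping selenium radii would be guesswork). Residues are
renumbered consecutively per chain in file order, so author numbering gaps
and insertion codes never inflate the sequence separation `d`; `d` is a
count of chain positions, not a difference of author numbers.

Because hydrogens are implicit, atoms carry *group* Van der Waals radii
(atom plus its bonded hydrogens), from a packaged table: backbone carbonyl
C 1.5 Å; nitrogens 1.55; carboxyl/hydroxyl oxygens 1.4 (other oxygens,
e.g. the terminal OXT, 1.44); sulfurs 2.0; aliphatic carbons 2.0; aromatic
ring carbons 1.75. Atom names such as CD1, CD2, CG and CZ name an aromatic
ring carbon in PHE/TYR/TRP/HIS but an aliphatic carbon elsewhere (LEU CD1,
ARG CZ), so the table is context-sensitive: an "aromatic" row wins in
ring-bearing residues, the generic row otherwise, and `X**` rows are
element-level fallbacks for names with no explicit entry. After
assignment every radius is one of {1.4, 1.44, 1.5, 1.55, 1.75, 2.0}.

Training-set curation keeps structures that (a) do not report a resolution
worse than 2.5 Å, (b) are not NMR models, and (c) have every residue's
expected heavy-atom set present (extra atoms like OXT are fine).
Structures with *no* resolution/method metadata pass filters (a) and (b):
the filters exist to reject poor experimental models, and generated
structures have no experiment to judge. Each file is treated as one
structure; only intra-chain residue pairs are counted anywhere (sequence
separation is undefined across chains).

## Contact area

The contact area between residues is computed by probe-sphere point
sampling. Per source atom (radius `Ra`, probe `Rp`), `n` quasi-uniform
directions (golden-spiral lattice, deterministic in `n`) are scaled to the
sphere of radius `Ra+Rp`; a sample point touches a partner atom of radius
`Rb` if it lies within `Rb+Rp` of its centre. Consequences and choices:

- **Contact criterion.** Two atoms can share area only if their centres
  are within `Ra+Rb+2Rp`; a 1e-12 absolute slack keeps exact boundary
  geometries inside.
- **Lattice orientation.** The lattice is expressed, per source atom, in a
  local frame whose z-axis points at the partner centroid (x along the
  in-plane component of the first off-axis partner offset). The frame
  co-rotates with the structure, so rigid motions change no area at all —
  a world-fixed lattice would jitter by about one point weight
  (≈0.06 Å² at n = 1024) under rotation — and aligning z with the contact
  axis centres the quadrature on the cap being measured: at n = 10000 the
  directed two-atom area matches the analytic spherical cap to about
  0.1% away from degeneracies.
- **Single crediting.** A sample point touching several atoms of the
  partner residue counts once toward that residue (at the atom level, it
  is credited to the nearest touching partner, ties to the lowest index),
  so per-partner areas never double-count surface and sum to at most the
  sampled sphere's area.
- **Symmetrisation.** The two directed sums differ slightly (different
  sphere radii), so the reported pair area is their mean — exactly
  symmetric in the arguments.
- **No occlusion.** A point touching a partner atom counts even if a third
  atom lies in between: the statistic is sphere overlap, not solvent
  accessibility. (Occlusion would turn this into a SASA-style quantity —
  a different measurement.)
- **Default n = 1024** points per atom: cap-area error well under 1% at
  interactive cost; n = 10000 is used where quadrature accuracy itself is
  under test.
- **Separation bins** d = 1…9 plus a pooled d ≥ 10 bin (10 bins). Only
  d = 1 enters the default score, so the fine structure of the long-range
  bins is not load-bearing.
- **Neighbour search.** A k-d tree over atoms prunes residue pairs whose
  atoms all exceed the largest possible cutoff `2·max(R)+2Rp`; pruned
  pairs have exactly zero area, so the accelerated table equals the
  all-pairs enumeration bit for bit (`use_grid=False` forces the latter).

## Potential

Let `Ā_ab(d)` be the mean over training structures of the per-structure
total (a,b) contact area at separation d — each structure contributes its
total once, so large proteins do not dominate — stored as a symmetric
20×20 matrix whose off-diagonal cells both hold the unordered pair total.
With `Ā_a = Σ_b Ā_ab` (row sum; the diagonal counted once) and
`Ā = Σ_a Ā_a` (full sum; off-diagonal pairs counted from both sides),

    K(a,b,d) = Ā_ab · Ā / (Ā_a · Ā_b),    E(a,b,d) = −T · ln K̃.

This bookkeeping is chosen so the reference state is exact: on a corpus
whose pair areas factorise into type marginals, K ≡ 1 and E ≡ 0
identically (counting the total as a sum over unordered pairs instead
would bias K by 210/400 on a uniform corpus). K is homogeneous of degree
zero in the areas, so rescaling every contact area leaves the potential
unchanged. The smoothing `K̃ = (K·n_obs+1)/(n_obs+1)`, with `n_obs` the
number of structures contributing a nonzero observation, sends unobserved
pairs to the neutral E = 0 and leaves well-observed pairs essentially raw.
The temperature factor T defaults to 1 (energies in RT-like units; only
rankings matter downstream).

The structure score multiplies area by the *energy* E (a flag switches to
raw K for experiments), summed over the separation filter. Defaults —
probe 0.25 Å, d = 1 only — are the configuration that discriminates best:
the contact area of consecutive neighbours carries most of the signal,
and it reacts strongly to side-chain (Cβ) orientation.

## Evaluation

- **Rank**: 1 + number of decoys strictly below the native energy; ties do
  not worsen the native (the tie case is a judgement call; favouring the
  native matches "the native was not beaten").
- **Z-score**: population (divide-by-N) standard deviation in the
  denominator; with realistic set sizes the sample/population difference
  is negligible, but one convention is fixed.
- **Pe = ln(rank/N_structures)**: natural logarithm; 0 (native ranked
  last) is the worst value, and first place improves with set size.
- **RMSD**: Cα coordinates after optimal proper-rotation superposition
  (SVD-based; the residual is measured explicitly after applying the
  fitted rotation, because the solver's reported deviation loses precision
  to square-root cancellation near zero). Length-mismatched decoys keep
  their energy but are excluded from RMSD pairs; unscorable decoys are
  skipped and counted.

## Synthetic generators

`make_toy_structure` builds idealized single-chain peptides by natural
extension: standard bond lengths/angles, ω = 180°, (φ,ψ) = (−57°,−47°)
for helices and (−120°,120°) for extended chains, carbonyl O in the
peptide plane and Cβ at ideal tetrahedral geometry. Side chains stop at
Cβ — enough to exercise every geometric property (orientation dependence,
symmetry, invariances) without rotamer building.

`make_planted_corpus` skips geometry entirely and draws per-structure pair
totals as `marginal product × planted enrichment × unit-mean lognormal
noise`, so trained K is checked against a known ground truth. With a
single pair enriched 2×, the recovered K is ≈1.82, not 2.0: the reference
state renormalises by the (slightly inflated) marginals of the enriched
types. That shrinkage is a property of odds-ratio-style preferences, not
an estimation error.

`make_decoy_ensemble` perturbs each atom with Gaussian noise (side chains
at full scale, backbone at half scale — the score is most sensitive to
side-chain orientation) and then relaxes steric overlaps: inter-residue
atom pairs may not sit closer than 0.9·(Ra+Rb), except that a pair's
native distance is always allowed (peptide bonds and tight native packing
are legitimate), so zero perturbation is a fixed point. The relaxation
matters: published decoy sets are minimised, clash-free conformations,
whereas raw Gaussian noise interpenetrates Van der Waals spheres and
*inflates* contact area — and since the potential has no repulsive term,
unrelaxed clashing decoys can out-score the native. With relaxation, a
3 Å perturbation lands decoys at ≈2.5 Å mean Cα RMSD with systematically
degraded d = 1 contacts.

`make_demo_corpus` plants a residue-type/packing association for
end-to-end tests: helical peptides with hydrophobic-biased sequences
(80% mass on A/V/I/L/M/F/W/Y) alternate with extended peptides carrying
polar-biased sequences. Helical neighbours bury more mutual surface, so
hydrophobic–hydrophobic pairs train to K > 1 (E < 0) — a toy analogue of
hydrophobic packing. The association is necessary: a corpus of
uniform-sequence helices trains to K ≈ 1 everywhere and scores everything
near zero.

**What passing tests do and do not show.** The generators reproduce the
statistical shape of the problem — type-dependent contact-area
preferences, ensembles of worse-packed alternatives — not protein physics.
A pipeline that recovers planted preferences and ranks toy natives first
is verified as *correct machinery*; its discrimination power on real
decoy sets depends on training on a real curated PDB corpus, which this
repository's tests deliberately do not require. Problem sizes in the
default suite (24-residue peptides, 120-structure corpora, 30-decoy
ensembles, 500-structure planted corpora) are chosen so the full suite
runs in well under a minute of compute while keeping sampling error far
from every asserted threshold.

## Known limitations

- No repulsive/clash term: interpenetrating conformations are rewarded
  with area, not penalised; the method presumes physically plausible
  inputs.
- Inter-chain contacts are ignored (no sequence separation across chains).
- The potential is residue-typed, not atom-typed; secondary-structure or
  solvent terms are out of scope.
- PDB input only (no mmCIF); first MODEL only; no hydrogen handling.
- Pe and Z summarise single sets; no significance test across sets is
  provided.
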