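# Methods

This note documents the models and procedures implemented in `leapfs`,
the parameters that matter, the numerical choices behind them, and what
the synthetic-data generators do and do not emulate.

## Structure-based prediction: dynamics perturbation over an elastic network

**Model.** A protein domain is reduced to an anisotropic elastic network
of Calpha nodes. Nodes *i*, *j* within a cutoff *r_c* are joined by a
harmonic spring of stiffness γ acting along the bond direction, giving
the 3N×3N Hessian with off-diagonal blocks −γ·**u**ᵢⱼ**u**ᵢⱼᵀ and
diagonal blocks that make every block row sum to zero. In thermal
equilibrium the conformational density is the Gaussian
P⁽⁰⁾(**x**) ∝ exp(−**x**ᵀH⁰**x**/2); k_BT is absorbed into γ, which
defaults to 1 because only ratios of stiffnesses enter the result.

**Perturbation.** Test points *m* are scattered just outside the
molecular surface. Point *m* is tethered to every node within *r_s* by
springs of stiffness γ_s = 12γ; each tethered node's diagonal block
gains γ_s·**u**ᵀ**u** along the node-to-point direction (the point is
held fixed, adding no degrees of freedom). The signal at *m* is the
relative entropy

D_x = KL(P⁽ᵐ⁾ ‖ P⁽⁰⁾)

between the perturbed and unperturbed Gaussians. The direction follows
the original dynamics-perturbation literature; the reverse divergence is
available via `direction="0_to_m"`.

**Null modes and the low-rank form.** Both quadratic forms are projected
onto the complement of H⁰'s null space (the six rigid-body modes for a
connected 3-D network; more for degenerate geometries — the projection
drops whatever is numerically null rather than assuming six). A
pseudo-determinant treatment was rejected because the perturbed form may
be nonsingular where the unperturbed one is not. Because the
perturbation is a sum of rank-one terms, on the projected basis
Hᵐ = A⁰ + WWᵀ and

D_x = ½ Σᵢ [ln(1+λᵢ) − λᵢ/(1+λᵢ)],

over the eigenvalues λᵢ ≥ 0 of B = WᵀA⁰⁻¹W — manifestly non-negative,
zero only for an untethered point. `DPAEngine` shares one
eigendecomposition of H⁰ across the whole field; `relative_entropy`
evaluates the same quantity from two explicit Hessians, and the two
routes are tested against each other.

**Surface points.** An internal deterministic generator decorates every
heavy atom with a Fibonacci lattice on a sphere of radius r_vdw +
2·probe (probe 1.5 Å), at the target areal density (1 point/Å², count
⌈4πR²·density⌉ per atom), then removes points buried inside another
atom's expanded sphere. Lattices are laid out in a principal-axes frame
of the heavy atoms, with axis signs fixed by third moments and
handedness by the cross product, so the point field co-moves exactly
under global rotation/translation of the structure — the whole pipeline
is rigid-motion equivariant by construction. The optional `seed` adds a
reproducible extra rotation. Triangulation vertices from an external
molecular-surface program can be supplied instead wherever a point
array is accepted; site membership is robust to the generator choice at
the 5 Å residue cutoff, but point-for-point output is not expected to
match any particular triangulator.

**Selection, clustering, sites.** The D_x field is fit by a Gumbel
(extreme-value) distribution via maximum likelihood; points with fitted
CDF ≥ 0.96 are selected (roughly the top 4% of a well-fit field — the
literal "upper 96% of points" reading would contradict the sparse
cluster labels of the output format). Selected points are clustered
with OPTICS extracting DBSCAN-style clusters at a single reachability
of 5 Å and a minimum of 3 points; selected-but-unclustered points are
labelled XX, sub-threshold points NN. Residues with a heavy atom
within 5 Å of any cluster point form the site; sites are ranked by
cluster mean D_x and lettered O, P, Q, … A residue near two clusters
belongs to both sites.

**Defaults** (all overridable on `predict_sites` and the CLI):
r_c 10.5 Å, r_s 15.5 Å, γ_s/γ = 12, probe 1.5 Å, density 1 Å⁻²,
quantile 0.96, eps 5 Å, min points 3, site cutoff 5 Å, Cα nodes.
An all-heavy-atom node option exists (`nodes="heavy"`); Cα is the
default because the network model is parameterized for residue-level
granularity.

## Annotations

* **NSM sites** — a "small molecule" is any mmCIF chain (gemmi
  subchain) not part of a protein chain associated with a domain:
  organic molecules, ions, nucleic acids, and short peptides all
  qualify; water is excluded; there is no molecular-weight filter. A
  site is the set of residues with a heavy atom within 5 Å of the
  molecule's heavy atoms. Hydrogens are ignored on both sides even if
  present.
* **Ligand validity** — MOAD-style records (`pdb_id,codes,validity`)
  are matched to sites by the ordered hetero-code list; matching is
  exact by default, with an optional synonym map for naming drift
  between the PDB and curation databases (e.g. GGL↔GLU in
  glutathione). One record labels every instance of the molecule.
* **Catalytic residues** — CSA-style CSV rows keyed by author chain and
  residue number; only literature-evidenced (`LIT`) rows are used,
  PSI-BLAST transitive rows are dropped at load time.

Residues are keyed `(chain_id, auth_seq_num, icode)` with a blank
default insertion code; the first alternate location is kept when a
file provides several.

## Text mining

Patterns are composed from sub-expressions for amino-acid names (full,
3-letter, 1-letter), positions (1–99999), connectors (space, hyphen,
en/em dash) and mutation linkers (arrows including U+2192, "mutated
to"-style phrasing). One-letter codes are accepted only inside the
compact mutation form (G146A); a bare name without a position is never
a mention. Mutations are normalized to (wild-type, position, mutant);
records where the two codes coincide are discarded.

The default *compat* mode reproduces two documented over-generations of
the original extraction system — full name + parenthesized number
("tyrosine (6)") and a trailing capital after a 3-letter mention
("Cys105L", where the letter may in fact denote a chain) — because the
evaluation counts this package reproduces were produced by a system
with those behaviours. `strict` disables both classes. Gene/cell-line
lookalikes (E2F, T47D) are deliberately not filtered in either mode;
the physical-grounding step is the designed filter for them.

Evaluation matches normalized records (code + position, plus mutant
code for mutations); span agreement is additionally required for
corpora annotated with character offsets. Micro-averaged
precision/recall/F1 use the standard formulas; undefined precision
(no system output) is reported as 0 with a flag.

## Grounding

Per abstract: group mentions by position into text residues; discard
groups with conflicting wild-type codes (ambiguous text); match the
rest against all protein chains of every linked structure by author
residue number and residue name (primary or any mutant code, so mutant
structures match); within one entry, accept multiple matches only when
they share a molecular entity (homodimer chains ground together,
cross-entity matches are dropped as ambiguous). Matching is exact —
no renumbering offsets — and only residues with a blank insertion code
are eligible. Entity identity comes from mmCIF `label_entity_id`; for
PDB-format input gemmi assigns one entity per chain, so same-entity
multi-chain grounding is only meaningful for mmCIF input.

## Transfer and conservation

Protein-level MSAs align the domains of one protein; the family MSA
aligns one representative per protein (longest domain, ties broken
alphabetically by SID) and requires at least two distinct proteins.
Composing the two yields the virtual alignment. Annotations propagate
along columns only between residues in the same fuzzy amino-acid group
({D,E}, {K,R,H}, {S,T}, {N,Q}, {I,L,V,M}, {F,Y,W}, {A,G}, {C}, {P}) —
shipped as an explicit, versioned, overridable YAML table, since the
historical curation web page defining the grouping is no longer
canonical. Family scope includes protein scope by construction, so the
set of transfers grows monotonically from protein to family level.

Column conservation is H.norm = 1 − H/ln 22 over the 22-symbol
alphabet (natural log; the base cancels). Percentile ranks within a
domain are rank/N, descending, ties averaged (the rank/N convention was
chosen over (rank−½)/N; at typical domain sizes the difference is below
any threshold used here). The lumped site score z is the product of a
site's L percentile ranks, excluding unscored residues from L rather
than imputing them, and its p-value is Q(L, −ln z), the upper
regularized incomplete gamma — the closed form of the
product-of-uniforms null, evaluated this way for numerical robustness
at large L. Conservation requires a family alignment of at least 10
sequences.

## Integration

Site overlap uses residue sets: recall of an annotated site is the
covered fraction against the union of all predicted residues; precision
of a predicted site is its fraction inside the reference set (all NSM
residues, or only validated ones). "A site matches" means nonempty
intersection; threshold curves use ≥ comparisons. Enrichment ratios
support two rounding modes: `paper` rounds each rate to a whole percent
before dividing (the convention of printed worked examples), `exact`
divides raw fractions. The per-residue report has the fixed 13-column
layout (cluster id = domain id + "." + rank letter, entity/chain/
number/icode/name, six binary flags, hetero-code list with curation
status in parentheses), one row per (site, residue) pair.

## Synthetic data

`fixtures.make_structure` builds a V-shaped two-arm Cα/Cβ scaffold:
two jittered arms (3.8 Å spacing, 40° apart, slight out-of-plane
modulation) meet at a hinge, and a three-atom hetero molecule can be
placed in the cleft at a controlled distance from each arm. The cleft
is small relative to the total surface, which keeps the perturbation
field right-skewed the way real pocketed proteins behave under this
analysis; an earlier uniformly-concave design saturated the field and
is documented here as a warning about generator realism. Gold pocket
residues come from a direct all-pairs distance scan over the rounded
coordinates actually written. `make_abstract` plants mentions in
controlled styles with exact spans, plus distractor tokens (gene and
cell-line lookalikes) whose positions are chosen outside the
structure's numbering range so that grounding, not extraction, rejects
them. `make_msa` plants fully conserved columns among near-uniform
ones. Identical seeds give byte-identical files.

What the generators do **not** emulate: real secondary structure and
packing, crystallographic noise, altloc/icode complexity, multi-domain
entries, abstracts with genuine linguistic variety beyond the
documented styles, and alignments with realistic phylogenetic
correlation. Passing tests therefore demonstrate the correctness of the
algorithms under controlled geometry and text, not field performance on
PDB-scale data; corpus-wide statistics additionally depend on database
snapshots and are out of scope by design.

## Problem sizes and determinism

Tests and the acceptance script use 30-residue fixtures (~3,800 surface
points, sub-second per pipeline run) and 10⁵-draw Monte-Carlo checks —
sizes chosen so the whole suite exercises every stage in seconds while
leaving the algorithms identical to what larger inputs would use. All
randomness flows through explicit seeds; a fixed seed reproduces the
full pipeline bit-for-bit.
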