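# Methods

## The model

`ensemblepharm` implements a structure-based pharmacophore workflow built on
the conformational-selection picture of ligand binding: a protein samples an
ensemble of binding-site conformations, and ligands preferentially bind a
minority subset of them.  Given (i) an ensemble of N site conformations with
identical atom ordering, and (ii) a per-frame binary label marking the
binding-selected conformations (obtained upstream, e.g. from ensemble
docking), the workflow identifies the pharmacophore features that
discriminate binding from non-binding frames and turns them into a screening
query:

1. **Superposition.** All frames are least-squares superposed (Kabsch,
   proper rotations only) onto the first frame using the heavy atoms of the
   site; hydrogens never enter the fit.
2. **Perception.** Site atoms are typed into annotation points — donor
   (Don), acceptor (Acc), cation (Cat), anion (Ani), aromatic/π-ring
   (Aro/PiR), hydrophobic atom/centroid (Hyd/HydA) — via an explicit
   residue-template rule table (`rules.py`, versioned).  Points become
   radius-bearing spherical features: 1.2 Å for Don/Acc/Cat/Ani, 1.4 Å for
   aromatic, 1.6 Å for hydrophobic.  Hydrophobic points within 1 Å are
   transitively grouped into one feature whose radius grows to cover the
   members, capped at 3 Å.  Co-located Don/Acc, Don/Cat, Aro/PiR and
   Hyd/HydA points (within 0.5 Å, configurable) merge into combined
   classes, which matching treats as satisfied by either member.
3. **Consensus.** Per-frame features are clustered class-by-class by greedy
   leader clustering (default radius 1.5 Å); each consensus feature carries
   the fraction of frames contributing at least one member.  Frequency
   counts distinct frames, so the binary occurrence matrix (frames ×
   consensus features) has column means exactly equal to the frequencies.
4. **Frequency bands.** Analysis can be restricted to features whose
   frequency lies in a band (1 %–{5, 10, 15, 20, 25} %, or no threshold):
   features of minority binding conformations are necessarily infrequent,
   and ubiquitous features carry no discriminative signal.
5. **Ranking and voting.** Every column is scored against the label by four
   statistics — one-way ANOVA F, plug-in mutual information (bits),
   recurrence-plot diagonal-line entropy (nats) of the column in frame-time
   order, and |Spearman ρ|.  Each method keeps its top-k; features kept by
   all four (voting score 4) are selected.
6. **Screening.** Selected features form a query (≥ 3 features).  A ligand
   conformer matches when some class-compatible assignment of its
   annotation points to the query features admits a proper rigid
   superposition placing every point inside its feature sphere (plus an
   optional tolerance); the match RMSD is the least-squares residual and
   the minimum-RMSD conformer represents the molecule.  Screening an
   active/decoy library yields the hit-ratio enrichment factor
   EF = (active_hits/decoy_hits)/(actives_total/decoys_total).

## Statistical conventions

- **ANOVA F** is the textbook MS_between/MS_within.  Perfect separators
  (zero within-group variance, nonzero between) receive a +∞ sentinel and
  rank first — they are precisely what the method seeks; columns with equal
  group means give F = 0.
- **Mutual information** is the plug-in estimate over the empirical 2×2
  table in log base 2, so a balanced column identical to the labels scores
  exactly 1 bit.  No normalisation is applied by default.
- **RQA entropy** is the Shannon entropy of the maximal diagonal-line
  length histogram of the exact-match recurrence plot of a column's binary
  presence series, with minimum line length 2 and the line of identity
  excluded.  Lines spanning an entire diagonal are excluded as well: their
  length is set by the finite plot border, not by the dynamics, so a
  constant series carries no line structure and has entropy 0.  The series
  order is the frame (time) order of the ensemble, which the pipeline
  preserves end to end.
- **Spearman** uses average ranks for ties and returns |ρ|; a constant
  column scores 0 (degenerate) rather than erroring, but constant columns
  are dropped before ranking anyway.
- **Ties** in any ranking are broken by ascending feature id, which makes
  the whole pipeline bit-reproducible.

## Matching semantics

The correspondence search enumerates injective class-compatible
assignments with admissible pairwise-distance pruning
(|d_query(i,j) − d_ligand(i,j)| ≤ r_i + r_j + 2·tol implies the pair can
still be placed inside its spheres), evaluating each survivor by proper
Kabsch superposition; the search is therefore exact, and it is verified
against an exhaustive assignment enumeration in the tests.  Reflections are
never accepted (det = +1).  Default matching requires all query features;
m-of-n relaxation is available and can only grow the hit set.

## Tunable parameters

| parameter | default | unit | role |
|---|---|---|---|
| site cutoff | 6.5 | Å | proximity radius defining the site around reference points |
| feature radii | 1.2 / 1.4 / 1.6 | Å | Don,Acc,Cat,Ani / aromatic / hydrophobic sphere radii |
| Hyd merge distance | 1.0 | Å | transitive grouping threshold for hydrophobic points |
| Hyd max radius | 3.0 | Å | cap on a merged hydrophobic feature |
| overlap tolerance | 0.5 | Å | Don&Acc / Don&Cat / Aro&PiR co-location threshold |
| cluster radius | 1.5 | Å | leader-clustering radius for consensus features |
| band (low, high) | (1 %, none) | frequency | retained consensus-feature frequency band |
| k | required | — | per-method top-k before voting |
| match tolerance | 0.0 | Å | slack beyond feature radii during matching |
| l_min | 2 | — | minimum diagonal line length for RQA entropy |

The Cat/Ani radius (1.2 Å) and the overlap tolerance are package choices —
the reference feature scheme publishes only the Don/Acc/aromatic/
hydrophobic radii — and both are configurable.  The cluster radius is
likewise not published by the upstream clustering tool; 1.5 Å is of the
order of the feature radii and is exposed as `--cluster-radius`.

## Synthetic data: what it emulates and what it does not

`synthetic.make_ensemble` generates a pocket of inert scaffold pseudo-atoms
jittered i.i.d. per frame, plus one pseudo-atom per planted or nuisance
feature whose per-frame presence is a recorded Bernoulli draw — planted
features occur at high rate (default 0.9) in the binding minority (default
10 % of frames) and low rate (0.05) elsewhere; nuisance features occur at
label-independent rates.  An absent feature's atom is displaced 60 Å out of
the site sphere so every frame keeps the same atom count.  Because the
draws are recorded, downstream occurrence frequencies are checkable
bit-exactly.  `make_library` plants actives with exactly one
guaranteed-matchable conformer (points within a jitter radius of the query
centers, then randomly rigidly moved) and decoys that provably cannot match
(one feature short, or geometry scaled past any distance-consistent
assignment).

This validates the machinery, not the biology: real binding sites have
correlated (not i.i.d.) atomic motions, features that drift and exchange
between clusters, imperfect labels, and decoys that fail softly rather
than by construction.  Passing tests demonstrate that the pipeline
recovers signals it is designed to recover under controlled conditions,
not that any particular protein's screening enrichment will be reproduced.

## Numerical and design choices

- Superposition, and match scoring, use `scipy`'s rotation alignment
  (proper rotations by construction); ill-conditioned fits (< 3 heavy
  atoms, collinear sites) are hard errors.
- Greedy leader clustering is O(N·K) and deterministic in frame order; a
  feature joins the first (earliest-founded) cluster within the radius.
  Consensus ids are assigned in descending frequency ("F1_…" most
  frequent).
- The site atom set is fixed from frame 1 in residue-list mode and
  re-evaluated per frame in proximity mode (so conformational excursions
  out of the pocket drop their features).
- The "no threshold" run keeps all columns; the 1 % lower bound applies
  only to banded runs.
- Zero-variance columns are dropped before ranking; requesting k larger
  than the surviving column count is an error rather than a silent
  truncation.
- Enrichment edge cases are flagged, never silent: no hits → NA, no decoy
  hits → +∞ sentinel, no active hits → 0.  A decoy-free library can only
  produce NA or the sentinel.  A conventional top-x % EF is provided
  separately (`ef_at_fraction`) and is never mixed into reports.
- Manual feature curation is supported (`manual_ids` / `--features`): the
  vote table is still computed, but the query is assembled from the given
  ids.

## Problem sizes

The shipped study sizes are chosen for a laptop-scale reproduction:
ensembles of 150–600 frames with 20 scaffold atoms and 3 planted + 4–6
nuisance features, libraries of 50 actives and 500 decoys with 3 conformers
per molecule, and 20-seed replicate sweeps.  All stages scale linearly in
frames and molecules except correspondence search, which is exponential in
query size in the worst case but pruned to negligible cost at the ≤ 8
features typical of pharmacophore models.

## Known limitations

- Protein typing relies on residue templates; nonstandard residues (and
  residues missing from the table) are silently untyped.  The table's
  histidine convention is the neutral δ-tautomer (ND1 acceptor, NE2 donor);
  `HIP` is treated as imidazolium.
- No directional (vector) donor/acceptor constraints and no excluded
  volumes — features are point spheres.
- No conformer generation, protonation, or docking: multi-conformer input
  is consumed as given.
- Binding labels are an input; the package neither produces nor audits
  them.
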