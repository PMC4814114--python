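# Methods

## Model of the TM bundle

A receptor's membrane-spanning region is represented as a `TMBundle`: seven
ordered, gapless runs of residues in author (structure-file) numbering, each
residue carrying its heavy atoms. TM extents are input, not derived: the
membrane-slab core comes from an OPM-style annotation table, optionally
widened outward by `extend_tm_by_helix` while DSSP labels the residue 'H'
(strictly α-helix; 3₁₀ and π codes do not extend a TM). Annotations are a
user-editable CSV precisely because published helix extents occasionally
need manual correction; the table is the source of truth.

Structure reading (gemmi) drops hydrogens and zero-occupancy atoms,
collapses alternate locations to the highest-occupancy atom (ties broken
toward altloc 'A' — deterministic and the common convention), and maps
modified residues to standard parents (MSE→M etc.) via a small built-in
table: contact counting needs side-chain bulk, not chemistry.

## Contacts

Two residues on different helices are in contact when any heavy-atom pair is
closer than r(a) + r(b) + slack. Defaults: Bondi radii (C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80, Se 1.90 Å; 1.70 Å for anything else) and slack
0.6 Å, both overridable through `ContactParams`. Backbone and side-chain
atoms are not distinguished — the chemically nonspecific definition is what
lets a contact be traced between receptors whose residues are unrelated.
Detection is vectorized (one distance matrix over all heavy atoms); the test
suite checks it bit-for-bit against an independent double-loop oracle on
randomized bundles.

Conserved sets are pure counting: class-A conserved contacts are those in at
least `min_count` of the class-A panel (the reference analysis uses
23-of-24, including active conformations); CHICOs are the subset also
present in every non-class-A structure. Whether "every structure" should
instead read "every class" is not decidable from the published description,
so all-structures is the default and `min_count` is exposed.

## Anchor search

BW labels follow from per-helix n.50 anchors; aligning a structure means
choosing seven anchors. Candidates are scored by the cumulative number of
BW-identical contacts shared with a reference panel (a contact matched in 20
references adds 20). The joint ±10-per-helix space (21⁷ anchor sets) is
never enumerated directly: shifting helix *n* only relabels contacts that
involve *n*, so the score decomposes into per-helix-pair tables
f_{mn}(s_m, s_n) computed once. The default search is coordinate ascent over
these tables (exhaustive per helix with the other six fixed, iterated to a
fixed point — exact whenever the pairwise landscape is separable, which the
planted-shift tests confirm for contact-rich bundles); a joint exhaustive
mode over the full grid is available for windows ≤ 4 (±1 helical turn).
Shifts that push an anchor outside its TM range are skipped. Ties are broken
by lower Cα RMSD against a designated primary reference, then by smaller
total |shift|; the enumeration order of the published analysis is not
stated, so both search modes are provided. A `pinned` override fixes chosen
helices to a given shift (logged) for cases where an alignment is selected
for cross-receptor consistency rather than raw score — the situation that
arises when two close paralogs should share one alignment.

Superposition RMSD pairs Cα atoms by BW label over the maximal overlapping
span of each helix and solves the least-squares rotation by SVD (Kabsch,
proper rotation enforced); tests cross-check against scipy's
quaternion-based `Rotation.align_vectors`.

## Activation comparison

Contacts from inactive/active panels split into: common to every structure
of both states; present in all inactive and no active structure; and the
reverse. The strict all-or-none rule is the default because the published
criterion is not stated more precisely; `min_present` relaxes presence to
≥m structures of a state (absence stays absolute). NACHO residues are the
deduplicated participants of the changed contacts.

## Similarity, trees

TM percent similarity between two aligned receptors counts BW columns whose
substitution-matrix entry is positive, over the compared span (default: the
extent both proteins share; the class-average span of an alignment table via
`average_tm_spans` reproduces table-driven comparisons). BLOSUM62 comes from
biopython's canonical matrix; any whitespace-separated square matrix with a
header row of letters (e.g. GPCRtm, published elsewhere) can be loaded from
file. Group-versus-group shift scans displace one group's anchor on one
helix by −5..+5 and report mean cross-pair similarity (self-pairs excluded)
— the robustness test used to place chemosensory subfamilies.

Trees: UPGMA on dissimilarity 100 − similarity. The implementation is
in-package (~50 lines) because determinism requires an explicit tie rule —
minimum average dissimilarity, ties broken by the lexicographically smallest
pair of cluster labels — and because a greedy sequential variant (grow one
cluster by absorbing the outsider with lowest average dissimilarity), which
matches an alternative reading of the published prose, is offered as a
second mode. Node height is the merge dissimilarity; branch lengths are
half-height differences, so leaf-to-leaf path lengths reproduce an
ultrametric input exactly. scipy's average-linkage is the independent
cross-check in the tests, and output is standard Newick via scikit-bio.

## Variants

A variant maps through the alignment table to a BW position iff its sequence
position falls inside a TM range. Scoring:
`d_nacho + d_chico − mult_nacho − mult_chico + blosum62(wt, mut)`, where
distance is |ΔBW index| to the nearest roster residue *on the same helix*
(sequence residues, not Å — the rosters are defined per TM), multiplicity is
the number of roster contacts at that nearest residue, and the matrix entry
keeps its sign. Distance ties resolve to the higher-multiplicity residue
(then lower index) so the score is deterministic and conservative. A helix
carrying no roster residue contributes a sentinel distance of +20 — larger
than any real TM offset — keeping the ranking total and finite; such records
are flagged. Cohort summaries report the all/TM/non-TM/CHICO/NACHO/both
partition with disease-annotated counts and one-decimal percentages;
olfactory and unassigned receptors are excluded below the "all" row by
default, matching how published cohort tables are restricted.

## Rigid helix moves

Bundles are first superposed globally over all BW-paired TM Cα atoms (the
fit can be restricted, e.g. to exclude a helix known to bend). Per helix:
the axis is the rotation axis of the least-squares screw superposing the Cα
trace onto itself shifted by one residue — exact for ideal helices of any
rise/turn and robust to coordinate noise (≤ ~1.4° at σ = 0.2 Å), with a PCA
fallback for degenerate traces; orientation follows residue order so signs
agree between structures. The centroid displacement splits into the axial
projection (signed) and its perpendicular norm; tilt is the angle between
the two axes; spin is the least-squares rotation about the axis after
removing translation and tilt (signed, (−180, 180]); residual RMSD is the
per-helix Kabsch fit. Swapping the structures negates axial translation and
spin and preserves tilt. Signed axial values are kept in tables; magnitudes
are what move-size-versus-similarity scatters plot.

## Synthetic fixtures

The generators define the study conditions for every self-contained test:

* **Bundles**: seven ideal α-helices (1.5 Å rise, 100°/residue, Cα at 2.3 Å
  from the axis) on a ring, with Cβ (+1.53 Å) and Cγ (+3.06 Å) pseudo-atoms
  standing in for side-chain bulk (none for Gly, Cβ only for Ala). Because
  two pseudo-atoms carry less bulk than real side chains, the default ring
  radius is 9.0 Å (adjacent axis separation ≈ 7.8 Å), chosen so a default
  bundle yields ~150–200 inter-helical contacts — the same order as a
  receptor crystal structure, and the richness the planted-shift recovery
  guarantees assume. Gaussian coordinate noise and per-helix tilt/phase are
  available; everything is deterministic per seed.
* **Planted scenarios**: `renumber` shifts author numbering without touching
  coordinates (anchor-search ground truth); `perturb` applies exact rigid
  per-helix moves and optional whole-bundle motion (move-decomposition
  ground truth).
* **Families**: ancestor TM sequences mutated per site with a set
  probability (uniform over the other 19 letters), assembled into alignment
  entries with short linker loops. With the default 10% substitution rate,
  within-family similarity is ~80–85% and between-family ~15–17%, mirroring
  the within-subfamily versus cross-class contrast of real receptors.

What the fixtures do *not* emulate: real side-chain packing and rotamers,
helix kinks and bends (notably the proline-induced TM6 kink), loop
similarity, and the uneven class sizes of the real superfamily. Passing
tests therefore demonstrate the correctness of the algorithms — detection,
search, decomposition, clustering, scoring — not the biological values of
the published analysis, which depend on the experimental structure panel.

## External regression inputs

Two acceptance tiers re-run the published analyses when their inputs are
supplied (they are not shipped; the tests state what is missing otherwise):

* `data/external/s2_alignment.csv` — the superfamily alignment table
  (columns `uniprot_ac, class, bw150_idx..bw750_idx, tm1_start..tm7_end,
  sequence`) and `data/external/s3_variants.csv` — the natural-variant list
  (`uniprot_ac, position, wt, mut, annotation` plus tabulated
  `d_chico/d_nacho` and roster columns).
* `data/external/structures/` — the crystal-structure panel: `manifest.csv`
  (`structure_id, path, chain, class, state`), per-structure
  `annotations.csv` and `anchors.csv`, `initial_anchors.csv` for the
  cross-class searches, and `similarities.tsv` for the move-bound checks.

## Problem sizes

Default test and acceptance runs use 26-residue helices (182 residues,
~550 heavy atoms, ~160 contacts per bundle), reference panels of 1–6
bundles, families of 4 × 8 sequences, and variant cohorts of 120–300
records — sizes at which every oracle comparison is exact and the full suite
runs in seconds.

## Known limitations

Coordinate-ascent anchor search is exact only for separable landscapes
(joint mode covers small windows exhaustively); contact detection is a hard
distance threshold, so near-threshold atom pairs flip with coordinate noise;
the greedy tree mode is a deliberately literal reading of an ambiguous
published description and produces caterpillar topologies; variant scoring
treats all helices as independent and ignores Å-space proximity across
helices.
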