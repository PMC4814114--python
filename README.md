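# gross

Structure-based, gap-free sequence alignment of G-protein coupled receptor
(GPCR) transmembrane domains, and the analyses it enables.

## The problem

GPCRs share a fold of seven membrane-spanning α-helices (TM1–TM7), but
sequence identity between the receptor classes (A, B, C, F, Adhesion) drops
to 20–30%, where ordinary sequence aligners fail or insert gaps inside the
helices — fatal for homology modelling. What *is* conserved across the
superfamily is the packing of the helices: the inter-helical residue
contacts. This package aligns TM domains by maximizing conserved
inter-helical contacts instead of sequence similarity.

The key objects:

* **Ballesteros–Weinstein (BW) numbering** `n.x`: helix `n`, offset `x`,
  with the reference residue of each helix fixed at `n.50`. Because the TM
  alignment is gapless, choosing one anchor residue per helix fully
  determines every label: `x = 50 + (author_index − anchor_index)`.
* **Inter-helical contact**: a residue pair on different TMs with any two
  heavy atoms closer than the sum of their van der Waals radii + 0.6 Å.
* **Anchor search**: candidate anchor sets (per-helix shifts up to ±10
  residues, no gaps) are scored by the cumulative number of contacts shared
  with a reference panel, `score(s) = Σ_ref |C_target(s) ∩ C_ref|`; shifting
  helix `n` only relabels contacts involving `n`, so the score decomposes
  over helix pairs and the search is exact.
* **CHICOs** (Conserved inter-HelIcal COntacts): contacts present in nearly
  all class-A structures and in every structure of the other classes — the
  superfamily structural fold.
* **NACHOs** (Native ACtivation Hot-spOt residues): residues whose contacts
  differ systematically between inactive and active conformations.
* **Variant score** for a natural variant mapped to BW position `p`:
  `d_NACHO(p) + d_CHICO(p) − mult_NACHO − mult_CHICO + BLOSUM62(wt, mut)`,
  lower = more likely to disrupt fold or activation.
* **Rigid helix moves**: between two superposed structures, each helix's
  residual motion is decomposed into axial/perpendicular translation, axis
  tilt, and rotation (spin) about the axis.

## Worked example

Plant a known numbering shift on one helix of a synthetic bundle and let the
anchor search recover it:

```python
from gross.synthetic import BundleSpec, make_bundle, renumber
from gross.contacts import detect_contacts
from gross.alignment import search_anchors

sb = make_bundle(BundleSpec(seed=1))                 # idealized 7-TM bundle
reference = detect_contacts(sb.bundle, sb.anchors)
print(len(reference))                                 # 157 inter-helical contacts

shifted = renumber(sb, {4: +3})                       # renumber TM4 by +3
best = search_anchors(shifted.bundle, sb.anchors, [reference], window=5)[0]
print(best.shifts)          # {1: 0, 2: 0, 3: 0, 4: 3, 5: 0, 6: 0, 7: 0}
print(best.cumulative_common)                         # 157
```

The search finds the anchor set that restores all 157 contacts — the +3
shift on TM4 and zero elsewhere. The same machinery, run with a class-A
reference panel against a class B/C/F structure, produces the cross-class
anchor tables; `gross --help` exposes the pipeline as shell commands
(`contacts`, `align`, `nacho`, `tree`, `variants`, `simulate`).

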