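# ribrot

Planar inter-subunit rotation analysis and model comparison for two-state
macromolecular assemblies.

Large ribonucleoprotein machines such as the ribosome move between
conformational states largely by rigid-body rotation of one subunit
relative to the other. Given two atomic models of the same assembly —
for example the two conformational classes of the yeast mitochondrial
ribosome, where the small subunit (mtSSU) reorients against the large
subunit (mtLSU) — `ribrot` answers: *by how much did the mobile subunit
rotate, about what center, and which residues moved beyond that rigid
rotation?* It is aimed at structural biologists comparing cryo-EM
conformational classes or depositions of the same complex.

## Method

With models A (start state) and B (end state) and a chain partition into
a reference subunit, a mobile subunit, and excluded chains (tRNA, mRNA,
ligands):

1. **Correspondence & frame.** Backbone atoms (nucleotide P, amino-acid
   Cα, or both) are matched by identity `(chain, residue, atom)` and
   model B is superposed onto model A by a least-squares proper rigid
   transform (Kabsch) on the reference-subunit backbone.
2. **Separating plane.** A plane maximally separating the two subunit
   point clouds is fitted; the normal **n** is the Fisher
   linear-discriminant direction
   **n** ∝ S_w⁻¹(μ_mobile − μ_ref), where S_w is the pooled within-subunit
   scatter.
3. **Displacement field.** Mobile-atom start positions and displacement
   vectors **d**_i = **x**_i^B − **x**_i^A are projected into the plane.
   Atoms with |**d**_i| ≤ 3 Å (3D distance, strict threshold) are
   discarded so coordinate error does not masquerade as motion.
4. **Rotation center.** The in-plane center **c** maximizes the
   tangentiality of the field: it minimizes the mean squared cosine
   between each displacement and the radial direction from **c** to the
   chord midpoint (for circular motion the chord is exactly perpendicular
   to that radius). The search is a deterministic coarse grid followed by
   Nelder–Mead refinement.
5. **Angles.** Each retained atom gets the exact chord angle
   θ_i = 2·arcsin(|**d**_i^∥| / 2 r_i), with r_i its in-plane distance
   from **c**; the field is summarized by the median (default) or mean,
   with the interquartile range as dispersion and the majority
   cross-product sign as the rotation sense.

Beyond the rotation, per-residue displacement profiles, threshold-based
difference-region calling, single-residue displacement measurement and
chain-composition diffs (on canonical entity names) cover the
non-rotational comparisons. A synthetic-assembly generator with known
ground truth (rotation angle, axis, center, noise, remodeled residues)
makes every stage verifiable without any downloads.

## Worked example

```sh
ribrot make-synthetic --seed 11 --out assembly
ribrot analyze-rotation \
    --model-a assembly/model_a.pdb --model-b assembly/model_b.pdb \
    --partition partition.yaml --atoms both --out run/rot
```

with `partition.yaml` containing:

```yaml
reference_chains: [R]
mobile_chains: [M]
```

The generator defaults emulate the study geometry: a 5.2° rotation of a
~130 Å mobile subunit with 0.2 Å Gaussian coordinate noise. The run
prints

```
INFO match_backbone[mobile]: 500 matched, 0 only in A, 0 only in B
INFO rotation center (-91.186, -1.839) Å, objective 7.806e-04, 489 atoms
INFO atom_class=both: angle 5.1448 deg (median), 5.1328 (mean), 489 retained
```

i.e. 489 of 500 mobile backbone atoms moved more than 3 Å and their
median chord angle recovers the built-in 5.2° rotation to within 0.06°;
the tangentiality objective (mean squared cosine, 0 = perfectly
tangential field) is 7.8·10⁻⁴. `run/rot.both.summary.json` carries the
same numbers plus the plane, center, IQR (0.21°) and rotation sense
(ccw); `run/rot.both.field.tsv` holds the per-atom table from which every
summary value can be recomputed.

`ribrot diff-models` produces the per-residue displacement profile,
called difference regions and (given a chain-name map) the composition
diff; `ribrot analyze-rotation --figures` adds the in-plane vector-field
figure with arrows colored by 3D displacement.

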