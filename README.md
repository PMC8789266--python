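# dentmark

Automated landmark recognition and occlusal scoring for 3D dental arch
meshes.

Quantifying dental arch relationships — for example maxillary arch
constriction after cleft lip/palate surgery — traditionally requires an
expert to place cusp landmarks on each digital model by hand. `dentmark`
automates the whole chain on intra-oral scans and scanned study casts
(STL, millimetres): it orients the arch, finds cusp-tip candidates,
partitions the surface into individual teeth, labels them with Palmer
notation, extracts one landmark per tooth, and converts an
occlusion-registered maxillary/mandibular pair into modified
Huddart–Bodenham (MHB) ordinal scores. It is aimed at orthodontic and
cleft-care researchers who need objective, reproducible scoring of large
model collections.

## Method in brief

* **Orientation** — PCA of the vertex cloud (arch width > length >
  height fixes the axes), shape heuristics for the signs, and a
  least-squares plane through the tooth tips to refine the occlusal
  direction.
* **Peak points** — local maxima of occlusal height within 6 mm of the
  highest point: candidate cusp tips.
* **Tooth partition** — signed dihedral curvature per edge
  (κ > 0 convex, κ < 0 crease); breadth-first region growing from each
  peak that will not cross creases with κ ≤ −0.6 rad; regions that run
  more than a tooth's width instead of meeting a crease are "spilled" and
  discarded; overlapping regions and same-arch-position halves merge.
* **Tooth assignment** — each blob's feature vector (area, mesiodistal
  and buccolingual widths, crown height, cusp count) is matched to
  per-type training statistics by summed squared z-scores; a dynamic
  program aligns the ordered blobs onto the arch template
  MMMPPCIIIICPPMMM (permanent) or mmciiiicmm (deciduous), with gaps
  (missing teeth), discards (non-tooth residue) and mesial/distal
  half-molar pairs (UR6.0/UR6.1).
* **MHB scoring** — a chord-length cubic spline through the mandibular
  cusp landmarks and a least-squares horizontal reference plane; each
  maxillary landmark's shortest-distance vector to the curve is projected
  into the plane and signed along the buccal direction
  (d < 0 = lingual/crossbite), then mapped through the ordinal MHB step
  function and summed into an arch total.

A deterministic synthetic-arch generator (implicit surfaces + marching
cubes, full ground truth: per-tooth face masks, cusp apexes, intended
displacements) stands in for clinical scans in the test suite, and also
derives the packaged default training set. See `docs/methods.md` for the
full account.

## Worked example

Generate a synthetic mandibular arch and recognize it:

```bash
$ dentmark synth --seed 1 --out .
wrote synth1_L_perm.stl
$ dentmark recognize synth1_L_perm.stl --out report.json
synth1_L_perm.stl: 16 labelled blobs, 16 landmarks, cost 27.81
```

All 16 teeth were found and labelled (`report.json` lists the labels in
arch order — LR8, LR7, LR6, LR5, … — the landmark coordinates in mm, and
the total mismatch cost 27.81, i.e. about 1.7 squared-z units per tooth).
Jaw and dentition come from the `*_{U|L}_{perm|decid}.stl` filename
convention or from `--jaw/--dentition` flags.

Score an occluded pair:

```bash
$ dentmark synth --seed 3 --pair --out .
wrote synth3_U_perm.stl + synth3_L_perm.stl
$ dentmark score-mhb --maxillary synth3_U_perm.stl --mandibular synth3_L_perm.stl
tooth_type  displacement_mm segment  score
       UR6         0.870200  buccal     -1
       UR5         0.191473  buccal     -1
       ...
MHB total: -12
```

This pair was generated in neutral occlusion (every maxillary cusp
directly over the mandibular curve), so every signed displacement is
within ±0.9 mm of zero and each of the 12 scored teeth maps to the
ordinal score −1 (between the −1 mm and +1 mm breakpoints); the arch
total is the sum, −12. A crossbite tooth (e.g. generated with a −3 mm
transverse offset) would report d ≈ −3 and score −2.

`dentmark score-mhb` also accepts landmark CSVs (`tooth_type,x,y,z`)
instead of STLs, `dentmark train` rebuilds the training CSV from
synthetic arches, and `dentmark evaluate` runs the synthetic end-to-end
evaluation (outcome tally plus landmark deviation statistics).

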