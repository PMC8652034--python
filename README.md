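# flatfold

Family-wide protein secondary-structure 2D diagrams from Cα traces.

Classic topology-diagram tools draw each protein in isolation, so two members
of the same family — domains that are nearly identical in 3D — can receive
wildly different cartoons.  `flatfold` instead lays out a whole CATH-style
family at once: it detects α-helices and β-strands from Cα geometry, gives
topologically equivalent elements the same name across every member, and then
places each member's elements in the plane by **minimizing the error of
projecting their 3D arrangement into 2D**.  Elements close in space stay close
on paper, member diagrams are directly comparable, and a family-level
"multiple" diagram overlays the averaged elements with opacity proportional to
how often each one occurs.

## The layout model

Every diagram element (a helix, or a β-sheet moving as one rigid template) has
a 3D anchor point **a**ᵢ (helix axis midpoint; strand-midpoint centroid for a
sheet).  The layout chooses 2D positions **p**ᵢ minimizing the stress

```
S(p) = Σ_{i<j} ( ‖p_i − p_j‖ − ‖a_i − a_j‖ )²  +  λ Σ_i ‖p_i − s_i‖²
```

where **s**ᵢ is the element's position in a previously computed family
member's diagram (when one shares enough elements) and λ ≥ 0 restricts
deviation from that starting layout — this is what keeps diagrams of related
domains mutually consistent.  Minimization is deterministic gradient descent
with backtracking line search from a principal-plane projection of the
anchors, run in two stages: *primary* elements (present in ≥ 50% of members)
are placed first, then frozen while the rarer *secondary* elements are added.
Glyph angles come from projecting each element's 3D axis into the layout
plane.

Everything upstream and downstream of the layout is included: PDB/mmCIF
reading (via gemmi), P-SEA-style Cα secondary-structure detection,
cross-member label assignment by rigid superposition plus order-preserving
dynamic programming, β-sheet ladder detection with rigid sheet templates,
family occurrence statistics, SVG rendering, and a synthetic-structure module
that generates ideal helices/strands, composite domains and perturbed families
with ground-truth labels so the entire pipeline is testable offline.

## Worked example

```python
from flatfold import (FamilySpec, LayoutConfig, annotate_family,
                      compute_family_stats, detect_sses, layout_family,
                      make_family)
from flatfold.synthetic_data import mixed_recipe

# 5 jittered copies of a 2-helix + hairpin domain (σ = 0.3 Å)
spec = FamilySpec(recipe=mixed_recipe(), n_members=5, jitter_sigma=0.3, seed=7)
family = make_family(spec)
members = {d: (dom, detect_sses(dom)) for d, (dom, _) in family.items()}
annotated = annotate_family("9.99.99.99", members)
stats = compute_family_stats(annotated)
for label, ls in sorted(stats.per_label.items()):
    print(f"{label}: {ls.sse_type:6s} freq={ls.frequency:.2f} "
          f"avg_len={ls.avg_length:.1f} class={ls.sse_class}")

structures = {d: dom for d, (dom, _) in family.items()}
diagrams = layout_family(annotated, structures, stats, LayoutConfig())
d = diagrams["synA00"]
print(f"synA00: stress={d.stress:.4f} normalized={d.normalized_stress:.2e}")
```

prints

```
E1: strand freq=1.00 avg_len=6.8 class=primary
E2: strand freq=1.00 avg_len=7.4 class=primary
H1: helix  freq=1.00 avg_len=11.8 class=primary
H2: helix  freq=1.00 avg_len=10.0 class=primary
synA00: stress=0.0000 normalized=6.51e-32
```

Every element occurs in all five members (frequency 1.0, hence primary), and
this domain's element anchors happen to admit an essentially exact planar
embedding, so the final projection stress is numerically zero.  The hairpin
strands E1/E2 form one sheet element `S[E1+E2]` that moves rigidly during
layout.  `render_domain_svg` / `render_family_svg` turn the diagrams into SVG
cartoons (helices as rounded rectangles, strands as N→C arrows, family overlay
with `fill-opacity` equal to each label's frequency).

## Command line

```sh
flatfold synth    --out fam --recipe mixed --members 10 --jitter 0.3 --seed 7
flatfold annotate --domains fam/family.json --out out/annotation.json
flatfold layout   --annotation out/annotation.json --domains fam/family.json --out out/layouts
flatfold render   --layout-dir out/layouts --out out/svg
# or all four stages at once (byte-identical outputs):
flatfold run      --domains fam/family.json --out out
```

Annotation, statistics and layouts are plain JSON at documented schemas, so an
external annotator's output can be converted and dropped in at the
`annotate`/`layout` boundary.  Identical configuration and seed reproduce
every JSON and SVG byte for byte.

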