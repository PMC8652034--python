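# Methods

This note documents the models and numerical choices behind `flatfold`: what
each pipeline stage computes, which parameters matter, what the synthetic data
does and does not emulate, and where the design was genuinely open.

## Structures and domains

A structure is reduced to its Cα trace: one record per residue possessing a CA
atom, identified by (chain, author sequence number, insertion code).  Author
numbering is used throughout because CATH domain ranges are expressed in it;
ranges are inclusive at both ends.  Multi-model files contribute only their
first model; alternate locations resolve to the highest-occupancy CA (first on
a tie); HETATM residues are excluded.  Consecutive residues separated by more
than **5.5 Å** are treated as a chain break, and secondary-structure elements
never span a break.  The threshold separates two populations: an intact trace
has Cα steps of 3.8 ± a few tenths of an Å even under substantial coordinate
noise (staying below ~5 Å), while a single missing residue already leaves a
gap of ~5.6 Å or more.

## Secondary-structure detection

Detection is a P-SEA-style distance criterion on the Cα trace.  Residue *i* is

* helix-like when d(i,i+2) ∈ [5.1, 6.4] Å **and** d(i,i+3) ∈ [4.6, 6.0] Å,
* strand-like when d(i,i+2) ∈ [6.4, 7.4] Å,

runs of ≥ 4 helix-like / ≥ 3 strand-like residues become elements (the element
span extends to the last residue entering the defining distances), and helices
win where spans overlap.  Two robustness devices are layered on the literal
windows, both configurable in `DetectionParams`:

* `window_slack` (default **0.35 Å**) widens every window on both sides.  An
  ideal strand has d(i,i+2) = 6.6 Å, only 0.2 Å above the strand window's
  lower edge; under Cα noise of σ = 0.3 Å per coordinate the pairwise
  distances fluctuate with σ ≈ 0.42 Å, so without slack roughly a third of
  genuine strand residues fall out of the window and whole strands vanish.
* `bridge_gaps` (default on) closes single-residue holes inside flag runs
  (morphological closing), so one noisy residue cannot split an element.

Both devices leave ideal geometry classified identically — every ideal value
sits inside (or outside) the same windows with or without slack — and
`DetectionParams(window_slack=0, bridge_gaps=False)` restores the strict
literal criteria.

Element axes are total-least-squares lines through the element's Cα
coordinates, oriented N→C, with endpoints at the projections of the first and
last Cα.  For short ideal helices the fitted axis is tilted against the true
axis by a sampling-phase artifact (≈ 9° at 8 residues, ≈ 2° at 12, < 0.5° at
20); this is a property of fitting a discrete spiral, not noise.

## Family-consistent labelling

The member with the most elements is the reference (ties: lexicographically
smallest domain id); its elements are named H1, H2, …/E1, E2, … in sequence
order.  Every other member is rigidly superposed onto the reference (Kabsch on
the full traces truncated to equal length — this avoids needing a sequence
alignment) and matched to it by order-preserving, type-constrained dynamic
programming on element axis midpoints: a pair scores `10 − distance` (Å),
pairs beyond 10 Å are forbidden, gaps cost 0, so any allowed match is
preferred to none.  The superposition is refined once on the Cα of matched
elements and the match repeated.  Matched elements inherit the reference
label; unmatched ones get fresh labels suffixed with their domain id
(`H3.synA05`) so labels stay globally unique and each label carries exactly
one element type family-wide.

## Family statistics

Per label: occurrence count, frequency = count / members, arithmetic-mean
residue length.  Labels with frequency ≥ `primary_threshold` (default **0.5**,
boundary inclusive) are *primary*, the rest *secondary*.  The 0.5 default is a
declared convention for "common to most of the family"; it is a parameter, not
a derived value.

## Sheets

Two strands are ladder-paired when the symmetric mean nearest-Cα distance
between them is ≤ **5.5 Å** (typical ladder spacing of 4.8–5.0 Å plus slack);
orientation is parallel iff the N→C axis directions have non-negative dot
product.  Connected components of the pairing graph become sheets and must be
simple paths: β-barrels (cycles) and bifurcated sheets (a strand with three
ladder partners) raise `UnsupportedTopologyError` naming the strands —
drawing them approximately would misrepresent the topology, so they are
rejected rather than guessed at.  A sheet's 2D template places its strands as
parallel segments in path order, spaced **4.8** units apart, direction signs
propagated from the first strand through the ladder orientations (antiparallel
neighbours get opposite signs).  The template is rigid: layout moves only the
sheet's center and angle.  The path is traversed from the endpoint with the
lexicographically smaller label, making the template independent of input
order, and a sheet's element name is its sorted strand set (`S[E1+E2]`), which
is stable across members.

## Layout

Anchors: helix axis midpoint; sheet centroid of member-strand axis midpoints.
The objective is the raw squared distance-difference stress plus the
deviation penalty (README formula).  Numerical choices:

* **Initialization** — projection of the anchors onto their best-fit plane
  (principal axes; the first axis is 2D x, sign chosen so the first element
  in sequence order has non-negative x).  When a starting layout exists,
  labels it covers take its coordinates exactly and the projection of the
  rest is rigidly aligned (2D orthogonal Procrustes on the shared labels)
  into its frame.
* **Optimizer** — gradient descent with Armijo backtracking; iteration cap
  2000; convergence when the relative objective change drops below 1e-8;
  descent is monotone by construction.  Without a starting layout the three
  principal planes (1–2, 1–3, 2–3) are each tried and the lowest final
  objective wins — a deterministic multi-start; with a starting layout a
  single descent from the aligned start is used so the deviation penalty
  retains its meaning.  No randomness is involved by default.
* **Staging** — stage 1 minimizes over primary elements with only
  primary–primary pair terms; stage 2 freezes them and minimizes over
  secondary elements with every pair term touching a secondary element.
* **Deviation penalty normalization** — λ (default **0.05**) is scaled by
  `n_active_pairs / n_started_labels` inside each stage so the penalty is
  commensurate with the stress term regardless of family size.  The public
  `stress` function keeps the unnormalized form.
* **Starting-layout selection** — the previously computed member diagram
  maximizing the shared-label fraction, accepted when that fraction is ≥
  `min_overlap` (default 0.5); ties go to the smaller domain id.  Members are
  processed by descending element count so the richest member anchors the
  family frame.
* **Angles** — each element's 3D axis direction (for sheets, the mean
  sign-corrected strand direction) is projected into the layout frame; a
  zero-length projection falls back to angle 0 with a recorded warning.
  Afterwards a deterministic sweep reduces glyph overlap: any overlapping
  element may rotate by up to ±15° in 5° steps, choosing the angle minimizing
  its total rectangle-intersection area (computed with shapely), elements
  visited in sorted label order, secondary elements swept against frozen
  primary angles.
* **Degenerate inputs** — a single element is placed at the origin with zero
  stress; a family whose threshold marks everything secondary is placed in
  one stage; coincident 2D positions contribute zero gradient for their pair
  term.

A sheet is classed primary when any of its strands is primary: a sheet that
contains a core strand is part of the family scaffold even if its edge
strands are variable.

The recorded `stress` of a diagram is the λ-free all-pairs projection error of
the final layout; `normalized_stress` divides by Σ d₃ᵢⱼ² so that 0 means a
perfect embedding and values are comparable across domains of different size.

## Rendering

Helices are rounded rectangles, strands N→C arrows (drawn per strand inside
the transformed sheet template), connectors are three-point polylines with a
single fixed perpendicular midpoint offset joining consecutive elements in
sequence order.  Layout coordinates are mathematical (y up); the y axis is
flipped once at render time.  The family ("multiple") diagram averages each
label's glyph over the members containing it — arithmetic-mean centers,
circular-mean angles (so −170° and +170° average to 180°, not 0°) — with
display length equal to the family-average residue length times the type's
axial rise (1.5 Å/residue helix, 3.3 Å/residue strand) and `fill-opacity`
exactly equal to the label's frequency (an optional legibility floor exists
but defaults to off).  No connectors are drawn in the overlay because members
may order shared elements differently.  All output is plain SVG 1.1 text with
fixed-precision numbers; rendering is a pure function of (diagram, style).

## Synthetic data

The generators exist so every stage is testable with no downloads:

* Ideal α-helix: radius 2.3 Å, rise 1.5 Å/residue, 100°/residue (Cα step
  ≈ 3.83 Å).  Ideal strand: 3.3 Å/residue rise with alternating ±0.9 Å
  lateral offset (d(i,i+2) = 6.6 Å).
* Composite domains join element traces with 3-residue coil linkers.  A
  linker is chosen by a vectorized grid search (lateral zigzag plus
  out-of-plane bow, polished by Nelder–Mead) maximizing the clearance of its
  d(i,i+2)/d(i,i+3) signature from the detection windows while keeping every
  Cα step in [2.8, 4.2] Å — so coils stay coils even under moderate noise.
  Re-bridging after an element deletion can need to span tens of Å; those
  gaps use an arbitrary-length coil on a wide circular helix (step 3.4 Å,
  d(i,i+2) ≈ 4.3 Å, below every window).
* Families are jittered copies of a base recipe (i.i.d. Gaussian Cα noise,
  default σ = 0.3 Å) with optional per-element deletion.  One RNG substream
  per member, spawned from the family seed by member index, so adding or
  removing members never shifts another member's noise.  Ground-truth labels
  and residue ranges accompany every member.
* Random all-helix domains for geometry stress-testing follow a layered
  bundle model: helix axes near ±z with up to ~30° tilt, origins on a lateral
  random walk alternating between two layers ~11 Å apart — the quasi-layered
  packing of real α-domain architectures.  An isotropic 3D walk was rejected
  as the model because it produces tangles no 2D embedding can represent
  faithfully, which misstates what the method is asked to do on real
  domains.  All-helix recipes are used here because random strand placement
  can create barrel/bifurcated topologies that the sheet stage (correctly)
  refuses.

What the generator does **not** emulate: real loop conformations, sequence
effects, β-sheet twist, correlated (B-factor-like) noise, or insertions.
Passing tests therefore demonstrate the pipeline's geometric correctness and
robustness to uncorrelated coordinate noise, not performance on experimental
structures — in particular, detection quality on real data depends on window
calibration that only Cα-geometry benchmarks against DSSP-style assignments
could establish.

## Known limitations

* β-barrels and bifurcated sheets are rejected, not drawn.
* Hydrogen-bond-based assignment (DSSP), 3₁₀/π helices, and β-bulges are out
  of scope; detection is purely Cα-geometric.
* The DP matcher assumes members share a global rigid superposition; families
  with large hinge motions would need per-segment alignment.
* Connector routing is a single midpoint offset — no crossing avoidance.
* The layout optimizer is local; the deterministic principal-plane
  multi-start covers the common basins but global optimality is only
  verified against exhaustive oracles at small sizes.
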