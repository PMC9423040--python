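# Methods

Definitions, conventions, default parameters and known limitations of the
`liface` analyses.  Internal units throughout: ångström (Å), picoseconds
(ps), degrees, electrons, kcal/mol.

## Topology and atom roles

A `Topology` is a flat list of `AtomRecord`s: atom id, name, molecule id,
molecule kind (`LIPID`/`WATER`/`OTHER`), head-group moiety (`alpha_ring`,
`beta_ring`, `glycerol`, `other`), electron count, acceptor flag, and the
ids of covalently bound hydrogens (an atom with hydrogens is a donor).
Roles are assigned from a YAML annotation config mapping residue names to
per-atom rules; presets cover MGDG/DGDG sugar-head numbering, TIP3P-style
water (OW donor+acceptor, HW1/HW2), and the synthetic test lipid SLX.
Unknown atoms are annotated `other` with a warning; a donor rule whose
hydrogen is missing from the residue is a configuration error.

## Hydrogen-bond detection

A geometric criterion on donor–hydrogen–acceptor triples:

- donor···acceptor distance ≤ `d_max` (default **3.25 Å**);
- donor–H···acceptor angle ≥ `angle_min` (default **150°**);
- donor and acceptor in different molecules unless
  `exclude_intramolecular=False`.

All distances use the minimum-image convention; only orthorhombic boxes
are supported (a triclinic box raises).  Candidate pairs come from a
periodic `scipy.spatial.cKDTree`; the angle test compares cosines with a
`1e-12` tolerance so boundary geometries are classified stably.  Output is
a deterministic, sorted list of `(frame, donor, hydrogen, acceptor)`
records annotated with distance, angle, molecule kinds and moieties.

### Tally conventions

All per-head quantities are computed per frame first (count divided by the
number of lipid heads in the region), then averaged over frames; the
spread is the **population** standard deviation over frames (ddof = 0).

- *Lipid–water*: every lipid–water H-bond counts once.  `rings_via_H`
  means the lipid ring atom donates (acts through its hydroxyl H);
  `rings_via_O` means it accepts.  `hbonded_waters_per_head` counts
  distinct water molecules bound to ≥ 1 lipid.
- *Lipid–lipid* (and water bridges): an interaction between two heads
  counts once **per endpoint head**, i.e. contributes 2 to the raw count
  before dividing by the number of heads.  Orientation is *horizontal*
  when both lipids are in the same leaflet, *vertical* otherwise;
  `total = horizontal + vertical` holds exactly.

## Water bridges

A water molecule H-bonded to k ≥ 2 distinct lipids in the same frame
yields C(k, 2) pairwise bridges.  Each bridge records:

- the moiety category of its two lipid contacts (`alpha_alpha`,
  `alpha_beta`, `beta_beta`, `gly_ring`, `gly_gly`); when a water–lipid
  contact involves several lipid atoms, the representative bond is chosen
  by moiety priority ring > glycerol > other, ties broken by lowest lipid
  atom id;
- the water role: `double_donor` (water donates both bonds),
  `double_acceptor`, or `mixed`;
- orientation (horizontal/vertical), from the leaflet labels of the two
  lipids.

Category counts are conserved: the sum over categories equals the total
bridge count, and horizontal + vertical equals the total.

## Interface geometry

**Leaflet assignment.**  Each lipid head gets a time-averaged,
electron-weighted centre of mass along the box normal (z).  For a bilayer
the two leaflets split at the midplane; for a double bilayer (4 leaflets)
a deterministic 1-D k-means (quantile initialisation + Lloyd iterations)
clusters the head positions.  Labels are sorted by ascending z; the
outward normal of leaflet *i* points along −z for even labels and +z for
odd labels, matching alternating orientation in a lamellar stack.
Degenerate inputs (fewer heads than leaflets, coincident planes) raise.

**Scalars.**  Area per lipid A_L = (box x-area) / (heads per leaflet).
Bilayer widths are distances between per-leaflet electron-weighted mean
z positions: `D_RR` uses ring-moiety atoms, `D_CC` a named carbon (e.g.
C2); both report mean ± population SD over frames.

**Orientation distributions.**  The head-vector tilt is the angle between
a per-lipid atom-pair vector (e.g. C2→O4) and the outward leaflet normal;
the ring-plane dihedral is the angle between least-squares ring planes
(normals from an SVD of the centred ring coordinates; collinear rings
raise).  Angles are histogrammed in fixed-width bins (default 2°), the
distribution is normalised to sum to 1, and the mode is the centre of the
maximal bin with ties resolved toward the smaller angle.

**Electron densities.**  Per-selection electron histograms along z,
divided by slab volume.  Integrating a profile recovers the selection's
total electron count up to floating-point summation — conservation is
exact by construction and asserted to 0.1 % in the tests.  The
interface-overlap probability is the fraction of a probe selection's
electrons (e.g. terminal CH₃) lying in bins where the water density is
nonzero on the head-group side of the midplane; both profiles must share
the same binning.

## Interaction networks

Per frame and per leaflet, an undirected graph over that leaflet's lipids
(isolated nodes kept) with one edge per interacting pair, carrying
`n_hbond` (direct horizontal lipid–lipid H-bonds) and `n_wb` (horizontal
water bridges).  Vertical interactions are excluded from graphs by
construction.

- **Cluster statistics**: connected components; mean cluster size is
  averaged per graph first, then over graphs, reproducing e.g. alternating
  1-/2-cluster leaflets → 1.5 and {1, 1, 98} plus one fully connected
  leaflet → 2.
- **Network bridges**: edges whose removal disconnects a component, found
  by chain decomposition over a DFS tree; cross-checked in tests against
  `networkx.bridges` and a remove-edge-and-recount oracle.
- **Node strength**: Σ over incident edges of
  `n_hbond·|E_hb| + n_wb·|E_wb|`, with default per-interaction mean
  energies E_hb = −5.12 and E_wb = −14.23 kcal/mol.  Strength is linear in
  edge counts and invariant under node relabelling.  An optional lifetime
  weighting multiplies each edge term by its mean lifetime; the formula
  used is echoed in the result metadata.
- **Edge lifetimes**: for each node pair, the sorted frames where the edge
  exists are split into runs of consecutive frames; a run of L frames
  lasts L·Δt.  `gap_tolerance = g` merges runs separated by ≤ g missing
  frames, measuring the merged span.  Reported: mean, population SD and
  SEM over all runs.  Frames must be uniformly spaced.

## Synthetic fixtures

Lattice membranes of a 16-atom test lipid (two 4-atom rings with hydroxyl
O/H, a glycerol oxygen, C2 and terminal-CH₃ carbons) on a 10 Å grid, head
planes at ±20 Å (bilayer, box z 60 Å) or ±45/±15 Å (double bilayer, box z
120 Å).  Planted interactions place water/hydroxyl atoms at ideal H-bond
geometry (O···O 2.8 Å, O–H 0.95 Å, collinear); positional noise is capped
at 0.10 Å so planted bonds can never drift out of, and unplanted contacts
never drift into, the detection window.  The generator runs the real
detectors on every frame and raises `GenerationError` if the detected set
differs from the manifest, so the manifest is ground truth by
construction, not by trust.

Feasibility rules enforced (violations raise): one plant per lipid site;
glycerol is acceptor-only; horizontal pairs must be lattice-adjacent;
vertical bridges need laterally aligned lipids with plane separation
≤ 31 Å (only the inner leaflets of a double bilayer qualify — a bilayer's
40 Å separation cannot be bridged by one water).

The generator also produces non-spatial fixtures: per-edge on/off
schedules (deterministic or exponential on/off times) rendered as graph
sequences for lifetime statistics, and angle/density clouds with exact
planted tilt and ring-dihedral angles for closed-form orientation checks.

### Realism limits

Fixtures are *detector test beds*, not physical membranes: lipids sit on a
rigid lattice with sub-0.1 Å jitter, water is sparse and placed only where
needed, there are no acyl-chain conformations, no thermal disorder beyond
the noise cap, and no dynamics (planted sets are constant over frames
unless an explicit schedule says otherwise).  Quantities like A_L or
widths are exact lattice/plane properties, not ensemble averages.

## Numerical choices

- Boundary comparisons on the H-bond cosine use a 1e-12 tolerance; all
  set-equality tests against oracles are exact.
- Per-head counts divide by head counts that are powers of two in the
  shipped fixtures, so tallies are exactly representable and compared at
  1e-12 in the end-to-end tests.
- Population SD (ddof = 0) everywhere a spread over frames is reported;
  SEM over runs for lifetimes.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; derived seeds are drawn below 2³¹.

## Limitations

- Orthorhombic boxes only; the membrane normal is assumed to be z.
- Donor–H covalency comes from the annotation config, not from distances;
  misannotated hydrogens silently change donor sets.
- Leaflet assignment uses time-averaged head positions, so lipids that
  flip-flop between leaflets mid-trajectory are assigned to one leaflet
  for the whole run.
- Water bridges consider single waters only (no two-water chains).
- Edge lifetimes assume uniform frame spacing and do not correct for
  trajectory-end truncation of runs.
- Energy weights in node strengths are user-supplied constants per
  interaction type, not per-configuration energies.
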