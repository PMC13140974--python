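# Methods

## Escape detection

A tracked ligand's state is reduced to one scalar per analysis frame: the
Euclidean distance between its centre of mass and the binding-site centre
of mass, both mass-weighted (masses inferred from atom names/elements;
unresolvable names fall back to 12 u with a warning, a negligible
perturbation of a centre of mass).  Raw frames may be block-averaged into
analysis frames (`bin_factor`); the block mean — not subsampling — is
used, and a trailing partial block is dropped.  Binning distances rather
than coordinates is a deliberate choice: averaging coordinates first would
shrink excursions toward the site and is not what a per-frame distance
plot shows.

An escape is the first window of `persistence_ns` (default 2 ns, i.e. 10
analysis frames at 0.2 ns) in which every frame's distance strictly
exceeds `threshold_A` (default 16.31 Å, the mean channel length).  The
escape time is the window's first frame, which is provably the start of
the excursion containing it: if the preceding frame were also above
threshold, an earlier qualifying window would exist.  Shorter excursions
("re-entries") never count; censored ligands contribute to `n_tracked`
but not to the mean escape time, which is the plain average over escapers.
"Sustained excursion above the channel-length threshold" is the reading
adopted for the criterion's wording; an alternative reading (distance
exceeding threshold *plus* a margin) was rejected because escape-time
colour-coding of trajectories implies a time-based qualifier.  A
per-channel mode re-detects each escape against its assigned channel's own
`avg_length_A` after assignment, for channel catalogues whose lengths
differ materially.

The distance histogram pools all analysis frames of a variant (9000 at
the full replicate design) with 3 Å bins; "bin size 3" is interpreted as
3 Å, since the binned axis is a distance.

## Channel assignment and contact occupancy

Channels are user-supplied residue lists (chain:resid) with an optional
mean length; no geometric tunnel detection is performed.  Contact
occupancy counts analysis frames in which the minimum distance from any
ligand atom to any heavy atom of a residue is ≤ 4 Å — the conventional
van-der-Waals contact distance; hydrogens are excluded because coarse or
united-atom trajectories may lack them.  The exit window runs from 5 ns
(configurable) before the escape excursion's start through the escape
frame.  An escape is assigned to the channel whose member residues
(deduplicated) sum to the largest occupancy; ties resolve to the earlier
channel in the catalogue with a logged warning, and an all-zero window
yields `unassigned` rather than a guess.  Rankings break occupancy ties
deterministically by (chain, resid).

## The Brownian-dynamics generator

The generator exists to give every analysis stage a ground truth.  It is
not an MD surrogate in any energetic sense: only the first-passage
structure of the escape problem is reproduced.

*Geometry.*  A spherical cavity (radius 8 Å) with straight cylindrical
tunnels; each tunnel's axis passes through the cavity centre, its length
(16.31 Å, measured from the centre so the default detection threshold
coincides with the tunnel end) terminating in an absorbing plane, its
radius 1.5 Å (narrow variant) or 3.0 Å (wide variant, radius scaled by
`wide_factor = 2`).  The default geometry has two tunnels ("primary",
"secondary") on perpendicular axes.

*Dynamics.*  Overdamped position-Langevin: per step an isotropic Gaussian
displacement with σ = √(2 D Δt), D = 20 Å²/ns (an oxygen-like diffusivity
in a condensed environment), Δt = 10⁻⁴ ns.  Walls reflect by a single
specular fold per violated surface (radial fold in a tunnel, axial fold at
the tunnel's inner end, radial fold across the cavity sphere); a proposal
still outside after its fold is rejected.  The precondition σ < min tunnel
radius / 3 keeps multi-fold events negligible.  Ground truth is the first
step crossing an absorbing plane inside the bore; afterwards the walk
continues force-free in "solvent" so recorded trajectories show what the
persistence detector needs to see.  Everything is deterministic given a
seed; zero diffusion is allowed as the static-ligand degenerate case.

*Calibration.*  In the single-tunnel, vanishing-cavity limit the axial
coordinate is an exact 1-D reflecting/absorbing diffusion, so the mean
escape time must equal L²/(2D); the acceptance suite verifies this over
2000 seeds to within three standard errors.  At Δt = 10⁻⁴ ns the
discrete-time boundary bias is below 1% of the mean, an order of magnitude
inside that band.

*Pseudo-residues.*  Static spheres decorate the geometry purely for the
contact analysis; they exert no forces.  Tunnel linings are rings (6
spheres every 2.5 Å) standing 1 Å outside the bore — narrow tunnels are
side-chain-lined, so their marker atoms hug the surface — while cavity
markers stand 3 Å behind the wall, the typical CA standoff of a cavity
surface.  In the wide variant three lining positions of the primary tunnel
are relabelled as engineered substitutions (F210L, L213T, M242Q), so
mutation reports have a ground truth: any primary-tunnel escape must pass
them.

*Replicate design.*  Six replicates per variant (3 × 200 ns + 3 × 100 ns)
with two tracked ligands each and 0.2 ns analysis frames — 9000 pooled
frames per variant at full scale.  A `time_scale` parameter shrinks every
duration proportionally; the bundled analyses and tests run at 25% (2250
frames per variant), which regenerates in seconds while still producing
escapes in both variants.  Scaling down shortens the censoring horizon, so
desk-scale conditional means can order variants differently from the
uncensored contrast; the acceptance checks therefore compare uncensored
first-passage times (64.8 ns narrow vs 29.2 ns wide at 200 ns horizons,
seed-dependent).

*What the generator does not emulate.*  Protein flexibility, ligand
interactions, curved or branching tunnels, re-entry barriers at the
protein surface, and solvent structure.  Passing tests therefore certify
the *analysis machinery* — detection, counting, assignment, statistics —
not any biophysical claim about a real enzyme.

## Kinetics

Two limiting two-substrate schemes are implemented.  Ping-pong:
v = Vmax·S·O/(KM_S·O + KM_O·S + S·O), whose fixed-O2 projection is exactly
Michaelis–Menten with Vmax_app = Vmax·O/(KM_O+O) and KM_app =
KM_S·O/(KM_O+O) — apparent efficiency invariant in O2 as an algebraic
identity.  Independent sites: v = Vmax·S/(KM_S+S)·O/(KM_O+O), where only
Vmax_app varies, so efficiency rises with O2.  Full ordered bi-bi fitting
is out of scope; these two bracket the diagnostic question.

Fits use Levenberg–Marquardt nonlinear least squares (scipy `curve_fit`),
unweighted, initialised at Vmax⁰ = max rate and KM⁰ = the substrate
concentration whose rate is closest to half-maximal.  Substrate
concentrations strictly above 16 mM are excluded by default (reporter-
peroxidase inhibition); the threshold is configurable and the excluded
points are reported.  At least three usable points are required.

The synthetic assay uses the 2-fold dilution series from 128 mM, additive
Gaussian noise (default studies use σ = 2% of Vmax), and generating
constants Vmax = 1 (arbitrary rate units), KM_S = 5 mM (mid-range of the
retained series) and KM_O = 0.33 mM, the literature oxygen KM of an amine
oxidase — chosen once as a realistic oxygen-limited regime.  The three
oxygenation conditions map to 0.10 mM (unsparged, a plausible partly
degassed buffer), 0.255 mM (air, 21% of 1 atm via Henry's law) and
1.216 mM (pure O2 at 1 atm); the Henry constant is 1.2×10⁻⁵ mol m⁻³ Pa⁻¹
with 100% saturation anchored to pure oxygen at 101 325 Pa.  Absorbance
slopes convert by Beer–Lambert with ε = 29 400 L mol⁻¹ cm⁻¹; the path
length has no default because plate-reader paths depend on well volume.
Enzyme-normalised kcat values are only reported when a molar enzyme
concentration is supplied.

## Numerical choices and degenerate inputs

- Persistence windows round to the nearest whole frame and must be ≥ 1
  frame and ≤ the series length (else the persistence is unverifiable and
  the run fails rather than guessing).
- RMSD uses unweighted Kabsch superposition (scipy `align_vectors`) after
  centroid removal; frame 0 is pinned to exactly 0; fewer than 3 atoms is
  fatal (under-determined superposition).
- Text coordinate formats (multi-model PDB, XYZ) carry no physical time;
  the frame interval must be supplied explicitly, never defaulted.
- Seeds derive from a single base seed by fixed integer arithmetic and
  stay below 2³¹; identical manifests regenerate byte-identical bundles.

## Known limitations

- A ligand's free post-escape walk can re-approach the site, delaying the
  persistent excursion past the true exit and leaving its contact window
  in solvent (reported as `unassigned`).  A longer lead-in or per-channel
  thresholds mitigate this.
- The exit-window length and the contact cutoff are conventions, not
  measurements; occupancy rankings shift with both, which is why they are
  explicit parameters rather than constants.
- Censored-aware statistics stop at counting: no survival-curve or
  rate-constant fitting is attempted on escape times.
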