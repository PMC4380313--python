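# Methods

## System and coordinate conventions

The channel model is a C5-symmetric pentamer embedded in a membrane slab
normal to z. Every analysis works in a shared channel frame: the origin is
the geometric centroid of the five Cα atoms of a reference pore residue
(21 by default, the most constricted site), the axis is the +z membrane
normal (an `axis="inertia"` mode instead takes the protein's principal
axis closest to z; the default is the fixed normal because the channels
analysed here stay nearly upright, and a fixed axis keeps profiles from
different frames commensurable). Axial positions are z′ = (r − origin)·ẑ,
+z′ toward the periplasm. Residue numbering is the structure's author
numbering, 1-based.

Structures and trajectories are plain text: single/multi-model PDB,
multi-frame XYZ with a TSV topology table (per-atom residue, subunit,
element, Cα flag, van der Waals radius). Van der Waals radii default to
the Bondi table; a HOLE-style AMBER-like dialect is selectable
(`radius_table="hole"`) since published radius sets differ by ~0.1–0.3 Å
and pore radii shift accordingly.

## Pore geometry

The pore radius at axial position z is the largest sphere centred in the
plane at z that touches no atom:

    R(z) = max_{|c_xy| ≤ s} min_i ( |c − x_i| − r_vdW,i ),

with the centre constrained within a lateral search radius s (5 Å
default) of the axis. The maximisation uses seeded simulated annealing
(200 moves, geometric temperature schedule 1 → 0.01, Gaussian moves of
0.6 Å) followed by a Nelder–Mead polish; the test suite pins it against
an exhaustive 0.05 Å lattice oracle. Slices with no atom within 10 Å
along z report a configurable cap (15 Å) and are flagged. A per-slice
planar search (rather than a curved HOLE path) is adequate for a straight
channel; this is verified against the brute-force oracle rather than
assumed. "Backbone" means N, CA, C, O; a side-chain-inclusive mode
exists for diameter statements that include side chains.

Two derived summaries: the per-frame minimum radius over the z-interval
spanned by a residue window (mapped through the mean Cα z′ of each
residue, because constriction windows are specified as residues, not z),
and the pentagon pore area per residue ring, A = (5/4) e²/tan 36° with e
the mean Cα–Cα distance over the five adjacent subunit pairs.

## Ion permeation and conductance

Each ion of a species runs a finite-state machine on its channel
coordinates: OUTSIDE_TOP (z′ > z_top), INSIDE (z_bottom ≤ z′ ≤ z_top and
radial distance ≤ cutoff), OUTSIDE_BOTTOM, plus an out-of-cutoff side
state. Crossing a mouth into the slab within the radial cutoff counts one
entry; leaving through the opposite mouth counts one exit (= one
permeation); returning through the same mouth is a rejected entry;
drifting radially out of the cutoff aborts the pending entry. Re-entries
are new entries. Frames before the burn-in time (10 ns default, during
which models structurally relax) are ignored. Periodic wraps in z are
recognised by their > L_z/2 raw jump and never read as crossings; a
genuine whole-slab traversal between consecutive frames (sub-L_z/2 jump,
in-cutoff at both ends) counts as entry+exit. TM bounds default to z′ =
±16 Å with a 12 Å radial cutoff — the slab numbers are not stated in the
study this follows, so they are config keys sized to span the TM helices
of a closed-state structure; the radial cutoff excludes ions diffusing
around the protein through bulk.

Permeation rate is 100·exits/entries (reported to the nearest integer;
zero entries defines rate 0 with a warning). Conductance is the counting
estimate G = N·e/(t·V) with N completed crossings in analysis window t
under applied voltage V; a reporting helper rounds to the nearest 10 pS,
matching how such estimates are conventionally quoted. The flux API
reports per-species counts; anions never permeate the engineered systems
considered here, so K⁺ exits and net charge flux coincide.

## Solvation

Coordination profiles sample every (frame, ion) pair in the INSIDE state
— "permeating" means inside the pore, not only ions that later complete
a crossing (a completed-only flag exists). For each sample the number of
water oxygens within 3.5 Å and of other cations within 5 and 4 Å
(self excluded) is binned by the ion's z′ and averaged; unsampled bins
are reported missing (NaN), never zero. Water position is the oxygen
atom. The 2D water map is a (z′, radial) histogram over frames after
burn-in; its radial cutoff defaults to 10 Å.

## Structural metrics

Superposition is the Kabsch SVD fit (proper rotation, det +1) over a
selection; RMSD is evaluated over the same selection after fitting.
Collinear or < 3-atom selections are rejected. RMSF superposes all frames
onto an iteratively refined mean structure (convergence 1e-6 Å) and
reports each atom's RMS excursion; an independent fit selection can hold
the frame on rigid atoms.

Native contacts are all inter-subunit Cα pairs within 8.0 Å in a
reference frame, restricted to an inner-helix residue range (default
15–40, the TM1 span; the synthetic scaffold carries residues 9–33).
Retention per frame is the fraction of native pairs within
cutoff × tolerance (1.2 default; 1.0 gives the strict native criterion —
the looser default tolerates thermal breathing without losing the
displacement signal, and both modes are exposed because published
retention curves rarely state which was used). The 8 Å cutoff is the
standard Cα contact convention; only relative retention is interpreted.

## ABF free-energy estimator

The estimator targets 1D single-particle overdamped Langevin systems
(units kcal/mol, Å, ps; kT = 0.0019872·T kcal/mol; friction ζ in
kcal·ps/mol/Å², mobility 1/ζ). Each step records the instantaneous
system force into the particle's current bin and applies the opposing
running-mean bias scaled by min(1, n_bin/N_ramp) (N_ramp = 500 default) —
the linear ramp avoids applying noisy early estimates at full strength.
Windows are 2 Å wide with 0.2 Å bins and reflecting walls; the PMF per
window is −∫⟨F⟩dz by the trapezoid rule on bin centres (every bin must
reach N_ramp samples). Abutting windows are stitched by offsetting each
successive window so values agree at the junction (shared grid points
averaged; abutting edges matched by linear extrapolation to the shared
edge); the stitching convention is ours, as windowed ABF protocols rarely
state one. The global profile is anchored to min = 0.

In 1D the instantaneous force is a deterministic function of position, so
the bin-mean force converges to −dA/dz up to bin-centre discretisation;
recovery of analytic potentials is therefore tight (harmonic k to < 1 %)
and the stochastic content of the test is whether sampling covers all
bins. The double-well case additionally shows the flat-histogram
signature (max/min bin occupancy < 3 after convergence). PMFs are not
extracted from the 3D synthetic trajectories: their steered/rejected ion
moves are not thermodynamically consistent by design.

## Synthetic data generator

The generator emulates the study conditions at desk scale, with planted,
machine-readable ground truth:

* **Scaffold.** Five Cα-only helix traces of 25 residues (rise 1.5 Å,
  twist 100°/residue, C5-rotated), residue 21 at the constriction centre.
  The wall surface realises an hourglass
  R(z) = r_min + (r_mouth − r_min)·min(1, ((z−c)/w)²) with defaults
  r_min = 2 Å (closed-state constriction), r_mouth = 8 Å, w = 10 Å;
  atoms sit at R(z) + r_C so their surfaces define the wall. Because the
  probe-sphere radius is also limited by neighbouring rings on steep
  stretches, the ground truth exposed to tests
  (`GroundTruth.true_pore_radius`) is the exact sphere-measurable
  profile min_j (√(ρ_j² + (z − z_j)²)) − r_C, not the nominal wall curve
  (off-axis centres only lose clearance against a C5 ring, so the
  on-axis closed form is the true optimum).
* **Ions.** Overdamped Langevin point ions: drift qE_z D/kT with
  E_z = −V/L_z (V = +1 V drives cations toward −z, periplasm →
  cytoplasm), isotropic diffusion D = 20 Å²/ns, step noise √(2DΔt),
  periodic wrapping, and rejection of moves into the membrane wall. The
  closed pore is impassable to free ions (a 2 Å wall margin closes the
  constriction), so every completed crossing is planted — this is what
  makes "zero false positives" a checkable claim. Steered cations descend
  linearly through the pore between scheduled frames; entry/exit frames
  are read off the realised path.
* **Waters.** Non-interacting occupancy markers resampled uniformly each
  frame, rejected from the protein/membrane wall and (unless
  `hydrate_pore`) from the occluded core (|z′| < 4 Å inside the pore) —
  sufficient for testing counting and mapping, not water physics.
* **Planted structure.** Single-subunit radial displacement and pore
  dilation ramp linearly from frame 0 to the final frame, so the first
  frame is a valid native-contact reference. Cα positions carry 0.05 Å
  Gaussian jitter.

Defaults are the study conditions at desk scale: 1 V, 300 K,
100×100×120 ų box, 20 ns at 0.05 ns/frame, 60+60 ions and 1500 waters
(a 1 M salt at this box size would need ~700 pairs; the reduced counts
keep desk-scale runtimes while leaving every counting analysis
exercised). What passing tests show is that the analyses are correct
against known ground truth; they do not show force-field realism —
trajectory-dependent published quantities (absolute radii, PMF depths,
coordination curves, retention percentages) depend on the original MD
trajectories, which are not deposited, and are covered here as
qualitative signatures (orderings, exclusion zones) rather than numbers.

## Numerical choices and degenerate inputs

Annealing and all simulations are seeded; identical configs are
bitwise-reproducible. Pore radii are clamped at 0 and capped at 15 Å with
flags for empty slices. Rates with zero entries, empty contact sets, and
empty coordination profiles warn rather than raise; malformed files,
missing selections, infeasible geometry, unsampled ABF bins, and window
gaps raise with specifics (line numbers, block indices, bin lists).
Problem sizes in tests and the acceptance script (150–200-frame
trajectories, 10⁵-step ABF windows, 20-seed recovery matrices) were
chosen as the package's own desk-scale defaults.

## Known limitations

No curved pore-path search; no binary trajectory formats in core (an
adapter may delegate to MDAnalysis); ion dynamics are not Newtonian MD
and carry no thermodynamic meaning; waters do not interact; the pentagon
area assumes near-C5 symmetry; conductance is a counting estimate, not a
Nernst–Planck model.
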