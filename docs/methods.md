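# Methods

## Franz-cell kinetics

A Franz diffusion cell mounts a skin sample between a donor chamber
containing the drug formulation and a stirred receptor chamber sampled at a
fixed schedule; each draw of volume `V_i` is replaced with blank medium.
The cumulative amount therefore needs a bookkeeping correction for the drug
removed by earlier draws:

    Q_n = (C_n·V_r + Σ_{i<n} C_i·V_i) / A .

`cumulative_amount` implements this exactly, with a uniform `V_i` by
default and an optional per-draw override for cells where the withdrawn
volume varied. The flux `J` is the slope of an ordinary least-squares fit
of `Q` on `t`. The fit uses **all sampling points by default** with an
optional user window: zero-order permeation makes the whole profile linear,
and excluding early points is a judgement call best left explicit. A
negative fitted flux is reported with a warning rather than clamped — it is
diagnostic of a failed assay, and silently flooring it would hide that.

Units: concentrations in µg/mL (≡ µg/cm³), volumes in mL (≡ cm³), areas in
cm², times in h, so `K_p = J/C_0` comes out in cm/h directly. A donor
loading quoted as a percentage is interpreted as w/v (0.2% → 2000 µg/mL),
the standard pharmaceutics convention; the ER is insensitive to this choice
because control and treated arms share `C_0` and the donor concentration
cancels. Report tables round `J`, `B`, `Q_last`, and `ER` to 2 decimal
places; internal values keep full precision.

## Trajectory model

Trajectories are stacks of frames over a constant bead roster, coordinates
in nm and times in ns, orthorhombic boxes only, frames indexed from 0.
Two dialects are supported: multi-frame concatenated GRO (read and written
through mdtraj; velocities ignored) and a plain-text `frames_csv` dialect
(`frame,time_ns,bead_id,species,x_nm,y_nm,z_nm` with a `#box,Lx,Ly,Lz`
line per frame) that round-trips exactly to 1e-6 nm and diffs cleanly in
test fixtures. GRO residue/atom name pairs map to species tags through a
configurable table because GRO's 5-character fields cannot carry tags like
`CER_HEAD` directly.

z-unwrapping applies the minimum-image convention to consecutive-frame
displacements, which is unambiguous as long as no bead moves more than
`Lz/2` between frames (a near-boundary displacement is logged as a
warning). Centering translates each frame so the mean z of the midplane
reference beads sits at `Lz/2`. The bilayer center is defined as the mean
z of all hydrophobic-class beads: the head-group planes are bimodal and
solvent is outside the membrane, so the hydrophobic core is the most robust
single-frame proxy for the midplane. Centering is configurable (on by
default for density and pore analyses, off for MSD) because whether a lab
frame or a bilayer frame is appropriate depends on whether the membrane
itself drifts.

## Bilayer observables

**Density profiles** are per-species histograms of wrapped z over all
frames, half-open bins of width 0.1 nm by default covering `[0, Lz)`, with
a trailing bin narrower than half a width merged into its predecessor.
Number density (beads/nm³) is the default; mass density requires an
explicit species→mass table since bead masses are model-dependent. The
defining invariant, `Σ values·bin_volume = mean selected-bead count per
frame`, holds to floating-point precision by construction.

**MSD** is single-origin by default — `(z(t) − z(0))²` averaged over the
selection — because that is the form the quantity is usually defined in
and it makes no stationarity assumption. All-origin averaging (an O(F log F)
FFT decomposition) is available behind `multiple_origins=True`; it reduces
the estimator variance severalfold and is what the single-run unit checks
use, but it is opt-in, never silently substituted.

**Diffusion** fits a straight line to MSD over a lag window, by default the
second half of the lag range as a practical stand-in for the `t → ∞` limit.
The divisor convention is explicit: `physical_1d` divides the slope by 2
(the correct 1-D Einstein divisor) and `paper` by 4 (a convention seen in
the applied literature where the planar divisor is applied to a z-only
displacement). `paper` is the default for comparability with published
values; recovery tests validate `physical_1d`, and the two differ by an
exact factor of 2 on any input. Estimator spread at the reference study
scale (1000 beads, 3000 frames at 0.1 ns, single origin) is about 7%
per run, so recovery claims are made on 20-seed means, which land within
5% of truth.

**Pores** are detected from the occupancy series of hydrophilic head beads
in a midplane slab. The three detector parameters — slab half-width 0.5 nm,
`min_count` 3, `min_persistence_frames` 2 — are package-defined operational
choices (visual criteria in the source studies are not algorithmic) and are
all exposed on the CLI. Close time is the first frame after the run, so a
single-frame event at spacing `dt` has duration `dt`; an event still open at
the trajectory end is closed at the last frame time and flagged
`open_at_end`. The detector is verified against a brute-force run-length
oracle on random occupancy vectors.

## Synthetic generators

The generators exist to give every analysis stage an input with exactly
known ground truth; they are deliberately simple and bit-reproducible under
a fixed seed.

`simulate_franz_series` inverts the cumulative-amount relation sequentially
from `Q(t) = max(0, J*·(t − lag))`, then applies multiplicative Gaussian
noise `(1 + ε)`, `ε ~ N(0, noise_sd)`, to each concentration (floored at
zero — a measured concentration cannot be negative). At zero noise it is an
exact right-inverse of `cumulative_amount`, which pins the bookkeeping.
Default schedule 2, 4, 6, 8, 10, 12, 24 h; default cell `V_r = 15 mL`,
`V_i = 1.5 mL`, `A = 1.23 cm²`, `C_0 = 2000 µg/mL` — a standard vertical
Franz configuration. A relative noise SD of 1% emulates HPLC quantification
error.

`simulate_bilayer_trajectory` builds: two head-group planes at
`Lz/2 ± leaflet_offset` (default 2.0 nm, i.e. a ~4 nm hydrophobic core,
typical of a ceramide-rich bilayer) with per-frame Gaussian z-jitter
(SD 0.1 nm); hydrophobic core beads uniform in the core slab; solvent
uniform outside it; and permeant beads performing Brownian walks with step
variance `2·D·dt` per axis, reflecting at the z faces and periodic in x, y.
Reflecting z-boundaries avoid unwrap ambiguity in fixtures; diffusion
studies use a tall box (Lz = 40 nm) with permeants started in the central
half so a 300 ns walk at `D = 0.01 nm²/ns` (rms ≈ 2.4 nm) essentially never
touches a wall. Default roster: 64 head, 128 core, 32 FFA-tagged, 200
solvent, 20 permeant beads over 3000 frames at 0.1 ns — generated in
seconds. The default composition tag records the 2:2:1
ceramide:cholesterol:free-fatty-acid mixture the roster emulates; the core
beads collectively stand in for all hydrophobic material.

What the generator deliberately does **not** emulate: membrane
partitioning of the permeant (no free-energy landscape), lipid diffusion
and undulations, enhancer-lipid interactions, or any force field. Passing
recovery tests therefore demonstrates that the *estimators* are correct on
data satisfying their assumptions — not that any physical conclusion about
real membranes follows.

`inject_pore_event` moves the lowest-index available head beads to
`z = Lz/2` (± 0.05 nm jitter) for an inclusive frame interval and restores
them outside it, recording the bead identities on the trajectory;
overlapping injections on the same beads are rejected. Round trips through
the detector (count, order, frame extents) are exact at the default
detector parameters.

## Pipeline and numerical choices

`run_pipeline` executes the configured stages (franz, density, diffusion,
pores) from one TOML file, writes TSVs with a fixed float format so
identical config + seed gives byte-identical outputs, and records a
manifest with parameters, seed, package version, and SHA-256 hashes of all
inputs. A stage failure removes that run's partial outputs.

Degenerate inputs are errors, not silent results: fewer than two fit
points, zero time variance, empty selections, bin widths exceeding the box,
non-orthorhombic GRO boxes, inconsistent bead rosters between frames. OLS
fits go through `scipy.stats.linregress`; r² is reported as 0 for an
exactly constant response (where the correlation coefficient is undefined).

Problem sizes in the test and acceptance suites (20 seeds; 1000 beads ×
3000 frames for diffusion; 100–150-frame fixtures elsewhere) were chosen as
the smallest scales at which the stochastic claims are statistically
comfortable, and keep the full suite under a minute.

## Known limitations

* GRO support is orthorhombic-only and ignores velocities; binary XTC/TRR
  readers are out of scope (convert externally, or use frames_csv).
* The density profile uses the frame-mean box, so strongly
  barostat-fluctuating boxes smear the profile slightly.
* Single-origin MSD on a non-stationary selection (e.g. a drifting
  membrane) conflates drift with diffusion; center first, or use multiple
  origins and inspect the intercept.
* The pore detector is purely occupancy-based; it does not check that the
  occupying beads form a connected channel.
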