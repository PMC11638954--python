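# Methods

This note documents the models and estimators implemented in `slitwater`,
the assumptions behind them, the synthetic data used to validate them, and
the numerical choices that are genuinely open.

## Physical picture

In bulk water nearly every molecule is four-coordinated and translational
diffusion is dominated by solvation-shell exchanges: a molecule waits in a
stable shell until one member is replaced, hops, and waits again.  Under
extreme planar confinement (a water monolayer between two smooth walls) the
molecules can only reach two or three H-bond partners, and a large fraction
of O–H bonds dangle toward the walls.  Those frustrated dangling bonds open
a second transport channel: an H-bond can break and throw the pair apart — a
"kick" — while the solvation shell stays intact, the pair rebonding later in
the same or a different donor/acceptor combination.  The package quantifies
both channels and reassembles the diffusion coefficient from them through a
continuous-time random walk (CTRW) model.

## State classification

Each O–H bond is labeled per frame by a purely geometric criterion:
H-bonded (HB) to acceptor `a` iff R(O_d–O_a) ≤ `r_oo_max` and the angular
deviation ≤ `angle_max`, dangling (DB) otherwise.  Defaults are the standard
bulk-water choice, R_OO ≤ 3.5 Å and 30°; both the cutoffs and the angle
convention (`dha`: deviation of O_d–H···O_a from linearity measured at H;
`hda`: H–O_d···O_a at the donor) are configurable, because published
criteria differ and the downstream statistics are insensitive to the exact
choice only in well-separated systems.  Classification is stateless;
persistence requirements belong to the event definitions, not the labels.
When several acceptors qualify, the smallest angular deviation wins, ties
broken by the smaller R_OO (implemented as a 1e-9·R perturbation of the
angle score, i.e. angle differences below ~3.5e-9 degrees count as ties).

Coordination populations default to counting *distinct* H-bonded neighbors
per molecule rather than bonds: a closed H-bond graph obeys the sum rule
⟨bonds per molecule⟩ = 4·(1 − DB fraction) exactly, so bond counting carries
no independent information, while neighbor counting is what population plots
of 2-/3-coordinated molecules show.  The multiset count remains available
(`CoordinationSeries.counts`).  The population-weighted mean coordination is
also the kick multiplicity factor `f` below.

## Survival correlations and lifetimes

S(t) = ⟨h(0)H(t)⟩/⟨h⟩ with dense time origins: every frame in which a bond
occupies the state is an origin, matching the ⟨h⟩ normalization.  H(t)
demands uninterrupted occupancy; optionally interruptions shorter than
`filter_window` are bridged first (default 0: strict continuous definition).
Gaps touching the trajectory ends are never bridged (their length is
unknown).  τ is the trapezoidal integral of S; the plain integral method
refuses to integrate a curve that has not decayed below 0.05 within the
window, and `integral_with_tail` adds an exponential tail fitted to the last
decade of the decay.  On an exactly Markovian telegraph the estimator is
unbiased by construction (per-step transition probabilities 1 − exp(−k·dt)
make the discrete survival exactly exp(−k·n·dt)).

## Stable states and exchange events

The solvation shell of a molecule is either the union of its donated-to and
accepted-from partners (default, since the stable states are coordination
states) or all oxygens within `r_shell` (full 3D minimum-image distance even
in slabs).  Two filtering passes produce stable-state segments: flickers
that revert to the prior composition within `t_filter` (default 0.2 ps) are
erased, and remaining sub-window runs — the staggered intermediates of an
exchange, where the departing and arriving member cross the shell boundary
a few frames apart — are absorbed into the neighboring stable run so that
consecutive stable states meet at a single boundary.

An SWE event is a boundary whose compositions differ by n departing and n
arriving members, decomposed into pairwise swaps by greedy minimal-distance
matching at the boundary frame.  Its time origin is the linearly
interpolated |O\*–Oa| = |O\*–Ob| crossing nearest the boundary within
±max(0.5 ps, 5·dt); boundaries without a crossing are kept but flagged
unresolved and excluded from averages.  Pure losses or gains (a neighbor
leaving without replacement) are composition changes but not exchanges and
produce no event.

δ²_O\* uses the basin-centroid convention: the squared displacement between
the mean unwrapped O\* position over the pre- and post-segments, in-plane
for slabs.  Centroids are robust to intra-basin rattling but acquire a
positive bias from genuine intra-basin *diffusion* (frame or kick motion) of
order (2/3)·2d·D_intra·τ per segment side; for that reason the additivity
validations on jump walks (below) take per-event amplitudes from the
recorded event displacements, while centroid extraction is itself validated
on pure-jump processes where it is exact.

τ_SWE is the time integral of the jump-time correlation 1 − ⟨p_i(0)p_f(t)⟩
with an absorbing final-basin indicator, evaluated over dense origins in the
pre-segments of resolved events.  For a Poisson exchange process this equals
the mean waiting time 1/λ; on a finite trajectory of length T it carries a
~τ/T truncation bias (intervals that do not complete within the window are
unobservable), so production runs should satisfy T ≳ 100·τ.

## Kick events

A kick is an HB→DB transition whose DB episode lasts at least `t_db_min`
(default 0.05 ps, suppressing single-frame librational flicker) and whose
partners remain mutually in-shell (filtered compositions) throughout
[t0, t0 + `t_persist`] (default 0.5 ps).  Transitions whose partner leaves
the shell are exchanges, not kicks, and are excluded — this exclusion is
what makes the kick and SWE event sets disjoint on matched windows.  The
time origin is the first DB frame.  Event-synchronized traces average the
O\*–O distance, the tagged-bond HB indicator (1 by construction at lag −dt)
and the O–H/normal angle; the displacement amplitude δ²_kick uses the same
centroid convention over ±`delta_window` (default 0.5 ps) around t0.  Note
that when DB episodes are much shorter than the window and the displacement
relaxes back, the centroid amplitude underestimates the instantaneous kick —
this is a property of any finite-window measure of transient displacements.
τ_kick is the mean waiting time between successive kicks of a tagged
molecular pair, pooled over pairs; for per-pair Poisson kicks this is the
exact inverse rate.

Recombination statistics classify the first re-formed H-bond of the broken
pair within `t_rebond_max` (default 1 ps) into four combinations: same donor
hydrogen, the donor's other hydrogen, or the reversed direction with either
of the previous acceptor's hydrogens.

The O–H/normal angle uses the unsigned convention arccos|û·n̂| ∈ [0°, 90°],
folding the two walls together (dangling bonds point at either wall); a
signed per-wall variant would only relabel the histogram.

## Diffusion decomposition

MSD curves are time- and particle-averaged over unwrapped oxygen
coordinates; slab analyses use the two in-plane components (d = 2), bulk all
three (d = 3) — the dimension is forced by the 2d denominators of the CTRW
formulas.  D is the least-squares slope over a configurable fit range
(default 1–5 ps, past the sub-0.2 ps ballistic/librational regime) divided
by 2d.  The frame contribution restricts MSD origin/lag pairs to single
stable segments, every valid pair weighted equally (the same dense-origin
convention as the survival functions).  The CTRW contributions are

    D_SWE  = δ²_O* / (2 d τ_SWE)
    D_kick = f · δ²_kick / (2 d τ_kick),   d = 2,

with f = mean H-bonded pairs per solvation basin from the coordination
populations (≈2.5 for the monolayer statistics).  The report carries the
additivity residual |D − (D_SWE + D_kick)|/D in monolayer mode and
|D − (D_frame + D_SWE)|/D in bulk mode, plus all τ/δ² ingredients and
10⁻⁵ cm²/s mirrors.

## Structure profiles

The 3D RDF is normalized by spherical ideal-gas shells.  The slab RDF
divides pair counts (full 3D minimum-image distances) by circular annuli
times an effective thickness, taken as the central 95% interval of the
oxygen density along the normal; 2D RDF conventions vary, so the thickness
used is reported with the profile.  The PMF is −ln g in units of kT, NaN
where g = 0.  Orientation histograms are normalized densities over
[0°, 90°], optionally split by HB/DB state.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical structure* the analysis assumes —
never force-field physics.  Three families, with a deliberate division of
labor:

**Telegraph series** give exact two-state Markov kinetics (per-step
probabilities 1 − exp(−k·dt), stationary fractions exact by construction)
for the survival/lifetime estimators.

**Jump walks** (`gen_ctrw`, `gen_two_channel_walk`) superpose Brownian
"frame" motion with Poisson jump channels and log every jump.  Their
closed-form D = D_frame + σ²/(2τ) per channel is the oracle for the MSD fit,
the CTRW estimators, and the additivity of the decomposition.  The
two-channel walk gives each walker 2 or 3 independent kick sources (mean
2.5, matching the monolayer coordination multiplicity) plus one exchange
source; its defaults place the kick channel at roughly three times the
exchange channel, the balance characteristic of strongly confined
monolayers, with a total near 0.56 Å²/ps.

**Geometric lattice toys** (`gen_toy_monolayer`, `gen_toy_bulk`) put
molecules on a jittered quasi-2D square lattice in a slab (or a 3D diamond
lattice) with valid H-bond geometry in every frame: H's aim at their
assigned acceptor when HB and along the wall normal (monolayer) or into the
tetrahedral void (bulk) when DB.  Acceptor targets follow an Eulerian
orientation of the lattice edges, so every molecule donates two and accepts
two with no mutually-donating pairs; a computed fraction of double-donation
pairs then tunes the mean distinct coordination to its target
independently of the DB fraction.  Kicks displace the donor away from its
partner (rising a configurable lead ahead of the orientation flip — the
planted cause of the "distance rises before the H-bond population drops"
signature); exchanges are vacancy-mediated: a shell member hops to an
adjacent vacant site while another molecule fills its place, and every
induced pairwise swap, including those seen by bystander neighbors, is
logged with its true time for recall/precision scoring.

The split is fundamental, not a convenience: a lattice toy with a
permanently valid H-bond topology necessarily has bounded relative
displacements, so it cannot also realize unbounded CTRW diffusion, and an
unbounded jump gas destroys the geometric H-bond network within a few jumps.
Detectors are therefore validated on the lattice toys (recall/precision
against the planted log) and estimators/additivity on the jump walks.
Consequently a full pipeline run on a lattice toy reports a large additivity
residual by design — its kick displacements relax back — and passing tests
say nothing about force-field realism, hydrodynamics, or wall corrugation.

Default generator conditions mirror the confined-monolayer statistics:
stationary DB fraction 0.35 with DB relaxation 0.24 ps (HB relaxation then
follows as 0.446 ps from the stationary balance), mean distinct coordination
2.5, lattice spacing 2.85 Å in an 8 Å slab; bulk: DB fraction 0.04, DB
relaxation 0.03 ps, near-four coordination on a diamond lattice sampled at
dt = 0.002 ps to resolve the fast DB kinetics.  Monolayer frames default to
dt = 0.01 ps, a typical AIMD output stride.  Detection-condition runs use
slower orientation kinetics (DB relaxation 1.2 ps) and a small kick
amplitude (0.12 Å) so planted events are separated from the transient
filter and frame jitter by an order of magnitude in time scale.

## Numerical choices and degenerate inputs

* Minimum images use fractional rounding (exact for displacements within
  ±1.5 cells, i.e. any wrapped configuration); unwrapping accumulates
  minimum-image steps and raises only when a step reaches the folding
  ambiguity at half a cell vector — true undersampling beyond that is
  aliased and undetectable in principle.
* Unresolved SWE boundaries (no equidistance crossing in the search window)
  and events with degenerate (<2-frame) segments are excluded from averages
  with a log notice, never silently dropped into the statistics.
* Kick events whose persistence window does not fit inside the trajectory
  are skipped rather than scored on a truncated window.
* Zero events is a valid result everywhere; averages over empty event sets
  raise `EmptyStatisticsError` instead of returning NaN.
* The pipeline records stages that legitimately produce no statistics as
  null entries in `summary.json` and continues; hard errors (geometry,
  config) abort.

## Problem sizes

The shipped validation suite and `scripts/acceptance.py` use 64–72-molecule
lattices over 25–60 ps, 150–1000-walker jump ensembles over 100 ps, and
10⁴–10⁵-episode telegraph series.  These sizes put the Monte-Carlo error of
every recovered quantity well inside its stated tolerance (e.g. ~1% on τ
recovery at 10⁴ episodes, ~2% truncation bias on τ_SWE at T = 100·τ) while
keeping the full run in the minutes range on one CPU.

## Known limitations

* No variable-cell (NPT) trajectories, velocities, or binary DCD/XTC input.
* The slab RDF thickness convention is a documented choice, not a community
  standard.
* τ_kick from pooled inter-event gaps is length-biased on trajectories much
  shorter than the per-pair kick period.
* The synthetic monolayer's H–O–H internal angles are not constrained to the
  water geometry; only O–H directions carry signal, so intramolecular
  observables are out of scope.
* Wall atoms are carried through I/O but no water–wall H-bond definitions
  are provided.
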