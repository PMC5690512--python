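# Methods

This note records the models, numerical choices and known limitations behind
`planpilot`, in the order the pipeline runs.

## Synthetic planning cases

A phantom is a 2D axial slice on a regular voxel grid (default 64×64 voxels of
2 mm): a circular external (body) contour, a central circular planning target
volume (PTV, default radius 12 mm) and 1–3 organs at risk (OARs) placed by
centre offset and size, so target–OAR proximity is a free parameter. Masks are
defined analytically; contours are extracted at the half-level between voxel
centres (marching squares), which makes mask → contour → mask round trips exact
on the generating grid. Physical coordinates are voxel-centre millimetres;
contours are closed polygons in mm.

Dose physics is a deliberately simple surrogate for a clinical beam model: each
of 16 coplanar beams (default) carries a fan of 17 beamlets covering the PTV
plus an 8 mm margin, and each beamlet deposits dose with exponential depth
attenuation (0.004 mm⁻¹, about 4%/cm, roughly 6-MV-like) and a **double-Gaussian
lateral kernel** — a 6 mm primary penumbra plus a broad scatter component
(relative weight 0.1, sigma 80 mm) and mild depth broadening (0.02 mm/mm).
The scatter term matters: it produces the smooth low-dose "bath" that real
multi-beam treatments have. With a single narrow Gaussian, all dose outside the
field edge lives in steep exponential tails whose position is not reproducible
between two geometries that differ by a couple of millimetres, and no
per-structure weight can then hold DVHs of two such geometries within a few
percent of each other; with the scatter bath, the dose an out-of-field organ
receives is a smooth, weight-controllable level. The standard study phantom
places its OARs beyond the primary field edge, inside that bath — the regime
in which a DVH-matching outer loop is well posed.

A reference library emulates previously treated patients: each case perturbs
every non-external structure of the base phantom by at most `jitter_mm`
(default 2 mm, split half/half between a random centre shift and a size
change), then optimizes a plan to convergence **on its own geometry**, so every
stored reference DVH is achievable where it was planned. All randomness in the
package lives here, under a single integer seed.

## Inner optimizer

The inner loop minimizes the standard convex fluence-map objective
`F(x) = Σ_s w_s · mean_{v∈s} pen(d_v)` over beamlet fluences `x ≥ 0`, with
`d = Dx`, a two-sided quadratic pulling targets to the prescription and a
one-sided quadratic penalizing OAR dose above an upper goal (default 0.2 × the
prescription, weight 0.5 — below the scatter-bath level, so the whole OAR DVH
responds to the weight). Default prescription: 50 Gy in 25 fractions.

Numerically the problem is nastier than it looks: the scatter component makes
`DᵀD` nearly singular along many directions, so the objective has long, almost
flat valleys. Plain projected gradient descent (including Barzilai–Borwein
stepping) stalls in those valleys orders of magnitude above the optimum while
its per-iteration progress drops below any relative-change tolerance — and the
~0.2 Gy DVH errors of such stalled solutions are comparable to the outer loop's
tolerance bands. The solver is therefore a bound-constrained quasi-Newton fit
(L-BFGS-B) run to tight tolerances (ftol 1e-12, up to 20 000 iterations) with
up to 20 fresh-memory restarts, because a single L-BFGS-B run can also
terminate prematurely on these valleys with a stale curvature model. With
restarts, cold starts and warm starts agree to ~1e-6 in the objective, which is
what makes the convexity property ("a warm start changes speed, not the
solution") observable. The line search only accepts descent steps, so the
recorded objective trace is monotone nonincreasing. Zero-weight structures are
dropped from the objective exactly, so `w=0` and "omitted" are bitwise
identical.

## DVH machinery

Cumulative DVHs use the universal clinical "volume receiving ≥ dose"
convention on a regular dose grid (bin width 0.001 Gy by default — the finest
resolution the file dialect is specified for). Header statistics
(Dmin/Dmax/Dmean) always come from raw voxel doses, not from the binned table.
The inverse curve `D_x` (minimum dose to the hottest x% of the volume) is read
off the binned curve by linear interpolation; segments are `D_x` at J fixed
volume fractions, default J = 20 evenly spaced from 2.5% to 97.5%. The file
dialect is a per-structure block of plain comma-separated text (name, three
header statistics, then a dose/volume table); it round-trips losslessly at the
stored resolution. Per-iteration exports use a coarser 0.01 Gy bin width
purely to keep output volumes reasonable; all comparisons run at full
resolution.

## Reference selection

Candidates are filtered on anatomical site (exact), structure-name set (after
whitespace/case normalization), physical target volume (±25%) and prescribed
dose (±10%). Survivors are scored with the signed radial metric: per structure,
144 rays (2.5° resolution) from the structure's own centre of mass in each
case; crossing radii matched by sorted index; signed difference
`r_reference − r_current`. Rays whose crossing counts differ cannot be matched
pointwise and are treated as exceeding any threshold — a conservative rule that
keeps the metric well defined for concave organs. Per-structure thresholds
default to a volume rule (< 10 cc → 2 mm, else 10 mm, both configurable within
the clinically quoted 1–3 mm / 5–15 mm ranges). Selection minimizes the worst
per-structure deviation, with RMS and case id as tie-breaks, and returns an
explicit no-reference result (CLI exit 3) rather than an exception when all
candidates fail. An overlay figure of current and reference contours is written
for human review in place of an interactive visual check.

## Outer loop

The loop warm-starts from the reference plan's parameters (and its fluence when
the beam layout matches). Constraint check: `|d_sj − d_sj_ref| < eps_sj` with
`eps_sj = max(0.03 · d_sj_ref, 0.1 Gy)`; ties at exactly the tolerance count
as violations, and each violation carries its signed excess beyond the band.

Weight update: aggregate each structure's signed excesses into `V_s` (Gy) and
set `w ← max(w · exp(clip(±eta · V_s / D_rx, −1, 1)), 0.05)`, the sign chosen
so an OAR overdosed relative to the reference gains priority and a target
gains priority on underdose. Three stabilizers, each motivated by an observed
failure mode:

* **eta = 300** — the clip saturates once a structure's aggregate excess
  reaches ~0.3% of the prescription. Far smaller rates cannot move the weakly
  weight-coupled bath segments within the iteration cap.
* **Sign-flip damping** — a structure's step scale halves whenever its
  aggregate violation changes sign between iterations (RPROP-style). Without
  it, many small same-sign bath violations saturate the clip and the weight
  oscillates across the tolerance band indefinitely.
* **Weight floor 0.05** — multiplicative updates are meant to keep weights
  positive, but sustained down-updates underflow to zero in floating point,
  after which the structure's dose is entirely uncontrolled. The floor is what
  bounds the damage an inflated (degraded) reference can do.

When the rule makes no progress on the worst excess for 4 consecutive
iterations, the loop switches to a deterministic pattern search: single-
structure log-weight moves (±0.5 and ±0.125, halving each exhausted round,
floor 0.01) proposed around the best parameters seen so far and kept only if
the worst excess drops. The rationale is empirical: stalled runs were shown by
independent coordinate search to be *feasible* in weight space, but the
feasible point required adjusting structures that had no violations of their
own (typically the target and the satisfied OAR) — moves the per-violator rule
never proposes. Every probe costs one outer iteration, so the printed
iteration count remains an honest measure of inner optimizations. If the
50-iteration cap is reached, the iterate with the smallest worst excess is
returned with a not-converged flag (CLI exit 2).

Trial refinement then visits targets first, OARs by descending weight: each
trial perturbs that structure's objective dose by 5% (targets up, OARs down),
re-optimizes, and is accepted only if no DVH segment of any structure worsens
by more than one DVH bin width (worsening = dose drop for target segments,
dose rise for OAR segments). Converged plans are inner-Pareto-optimal, so on
them essentially every trial is rejected and the plan is returned unchanged —
the expected fixed-point behavior. One pass by default; `trial_step = 0`
short-circuits.

## What the tests do and do not show

The phantoms exercise every algorithmic component under controlled geometry
noise, but they are 2D, use surrogate physics with a single beam energy, no
heterogeneity and no delivery constraints (no MLC sequencing, no arcs), and
their inter-patient variability is a bounded contour jitter rather than real
anatomical variation. Convergence results on phantoms therefore demonstrate
the mechanics of the decision function — not clinical plan quality. Problem
sizes used throughout (64×64 grids, 272 beamlets, 10-seed sweeps) are the
package's default study scale and run in minutes on one CPU.

Known limitations: the two-sided segment constraint means a plan *better* than
its reference on some segment is also "violating", which is faithful to the
absolute-difference stopping rule but occasionally forces the loop to give
dose back; references whose scatter-bath level differs from the current case's
by more than the tolerance below the OAR objective dose are not correctable by
any weight setting and end at the cap (about 1 draw in 30 at default
conditions); and the refinement stage is intentionally conservative at its
one-bin worsening tolerance.
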