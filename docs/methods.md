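# Methods

## The assay and its timeline

The pipeline analyzes time-lapse images of up to four 96-well shallow-well
plates (wells of 7.15 mm diameter and 3.25 mm depth, giving each larva an
effectively two-dimensional arena) acquired at one frame per 6 s. A
recording is divided into 10-minute periods: in the standard two-hour assay,
periods 1–2 show a blank gray background and periods 3–12 show red lines
(1 mm thick, 8 mm pitch) sweeping at 7 mm per 8 s, alternating direction —
down in odd periods, up in even ones. A one-hour acclimation precedes the
recording; if acclimation frames are present in a series they are tagged
period 0 and excluded from all scoring.

Coordinates follow raster conventions (origin top-left, y downward), all
rectangles are half-open, and "up" in a well means smaller y. Each
user-outlined row rectangle is partitioned into equal-width well regions
(integer remainders go to the leftmost regions, so the partition is
deterministic and tiles the outline exactly). Measurement regions are
rectangles by default; restricting to the inscribed 7.15 mm disc is an
opt-in refinement (`mask_shape: circle`) and requires the pixel scale.

## Detection model

Movement is measured by consecutive-frame subtraction: the absolute
per-pixel difference of frames *i* and *i+1* in a single color channel.
The channel is chosen to minimize |mean line intensity − mean background
intensity| (ties resolved in R, G, B order), so the moving stimulus is
nearly invisible in the analyzed channel while static structure cancels in
the subtraction and displaced larvae remain. Within each well region,
pixels with difference ≥ `diff_threshold` (default 25 of 255) are
foreground; their count is the area and their unweighted mean position
(pixel centers, i.e. index + 0.5) is the centroid. A well scores
`move = 1` when area ≥ `move_area_min` (default 20 px). The centroid over
*all* suprathreshold pixels — not the largest connected component — is
deliberate: a moving larva leaves a two-lobed difference blob (old plus new
position) and the up/down call should reflect both. `up = 1` when the
centroid's y is strictly above the well center; an exact tie counts as
down, and intervals with zero area have no centroid and no up value.
Difference rows are assigned the period of the *later* frame, attributing
movement to the time it is observed. A background-subtraction mode (each
frame against a per-pixel median or supplied reference) is provided for
sparse plates where static larvae must also be found; it feeds the same
thresholding. Processing is 8-bit throughout; deeper inputs are rescaled on
load with a warning.

Raising either threshold can only shrink the foreground or the set of wells
scoring a move, a monotonicity the tests assert alongside equivalence with
a brute-force per-pixel oracle.

## Scoring

Per larva and period, activity% is 100 × moved intervals / scored intervals
("lmpi", movement per 6-s interval), and up% is computed over the intervals
with a defined centroid only — missing positions are excluded from the
denominator rather than imputed or carried forward. The visual response is

    E-O = mean(up% over stimulus-up periods) − mean(up% over stimulus-down periods)

using only the stimulus periods (3–12 by default; blank periods are scored
for activity but never enter E-O). With the balanced default schedule this
equals the frame-level computation, so the distinction between per-period
and pooled averaging is immaterial. The headline activity value is the
first 10-minute period after acclimation; the whole-recording activity is
also reported. Larvae with overall activity below `activity_floor`
(default 5%) produce too few positions for a reliable E-O and are flagged
`eo_valid = False`. The floor is applied per larva — a stricter, well-defined
version of the group-level screening rule — and is configurable. Group
summaries report mean and SEM (sample SD / √n, undefined at n = 1), with
E-O statistics restricted to valid larvae, plus per-row means (a row of 12
larvae is the natural stable unit of this design).

## Group statistics

Activity and E-O scores are heavily non-normal across larvae, so all group
comparisons are nonparametric. Scores are binned — activity into quartile
bands [0,25), [25,50), [50,75), [75,100] (boundaries close upward except
the final bin); E-O into (−∞,0), [0,10], (10,∞), so an E-O of exactly 0 or
10 falls in the middle band — and compared with the classical Pearson
chi-squared homogeneity test (no continuity correction), expected counts
from pooled margins, dof = bins − 1 for two groups. Bins empty in both
groups are pruned first (they would give 0/0 expected counts); a bin empty
in only one group is kept, since that asymmetry *is* signal. The 50–50
goodness-of-fit test compares the positive/non-positive E-O split to
(n/2, n/2) with 1 dof; an E-O of exactly 0 counts as non-positive,
consistent with the tercile convention. Multiple comparisons use Bonferroni
thresholds α/n, and repeat experiments (run on separate days to keep samples
independent) are summarized by the median of the per-experiment p-values,
with unavailable entries dropped. Normality pre-testing is not implemented:
the workflow is unconditionally nonparametric. `molar_from_mass` converts
treatment concentrations (mg/L with a formula weight) to µM for reporting.

Monte-Carlo checks in the suite show the quartile-binned homogeneity test
rejects at 3.5–5% under identical group parameters (nominal 5%, n = 48 vs
24, 200 replicates) and that rejection frequency rises monotonically with
the simulated activity difference.

## The synthetic plate

The simulator's purpose is parameter recovery: the pipeline must read back
the behavior that generated the images. Each larva is a rigid dark ellipse
(semi-axes 2.0 × 0.5 mm, matching a ~4 mm 5-dpf larva; intensity (60,60,60)
on the 191-gray background, so a displaced larva produces |Δ| = 131 ≫ 25)
whose center lives in the disc of radius 3.575 − 2.0 = 1.575 mm. Per
interval it moves with probability `p_move`; the step direction is a
mixture distribution — with probability `g` exactly the stimulus direction,
otherwise uniform (always uniform when no stimulus is shown). The
probability mixture keeps the E-O response graded over the whole gain range
(group means ≈ 0, 36, 60, 76, 95 at g = 0, 0.25, 0.5, 0.75, 1 in the test
fixture) where a normalized vector blend saturates almost immediately in an
arena only three step lengths wide. Step length is 1 mm per moving interval,
a free simulator parameter (larval speed is not part of the detection
contract); only 6-s snapshots are observable, so no finer swim kinematics
are modeled. Directions whose step would exit the disc are re-drawn (16
attempts); when the direction distribution is too concentrated to stay
inside — a high-gain larva pressing against the wall — the larva instead
slides one step length of arc along the boundary toward the step's
tangential component, the wall-following seen in circular arenas. This
matters numerically: boundary handling that can return a larva near its
origin (radial reflection has a fixed-point locus) produces sub-threshold
difference blobs and breaks exact move-flag recovery, whereas sliding keeps
every displacement at ≈ 0.93–1.0 step lengths.

Rendering is desk-scale by default at 4 px/mm (the original rig resolves
48.3 µm/px ≈ 20.7 px/mm); at 4 px/mm a 1 mm step of the ellipse yields a
difference blob of ≥ 22–24 px, safely above the 20 px movement cutoff, at
roughly 1/25 the pixel count. The renderer draws the lines as the *camera*
sees them: the projector's nominal red (255,0,0) is brightness-matched to
the camera so the analyzed red channel carries only a 19-unit residual
(default rendered color (210,60,60)), below the 25 threshold — without this
camera model, the moving pattern itself would register as movement in every
well. Channel selection still picks red (|210−191| = 19 beats 131 in green
and blue). Per-larva rng substreams are derived from (seed, plate, row,
col), so results are independent of iteration order and bit-reproducible
from the seed; frames are rasterized lazily so a full 384-well, 1200-frame
series never resides in memory at once.

What the simulator does *not* emulate: tail kinematics and body bending,
pigmentation or background-adaptation changes, eye morphology, optics
(vignetting, perspective, debris), or pharmacokinetics — treatment presets
("untreated", "immotile", "hyperactive", "blind") simply set `p_move` and
`g`. Passing tests therefore demonstrate that the measurement chain is
correct and calibrated on images with known content, not that it is robust
to every artifact of a physical rig; on real data the thresholds and the
channel choice are the knobs to revisit.

## Numerical and design choices

- Centroids use pixel centers (index + 0.5); the up/down tie at the exact
  well center goes to down. Both are measure-zero events on real data but
  keep the pipeline total and deterministic.
- Stimulus offset is speed × t wrapped modulo the 8 mm pitch, signed
  positive downward; "spaced apart by 7 mm" is read as edge-to-edge gap
  (pitch = thickness + gap = 8 mm), with the gap configurable if
  center-to-center spacing is intended.
- Line-pattern displacement between rendered frames is measured by
  row-mean profile cross-correlation over circular shifts within one pitch
  (the displacement is identifiable only modulo the pattern period).
- Degenerate inputs raise typed errors (`GeometryError`, `ScheduleError`,
  `DetectionError`, `ScoreError`, `StatsError`, `FrameFormatError`) naming
  the offending quantity or file; empty groups and all-missing p-values are
  errors or NaN, never silently zero.
- `run_all` writes CSV/JSON/YAML artifacts plus a manifest (version, seed,
  config hash); identical (config, seed) reruns are byte-identical.
- Simulation problem sizes in the tests (a 120-larva gain ladder, one
  384-larva null experiment, 200-replicate score-level Monte Carlo for test
  calibration) are chosen to estimate each quantity well inside its
  tolerance while keeping the default suite fast on a single CPU.

## Known limitations

- The detector has no larva identity model: a dirt particle that moves, or
  two larvae in one well, are indistinguishable from a single larva.
- Subtractive mode cannot see a larva that never moves (by design); the
  background mode covers that case only when a clean reference exists.
- The chi-squared tests assume one independent score per larva; they are
  not suited to repeated measures within a larva.
- E-O validity uses a hard activity floor; larvae hovering near the floor
  contribute noisy E-O values just above it.
- The simulator's wall-sliding rule concentrates high-gain larvae on the
  boundary arc nearest the stimulus pole, which is plausible but untested
  against real trajectories.
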