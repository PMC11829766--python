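# Methods

## The color model

Cells carry a multicolor transgene; each integrated copy either stays in
its default far-red state or recombines to one of three fluorophores,
mapped onto RGB axes (tdTomato → R, YFP → G, mTurquoise → B). A cell's
measured channel means are normalized to simplex coordinates
`(r, g, b) = (R, G, B)/(R+G+B)`, which removes per-cell illumination and
expression-level differences; classification is therefore invariant to
rescaling the raw channels.

The simplex is partitioned into 25 color-identity regions: the
triangular grid with each edge divided into `N_SUBDIV = 5` equal
intervals (15 upward + 10 downward unit triangles; the implementation
validates `N_SUBDIV² = 25`). A point is located by the half-open floors
`i = ⌊5r⌋, j = ⌊5g⌋, k = ⌊5b⌋`: `i+j+k = 4` is an upward triangle,
`i+j+k = 3` a downward one, and lattice points (sum 5) are pushed into an
upward triangle by decrementing the largest coordinate's floor (ties in
r, g, b order). A snap tolerance of 1e-9 below each grid line makes the
assignment stable under floating-point round-off. The triangular tiling
is a design choice: 25 identities constrain the partition to a 5-fold
edge subdivision, but not the tiling itself; the grid is the unique
triangular one with that count and the tests validate it only through
the region count and geometric self-consistency (brute-force
point-in-triangle oracle).

Region frequencies over a cohort are classed frequent (fraction > 0.10),
rare (< 0.025) or intermediate. Clone red content is the per-cell mean
of r = R/(R+G+B) (normalized by default for illumination invariance; a
raw-intensity mean is available via `normalized=False`): red > 0.05,
non-red < 0.01, otherwise excluded from functional comparisons.

Cells whose channel sum falls below `min_total_intensity` (default 0.2
in normalized units, i.e. background level) are unclassifiable —
operationally these are unrecombined (far-red-only) cells, which the
color analysis excludes.

## Clone calling and traceability

Clones at one timepoint in one boundary are the connected components of
the graph joining cells that share a region index and lie within
`d_contact` of each other. `d_contact` defaults to 12 µm — roughly one
nuclear diameter at these stages — because "close contact" is qualitative
in practice; it is exposed in `PipelineConfig`. Components are numbered
by mean mediolateral, then dorsoventral position, giving stable ids of
the form `<boundary>-<n>`; the assignment is invariant to input row order
(cells are canonically sorted first) and decreasing `d_contact` can only
refine, never merge, the partition.

Traceability filters for time-lapse work keep clones of 1–3 cells whose
members all lie in the progenitor domain at t0 (apical contact, or
nucleus within the ventricular-zone band `vz_fraction` of the DV extent).
Clones with non-rare colors are kept only when isolated: no other clone
of the same region within `isolation_factor × d_contact` (default
factor 2 — conservative, since the isolation radius is not quantified in
the underlying protocol). Cross-timepoint linking is greedy one-to-one
matching on identical region and nearest (ML, DV) position; equidistant
candidates are flagged ambiguous rather than auto-assigned.

## Fate and division-mode rules

A cell is a progenitor (P) when its nucleus is ventricular-proximal and
it has an apical contact, a neuron (N) when mantle-proximal without
contact; conflicting evidence gives `unassigned`, and without a contact
flag the call degrades to position only. The VZ/MZ line defaults to a
fractional DV cutoff per boundary (an explicit per-boundary geometry
could substitute; the fractional form matches how the line is drawn on
transverse views).

A tracked division is classified from its daughters: PN when they are
out of contact on opposite sides of the VZ/MZ line; PP (both P) or NN
(both N) when in contact at the same DV level (`|ΔDV| ≤ dv_tol`,
default `d_contact/2 = 6 µm`). A daughter that divides again is a
progenitor by definition; otherwise its fate is read
`fate_exclusion_h = 3 h` after the division, and daughters observable
for less than that (and not dividing) leave the mode unassigned.
Raising the exclusion window can only reduce the number of assigned
modes.

Endpoint (composition-based) inference for two-timepoint designs counts
PP = number of progenitors and PN = number of neurons in a clone — every
PP division leaves one extra progenitor, every PN one neuron. NN
divisions are counted as mutually-nearest neuron pairs in contact at the
same DV level, each pair removing two from the PN tally; under the
literal rule NN is considered only in even-neuron clones. Two
conventions are provided:

- `literal` (default): PP equals the progenitor count, founders
  included, matching the published counting rule verbatim (whether
  founders were discounted is not stated there; we default to the
  letter of the rule).
- `founder_discount`: PP = P − founders + NN, which restores the
  NN-consumed progenitors and removes the founder offset. On fully
  tracked, zero-noise synthetic data this convention makes endpoint
  counts equal track-based counts for every clone — the consistency the
  acceptance check exercises. It also drops the even-neuron parity gate,
  since an odd neuron count can legitimately contain one NN pair plus a
  PN neuron; with the gate, such clones are the one case where the two
  counting routes must disagree.

An `all_even` NN rule (every even-neuron clone pairs all its neurons) is
available for sensitivity analysis.

## Sister statistics, growth, time-course

For two-cell clones at t0, sisters are concordant when both or neither
divide; synchrony is defined only when both divide — synchronous when
the division times differ by at most one frame interval, else
asynchronous with the delay in hours. Division-mode concordance is
reported when both modes were assigned. Clonal growth is cells per clone
per timepoint (non-decreasing absent track loss; violations are logged).
The division-mode time-course bins assigned PP/PN divisions per hour and
reports each fraction's least-squares slope, R² and p; a single usable
bin or a constant fraction leaves the slope flagged (R² = 0 by
convention for constant data).

## Group statistics

Two-group comparisons apply a Shapiro–Wilk gate at α = 0.05 per group
(the choice of normality test is a configurable convention): both groups
consistent with normality → Welch's unequal-variance t-test, otherwise
two-sided Mann–Whitney; groups below n = 3 skip the gate (Mann–Whitney,
with a note), and constant-valued groups fall back likewise. All tests
are two-sided. A summary-statistic Welch mode takes means/s.d./n
directly so printed figure-legend values can be checked without raw
data. Multi-group designs use one-way ANOVA followed by Dunnett
comparisons against a named reference with family-wise adjusted
p-values. The experimental unit (embryo, boundary or clone) is carried
on each sample and reported alongside the test.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
with defaults fixed at the study conditions of hindbrain-boundary
clonal tracking:

| parameter | default | meaning |
|---|---|---|
| `t_start`, `t_end`, `frame_interval` | 32, 45, 1 h | hourly imaging window (hpf) |
| `n_founders` | 44 | clones per cohort |
| `t0_size_probs` | {1: 0.10, 2: 0.77, 3: 0.13} | clone size at t0 (mean 2.0 ± 0.5, two-cell dominant) |
| `mode_probs` | (0.40, 0.58, 0.02) | PP / PN / NN per division |
| `division_prob_per_frame` | 0.043 | per-frame hazard; calibrated so ~half of t0 progenitors divide in the 13-h window |
| `sister_delay_mean/sd` | 2.8 / 1.9 h | zero-clipped normal inter-sister delay |
| `copy_number_distribution` | {1: 0.5, 2: 0.35, 3: 0.15} | transgene copies per founder (not known empirically; configurable) |
| `recombination_probs` | (0.1, 0.3, 0.3, 0.3) | far-red default vs the three fluorophores, per copy |
| `vz_fraction`, `dv_extent_um` | 0.5, 60 | ventricular band as a fraction of the DV extent |
| `channel_noise_sd` | 0.02 | additive Gaussian noise per normalized channel |

Founder colors are copy-weighted averages of the recombined copies' RGB
axes; all-unrecombined founders are emitted as far-red-only cells with
near-zero RGB (flagged in the ground truth). Division times sit on the
frame grid (an optional half-frame jitter supports half-hour timing);
divisions start strictly after t0 so clones are established, not caught
mid-division, at the first frame. After a PP division the first sister
divides on its own per-frame clock and the second after a delay drawn
from a normal(2.8, 1.9) clipped at zero and snapped to the grid. The
clipping convention matters: the clipped distribution has mean ≈ 2.86 h
and puts ~11% of pairs within the same frame, jointly matching the
reported mean delay and synchrony share, whereas rejection re-sampling
would inflate the mean to ≈ 3.2 h. Neurons never divide and appear in
the mantle zone from the frame after their birth.

Rendering assigns static positions satisfying the classification
geometry pairwise for sisters: progenitors form a tight
binary-subdivided cluster at one DV level inside the VZ (PP sisters in
contact at the same level), each PN neuron gets an isolated mantle-zone
slot, and each NN pair an adjacent mantle-zone slot pair (mutually
nearest, in contact). Clone anchors are spaced 120 µm mediolaterally and
25 µm anteroposteriorly, so distinct clones never touch. Measured
channels are the true color plus independent Gaussian noise clipped at
zero; positions are noise-free. The table withholds clone identity; a
ground-truth sidecar carries colors, lineage, modes, fates and realized
sister delays.

What the generator does **not** emulate: pixel-level images,
photobleaching or channel crosstalk, cell migration within zones, track
loss, or segmentation error. Passing tests therefore demonstrate the
correctness of the analysis logic under the stated statistical model,
not robustness to imaging artifacts; with real data the contact distance,
VZ geometry and intensity floor need per-dataset review.

## Problem sizes and verification

The test suite and the acceptance script verify: the 25-region partition
against a brute-force point-in-triangle oracle (10,000 random simplex
points plus a dense grid); recombination mixtures against exhaustive
two-copy enumeration; mode-fraction and dividing-fraction recovery on
cohorts of 400–600 clones at 3-standard-error tolerance;
endpoint-vs-track counting equality on 150 zero-noise clones;
clone-calling fidelity (adjusted Rand ≥ 0.95, in practice 1.0) on 300
default-noise clones; and the summary-statistic Welch test against a
hand-computed closed form. Cohorts of 500 clones run the full pipeline
in a few seconds, so the default sizes favor tight Monte-Carlo error
over speed.

## Known limitations

- Clone connectivity and division geometry conflict for clones
  containing neurons: a PN pair must be out of contact, so
  color+contact clone calling is faithful at t0 (all-progenitor clones)
  and clone membership at later times follows tracks, mirroring the
  tracking-first experimental procedure.
- The literal endpoint counting rule cannot match track-based counts
  exactly (founder offset, odd-neuron NN clones); the founder-discount
  convention exists precisely to close that gap and is the one used for
  consistency checks.
- Sister-delay recovery is compared against the generator's realized
  (grid-snapped, window-censored) delays, not the nominal 2.8 h:
  truncation, discretization and censoring are generator properties, not
  pipeline error; the measured mean under default conditions is ~2.5 h.
- The tracking-XML importer covers the spot/link subset only (IDs,
  frames, positions, edges), not the full feature model of the source
  tools.
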