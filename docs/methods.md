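# Methods

## The generative model

`flocknoise` simulates individuals that *co-move without interacting*. One
correlated random walk — the common path — is generated per flight, and
every individual is pinned to it at a fixed offset; all variation between
individuals is independent positional noise. Any structure the analysis
layer finds in the relation between one individual's movement and another's
position is therefore an artefact of (a) the maintained mutual positions
and (b) the noise process, never of behavioural rules.

### Common path

The path of N steps (default N = 4096) is defined by a speed series and a
turning series. Both start from i.i.d. uniform[-0.5, 0.5] draws that are
low-pass filtered in the frequency domain: the length-N discrete spectrum
is multiplied by `exp(-omega^2 / (2 sigma^2))`, with `omega` on the
two-sided integer frequency grid {0, 1, ..., N/2, -(N/2-1), ..., -1} and
`sigma = N / C` for a cut-off period of C steps. This is the only
convention under which `sigma = N/C` makes the surviving fluctuations live
on periods of order C or longer; the filter's DC gain is exactly 1, so
means are untouched, and filtering is applied to the raw draws with
circular boundary handling and no windowing (flights are long relative to
every cut-off used). The filtered series are normalized by their maximum
absolute value, which makes any linear rescaling before normalization
irrelevant, so none is applied.

Speeds are `S0 + s * eps1_hat` and per-step turning angles `a * eps2_hat`
(hats denote max-abs normalization): speed stays within [S0-s, S0+s] and
turning within [-a, a] by construction. Defaults S0 = 5, s = 0.2 a.u./step,
a = 0.02 rad/step, path cut-off C_T = 300 steps, and 5 steps per second
(dt = 0.2 s). Headings accumulate the turning angles; the path starts at
the origin heading along +x (all analyses are frame-invariant, so the
initial pose is irrelevant).

### Placement

At each step a placement segment crosses the path point at a configuration
angle theta relative to the direction of the step being taken (the final
step reuses the preceding direction, which does not exist at the boundary).
Individuals occupy equally spaced offsets on this segment with spacing
r = 5 a.u., centred on the path: ±r/2 for two individuals, {-r, 0, +r} for
three. Centring keeps the individuals statistically exchangeable relative
to the common path, which the left/right and front/back symmetries of the
analyses rely on; the assignment of individuals to offsets is drawn
uniformly at random once per flight and held fixed, so roles (front/back,
left/right) never switch within a flight. theta = 0 gives the front-back
configuration, theta = pi/2 side-by-side (positive offsets to the left in
the internal mathematical convention).

### Recording noise

Each individual's recorded position is its ideal position plus a
displacement whose x and y components are independent standard-normal
series filtered with cut-off C_D (default 20 steps; 100 models smoother,
e.g. tracker-smoothed, noise) and then rescaled to sample standard
deviation r/2 = 2.5 a.u. Rescaling happens after filtering, per flight and
per component — the only option when flights are generated independently —
so the pooled displacement amplitude is exact by construction while its
spectrum retains the imposed cut-off. Displacements of different
individuals are uncorrelated. The same noise term can be read as imperfect
station-keeping by real movers or as pure tracking noise on perfectly
rigid movers; the analyses cannot distinguish the two.

### Seeding

One seed defines a flight. Sub-streams are spawned deterministically
(common path: eps1 then eps2; offset assignment; then per-individual x and
y displacement series in individual order), and experiment-level seeds are
derived from a single master seed via `numpy.random.SeedSequence`, so every
experiment is reproducible bit-for-bit from one integer.

## The analysis layer

All quantities are estimated from recorded positions only, exactly as an
observer of real tracks would: speed and heading at time t from the
displacement arriving at t, tangential acceleration and turning rate at t
as the forward differences over t -> t+1 divided by dt (angular differences
wrapped to (-pi, pi]). Binning the forward change against the configuration
observed at t enforces that a response follows the configuration it is
attributed to; the alternative backward attribution would have responses
precede their stimulus. Steps with zero displacement carry the previous
heading forward and are flagged.

Pairwise geometry in the focal frame is reported right-positive (positive
angles to the focal's right), the convention force maps are usually drawn
in; internally all angles are mathematical convention and the single
negation happens in the geometry layer. The neighbour's direction is
`theta_ij = wrap(psi_focal - atan2(dy, dx))` — the focal *heading* is
subtracted, a position angle minus a heading being the only dimensionally
consistent reading — and the relative bearing is
`phi = wrap(psi_focal - psi_neighbour)`.

### Grids and reliability

Polar maps use 12 angular x 8 radial bins out to 20 a.u.; (theta, phi)
maps 12 x 12 bins over (-pi, pi]^2; front-back profiles 1 a.u. bins over
[-15, 15] a.u. At roughly 4 x 10^5 observations per 100-flight condition
this resolves the map structure while keeping typical cell means well
estimated. Cells with fewer than `min_count` = 100 observations are
flagged unreliable and never silently averaged; observations outside a
grid are counted as dropped so totals are conserved. Sign assertions on
cell means are made only for reliable cells, and — for the side-by-side
turning band — only in the interior of the band (lateral distance between
0.2 r and 0.8 r, fore-aft distance within 1.5 r), because the turning
signal necessarily vanishes at the symmetry axis d_lat = 0, changes sign
at the band boundary |d_lat| = r, and is dominated by rare longitudinal
excursions in the far fore-aft tails.

### The acceleration boundary

The repulsion-to-attraction boundary is located on the neighbour-ahead
branch of the front-back acceleration profile as the first adjacent pair of
reliable bins whose means pass from negative to positive, interpolated
linearly between bin centres. The negative-to-positive direction is part of
the definition: the profile also passes through zero near d_fb = 0, where
the two per-flight target populations (+r and -r) mix with opposite signs,
and that symmetry crossing is not the boundary of a repulsion zone. The
measured boundary sits slightly below r (typically ~4.7 a.u. at the
reference parameters) because of the same population mixing; the bias is
well within one bin width.

### Alignment modulation

The dependence of the turning response on relative bearing needs care. Two
facts about these trajectories break the obvious estimator (range of the
phi-marginal of the map): first, the apparent alignment response reverses
sign between the neighbour-ahead and neighbour-behind halves of the map —
the follower appears to copy the leader's heading because the common path's
current turning enters phi through the one-step geometric delay between
front and back positions, with opposite sign for the two roles — so a
marginal over theta cancels it almost exactly. Second, smoother noise
(larger C_D) shrinks the spread of measured phi itself, so any index based
on the observed phi range conflates shrinking support with the strength of
the dependence. `alignment_modulation` therefore reports the count-weighted
mean over theta rows of the magnitude of the per-row linear slope of
turning on phi (units (rad/s)/rad), in the attraction zone, skipping rows
holding under 0.5% of the observations. Under this index the apparent
alignment response roughly doubles from C_D = 20 to C_D = 100 at the
reference parameters, while the apparent attraction response collapses —
the qualitative shift that smooth noise produces.

### Multi-neighbour maps

For three-individual flights, responses are binned by the signed front-back
distances to the two neighbours; by default the nearer neighbour (by
|d_fb|) defines axis 1, with a documented `ordering="random"` alternative
used for symmetry checks. The pairwise-average prediction
`(p(d1) + p(d2)) / 2` uses a profile estimated from two-individual flights
on identical bins. Observed and predicted surfaces are compared on the
observed map's reliable cells. The comparison is made on the turning
response; for the acceleration response the pairwise prediction *overshoots*
in the rare extreme cells, because the two-individual profile attributes a
large front-back reading entirely to a deviation of a target-r pair,
whereas in a trio the same reading is often a modest deviation of the
target-2r neighbour — a mixture effect worth knowing about when comparing
such maps on real data.

### Directional correlation delays

`tau*` maximizes the mean cosine of heading differences over lags in
[-50, +50] steps (10 s; far beyond every noise scale studied), averaging
only over indices where both headings are defined — no wrapping or padding,
which would manufacture spurious correlation. Ties are broken toward the
smallest |tau|, then toward positive, deterministically. The delay
experiment computes tau* twice per flight (each individual as focal) and
labels results by the focal's role; positive tau* means the focal
anticipates. Front individuals are flagged as leaders purely because the
common path reaches their position first; at C_D = 100 the heading
estimates are accurate enough that the delay locks to ±1 step in nearly
every flight, and the interquartile range collapses relative to C_D = 20.

## What the generator does and does not emulate

The generator reproduces the statistical skeleton of tracked co-moving
pairs: realistic speed/heading persistence, fixed formation geometry, and
positional noise with tunable amplitude and autocorrelation. It omits,
deliberately: any behavioural response (so detected "rules" are provably
artefacts), switching of relative positions within a flight (real animals
do switch sides, which rounds the band-shaped repulsion zones seen here
into the circular zones reported for real groups), 3-D movement, body
orientation distinct from movement direction, and observation gaps or
outliers. Passing tests therefore demonstrate properties of the inference
machinery on this null model — not that any real species moves this way.

## Numerical choices and degenerate inputs

Sample standard deviations use the n-1 divisor throughout. The spectral
filter requires n >= 2 and a positive cut-off; max-abs normalization
rejects all-zero input, rescaling rejects zero-variance input. Kinematics
require at least 3 positions; coincident focal/neighbour positions make
the direction undefined and the step is excluded from binning. With zero
displacement noise the recorded tracks equal the ideal tracks exactly and
adjacent inter-individual distances equal r at every step. Map edges must
be strictly increasing; profile/template grids must match exactly for the
pairwise prediction. Zero-crossing interpolation is linear between bin
centres, making the reported boundary resolution-independent to first
order.

## Default problem sizes

Reference experiments use 100 flights of 4096 steps (two individuals;
~4 x 10^5 pooled observations) for maps and profiles, 120 flights for
delay distributions, and 100 three-individual flights for multi-neighbour
maps — sizes at which every reported effect is stable across master seeds
while a full experiment runs in seconds on one CPU.
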