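# Methods

## Problem and model

Repeated motion-capture takes of one action (a karate kick, a block, a
stance) never coincide: phases of the movement are stretched and
compressed nonlinearly between takes, every sample carries small sensor
noise, and subjects face arbitrary directions after calibration. The
package builds a single *template* — an averaged, smoothed full-body
recording — from such a set, and uses templates to compare, visualize
and classify actions.

Motion is modeled as a hierarchical kinematic chain rooted at the hips:
each joint stores the local rotation of its bone relative to the parent,
the root stores the global body rotation, and translation is ignored
(angle-only modeling makes everything invariant to body proportions).
Rotations live as unit quaternions internally. Working on the quaternion
double cover rather than Euler angles removes the ±180° wrap
discontinuities and gimbal-lock degeneracies that break naive averaging;
the price is that `q` and `−q` encode the same rotation, so every
operation here is constructed to be sign-invariant.

## Distances

The working DTW cost is `cf(x, y) = 1 − |x·y|` (4-D dot product): cheap,
bounded in [0, 1], and zero exactly on equal rotations. Three
alternatives are provided for comparison studies: the geodesic distance
`2·arccos(|x·y|)` (the rotation angle between the two attitudes, taking
the shorter of the two sign representatives), the tangent-space distance
`‖log x − log y‖` (with both arguments canonicalized to the w ≥ 0
hemisphere so it is sign-invariant), and the relative-rotation-angle
distance `2·arccos(|re(x·ȳ)|)`. The last is also exposed in an
"as-printed" mode returning `|re(x·ȳ)|` itself; that quantity is 1, not
0, for identical rotations and is kept only for completeness — it is
not a metric and nothing downstream uses it.

## Markley averaging

The barycenter of a weighted quaternion set is the dominant eigenvector
of `M = Σᵢ wᵢ qᵢ qᵢᵀ`. Because `qqᵀ = (−q)(−q)ᵀ`, the mean is invariant
to input signs, and the eigenvector is unit-norm by construction. The
4×4 symmetric eigenproblem is solved with a standard symmetric solver
(`numpy.linalg.eigh`), batched over time indices where whole signals are
averaged. Output signs follow a fixed canonical rule (w ≥ 0, ties broken
on x, then y, then z); a (near-)degenerate top eigenvalue — e.g. two
orthogonal attitudes with equal weight — means the maximizer is not
unique, in which case one maximizing eigenvector is returned with a
warning.

## Heading correction

The body's forward direction is the first-frame root rotation applied to
`[1, 0, 0]`. A yaw-only quaternion φ is found by brute-force search over
yaw ∈ [0°, 360°) in 0.05° steps (well below the ~0.5° static accuracy of
inertial capture hardware; the search is a single vectorized pass),
scoring the angle between the re-rotated forward vector and `[1, 0, 0]`.
φ is pre-composed onto every root sample; all other joints are untouched.
Ties on the grid go to the smallest yaw.

## DTW and DTWND

Classic unconstrained dynamic programming with steps (1,1), (0,1), (1,0)
and no window; an optional Sakoe–Chiba band exists in the configuration
for speed but is off by default. Ties are broken preferring diagonal,
then (0,1), then (1,0), which makes paths deterministic across
platforms. The *normalized* distance (DTWND) is the total path cost
divided by the number of path pairs: this keeps DTWND on the scale of
the cost function regardless of signal lengths, and is the standard
normalization for the symmetric step pattern. DTWND symmetry under
argument swap holds whenever the optimal path is unique (always, in
practice, for continuous-valued signals); under exact cost ties the
tie-break may select transposed paths of different lengths.

The inner DP kernel is numba-jitted with a pure-Python fallback of
identical semantics; correctness is pinned by an exhaustive
path-enumeration oracle at small lengths.

## DBA with Markley means

Template averaging is DTW barycenter averaging: initialize with the
medoid (the input with the smallest summed DTWND to the others; ties to
the lowest index, making the result input-order-invariant), then
iterate: align every input to the template by DTW, pool for each
template index all input samples the warping paths match to it, and
replace that index with their uniform-weight Markley mean. The DTW
boundary conditions guarantee every template index receives at least one
sample (asserted). The objective is `Σᵢ DTWND(template, sigᵢ)²`.

The Markley mean maximizes `Σ (q·qᵢ)²` whereas the DTW cost is
`1 − |q·qᵢ|`; the two are minimized by the same point only
approximately, so per-iteration descent is not a theorem. The iteration
therefore evaluates the objective after each update and rolls the update
back (stopping) if it did not improve; the recorded convergence trace is
non-increasing by construction. In practice the rollback never fires on
data resembling the generator's output. Defaults: at most 10 iterations,
stopping when the objective improves by less than 1e-10.

For a *full-body* template one body-level medoid is chosen (smallest
summed per-joint DTWND) and used to initialize every joint's DBA —
per-joint medoids could come from different takes with different frame
counts, which would leave the assembled template without a common
length. Heading correction runs on each take before averaging; each
joint (root included) is then averaged independently and smoothed.

## Manifold smoothing

DBA can leave single-sample "leaps" that no human movement at 100 Hz
could produce. The smoother replaces each sample `j` with the Markley
mean of the window `j−ws … j+ws` under symmetric Gaussian weights — a
low-pass convolution where the weighted sum is replaced by the
eigenvector mean, so the result stays on the unit sphere. At the
boundaries the window is truncated; rescaling the kernel would multiply
`M` by a constant and cannot change its dominant eigenvector, so
truncation alone is exact. Output signs are chained for continuity (the
first output sample aligned with the first input sample), which makes
constant signals exact fixed points and `ws = 0` the identity.

Defaults: `ws = 10` samples (0.1 s at 100 Hz) and `σ = ws/3`, placing
the window edge at three standard deviations. 0.1 s suppresses
single-sample spikes without flattening actions lasting 2–4 s; both are
configurable.

## Matching and visualization data

Comparisons are emitted as data, not pixels (PNG rendering is an
optional cosmetic layer): a per-(recording, joint) DTWND matrix; a 3-D
*mapping plot* (both trajectories as time × two projected Euler
components — X and Z rotation by default — with one costed
correspondence segment per warping-path pair, segment costs summing to
the DTW total); a 2-D *distance plot* (signal 1 as a line of anchors,
signal 2 offset perpendicular by the cost to its matched anchor); and
the raw warping path as the alignment plot. Offsets below 1e-12 are
snapped to zero so dot-product round-off cannot fabricate extrema.
Extreme correspondences are strict local maxima/minima of the offset
sequence (plateaus count once at their first index, endpoints compared
one-sided, an all-constant sequence has none), reported top-k each with
the matched frame indices of both signals.

## Classification

Kick classification uses twelve angle features per frame: the angles
between the body-frame axes `X = LeftThigh−RightThigh`,
`Y = Chest−Hips`, `Z = X×Y` (positions from forward kinematics) and the
limb vectors `V1 = LeftLeg−LeftThigh`, `V2 = LeftLeg−LeftFoot`,
`V3 = RightLeg−RightThigh`, `V4 = RightLeg−RightFoot`, each via the
arccos of the normalized dot product (degrees in [0, 180]). Being angles
between position differences, the features are invariant to global
translation, global rotation, and uniform skeleton scaling. Feature
vectors enter DTW raw, with plain Euclidean per-frame cost.

A recording is assigned to the class whose template's feature sequence
has the smallest DTWND; ties go to the lexicographically first label
with a warning. Templates come from the full averaging pipeline. Two
protocols ship: leave-one-out (the held-out take's own class template is
rebuilt from the remaining takes; other classes keep templates from all
of their takes, since a held-out take exists in only one class) and
cross-subject (population A's templates classify all of B and vice
versa; the rate pools both directions). An experimental mode sums
per-joint quaternion DTWNDs against template recordings instead of
using features.

## Synthetic data

The generator emulates what distinguishes real repetitions of one
action: smooth per-joint trajectories (slerp through axis-angle
keyframes at 100 Hz) distorted by a monotone random time warp (the warp
is a normalized cumulative sum of strictly positive smooth speeds, so
monotonicity holds by construction and the derivative stays within
`[(1−s)/(1+s), (1+s)/(1−s)]` for strength `s`), per-sample random-axis
rotation noise, random contiguous-segment quaternion sign flips, and a
random constant heading on the root. Defaults, chosen once: warp
strength 0.3, noise ≤ 2° per sample (between the hardware's 0.5° static
and 2° dynamic accuracy), sign-flip probability 0.2 per ~0.2–0.6 s
segment, heading uniform over [0°, 360°), take durations 2.0–2.8 s with
±10% jitter (all within the 2–4 s range typical of short techniques).

Eight built-in classes mimic kick families (mawashi / mae / hiza / yoko
× left/right, mirrored parameterizations). The mae- and hiza-like
classes share the thigh trajectory exactly and differ only in the shin:
mae briefly extends the knee to 55° flexion at the apex while hiza holds
~95°, making them deliberately the most confusable pair. Mawashi and
yoko are held apart by thigh abduction (45° vs 80°), a component that
inter-subject style never touches.

A *subject style* is a set of constant per-joint rotation offsets about
the flexion axis — kick height and knee-extension depth are where
individuals differ most — with shin offsets weighted twice thigh
offsets and signed fractions drawn once per subject, so an offset sweep
scales the same style directions monotonically. What the generator does
**not** model: kinetics, ground contact, balance adjustments, sensor
drift, or correlated (colored) noise. Passing tests therefore
demonstrate the algorithmic contracts (optimality, invariances,
convergence, separability under the modeled distortions), not
performance on any particular real dataset.

## Numerical choices and degenerate inputs

* Quaternions are w-first arrays; all constructors normalize and reject
  non-finite input; `cost_dot` clamps dot-product round-off at 0.
* Euler conversions go through `scipy.spatial.transform`; gimbal-lock
  frames (middle angle ±90°) are resolved by zeroing the third angle —
  the recomposed rotation is unchanged. Outer angles wrap to [−180, 180).
* BVH: degrees in files, radians never written; frame time printed with
  7 decimals; reading obeys the file's declared channel order, writing
  uses each joint's stored channel specification (default Z, X, Y).
  Root translation is parsed, carried through and written back, but
  excluded from all analysis. Parse errors name the offending line.
* Degenerate feature vectors (coincident joints) raise an error naming
  the vector and frame rather than emitting NaN angles.

## Problem sizes

The shipped experiments run at 8 classes × 10 takes (leave-one-out, 80
decisions) and 8 classes × 5 takes × 2 subjects per sweep level
(cross-subject). These sizes exercise every pipeline stage at the take
counts the protocols were designed for while keeping a full run in the
order of a minute on one core.

## Known limitations

* DBA is a heuristic: it converges to a local optimum that depends on
  the medoid; no global optimality is claimed.
* DTWND magnitudes depend on the normalization convention (path length
  here); absolute values are comparable only within one convention.
* The heading objective uses the first frame only; takes that begin
  mid-turn would be better served by a robust multi-frame variant.
* The classifier's feature set targets lower-body actions; upper-body
  actions need a different feature set by design.
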