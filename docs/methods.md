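# Methods

`kinfp` analyzes single-molecule kinetic fingerprinting experiments: a
surface-captured analyte (a miRNA, a protein epitope, a mutant DNA strand)
is repeatedly and transiently visited by a fluorescent probe, and the
temporal pattern of those visits — not a static intensity — identifies the
molecule. This note records the models, the defaults and the reasoning
behind the open design choices.

## Binding model and simulator

Each molecule is an alternating renewal process: bound dwells are
exponential with mean τ_on, unbound dwells exponential with mean τ_off,
and the initial state is drawn from the stationary distribution, so the
long-run bound fraction is τ_on/(τ_on+τ_off). The camera integrates the
continuous path frame by frame (default frame time 0.1 s): a dwell
covering 40% of a frame contributes 40% of the bound amplitude to that
frame, matching photon integration; per-frame Gaussian noise is then
added. A per-frame binary state (`integration: "binary"`) is available
for comparison.

Default emission puts the bound/unbound means at 1/0 with noise SD 0.2
(trace S/N 5, typical of a well-tuned TIRF acquisition). The default
three-plex target set is (τ_on, τ_off) = (0.49, 10.35), (2.29, 2.69) and
(6.25, 16.47) s — the ensemble values of the miR-29 / miR-16 / let-7a
probe designs that the multiplexed studies use throughout.

Nonspecific binders are modeled as sparse, short events: a
truncated-Poisson number of events per acquisition (mean 1.5, at least 1)
with exponential bound dwells of mean 0.3 s, started uniformly in time.
Short, rare, irregular sticking is exactly what kinetic filtering is
designed to reject; the parameters are exposed in the config.

A C12 (mixed-dye) molecule runs one renewal process; each bound event is
colored Cy3 or Cy5 with probability ½ (the molecule is bound by at most
one probe at a time), producing one trace per color whose union is the
molecule path.

Movie rendering places molecules uniformly at random with ≥4 px pairwise
separation, draws each as a symmetric 2-D Gaussian punctum (σ = 1 px)
whose integrated amplitude follows the noiseless occupancy path, and adds
per-pixel Gaussian read noise. The simulator records exact transition
times per molecule, which serve as the oracle for every downstream stage.

What the simulator does *not* emulate: photobleaching, blinking of the
dye itself, drift, uneven illumination, camera offset/gain structure, or
aggregates. Tests passing on simulated data therefore validate the
pipeline's statistical machinery, not its robustness to those
instrumental artifacts.

## Movie processing

The fluctuation map is the mean absolute frame-to-frame intensity change
per pixel; it is invariant to static offsets and highlights blinking
puncta. ROIs are 3×3-pixel windows centered on local maxima (plateau-
tolerant 3×3 maximum filter) above a threshold — default the 99.5th
percentile of the map, configurable as an absolute value — kept greedily
in order of descending value (ties: lexicographic center) subject to a
minimum Chebyshev separation of 3 px. Traces are the 9-pixel window sum
minus 9× a per-frame local background, estimated as the median of the
7×7-minus-3×3 annulus (robust to neighboring puncta); a global per-frame
median is available as a fallback.

## Idealization

Traces are idealized with a two-state hidden Markov model with Gaussian
emissions sharing a single noise SD, fitted per trace by Baum–Welch EM
(init: per-trace 1-D two-means; transition matrix started at 0.9/0.1;
per-trace convergence at relative log-likelihood change < 1e-5, max 50
iterations; non-converged traces keep their best iterate and are
flagged). The Viterbi path is decoded and the state with the larger mean
is "bound". The fixed two-state model replaces variational-Bayes state
selection: this analysis only ever distinguishes probe-bound from
probe-unbound.

The EM and Viterbi kernels are batch implementations vectorized across
traces (compiled with numba when available, with an equivalent numpy
fallback) because a study idealizes tens of thousands of traces; batches
are chunked to bound working memory.

Dwell bookkeeping treats the first and last runs of every path as
censored by the observation window: they are excluded from dwell lists
(flags record them) because truncated dwells bias exponential statistics.
`min_event_frames` (default 1) can merge shorter runs into their
flanking state; the default keeps single-frame events because the
shortest real bound dwells are one 100-ms frame.

Known limitation: any frame-based idealization has a dead time of about
half a frame. Dwells shorter than ~Δ/2 are missed, which removes short
dwells and merges their neighbors, biasing fitted mean dwell times
upward by roughly the missed-event fraction — a few percent when
τ ≳ 20 frames, negligible for the slow three-plex targets, and
substantial when τ approaches one frame. Ensemble τ recovery is
validated in the regime where the dead-time correction is below the 5%
test tolerance.

## Fingerprints and filtering

The kinetic fingerprint of a molecule is N_b+d (the number of binding
plus dissociation transitions in the path), the median complete bound and
unbound dwells (τ_on,med, τ_off,med), the maximum complete unbound dwell
(τ_off,max), and S/N. S/N is implemented as (mean_bound −
mean_unbound)/noise_sd — signal over noise — because a *minimum* S/N
filter only makes sense with signal in the numerator; the inverse ratio
is available behind `literal_inverse`. Undefined statistics (no complete
dwells) are NaN and fail any filter bound on that parameter.

Filtering accepts a molecule iff every bounded parameter lies within its
bounds. Thresholds are optimized by exhaustive grid search maximizing
accepted target-sample molecules subject to accepted blank-sample
molecules per FOV ≤ a cap (default 0 on the training blanks); ties prefer
fewer accepted blanks, then fewer active bounds. The default grid spans
N_b+d minima 2–20, dwell-median bounds 0.1–30 s in logarithmic steps, and
minimum S/N ∈ {2, 3}. The S/N bound matters: a trace with no real events
fits a two-state model to pure noise and produces a long jittery path
(large N_b+d, sub-frame dwells, S/N ≈ 1), and the S/N gate removes that
failure mode wholesale.

## Chromatic demultiplexing

Molecules accepted in Cy3 only are C1, Cy5 only C2; molecules kinetically
accepted in both channels *and* colocalized within 2 px are C12. ROI
colocalization is greedy nearest-neighbor matching (each ROI used once,
deterministic order: descending fluctuation value, lexicographic
tie-break); greedy matching is adequate at the sparse surface densities
simulated and is documented as a limitation at high density. A molecule
accepted in both colors but not colocalized is two molecules. The C12
merged path is the frame-wise union of the two color paths (bound
whenever either probe color is bound), with dwells recomputed on the
merged path; emission statistics are averaged, as they only feed S/N.

## Cluster training and assignment

Targets form clusters in (τ_on,med, τ_off,med) space, log10-transformed
by default — dwell medians span decades, and axis-aligned Gaussians are
only plausible on log axes (identity transform available). Color is the
discrete third dimension: clusters compete only for molecules of their
own channel. Training fits a per-axis mean and SD after iteratively
discarding points >3σ from the current mean on any axis until nothing is
discarded ("3D Gaussian fit without covariance": two log-dwell axes plus
the categorical color axis; no Gaussian is fitted across color).

Assignment offers two rules. The *ellipse* rule is pure containment: a
molecule belongs to a cluster iff its squared scaled distance d² =
Σ_axis((x−μ)/σ)² is within the χ² (2 dof) quantile of the confidence
level (5.991 at 95%), and it takes the smallest-d² containing cluster;
assignment sets nest as the confidence level rises. Containment alone,
however, has a structural floor: a 95% ellipse fitted to same-condition
training data excludes ~5% of the very population it describes, no matter
how long the acquisition. Measured cluster scatter shrinks as 1/√(number
of dwells) with acquisition time, so the data tighten but the fitted
ellipse tightens with them, and the unassigned fraction plateaus near 5%.

The *confidence* rule (pipeline default) removes that floor while keeping
every exclusion that is scientifically meaningful: a molecule is assigned
when it lies inside some confidence ellipse *or* its posterior
classification probability under the equal-prior diagonal-Gaussian
mixture of same-channel clusters reaches the confidence level, provided
it falls within the 3σ per-axis envelope of that cluster — the same 3σ
outlier criterion used in training. Points in cluster-overlap regions
(ambiguous posterior) and genuine outliers stay unassigned; the ~5% of
well-behaved points just outside their own ellipse are rescued. Under
this rule the unassigned fraction of the three-plex simulation falls from
~12% at 50 s (dominated by molecules with too few complete dwells to
define medians, which the pipeline counts as unassigned, plus broad
overlapping clusters) through ~1–3% at 300 s to below 1% at 1000 s. The
union of a growing ellipse family and a tightening posterior gate is not
monotone in the confidence level, so no nesting is claimed for this rule;
it always assigns a superset of the ellipse rule at the same level.

Exact d² ties go to the first cluster in model order (a measure-zero
event). k-means proper appears only as a cross-check: initialized at the
pretrained means with no refinement it reduces to nearest-center
assignment, which the tests compare against the scaled-distance path on
equal-σ models.

## Quantification

Ensemble dwell statistics come from the cumulative frequency of pooled
dwell times, binned at the frame time, fitted to y = −exp(−x/τ) + c (the
amplitude fixed at −1 for the single-exponential case; c → 1 for
exponential data). The coefficient τ is the ensemble mean dwell; a fit is
accepted iff SSE < 0.05 and R² > 0.99. Standard curves are unweighted OLS
of mean accepted counts per FOV on concentration (replicate SDs are
reported, not used as weights); the limit of detection is 3·(blank-count
SD)/slope, an exact closed form; concentrations are (count −
intercept)/slope floored at zero; spike-in normalization multiplies by
(true/measured) recovery of a doped control (default 5 pM). Group
comparisons use the classical pooled-variance two-sample t test.

Counting studies (standard curves, LOD, ratio-metric mixtures) simulate
at the digital-counting level: accepted counts per FOV are Poisson with
mean proportional to concentration plus a small nonspecific background —
digital single-molecule counting is a Poisson process by construction,
and this isolates the quantification arithmetic from trace-level detail.

## Problem sizes and numerical choices

The packaged studies use 500 molecules per target (plus 200 per target
for independent cluster pretraining) over 10 seeds for the
acquisition-time study; 20 target-free FOVs of 500 nonspecific traces
each for filtering specificity; ≥1,000 pooled dwells per τ for CDF-fit
recovery; and 10,000 draws for confidence-containment checks. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; no global random state is used anywhere.
Degenerate inputs are handled explicitly: zero-variance traces raise (or
yield all-undefined fingerprints in batch), zero-variance cluster axes
raise, infeasible threshold constraints raise with the best achievable
blank count attached.
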