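# Methods

## Scope and model

`pvsmap` quantifies enlarged perivascular spaces (PVSs) on a T2-like
intensity volume that is already in T1 space, together with a region label
volume and white-matter (WM) / basal-ganglia (BG) masks. Tissue
segmentation, T2→T1 rigid registration, and scanner-specific intensity
calibration are upstream of the package: phantoms are generated
co-registered, and the detection threshold is configurable because an
absolute intensity-difference cutoff is meaningful only within one
uniformization convention.

The analysis chain is: intensity uniformization → local-contrast detection
→ 26-connectivity clustering → per-cluster morphometry → per-region and
per-network tables → extreme-of-outcome Mann–Whitney comparison → severity
map.

## Parcellation registry

The quantification frame is 72 areas (36 per hemisphere: 8 temporal, 11
frontal, 5 parietal, 4 occipital, 4 cingulate, 4 basal ganglia), DKT-style
labels. Network membership is hemisphere-symmetric: DMN = {angular gyrus,
medial orbitofrontal, middle temporal, posterior cingulate, precuneus},
CEN/FPN = {caudal anterior cingulate, inferior parietal, inferior temporal,
lateral orbitofrontal, caudate, rostral middle frontal}, SN = {insula,
rostral anterior cingulate}.

Two reconciliations were needed to keep the printed network sizes (5, 6, 2
per hemisphere) consistent with the 72-area frame:

- the **insula** is an SN key region but not one of the 72 quantified
  areas. It is carried as an extra label (ids 37/137) present in the
  *analysis* region set but excluded from the strict-72 view that defines
  the 288-data-point frame.
- the **angular gyrus** (a DMN key region) falls inside the inferior
  parietal label in DKT-style parcellations, and inferior parietal is a
  CEN/FPN key region. To keep DMN and CEN/FPN disjoint — which the (5, 6)
  sizes require — inferior parietal carries CEN/FPN membership only, and a
  distinct angular-gyrus label (ids 38/138, analysis set only) carries the
  DMN membership.

The registry's `Region.group` field gains an extra value `insula` for the
insular label, since it belongs to none of the six lobe/BG groups of the
72-area listing; the (8, 11, 5, 4, 4, 4) group cardinalities are invariants
of the strict-72 view. Label ids: left 1–36 in listing order, right +100,
extras 37/38 (+100). The caudate is carried as the whole-caudate label;
thalamus, putamen, and pallidus are quantified but belong to no analyzed
network.

## Segmentation

**Uniformization.** The intensity field is divided by a smooth low-frequency
field estimated within the tissue mask by normalized convolution (Gaussian,
default FWHM 10 mm — large against PVS calibre of 1–3 voxels, small against
the across-brain bias it must track), then rescaled to preserve the masked
median. On a flat image the operation is the identity to numerical
tolerance; on a constant image under a low-frequency multiplicative bias it
recovers the constant to well under 2 % relative error. This is a simple,
stated stand-in for scanner-side inhomogeneity correction, not a
reimplementation of any particular tool.

**Local contrast.** Per masked voxel: intensity minus the mean of its
surrounding voxels. The default surround is the full 3×3×3 shell (26
neighbours); an in-plane 3×3 shell (8 neighbours) is exposed for strongly
anisotropic data. At volume borders the neighbourhood truncates to
in-volume voxels (no padding artefacts). A voxel is PVS when its contrast
**strictly** exceeds the threshold (default 60): a contrast of exactly 60
is not a PVS.

**Clustering.** 26-connectivity connected components
(`scipy.ndimage.label` with a full 3×3×3 structuring element); an
independent union-find oracle pins the behaviour in tests.

**Diameter.** Defined as the maximum over axial slices of the equivalent
circular diameter `2·sqrt(A/π)`, where `A` is the in-slice cluster area in
mm². In-plane, because slice thickness (4.4 mm) exceeds PVS thickness.
Note a consequence: for a tube lying within one slice the in-slice footprint
is the whole tube, so this "diameter" scales with in-plane extent rather
than tube calibre — it is an area-equivalent index, deterministic and
rotation/translation invariant in-plane, not a caliper width. (Whether a
per-cluster mean, max, or caliper measure is the better summary is an open
design choice; max-over-slices equivalent diameter was chosen and is used
consistently.)

**Region assignment.** A cluster spanning several labels is assigned by
majority voxel count, ignoring background; ties break to the smallest label
id, so each cluster counts exactly once and network sums cannot
double-count. Clusters entirely on background get a sentinel and are
excluded from region metrics (logged).

## Quantification

Per region: PVS count, PVS volume in voxels, mean cluster diameter (0 for
empty regions — kept as a valid observation so tables stay rectangular),
and region voxel volume; 72 × 4 = 288 data points per subject in strict
mode. Normalizations: volume fraction and count fraction divide by the
region's voxel count; whole-brain WM PVS volume divides by WM voxel count.
Network rows (3 networks × 2 sides) sum counts and volumes over member
regions; the network diameter is the cluster-count-weighted mean of member
region diameters (an unweighted mean would over-weight near-empty regions).
The Potter visual scale (0; 1–10; 11–20; 21–40; >40) applies per scoring
unit — whole-brain WM count by default, per-region optionally — and a
Spearman rank correlation (average ranks under ties) compares visual and
quantitative scores.

## Group comparison

The extreme-of-outcome design compares only the lowest and highest symptom
categories: language none/low vs absent (intermediate excluded), sensory
no vs yes, stereotypies no vs yes, support level 1 vs 3 (level 2 excluded);
unknown values are always excluded. Each of the 18
(network, side, measure) cells gets a two-sided Mann–Whitney U test
(U reported for the low group): exact null distribution when the combined
sample is ≤ 20 and tie-free, otherwise the normal approximation with tie
and continuity corrections. Significance at α = 0.05 with **no**
multiplicity correction by default, mirroring the bivariate design this
emulates; Benjamini–Hochberg FDR is available behind a flag. Severity per
(network, side): the number of significant measures among {count, volume,
diameter} maps 0/1/2/3 → none/yellow/orange/red, rendered as a tile figure.

## Synthetic data

**Phantom.** Default grid 64×64×16 voxels at 0.8×0.8×4.4 mm. The label map
partitions the volume into near-cubic boxes assigned registry labels (BG
labels form the BG mask, other labels the WM mask). Background intensity is
a per-region constant (base 100, region offsets N(0, 5) — small against the
threshold so region borders never masquerade as PVSs), scaled by a smooth
multiplicative bias field (amplitude 5 %, to exercise uniformization), plus
optional Gaussian noise. Tubes are rasterized in physical mm
(voxel-center-in-radius), radius 0.5–1.0 mm, length 4–12 mm, contrast
default 120 (= 2× threshold), pairwise non-adjacent under 26-connectivity
by construction (candidate tubes are rejected if they touch the dilation of
previously placed ones), connected, within tissue, and off the volume
border (a border voxel's truncated neighbourhood plus field-estimation edge
bias would erode its contrast). Orientation is near-in-plane
(default max tilt 5°): with 4.4-mm slices a steep tube either rasterizes to
laterally disconnected per-slice segments or stacks disks whose interior
voxels keep >half their neighbours inside the tube, which destroys the
local-contrast signal — both are degeneracies of through-plane tubes on
this grid, and real acquisitions of this anisotropy are read in-plane for
the same reason.

**Cohort.** 36 subjects with exact categorical marginals (22 M / 14 F;
language 17 none-low / 4 intermediate / 15 absent; sensory 20/13/3 unknown;
stereotypies 17/16/3 unknown; support 10/6/20; age N(4, 2.3) truncated to
1–9 y). Unknown symptom values sit on the last subjects in enrollment order
so split sizes are reproducible. Metrics per (network, side): counts
Poisson(λ = 12), volumes lognormal(median 60 voxels, σ_log = 0.5),
diameters lognormal(median 1.2 mm, σ_log = 0.15), WM volume
N(4×10⁵, 4×10⁴) voxels — positive, right-skewed baselines typical of
morphometry; no per-region burden distributions are published for the
emulated cohort, so these are the generator's own stated conditions, chosen
once for clear power at n ≈ 30. Effects are in baseline-SD units *d*:
lognormal metrics shift by d·σ on the log scale (indistinguishable from a
d-SD normal shift to a rank test), Poisson rates become λ + d·√λ; they
apply to the symptomatic (high) group of a chosen symptom (default
language). A male elevation of count/volume burden (default d = 0.8)
emulates the reported sex difference in WM-PVS burden; it is set to 0 in
null-calibration settings.

**What the phantom does not model.** No MRI physics (no Rician noise, no
partial-volume averaging beyond centre-in-radius rasterization), no T1
channel, no anatomy (box-grid parcellation), no spatially correlated noise.
Passing recovery tests therefore show the detector implements its
definition exactly on its own terms — voxel-exact recovery of non-adjacent
high-contrast tubes — not that it matches human raters on clinical scans.
The cohort generator likewise fixes the correlation structure (cells
independent given group), so calibration results speak to the statistics,
not to real covariance of brain networks.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng(seed)`; equal
  seeds give bit-identical phantoms and cohorts.
- Desk-scale problem sizes throughout: 64×64×16 phantoms segment in tens of
  milliseconds; the full simulate→segment→quantify→compare CLI run
  completes in well under a minute on one CPU; calibration suites use
  ~100–500 replicate cohorts.
- Degenerate inputs are errors, not silent defaults: empty masks, empty
  split groups, inconsistent cohort marginals, unknown labels/symptoms,
  constant vectors in rank correlation, geometry mismatches (the offending
  file is named).
- Known limitations: the diameter index conflates calibre with in-plane
  extent (see above); the box-grid phantom cannot test region-boundary
  anatomy; the absolute threshold 60 presumes the shipped uniformization
  convention and should be recalibrated for other scanners; group
  comparisons are bivariate by design (no covariate modeling).
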