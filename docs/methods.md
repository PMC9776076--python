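# Methods

`eegfc` estimates functional connectivity between EEG channels as
histogram mutual information, summarizes the resulting weighted networks
with small-world graph metrics, and tests stage effects across a cohort
with a repeated-measures battery. Because multichannel task EEG is rarely
shareable, the package ships a synthetic generator with known coupling
structure so every stage of the chain is testable end to end.

## Signal model and preprocessing

A recording is a channels × samples block at a fixed sampling rate
(default: 29 channels of the 10-10 montage at 500 Hz; Fp1/Fp2 excluded and
Fz used as reference, matching a 32-electrode cap worn under a VR
headset). Preprocessing applies, in order:

1. **High-pass** at 0.53 Hz, removing DC offset and drift.
2. **Notch** (band-stop) at 59–61 Hz for mains interference.
3. **Band-pass** into one of six conventional bands: delta (1–4 Hz),
   theta (4–8), alpha (8–13), beta (13–32), low gamma (32–50), high gamma
   (50–80).

All filters are 4th-order Butterworth designs applied forward–backward
(`sosfiltfilt`), i.e. zero-phase: band content is not delayed, so epoch
boundaries line up across bands. The filter family is a design choice —
any reasonable zero-phase IIR band-pass gives equivalent downstream
results; linearity and the stated stop-band attenuation are covered by
tests. Filtering runs on the continuous record *before* segmentation so
filter edge transients do not sit inside analysis epochs.

The filtered record is consecutively segmented into non-overlapping
one-second epochs (trailing remainder discarded), and the first *n* = 50
epochs whose peak-to-peak amplitude stays at or below `ptp_limit` (default
100 signal units) on every channel are kept. The threshold rule is a
deterministic stand-in for manual epoch vetting; with fewer than *n* clean
epochs the result is flagged (`shortfall`), never silently padded.
Temporal-order selection (the *first* n clean epochs) is a convention; any
deterministic rule would do.

## Mutual-information connectivity

For two channels x, y within one epoch, dependence is measured by plug-in
(maximum-likelihood) mutual information of the 2-D histogram:

    MI(x, y) = Σ_ij p_ij ln[ p_ij / (p_i p_j) ]   (nats)

The bin count per axis follows the Freedman–Diaconis rule computed per
channel, per epoch: bin width h = 2·IQR·n^(−1/3), bins = ⌈range/h⌉, one
bin for degenerate data. The joint histogram uses the product of the two
marginal bin counts over each channel's [min, max]. Empty cells contribute
zero (p ln p → 0); no bias correction is applied. MI is reported in nats
so the bivariate-Gaussian closed form −½ln(1−ρ²) can serve directly as a
calibration oracle.

Two properties of this estimator matter for interpretation:

* **Bias floor.** For independent channels the plug-in estimate is not 0
  but ≈ M/2n where M is the number of occupied joint cells. At one-second
  epochs (n = 500, ~15–20 FD bins per axis on band-limited noise) the
  floor is ≈ 0.3 nats; it decays only as n^(−1/3). Every "no coupling"
  entry of a stage matrix sits at this floor, which is why normalized
  matrices have no zero off-diagonal entries. At n = 10⁵ the floor is
  ≈ 0.06 nats for Gaussian marginals and ≈ 0.01 for bounded (uniform)
  data — the difference is purely the number of occupied tail cells.
* **Per-epoch binning.** The FD rule is applied per epoch (not once per
  stage), reading "for each epoch" literally; bins therefore adapt to
  epoch-level amplitude.

The stage matrix is the entrywise mean of the 50 per-epoch matrices. The
all-pairs computation is vectorized: each channel is digitized once per
epoch, all 406 pair joint histograms are accumulated in a single
`bincount` over offset-encoded codes, and MI follows from
MI = (1/n)Σc·ln c − m_x − m_y + ln n with per-channel marginal terms m;
this is algebraically identical to the naive per-pair histogram (verified
to 1e-15 in tests) and ~50× faster.

**Weight conversion.** Each stage matrix is normalized by its largest
absolute off-diagonal entry, forcing weights into [0, 1] with max = 1 and
a zero diagonal; an all-zero matrix passes through unchanged. Stage
contrasts (e.g. task − baseline) are entrywise differences of normalized
matrices, so their entries lie in [−1, 1]. Edge thresholding
(`top_fraction_edges`) keeps the round(q·n_edges) heaviest edges —
rounding half away from zero, matching the "29 × 0.3 ≈ 9" hub convention —
with deterministic (weight desc, label pair) tie-breaking.

## Graph metrics

Stage matrices are weighted undirected graphs (weight 0 = no edge). Path
metrics map weights to lengths reciprocally, l = 1/w: stronger coupling =
shorter path. This is the standard convention for weighted brain-network
path metrics; the alternative (1 − w) compresses strong edges and is not
used. On the lengths:

* **Betweenness centrality** — BC_i = 2/((N−1)(N−2)) Σ_{h≠j≠i}
  n_hj(i)/n_hj over unordered pairs, via Brandes' accumulation on weighted
  Dijkstra with path-multiplicity counting. Two candidate path lengths
  count as tied when they differ by ≤ 1e-10 relative tolerance — floating
  point Dijkstra needs an explicit tie rule for multiplicities. The
  normalization puts a star center at exactly 1.
* **Characteristic path length** — mean over nodes of the mean shortest
  path to all others. Disconnected pairs have infinite distance, so CPL
  is reported as ∞ with a `connected=False` flag rather than silently
  dropping pairs.
* **Global efficiency** — mean of 1/l_ij over ordered pairs with
  1/∞ := 0, staying finite and informative on disconnected networks.
* **Clustering coefficient** — binary mode: CC_i = 2t_i/(k_i(k_i−1)) with
  t_i the triangle count and CC_i = 0 for degree < 2. Weighted mode: the
  Onnela geometric-mean triangle intensity t_i = ½Σ(ŵ_ij ŵ_ih ŵ_jh)^(1/3)
  on weights rescaled by the network maximum, same denominator.
* **Transitivity** — Σt_i / Σk_i(k_i−1)/2 (triangles over connected
  triples), with the weighted t_i in weighted mode; 0 when no triples.

Both binary and weighted modes are exposed because published analyses are
often ambiguous about binarization; the pipeline default is weighted,
since stage matrices are genuinely weighted. All five metrics are verified
to 1e-9 against independent oracles (Floyd–Warshall distances, exhaustive
simple-path enumeration for betweenness, direct triangle/triple loops) on
200 random graphs and against networkx, plus closed forms (complete graph,
cycle, star).

## Hubs, pathways, lateralized contrast

Hubs are the round(0.3·N) nodes of largest betweenness (9 of 29), ties
broken lexicographically so hub sets are deterministic and nested in the
fraction. Hub pathways are the top 30% of weights within the hub
principal submatrix (11 of 36 edges for 9 hubs). Hubs are recomputed per
stage × band; cross-stage pathway comparisons use each stage's own hubs.

The lateralized occipital contrast asks whether one of the two occipital
channels (O1/O2) — plausibly the one aligned with the subject's dominant
eye — gains betweenness from baseline to task. Per subject, the channel
with the larger BC increase is chosen (ties resolve to the first listed
channel); a paired t-test then compares chosen-channel BC between stages
across subjects. The per-subject argmax is a modeling choice: the
alternative (testing O1 and O2 separately) is less powerful when the
lateralized side varies across subjects. All-zero differences flag the
result as degenerate instead of raising.

## Statistics

* One-way repeated-measures ANOVA from the within-subject decomposition
  (SS_total = SS_subject + SS_condition + SS_error), F with
  (k−1, (k−1)(n−1)) df, partial η² = SS_cond/(SS_cond+SS_error). No
  sphericity correction is applied, matching the plain one-way design;
  with k = 3 stages and mild violations this is slightly liberal, which
  the type-I calibration test bounds empirically.
* Post-hoc two-sided paired t-tests per condition pair at Bonferroni
  α = 0.05/n_pairs (0.0167 for three stages).
* Paired t-test for the pre/post closed-eyes contrast.
* Mann–Whitney U for between-group (e.g. sex) comparisons: exact null
  distribution for combined n ≤ 20 without ties, otherwise the normal
  approximation with tie and continuity correction.

Zero-variance degenerate inputs return flagged results (p = NaN) rather
than raising, so sparse synthetic cohorts never abort a pipeline run.
P-values are not corrected across bands or metrics (only within the three
stage pairs); consumers should treat per-band significance descriptively.

## Synthetic generator

Each channel is independent 1/f^α pink noise (α = 1 default, the typical
broadband EEG spectral slope) plus a sum of shared sources. A shared
source is white noise band-limited by the same 4th-order zero-phase
Butterworth band-pass used in preprocessing — guaranteeing the injected
dependence lives in the intended band (verified by periodogram: < 5%
out-of-band power) — rescaled to unit variance and added to its target
channels with a per-stage gain. Randomness derives from a single seed via
`SeedSequence(seed, spawn_key=(stage,))` with one child stream per
channel and per source: bit-identical regeneration of any stage in
isolation, independent noise across stages.

The **task-effect preset** (`vr_effect_config`) encodes, per
high-frequency band (beta, low gamma, high gamma):

* four coupling blocks mirroring a posterior block, a right-frontal
  block, and two fronto-posterior interaction blocks, with gains
  stage 1 = stage 2 = 0.2 < stage 4 = stage 5 = 0.35 < stage 3 = 0.65
  (task strongest, partial persistence post-task);
* a stage-constant **anchor** pair (Cz–C3, gain 1.5) emulating the
  near-ceiling MI that volume conduction produces between adjacent
  electrodes. The anchor pins the max-normalization so that weight
  conversion divides every stage by (statistically) the same constant;
* a stage-constant global background coupling at gain 0.1, deliberately
  weak.

The anchor and the weak background encode a lesson from the generator's
design: the MI between two channels falls when *either* channel gains
variance from sources the other does not share. Raising only block gains
therefore *dilutes* any appreciable stage-constant background coupling
network-wide and can invert the expected CPL/GE orderings; keeping the
stage-constant baseline in the (zero-covariance, hence undilutable)
estimator bias floor makes the injected orderings recoverable. For the
same reason the block gain 0.65 sits inside the region where CPL is still
monotone in the gain. Gain magnitudes are calibration choices — the
emulated study reports no MI effect sizes — fixed once from this power
budget.

The **null preset** is identical with all stage gains equal (0.4), so any
systematic stage differences downstream are false positives. The
**occipital-lateralized preset** couples O2 to two distant channels (F3,
CP5, gain 3.0 in the task stage vs 0.3 at baseline) so O2 becomes an
intermediary on shortest paths; a seed-dependent random background
connectome (60 stage-constant pair couplings, gains U(0.25, 0.4)) plus a
spoke-variance jitter gives betweenness realistic between-subject
variability. Exactly two spokes is deliberate: with k spokes sharing a hub
the hub–spoke correlation is capped at 1/√k, and k > 2 pushes hub-edge MI
below twice the bias floor, at which point two-hop routes through the hub
never beat direct floor edges and the hub's betweenness vanishes.

### What the generator does and does not emulate

It reproduces the dimensions of the emulated study (29 channels, 500 Hz,
five stages, 50 one-second epochs), band-specific stage-dependent
coupling, a 1/f background, and near-ceiling neighbor-pair dependence. It
does **not** model rhythmic oscillations (alpha peaks), ocular/muscle
artifacts, genuine volume conduction (a continuum of spatially correlated
leakage), non-stationarity within stages, or inter-subject anatomical
variability. Passing recovery tests therefore demonstrates that the
estimation chain recovers known coupling structure under EEG-like noise —
not that it would be robust to artifacts or leakage in real recordings.

## Problem sizes and numerical choices

Simulation studies use the emulated study's scale: 10 subjects, 50
one-second epochs per stage, 60 s of generated signal per stage (enough
for 50 clean epochs with headroom), the high-gamma band, and 20 replicate
cohorts for ordering-recovery rates. The pipeline's null-preset
calibration uses the same 20-cohort design with a binomial bound (≤ 4/20
rejections at α = 0.05), while the 1000-replicate type-I calibration of
the tests themselves runs directly on Gaussian null tables — the
full-pipeline variant at 1000 replicates would add nothing statistically
and hours of compute. Path-length ties use 1e-10 relative tolerance;
oracle agreement is asserted at 1e-9; byte-identical reruns are asserted
at the pipeline level (fixed float formatting in all writers).

## Known limitations

* Plug-in MI bias: all reported MI values are biased upward by the
  occupied-cell count over 2n; comparisons across conditions at equal n
  are unaffected, absolute values should not be read as information
  content.
* Max-normalization couples every weight to the single largest entry; a
  stage where the anchor pair's estimate is noisy rescales the whole
  matrix (visible as a small common factor in CPL/GE).
* With 29 nodes the hub fraction rule quantizes to exactly 9 hubs; for
  other montages the round-half-away rule is kept for comparability.
* The RM-ANOVA assumes sphericity; the Mann–Whitney exact path assumes no
  ties (midrank approximation otherwise).
* EDF export is out of scope (reading is supported when `mne` is
  installed); recordings interchange as TSV + JSON sidecars.
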