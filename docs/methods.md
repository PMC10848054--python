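# Methods

`thalmod` re-implements, at desk scale and on fully synthetic data, a
modular-network analysis of resting-state fMRI in temporal lobe epilepsy
(TLE): cortical network modularity and segregation, winner-take-all
functional parcellation of the thalamus into the seven canonical
resting-state networks, hub metrics of the resulting thalamic subdivisions
on a 207-node thalamocortical graph, and the accompanying group statistics.
This note documents the models, the generator, the numerical conventions,
and what the validation experiments do and do not show.

## The analysis model

**Connectivity and graphs.** Functional connectivity between two regions is
the Pearson correlation of their time series. An undirected binary graph at
sparsity S keeps the K = round(S·N(N−1)/2) strongest *positive*
correlations as edges; S is swept over 0.1, 0.2, …, 1.0 and every metric is
summarised threshold-free by the trapezoidal area under its curve (AUC)
across the sweep. Negative correlations never become edges: edge *counts*
over negative weights are ill-defined, and the standard proportional-
threshold practice discards them (when fewer than K positive entries exist,
all positives are kept and the achieved sparsity is recorded). Rounding is
half-away-from-zero and ties on equal correlation break by ascending
(i, j) index pair; both conventions change edge sets on degenerate inputs
and are therefore fixed and tested.

**Cortical modular metrics.** All metrics use the fixed a-priori 7-network
partition (VIS, SMN, DAN, VAN, LIM, FPN, DMN) of the 200 cortical parcels —
no community detection (a Louvain-based detected-partition Q exists as a
cross-check only). Modularity is the Newman form

    Q = (1/2E) Σ_ij [A_ij − k_i k_j / 2E] δ(c_i, c_j).

The modular segregation index of module m is MSI(m) = (W̄ − B̄)/W̄ with W̄
the mean positive within-module correlation and B̄ the mean positive
correlation from m to the rest of the cortex; negative entries count as
zero. MSI is computed once on the unthresholded weight matrix (default):
on binary graphs it would collapse into a deterministic function of the
intra/inter edge counts, which are already reported separately per level.
A per-level binary mode is retained for comparison. Intra-/inter-module
connections are raw edge counts (no size normalisation — the module sizes
are fixed across subjects and groups).

**Thalamic parcellation.** Thalamic voxels come from a probabilistic mask
thresholded strictly above 10%. Per subject, each network's seed signal is
the mean of its parcels' series, and a 7 × V seed-to-voxel correlation map
is computed. Maps are averaged across *all* participants through the
Fisher z transform (variance-stabilised averaging; raw-mean and per-group
modes exist behind flags), and each voxel takes the label of its strongest
seed. Ties break by the fixed network order with a warning; a non-positive
winning correlation is labelled by the argmax anyway but flagged. No
spatial constraint or smoothing is applied to the labels.

**Thalamocortical hub metrics.** The 7 subdivision mean series are appended
to the 200 parcels (fixed network order; each thalamic node inherits its
network's module label), giving a 207 × 207 correlation matrix.
Thresholding this matrix as a whole would discard thalamocortical edges —
they are systematically weaker than cortico-cortical ones — so the same S
is applied *independently* to the cortical (200×200), thalamo-thalamic
(7×7) and thalamo-cortical (7×200) blocks before reassembly ("two-step
thresholding"). The bipartite block therefore always carries exactly
round(S·1400) edges; an adversarial construction in the tests shows
single-step thresholding retaining zero of them. At S = 0.1 the 7×7 block
rounds to 2 edges; whether that block should instead be fully retained is
not determinable from the source analysis, so same-S is the default and a
full-retention mode is provided. On the binary 207-node graph the thalamic
nodes get the participation coefficient PC_i = 1 − Σ_m (k_im/k_i)²
(0 for an isolated node) and the within-module degree z-score
WMD_i = (κ_i − mean κ)/sd κ over the nodes of i's module, with population
SD and z = 0 when the SD vanishes.

**Statistics.** A one-sample Kolmogorov–Smirnov test against a normal with
estimated mean/SD gates every quantitative comparison into pooled-variance
t / one-way ANOVA (normal) or Mann–Whitney U / Kruskal–Wallis H
(non-normal); the estimated-parameter bias of this KS usage is known
(conservative) and a Lilliefors-style correction is deliberately not
applied because the published statistics reproduce under the plain form.
Chi-square for categoricals has no continuity correction — the published
2×3 and 2×2 sex statistics (3.364, 2.777) reproduce exactly without it,
and the published t values (2.336, −4.505, 0.703) reproduce under pooled
rather than Welch variance; both choices are therefore fixed, with Welch
behind a flag. Mann–Whitney reports a tie-corrected z without continuity
correction and switches to the exact null distribution for total n ≤ 10
without ties; Kruskal–Wallis likewise enumerates group assignments exactly
for total n ≤ 10. Correlations between metric AUCs and MoCA are Pearson
when both variables pass the normality gate, Spearman otherwise. Bonferroni
correction is corrected_p = min(1, m·p) with families defined per metric
across nodes and group pairs and recorded in every report.

## The synthetic cohort generator

No raw data accompany the source study, so the package ships a generator
whose defaults *are* the study conditions; every validation experiment runs
against its planted truth.

Per subject, seven unit-variance latent network signals are drawn with
pairwise latent correlation b (the between-coupling). A parcel of module m
is x = √a·L_m + √(1−a)·ε with a the within-coupling, so the expected
within-module correlation equals a exactly and the between-module
correlation is √(a_m a_n)·b. A thalamic voxel of network n mixes latents
with diffusivity d (own-latent weight √(1−d), √(d/6) for each other
network, renormalised to unit variance), scaled by coupling strength c,
plus noise of which a fraction ρ is shared by all voxels of that network:

    voxel = √c·base + √(1−c)·(√ρ·η_n + √(1−ρ)·ε_v).

The shared component ρ emulates spatially correlated thalamic noise; it is
load-bearing: without it, averaging ~50 voxels into a subdivision series
removes the noise entirely and the coupling strength c cancels out of every
subdivision-level metric. The two hemispheres are 6×6×6 voxel blocks with
mirrored labels (and mirrored noise draws by default, making hemispheric
symmetry of the recovered parcellation exact); the probabilistic mask is
0.9 inside the blocks and 0.05 in a one-voxel shell. The default-mode
subdivision is planted largest, matching its known dominance in the
thalamus.

**Group conditions (defaults, chosen once for detectability at the study
scale — the source reports effect directions but no magnitudes).** Controls:
a = 0.6 everywhere, b = 0.2, c = 0.5 and d = 0.15 to every network. Both
patient groups: ventral-attention and default-mode within-coupling lowered
to 0.20 with the latent couplings of pairs touching those networks at 0.19.
The depth of that deficit matters structurally: under proportional
thresholding the graph's intra/inter composition only changes when the
affected networks' internal correlations sink to the level of their
external ones, so a milder deficit would leave binary-graph modularity
untouched (the segregation index, computed on weights, responds to any
deficit). Both patient groups also have the default-mode thalamic coupling
lowered to 0.35. The impaired group additionally has an elevated and more
diffuse somatomotor thalamic coupling (c = 0.90, d = 0.20), which raises
both the tha_SMN participation coefficient (through the diffusivity) and
its within-module degree (through the strength, via ρ).

**Subject heterogeneity and cognition.** Two independent per-subject draws
jitter the thalamic parameters: a truncated-normal multiplicative scale on
c (SD 0.04) and an additive normal shift on d (SD 0.20). The scalar
"somatomotor-thalamic coupling" of a subject is c_SMN + d_SMN, and the MoCA
score is intercept + slope·coupling + noise, clipped into the group's range
(impaired 0–25, intact 26–30, consistent with the < 26 screening cutoff
used for classification). The impaired group's slope is positive
(16 points per coupling unit, noise SD 0.6), so cognition is tied to the
same subject-level parameter that drives the connector-hub behaviour — the
generative counterpart of the compensation interpretation in the source
literature. The two jitters are independent because the participation
coefficient is nearly invariant to a uniform scaling of a node's
correlations: strength and diffusivity push PC in opposite directions, and
a single joint scale would cancel the subject-level signal.

Demographics (age, sex, education, onset age, duration, seizure rate,
mono-/polytherapy) are drawn from normal/lognormal/Bernoulli families
parameterised to the published marginals; duration is drawn independently
of age and onset rather than as their difference, a simplification that
only affects the realism of the phenotype table, not any network analysis.

## Validation experiments

* **Label recovery** — homogeneous control cohorts (d = 0, c = 0.5,
  T = 300, 20 subjects) parcellated by the full pipeline recover ≥ 95% of
  planted voxel labels across seeds (in practice 100%).
* **Direction of effect** — each planted manipulation is studied in
  isolation at n = 25/group, T = 300, 20 seeds: the cortical deficit alone
  must lower Q AUC and VAN/DMN MSI; the thalamic manipulation alone must
  raise tha_SMN PC and WMD AUC and produce a positive PC–MoCA correlation
  within the impaired group. Isolation is deliberate: in a combined cohort
  the cortical deficit concentrates low-sparsity edges into the unaffected
  modules, saturating somatomotor parcel degrees and contaminating the WMD
  contrast with a cortical artefact.
* These experiments run on the generated series directly; the generator's
  output is stationary and artefact-free, so temporal cleaning would only
  add estimation noise. The full path including preprocessing and motion
  exclusion is exercised by the pipeline runner and the analysis drivers.

**Problem sizes.** The experiments use 10 seeds (recovery) and 20 seeds
(direction of effect) at the study scale above; the demo analysis under
`analysis/` uses 10 subjects per group at T = 300. These sizes make every
run reproducible on a laptop in minutes while keeping the group tests
well-powered for the planted effects.

## What passing does and does not show

The generator is a block-correlation model: it has no scanner drift,
physiological spectra, spatial autocorrelation, registration error, or
heavy-tailed motion, and its thalamus is rectangular. Passing therefore
shows that the *analysis stack* is correct and directionally sensitive
under known ground truth — not that the published effect magnitudes
reproduce (no raw data are released, and magnitudes are explicitly out of
scope). The within-module degree contrast is the least powered read-out:
its detection rate sits near the 80% design point and dips toward 70% on
some seed sets, a consequence of the same subject-level diffusivity spread
that powers the cognition correlation.

## Known limitations

* MSI's exact published formula is cited, not printed, in the source; the
  system-segregation form on positive weights is adopted here.
* The nuisance model consumes white-matter/CSF columns as given; whether
  they were extracted before or after filtering originally is unknowable.
* Band-pass is a zero-phase 4th-order Butterworth (an ideal-FFT filter is
  available for cross-checks); the original toolbox's filter family is
  unspecified.
* The cognitive link is planted only through the somatomotor-thalamic
  coupling; real cognition has many more determinants.
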