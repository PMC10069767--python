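# Methods

This note records the models the package implements, the assumptions and
tunable parameters behind them, what the synthetic generators do and do
not emulate, and the design choices made where the design was genuinely
open.

## Depth deconvolution of a two-strain mixture

**Model.** A host doubly infected by strains A and B yields one pooled
read set.  Aligned to strain A's assembly, the expected per-base depth is
proportional to the titer-weighted copy multiplicity: 1 for shared
single-copy backbone, *f* (strain A's titer fraction) for A-private
intervals, and f·c_A + (1−f)·c_B for an interval present in c_A/c_B
copies.  Two closed forms follow: a k→k−1 copy loss sits at (k−1)/k
normalized depth and requires k same-level partner regions; a private
region sits at *f* relative to the backbone.

**Windowing.** Windows are 1000 bp stepped by 500 bp, starting at
position 1 (1, 501, 1001, …); a window exists only if it fits entirely on
the genome, and trailing bases enter the genome mean but produce no
window.  The genome mean is computed from raw per-base depth before
capping; capping (default 5) affects only the capped track that
segmentation reads.  Circularity is ignored for windowing — no wraparound
windows — since end effects are negligible at megabase scale.

**Segmentation.** Runs of windows whose capped depth falls in a band
(low: 0.35–0.90; high: >1.15) are merged across interruptions of at most
2 windows and reported when they contain ≥10 in-band windows.  These
thresholds are calibration choices, not measurements: they recover
50–100 kb regions at ~0.7 depth while leaving isolated noisy windows
(a few thousand bases of repeat-driven pile-up) uncalled.

**Classification.** Depressed regions are clustered by depth level
(pairwise within tol = 0.06) and labelled by ordered rules: a cluster
within tol of (k−1)/k *with* its k partner regions and *no* independent
duplication evidence is `cnv_loss`; otherwise a shared level inside the
low band is `strain_private`; anything else is `ambiguous`.  A positive
duplicated-single-copy-gene count (BUSCO-style evidence that two related
genomes co-assembled) overrides the copy-number reading: a pair of
regions at 0.5 is genuinely ambiguous between a 2→1 loss and a 50% titer,
and the duplication evidence is what breaks the tie in favour of a second
strain.  Rationale strings record which clause fired, so calls are
auditable.

**Titer estimation.** f̂ is the mean raw normalized depth over member
windows of strain-private regions **rescaled by the mean over background
windows** (windows outside every called region).  The rescaling matters:
global-mean normalization leaves private windows at f/(1−(1−f)·ρ), where
ρ is the private fraction of the genome — 0.733 rather than 0.70 on the
standard 1 Mb fixture with 15% private sequence — because the depressed
intervals depress the mean they are divided by.  Measuring against "the
rest of the genome" recovers f without bias.  The confidence interval is
a seeded percentile bootstrap (default 1000 draws, 95%) resampling
private and background windows independently.  The estimate concerns the
strain *carrying* the regions; 1−f̂ is the co-infecting strain's share,
and regions private to the other strain are invisible on these
coordinates by construction.

## Locus assignment

The reference assembly derives from a singly infected (CI-only) host, so
every reference locus belongs to the CI strain; the discriminating
questions are which copies the MK strain adds and which reference copies
the MK strain lacks.  Rules, in order: a reference hit with ≥50% of its
span inside a strain-private region is `ci_strain` (partial overlaps
1–49% are `unresolved` — the threshold is a design choice, as no
convention exists for partial membership); a mixed-assembly hit identical
to a reference hit inherits that copy's assignment (`ci_strain` if the
reference copy is private, otherwise `shared`); a mixed-assembly hit with
no identical counterpart is `mk_strain`.  "Identical" means 100% identity
over the full span (tolerance configurable, default 0).  Collapsed-copy
prediction flags a mixed assembly showing fewer identical copies than the
reference — fragmented assemblies collapse identical repeats — and
predicts the reference count.  Percent identity is ungapped positional
identity over a stated 1-based inclusive base range, reported at 0.1
resolution; unequal spans are rejected rather than silently aligned.
The pseudogene check translates in a given frame and calls a stop
premature when its codon index precedes 90% of the ORF length (the
threshold operationalizes "pseudogenized"; a terminal stop never
triggers), reporting the next downstream ATG offset as a candidate
re-initiation site.

## Sweep mapping

**Statistics.** Per group, heterozygosity uses the complete-cases rule:
sites with any missing genotype in the group are dropped for H_O/H_E/F_IS
(monomorphic sites retained by default).  H_O is the mean heterozygote
fraction, H_E the mean of 2p(1−p), F_IS = 1 − H_O/H_E (undefined at
H_E = 0; −1 when every call is heterozygous).  SNP filtering retains
sites called in ≥95% of individuals with ≥3 minor-allele copies, and is
idempotent.  Contig contrasts report (value − mean of other contigs) /
|mean of other contigs| per group.

**Two-stage interval calling.**  `detect_sweep` finds maximal runs of
consecutive SNPs with focal-group MAF < 0.1, tolerating ≤2 violating SNPs
per run; interval bounds are the first and last qualifying SNP and the
reported length is the exclusive difference end − start (the convention
under which the printed bounds 3,321,074 and 4,637,826 give 1,316,752 bp;
the alternative end coordinate 4,677,392 that appears elsewhere for the
same region is surfaced via the optional `pad`/`padded_interval` fields
rather than reconciled).  `map_suppressor` wraps it in the two-stage
procedure the analysis actually needs: first flag contigs showing the
sweep signature — H_O reduced ≥15% in the unsuppressed group *and*
elevated ≥15% in the suppressed group relative to the other contigs —
then keep only low-MAF runs of ≥150 SNPs on flagged contigs.  The 15%
floor sits below the weakest contrast the method is meant to detect
(~23%), and the run floor reflects the scale a single-haplotype sweep
produces (hundreds of SNPs; the mapped region carries 212).  Both stages
are necessary: after two backcrosses the unsuppressed group's background
allele frequency is (1/2)^3 = 0.125, close enough to the 0.1 threshold
that chance contig-scale excursions in a 24-sample group produce low-MAF
runs of tens-to-hundreds of SNPs on their own; measured over seeded
panels, no single-stage run-length cutoff separates them from the true
sweep, while the gated pipeline recovers the planted suppressor in 19/20
panels with no background calls and is silenced by phenotype-label
permutation.

## Inheritance model

Per individual: sex, suppressor genotype (S dominant; ss/Ss/SS), and
cytotype ⊆ {CI, MK}, acquired strictly maternally (each strain
transmitted independently with probability τ_CI / τ_MK).  Phenotype
rules: (i) CI — father carries CI and mother does not → hatch h_ci,
else h_0; a CI-carrying mother is fully rescued regardless of the MK
strain, and MK-carrying females are fully compatible with CI males;
(ii) late MK — a male inheriting MK with no effective suppressor dies
before adulthood with probability (1−leak)·μ, so MK reduces egg-to-adult
viability, not hatch; (iii) suppression is dominant with penetrance 1 by
default (a penetrance dial exists for sensitivity analysis);
(iv) paternal transmission is zero, and a `male_ci_loss` probability
(default 0) lets CI fathers fail to induce, reflecting that CI strength
is independent of male titer.  No female fitness benefit of MK is
modelled (the observed associations were negative); a hook exists with
default 0 effect via the baseline parameters.

Defaults: τ_CI = 1.0, τ_MK = 71/73, h_ci = 0.0617, h_0 = 0.76,
v_0 = 0.7 (baseline egg-to-adult), μ = 1.0, leak = 0, sex ratio 0.5.
The deterministic calculator yields the identities the tests enforce:
egg-to-adult of an MK-mother compatible cross is
v_0·(1 − (1−leak)·μ/2) — exactly half the control at full penetrance —
and with τ_MK = 1, μ = 1, leak = 0 every surviving adult male descending
from an MK mother carries S.

**Brood sizes.** Females lay Poisson(18) eggs per day over a 4-day laying
window, so broods are Poisson(72); vials with fewer than 7 eggs are
re-drawn (unscoreable replicates are replaced).  The per-day rate matches
observed means of ~18–22 eggs; using a single day's eggs would put nearly
every brood under the ≥15-offspring classification minimum and make the
design unscoreable.

**Line classification.** Fewer than 15 offspring → excluded; no males →
MK; ≤70% female → MKS; 71–99% female → excluded (possibly leaky MK).

**Segregation panel.** Donor females (SS, carrying CI+MK) are crossed to
cured recurrent males (ss, uninfected); each generation, broods of
single females are classified and daughters pooled as the next mothers.
With S fixed in the donor, the idealized expectation for percent
female-only lines is 0 (F1 brood), 0 (backcross 1), 50 (backcross 2),
75 (backcross 3): the mothers of backcross-k broods are backcross-(k−1)
females, homozygous ss with probability 1 − (1/2)^(k−1).  Percentages
are reported over all tested lines, as segregation tables print them.
Under the default leaky transmission (τ_MK = 71/73) a female-only brood
of ~70 eggs expects ~0.7 surviving uninfected sons, so literal
female-only classification is run under full transmission (τ_MK = 1)
when the Mendelian expectation is the object of interest.

**Vial simulator.** Discrete generations; each female mates once with a
male drawn uniformly from the vial's males (five cured recurrent-line
males are supplied only when a vial has no males, mirroring how
female-only lines are maintained); the recorded sex ratio is the percent
of females among all adults emerging that generation, and the next
generation breeds from a random sample of `vial_size` (default 40) of
them.  MKS founders are SS and pre-mated to MKS males; MK founders are ss
and pre-mated to cured males.  Single mating per female per generation is
assumed.  Under defaults, vials seeded at 90% MK revert to ~52–56%
female by generation 5; all-MK vials decline slowly from ~97% female as
imperfect transmission (2/73 per generation) seeds uninfected
matrilines — a direct consequence of treating the 71/73 carriage figure
as a per-generation per-offspring rate, which likely overstates the
long-run loss (lines retain the strain over tens of generations, implying
near-perfect effective transmission).

**Field statistics.** The G-test is the likelihood-ratio statistic
2·ΣO·ln(O/E) on a k×2 table (df = k−1, chi-squared reference), computed
via `scipy.stats.chi2_contingency(lambda_="log-likelihood")` and
cross-checked in tests against a direct computation.  The sex-ratio test
is χ² = (n_f − n_m)²/(n_f + n_m) on 1 df.  qPCR relative density is
2^(mean Cp_host − mean Cp_target) over replicate runs, flagged when
either marker's replicate SD exceeds 2.5.

## Synthetic generators: what they emulate, and what they do not

Coverage is independent per-base Poisson (the Lander–Waterman
expectation) — depth is the sufficient statistic the deconvolution
consumes, so read placement, GC bias, mapping error and duplicate
artefacts are not modelled; passing the recovery tests says the
*inference* is correct given clean depth, not that alignment artefacts
cannot mimic depressed regions.  Strain-B-private sequence is modelled as
novel insertions anchored at backbone coordinates; it is invisible to the
reference-coordinate analysis, matching the method's stated blind spot.
Backcross genotypes assume founder lines fixed for alternate alleles
(donor) and reference alleles (recurrent): real isofemale lines segregate
residual variation and real SNP panels are ascertained against an outside
reference genome, both of which raise background minor allele frequencies
above the idealized 1/8 — the synthetic background is therefore *harder*
for the sweep caller than real data, which motivates the two-stage
pipeline.  Recombination is Poisson-count crossovers at uniform positions
(default 1 per contig per meiosis — a nominal placeholder; no
species-specific map is implied), with no interference.  Sequencing
error, indels and structural variation are out of scope throughout.
The suppressor position is included among the genotyped sites of its
contig so the truth-locus heterozygosity invariant is directly checkable.

## Problem sizes and numerics

Default test and acceptance workloads: 1 Mb mixture genomes at 50×
(≈2000 windows), backcross panels of 48 females × 1500 SNPs with 20
seeded replicates, and vial runs of 10 replicates × 5 generations ×
~40 founders — sizes at which every recovery property is measurable in
seconds while preserving the statistical structure (Poisson window noise
≪ band widths; binomial group-frequency noise at 48 alleles is the
regime the two-stage caller is designed for).  All stochastic operations
take explicit integer seeds (default 42) through
`numpy.random.default_rng`; bootstrap intervals are percentile-based;
ties and degenerate inputs (empty groups, monomorphic sites, zero-male
broods, extinct vials) raise explicit errors or flagged truncations
rather than propagating NaNs silently.
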