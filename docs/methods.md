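# Methods

This note documents the models and procedures implemented in
`expressome`, the assumptions behind them, the parameters that matter,
and the design choices made where the design was genuinely open. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The measurement model

Three layers of one stress experiment are analysed. Total RNA before
stress (reference) and at 7, 45 and 90 minutes after is hybridized
competitively to two-color arrays (stress in Cy3, reference in Cy5);
polysome-fraction RNA at 90 minutes gives the translatome on the same
platform. Proteins at 90 minutes are quantified against a common fully
heavy-labeled (¹³C₆-lysine) protein standard spiked 1:1 into both the
reference and the stressed sample, so each mix yields heavy/light
peptide ratios against the same denominator.

### Two-color arrays

Per probe, M = log2(Cy3/Cy5) and A = ½·log2(Cy3·Cy5). Dye chemistry
makes M depend smoothly on A; within-array normalization therefore
subtracts a LOESS fit of M on A.

*LOESS implementation.* `expressome.loess` implements a robust
**local-quadratic** LOESS (tricube weights, window = span·n nearest
neighbours, 2 bisquare robustness iterations, span 0.3 by default). The
quadratic degree is deliberate: the dye bias is curved on the scale of
a 0.3 span, and a local-linear smoother leaves systematic lack of fit
several times larger than the per-probe noise floor, while the
quadratic fit tracks a smooth closed-form bias to well below 0.02 log2
units (asserted in the acceptance suite). Robustness iterations protect
the fit from regulated genes, which are outliers in M. Two numerical
edge cases are defined explicitly: a numerically constant A degenerates
to median-centering, and fewer than 10 probes is an error.

Note that LOESS, like any locally weighted smoother, is not exactly
idempotent (the smoother matrix is not a projection): re-normalizing a
normalized array moves M by an amount on the order of the residual
approximation error. The test suite bounds this second-pass movement by
the same 0.02 tolerance used for bias removal rather than asserting
exact idempotence.

*QC floor.* Probes are kept when A meets the experiment-specific
background floor determined by control probes (defaults 10.27 / 10.61 /
10.45 / 10.44 for total 7/45/90 min and polysome 90 min; boundary
inclusive). Filtering happens after normalization, so low-intensity
probes still inform the dye-bias fit.

*Replicate combination.* Gene-level normalized ratios from biological
replicates are averaged; significance against zero uses one of two
error models:

- `pooled` (default): a common-error (moderated) test that pools the
  residual variance across all genes, with df = Σ(nᵢ−1). With only two
  biological replicates a per-gene t-test has one degree of freedom and
  essentially no power (|t| > 12.7 needed for p < 0.05); sharing the
  variance across thousands of probes is the standard remedy on this
  design and is what makes a two-replicate study usable.
- `per_gene`: the ordinary one-sample t-test, appropriate when four or
  more replicates are available; the calibration tests exercise it at
  n = 4.

Genes surviving QC in a single replicate keep their ratio but receive
no p-value and are never called regulated. Calls use log2 ≥ 0.8 (up) or
≤ −0.8 (down), both boundary-inclusive, with p < 0.05 strict.

### Heavy-standard SILAC

Peptide H/L ratios (rows with zero light intensity are dropped) are
aggregated per protein, sample and replicate as the **median on the
log2 scale** — the geometric mean of the two central values for even
counts — with a minimum of two ratio counts for quantification. The
stress-vs-reference change is the direct ratio
log2[(H/L)_ref] − log2[(H/L)_stress]; the standard cancels exactly, so
rescaling the standard globally leaves every direct ratio unchanged and
swapping the two mixes negates it (both asserted to machine precision).

Significance is a per-protein two-sided one-sample t-test over the
replicate direct ratios (default four replicates, modeling two
digestion protocols in biological duplicate), Benjamini–Hochberg
adjusted over all tested proteins at FDR 0.05. Zero-variance replicate
sets return p = NA and no call — a deliberate refusal of spurious
certainty, which is also why the "zero-noise" pipeline test keeps a
vanishing but nonzero replicate spread.

Label incorporation is estimated from a heavy-only run of the standard
as ΣH/(ΣH+ΣL) per protein; the global rate is the mean over proteins.

### Kinetics and clustering

Genes significantly induced (log2 ≥ 0.8, p < 0.05) at any of the three
time-points enter k-means clustering of their raw 3-point log2 profiles
(Euclidean distance, maximum 50 iterations, random member
initialization under an explicit seed, k = 3 with the largest cluster
subdivided into three). Raw rather than standardized profiles are used
so cluster centroids remain interpretable on the heat-map scale.
Incomplete profiles are excluded (Euclidean distance needs complete
vectors). k-means is delegated to scikit-learn with `n_init=1` and a
fixed `random_state`, which makes assignments reproducible.

Regulon profiles average the log2 ratios of member genes that reach
log2 ≥ 0.8 at one or more time-points; the immediate (RpoE) versus
delayed (RpoH2) induction contrast is asserted on the synthetic study.

### Cross-layer integration

Layer pairs are compared over genes quantified in both: Pearson r with
r² reported from the **unrounded** correlation (both rounded to two
decimals in outputs — consequently a printed r of 0.63 can accompany a
printed r² of 0.39, since 0.628² = 0.394). Per-gene concordance applies
to genes regulated (|log2| ≥ 0.8) in at least one layer of the pair:
unidirectional when the absolute log2 difference is < 0.4, biased at
≥ 0.4; unregulated genes remain unchanged. Two directional detectors
use the signed difference: translationally triggered genes (polysome
log2 ≥ 0.8, p < 0.05, and ≥ 0.4 above the transcriptome) and protein
declines without a matching RNA change (protein log2 ≤ −0.8, adjusted
p < 0.05, RNA − protein ≥ 0.4). The master table is an outer join over
all layers with explicit NA for missing quantifications; duplicate ids
within a layer are an error, never silently collapsed.

### Operon polarity

An operon is an ordered gene list in transcription direction (first
gene = 5′-most = first transcribed, independent of genome strand). The
polarity call on a layer combines a rank trend — Spearman ρ of value
against gene position, |ρ| ≥ 0.5 — with a magnitude gate: the
first-minus-last difference must reach ε. Two-gene operons always have
ρ = ±1, so the gate alone decides. ε defaults to 0.4 log2, the same
magnitude the concordance analysis treats as a meaningful between-layer
difference: with two averaged replicates at probe noise sd 0.15 the
end-difference noise is ~0.15 sd, and a much smaller gate would call a
large fraction of flat two-gene operons polar. Pre- versus post-stress
polarity is compared on log2 expression *levels* (reference-channel
versus stress-channel intensities), where the gene-specific baselines
cancel in the delta. Cross-layer comparison flags operons polar on the
translatome but flat on the transcriptome, the signature of
post-transcriptional polarity.

### Proteogenomics

The six-frame ORF database translates both strands in all three frames
and keeps every stop-to-stop stretch of ≥ 7 aa, with identifiers
`<replicon>:<frame>:<1-based aa start>` and reverse-frame coordinates
mapped back to the forward strand. Lys-C digestion cleaves after every
lysine (including K-P bonds, per Lys-C's specificity), enumerating
peptides with ≤ 2 missed cleavages and ≥ 6 aa. Peptide-to-database
matching requires Lys-C-consistent termini and is implemented as digest
lattice membership, which is equivalent and fast. Protein groups are
connected components of the bipartite sequence–peptide graph; groups
with no annotated member and ≥ 2 unique peptides become novel-ORF
calls, validated against the strand-matched coverage track: supported
iff mean coverage ≥ 10 reads/nt and ≥ 80% of positions covered. No
start-codon refinement is attempted — calls are stop-to-stop, like the
database they come from.

## The synthetic study

The generator emulates the study design rather than any real data set.
A genome is built bottom-up from proteins: each gene's amino-acid
sequence is composed of blocks of 6–11 non-lysine residues terminated
by K, guaranteeing ≥ 2 Lys-C peptides of ≥ 6 aa (so every protein is
quantifiable), then back-translated codon by codon and placed with
intergenic spacers; operons are runs of adjacent co-stranded genes.
Nineteen unannotated ORFs are planted — intergenic ones flanked by
in-frame stops, plus one embedded inside an annotated gene on the
opposite strand — and thirteen of them are transcribed in the coverage
track, the others receive background only.

Classes are **assigned, not sampled**, at exact configured counts:
51 immediate-induction (RpoE) genes (log2 1.5 at all time-points),
90 delayed (RpoH2: 0.3 at 7 min, 1.5 later), 30 pulse (1.5 at 7 min
only), 60 repressed (−1.5 everywhere; a class added so down-calls are
measurable), 45 translational-only (polysome 1.5, transcriptome 0) and
45 protein-decline (protein −1.5, RNA 0) genes. Polar operons receive
position-dependent offsets (linear from +0.4 to −0.4 along gene order,
0.8 log2 end-to-end) on every layer; translatome-only polar
operons apply ±0.5 offsets to the polysome layer alone. Truth
concordance labels are derived by applying the classification rule to
the noise-free planted effects, so the zero-noise limit is exactly
self-consistent.

Array intensities are reconstructed from (A, M): Cy3 = 2^(A+M/2),
Cy5 = 2^(A−M/2) with M = effect + N(0, sd) + d(A), where the dye bias
d(A) = amplitude·sin(A/2) is added on the M scale leaving A untouched —
exactly the artifact LOESS must remove, with a closed-form oracle. The
noise sd (default 0.15) is defined on the log2-ratio (M) scale. An
exact fraction of probes (12%) receives baseline A below the background
floor.

SILAC evidence applies, per peptide and sample, a correlated noise pair:
both intensities carry the configured CV (default 20%), but most of it
is a shared feature-level factor and only half the CV is
pair-independent and reaches the H/L ratio — reflecting that a SILAC
pair is one co-eluting isotope doublet whose common ionization and
sampling noise cancels in the ratio. A per-protein, per-replicate
biological factor (sd 0.1 log2) on the light sample gives replicates
genuine variance. The heavy-only run splits each peptide's signal
96:4 between heavy and light (incorporation 0.96). Coverage is Poisson
per nucleotide: expressed novel ORFs at the configured depth (50),
annotated genes scaled by a lognormal expression factor, background
rate 0.2; a depth of zero means no sequencing and yields an empty
track.

All randomness flows from one seed through per-stage independent
streams; identical configs give byte-identical output bundles
(checksummed in the run manifest).

### What the simulation does and does not show

The generator reproduces the *structure* of the study — layered
effects, dye bias, QC attrition, a shared heavy standard, operon
staircases, hidden ORFs — with Gaussian/lognormal/Poisson noise and one
probe per gene. It does not model probe cross-hybridization, raw
spectra or peak detection, peptide misidentification, read mapping
artifacts, or correlated biological variation between genes. Passing
recovery tests therefore demonstrates that the estimators invert the
stated measurement model at realistic noise, not that they are robust
to every artifact of real platforms.

Recovery metrics condition on quantifiability: sensitivity and
precision are computed among genes quantified in the relevant layer,
since a probe below the A floor cannot be called anything. For the same
reason the always-up core set equals its planted size (51) only when no
planted gene falls below a floor; under the default 12% low-intensity
fraction the recovered core set is correspondingly smaller.

## Problem sizes and defaults

The default study is 1500 genes in 150 operons (sizes 2–5, of which
12 are 5′-polar, 6 are 3′-polar and 5 translatome-only polar), two
array replicates per condition, four SILAC replicates plus a heavy-only
run (~67k evidence rows), and a ~0.5 Mb genome whose six-frame database
holds tens of thousands of ORFs. The full pipeline — simulation through
evaluation — runs in well under a minute on one CPU; the test suite
uses a 300-gene version of the same scenario for most fixtures and the
full default study for the end-to-end acceptance checks.

Optional figure output (heat maps, MA and scatter plots) named in the
interface sketches is not implemented; all results are emitted as TSV
tables that plot directly with standard tools.

## Known limitations

- The per-gene t-test option is honest but underpowered below four
  replicates; the pooled default assumes roughly exchangeable residual
  variance across genes.
- Protein grouping treats shared peptides by connectivity only; no
  razor-peptide apportioning is attempted, so a peptide shared between
  an annotated protein and an overlapping six-frame ORF always
  suppresses the novel call (by design).
- Polarity is a descriptive trend call, not a mechanistic model;
  non-monotone operons dominated by their first gene are called "none"
  by the rank gate.
- The pipeline takes identification as given: peptide evidence tables
  are assumed identification-true, and coverage tracks are assumed
  correctly mapped and strand-assigned.
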