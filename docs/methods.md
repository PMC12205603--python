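# Methods

This note documents the models and procedures implemented in `astrotau`,
the parameters that matter, the synthetic-data generators behind the test
suite, and the design choices made where more than one reasonable
convention exists.

## Tau isoform coordinates and peptide mapping

The six CNS tau splice isoforms are block-deletion variants of the longest
one, 2N4R (441 residues): exon 2 encodes residues 45–73, exon 3 residues
74–102, exon 10 (the second microtubule-binding repeat) residues 275–305.
`sites.build_coordinate_map` recovers this structure with a greedy
maximal-run matcher and verifies every block by substring equality, so a
user-supplied FASTA is re-validated rather than trusted. Site labels use
2N4R numbering (S202, T181, S262, …) because that is the convention in the
tau literature; the 758-residue full-length P10636 numbering is deliberately
not used. At the exon-10 junction the alignment is ambiguous over the
repeated `VQI` motif and the matcher extends the upstream block through it;
the two alignments are equivalent and no S/T/Y residue is affected.

Peptides are located by exact substring search over all isoforms. A peptide
whose phospho offset maps to more than one canonical position is ambiguous;
such evidence is excluded by default (`include_ambiguous=False`) — a
conservative attribution choice, since crediting every matching site would
double-count intensity.

In-silico digestion is fully tryptic: cleave after K or R, never before P,
zero missed cleavages (so the peptides tile the protein exactly). A
`missed_cleavages` extension emits merged runs of adjacent peptides but is
off by default and unused by the generators.

## Site quantification

For each case and canonical site, the modified abundance is the sum of
precursor intensities of all phosphopeptide rows covering the site (a
doubly phosphorylated peptide contributes its full intensity to both of its
sites); the unmodified abundance is the summed intensity of rows with the
identical peptide sequence and no modification. The adjusted ratio is

    modified / (unmodified + pseudo-count).

Choices that were genuinely open:

- **Pseudo-count scope.** Computed per case as 1/10 of that case's smallest
  non-zero combined unmodified peptide abundance; if a case has no
  unmodified evidence at all, the global minimum across cases is used and
  logged. Per-case scope matches the per-case normalization that follows.
- **Pseudo-count application.** Added to every denominator unconditionally,
  as the formula reads; a `pseudo_mode="when_missing"` switch restricts it
  to sites lacking an unmodified counterpart, for sensitivity analysis.
- **Normalization.** Min–max over the case's detected sites (undetected
  cells stay missing). Divide-by-max was the alternative; min–max is chosen
  so detected values span the full [0, 1] color scale, with undetected
  kept distinct as missing. A degenerate range (all detected ratios equal,
  or one detected site) maps to 1: detection without spread is
  top-of-scale presence.
- **Detection.** Any modified evidence counts as detected; a configurable
  intensity floor (`min_modified_abundance`, default 0) can impose a
  stricter rule. Binarization sets detected cells to 1 and missing to 0.

The standard curve for absolute tau quantitation is an ordinary
least-squares line y = m·x + c of band intensity on known amount, inverted
as x = (y − c)/m.

## Case clustering and differential protein abundance

Hierarchical clustering uses Euclidean distance with Ward linkage (binary
phosphosite profiles; standardized protein abundances) or average linkage
(the merged fold-change heatmap). Linkage is computed by scipy's
Lance–Williams implementation; the test suite checks it merge-for-merge
against an independent O(n³) agglomeration oracle with
lowest-cluster-index tie-breaking. Missing values are rejected rather than
silently imputed — the fold-change heatmap path imputes zero explicitly
(no change relative to untreated) before clustering. k-cluster partitions
undo the last k−1 merges.

Per-case protein rankings take the top n (default 20) by abundance, ties
broken by identifier, and the per-case selections are unioned.
Standardization is per protein: subtract the mean, divide by the
population standard deviation (ddof = 0, matching the common
machine-learning scaler convention). Group comparison is a two-sided
Student t-test on per-group mean log2 abundance (equal variances pooled);
"unpaired t test" is ambiguous between Student and Welch, Student is the
default and Welch available via `equal_var=False`. Proteins with fewer
than two values in either group are skipped and logged. Zero raw
intensities are treated as missing on the log2 scale, not as log2(0).

## DEG concordance

Significance is adjusted p strictly below alpha (default 0.05); rows with
missing adjusted p are excluded and logged, and a raw-p mode
(`p_column="pvalue"`) exists because published summaries sometimes quote
raw p. Direction is the sign of log2FC; an exactly zero fold change stays
in the set but carries no direction. The Jaccard index is computed on the
combined significant sets by default, with a direction-split variant
(mean of up-set and down-set Jaccard) behind a flag; two empty sets give 0
with a warning. Group similarity is the mean over unordered within-group
pairs. The fold-change correlation of shared genes is Pearson's r and
requires at least 3 shared genes; fewer are reported as missing, not 0.
The top-DEG table takes the n smallest p-values among significant genes
with |log2FC| above the floor (default 1.5), ties broken by gene id.

## Co-expression modules

The network is unsigned: a_ij = |cor(i, j)|^β with zero diagonal (signed
available via flag; unsigned is the long-standing default). β is the
smallest integer in 1..20 whose connectivity distribution fits scale-free
topology at R² ≥ 0.8, where the fit regresses log10 degree density on
log10 degree over at least five equal-count bins (density, not raw count,
because quantile bins have near-equal occupancy by construction); if no
power reaches the target the best-fitting one is used. Topological overlap
follows the standard formula, and genes are clustered by average linkage
on 1 − TOM.

**Deliberate simplification:** module detection uses a static cut at a high
quantile (default 0.99) of the merge heights plus a minimum module size
(default 10), not the dynamic hybrid tree cut of the reference R package.
The static cut recovers well-separated planted modules exactly but will
not resolve nested or marginally separated modules the way the dynamic
algorithm can.

The module eigengene is the first principal component of the
gene-standardized module submatrix, unit norm across samples, with the
PCA sign fixed by non-negative correlation with the module's mean
standardized profile. Module selection scores each module by the mean over
conditions of the population standard deviation of its eigengene across
that condition's technical replicates; modules at or below `sd_threshold`
(default 0.5 — permissive, since a unit-norm eigengene's values shrink
with sample count; the threshold is a required user decision) are
selected. Hub genes need |cor(gene, eigengene)| ≥ 0.8 and intramodular
connectivity in the top decile, ranked by kME.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of (config, seed) via
`numpy.random.default_rng`; no global state. Defaults mirror the modeled
study design: 9 cases in 3 groups (3 control, 3 seeding-competent disease,
3 non-seeding disease), ~20 quantified phosphosites, 9 treatment
conditions with 3 technical replicates, within-group DEG Jaccard targets
0.33 (control-like) and 0.13 (disease-like), shared-gene fold-change
correlation 0.99.

- **PSM tables.** Each tryptic peptide of each case draws a log-normal
  total abundance (ln-mean ln(1e6), ln-sd 1.0 — intensities spanning about
  two orders of magnitude, as ionization efficiency does). A site with
  occupancy θ puts fraction θ of the peptide total into a singly
  phosphorylated row and the joint non-occupancy into the unmodified row,
  each with independent unit-mean multiplicative log-normal noise
  (ln-sd 0.15, i.e. ~15% CV, a typical technical variability for precursor
  intensities). Only peptides of ≥6 residues are emitted (shorter ones are
  rarely observed in practice). Occupancy truths plant at most one site
  per peptide, because the modified/unmodified ratio of a multiply
  occupied peptide confounds each site's occupancy with its neighbours' —
  on real data co-occupied peptides do occur, and there the adjusted ratio
  is only an approximate occupancy readout. Spectrum-level realism (m/z,
  retention time, identification FDR) is out of scope.
- **Binary matrices.** Group prototypes are redrawn until all pairwise
  Hamming distances reach the configured separation (default 10 of 25
  sites); cases flip each prototype bit independently at `flip_rate`
  (default 0.05). A warning fires when the separation is under twice the
  expected flips.
- **DEG tables.** Within a group, significant sets share a core sized so
  the pairwise Jaccard matches the target (specific genes are disjoint
  across conditions), which makes the realized Jaccard deterministic up to
  integer rounding. Core log2 fold changes follow a one-factor bivariate
  model with the target pairwise correlation (exact Cholesky construction
  for negative targets with two conditions). Non-significant genes get
  adjusted p uniform on (0.05, 1]. Set sizes and the gene-universe size
  are free parameters (defaults 100 and 2000 library-wide; the round-trip
  checks use a 500-gene universe), since the original summaries do not
  determine them.
- **Expression matrices.** Module genes load on a per-condition latent
  factor with loading equal to the configured latent correlation, so two
  module genes correlate at its square (0.8 → 0.64); replicates share the
  factor up to replicate noise (sd 0.1); leftover genes are independent.
  Latent factors are made exactly mean-zero and mutually uncorrelated
  across conditions (QR against the constant vector): with few conditions,
  i.i.d. factors can correlate strongly by chance, which would contradict
  the planted claim that the modules are distinct. Real co-expression
  modules are of course not exactly orthogonal, share genes, and sit on
  correlated library-size and batch structure that the generator does not
  model — passing recovery tests shows the pipeline's statistics are
  implemented correctly, not that module detection is robust on real data.
- **Standard curve.** Points y = m·x + c + Normal(0, sd) at distinct
  integer amounts.

## Problem sizes and numerical conventions

The validation suite and `scripts/acceptance.py` use: 100 seeds for
occupancy recovery (9 cases × 20 sites) and for case-cluster recovery
(9 × 25, 5% flips); 200 random matrices of ≤8 rows for the linkage oracle;
1000 random set pairs for Jaccard; 500 replicates per Jaccard/fold-change
target; 100 seeds (50 in the script) of the 150-gene, 3-module
co-expression recovery. These sizes give Monte-Carlo error comfortably
inside the asserted tolerances while keeping the whole suite around twenty
seconds.

Numerical conventions: population (ddof = 0) standard deviations
throughout; ranking ties broken lexicographically by identifier;
agglomeration ties broken by lowest cluster index; eigengene sign fixed by
the module mean profile; Pearson r undefined below 3 pairs; strictly
`padj < alpha`. Degenerate inputs (constant rows, empty sets, all-zero
unmodified evidence, rank-1 expression) either take a documented fallback
or raise with the offending identifier in the message.

## Known limitations

- The static quantile tree cut is a stand-in for dynamic hybrid tree
  cutting; module counts on real data will differ from the reference
  implementation.
- Site attribution ignores phosphosite localization probability; a peptide
  is credited to the site its search-engine offsets name.
- The adjusted ratio is not an absolute stoichiometry: it is monotone in
  occupancy for singly occupied peptides but compresses when the
  pseudo-count rivals the unmodified abundance.
- Protein-level t-tests are reported unadjusted for multiple testing, as
  in the workflow this package reproduces.
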