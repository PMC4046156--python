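# Methods

This note documents the models, statistics and numerical choices behind
`nucmir`, in the order the pipeline runs them. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## CT scale and relative expression

All quantification starts from RT-qPCR cycle-threshold (CT) values. Under
100% amplification efficiency one cycle equals one doubling, so the relative
expression of a test condition against a reference is

    RQ = E^(CT_ref − CT_test),  E = 2 by default.

The efficiency `E` is configurable but fixed at 2.0 throughout the defaults:
the assays this package targets (TaqMan low-density arrays) provide no
standard-curve information from which to estimate per-assay efficiencies.

"Undetermined" wells — reactions that never crossed threshold — are kept as a
sentinel distinct from CT = 40 and are never imputed: imputing the cycle
ceiling would fabricate abundance (and hence enrichment) signal. They are
excluded from replicate means, and any ratio involving one is undefined
("not detectable") rather than zero or infinite. Valid CTs must lie in
[0, 40], the standard 40-cycle run; both bounds are configurable.

Replicates are collapsed by the arithmetic mean of CT values, i.e. the
geometric mean of linear expression — the conventional qPCR treatment. The
number of wells contributing to each mean is retained.

## miRNA differential expression

An assay is *detectable* when its CT is strictly below 30 in at least one
cell type; quantification above CT 30 is unreliable and such assays are never
called differentially expressed. For every detectable assay and ordered pair
of stages, fold = 2^(CT_ref − CT_test); a call passes at fold ≥ 2 or ≤ 0.5
(inclusive). Fold values satisfy fold(A vs B) · fold(B vs A) = 1 by
construction.

Significance of fold changes across replicated ΔCT panels uses the Wilcoxon
signed-rank test. Zero differences are dropped (Wilcoxon's original
treatment) and ties take mid-ranks. For n ≤ 25 the exact null distribution of
W⁺ is built by convolution over the (doubled) ranks — equivalent to
enumerating all 2ⁿ sign assignments — and the two-sided p is
2·min{P(W⁺ ≤ w), P(W⁺ ≥ w)} capped at 1. Above n = 25 a normal approximation
with continuity and tie corrections is used. The exact path is hand-rolled
because library implementations do not combine exact enumeration with
mid-rank ties and dropped zeros; `scipy.stats.wilcoxon` serves as an
independent cross-check on tie-free inputs in the tests.

Highly expressed assays (CT < 25 in ≥ 1 cell type, strict) that pass
differential expression in at least one stage comparison are clustered
hierarchically. Profiles are mean-centred negative CTs (so correlations
reflect expression trajectories); the default distance is Pearson correlation
distance (1 − r) with average linkage, with euclidean/complete as alternates.
The "at least one comparison" selection mirrors the differential-expression
summary; a stricter minimum is exposed as a parameter. Rows with zero
variance receive an infinitesimal deterministic perturbation so the
correlation distance is defined.

Cross-species concordance of fold changes is a Spearman rank correlation over
the entities common to the two panels after name normalisation (species
prefixes such as `mmu-`/`hsa-` stripped, case-insensitive). Because figure
conventions vary, both Spearman ρ and the R² of the fold–fold least-squares
fit are reported, along with up/down direction agreement counts restricted to
entities passing the fold filter in the first panel.

## Moderated t for the mRNA arm

The microarray arm uses the empirical-Bayes moderated t-statistic. Per gene,
with groups of sizes n₁, n₂ and pooled variance s²_g on d_g = n₁ + n₂ − 2
degrees of freedom, the prior (d₀, s₀²) is estimated by moment matching on
log variances: with e_g = log s²_g − ψ(d_g/2) + log(d_g/2),

    ψ′(d₀/2) = var(e) − ψ′(d_g/2),
    s₀² = exp( mean(e) + ψ(d₀/2) − log(d₀/2) ),

the trigamma inversion solved by Newton iteration. The posterior variance

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g)

always lies between s₀² and s²_g; the moderated t is the two-sample t with
s̃_g in place of s_g and is referred to a t distribution on d₀ + d_g degrees
of freedom. When var(e) shows no excess over ψ′(d_g/2), d₀ = ∞ and every gene
uses the common variance; `prior_df=0` disables shrinkage and recovers the
ordinary t exactly. Genes with zero sample variance are excluded from prior
fitting; if all variances are zero the prior is degenerate and an error is
raised. A gene is significant at |fold| ≥ 2 and moderated p ≤ 0.05. No
multiple-testing correction is applied by default, matching the raw
thresholds this analysis style reports; Benjamini–Hochberg can be applied
downstream. Tests verify the implementation against an independent
step-by-step recomputation and against the canonical R implementation
(limma) on a toy matrix.

## Seed-match target inference

The seed is miRNA nucleotides 2–8 (5′ end). Site types on a 3′UTR follow the
TargetScan conventions: 8mer (Watson–Crick match to the reverse complement of
positions 2–8 followed by an A), 7mer-m8 (match to positions 2–8, no A),
7mer-A1 (match to positions 2–7 followed by an A). The A opposite position 1
must be a genomic A regardless of the miRNA's first nucleotide. Each
occurrence of the position 2–7 core defines a locus and is reported at most
once with the strongest applicable type (8mer > 7mer-m8 > 7mer-A1).
Coordinates are 0-based half-open in machine outputs. DNA input is accepted
(T→U); ambiguity codes either raise or, under `on_invalid="skip"`, are masked
so they can never match.

Candidate miRNA→mRNA pairs require: the miRNA passes its fold filter, the
gene passes fold ≥ 2 and moderated p ≤ 0.05 on the same stage comparison, the
directions are opposite, and the UTR carries ≥ 1 seed match. Stage-specific
pairing additionally keeps only pairs whose miRNA expression peaks, and whose
gene expression bottoms out, in the same stage; exact ties at either extremum
exclude the pair (conservative). Conservation-based filtering is *not*
implemented — a user-supplied whitelist hook stands in — and "known
validated" annotation is a user-supplied lookup, not computed.

## Nuclear/cytoplasmic fractionation

Fractions are compared on a cell-equivalent basis (equal input volumes from
one lysate split), so nuclear and cytoplasmic CTs compare directly without
housekeeping normalisation. The N:C ratio of an assay is 2^(ct_cyto − ct_nuc).

Marker QC requires every nuclear marker (e.g. a snoRNA) enriched ≥ 4-fold in
the nuclear pool and every cytoplasmic marker (e.g. Y1 RNA) enriched ≥ 2-fold
in the cytoplasm; these floors sit below the conventionally observed 8–56×
and 4–9× ranges so that passable real preparations pass.

Under pure carry-over contamination at fraction α, a miRNA with no true
nuclear pool has ct_nuc = ct_cyto + log2(1/α); regressing nuclear on
cytoplasmic CT over detectable non-marker assays therefore gives slope ≈ 1
and an intercept whose antilog, 2^(−intercept), estimates α. The fit is
ordinary least squares and requires ≥ 10 detectable points. Planted
nuclear-enriched assays act as high-leverage outliers on this fit: in
simulations with 6 enriched among 200, per-run intercepts scatter roughly
±1 cycle around log2(1/α) while the across-run mean stays within 0.2 cycles.

Enrichment calling proceeds per assay per cell type: assays whose nuclear CT
is ≥ 30 in every cell type are not detectable; a detectable assay with N:C
ratio > 0.1 is a *candidate*; a candidate is *nuclear-enriched* when a
one-sided Welch t-test of its per-replicate log2 ratios against the pooled
per-replicate log2 ratios of cytoplasmic control miRNAs gives p < 0.05.
Ratios above 1 (more nuclear than cytoplasmic) are flagged. Ranking uses
replicate-collapsed ratios; testing uses per-replicate ratios. The default
control set is the 10 detectable non-marker assays with the lowest mean N:C
ratio across cell types (user-overridable); Welch (unequal variance),
one-sided "greater", was chosen because the candidate and the pooled controls
have very different replicate counts.

**Known limitation.** With a per-test α = 0.05 and several hundred null
(assay, cell type) tests, some null assays will always be called enriched:
the procedure controls the per-test error rate, not the family-wise rate. In
a simulated world where every null assay sits exactly at the 0.1 ratio
threshold (contamination fraction 0.1), half the nulls pass the candidate
gate and the t-test rejects at roughly its nominal level — the test suite
documents this as a red "zero false positives" acceptance check. Real
preparations whose null ratios sit well below 0.1 are gated far more
aggressively by the ratio threshold. Users wanting family-wise control should
tighten `alpha` or apply multiplicity correction to the reported p-values.

## Duplex MFE screening of pri-miRNA transcripts

Binding of a nuclear miRNA to a primary transcript is scored with a
deliberately simplified intermolecular hybridisation model: antiparallel
base pairs only (Watson–Crick plus G:U wobble, toggleable), nearest-neighbour
stacking energies, and affine penalties for bulges (3.2 + 0.6·len kcal/mol,
max 3 nt) and internal loops (1.7 + 0.65·(l₁+l₂), max 3 nt per side). The
Watson–Crick stack table uses published nearest-neighbour magnitudes
(−0.93 … −3.42 kcal/mol) and is symmetric under reading the duplex from the
other strand; wobble-containing stacks are simplified to −1.3 (one G:U) and
−0.5 (two). A lone pair scores 0; no intramolecular structure is considered.
A dynamic program over (query, target) positions with bounded-gap
predecessors returns the optimal duplex energy and pairing trace; sequences
admitting no pair score 0. The inner loop is numba-compiled — shuffle
calibration evaluates millions of DP cells.

Because the energy model is an explicit stand-in for full hybridisation
programs, absolute MFE values differ from theirs; the conventional
−30 kcal/mol candidate cut is therefore a calibratable parameter, not a
constant. Transcripts are scanned in 60-nt windows with 10-nt steps (a final
flush window is always evaluated); the best hit per transcript is reported,
ties resolving to the earliest window.

Significance is calibrated per (miRNA, transcript) by dinucleotide-preserving
shuffles of the transcript (Altschul–Erickson random Eulerian walk on the
dinucleotide multigraph, preserving all dinucleotide counts and the terminal
bases exactly). The best MFE is recomputed for each of ≥ 50 (default 200)
shuffles; a Gumbel extreme-value distribution is moment-matched to the
shuffled minima (β = sd·√6/π, μ = mean − γ·β on −MFE) and
p = P(null MFE ≤ observed) reported, together with the empirical rank p-value
(1 + #{null ≤ observed}) / (n + 1), whose floor at n shuffles is 1/(n+1).
Candidate filtering keeps hits with MFE strictly below the cut and empirical
p < 0.05, then flags anti-correlation when the nuclear miRNA's expression
change between the compared stages is opposite to that of the mature miRNA
processed from the targeted transcript.

## Synthetic data: what it emulates, and what a green test establishes

The generator emits every input the pipeline consumes, with planted truth:

* **CT matrices.** Baseline whole-cell CTs uniform on [20, 29] (the range
  typically observed for reliably detected miRNAs); Gaussian CT noise,
  default σ = 0.25 cycles (multiplicative lognormal on abundance, matching
  qPCR error); values beyond the detection limit (default CT 35) censored to
  "Undetermined". Planted differentially expressed miRNAs are shifted by
  log2(4) cycles in the granulocyte stage, alternating up/down — a 4-fold
  effect, comfortably inside the "2-fold or more" regime yet realistic for
  stage-specific miRNAs. Nuclear CTs follow the contamination mixing model
  (α = 0.1 by default); planted nuclear-enriched assays get true N:C = 2.
  Markers are planted at 16× (nuclear) and 6× (cytoplasmic), inside the
  conventionally reported 8–56× and 4–9× purity ranges.
* **Transcriptome.** Gene log2 expression uniform on [6, 12] with Gaussian
  replicate noise (σ = 0.25); planted target genes move 1.5 log2 units
  opposite to their miRNA between promyelocytes and granulocytes — the
  smallest effect at which a 3 vs 3 moderated t detects nearly every gene.
  UTRs are uniform random sequence, 200–800 nt, each true pair receiving one
  seed site of a uniformly drawn type at a recorded position. Accidental seed
  matches of *any* panel miRNA elsewhere are removed by single point
  mutations (iterated until clean) and the removal count recorded: without
  scrubbing, ~3–6% accidental 7-mer rates per UTR would contaminate the
  planted truth and make precision unmeasurable.
* **Pri-miRNA transcripts.** Uniform random, 0.5–2 kb, named `pri-<mature>`;
  target transcripts carry an exact (or k-mismatch) reverse complement of a
  nuclear miRNA at a recorded position.

All randomness derives from the single config seed through independent named
streams, so every emitted file is reproducible from the config alone.

What the generator does **not** emulate: probe cross-hybridisation,
per-assay amplification-efficiency variation, batch effects, compositional
UTR structure (GC skew, repeats), expression correlation between genes, or
partial fractionation of genuinely shuttling RNAs. A green end-to-end test
therefore establishes that the algorithms recover a *clean* planted signal at
realistic noise levels — not that the thresholds are optimal for any
particular real dataset.

## Numerical and design choices

* All logarithms are base 2 unless they are part of a named statistical
  formula (the variance-prior moments use natural logs).
* Trigamma inversion: Newton iteration from y₀ = 0.5 + 1/x with asymptotic
  shortcuts at extreme arguments; tolerance 1e−10.
* Cluster tie-breaks and window tie-breaks are deterministic (first/earliest
  wins), and the pipeline summary excludes filesystem paths and wall times so
  identical configurations and seeds produce byte-identical summaries.
* Degenerate inputs: empty UTRs scan to an empty list; one-replicate groups
  collapse to themselves; all-sentinel groups stay undetermined; clustering
  with fewer than two selected assays returns an empty result with a warning;
  the signed-rank test on all-zero differences returns p = 1 with a warning.
* The CLI (`nucmir simulate|run|de|targets|fractions|priscan|report`) is a
  thin layer over the library; every threshold it exposes defaults to the
  conventional values above and is recorded in the run summary.
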