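# Methods

This note documents the models implemented in `mutaccum`, the defaults
and the reasoning behind the open design choices, and what the synthetic
cohort generator does and does not emulate.

## Survival model

Seed survival after acute irradiation follows the single-hit multitarget
model, S(D) = 1 − (1 − e^(−D/D₀))^m, with D the dose in Gy, D₀ the dose
reducing survival to 1/e on the exponential tail, and m the extrapolation
number (m ≥ 1; m = 1 is the single-target exponential).  The shoulder
dose D_q = D₀·ln m locates the bend of the curve; treatment doses for
different radiation qualities are placed at matched fractions of D_q
(e.g. 50% and 75%) to compare mutagenic effects at the same effective
survival dose.

Fitting is plain least squares on survival fractions via
`scipy.optimize.least_squares`, bounded (D₀ > 0, m ∈ [1, 1000)), with
default initial values (max dose / 3, 5).  The source data are replicate
counts, so points can be given as counts (which take precedence and set
survival = survived/total) or as fractions; an optional inverse-variance
weighting flag uses per-point standard errors, but unweighted least
squares is the default since no weighting scheme is prescribed for this
kind of fit.  Replicate-level and mean survival values are both accepted;
fitting the means is the default usage.  Degenerate inputs (all survivals
identical, or fewer than three distinct doses) raise rather than return a
silently unidentifiable fit.  D_q is always derived exactly from the
fitted (D₀, m), never refit.

## Mendelian transmission under selfing

An induced mutation starts heterozygous.  Each selfing resolves it
1/4 homozygous : 1/2 heterozygous : 1/4 lost, independently per mutation,
and fixation/loss is absorbing, so after k selfings
P_het = 2⁻ᵏ and P_homo = P_lost = (1 − 2⁻ᵏ)/2.

For an accumulation design with equal expected induction in each of G
generations and scoring one generation later (generation G+1), a mutation
induced in generation g has had k = G+1−g selfings.  Hence:

* accumulation factor = Σ_{k=1..G} P_homo(k) / P_homo(1); for G = 5 this
  is (129/64)/(1/4) = 8.0625, i.e. ~8.1× the homozygous count of a
  single-induction M2 experiment;
* advancement correction = 1 − G·P_homo(1)/Σ_{k=1..G} P_homo(k) ≈ 0.380
  for G = 5: the share of the observed count attributable to generation
  advancement rather than mutagenesis.

The Monte-Carlo cross-check (`simulate_lineages`) models single-seed
descent — one plant propagates each lineage per generation, matching a
design where a single M6 plant per batch is sequenced — with Poisson
inductions per generation (the design fixes only the mean).  There is no
selection against homozygous deleterious mutations: observed fertility
loss in real populations would deplete some homozygous classes, so the
analytic factor is an upper bound in that respect.  The M2 homo/het
expectation P_homo(1)/P_het(1) = 0.5 is the standard check that observed
M2 zygosity ratios are Mendelian.

## Post-calling pipeline

Filter order: load → background exclusion → AF filter → scanner filters
→ zygosity → complex merge → classify.  Each step returns kept and
rejected records so the audit can prove conservation (every input call is
either an event member or rejected with a reason).

Decisions worth making explicit:

* **Background exclusion** removes small-variant sites called in ≥ 3
  independent samples (`background_share_min = 3`, configurable).  The
  literal reading "more than two samples" is kept because sites shared by
  exactly two samples are still eliminated later by the other-sample
  AF < 5% rule, preserving the two-rule structure.
* **AF boundaries** are verbatim: AF exactly 0.25 is excluded ("25% or
  less"), AF exactly 0.80 is homozygous ("≥ 80%").  The AF rules apply to
  any record carrying an AF (derived from FORMAT/AD when present, else
  FORMAT/AF); symbolic SV records without read support pass the AF filter
  and are controlled by the scanner uniqueness rule instead.
* **Scanner filters**: indel-scanner calls ≤ 10 bp are dropped (that size
  range belongs to the small-variant caller), and indel-/sv-scanner calls
  present in more than one sample are dropped.
* **Complex merging** chains small-variant calls transitively: consecutive
  calls with < 10 intervening reference bases (gap = next.start −
  prev.end − 1) join one chain; a chain of ≥ 2 members with uniform
  zygosity becomes one Complex event.  Two members suffice — that is the
  only reading under which an SBS+indel pair can merge — and mixed-zygosity
  chains are left unmerged and logged.  Both the gap and the member
  minimum are configurable.
* **Classification**: SV is assigned by caller origin or SV type first;
  linear indels of ≥ 100 bp (`sv_min_len`) also count as SV.  The
  threshold sits at 100 bp, not 50, because deletions in the 51–99 bp
  range are still tabulated as deletions in the size distribution.
* **Coordinates** are 1-based inclusive; deletion length is
  len(ref) − len(alt) for left-anchored records; multi-allelic records are
  split before filtering, each alt an independent candidate.
* A cohort of one sample passes the other-sample AF check vacuously.

## Statistics

* Mutation frequency = events / reference length, with the reference
  length computed from the supplied FASTA (no hard-coded genome constant);
  accumulation-line MFs are divided by the number of irradiated
  generations for per-generation rates.  Complex events count once;
  their member SBSs do not enter the substitution spectrum.
* The substitution spectrum folds complementary substitutions into six
  classes (e.g. C→T and G→A are both G:C>A:T).  Ti/Tv = transitions
  (G:C>A:T + A:T>G:C) over the four transversion classes; zero
  denominators are flagged (inf/nan), not raised.
* Ti/Tv comparisons use Pearson's chi-squared without continuity
  correction on the 2×2 [ti, tv] × [group] table, df = 1, no
  multiple-testing correction (per-treatment comparisons are reported
  individually).
* Deletion sizes are binned 1 / 2–10 / 11–50 / > 50 bp; the fraction of
  deletions ≥ 2 bp is the headline contrast between radiation qualities.
* Gene impact intersects event spans with protein-coding gene models
  (GFF3 gene/mRNA/CDS).  Any indel/complex/SV touching a CDS is counted
  as affecting the protein; an SBS in a CDS is translated codon-by-codon
  (both strands) and only non-synonymous changes are flagged.  If a codon
  cannot be resolved the annotation falls back to CDS overlap and logs it.
* Indel context: for 1-bp indels, the length of the reference homopolymer
  run containing/adjacent to the site ("homopolymer-associated" at run
  ≥ 3; the threshold is configurable because the source criterion is
  inherited from earlier work).  For deletions ≥ 2 bp, microhomology is
  max(longest common prefix of the deleted segment with the 3′ flank,
  longest common suffix with the 5′ flank) — the standard MMEJ signature —
  "associated" at ≥ 2 bp, and a tandem-repeat-unit flag marks deletions
  whose segment exactly repeats in the adjacent flank.

## Synthetic cohort generator

The generator produces what the pipeline consumes: a random reference
(default GC 0.36, the Arabidopsis-like value), optional gene models with
genuine ATG..stop ORFs embedded in the sequence on both strands, and
per-sample VCFs with AD/DP/AF genotype fields.

* **Treatment presets** (control, gamma-1000, gamma-1500, carbon-125-175,
  chronic-500mGy, chronic-100mGy) carry category mixes, folded spectra
  and deletion-size distributions transcribed from the reported ranges
  for each arm (SBS share ~70% for gamma vs ~35% for carbon; Ti/Tv 3.0
  control, ~1.25 gamma, ~0.6 carbon, ~0.75 chronic; deletions ≥ 2 bp
  ~45%/57%/72% for acute gamma/chronic gamma/carbon; SV shares 3.5% and
  0.3% for carbon and chronic-500).  They are labelled approximations —
  data, not ground truth — and editable.
* **Induced rates**: each preset stores the *observed homozygous* MF per
  generation (e.g. 11.1 × 10⁻⁹ control, 2.2 × 10⁻⁷ gamma-1500,
  2.8 × 10⁻⁷ chronic-500) and back-calculates the induced heterozygous
  rate through the transmission model (μ = MF·G/Σ P_homo(k); μ = 4·MF
  for M2 designs), so simulated cohorts reproduce the observed
  homozygous MFs in expectation.
* **Zygosity** is drawn from the analytic after-k-selfings distribution
  (M2: k = 1; M6: k = 6 − g for generation-g inductions); lost mutations
  are dropped before emission.
* **AF structure**: homozygous AFs ~ Beta(97, 3) (sharp peak near 1.0),
  heterozygous ~ Beta(50, 50) (broad symmetric peak at 0.5); read counts
  are Poisson(40) depth with the drawn AF converted to allele depths.
  Noise records use floor-rounding so injected low-AF calls stay below
  the exclusion threshold by construction.
* **Artifacts**: shared background sites are injected into ≥ 3 samples
  with het-like AFs (removed by background exclusion), and
  Poisson-distributed spurious records with AF ∈ (0.05, 0.24) per sample
  (removed by the AF filter).
* Placement is uniform and collision-free with a 12-bp guard band so
  independent events never fall within complex-merging distance; one
  global seed fans out into per-stage generators (reference, genes,
  truth, emission), so each stage is independently reproducible.

What the generator does **not** emulate: read-level errors and mapping
artifacts, caller-specific quirks (it writes clean AD/AF fields), real
genomic repeat structure and its effect on callability, selection against
deleterious mutations, and linkage between nearby induced mutations.
Passing end-to-end tests therefore demonstrates that the *decision logic*
of the pipeline is correct under the stated statistical structure, not
that upstream calling on real reads is error-free.

## Problem sizes and tolerances

Analytic quantities are exact.  Monte-Carlo checks use 10⁵ lineages and
3-standard-error bands.  End-to-end cohort checks use 8 samples on a 1-Mb
genome at an induced rate of 10⁻⁶ per site per generation under the
five-generation accumulation design (a few dozen events), with fixed
seeds; recovery is compared event-for-event against the truth table, and
MF/Ti/Tv/zygosity ratios are checked within 3 SE of their generating
values on the appropriate Poisson/binomial scales.  The noiseless
survival-fit round trip is required to recover (D₀, m) to 10⁻⁴ relative;
with binomial noise (75 seeds per dose) D₀ is recovered within ~10% while
m is identified more weakly, as expected from the flat likelihood in the
shoulder region.
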