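# Methods

This note documents the models implemented in `varkat`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical and design decisions a maintainer would want recorded.

## Trio prioritization

Stages run in a fixed order — quality → region of interest → effect/splice
→ population frequency → inheritance models — and report survivor counts
per stage. Each quality criterion is a pure predicate on the proband's
genotype call, applied with the inequality exactly as named: a record is
removed when GQX < 10, variant-read fraction < 0.20, GQ < 30, R8 > 8,
SB > −10, or DP < 20, so boundary values (DP = 20, GQX = 10) survive.
Because the filters are pure predicates, the surviving *set* is
order-independent; only the per-stage counts depend on the stated order.

Two semantic choices deserve note:

* **R8** is a homopolymer-adjacent indel metric and is evaluated for indel
  records only; for SNVs the criterion is skipped rather than treated as
  missing data. Both R8 and SB are opaque thresholds on supplied values —
  the package does not recompute them from reads.
* **LowVariantFreq** is evaluated only for calls carrying at least one
  alternate allele. The variant-read fraction of a hom-ref call is
  legitimately near zero; the metric measures read support for a *called*
  variant, and applying it to hom-ref calls would discard most of a
  family's sites for no informational reason.

Missing population-frequency annotation is treated as "rare" (the record is
retained): in rare-disease discovery, absence of evidence of commonness is
the interesting case. Records above the ceiling (default 1%) in *any*
source are removed.

Compound-heterozygous calling phases by transmission only: a proband-het
variant is paternal (maternal) when exactly one parent carries the
alternate allele. Sites where both parents are heterozygous are ambiguous
and excluded from pairing, and are reported separately. A gene is a
candidate when it carries at least one variant of each origin (trans).
De-novo calls require both parents above a depth floor (default 10×);
below it the call is unevaluable rather than negative.

With several affected siblings the default (`require_all_affected=True`)
intersects candidates across their trios — a causal recessive variant must
be present in every affected child — with a per-proband mode available,
since panel-era pipelines differed on this point.

Coordinates follow VCF externally (1-based inclusive); interval arithmetic
is 0-based half-open internally (BED). The signed `boundary_offset` is
negative for intronic positions (−1 = first intronic base) and positive
for exonic ones (+1 = boundary-adjacent exonic base); the splice window is
|offset| ≤ 8 intronic or ≤ 3 exonic. Multiallelic records are rejected at
the door — decomposition is an upstream responsibility.

## Cross-family analysis

Site PASS flagging uses the GATK-style hard filters (SNV: QD < 2, MQ < 40,
FS > 60, HaplotypeScore > 13, MQRankSum < −12.5, ReadPosRankSum < −8,
≥ 3 SNVs in 35 bp; indel: QD < 2, FS > 200, ReadPosRankSum < −20); missing
statistics skip their criterion. The SNV-cluster window is implemented as
sliding (any 35-bp span containing the site), configurable, since anchored
vs sliding is underdetermined.

Shared variants are identical (chrom, pos, ref, alt) records qualifying in
both cases; a shared variant is classified homozygous only when
homozygous-alternate in both cases. Case-only compound-het analysis cannot
establish trans configuration and is deliberately implemented as
"≥ 2 qualifying hets per gene in each case", with that caveat attached to
the report.

Kinship uses the KING-robust within-pair estimator
φ̂ = (N_Aa,Aa − 2·N_AA,aa)/(N_Aa⁽¹⁾ + N_Aa⁽²⁾): allele-frequency-free,
standard for WGS QC, with expectation 0.5 (duplicates/MZ), 0.25
(parent-offspring, full sibs), 0 (unrelated). Multi-sample-calling noise
can shift the unrelated centre upward in production pipelines; the clean
expectation 0 is the test target here.

Shared homozygous blocks are maximal runs where both samples are
homozygous for identical alleles, with a het tolerance (default 0) and a
minimum length (default 1 Mb). Block length is reported as end − start,
the coordinate-difference convention. Run detection is only meaningful on
*informative* sites — common polymorphisms where a heterozygote is likely
outside a founder block — so callers should pre-filter to sites with
population AF above ~5%; on sparse rare-variant data, long
both-hom-reference runs are vacuous.

## Exon-skip consequence

All arithmetic happens in cDNA space (strand handled by the
genomic-to-cDNA map), with c. positions 1-based from the A of ATG and the
residue of position n being ⌈n/3⌉. Skipping an internal coding exon with
cDNA interval [first, last] deletes last − first + 1 nucleotides; the frame
is preserved iff that is divisible by 3. Codon-aligned in-frame skips are
pure residue deletions (⌈first/3⌉ … last/3). In-frame skips that straddle
codons remove deleted_nt/3 residues *and* create one novel junction
residue; these are flagged (`junction_substitution`) rather than reported
as pure deletions, because the distinction matters for general transcripts
even when the motivating exon happens to be codon-aligned. Skips touching
the start codon set `start_lost` and carry no p. interval.

`verify_by_translation` is the independent oracle: it translates the CDS
with and without the skipped interval and aligns the two proteins by
longest common prefix/suffix. Greedy alignment can place a repeated-residue
deletion at a different (equivalent) offset than the HGVS arithmetic;
agreement is therefore asserted on the edit itself (deleted count, and
reconstructed protein equality), not on span identity.

## Channel assays

Efflux rate fitting honours the early-window restriction (2.5–12.5 min)
because real efflux diverges from a mono-exponential later; points outside
the window cannot influence the fit (tested). k₁ comes from GFP-only
wells; k₂ is then fitted with k₁ held fixed, replicates pooled. Both fits
are bounded least squares (rates ≥ 0) initialized by log-linearization of
1 − efflux; since a bounded optimizer cannot land exactly on a bound, the
k = 0 boundary candidate is taken whenever it fits at least as well as the
interior optimum — this is an optimum selection, not post-hoc clipping.

The Hill fit fixes Imax = 1 (currents are pre-normalized to the basal
nucleotide-free current), leaving three free parameters (Imin, IC₅₀, H)
bounded to [0, 1], > 0, > 0. IC₅₀ initializes at the geometric mean of the
concentration range and H at 1. Non-monotone data beyond a 0.2 tolerance
produce a convergence warning on the returned fit rather than an error.

Relative expression uses the Pfaffl ratio E_t^ΔCt_t / E_ref^ΔCt_ref with
ΔCt = mean WT Ct − sample Ct and efficiencies defaulting to 2.0 (reducing
exactly to 2^−ΔΔCt); the Pfaffl path activates automatically whenever an
efficiency differs from 2.

## Physiology

Ventricular volume applies V = 4/3·π·a·b² verbatim to the supplied long
and short axis values. Whether a and b are full axis lengths or semi-axes
changes only a constant factor that cancels in SF, FAC, EF and any
relative comparison; an optional semi-axis mode (π·a·b²/6) is provided.
EF, not given by a printed formula, is the universal
(EDV − ESV)/EDV × 100. Heart rate averages 60/mean-interbeat-interval over
consecutive three-beat triplets. Diastole/systole annotations always take
precedence; unannotated traces would need extrema detection, which the
simulator sidesteps by emitting annotations.

Locomotor analysis drops frame-to-frame speeds below 2 mm/s (system-noise
floor) from distance and moving time, classifies moving frames as small
(< 10 mm/s) or high-speed, and aggregates into 30-s bins. The high-speed
threshold has no published value and defaults to 20 mm/s — a package
default, clearly not a literature constant.

## Synthetic generators

The cohort generator emulates the discovery conditions: two nuclear
families (2 parents + 4 affected, and 2 parents + 2 affected + 1
unaffected), one planted splice-donor causal variant (hom-alt in every
affected individual, het in every parent, annotated at AF 0.0007 in one
source), a shared founder block around it whose sites are common
polymorphisms homozygous in all affected individuals (visible to ROH
scanning, removed by the rarity filter — which is exactly how founder
blocks behave in real data), and a Beta(0.5, 3)-shaped rare-skewed
background AF spectrum scaled to (0, 0.5), with Hardy–Weinberg founders
and Mendelian transmission. Default 5,000 background variants: a
desk-scale stand-in for the ~10⁴-variant funnels of production panels,
chosen so the full pipeline plus its brute-force oracles run in seconds.
A configurable fraction (default 2% per criterion) of background records
deliberately fails each quality filter so every filter is exercised in
both directions; site statistics likewise fail one PASS criterion at a 3%
rate. Block bounds are anchored by sites at the exact planted ends, so the
detectable extent equals the planted extent up to one informative-site gap
on each side. All draws come from a single seeded `numpy` generator:
identical spec + seed ⇒ byte-identical output files.

What the generator does **not** emulate: linkage disequilibrium, mutation
clustering, multiallelic sites, genotyping-error correlation with depth,
population structure, or realistic gene structure (genes are uniform
tiles with one exon). Passing recovery tests therefore demonstrate the
pipeline's logic — predicate semantics, inheritance calling, set
operations, run detection — not robustness to real-data artefacts.

Assay simulators draw from the same closed forms their analysis
counterparts fit, so noiseless data round-trip exactly and noisy recovery
is measured against the emitted truth ledger. Noise defaults: Poisson
counting statistics on 50,000 loaded counts per efflux well; 0.03 sd on
normalized currents (typical patch-to-patch scatter); ventricle and track
noise off by default. Efflux defaults k₁ = 0.01/min, k₂ = 0.10/min give
the qualitative picture of robust channel-dependent efflux over a small
background within the 37.5-min assay. Dose-response defaults
IC₅₀ = 100 µM, H = 1.3, Imin = 0 are typical of ATP inhibition of
Kir6.2/SUR2A currents. The ventricle simulator rounds the beat period to
a whole number of frames (150 fps, ~180 bpm, 10 s ≈ 30 cycles) and reports
the implied exact rate in its truth ledger so annotated frames carry
exactly the planted geometry.

## Problem sizes in the test suite

The bundled suite uses a 1,000-variant cohort fixture, 10,000-SNP kinship
panels, 200 seeded noisy simulations per fit family, and 1,000 random
transcripts against the translation oracle — sizes chosen so the whole
suite runs in well under a minute while keeping every estimate's Monte
Carlo error far below its asserted tolerance.

## Known limitations

* Effect classification handles SNVs and simple indels against a
  single-transcript model; it is not a general annotator (no VEP-style
  multi-transcript or regulatory logic).
* Case-only compound-het candidates are unphased by construction.
* ROH detection assumes informative-site input; it does not model
  genotyping error beyond the het-tolerance parameter.
* The efflux model ignores the late-time divergence from
  mono-exponential behaviour by design (early-window fitting only).
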