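# Methods

`mutclust` implements the statistical analyses used to characterise the variant
catalogues of two neurodevelopmental syndromes: Okur-Chung (OCNDS, heterozygous
*CSNK2A1* variants affecting the 391-residue kinase subunit CK2α) and
Poirier-Bienvenu (POBINDS, *CSNK2B* variants affecting the 215-residue
regulatory subunit CK2β). The curated point-mutation tables — 60 CK2α rows
carrying 121 patients and 48 CK2β rows carrying 74 patients — ship as packaged
TSV fixtures, together with domain definitions and gene configurations
(UniProt P68400/P67870). Splice variants are modelled as a consequence class
but carry no residue coordinate and are excluded from every statistic.

## Variant model

Each table row is one protein-level variant: an HGVS-style protein change, one
or more coding-DNA descriptors (two nucleotide changes can produce the same
amino acid substitution, e.g. S51R), a patient count and sources. Parsing is
deliberately lenient about dialect — `p.`/`P.` prefixes with stray whitespace,
one- and three-letter codes, `Ter`/`*`, `fs*`/`fsTer`, missing prefixes — because
the source tables mix all of these; anything unrecognisable is a hard error
naming the offending token, never a silent skip. Events are anchored at the
first affected residue (relevant for frameshifts, duplications and stop
gains). Patient counting is per row; variant counting is per distinct cDNA
change, so the CK2α fixture yields 61 single-nucleotide variants from 60 rows.
Known typos in the sources (e.g. the D175E row's cDNA descriptor, which
implies residue 199) are preserved verbatim and downgraded to warnings.

## Per-domain density

A domain is a named residue set built from closed 1-based ranges and explicit
lists; sets may be discontiguous and may overlap (the activation segment
contains the P+1 loop), and overlap is preserved rather than resolved. Density
is patients per residue, displayed with half-up 2-decimal rounding. The
"interdomain" region is the complement of the union of *all* listed sets,
single-residue phosphosites included. On the CK2α fixture this complement has
247 residues carrying 19 patients; on CK2β it is residues 71–105 (35 residues,
15 patients). Some published range lists for the CK2β interdomain row are
internally inconsistent; the complement rule is used throughout and the
discrepancy is noted in the analysis output.

## Nonrandom mutation clustering (NMC)

Under the null, the m patient events are independent uniform draws on the
protein. After sorting, the spacing between order statistics i < j (rescaled
to the unit interval) follows Beta(d, m−d+1) with d = j−i; a cluster is a pair
whose observed spacing sits improbably far into the lower tail. The scan tests
all m(m−1)/2 pairs and adjusts with Benjamini–Hochberg across the whole
family. Two conventions matter:

- **Span.** A pair spanning residues x_i..x_j covers (x_j − x_i + 1)/N of the
  sequence. The +1 keeps the central use case — many patients mutated at one
  residue — at span 1/N instead of a degenerate 0.
- **Events, not variants.** Each patient contributes one event, so a residue
  with 24 patients forms a 24-event run regardless of how many distinct
  nucleotide changes underlie it.

A *single-residue cluster* is a pair whose start and end coincide; for each
residue with ≥2 events the representative pair runs from its first to its last
event, and it is reported when the adjusted p is below α = 0.05 (both raw and
adjusted values are emitted). On the CK2α catalogue the scan ranks residue 198
first (24 events, adjusted p ≈ 5 × 10⁻³², raw ≈ 6 × 10⁻³⁶), then 50, 47, 80,
{191, 312}, {51, 156, 160}, {39, 175, 195} — reproducing the published
significance ordering of the CK2α hotspots exactly, tie groups included.

The reference hotspot list shipped in `data/ck2a_reference_clusters.tsv`
prints p-values whose generating convention is not fully recoverable: no pure
function of (d, m, N, span) — raw or BH-adjusted, residue- or
nucleotide-coordinate, continuous or exact-discrete — reproduces all of them
(the list even assigns different values to two equal-count clusters on CK2β).
Mid-size clusters agree with our raw spacing probabilities within ~2–10%
(e.g. residue 47: 4.09 × 10⁻¹¹ vs 4.16 × 10⁻¹¹ reported); the extreme cluster
at residue 198 differs by about 1.6 decades. `analysis/03_nmc_clusters.py`
writes these residuals; the tests assert exact rank-order agreement and the
exact reproduction of every cluster's sample count, not the irrecoverable
p-value digits.

## Exact multinomial per-codon test

A codon admits nine single-nucleotide variants; under the null each occurs
with probability 1/9, so the patient counts across the nine categories at one
residue are multinomial. The statistic is Σ(O − n/9)²/(n/9) over the nine
categories and the p-value is the exact tail: the total multinomial
probability of all ordered outcomes with a statistic at least the observed one
(ties included — conservative). Enumeration runs over integer partitions of n
into ≤9 parts, weighting each by its multinomial coefficient and its number of
distinct category arrangements; this is exact and fast for n ≤ 25 (the
default cap), with a seeded 10⁶-draw Monte Carlo fallback beyond. Where a row
carries several cDNA changes whose per-patient split is unrecorded, patients
are split across the categories as evenly as possible and the protein-level
tabulation is reported alongside. Start-loss codons are tested like any other.
On the fixtures the significant sets at p < 0.05 are residues
{47, 50, 80, 160, 191, 195, 198, 312} for CK2α and {32, 47, 86, 111, 165} for
CK2β.

## Predictor concordance

Categorical predictor outputs are recoded to binary benign/effect through an
editable scheme (severity-graded vocabularies collapse to "effect"; the
default scheme ships as `data/rating_scheme.json`). For each unordered
predictor pair, only variants rated by both enter the 2×2 table
(a = both effect, b/c = discordant, d = both benign). Reported per pair:
percent agreement, Cohen's κ = (p_o − p_e)/(1 − p_e) (undefined and reported
as such when p_e = 1, i.e. both raters unanimous), and McNemar's test of
marginal homogeneity with statistic (b − c)²/(b + c) referred to χ²₁ —
asymptotic and uncorrected, the convention whose closed forms give the
familiar p = 0.3173 at one discordant pair and p = 0.5637 at statistic 1/3.
With b + c = 0 the test is flagged not computable. Real rating matrices
require calls from external prediction services, so the shipped analysis
demonstrates the stage on synthetic matrices with known agreement.

## Synthetic data and calibration

The generators emit the same TSV dialect the parsers read, so every pipeline
test runs through real I/O. Defaults mirror the CK2α study conditions: a
391-residue protein with m = 121 patient events; the hotspot alternative
seeds a 24/121 fraction of events at residue 198 (the strongest observed
cluster) with the remainder uniform. Codon counts are drawn multinomially
(uniform 1/9 by default); paired predictor calls are drawn from the 2×2 cell
probabilities implied by the two marginal effect rates and the target percent
agreement, with infeasible triples rejected alongside the feasible interval.
The default rater model (marginals 0.8/0.8, agreement 0.9) reflects panels
whose members overwhelmingly call pathogenic variants "effect". All draws are
integer-based through per-stream children of one root `SeedSequence`, so
results are reproducible across platforms and stages are independently
re-seedable.

The calibration harness reports empirical rejection rates at α = 0.05. At
desk scale (200–500 replicates, the sizes also used by the acceptance
script): the NMC family false-positive rate under the uniform null at
m = 121, N = 391 is ≈ 0 (well under the 0.10 bound — BH across 7260 highly
dependent tests is conservative here); a 24/121 hotspot is detected in 100%
of replicates, a 6/121 hotspot in roughly half; the exact multinomial null at
n = 10 rejects in ≈ 2–4% of replicates (exact tests are conservative at
small n). Hotspot-weight recovery from a 10⁴-event profile is accurate to
well under ±0.05 after subtracting the uniform leak-in at the hotspot
residue.

What the generators deliberately do not model: mutational opportunity
(trinucleotide context, CpG hypermutability, transition/transversion bias),
splice variants, patient relatedness, or ascertainment bias across source
databases. Passing calibration therefore shows the statistics behave as
designed under their own nulls, not that real mutation data satisfies those
nulls.

## Numerical choices and limitations

- Beta tails come from `scipy.stats.beta.cdf`; BH adjustment from
  `statsmodels.stats.multitest.multipletests` (step-up, running minimum,
  capped at 1; ties receive equal adjusted values).
- Multinomial tie handling uses a 10⁻⁹ absolute tolerance on the statistic.
- Sorting of tied event positions is irrelevant to every statistic
  (asserted by a permutation test).
- Hotspot tables are ordered by adjusted p then residue for reproducibility.
- The NMC model assumes the number of samples exceeds the number of distinct
  mutated positions; with very small m (< 2) the scan refuses to run.
- p-values below ~10⁻³⁰⁰ underflow to 0 in double precision; the acceptance
  script reports log10 values and clamps before taking logs.
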