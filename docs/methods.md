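# Methods

## Background mutability model

The unit of modeling is a coding sequence with one flanking base on each
side. A premixed 96-channel single-base-substitution spectrum
(pyrimidine-centered, COSMIC channel ordering) assigns each (site, alt)
pair a weight equal to the frequency of its trinucleotide channel;
purine-reference coding-strand sites are folded by reverse complement.
Weights are normalized over the gene, so the profile is the distribution of
a single substitution's location conditional on it hitting the gene. The
spectrum is taken as a single already-mixed table — no signature refitting
or de-novo extraction is done; a cohort-specific mixture should be
assembled upstream and supplied as one 96-channel TSV.

Conventions and edge cases:

- A terminal stop codon in the supplied CDS is accepted but excluded from
  the model (codons are indexed 1..protein_length over amino-acid codons);
  stop-gain at the natural stop is not a modeled event.
- Flanking bases are required; the model refuses to wrap or pad terminal
  contexts.
- Sequences with internal stop codons are rejected; when the reverse
  complement translates cleanly the error advises a strand check.
- Indels are modeled minimally: optional spectrum-level rates for 1-bp
  insertion/deletion in homopolymer runs (default minimum run length 3),
  spread over qualifying runs in proportion to run length. This captures
  the insertion/deletion asymmetry between mismatch-repair-proficient and
  -deficient tumors without the full indel-channel taxonomy, which is out
  of scope. Splice annotations are accepted on input but carry no model
  mass, since panel splice annotations are too heterogeneous to model.

## Goodness-of-fit testing

Observed-versus-expected comparisons use the Pearson statistic with a
Monte-Carlo p-value: replicate count vectors are drawn multinomially under
the expected proportions and the p-value is the add-one-corrected fraction
of replicates at least as extreme. This replaces the asymptotic chi-square
reference, which is unreliable for sparse spectra. For the low-dimensional
class-level comparisons, channels with expected count < 5 are pooled
(all undersized channels merge into one; a still-undersized pool merges
with the smallest adequate channel). The per-codon synonymous deviation
test is deliberately *unpooled*: with ~400 codons and a few hundred events
almost every expected count is small, pooling would erase the signal, and
the Monte-Carlo reference is exact at any expected count.

The synonymous-only test isolates DNA-level mutational processes from
protein-level selection: synonymous changes share the gene's local sequence
features but not the protein consequences, so deviation there flags
background-model misspecification rather than selection.

## Functional classification and damage correction

Amino-acid changes are dichotomized LoF/WT from continuous activity
(lipid-phosphatase-type) and abundance scores on a wild-type ≈ 1 scale,
with clinical-database annotations taking precedence and inframe-indel
impact scores as a third channel; NA is emitted only when no channel has
data. The dichotomization cutoffs default to 0.5 on both scales and are
config constants (`lpa_cutoff`, `abundance_cutoff`): the source scoring
studies calibrate their own cutoffs, so these defaults are deliberately
overridable and all downstream statistics take the config.

The damage fraction of a codon is the background-probability-weighted share
of its nonsynonymous substitutions that are damaging under a given mode
(`sign` = no correction, `lpa`, `abund`, `lpa+ab`, `lof`). Stop gains count
as damaging under every mode. Unscored substitutions are excluded from
numerator and denominator (the alternative, counting them as intact, is a
config switch; exclusion avoids diluting the fraction toward zero when
coverage is incomplete). Codons with no scored nonsynonymous mass get a
missing fraction and keep their uncorrected mass during profile correction.

## dN/dS and driver fractions

ω = (N_obs/S_obs) / (N_exp/S_exp), with the expected ratio taken from the
mutability profile's class masses (a raw-site-count normalization would
ignore the spectrum and is not offered as a default; the signature-
normalized form is the point of the model). The truncating class is
nonsense + frameshift; when the profile carries no indel mass, frameshift
observations are dropped with a warning and the ratio is computed on
nonsense alone. The 95% CI uses the log-ratio normal approximation on two
Poisson counts, Var(log ω) ≈ 1/N + 1/S — chosen for transparency since the
estimator is a ratio of two counts scaled by a constant. Driver fraction is
(ω − 1)/ω floored at zero.

## Spatial statistics

Contacts: two residues are in contact when any inter-atomic distance is
≤ 5 Å (k-d tree over atoms; brute-force all-pairs is the test oracle).
3D hotspots operationalize "a group of residues no more than 5 Å apart" as
neighborhood balls — a residue plus its direct contacts — tested by
aggregating observed counts and expected mass into a one-sided binomial
test. Benjamini–Hochberg correction is applied within each structure
model; significant balls are merged into connected clusters on the union
of model edges. A cluster is reported when ≥ 1 model supports it and
flagged high-confidence when every model does. Gating on q-values is the
default; raw-p gating is a config option since per-model raw-p reporting
is also common. With edgeless graphs the procedure reduces exactly to the
single-residue caller, which is tested.

The dimer-interface consensus takes residues whose cross-chain contact
reproduces in ≥ 4 of 6 chain pairs (both thresholds exposed). Interface
depletion is a two-sided binomial test of the set's observed burden against
its mutability-weighted expected mass (uniform fallback); the fold is
expected/observed, +inf-capped at zero observed. Conservation contrasts
use the two-sample Mann–Whitney test, exact for groups of ≤ 25 without
ties, on scores where lower means more constrained.

## Association statistics

Two-sided Fisher exact p-values follow the probability-summation
convention (sum of all table probabilities ≤ the observed table's), which
matches exhaustive hypergeometric enumeration — the convention is stated
because implementations differ. Odds ratios and Woolf CIs use the
Haldane–Anscombe 0.5 correction when any cell is zero; the p-value stays
uncorrected. Degenerate margins yield an `untestable` flag rather than an
error. Driver-group labels concatenate A/P/B/K in fixed order from
mutation (not deletion) status. Allele fractions are normalized per sample
against a same-tumor driver mutation (the maximum-AF driver when several
are present), canceling purity; distributions are compared with the
two-sample KS test, exact when both groups have n ≤ 25. Stage-stratified
frequencies carry Wilson 95% intervals and pairwise Fisher equality tests.
The study-wide significance threshold is 0.005 throughout, read from the
shared config.

## Microsatellite subtype assignment

TMB windows are half-open: MT-L = [0, 16), MT-H = [16, 100],
MSS-htmb = (100, ∞). TMB above the hypermutator cutoff overrides
everything; otherwise known MS status wins over TMB imputation (the
known-MSS-with-MSI-window-TMB conflict is a config switch, default
known-status-wins); MSI sensor/MANTIS scores at their published cutoffs
(3.5 / 0.4) are used when TMB is absent. The threshold tree for panels
without TMB is a re-implemented conditional-inference-style recursive
partitioner: at each node the feature with the smallest permutation-test
association p-value (10,000 label permutations by default, seeded) is
chosen; the node splits only if p < α (default 0.001); the cutoff is an
exhaustive scan maximizing the 2×2 split chi-square, with ties broken at
the midpoint of the widest separating gap so the fit is deterministic.

## Synthetic cohorts

The generator emulates a large CRC panel cohort: subtype mixture
94.6% MT-L / 4.7% MT-H / 0.7% MSS-htmb; per-subtype lognormal TMB resampled
into the subtype's window; per-subtype spectra (MT-L: CpG-deamination-
dominated with insertion-biased homopolymer indels; MT-H: broader C>T plus
T>C with deletion-dominated indels; MSS-htmb: proofreading-deficient-like
C>A at TpCpT); focal-gene mutation frequencies 3.9% / 18.1% / 44% per
subtype; driver genotypes from a multivariate Bernoulli matched to
marginals and pairwise log odds ratios by iterative proportional fitting
over the exact 2^k joint; clonal allele fractions Beta-distributed around
purity/2 (purity 0.6, concentration 30) with a 25% subclonal fraction at
reduced AF. Mutation placement uses acceptance-resampling — weight each
candidate event by background probability × class selection multiplier ÷
interface depletion, renormalize, draw exactly n events — so realized
counts are exact and test tolerances stay simple.

Selection multipliers default to ω = 20 (truncating) and ω = 16.7
(non-truncating), the strengths at which ~95% and ~94% of observed
mutations in each class are selection-driven. With `damage_linked=True`
(default) the non-truncating multiplier applies only to LoF-classified
changes, which is the mechanistically realistic mode; class-wide dN/dS
then measures a damage-fraction-weighted average below the implanted
value. Estimator-recovery checks and the acceptance script therefore use
`damage_linked=False`, where the implanted multiplier *is* the class-wide
enrichment the estimator measures.

The synthetic reference gene is a 403-codon CDS with an elevated share of
CpG-bearing arginine codons, so deamination spectra produce arginine
hotspots — the mechanism behind recurrent R→Q/R→* hotspots in real tumor
suppressors. It is a stand-in, not a real gene's sequence: because its
CpG codons recur in identical trinucleotide contexts, predicted hotspot
mass has large tie classes, and exact top-k hotspot identities are not
identified (rank agreement between predicted and observed profiles is,
and that is what the tests assert). The synthetic score table likewise
emulates the coverage (~92%) and bimodal structure of
deep-mutational-scanning data without reproducing any real gene's scores.

What passing tests show — and do not show. The simulations validate that
each estimator recovers the parameter it targets under the package's own
generative assumptions (multinomial placement, pairwise-only driver
dependence, Beta AF model, boolean deletion status). They do not validate
robustness to panel-specific artifacts absent from the generator:
capture-bias in trinucleotide representation, copy-number-driven AF
distortion, sample-level duplicate records, or three-way driver
interactions.

## Problem sizes

Default validation sizes: 2,000 mutation events per dN/dS replicate
(grid ω ∈ {1, 2, 5, 10}, 50 replicates per cell in the test suite, 25 in
the acceptance script), 3,500 events for interface-depletion recovery,
n = 2,000 tumors for co-occurrence CIs, 100-seed null-calibration batches,
and 6,000-tumor cohorts for subtype bookkeeping. These sizes put
Monte-Carlo error comfortably inside the asserted tolerances while keeping
the full suite fast.
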