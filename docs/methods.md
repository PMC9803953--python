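# Methods

This note documents the models, parameter choices and numerical conventions
behind the package, and what the synthetic benchmarks do and do not show.

## Probe chemistry and mass conventions

All masses derive from two bundled tables: monoisotopic element masses
(`data/elements.tsv`, ≥6 decimals) and amino-acid residue *formulas*
(`data/residues.tsv`), so residue masses are themselves derived from the
element table — one source of truth for every module. A peptide's neutral
mass is the residue sum plus one water plus modification deltas; the bundled
deltas (carbamidomethyl +57.02146, oxidation +15.99491, phospho +79.96633,
carbamyl +43.00581, acetyl +42.01057) are computed from their formulas the
same way.

The default probe definition is the PF-06672131-phosphonate cysteine adduct,
C29H34N9O6ClFP = 689.20422 Da. Its ether bond breaks under collision, giving
two partial neutral losses (274.08309 and 292.09366 = 274.08309 + H₂O) plus
the full-adduct loss, and singly charged diagnostic ions. The printed ion
values are consistent with adding the hydrogen **atom** mass (1.007825)
rather than the proton mass (1.007276); `charge_carrier_mass` is therefore a
configurable probe field defaulting to the H-atom mass — the 0.00055 Da
difference is the electron. Two further diagnostic ions (645.15, 724.20) and
the MS1-level species are known only to two decimals; they are carried in
the ion table at printed precision but excluded from the sub-mDa
self-consistency check (`probe_ion_table`), which re-derives the intact ion,
the partial ion and the paired loss and flags deviations >1e-4 Da.

## Digestion

Tryptic digestion cleaves C-terminal to K/R unless proline follows, with up
to three missed cleavages and minimum length 4 by default. The wet workflow
this models uses LysC followed by trypsin, but LysC sites are a subset of
tryptic sites, so trypsin specificity alone defines the search space. Pepsin
digests are searched as a *nonspecific* space — every substring of length
6..30 — matching how loose-specificity proteases are handled by search
engines; pepsin's actual cleavage preference is deliberately not modelled.
Protein N-terminal methionine is not specially removed; N-terminal
acetylation is supported as a variable modification restricted to position 1
of protein-N-terminal peptides. Positions are 1-based throughout, matching
residue-level site nomenclature (e.g. Cys797).

Variable-modification enumeration allows at most one modification per
residue and a configurable count per peptide (default 2 in the search
index); peptides whose form count would exceed a cap (default 512) are
skipped with a logged warning rather than erroring, as search engines do.

## Scoring and FDR

The score is a binomial-model −log10 match probability: with k of N
candidate ions matched and a per-ion chance-match probability p estimated
from the spectrum's peak density and the fragment tolerance
(p = n_peaks · 2·tol·mean_mz / span, clamped to [1e-6, 0.5]), the score is
−log10 P[Binom(N, p) ≥ k]. It is zero when nothing matches and strictly
increasing as matches accumulate. b/y series up to charge 2 are scored;
candidates carrying the probe additionally contribute neutral-loss fragment
variants and the diagnostic ions — but diagnostic ions are
sequence-independent (every probe-carrying candidate in the precursor window
shares them), so they count only on top of at least one backbone fragment
match, and they never contribute to unlabeled candidates. Matching is
nearest-by-ppm, one peak per theoretical ion, one use per peak per
annotation class, ties to the lower m/z.

Decoys are full protein reversals (one per target). The best candidate per
spectrum is kept with ties broken toward fewer modifications then
lexicographic sequence; q-values are cumulative decoy/target counts at
descending score, monotonized. Accepted PSMs satisfy q ≤ 1% and, if
modified, a score floor `min_score_modified` (default 5.0, roughly the upper
tail of decoy scores of this scorer on small synthetic databases — score
scales are engine-specific, so no cutoff from other engines is claimed
numerically). A protein-level pass on best-peptide evidence applies the same
target-decoy logic at 1%. Precursor neutral mass uses the declared charge
and the configured charge carrier; isotope-error search is off.

## Site localization

For a PSM with one probe adduct and several target residues, each positional
isomer is rescored and the scores map to probabilities by a base-10 softmax
(the PTM-score convention, temperature 1). Isomer scoring uses backbone
fragments with the intact adduct only: a fragment minus the full-adduct loss
is mass-identical to its unmodified form, so neutral-loss variants (and
diagnostic ions) carry no positional information and are excluded. A peptide
with a single target residue localizes there with probability 1; with no
site-determining ions matched the distribution is uniform. Sites with best
probability ≥ 0.75 are localized — the boundary is inclusive because
ambiguity is defined strictly below the threshold. Peptides carrying more
than one probe adduct are excluded from site tables.

## Acquisition simulation

The simulator stands in for the instrument: topN data-dependent MS2 at base
NCE 28% with 12 s dynamic exclusion over a synthetic gradient (Gaussian
elution profiles, ~4 min, 3 s cycles — simplistic by design); when a survey
MS2 contains a trigger ion (194.05822 or 247.08477) within tolerance above a
configurable intensity floor (default 0), three extra scans at 28/32/36% NCE
are emitted as *separate* spectra with provenance links, searched
independently with the best PSM per peptide retained. Fragment detection
probabilities are per-NCE curves, separate for labeled and unlabeled
peptides: the labeled curves rise with energy while the unlabeled curve
falls, encoding the premise that the bulky adduct soaks up collision energy
at the base setting; diagnostic-ion and neutral-loss yields likewise rise
with NCE. Whether triggered scans should be summed is an instrument choice
the simulator does not make — separate scans are emitted.

## Synthetic data: what it does and does not show

The generator produces random proteomes (vertebrate-like residue
frequencies, configurable cysteine share, default 2.5%), spectra with
planted b/y ions (log-normal intensities), probe NL/DI peaks for labeled
peptides, Poisson uniform noise, and deterministic behaviour under a single
seeded RNG per run. Search benchmarks include ~30% spectra from a disjoint
"foreign" proteome so false matches are possible and realized FDR is
measurable. Quantification truth plants labeled cysteine sites with
replicate log2 intensities (base ~24 ± 1.5, replicate SD 0.4 — consistent
with the high replicate correlation typical of enrichment workflows), a
configurable fraction of true ±4-fold effects, and a logistic
missing-at-low-abundance mechanism, which is the regime the downshifted
imputation targets. Enrichment accounting uses planted class shares:
labeled intensity ~1e-5 of the total before enrichment and ~23% after, with
~14% residual phosphopeptide.

Passing tests on this generator demonstrate the *statistical machinery* —
FDR calibration, localization recovery, trigger logic, imputation and test
behaviour — under the stated assumptions. They do not demonstrate
performance on real LC-MS/MS data: real spectra have correlated fragment
intensities, co-isolation, charge-state errors and retention-time structure
the generator omits, and dataset-level counts (numbers of binding sites,
percentage identification gains) are properties of real datasets that
synthetic runs only mirror in direction, not magnitude.

## Quantification choices

The site filter keeps a site present in ≥2 of 3 replicates of at least one
condition (tryptic regime) or with ≥2 PSMs (pepsin regime); it is
idempotent. Imputation draws missing log2 values per column from
Normal(mean − 1.8·SD, (0.3·SD)²) — the 1.8-SD downshift is the method's
stated parameter, the 0.3-SD width is the de-facto convention of downshift
imputation and is config-exposed; imputation is per-column (per-sample), the
usual default. A Shapiro-Wilk normality diagnostic is reported beforehand
but never blocks. The condition comparison is a per-site two-sample
Student's t-test (equal variance; Welch by flag) with classes assigned at
|log2FC| > 1 and p < 0.05; orientation is fixed by sorted condition names so
relabeling mirrors the volcano exactly. Unadjusted p-values are the default
with optional Benjamini–Hochberg reported alongside. Zero-variance sites are
flagged, not classified. iBAQ is protein intensity divided by the count of
length-bounded (7..30) fully tryptic peptides; per-site priority is
log2(probe-peptide intensity / iBAQ), invariant to global intensity scaling.
Peptides shared between homologous proteins belong to one protein group and
are not duplicated per protein.

## Problem sizes

Default benchmarks use 25-protein proteomes (~240 residues), 200-spectrum
runs, 20-run FDR calibrations, 500-peptide localization panels and
200-replicate power simulations — sizes chosen so each check completes in
seconds while leaving binomial confidence intervals tight enough to be
informative.

## Known limitations

Single-protease evidence cannot always distinguish homologs sharing a
labeled peptide; the nonspecific (pepsin) space helps but quantification
there is PSM-count based. Open/mass-offset searches, chimeric spectra,
isotope-pattern modelling beyond monoisotopic, retention-time prediction and
match-between-runs are out of scope. The mzML writer emits a minimal
document sufficient for round-tripping this package's own output, not a
fully ontology-validated file.
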