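# Methods

## Overview

`iontally` implements a closed search for DDA MS/MS data: experimental
spectra are compared against theoretical fragment series of database
peptides within a predefined variable-modification space. The design
separates *evidence* from *intensity*: only primary *b*/*y* ions count as
matching evidence, while satellite ions (neutral losses and doubly charged
variants) contribute solely by boosting the intensity of the primary they
belong to. Scoring then measures whether matched primaries concentrate
among the most intense spectrum features.

## Modification-set compilation

A user specification lists fixed and variable modifications in
Unimod-style grammar (`Title (site)`, `Title (N-term)`,
`Title (Protein N-term)`, `Title (N-term = Q)`). Fixed and variable
modifications on one site (or one terminus) are chemically incompatible —
a residue cannot carry both masses — so the compiler:

1. coerces each conflicting fixed modification into the variable category;
2. enumerates all in/out combinations of the variable pool
   (terminal entries before Anywhere entries, user order within each);
3. removes combinations with two modifications on one terminus
   ("Protein N-term" and "Any N-term" count as the same terminus);
4. removes combinations that leave a coerced site or terminus uncovered
   by any modification — with several Anywhere coercions, every coerced
   site must be covered;
5. reverts a coerced modification to fixed when no competitor for its
   site remains in the combination.

A variable modification that displaces a coerced fixed one (e.g. protein
N-terminal acetylation displacing an N-terminal TMT label) is marked
*required*: every site assignment in that set must include it, and every
occurrence of a coerced residue site must carry one of the set's
modifications for that site. This encodes the chemistry that motivated
the coercion (a label applied as "fixed" hits every free site; a site can
only escape it by carrying the competing modification) and removes
chemically impossible unmodified forms from the search space.

Rule (4) is implemented with *coverage* semantics (a combination survives
when each coerced site is modified by something), which reproduces the
reference twelve-set example for the TMT specification — three N-terminal
states × two oxidation states × two deamidation states — and guarantees
that no emitted set allows a bare coerced site.

The per-modification position cap (at most 3) counts placements by
modification *title*, so "Phospho (S)" and "Phospho (T)" share one budget.

## Mass arithmetic

Element monoisotopic masses come from the NIST table bundled with
pyteomics; isotope labels (13C, 15N, 2H, 18O) are explicit symbols.
Composition strings follow the Unimod grammar with optional negative
counts (`H(-3) N(-1)` for pyro-Glu). The built-in registry ships the
~20 modifications needed for TMT, phospho, acetyl/ubiquityl and SILAC
workflows; entries can be added, removed, combined additively (composite
entries for e.g. TMT + pyro-Glu at one terminus) and persisted as a
plain-text table. Every lookup mass is validated to be residue mass plus
modification mass within 1e-4 Da.

## Digestion and decoys

Trypsin/P cleaves C-terminal to K/R with no proline exception. Full
specificity emits fragments bounded by cleavage sites or protein termini
with at most `max_missed` internal sites (default 4); semi-specific
requires one enzymatic terminus; non-specific emits every substring in
the length range (default 7–40 residues). Missed-cleavage counts are not
enforced in semi/non-specific modes. Peptides containing B/J/X/U/Z/O are
dropped and counted. Candidates starting at position 2 behind an
initiator methionine are flagged protein-N-terminal so that protein
N-terminal modifications stay reachable on mature termini. Decoys are
full sequence reversals with accession prefix `rev_` (applied after
appending any entrapment database). Candidate site assignments are binned
by neutral mass on a log grid whose relative bin width is twice the
precursor tolerance, so any ±tol query spans at most two bins; bin lookup
is verified against a linear scan in tests.

## Site assignments

At most five variably modified positions per peptide, at most three
positions per modification title, and at most 64 assignments per
(candidate, set); truncation is deterministic, favoring fewer modified
positions and leftmost placements. Candidates are dispatched to a set
only when they contain a site for every variable Anywhere modification in
it, mirroring the search-space minimization of the compilation stage;
duplicate modified-peptide forms arising from overlapping sets keep one
scored instance.

## Ion series

Primary ions are singly protonated *b*/*y* fragments. Satellite
channels: ammonia loss (−17.026549 Da) gated on R/K/N/Q in the fragment;
water loss (−18.010565 Da) gated on S/T/E/D; modification-specific
losses (phospho −97.976895 Da) gated on a modified position with a
neutral-loss attribute inside the fragment; doubly charged variants
(m/z + 1.007276)/2 of the six singly charged channels, generated for
precursors of charge ≥ 3. The gates are the field's standard choices and
are configurable at module level.

## Matching and scoring

Spectra are reduced to their `top_n` (default 100) most intense peaks
(ties keep the lower m/z). Matching is one-to-one and greedy by ascending
|ppm error| (default tolerance ±20 ppm, inclusive): each theoretical ion
takes at most one peak and each peak serves at most one ion per
candidate. The satellite stage runs only when at least
`min_primary_matches` (default 6) primaries matched; satellite peaks are
drawn from peaks not already claimed by primaries and their intensities
are summed onto the matched primary (the tally).

Scoring ranks the N retained features by boosted intensity and scans
depths k = 1..N: x_k matches among the top k features give
p_k = P(X ≥ x_k) under the hypergeometric with N features and K matched.
The scan minimum min_k p_k is a minimum over strongly dependent tests and
is therefore not itself calibrated; the reported P is the *exact* null
probability that the scan minimum reaches the observed value under random
placement of the K matches, computed by a lattice-path count over the
(k, x) grid with rejection-region cells removed (O(N·K) integer DP,
cached per (N, K)). This keeps the degenerate conventions (K = 0 or
K = N gives P = 1, score 0), reproduces the small worked case (N = 6,
K = 2, matches at ranks 1–2 → P = 1/15, score ≈ 11.76), and makes the
null distribution of P uniform-conservative by construction, which the
test suite verifies by Monte-Carlo. Scores depend only on intensity
ranks, so they are invariant under uniform intensity rescaling.

Candidates are ranked per spectrum by score, ties broken by smaller
|precursor ppm error|, then lexicographically by annotated sequence.

## FDR

Rank-1 PSMs are filtered (≥ 6 matched primaries, |precursor error| ≤ 10
ppm) and then assigned q-values by target-decoy counting
FDR(s) = #decoys(score ≥ s) / max(1, #targets(score ≥ s)), monotonized
from the bottom of the score range upward. Calibration uses the subclass
(modification-set index) with the most rank-1 PSMs; the score→q step
function is then applied to every PSM, with scores below all calibration
points mapped to q = 1. Zero decoys in the calibration subclass yield
all-zero q-values with a logged warning. `psmQ.txt` additionally requires
passing the same threshold under peptide-level and protein-level
target-decoy counting (best score per peptide / per leading accession).

## Localization

Competing placements of one modification multiset on one peptide are
compared by their matched *site-determining* primary ions — ions whose
m/z occurs in no competing placement's series. The probability of
placement i is its count divided by the total; a zero-count competitor
concedes fully (1:0 and 2:0 both give 100%), and all-zero counts fall
back to uniform with a flag. Counts are intensity-free.

## Protein groups

Accepted peptides × proteins form a sparse logical incidence. Proteins
sharing any peptide have distance 0, otherwise 1; single-link clustering
cut above height 0 — equivalently, connected components of the
shared-peptide graph — defines the groups, so unique peptides cannot
change the topology. Proteins without shared peptides form singleton
groups. Essential proteins per group are chosen by greedy set cover
(most uncovered peptides first; ties by more total peptides, then
lexicographic accession).

## Synthetic data

The generator defines the validation conditions: 50 spectra from a
5-protein random database (uniform residue composition with a K/R at
least every 12 positions), charges 2–3, log-normal fragment intensities
(µ = 10, σ = 1 on the log scale; y-ions 1.5× brighter than b-ions, as
typical of HCD), satellites planted for half the primaries at 0.3×
relative intensity, 30 uniform noise peaks per spectrum, and Gaussian
m/z jitter of 2 ppm (1 ppm on the precursor) — values chosen once as
representative of a well-calibrated Orbitrap acquisition. It emulates the
rank structure the scorer consumes, not isotope envelopes, co-isolation,
chimeric spectra or correlated chemical noise; passing tests therefore
demonstrate the engine's correctness and calibration machinery, not its
performance on real instrument data. Entrapment evaluation appends an
independently generated random database before decoy reversal and counts
accepted identifications attributable to it.

## Numerical choices and degenerate inputs

- All tolerances are inclusive at the boundary; ppm error is
  (observed − theoretical)/theoretical × 1e6.
- Intensity ties in preprocessing and ranking prefer lower m/z.
- Probabilities are floored at 1e-300 before the log transform.
- Empty spectra, candidate lists or incidence matrices return empty
  results rather than raising.
- MGF entries without a charge default to 2+ with a warning.

## Limitations

- Only b/y (and their satellites) are modeled; no a/c/x/z ions, internal
  fragments, immonium ions or fragment isotope envelopes.
- No open/mass-offset search, spectral-library matching, DIA support or
  post-search rescoring.
- Enzymes beyond trypsin/P are limited to a small built-in rule table.
- Quantitation (reporter ions, precursor intensities) is out of scope.
- The full Unimod database is not mirrored; the registry ships a small
  curated subset plus user extension hooks.
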