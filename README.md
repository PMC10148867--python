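# iontally

Closed database search for data-dependent acquisition (DDA) proteomics,
built around a **satellite-ion intensity tally**: MS/MS spectra are matched
in two stages — primary *b*/*y* ions first, then the satellite series
(*b*⁰/*y*⁰ water loss, *b*\*/*y*\* ammonia loss, doubly charged variants,
and modification-specific losses such as the 97.98 Da phosphate loss) —
and the satellite intensities are added onto their primary ions instead of
being counted as independent evidence:

```
I'(b_i) = I(b_i) + I(b*_i) + I(b0_i) + I(b²_i) + I(b*²_i) + I(b0²_i)
```

Peptide-spectrum matches (PSMs) are then scored by progressive
hypergeometric enrichment: with *N* retained spectrum features of which
*K* matched a primary ion, the top-*k* features by boosted intensity
contain *x_k* matches, giving tail probabilities
*p_k = P(X ≥ x_k | N, K, k)* for every depth *k*. The scan minimum is
calibrated to its exact null probability *P* and the PSM score is
−10·log₁₀(*P*).

Around that kernel the package provides the full closed-search workflow:

- **Modification compilation** — Unimod-style fixed/variable specifications
  (`"Carbamidomethyl (C)"`, `"Acetyl (Protein N-term)"`, …) are minimized
  into compatible *modification sets* by coercing chemically conflicting
  fixed modifications to variable, pruning combinations that double-modify
  a terminus or leave a coerced site bare, and reverting coercions where no
  conflict remains. Per-set amino-acid mass look-ups drive all mass
  arithmetic.
- **In-silico proteolysis** — FASTA ingestion, trypsin/P digestion at
  full/semi/no specificity, full-reversal decoys, and log-mass binning of
  precursor candidates so a ±ppm query touches at most two bins.
- **Target-decoy FDR with subclass transfer** — q-values are calibrated in
  the modification-set subclass with the most matches and transferred to
  all PSMs by a conservative step function.
- **Site localization** — a counting statistic over matched
  site-determining ions: counts 2:1 give the leading placement probability
  0.67; 1:0 (or 2:0) gives 100%.
- **Protein inference** — peptides × proteins incidence, groups connected
  through shared peptides, essential proteins by greedy set cover.
- **Synthetic-spectrum generator** — seeded DDA MS2 spectra with planted
  primary/satellite ions, noise peaks and ppm jitter, plus ground truth,
  so the whole engine is testable offline.

## Worked example

```sh
# generate a synthetic run: 5 proteins, 50 spectra with noise and jitter
iontally simulate --fasta target.fasta --out-mgf run.mgf \
    --out-truth truth.tsv --fixed "Carbamidomethyl (C)" \
    --variable "Oxidation (M)" --seed 101

# search it
iontally search --fasta target.fasta --peaklist run.mgf --out results \
    --fixed "Carbamidomethyl (C)" --variable "Oxidation (M)"
```

prints

```
accepted 50 PSMs in 5 protein groups
```

and writes `results/psmC.txt` (the complete ranked target+decoy list),
`results/psmQ.txt` (the subset passing 1% FDR at PSM, peptide and protein
level — here all 50 planted peptides are recovered with the correct
modified sequence), `results/prot.txt` (protein groups with essential
flags) and `results/manifest.json` (config snapshot, input hashes, stage
counters).

Library-level example:

```python
>>> from iontally import compile_mod_sets, parse_mod_spec, build_aa_lookup
>>> fixed = [parse_mod_spec(s) for s in
...          ["Carbamidomethyl (C)", "TMT10plex (N-term)", "TMT10plex (K)"]]
>>> variable = [parse_mod_spec(s) for s in
...             ["Acetyl (Protein N-term)", "Gln->pyro-Glu (N-term = Q)",
...              "Oxidation (M)", "Deamidated (N)"]]
>>> len(compile_mod_sets(fixed, variable))
12
>>> lk = build_aa_lookup(compile_mod_sets([], [parse_mod_spec("Oxidation (M)")])[0])
>>> round(lk.mass("M"), 4), round(lk.mass("M", "Oxidation"), 4)
(131.0405, 147.0354)
```

The twelve sets are the minimal compatible combinations of that TMT
specification (3 N-terminal states × 2 oxidation states × 2 deamidation
states); the look-up masses are the unmodified and oxidized methionine
residue masses in daltons.

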