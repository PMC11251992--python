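# Methods

`neoscreen` models the computational side of a shared-neoantigen discovery
campaign: from recurrent cancer point mutations and prevalent HLA class I
alleles, through a biochemical peptide–HLA stability screen and predictor
integration, to polyantigen cassette design, combinatorial T-cell pools and
targeted-MS absolute quantification. This note records the models,
parameter choices and numerical decisions behind each stage, and what the
synthetic data generator does and does not emulate.

## Target prioritization

Mutations are selected when their maximum per-indication case prevalence
reaches the threshold (default 2%, inclusive), deduplicated across
indications. HLA alleles pass three filters: (1) a floor — alleles below
1% allele frequency in *every* population are discarded; (2) overall allele
frequency, the **unweighted mean** across populations with a reported value
(missing populations are skipped and logged), at least 5%; (3) carrier
frequency in a typed cohort, at least 10%. Carrier frequency counts
*subjects* carrying ≥ 1 copy — a homozygote contributes once — and is
tabulated directly from the typing table rather than assuming
Hardy–Weinberg. All thresholds are inclusive ("at least"). Ranking is by
overall allele frequency; clinical-development considerations are out of
scope.

## Candidate enumeration

A point substitution at protein position *p* defines a mutant window
spanning `[max(1, p − flank), min(L, p + flank)]` with the variant residue
substituted; the default flank of 12 gives a 25-mer for interior mutations
(the window length is a convention, configurable). Candidate neoepitopes
are every 8–11-mer substring of the window that covers the mutated residue:
an interior mutation yields exactly k peptides of length k, 38 in total.
Coordinates are 1-based inclusive throughout, matching protein-change
nomenclature ("G12D"). Only single amino-acid substitutions are supported;
indels are rejected explicitly.

The screen manifest is the Cartesian product of candidates with the
retained alleles, collapsed to unique (sequence, allele) pairs. The
deduplication key is exact sequence identity — no I/L equivalence — and
collisions between overlapping variants are counted and keep provenance to
every contributing variant. Variant-level merging of "overlapping"
neoepitopes is a defensible alternative; exact-sequence dedup was chosen
because it is unambiguous and auditable.

## TR-FRET screen statistics

Raw readouts are per-well donor (615 nm) and acceptor (665 nm)
fluorescence. The working signal is the ratiometric
`RFU ratio = (RFU_665 / RFU_615) × 1e4`, which cancels well-to-well
brightness variation. Normalization is per plate against the no-peptide
(+HLA) negative controls:

- `%ΔF = 100 · (ratio − mean(ratio_neg)) / mean(ratio_neg)`
- `RZ = (%ΔF − median(%ΔF_neg)) / (1.4826 · MAD)`

A stable binder is `RZ ≥ 5` (inclusive) on a plate passing QC.

**Where the robust scale comes from.** The RZ center is always the
negative-control median, so the negative median scores exactly 0 on every
plate. The scale, however, defaults to the MAD of the plate's ~352
sample-well %ΔF values rather than of the 8 negative wells: a MAD
estimated from 8 points carries ~30% sampling error, and that error — not
the assay — then dominates the far tail of the null RZ distribution,
producing on the order of two spurious RZ ≥ 5 calls per 384-well plate.
The sample pool gives a stable scale and is itself overwhelmingly null at
realistic hit rates (a few percent of wells; the MAD tolerates far more
contamination than that). `rz_scale="negatives"` restores the
negatives-only scale for audit, and the scalar `robust_zscore(sample,
negatives)` primitive is negatives-based. Plates with fewer than 8 sample
wells fall back to the negative controls. A zero MAD falls back to the
standard deviation (logged); zero dispersion altogether is a degenerate
plate and an error.

**QC.** Plate quality is the screening-window coefficient computed from
the positive (pp65/A*02:01 exchange) and negative controls:
`Z′ = 1 − 3(sd_pos + sd_neg)/|mean_pos − mean_neg|`; plates qualify when
`Z′ > 0.4` (strict). A variant with a *difference* of the 3·s.d. terms —
which appears in some printed protocols but cancels to 1 whenever the two
control s.d.s are equal, regardless of separation — is available via
`as_printed=True` for auditing; it is not the default because it is not a
meaningful quality statistic. Records from failing plates are excluded
from binder calling with a warning, never silently called.

Expected control multiplicities (positive ≥ 4, no-peptide negative ≥ 8 per
plate) are validated with warnings; arbitrary layouts with annotated roles
are accepted.

## Predictor concordance and panel selection

Predictor output is consumed as (peptide, allele, BA %Rank, EL %Rank)
tables; the predictor itself is never re-implemented. Rank ≤ 2 (inclusive)
is a predicted binder; a missing rank classifies as non-binder with a
warning. Agreement between the screen and the predictor is Jaccard-style
on binder calls — |both| / |either| — reported per allele and overall,
alongside both-of-all-pairs and non-binder agreement; an empty union
reports null rather than 0.

The targeted panel applies the union rule at peptide level, aggregating
over alleles by best score (max RZ, min rank): peptides with max RZ ≥ 5
form the `trfret` arm; of the remainder, peptides with min rank ≤ 2 form
the `prediction_only` arm. The arms are exclusive by construction and
their union shrinks weakly as the RZ threshold rises. Allele-specific
pools then include a selected peptide for every allele where either
criterion holds at the pair level. EL rank is the default for panel
selection (it targets presentation, which is what the targeted-MS stage
measures); BA is available via `which_rank="ba"`.

## Cassette design and combinatorial pools

Cassette design is deterministic amino-acid bookkeeping: segments in input
order, controls appended last, an optional linker between consecutive
blocks, and an exact 1-based coordinate map (`full_seq[start−1:end] ==
segment`). The default linker is `GGSGGS` — published designs say only
"short flexible" Gly/Ser linkers, so the sequence is configurable and
non-G/S linkers warn. DNA-level elements (codon optimization, IRES,
reporters) are out of scope. `locate_peptide` classifies every occurrence
of a peptide as inside a segment, inside a linker, or spanning a junction;
junction-spanning matches are concatenation artifacts, which is exactly
what the classification exists to flag.

Pooling assigns each peptide a distinct k-of-n combination of stimulation
pools (default 6 of 11, capacity C(11,6) = 462). Assignment is
deterministic — lexicographic subsets in item order — so a design is
reproducible from its inputs; a seeded shuffle is optional. Deconvolution
inverts the scheme: `exact` mode matches a single responder's combination,
`subset` mode returns every item whose combination is contained in the
activated set (superimposed responders).

## Quantification

`amount_on_column = (light/heavy) × spike`, converted to attomoles
(1 fmol = 10³ amol). A missing heavy channel flags the row
not-quantifiable (NaN) rather than inventing a value. Background from the
synthetic-peptide-only run is subtracted with a floor at 0 — a negative
presented amount is non-physical; floor events are logged. Copies per
cell scales the net on-column amount back up by the injected fraction
(default 1/3, per-sample overridable), converts to molecules via
Avogadro's number and divides by cell input:
`copies/cell = (amol_net / fraction) × 10⁻¹⁸ × N_A / n_cells`, so 1 amol
at fraction 1 over 6.0221 × 10⁵ cells is 1 copy/cell. Presentation
summaries report, per neoantigen, the maximum net amount over its peptides
and alleles plus its cassette segment index (for positional analyses),
with explicit orphan and zero-detection reports. Specific lysis is
`100 · (P_mock − P_TCR)/P_mock`; negative values are returned as-is with a
warning.

## Synthetic data generator

The generator emulates the *structure* of the screen, not its chemistry.

- **Plates.** Per allele, peptides fill plates of ≤ 352 sample wells
  (384-well format, controls in columns 1–2: positive exchange control in
  quadruplicate, no-peptide negatives in octuplicate, no-HLA negatives in
  quadruplicate).
- **Noise.** RFU channels carry mean-1 log-normal noise (fluorescence is
  positive and right-skewed), default CV 5% — a typical well-behaved
  ratiometric plate assay.
- **Effect sizes** are expressed in robust units. A planted binder's mean
  ratio is raised by `binder_effect × scaledMAD(%ΔF_null)`, so its expected
  RZ is ≈ `binder_effect` (default 10). The positive control separates by
  20 of the same units: a strong, well-characterized viral epitope
  separates more than a typical hit, and a 10-unit positive control would
  put the true Z′ exactly at the 0.4 boundary (Z′ = 1 − 6σ/10σ), making QC
  a coin flip rather than a check. The scaled MAD of the mean-1 log-normal
  is computed by root-finding on its CDF, not by simulation.
- **Binder fraction** defaults to 3.5%, the candidate-per-screened-pair
  regime of a realistic campaign.
- **Ranks.** Null pairs draw percentile ranks uniformly on (0, 100], so
  they fall under the threshold at the ~2% base rate by construction; true
  binders fall under it with probability `rank_concordance` (default 0.3).
  These defaults put binder-call agreement in the under-30% range
  characteristic of biochemical-vs-predictor comparisons.
- **PRM.** Light and heavy areas carry independent log-normal noise
  (default CV 10%); the light channel encodes
  `truth × injected_fraction + background` relative to the 100-fmol spike,
  and the reported background column is itself a noisy synthetic-only
  measurement, so background subtraction is tested against realistic,
  imperfect background estimates.

Everything is a pure function of the configuration, seed included: the
same `SimulationConfig` reproduces tables byte for byte.

**What passing on synthetic data does not show.** The generator has no
peptide chemistry: binding is planted independently of sequence, so
nothing here validates motif-dependent behavior, allele-specific binding
preferences, cysteine artifacts, or MS detectability biases. Plate noise
is i.i.d. — no edge effects, drift or dispenser artifacts — so the QC
machinery is exercised but not stress-tested against structured error.
Recovery results bound algorithmic correctness, not assay performance on
real lysates.

## Problem sizes

The default test and reproduction runs use single-plate screens
(9 variants × 38 candidates = 342 sample wells) across ≥ 20 seeds for
hit-calling properties, one full-scale screen (47 variants × 15 alleles ≈
26,800 pairs, 90 plates) for concordance and panel statistics, and 25
peptides × 8 replicates for PRM recovery. These sizes give a few hundred
planted binders and several thousand null wells per property, enough to
resolve the documented rates well inside their tolerances.

## Known limitations

- The exact deduplication behind a published screen's pair count depends
  on that study's variant bookkeeping; exact-sequence dedup here is one
  defensible choice (see above).
- Study-level count reproduction (`neoscreen.study`) requires the
  published screen/MS tables as user-supplied TSV extracts; the package
  ships only synthetic stand-ins.
- Copies-per-cell is exercised on synthetic inputs only, since published
  figures rarely print the underlying cell counts.
- Pool assignment treats "groups of similar neoepitopes" as single items;
  grouping similar peptides before assignment is the caller's decision.
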