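# Methods

## The problem and the model

Knocking out one GalNAc-transferase isoform in isogenic cell clones removes
the O-glycans that only that isoform can initiate. In a multiplexed
quantification of enriched glycopeptides, those sites show a collapsed
KO/WT ratio in every clone of that knockout while staying near 1 in the
other knockouts; everything else — biological noise, clone-to-clone drift,
protein-level abundance changes — must be filtered out by the selection
rules. `glycodiff` implements those rules exactly as stated, plus the
plumbing around them, and treats the calling thresholds as configuration
rather than code.

The quantitative model underlying both the simulator and the rules is
multiplicative: a peptide's channel abundance is a base intensity times an
effect factor (the true KO/WT ratio for planted sites in matching KO
channels, 1 otherwise) times log10-normal noise, so all statistics are done
on log10 ratios where the noise is additive and symmetric.

## Selection rules

**Phospho (two clones, TMT).** Each KO-clone/WT contrast family gets its
own empirical median and sample SD (n-1); a peptide is called for an
isoform iff both clone log ratios fall strictly beyond median ± 2 SD on the
same side. The gate against replicate artifacts is the peptide's own
WT2/WT1 log ratio, which must lie inside the central 95% interval
(2.5th–97.5th empirical percentiles, linear interpolation) of all WT2/WT1
ratios. A normal-approximation interval (mean ± 1.959964 SD) is available
for runs with fewer than 20 WT pairs, and a robust SD mode (1.4826 x MAD)
for heavy-tailed runs. The KO denominator is the mean of the two WT
channels; this is a design choice — the rule's published form does not say
which WT channel anchors the KO ratios — and WT2/WT1 is kept as its own
contrast because the gate is defined on it.

Under independent normal log-ratio noise the expected null call rate per
isoform is 2 x (0.02275)^2 ~ 0.1% before the WT gate; the package's null
simulation (`simulate.null_phospho_ratio_rows`) draws contrasts
independently to match that arithmetic. Channel-level simulation with a
shared WT-mean denominator correlates the two clone contrasts (correlation
~ 1/3 at equal noise) and raises the joint tail; the null-rate check is
therefore defined at the ratio level, which is also where the rule itself
operates.

**Glyco (three clones, TMT).** Peptide ratios are aggregated to sites
first (median across supporting glycopeptides per contrast, mean-of-central
pair on even counts), then a site is changed for an isoform iff all three
clone ratios are <= 0.5 (down) or >= 2.0 (up). The isoform-selectivity
classifier layers three conditions: all-clones-down for exactly one
isoform, every available clone ratio > 0.5 for both other isoforms, and a
protein-level control (mean protein KO/WT clone ratio > 0.75; not-detected
passes with an audit flag). Two or more isoforms down classifies the site
as shared; partial data always downgrades to unchanged with an audit note —
missing clones are never imputed, every skip is counted.

**Dimethyl (single pair per isoform).** One ratio per peptide per pair,
thresholded at the same 0.5/2.0 defaults, merged across the three isogenic
pairs by site key. The published screens describe their dimethyl filters
only loosely, so the defaults mirror the TMT thresholds and are exposed in
the configuration.

**ANOVA mode.** One-way fixed-effects ANOVA on log10 site quantifications
across the three KO groups (three clones each), p from the F distribution,
BH q-values across sites, selection at q <= 0.1. Zero within-group variance
with unequal means is reported as p = 0 with a flag; all-identical values
are undefined and skipped with a flag.

## Site mapping and ambiguity

All protein coordinates are 1-based. Localized modifications map to
`peptide start + within-peptide position - 1` and are checked against the
protein residue (S/T for glycans, S/T/Y for phosphate). A peptide with `g`
unlocalized glycans and exactly `g` candidate residues yields `g` forced
unambiguous sites; more candidates than glycans yields one ambiguous site
group whose alternative positions are semicolon-joined in displays and in
the canonical site key `accession:pos1;pos2;...`. More glycans than
candidates is an annotation inconsistency and raises. Peptides that occur
at more than one position, or on unknown proteins, are dropped with a
logged warning and a counter — shared-peptide evidence is deliberately not
split.

For unique-site accounting a site supported by both single-glycan and
multi-glycan peptides is classed "single" (best evidence wins): the
single-glycan observations are the conservative core evidence, and a
precedence rule is needed for the single/multiple split to partition the
unique keys. Ambiguous groups overlapping an unambiguous site are kept as
distinct keys.

## The simulator

The generator emulates three designs: TMT 10-plex glyco (1 WT + 3 clones x
3 KOs), TMT phospho (2 WT replicates + 2 clones x 3 KOs), and two-channel
dimethyl pairs (WT light / KO medium, one pair per isoform over a shared
planted registry). Defaults are the standard study conditions used by the
test-suite and acceptance run: 300 proteins of 150–450 residues, 60
planted sites per isoform, true effect ratio 0.2, noise SD 0.05 on log10,
seed 42.

Choices a real dataset forced us to make concrete:

* **Proteome.** Residues drawn i.i.d. from an average vertebrate
  composition; sequences redrawn until they contain at least one K/R and
  one S/T so digestion and glycosylation are always possible.
* **Digestion.** Trypsin as the plain Keil rule — cleave after K/R unless
  followed by P (via `pyteomics.parser.icleave` with the rule
  `[KR](?!P)`); up to 2 missed cleavages; observable peptides are 6–40
  residues, the MS-typical window.
* **Planting.** Sites are placed on fully-cleaved peptides that locate
  uniquely in the proteome. The configured multi-site fraction (default
  0.3) of each isoform's sites lie on peptides carrying two glycans;
  the count is round-half-up of fraction x n, bumped to the next even
  number because multi-glycan sites are planted in pairs on one shared
  peptide (so every ratio-changed site is a truth entry and precision is
  well defined). One peptide hosts sites of one isoform only.
* **Abundance.** Base intensity 10^N(6, 0.5) per peptide — the scale of
  Orbitrap reporter intensities; all channels of a planted peptide's
  owning isoform are multiplied by the effect ratio (no clone-to-clone
  effect heterogeneity by default; an optional per-clone jitter SD
  exists); every channel value then gets independent 10^N(0, noise_sd)
  noise. With noise 0 all ratios are exact to floating-point.
* **Glycoforms.** The TMT screen (wild-type background, Jacalin
  enrichment) carries HexHexNAc; the dimethyl screen (SimpleCell
  background, VVA enrichment) carries HexNAc. Simulated annotations are
  always localized; unlocalized records (`KIND@?xN`) are exercised by
  hand-built fixtures in the unit tests.
* **Missingness.** A per-value missing rate is exposed (default 0 — no
  published value exists for it); missing cells drop the contrasts that
  touch them, never impute.

What the simulator does **not** model: spectra and identification error,
isotope-impurity crosstalk between TMT channels, intensity-dependent noise,
shared peptides between proteins, protein-level quantification, and real
sequence composition biases around acceptor sites. Passing recovery tests
therefore show that the rules are implemented correctly and are stable
under multiplicative noise at the stated level — not that the thresholds
are optimal for any particular real dataset.

## Numerical choices

* Ratios: absent numerators make a contrast absent; unusable denominators
  mark it undefined — never 0. Log10 ratios are attached wherever ratios
  exist and checked to 1e-12.
* Median: mean of central pair on even counts everywhere (distribution
  stats and site aggregation alike).
* Normalization: optional median-centering equalizes per-channel log10
  medians at the mean of the medians, making it idempotent; ratio tables
  can be computed on raw or normalized intensities and the configuration
  records the choice.
* Thresholds compare inclusively (<= down, >= up, interval bounds
  inclusive), so boundary ratios count as changed/inside; the exhaustive
  grid tests pin this down.
* BH q-values come from `statsmodels` (`fdr_bh`) and are cross-checked
  against a brute-force min-scan; note BH is *not* idempotent in general —
  only constant adjusted vectors are fixed points — and the tests assert
  the properties that actually hold (order preservation, q <= 1,
  re-application never lowers q).
* Enrichment is an exact hypergeometric upper tail over a background of
  all quantified proteins (the standard proteomics choice; configurable),
  with DAVID-style EASE (k-1) behind a flag for comparability.
* Determinism: one `numpy` Generator seeded from the design seed drives a
  run; identical seed and design give byte-identical FASTA/TSV/JSON
  outputs (floats are serialized with `repr`, the shortest exact
  round-trip form).

## Problem sizes

The test-suite and the acceptance script run entirely on generated data:
8,000-point exhaustive threshold grids per isoform, 10,000–20,000-peptide
null screens, and the 300-protein / 180-planted-site standard glyco screen.
These sizes give sub-percent Monte-Carlo error on the quantities checked
while keeping a full run in the single-digit seconds.

## Known limitations

* The glyco "consistently changed" thresholds beyond the published <= 0.5
  selective criterion, and the dimethyl filters, are defaults mirrored
  from the selective rule, not published constants; both are config keys.
* The WT2/WT1 "95% confidence interval" is read as the empirical central
  95% interval of all WT2/WT1 ratios; a normal-theory variant is provided
  but the empirical form is the default.
* Recovery scores are computed against localized simulated annotations;
  ambiguous site groups in real data would need the overlap report to
  reconcile them with single-position truth.
* No batch correction across plexes (single-run designs only), no
  identification FDR, no localization-probability modeling.
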