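# glycodiff

Differential PTM-omics calling for GalNAc-transferase isoform screens:
identify isoform-specific O-glycosites and knockout-specific phosphosites
from multiplexed quantitative proteomics ratio tables, with a synthetic-data
generator that makes every stage testable against planted ground truth.

## Who this is for

Mucin-type O-glycosylation is initiated by a family of 20 polypeptide
GalNAc-transferases (GalNAc-Ts) with overlapping but distinct substrate
preferences. A standard way to map the non-redundant substrates of one
isoform is to knock it out in isogenic cell clones, enrich glycopeptides (or
phosphopeptides) from KO and wild-type digests, quantify them in a
multiplexed MS run (TMT or stable-isotope dimethyl labels), and flag the
peptides whose KO/WT ratio collapses. `glycodiff` implements the downstream
half of that workflow — everything after peptide identification and
quantification — as a tested, reusable library and CLI.

## What it computes

Three multiplexing designs are supported:

* **TMT 10-plex glyco screen** — one WT channel + 3 clones x 3 KO isoforms
  (T1, T2, T3). A glycosite is *differential* for an isoform when its KO/WT
  ratio is consistently changed in **all three clones** (<= 0.5 down,
  >= 2.0 up by default). A site is *isoform-selective* for T1 when

  `T1/WT <= 0.5 (all 3 clones)` and `T2/WT > 0.5`, `T3/WT > 0.5` (all clones),

  with a protein-level control: the mean protein KO/WT ratio must exceed
  0.75 (not-detected proteins pass with an audit flag), so protein loss is
  not mistaken for site-specific deglycosylation.
* **TMT phospho screen** — 2 WT biological replicates + 2 clones x 3 KOs.
  A phosphopeptide is differential when its log10 KO/WT ratio (denominator =
  mean of the two WT channels) lies more than 2 SD from the contrast-family
  median in **both clones on the same side**, while its own WT2/WT1 ratio
  stays inside the central-95% interval of all WT2/WT1 ratios — an empirical
  null built from replicate variation.
* **Dimethyl pairs** — light WT / medium KO, one isogenic pair per isoform,
  thresholded per pair and merged by site key.

Around the calling rules the package provides peptide-to-protein site
mapping with the semicolon ambiguity convention (an unlocalized glycan on a
peptide with candidate residues at 402 and 403 becomes the ambiguous site
group `402;403`; when glycans equal candidates every position is forced and
unambiguous), single/multiple-glycan multiplicity accounting, site-level
median aggregation, a one-way ANOVA alternative selected at BH q <= 0.1,
Venn overlaps across isoforms, hypergeometric term enrichment with
Benjamini–Hochberg FDR, and precision/recall scoring against the simulator's
planted truth.

## Worked example

Simulate a small TMT glyco screen (80 proteins, 12 planted sites per
isoform, true effect ratio 0.2, multiplicative noise SD 0.05 on log10) and
recover the planted sites:

```python
from glycodiff import SimulationDesign
from glycodiff.pipeline import run_glyco_tmt, run_summary, selective_site_table_rows

design = SimulationDesign(kind="glyco_tmt10", n_proteins=80,
                          n_planted_per_isoform=12, seed=7)
result = run_glyco_tmt(design)
summary = run_summary(result)
print(summary["differential_sites"]["T1"])
print(summary["recovery"]["T1"])
for row in selective_site_table_rows(result)[:2]:
    print(row["accession"], row["glycosite"], row["isoform"],
          round(row["mean_ratio"], 4), row["protein_quant"])
```

prints

```
{'unique': 12, 'single': 8, 'multiple': 4, 'unambiguous': 12, 'ambiguous': 0}
{'precision': 1.0, 'recall': 1.0, 'f1': 1.0}
SYN0065 251 T1 0.163 ND
SYN0045 38 T1 0.1655 ND
```

All 12 planted T1 sites are recovered (8 on single-glycan peptides, 4 on
multi-glycan peptides, none ambiguous because the simulated annotations are
localized), precision and recall are 1.0, and the top of the
selective-site table shows mean three-clone ratios near the planted 0.2.
Protein quantification is not simulated, so the protein-level control
reports `ND` (passes with an audit flag).

The same pipeline is available from the shell:

```sh
glycodiff simulate --kind glyco_tmt10 --seed 7 --out-dir data/
glycodiff call-glyco --fasta data/proteome.fasta \
    --quant data/quant_glyco_tmt10.tsv --out calls.tsv
glycodiff evaluate --calls calls.tsv --truth data/truth.tsv --out recovery.json
```

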