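# rmscape

Comparative-genomics analysis of **restriction–modification (R-M) systems**
in annotated prokaryotic genomes: detection of complete systems and solitary
components from gene-neighbourhood rules, their association with mobile
genetic elements (MGEs) and other defense/competence systems, core/pan-genome
placement, integration-region analysis, and selection-pressure (dN/dS)
screening. A first-class synthetic-data module generates every input the
pipeline consumes, with machine-readable planted truth, so the whole analysis
is exercised end-to-end against known ground truth.

## Who this is for

Microbial comparative genomicists studying the interplay between host defense
systems and horizontal gene transfer. R-M systems pair a methyltransferase
(MTase), which marks a recognition sequence, with a restriction endonuclease
(REase), which cleaves the unmarked sequence — a poison/antidote pair that
acts as an innate immune system against incoming DNA and as an addiction
module stabilising the elements that carry it.

## The rules at the core

* **System assembly** — Types I/II/III systems are cognate MTase/REase genes
  (plus specificity S subunits for Type I) *less than 4 genes apart* (rank
  offset ≤ 3); overlapping candidate clusters of one type merge into a single
  system, and systems with several S genes stay one system. A Type IIC gene
  (REase+MTase fused in one polypeptide) is a complete system by itself; a
  Type IV REase (cleaves *modified* sites) forms an entry with no MTase.
  A system is *complete* iff it has both REase and MTase (or is IIC).
* **Solitary components** — an MTase/REase with no cognate gene *within 10
  genes*; the [4, 10) band is reported as *ambiguous*, never silently
  dropped.
* **Role calls** — best passing hit against a labelled reference library
  (score-derived significance < 10⁻³; subject coverage ≥ 50% for the
  BLAST-searched Type II/IV REase roles). One gene passing both an REase and
  an MTase reference is a IIC fusion.
* **Core genome** — bidirectional best hits (end-gap-free global alignment,
  ≥ 80% similarity, ≤ 20% length difference) kept as *positional orthologs*
  when ≥ 4 other BBH pairs lie within a 10-gene window around both members;
  the core is the intersection of the pivot's lists over all strains.
* **Pan-genome** — single-linkage families at ≥ 80% (stringent) or ≥ 40%
  (relaxed) identity covering > 80% of the smallest protein; families in
  < 1/3 of strains are non-persistent.
* **Integration regions** — the stretch between the two consecutive core
  genes flanking an element; its gene count *L* proxies the acquired-segment
  size. Flank pairs that are non-consecutive in another strain sit on
  rearrangement breakpoints and are excluded.
* **Enrichment** — E(type, MGE category) = total(type) × fraction of all
  systems in that category; O/E = 1 under uniform placement.
* **dN/dS** — pairwise counting estimators: Nei–Gojobori-style equal-pathway
  counting with Jukes–Cantor correction (`ng86`) and a Yang–Nielsen-style
  κ/F3x4-weighted variant with class-wise K80 correction and iterative
  pathway weighting (`yn00`); estimates with dS > 1 are saturated and
  discarded from selection summaries.

## Worked example

```python
from rmscape.synthetic_data import standard_dataset
from rmscape.pipeline import analyze_dataset

dataset = standard_dataset(seed=1)          # 20 genomes, 2 clades
result = analyze_dataset(dataset, run_dnds=False)
print(result.tables["census_types"].to_string(index=False))
```

prints the R-M type census over the 42 detected systems:

```
rm_type  count  fraction
      I      7  0.166667
     II     15  0.357143
    IIC     11  0.261905
    III      5  0.119048
     IV      4  0.095238
```

`result.tables["systems"]` holds each assembled system with its components
and span, e.g. a Type I system with two specificity subunits
(`MTase;S;REase;S`, ranks 24–27 of genome `G00`) and the IIC fusion planted
in `G01`. `result.tables["solitary"]` separates the 27 solitary components
(nearest cognate ≥ 10 genes) from the 10 ambiguous calls in the [4, 10)
band, and `result.tables["colocalization"]` shows that no two systems sit
within 10 genes of each other in this dataset while 74% share a 50-gene
neighbourhood.

The same analysis is scriptable from the shell:

```bash
rmscape simulate --seed 3 --n-genomes 2 --out data/
rmscape rm-detect --genome data/G00.gbk \
    --reference data/reference_library.faa --out out/
# -> "2 systems, 1 solitary, 0 ambiguous"
rmscape run --seed 1 --out results/   # full pipeline, all tables as TSV
```

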