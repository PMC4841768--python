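# ptmkit

Quantitative analyses around a PTM-regulated transcription factor, in one
tested Python package. The motivating system is SOX2 in mouse embryonic stem
cells, whose transactivation-domain (TAD) tryptic peptide carries
O-GlcNAc (HexNAc, +203.079373 Da) and phosphate (+79.966331 Da) in several
combinations; an O-GlcNAc-deficient S248A mutant changes the protein's
interactome, genomic occupancy and downstream gene expression. `ptmkit`
implements the four computational layers such a study needs, plus seeded
synthetic-data generators so every stage can be exercised and validated
without any external downloads:

1. **PTM proteoform stoichiometry** (`ptmkit.ptm_quant`) — theoretical m/z
   per modified peptide, extracted ion chromatograms (XICs) at a ppm
   tolerance, baseline-subtracted trapezoidal peak areas, and per-isoform
   fractions of total signal with limit-of-quantitation flags. For isoform
   *i* with integrated area *A<sub>i</sub>*, the occupancy is
   *f<sub>i</sub> = A<sub>i</sub> / Σ<sub>j</sub> A<sub>j</sub>*.
2. **AP-MS interactome scoring** (`ptmkit.interactome`) — bait-specific
   interactors from median-normalised log2 FLAG/HA LFQ ratios (one-sided
   2-SD rule), differential WT-vs-S248A interactors from the log2
   ratio-of-ratios z-score (|z| > 1.5), peptide-to-protein rollup excluding
   homologous peptides and the bait's modified region, and targeted
   top-2-peptide quantitation for complex subunits.
3. **ChIP-seq signal** (`ptmkit.chip_signal`) — tag deduplication and
   uniform subsampling, tag density within 75 bp of each 20 bp bin scaled to
   a fixed library size, bin-wise input subtraction (negatives kept), a
   threshold/merge peak caller, any-overlap partitioning of peak sets into
   shared/specific, and PWM log-odds motif scanning of both strands.
4. **Expression filters** (`ptmkit.expression`) — differential expression by
   a fold-change gate (default 1.5) combined with a paired t-test on log2
   values (p < 0.05), and RT-qPCR relative quantitation by
   2<sup>−ΔCq</sup> with ΔCq = Cq(gene) − Cq(reference).

The library is the primary interface; `examples/` holds one narrative script
per capability, and a thin `ptmkit` command-line wrapper exposes the stages
(`simulate`, `ptm-quant`, `apms-score`, `chip-track`, `chip-overlap`,
`motif-scan`, `de-filter`, `delta-cq`) for shell use.

## Worked example

```sh
python examples/ptm_stoichiometry.py
```

simulates an MS1 run whose four TAD proteoforms elute as separated Gaussian
peaks at a known composition with 1% multiplicative noise, then
re-quantifies it through the full XIC pipeline at 10 ppm:

```
simulated MS1 run: 411 scans
                   label      area  fraction  below_loq
              unmodified 3.318e+05     0.332      False
             GlcNAc-S248 4.412e+05    0.4414      False
            phospho-S253 1.089e+05    0.1089      False
GlcNAc-S248+phospho-S253 1.176e+05    0.1177      False

  unmodified                   recovered  33.2%  (truth  33.2%)
  GlcNAc-S248                  recovered  44.1%  (truth  44.1%)
  phospho-S253                 recovered  10.9%  (truth  10.9%)
  GlcNAc-S248+phospho-S253     recovered  11.8%  (truth  11.8%)
```

Each `fraction` is that proteoform's share of the summed XIC area — the PTM
occupancy. The generator's ground truth is recovered to well within one
percentage point; isoforms under 1% of total would be flagged `below_loq`
but kept in the normalisation. The other examples
(`apms_scoring.py`, `chip_signal_track.py`, `expression_filters.py`) print
the analogous recovery summaries for the interactome, ChIP and expression
stages.

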