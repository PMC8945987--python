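# cmaquant

Tools for profiling candidate substrates of chaperone-mediated autophagy
(CMA) from three kinds of evidence:

1. **SILAC lysosome proteomics** — parse Proteome Discoverer-style
   quantification tables (treatment/control abundance ratio, p-value,
   peptide count, FDR confidence), apply the standard three-filter
   cascade (high confidence with ≥ 2 peptides, p ≤ 0.05, two-fold
   change), and call each retained protein up- or downregulated.
2. **KFERQ-like motif scanning** — scan protein sequences for the
   pentapeptide targeting signal recognized by HSC70.  A window is
   *canonical* when a glutamine anchors one end and the four flanking
   residues comprise 1–2 hydrophobic {F,I,L,V}, 1–2 basic {K,R} and
   exactly one acidic {D,E} residue.  *Phospho-activated* motifs become
   canonical when one flanking S/T/Y is phosphorylated (acidic mimic);
   *acetyl-activated* motifs when a terminal lysine is acetylated
   (Q mimic); a dual class needs both.  Per-protein categories and
   motif × regulation breakdown panels are computed from the hits.
3. **Reporter-puncta imaging** — count fluorescent CMA-reporter puncta
   per cell in two-channel (DAPI + reporter) images: nucleus seeding,
   seeded-watershed cell segmentation, Phansalkar local thresholding
   `t = m·(1 + p·e^(−q·m) + k·(s/r − 1))`, particle splitting and
   per-cell assignment, and an unpaired t-test on per-replicate mean
   counts.

A synthetic-data module generates all three input types with known
ground truth (planted regulation, planted motifs, planted puncta), so
the whole pipeline is testable end to end without external data.

## Worked example

```python
>>> from cmaquant import classify_pentapeptide, scan_sequence
>>> classify_pentapeptide("KFERQ")
'canonical'
>>> classify_pentapeptide("KFSRQ")   # S phosphorylation completes the rule
'phospho'
>>> scan_sequence("MKFERQAAAA", "P1")[0].start
1
```

A full synthetic run — simulate a 300-protein SILAC table, filter it,
scan matched synthetic sequences, and assemble the panels:

```python
>>> from cmaquant import run_pipeline
>>> report = run_pipeline({
...     "outdir": "demo", "seed": 7,
...     "stages": ["simulate-quant", "simulate-seqs", "filter", "scan", "breakdown"],
...     "simulate_quant": {"n_proteins": 300, "rep_sd": 0.2},
... })
>>> report["regulation"]
{'n_total': 103, 'n_up': 53, 'n_down': 50, 'n_unchanged': 0, 'pct_up': 51, 'pct_down': 49}
>>> report["motif_breakdown"]["pct_with_motif"]
77
```

Here 103 of 300 simulated proteins survive the filter cascade (51% up,
49% down), and 77% of them carry at least one KFERQ-like motif — close
to the 80% planted by the sequence generator, which gives one protein
in five no motif.  The same stages are exposed as CLI subcommands
(`cmaquant simulate-quant | filter | scan | breakdown | puncta |
compare | report | export-string-list`); `export-string-list` writes
the up/down gene-symbol lists in the single-column form the STRING
website accepts.

Counting puncta in a two-channel TIFF:

```bash
cmaquant puncta --image field.tif --nuclei-channel 0 --reporter-channel 1
```

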