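# disptm

Proteome-wide statistics linking intrinsic protein disorder to predicted
post-translational modification (PTM) sites, in the style of plant
disorder/PTM surveys.

Given (a) a FASTA proteome, (b) per-residue disorder annotations
(long-format TSV, standing in for disorder-predictor output), and (c) PTM
site tables (TSV, standing in for PTM-predictor output), the package
computes:

* **dataset construction** — length filtering (keep 50–2000 aa) and a
  deterministic greedy redundancy reduction at 90% global identity;
* **motif scanning** — N-glycosylation sequons (`N-X-S/T`, X ≠ P) and the
  plant Hyp-O-glycosylation consensus
  `[A/S/T/V]-P(1,4)-X(0-10)-[A/S/T/V]-P(1,4)` directly from sequence;
* **disorder statistics** — per-protein disorder fractions and segments,
  and the residue-weighted proteome disorder degree;
* **PTM statistics** — normalized contents (sites per 400 residues), the
  enrichment ratio `Rd/o = (Nd/Ld) / (No/Lo)` between disordered and
  ordered sequence, and site-count binning (0…≥4, or 0…≥7 for
  methylation) against mean disorder;
* **significance** — Pearson correlation of bin ordinal vs bin mean
  disorder, with the one-tailed probability
  `P(T_{n-2} ≥ |r|·sqrt((n-2)/(1-r²)))`;
* **synthetic proteomes** — a generator with block-structured disorder and
  a configurable planted enrichment per PTM type, plus literal motif
  planting, so every stage can be tested against known ground truth.

## CLI

```bash
disptm simulate --config synth.yaml --out-dir sim/   # synthetic bundle
disptm filter in.fasta out.fasta --min-len 50 --max-len 2000 --identity 0.90 --stats stats.tsv
disptm scan in.fasta --pattern both -o sites.tsv
disptm disorder-stats --disorder disorder.tsv --fasta in.fasta -o summary.tsv
disptm ptm-stats --manifest species.yaml --ptm pSer -o content.tsv --rdo rdo.tsv --bins bins.tsv
disptm correlate --bins bins.tsv -o correlations.tsv
disptm run-all --manifest species.yaml --out-dir out/
```

`run-all` processes every species in a YAML manifest (see
`FORMATS.md`), writes per-species TSV tables plus a correlation grid,
monocot/dicot contrasts and a machine-readable `summary.json`; runs are
deterministic given fixed inputs and seed. Logs go to stderr
(`disptm --log-level info run-all ...`).

An example synthetic config:

```yaml
n_proteins: 500
length_law: [fixed, 400]
disorder_frac: 0.3
block_dis: 30
ptm_rates: {pSer: 0.2, N-gly: 0.1}
enrichment: {pSer: 3.0}
seed: 1
```

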