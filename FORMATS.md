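# File formats

All tables are tab-separated with a header line; floats are written with
4 decimal places (round-half-even); missing values are `NA`. Positions
are 1-based and inclusive everywhere.

## Inputs

### FASTA proteome
Standard FASTA, multi-line sequences allowed. The header token before
the first whitespace is the protein id (unique within a proteome).
Sequences are upper-cased on input; a single trailing `*` is stripped;
allowed residues are the 20 standard codes plus `X`.

### Disorder table (`disorder.tsv`)
Long format, one row per residue.

| column | meaning |
| --- | --- |
| `protein_id` | protein id |
| `position` | 1..L, contiguous within each protein |
| `score` | optional; real in [0, 1] |
| `call` | optional; `1` = disordered, `0` = ordered |

At least one of `score`/`call` must be present. Without `call`, calls
are derived as `score >= threshold` (default threshold 0.5, inclusive).

### Site table (`sites_*.tsv`)
| column | meaning |
| --- | --- |
| `protein_id` | protein id |
| `position` | 1-based residue index |
| `residue` | one-letter code; must match the sequence and the PTM type |
| `ptm_type` | one of `pSer pThr pTyr O-gly N-gly K-ace K-met R-met` |

### Species manifest (`species.yaml`)
```yaml
species:
  <name>:
    category: monocot | dicot
    fasta: <path>
    disorder: <path>
    sites:
      <ptm_type>: <path>
```
Relative paths resolve against the manifest's directory.

### Synthetic config (`synth.yaml`)
Keys of `disptm.synth.SynthConfig`: `n_proteins`, `length_law`
(`[fixed, L]`, `[uniform, a, b]` or `[lognormal, mu, sigma]`),
`disorder_frac`, `block_dis`, `block_ord` (optional, derived),
`ptm_rates`, `enrichment`, `composition` (optional), `seed`.

## Outputs (`run-all`)

* `<species>_dataset_stats.tsv` — `species, n_input, n_after_redundancy,
  n_after_length, mean_length`.
* `<species>_disorder.tsv` — per protein `protein_id, L, Ld, fraction,
  n_segments`; final `__proteome__` row carries the residue-weighted
  proteome degree (as a fraction).
* `<species>_content.tsv` — `species, ptm_type, total_sites,
  total_residues, per_400`.
* `<species>_rdo.tsv` — `species, category, ptm_type, Nd, No, Ld, Lo,
  rdo, undefined` (`undefined=1` flags No = 0).
* `<species>_bins.tsv` — `species, ptm_type, bin_ordinal, bin_label,
  n_proteins, mean_disorder` (labels `0..>=k`).
* `<species>_correlations.tsv` — `species, ptm_type, r, n, t,
  p_one_tailed` (n = populated bins).
* `table1_like.tsv` — species × PTM grid; per species an `r` row
  (3 decimals) above a `p` row (4 decimals, `<0.0001` floor).
* `contrasts.tsv` — `statistic, ptm_type, mean_monocot, mean_dicot,
  difference, t, p_two_tailed, method` (Welch's t, labelled a stand-in).
* `summary.json` — version, config hash, seed, per-species degree.

`simulate` additionally writes `truth.yaml` with the planted enrichment
and the realized `Nd/No/Ld/Lo` per PTM type.
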