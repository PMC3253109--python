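# qpcrkit

Analysis toolkit for relative gene-expression quantification from raw
RT-qPCR threshold-cycle (Ct) data. It chains five stages:

1. **efficiency** — per-gene PCR amplification efficiency from serially
   diluted standards (OLS of Ct on log10 relative concentration,
   `E = 10^(-1/slope) - 1`).
2. **stability** — reference-gene ranking by iterative M-value exclusion:
   a gene's M is the mean SD of its log2 expression ratios against every
   other panel gene; the least stable gene is removed each round until
   three remain, and ranks follow the reverse exclusion order.
3. **optimize** — pairwise variation V_n/n+1 (dispersion of
   log2 NF_n/NF_{n+1} across samples, NF = geometric-mean normalization
   factor) computed from V_1/2 upward; the minimal entry gives the optimal
   number of reference genes.
4. **normalize** — efficiency-corrected relative quantities calibrated to
   the control-type mean Ct, divided by the multi-gene normalizer; the
   control-type geometric mean of each target is 1 by construction.
5. **ratios** — fold change R = 2^d per (target, treatment), delta-method
   SE, pooled-variance two-tailed t-test, Benjamini–Hochberg FDR.

A synthetic-data generator (`qpcrkit.synthetic`) produces Ct tables with
known ground truth (true efficiencies, designed stability ordering,
per-sample loading offsets, designed fold changes) so every stage is
testable end to end.

## Input format

A long-format table (CSV/TSV, optionally xlsx) with five columns —
`gene`, `sample`, `type`, `serial`, `ct` (case-insensitive; remappable via
`column_map`). Standard dilution-series reactions are marked by their
`type` label (default `STD`, see `--standard-type`); `serial` is the
dilution level for standards and the technical-replicate index for
unknowns. Technical replicates are collapsed by mean Ct. Missing Ct
(`Undetermined`, `N/A`, ...) is excluded with a warning.

Each stage writes one TSV named after its sheet: `Efficiency`, `M_value`,
`Pairwise_V`, `Exp_R` (per-sample normalized expression), `Exp_ratio`.

## CLI

```sh
# simulate a dataset with the default shape (19 refs + 9 targets, 3 types)
qpcrkit simulate --seed 1 --out raw_ct.tsv

qpcrkit validate raw_ct.tsv

# stage by stage (later stages read earlier sheets from --out-dir) ...
qpcrkit efficiency raw_ct.tsv --dilut 10 --grad 5 --out-dir out
qpcrkit stability  raw_ct.tsv --e-excluded 0.95 --references Ref01,Ref02,... --out-dir out
qpcrkit optimize   raw_ct.tsv --control C05 --out-dir out
qpcrkit normalize  raw_ct.tsv --control C05 --out-dir out   # auto top-n refs
qpcrkit ratios     --control C05 --targets Tgt1,Tgt2 --out-dir out

# ... or everything at once (byte-identical to the stage-wise route)
qpcrkit run-all raw_ct.tsv --control C05 --references Ref01,... --out-dir out
```

`run-all` also accepts a YAML config (`--config run.yaml`; flags win) and
writes a provenance log (`run_log.txt`) with all parameters. Exit codes:
0 success, 2 validation error, 3 stage error.

## Notes on conventions

- Efficiencies are fractions internally (1.0 = perfect doubling); report
  columns also print percent.
- All logs are base 2; the base rescales M and V uniformly and never
  changes a ranking.
- V_n/n+1 uses the standard deviation by default (`--v-metric variance`
  switches); ties in the V minimum favor fewer genes.
- Exact-tie exclusion/ranking order is broken lexicographically for
  reproducibility.
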