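# sdrscan

Segregation-distortion analysis for outbred diploid (CP-type) F1 mapping
populations, plus a cross simulator that provides ground truth for every
analysis stage.

Markers follow JoinMap-style CP coding: maternal `<lmxll>` (codes `ll`/`lm`),
paternal `<nnxnp>` (`nn`/`np`), and biparental `<hkxhk>` (`hh`/`hk`/`kk`).
Linkage phase per parent follows the convention that homolog `phase + 1`
carries the segregating (marked) allele.

## What it does

- **I/O and map utilities** (`sdrscan.io`) — genotype/map TSV reading and
  writing with validation, collapse of redundant markers into bins, and
  map comparison (shared markers, chromosome discordance, order
  concordance).
- **Cross simulator** (`sdrscan.simulate`) — no-interference (Poisson)
  meiosis on arbitrary chromosome maps, with gametic transmission bias,
  single-locus zygotic viability selection, and two-locus viability
  incompatibilities, all by rejection sampling; returns genotype codes and
  a truth record of transmitted homologs and crossover positions.
- **Distortion tests** (`sdrscan.distortion`) — per-locus chi-square tests
  of 1:1 and 1:2:1 segregation (no continuity correction), distortion
  ratios (larger:smaller class; homozygote classes for 1:2:1), ratio
  threshold filters (1:10 and 1:5:5), and summary proportions at
  significance levels {0.05, 0.01, 0.001, 0.00001}.
- **SDR calling** (`sdrscan.sdr`) — chains of at least 6 significant loci
  (alpha = 0.001) with inter-locus gaps of at most 5 cM, called per
  chromosome and parent stream, with cM/Mb extents and peak loci.
- **Haplotype transmission** (`sdrscan.haplotypes`) — per-parent
  homolog-transmission frequency profiles from phased 1:1 loci, four-way
  maternal x paternal combination tests (1:1:1:1, df = 3), and per-progeny
  crossover counting.
- **Marey maps** (`sdrscan.marey`) — longest-non-decreasing-subsequence
  outlier pruning, monotone piecewise-cubic (PCHIP) interpolation, local
  cM/Mb rates from the derivative, chromosome/genome-wide averages, and
  OLS regression of distortion significance on local rate.
- **Epistasis scan** (`sdrscan.epistasis`) — phase-encoded allele codes at
  bin representatives, pairwise r² between unlinked loci with p from
  n·r² ~ chi²(1) (optional permutation mode), threshold p < 0.005, and a
  chromosome-pair summary.

## CLI

```sh
sdrscan --out-dir out simulate -c design.yaml        # genotype/map/truth TSVs
sdrscan --out-dir out distortion -g out/genotypes.tsv -m out/map.tsv
sdrscan --out-dir out sdr        -g out/genotypes.tsv -m out/map.tsv
sdrscan --out-dir out haplotypes -g out/genotypes.tsv -m out/map.tsv
sdrscan --out-dir out marey      -g out/genotypes.tsv -m out/map.tsv
sdrscan --out-dir out epistasis  -g out/genotypes.tsv -m out/map.tsv
sdrscan --out-dir out compare-maps -a map1.tsv -b map2.tsv
sdrscan --out-dir out run-all    -g out/genotypes.tsv -m out/map.tsv
```

Global flags: `--seed`, `--alpha`, `--out-dir`, `--log-level`.

A simulation design YAML looks like:

```yaml
n_progeny: 96
seed: 1
chromosomes:
  - {name: chr09, length_cM: 75, length_Mb: 60, seg_class: paternal, marker_spacing_cM: 1.0}
selections:
  - {kind: gametic, chromosome: chr09, position_cM: 68.0, parent: paternal, t: 0.722}
```

`seg_class` may be `maternal`, `paternal`, `biparental`, `mixed` (cycling),
or an explicit per-marker list.  Selection kinds: `gametic` (`parent`, `t`),
`zygotic` (`viability` over `M1P1`/`M1P2`/`M2P1`/`M2P2` homolog combos at
one position), and `zygotic_pair` (`chromosome_b`, `position_cM_b`;
viability over the maternal homolog at the first locus crossed with the
paternal homolog at the second).

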