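# designvar

Tools for asking how well computationally designed protein sequences cover
the sequence space of their natural homologs. Given, per protein structure,
an alignment of natural sequences, one or more alignments of designed
sequences (e.g. fixed-backbone designs or flexible-backbone designs over a
temperature sweep) and the native structure's per-residue solvent
accessibility, `designvar` computes:

- **Site entropy** `H_i = -Σ_j p_ij ln p_ij` (nats) — the variability of
  alignment column *i*, and its per-alignment mean.
- **KL divergence** `D_i = Σ_j p_ij ln(p_ij / q_ij)` of the designed
  frequencies `p` against the natural reference frequencies `q`, with a
  pseudocount of 1/20 added to every residue count to keep frequencies
  strictly positive, averaged over sites per protein.
- **Rank-ordered KL divergence** — the same sum after sorting both 20-vectors
  by descending frequency, comparing frequencies at equal rank: a pure
  distribution-*shape* comparison that ignores residue identity.
- **RSA and exposure classes** — DSSP ACC values normalised by per-residue
  maximum ASA (Tien 2013 theoretical scale by default); buried
  (RSA ≤ 0.05), partially buried (0.05 < RSA ≤ 0.25) and exposed
  (RSA > 0.25), with a two-class split at 0.05 for pooled amino-acid
  frequency tables.
- **Entropy–RSA correlations** per protein and condition, exposure-class
  entropy summaries, a natural split-half control (mean KL of one random
  half of the natural alignment against the other), and **hybrid designs**
  that splice core columns from one design condition with surface columns
  from another.

A synthetic-data module generates natural-like alignments (site variability
increasing with RSA, hydrophobic-enriched cores) and designed-like
alignments (Boltzmann sampling from per-site energies at a temperature-like
parameter, never containing Cys) with full ground truth, so the entire
pipeline is testable without any structural data or design software.

## Worked example

`examples/03_temperature_sweep.py` generates the default synthetic scenario
(150 sites, 100 natural sequences, 500 designs per temperature) and sweeps
the design temperature:

```
natural mean entropy: 1.589 nats
natural entropy-RSA correlation: 0.821
split-half control KL: 0.235 nats

    T  meanH     KL  rankKL      r
 0.03  0.046  1.318  0.9045  0.146
  0.1  0.268  1.144  0.7305  0.325
  0.3  1.060  0.782  0.2984  0.557
  0.6  2.063  0.963  0.4028  0.550
  0.9  2.524  1.353  0.8307  0.497
  1.2  2.711  1.648  1.1564  0.499
  1.8  2.836  1.929  1.5077  0.462
  2.4  2.879  2.104  1.6992  0.426
```

Designed variability (`meanH`) rises monotonically with temperature and
brackets the natural value; the divergence against natural sequences stays
well above the split-half control at every temperature; the rank-ordered KL
reaches its minimum at an intermediate temperature, where the designed
frequency *shapes* best match the natural ones; and no single temperature
reproduces the natural entropy–RSA correlation (0.82) — designed variability
is too uniform across exposure classes. `examples/04_hybrid_designs.py`
shows that a hybrid taking buried/partially-buried columns from T = 0.3 and
exposed columns from T = 0.6 restores a natural-like correlation (0.818).

The other examples cover single-column statistics, DSSP/RSA handling and the
end-to-end pipeline; each prints a short interpretation of its numbers.

## Command line

```sh
designvar synth --out data/ --seed 7        # write a synthetic scenario
designvar run   --config config.yml         # multi-protein pipeline run
designvar stats --alignment aln.fasta       # quick entropy summary
```

The run config is a single YAML file listing per protein the natural
alignment, the designed alignments keyed by condition tag, and either a
classic DSSP file plus chain or a precomputed RSA table; outputs are TSV
reports (per-protein metrics, condition summaries, class entropies, pooled
class frequencies, hybrids, failures) plus a log. Failures are isolated per
protein and re-runs are byte-identical.

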