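# opsinadapt

Analysis toolkit for studying depth-related visual-pigment adaptation in
haplochromine cichlid fishes — or any system where opsin alleles, their
molecular evolution and their spectral phenotypes need to be analyzed
together. The package chains the computational steps such a study needs:

* **Allele grouping** — haplotypes are translated and partitioned into
  amino-acid allele groups (synonymous variants collapsed, since they do not
  tune the pigment), with polymorphic-site tables labeling every variable
  column synonymous (`s`) or nonsynonymous (`n`), and allele-frequency
  tables stratified by species, locality or sampling depth.
* **Synonymous/nonsynonymous divergence** — Nei–Gojobori (1986) counting
  with equal pathway weights and Jukes–Cantor correction, averaged over all
  sequence pairs (mean Ds, Dn per gene).
* **HKA neutrality test** — the Hudson–Kreitman–Aguadé test of heterogeneity
  in the polymorphism/divergence ratio between two linked regions (e.g. a
  gene versus its flanks, with a designated outgroup allele), by method of
  moments with a χ²(1) or coalescent-simulation p-value.
* **Population structure** — Hudson's FST = 1 − Hw/Hb between species from
  haplotype alignments, and minimum-FST partner search.
* **Allele phylogenies** — IUPAC heterozygote expansion, Jukes–Cantor
  distances, Saitou–Nei neighbor joining with deterministic tie-breaking,
  and column-bootstrap supports.
* **Spectral analysis** — dark-minus-bleached difference spectra, λmax with
  standard errors from replicate curves, empirical standard-template
  construction, and estimation of the A1/A2 chromophore ratio of a
  photoreceptor by adjusting a template mixture to microspectrophotometry
  (MSP) data.
* **Synthetic data** — structured-coalescent sequence simulation, planted
  amino-acid allele alignments and Govardovskii-template pigment spectra
  with known ground truth, so the whole chain is testable without field
  data.

## The core statistics

For a sample of *n* sequences, the HKA model sets E[S] = θ·a_n with
a_n = Σ_{j<n} 1/j for within-group segregating sites, and E[D] = θ(T+1)
for mean divergence to a single outgroup lineage that split T coalescent
time units ago. The goodness-of-fit statistic over two regions is

    X² = Σ_i [(S_i − Ê S_i)²/Var̂ S_i + (D_i − Ê D_i)²/Var̂ D_i],

with Var S = θa_n + θ²b_n (b_n = Σ 1/j²) and Var D = θ(T+1) + θ², compared
to χ² with one degree of freedom.

A measured photoreceptor spectrum is modeled as
(1−φ)·A1(λ; λmax₁) + φ·A2(λ; λmax₂); the A2 fraction φ is found by grid
search, matching either the observed peak wavelength (`peak-match`) or the
full unit-peak curve (`curve-match`).

## Worked example

```python
import opsinadapt as oa

# estimate the A2 chromophore fraction of a rod photoreceptor
a1 = oa.simulate_spectrum(oa.SimSpectrumParams(503.0, 523.0, 0.0, 0.0))
a2 = oa.simulate_spectrum(oa.SimSpectrumParams(503.0, 523.0, 1.0, 0.0))
obs = oa.simulate_spectrum(oa.SimSpectrumParams(503.0, 523.0, 0.6, 0.005, seed=7))
fit = oa.fit_a1_a2_mixture(a1, a2, observed=obs, mode="curve-match")
print(f"A2 fraction {fit.a2_fraction:.2f}, mixture lambda-max {fit.lambda_max:.1f} nm")

# HKA test of a gene region against its flank
params = oa.SimSequenceParams(theta_per_region=5.0, divergence_time=2.0,
                              n_ingroup=20, seed=1)
(aln_up, aln_gene), (out_up, out_gene) = oa.simulate_two_region_data(params)
res = oa.hka_test(oa.region_counts(aln_up, out_up, "up"),
                  oa.region_counts(aln_gene, out_gene, "gene"))
print(f"X2 = {res.X2:.3f}, p = {res.p_chi2:.3f}")
```

prints

```
A2 fraction 0.59, mixture lambda-max 512.3 nm
X2 = 0.911, p = 0.340
```

The recovered A2 fraction matches the simulated 0.60 to one grid step; the
mixture peak sits between the A1 (503 nm) and A2 (523 nm) pigment peaks.
The HKA p-value of 0.34 does not reject ratio homogeneity for these two
neutral regions.

The same stages are available from the shell:

```bash
opsinadapt run --outdir demo --seed 4        # full demo pipeline
opsinadapt hka --fasta region1.fasta --fasta region2.fasta --out hka.csv
opsinadapt unmix --observed obs.csv --template-a1 a1.csv --template-a2 a2.csv
```

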