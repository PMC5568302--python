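# Methods

This note documents the models behind each analysis stage, the conventions
and defaults that matter, what the synthetic-data generators do and do not
emulate, and the design choices made where more than one convention is in
use in the field.

## Sequence containers and conventions

All sequence operations work on equal-length nucleotide alignments.
Coding-region coordinates are given as 1-based inclusive intervals (the
convention of published residue numbering) and converted internally to
0-based half-open slices. IUPAC ambiguity codes are accepted everywhere;
operations that need unambiguous bases drop affected columns either
listwise (HKA region counting: a column is excluded for all sequences if
any sequence is ambiguous there) or pairwise (distances, FST: a column is
excluded only for the pairs it affects). Gap columns inside a coding
region are removed before translation, with a warning, since the opsin
coding alignments this package targets are gap-free.

## Amino-acid allele groups

Haplotypes are translated with the standard genetic code; a codon whose
IUPAC expansions disagree translates to `X`, and an internal stop produces
a warning but not a failure (the haplotype is still reported). Groups are
the equivalence classes of exact protein identity — synonymous variants
collapse into one functional allele. When reference proteins are supplied
the groups inherit their names; otherwise labels are assigned in order of
first occurrence. A haplotype with `X` at a nonsynonymous position (an
unphased heterozygous call) is assigned only if exactly one reference
protein is compatible with it; otherwise it is reported unresolved. This
is a stated convention for direct-sequencing data, not an inference.

Polymorphic-site tables label a column `s` when substituting every
observed variant into every observed codon context leaves each context's
translation unchanged, and `n` otherwise; columns outside the coding
region are `noncoding`. Note the `s` rule is per-context: two codons may
differ nonsynonymously at *other* positions while a given column remains
synonymous.

## Synonymous/nonsynonymous distances

Nei–Gojobori (1986) counting. Each codon contributes fractional
synonymous sites (the fraction of its nine single-nucleotide neighbors
that preserve the residue); changes creating a stop codon count as
nonsynonymous, so the site counts always sum to 3 per codon. When a codon
pair differs at more than one position, all minimal single-step pathways
are enumerated and weighted equally; a step through a stop codon is
retained and classified nonsynonymous. Proportions ps = Sd/S and pn =
Nd/N receive the Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4
makes the distance undefined (reported as such, never infinite). Codons
with gaps/ambiguity in either sequence, and stop codons, are skipped
pairwise with site totals recomputed per pair. Gene-level values are
arithmetic means over all unordered pairs, with undefined pairs excluded
and counted. One practical consequence of the JC correction: a single
isolated codon with one synonymous difference has ps = 1 and therefore an
undefined ds — the correction needs surrounding synonymous sites.

## HKA test

Two genomic regions from the same ingroup sample (size n) are compared
against one outgroup sequence. The model has three parameters: θ₁, θ₂
(scaled mutation rates per region) and a shared split time T in units of
2N generations, with

    E[S_i] = θ_i a_n,   E[D_i] = θ_i (T + 1),
    Var[S_i] = θ_i a_n + θ_i² b_n,   Var[D_i] = θ_i (T + 1) + θ_i²,

where a_n, b_n are the first- and second-order harmonic numbers up to
n−1. The population-size ratio of the two lineages is fixed at 1 because
a single outgroup allele class leaves it unidentifiable. D is computed as
the mean pairwise difference count between ingroup sequences and the
outgroup (a declared convention; a single-sequence variant behaves nearly
identically).

The moment system — total S, total D, and the S+D total of the second
region — is solved by bounded least squares (θ ≥ 1e−9, T ≥ 0) started
from the closed-form interior solution; the same machinery absorbs
degenerate inputs such as S = 0 regions without special-casing. X² sums
the squared standardized residuals of all four observations; the default
p-value uses χ²(df = 1), and a coalescent-simulation p-value (parametric
bootstrap at the fitted parameters, refitting each replicate) is
available via `sim_reps`.

**Calibration.** The χ²(1) approximation is known to be conservative for
small counts, and the package's own simulations quantify this: at θ = 5,
T = 2, n = 2000-site regions and n = 20 sequences, the type-I error at
α = 0.05 is ≈ 0.030 (mean X² ≈ 0.76), approaching nominal as θT grows
(≈ 0.046 at T = 10). Two mechanisms are responsible: the model treats
S and D as independent although they share the ingroup genealogy
(correlation ≈ 0.18 at these parameters), and Var[D] is derived for a
single cross-species pair while the observed D averages over the sample.
Power against divergence-only alternatives is intrinsically modest with
two regions: three parameters are fitted to four observations, so a
divergence contrast is partially absorbed into θ̂₂ and T̂ — at a 5×
inflated split time the noise-free signal itself yields X² ≈ 4.1, barely
past the 5% threshold, and realized power is ≈ 0.5. Users needing exact
error control should prefer the simulation p-value.

## Hudson FST

FST = 1 − Hw/Hb with Hw the average of the two within-population mean
pairwise difference counts and Hb the between-population mean, computed
with pairwise deletion of gap/ambiguity sites. Hb = 0 leaves the value
undefined (flagged); negative estimates are reported as computed. The
estimator is a ratio statistic and carries an O(1/n) negative bias for
small samples; with samples of ~20 sequences per population (the scale of
mitochondrial control-region sampling in the studies this package
targets) the panmictic mean is within ±0.01 of zero. Minimum-FST partner
search skips undefined pairs and breaks ties by lexicographic label
order.

## Neighbor joining and bootstrap

Saitou–Nei agglomeration on Jukes–Cantor distances (the distance model is
a declared choice). Ties in the Q criterion are broken by joining the
pair whose sorted label pair (internal nodes labeled by their smallest
descendant leaf) is lexicographically smallest, making the topology
invariant to input order. A negative branch length is clamped to zero
with the excess transferred to its sister. The final three lineages are
joined by the three-point formulas, giving an unrooted tree with a
trifurcating root. Bootstrap supports resample alignment columns with
replacement, rebuild the tree, and report for each internal bipartition
of the point-estimate tree the percentage of replicates containing it
(default 1000 replicates). Heterozygote expansion splits biallelic IUPAC
codes into two allele sequences by a fixed convention (first listed base
to allele 1); multi-site phase is therefore arbitrary, and three- or
four-fold ambiguity is rejected with a site report.

## Spectral analysis

Absorbance curves live on strictly increasing wavelength grids;
mismatched grids are linearly interpolated onto their overlap. λmax is
the vertex of a quadratic fitted to the points within ±10 nm of the grid
argmax (window configurable; default 20 nm total) — robust to 1 nm grid
quantization, recovering a noiseless peak to well under 0.1 nm. A peak on
the window boundary is an error (peak not bracketed). Replicate curves
give a mean and standard error of the mean.

Standard templates are built by rescaling each curve to unit peak,
shifting it so its λmax sits at zero offset, averaging pointwise on the
common peak-relative grid, smoothing with a centered moving average
(default 5 nm) and renormalizing. The A1/A2 fit evaluates the mixture
(1−φ)·A1 + φ·A2 on a φ grid of step 0.01 and minimizes either
|λmax(mixture) − λmax(observed)| (`peak-match`, the default, appropriate
when only the measured peak is trusted) or the unit-peak sum of squared
residuals (`curve-match`, stricter, preferred when the full curve is
available). An observed peak outside the [A1, A2] interval clamps φ to 0
or 1 with a warning. Reported A2 percentages are conventionally rounded
to whole percent.

## Synthetic data: what it does and does not emulate

*Sequences.* The two-region generator simulates, per region, a two-species
structured coalescent: the n ingroup lineages coalesce as a standard
Kingman coalescent; at the split time T (times a per-region inflation
factor, the selection alternative) the single outgroup lineage joins and
coalescence continues in the ancestral population. Mutations fall on
lineages at rate θ/2 and occupy distinct sites (infinite-sites emulation
on the finite region; exceeding the region length is an explicit error).
This yields E[S] = θ a_n and E[D] = θ(T·inflation + 1) exactly, with the
full coalescent variance structure — which the package's calibration
experiments rely on. Not emulated: recombination within regions,
selection with linkage, demography, back-mutation.

*Coding alleles.* Planted alignments in which every pair of groups
differs at exactly the requested number of residues (each planted
position carries one distinct amino acid per group) and each group
segregates the requested number of third-position synonymous sites.
Stop-codon-free by construction. Real coding data differ in having
overlapping, non-planted substitution patterns; the generator's purpose
is exact ground truth for partition recovery and site labeling.

*Spectra.* Govardovskii et al. (2000) alpha-band nomograms for A1 and A2
pigments, mixed at a known φ, peak-normalized, plus i.i.d. Gaussian
noise. The default grid is 350–750 nm at 1 nm, spanning all cichlid opsin
peaks with margin. Beta bands, baseline drift and instrument effects are
not modeled, so recovery results bound performance on clean difference
spectra, not raw instrument traces. Default noise in the recovery
experiments is 0.5% of peak absorbance, the scale of averaged MSP
records; default template anchors are the documented cichlid values
(rod 503/523 nm; long-wavelength cone 544/595 nm).

*Allele counts.* Multinomial draws per species from specified mixture
probabilities with attached depth metadata, for frequency-table testing.

## Problem sizes and defaults

Calibration experiments use 1000 neutral and 500 alternative replicates
at θ = 5, T = 2, n = 20 and 2000-site regions (the flank sizes typical of
the opsin loci analyzed, ≈1.9 kb); chromophore recovery uses 100
replicates per φ ∈ {0, 0.25, 0.5, 0.75, 1}; topology recovery uses 100
random 8-taxon additive matrices; FST panmixia uses 200 splits of
40-sequence samples. The demo pipeline runs end to end in seconds with
bootstrap reduced to a few dozen replicates; production bootstrap default
is 1000.

## Known limitations

* The HKA χ² p-value is conservative for small θT (quantified above);
  the simulation p-value is the calibrated alternative.
* Two-region HKA has limited power against divergence-only alternatives
  by construction (three parameters, four observations).
* No statistical phasing: heterozygote expansion is a convention, and
  allele grouping of ambiguous haplotypes requires reference proteins.
* Maximum-likelihood dN/dS, multi-locus HKA, AMOVA/ΦST, and
  parsimony/likelihood tree inference are out of scope; only the methods
  listed above are implemented.
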