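"""Synthetic-data generators with known ground truth.

Three generators cover the data types the analysis pipeline consumes:

* :func:`simulate_two_region_data` — within-group polymorphism and outgroup
  divergence at two linked regions under a neutral coalescent with a
  per-region divergence-inflation knob (the selection alternative for the
  HKA test).
* :func:`simulate_coding_alleles` — codon alignments whose haplotypes fall
  into amino-acid allele groups with a controlled budget of nonsynonymous
  between-group and synonymous within-group differences.
* :func:`simulate_spectrum` — noisy absorbance curves of visual pigments as
  mixtures of A1 (retinal) and A2 (3-dehydroretinal) alpha-band templates
  with known peak wavelengths and mixing fraction.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import Alignment

_BASES = np.array(list("ACGT"))

# Codons free of stop codons used as neutral background filler.
_SAFE_CODONS = [
    "GCT", "GCC", "GCA", "GCG",  # Ala
    "GGT", "GGC", "GGA", "GGG",  # Gly
    "CCT", "CCC", "CCA", "CCG",  # Pro
    "ACT", "ACC", "ACA", "ACG",  # Thr
    "GTT", "GTC", "GTA", "GTG",  # Val
    "CTT", "CTC", "CTA", "CTG",  # Leu
]

# One codon per amino acid, used to plant between-group replacements;
# ordered so group g receives the g-th entry.
_AA_CODONS = [
    ("A", "GCT"), ("C", "TGT"), ("D", "GAT"), ("E", "GAA"), ("F", "TTT"),
    ("G", "GGT"), ("H", "CAT"), ("I", "ATT"), ("K", "AAA"), ("L", "CTT"),
    ("M", "ATG"), ("N", "AAT"), ("P", "CCT"), ("Q", "CAA"), ("R", "CGT"),
    ("S", "TCT"), ("T", "ACT"), ("V", "GTT"), ("W", "TGG"), ("Y", "TAT"),
]

# Fourfold-degenerate codon pair used to plant synonymous polymorphism.
_SYN_PAIR = ("GGT", "GGC")  # both Gly


# ---------------------------------------------------------------------------
# Two-region polymorphism / divergence generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimSequenceParams:
    """Parameters of the two-region neutral/selection generator.

    ``theta_per_region`` is the scaled mutation rate per region (the
    Watterson θ, so the expected number of segregating sites in a sample of
    n is θ·a_n with a_n = Σ_{j<n} 1/j).  ``divergence_time`` is the
    ingroup–outgroup split time T in coalescent units of 2N generations;
    expected mean pairwise divergence to the outgroup is θ(T+1).
    ``divergence_inflation`` multiplies T per region — 1.0 in both regions
    is the neutral null, a value > 1 mimics accelerated divergence of one
    region.
    """

    theta_per_region: float
    divergence_time: float
    n_ingroup: int
    region_lengths: tuple[int, ...] = (2000, 2000)
    divergence_inflation: tuple[float, ...] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta_per_region < 0:
            raise ValueError("theta_per_region must be >= 0")
        if self.divergence_time < 0:
            raise ValueError("divergence_time must be >= 0")
        if self.n_ingroup < 2:
            raise ValueError("n_ingroup must be >= 2")
        if len(self.region_lengths) != len(self.divergence_inflation):
            raise ValueError("region_lengths and divergence_inflation lengths differ")
        if any(L <= 0 for L in self.region_lengths):
            raise ValueError("region_lengths must all be > 0")
        if any(f <= 0 for f in self.divergence_inflation):
            raise ValueError("divergence_inflation must all be > 0")


def _structured_coalescent_mutations(
    n: int, theta: float, split_time: float, rng: np.random.Generator
) -> list[frozenset[int]]:
    """Two-species coalescent mutations for n ingroup samples + 1 outgroup.

    The n ingroup lineages coalesce as a Kingman coalescent (waiting times
    exponential with rate j(j−1)/2 while j lineages remain, time in units
    of 2N generations).  At ``split_time`` before present the single
    outgroup lineage (leaf index n) joins and coalescence continues in the
    ancestral population.  Mutations fall on every lineage as a Poisson
    process of rate θ/2 and are returned as the sets of leaves (0..n, with
    n = outgroup) carrying them.  The induced ingroup genealogy is exactly
    Kingman, so E[S_ingroup] = θ·a_n; the marginal ingroup–outgroup pair
    coalescence gives E[pairwise divergence] = θ·(T+1).
    """
    lineages: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    muts: list[frozenset[int]] = []

    def _drop(duration: float) -> None:
        if theta > 0 and duration > 0:
            counts = rng.poisson(theta / 2.0 * duration, size=len(lineages))
            for lin, c in zip(lineages, counts):
                muts.extend([lin] * int(c))

    def _merge() -> None:
        a, b = rng.choice(len(lineages), size=2, replace=False)
        merged = lineages[a] | lineages[b]
        lineages[:] = [l for k, l in enumerate(lineages) if k not in (a, b)]
        lineages.append(merged)

    # within-species phase: only ingroup lineages, capped at the split time
    elapsed = 0.0
    while len(lineages) > 1:
        j = len(lineages)
        wait = rng.exponential(2.0 / (j * (j - 1)))
        if elapsed + wait >= split_time:
            _drop(split_time - elapsed)
            elapsed = split_time
            break
        _drop(wait)
        elapsed += wait
        _merge()
    else:
        # ingroup fully coalesced before the split: idle until the split
        _drop(split_time - elapsed)

    # the outgroup lineage accrues its own mutations over the split phase,
    # then joins the ancestral population
    if theta > 0 and split_time > 0:
        muts.extend([frozenset([n])] * int(rng.poisson(theta / 2.0 * split_time)))
    lineages.append(frozenset([n]))
    while len(lineages) > 1:
        j = len(lineages)
        wait = rng.exponential(2.0 / (j * (j - 1)))
        _drop(wait)
        _merge()
    return muts


def simulate_two_region_data(params: SimSequenceParams
                             ) -> tuple[list[Alignment], list[str]]:
    """Simulate ingroup alignments plus one outgroup sequence per region.

    Each region gets an independent two-species structured coalescent
    genealogy (n ingroup samples plus one outgroup lineage joining at the
    split time T·inflation), so the ingroup sample carries polymorphism
    with E[S] = θ·a_n and the mean pairwise ingroup↔outgroup difference has
    expectation θ·(T·inflation + 1).  Mutations occupy distinct sites
    (infinite-sites emulation on the finite region).

    Returns ``(ingroup_alignments, outgroup_sequences)``, one entry per
    region.

    Raises
    ------
    ValueError
        If the number of requested mutations exceeds a region's length.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_ingroup
    theta = params.theta_per_region
    T = params.divergence_time

    alignments: list[Alignment] = []
    outgroups: list[str] = []
    for L, infl in zip(params.region_lengths, params.divergence_inflation):
        muts = _structured_coalescent_mutations(n, theta, T * infl, rng)
        total = len(muts)
        if total > L:
            raise ValueError(
                f"{total} mutations requested but region has only {L} sites; "
                "increase region length or lower theta/T"
            )
        bases = np.frombuffer(b"ACGT", dtype="S1")
        ref_idx = rng.integers(0, 4, size=L)
        sites = rng.choice(L, size=total, replace=False)
        # derived state: shift the reference base by 1-3 (mod 4), never equal
        shifts = rng.integers(1, 4, size=total)
        derived_idx = (ref_idx[sites] + shifts) % 4
        # row n is the outgroup lineage
        seq_idx = np.tile(ref_idx, (n + 1, 1))
        for k, carriers in enumerate(muts):
            seq_idx[list(carriers), sites[k]] = derived_idx[k]
        ids = [f"ingroup_{i}" for i in range(n)]
        seq_bytes = bases[seq_idx]
        alignments.append(Alignment(
            ids, [seq_bytes[i].tobytes().decode("ascii") for i in range(n)]))
        outgroups.append(seq_bytes[n].tobytes().decode("ascii"))
    return alignments, outgroups


# ---------------------------------------------------------------------------
# Coding-allele generator
# ---------------------------------------------------------------------------

def simulate_coding_alleles(
    n_groups: int,
    n_haplotypes_per_group: int,
    codon_count: int,
    aa_diffs_between_groups: int = 0,
    syn_diffs_within_group: int = 0,
    seed: int = 0,
) -> tuple[Alignment, dict[str, str]]:
    """Codon alignment whose haplotypes form known amino-acid allele groups.

    Every pair of groups differs at exactly ``aa_diffs_between_groups``
    residues (each planted position carries a distinct amino acid per
    group).  Within each group, ``syn_diffs_within_group`` third-position
    synonymous sites segregate, so haplotypes of one group translate
    identically but are not nucleotide-identical.  No stop codons are
    produced.

    Returns the alignment and a ``{haplotype_id: group_label}`` truth map;
    group labels are ``"G0"``, ``"G1"``, …

    Raises
    ------
    ValueError
        If the requested difference budget does not fit in ``codon_count``
        codons, if ``n_groups`` exceeds the 20 plantable amino acids, or if
        within-group polymorphism is requested for singleton groups.
    """
    if n_groups < 1 or n_haplotypes_per_group < 1 or codon_count < 1:
        raise ValueError("counts must be positive")
    if n_groups > len(_AA_CODONS):
        raise ValueError(f"at most {len(_AA_CODONS)} groups supported")
    if syn_diffs_within_group > 0 and n_haplotypes_per_group < 2:
        raise ValueError("within-group polymorphism needs >= 2 haplotypes per group")
    needed = aa_diffs_between_groups + n_groups * syn_diffs_within_group
    if needed > codon_count:
        raise ValueError(
            f"difference budget needs {needed} codons but only {codon_count} available"
        )

    rng = np.random.default_rng(seed)
    positions = rng.permutation(codon_count)
    aa_pos = sorted(positions[:aa_diffs_between_groups])
    cursor = aa_diffs_between_groups
    syn_pos_per_group: list[list[int]] = []
    for _ in range(n_groups):
        syn_pos_per_group.append(sorted(positions[cursor:cursor + syn_diffs_within_group]))
        cursor += syn_diffs_within_group

    background = [rng.choice(_SAFE_CODONS) for _ in range(codon_count)]

    ids: list[str] = []
    seqs: list[str] = []
    truth: dict[str, str] = {}
    for g in range(n_groups):
        label = f"G{g}"
        group_codons = list(background)
        for p in aa_pos:
            group_codons[p] = _AA_CODONS[g][1]
        for h in range(n_haplotypes_per_group):
            codons = list(group_codons)
            seqs.append("".join(codons))
            hid = f"{label}_h{h}"
            ids.append(hid)
            truth[hid] = label
        # plant synonymous polymorphism: a random proper nonempty subset of
        # the group's haplotypes carries the alternative synonymous codon
        base = len(seqs) - n_haplotypes_per_group
        for p in syn_pos_per_group[g]:
            k = int(rng.integers(1, n_haplotypes_per_group))
            carriers = rng.choice(n_haplotypes_per_group, size=k, replace=False)
            for h in carriers:
                s = seqs[base + h]
                seqs[base + h] = s[:3 * p] + _SYN_PAIR[1] + s[3 * p + 3:]
            for h in range(n_haplotypes_per_group):
                if h not in carriers:
                    s = seqs[base + h]
                    seqs[base + h] = s[:3 * p] + _SYN_PAIR[0] + s[3 * p + 3:]
    return Alignment(ids, seqs), truth


# ---------------------------------------------------------------------------
# Absorbance-spectrum generator
# ---------------------------------------------------------------------------

def govardovskii_a1(wavelengths: np.ndarray, lambda_max: float) -> np.ndarray:
    """Alpha-band absorbance template for A1 (retinal-based) pigments.

    Standard vertebrate visual-pigment nomogram parameterized by the peak
    wavelength; shape is invariant under λ/λmax rescaling.  Peak value ≈ 1
    at λmax.
    """
    x = lambda_max / np.asarray(wavelengths, dtype=float)
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    return 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )


def govardovskii_a2(wavelengths: np.ndarray, lambda_max: float) -> np.ndarray:
    """Alpha-band absorbance template for A2 (3-dehydroretinal) pigments."""
    x = lambda_max / np.asarray(wavelengths, dtype=float)
    A = 62.7 + 1.834 * np.exp((lambda_max - 625.0) / 54.2)
    a = 0.875 + 0.0268 * np.exp((lambda_max - 665.0) / 40.7)
    return 1.0 / (
        np.exp(A * (a - x))
        + np.exp(20.85 * (0.9101 - x))
        + np.exp(-10.37 * (1.1123 - x))
        + 0.5343
    )


DEFAULT_WAVELENGTH_GRID = np.arange(350.0, 751.0, 1.0)


@dataclass(frozen=True)
class SimSpectrumParams:
    """Parameters for a simulated A1/A2 pigment mixture spectrum.

    ``a2_fraction`` is the proportion φ of the A2 pigment in the mixture;
    the A2 peak must sit at a longer wavelength than the A1 peak, as the
    A2 chromophore substitution red-shifts absorbance.
    """

    lambda_max_a1: float
    lambda_max_a2: float
    a2_fraction: float
    noise_sd: float = 0.0
    wavelength_grid: np.ndarray = field(
        default_factory=lambda: DEFAULT_WAVELENGTH_GRID.copy()
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lambda_max_a2 > self.lambda_max_a1:
            raise ValueError("lambda_max_a2 must exceed lambda_max_a1")
        if not 0.0 <= self.a2_fraction <= 1.0:
            raise ValueError("a2_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        grid = np.asarray(self.wavelength_grid, dtype=float)
        if grid.ndim != 1 or grid.size < 3 or np.any(np.diff(grid) <= 0):
            raise ValueError("wavelength_grid must be strictly increasing")
        object.__setattr__(self, "wavelength_grid", grid)


def simulate_spectrum(params: SimSpectrumParams):
    """Noisy absorbance curve of an A1/A2 pigment mixture.

    The noiseless mixture (1−φ)·A1(λ; λmax_A1) + φ·A2(λ; λmax_A2) is
    normalized to peak 1, then Gaussian noise of sd ``noise_sd`` is added.
    Returns a :class:`~opsinadapt.spectra.SpectrumCurve`.
    """
    from .spectra import SpectrumCurve

    grid = params.wavelength_grid
    lo, hi = grid[0], grid[-1]
    if not (lo <= params.lambda_max_a1 <= hi and lo <= params.lambda_max_a2 <= hi):
        raise ValueError("wavelength_grid must bracket both lambda_max values")
    phi = params.a2_fraction
    clean = (1.0 - phi) * govardovskii_a1(grid, params.lambda_max_a1) \
        + phi * govardovskii_a2(grid, params.lambda_max_a2)
    clean = clean / clean.max()
    rng = np.random.default_rng(params.seed)
    noisy = clean + rng.normal(0.0, params.noise_sd, size=grid.size) \
        if params.noise_sd > 0 else clean
    return SpectrumCurve(grid, noisy, label=f"sim_phi{phi:.2f}")


# ---------------------------------------------------------------------------
# Depth-stratified allele-count tables
# ---------------------------------------------------------------------------

def simulate_allele_counts(
    species_mixtures: dict[str, dict[str, float]],
    n_per_species: int,
    depths: dict[str, float] | None = None,
    seed: int = 0,
):
    """Per-species allele-count table with depth metadata.

    ``species_mixtures`` maps species name → {allele label: probability};
    counts are multinomial draws of size ``n_per_species``.  Returns a
    pandas DataFrame with columns species, allele, count, depth_m.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for sp, mix in species_mixtures.items():
        alleles = sorted(mix)
        probs = np.array([mix[a] for a in alleles], dtype=float)
        probs = probs / probs.sum()
        counts = rng.multinomial(n_per_species, probs)
        for a, c in zip(alleles, counts):
            rows.append({
                "species": sp,
                "allele": a,
                "count": int(c),
                "depth_m": (depths or {}).get(sp, np.nan),
            })
    return pd.DataFrame(rows)


def write_spectrum_csv(curve, path: str | Path) -> None:
    """Write a spectrum as two-column CSV (wavelength_nm, absorbance)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["wavelength_nm", "absorbance"])
        for lam, ab in zip(curve.wavelengths, curve.absorbance):
            w.writerow([f"{lam:.6g}", f"{ab:.8g}"])
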