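"""Synonymous and nonsynonymous divergence (Nei–Gojobori counting).

Implements the classic Nei–Gojobori (1986) method: per-codon counting of
synonymous (S) and nonsynonymous (N) sites, equal-weight averaging over all
minimal mutational pathways when codons differ at more than one position,
and Jukes–Cantor correction of the resulting proportions.  Per-pair results
are aggregated as the arithmetic mean over all unordered sequence pairs —
the quantity used to contrast coding constraint across opsin genes.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

from .alleles import _forward_table

_STOPS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class DsDnResult:
    """Synonymous/nonsynonymous distance estimate for a pair or a set.

    ``ds``/``dn`` are Jukes–Cantor-corrected substitutions per synonymous /
    nonsynonymous site; ``None`` when the correction is undefined (observed
    proportion ≥ 3/4).  Site counts are fractional (Nei–Gojobori).
    """

    ds: float | None
    dn: float | None
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float = 0.0
    nonsyn_diffs: float = 0.0
    pairs_used: int = 1
    pairs_undefined: int = 0


def count_sites(codon: str, genetic_code: int = 1) -> tuple[float, float]:
    """Fractional synonymous and nonsynonymous site counts of one codon.

    At each position, the fraction of the three possible single-nucleotide
    changes that preserve the encoded residue counts toward synonymous
    sites; changes creating a stop codon count as nonsynonymous.  The two
    counts always sum to exactly 3.

    Raises
    ------
    ValueError
        For ambiguous codons; stop codons are rejected (they carry no
        residue to preserve).
    """
    codon = codon.upper()
    if any(b not in "ACGT" for b in codon) or len(codon) != 3:
        raise ValueError(f"ambiguous or malformed codon {codon!r}")
    if codon in _STOPS:
        raise ValueError("stop codons are excluded from site counting")
    fwd = _forward_table(genetic_code)
    aa = fwd[codon]
    syn = 0.0
    for pos in range(3):
        s_here = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if fwd[mutant] == aa:  # stop translates to '*', never equals aa
                s_here += 1
        syn += s_here / 3.0
    return syn, 3.0 - syn


def _codon_path_diffs(c1: str, c2: str, fwd: dict[str, str]) -> tuple[float, float]:
    """Mean synonymous/nonsynonymous difference counts between two codons.

    All minimal single-step pathways from ``c1`` to ``c2`` are enumerated
    and weighted equally; each step is synonymous iff it leaves the
    translation unchanged (a step to or from a stop codon is nonsynonymous).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_total = 0.0
    non_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = non = 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if fwd[cur] == fwd[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        syn_total += syn
        non_total += non
        n_paths += 1
    return syn_total / n_paths, non_total / n_paths


def _jc(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) if p > 0 else 0.0


def pairwise_ds_dn(seq1: str, seq2: str, genetic_code: int = 1) -> DsDnResult:
    """Nei–Gojobori ds/dn between two aligned coding sequences.

    Codons containing gaps or ambiguity in either sequence, and codons that
    are stops in either sequence, are skipped pairwise; site totals are the
    average of the two sequences' counts over the codons retained.
    Proportions ps = Sd/S and pn = Nd/N receive the Jukes–Cantor correction
    d = −(3/4)·ln(1 − 4p/3); a proportion ≥ 3/4 yields ``None`` with the
    pair flagged undefined.
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned (equal lengths)")
    if len(seq1) % 3 != 0:
        raise ValueError("length not divisible by 3")
    fwd = _forward_table(genetic_code)
    S = N = Sd = Nd = 0.0
    skipped_stop = False
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        if any(b not in "ACGT" for b in c1 + c2):
            continue
        if c1 in _STOPS or c2 in _STOPS:
            skipped_stop = True
            continue
        s1, n1 = count_sites(c1, genetic_code)
        s2, n2 = count_sites(c2, genetic_code)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = _codon_path_diffs(c1, c2, fwd)
        Sd += sd
        Nd += nd
    if skipped_stop:
        warnings.warn("stop codons skipped in ds/dn computation")
    if S <= 0 and N <= 0:
        raise ValueError("no comparable codons between the two sequences")
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ds, dn = _jc(ps), _jc(pn)
    return DsDnResult(
        ds=ds, dn=dn, syn_sites=S, nonsyn_sites=N,
        syn_diffs=Sd, nonsyn_diffs=Nd,
        pairs_undefined=int(ds is None or dn is None),
    )


def mean_ds_dn(alignment, genetic_code: int = 1) -> DsDnResult:
    """Mean pairwise ds and dn over all unordered pairs of an alignment.

    Pairs with an undefined (saturated) distance are excluded from the mean
    and counted in ``pairs_undefined``; if every pair is undefined a
    ``ValueError`` is raised.
    """
    ids = alignment.ids
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences")
    ds_vals: list[float] = []
    dn_vals: list[float] = []
    S = N = 0.0
    undefined = 0
    for i, j in itertools.combinations(range(len(ids)), 2):
        res = pairwise_ds_dn(alignment.seqs[i], alignment.seqs[j], genetic_code)
        if res.ds is None or res.dn is None:
            undefined += 1
            continue
        ds_vals.append(res.ds)
        dn_vals.append(res.dn)
        S += res.syn_sites
        N += res.nonsyn_sites
    if not ds_vals:
        raise ValueError("all pairwise distances undefined (saturation)")
    k = len(ds_vals)
    return DsDnResult(
        ds=sum(ds_vals) / k, dn=sum(dn_vals) / k,
        syn_sites=S / k, nonsyn_sites=N / k,
        pairs_used=k, pairs_undefined=undefined,
    )
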