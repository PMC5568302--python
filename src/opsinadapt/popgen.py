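"""Between-population differentiation (Hudson FST) from haplotype alignments.

FST is estimated as 1 − Hw/Hb where Hw is the average of the two
within-population mean pairwise difference counts and Hb the mean pairwise
difference count between populations (Hudson et al. 1992).  Sites with gaps
or ambiguity are dropped per pair.  Negative estimates are reported as
computed, with a flag, rather than truncated at zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .core import Alignment, hamming


@dataclass
class PopulationPair:
    pop1: str
    pop2: str
    fst: float | None
    hw: float
    hb: float
    negative: bool = False

    @property
    def undefined(self) -> bool:
        return self.fst is None


def _mean_within(seqs: list[str]) -> float:
    pairs = list(itertools.combinations(seqs, 2))
    if not pairs:
        return 0.0
    return sum(hamming(a, b)[0] for a, b in pairs) / len(pairs)


def _mean_between(seqs1: list[str], seqs2: list[str]) -> float:
    total = sum(hamming(a, b)[0] for a in seqs1 for b in seqs2)
    return total / (len(seqs1) * len(seqs2))


def pairwise_fst(pop1: Alignment, pop2: Alignment,
                 name1: str = "pop1", name2: str = "pop2") -> PopulationPair:
    """Hudson FST = 1 − Hw/Hb between two population samples.

    Hb = 0 (populations indistinguishable and monomorphic) leaves FST
    undefined (``None``) with the pair flagged.
    """
    if pop1.n < 2 or pop2.n < 2:
        raise ValueError("each population needs at least 2 sequences")
    if pop1.length != pop2.length:
        raise ValueError("populations are not aligned to the same length")
    hw = (_mean_within(pop1.seqs) + _mean_within(pop2.seqs)) / 2.0
    hb = _mean_between(pop1.seqs, pop2.seqs)
    if hb == 0:
        return PopulationPair(name1, name2, None, hw, hb)
    fst = 1.0 - hw / hb
    return PopulationPair(name1, name2, fst, hw, hb, negative=fst < 0)


def fst_matrix(populations: dict[str, Alignment]) -> list[PopulationPair]:
    """All pairwise Hudson FST values among labeled populations."""
    out = []
    for n1, n2 in itertools.combinations(sorted(populations), 2):
        out.append(pairwise_fst(populations[n1], populations[n2], n1, n2))
    return out


def min_fst_partner(focal: str, populations: dict[str, Alignment]
                    ) -> tuple[str, float]:
    """The candidate population least differentiated from ``focal``.

    Ties are broken by lexicographic label order; undefined pairs are
    skipped, and a ``ValueError`` is raised if every pair is undefined.
    """
    if focal not in populations:
        raise KeyError(focal)
    candidates = sorted(k for k in populations if k != focal)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate partners")
    best: tuple[str, float] | None = None
    for cand in candidates:
        pair = pairwise_fst(populations[focal], populations[cand], focal, cand)
        if pair.fst is None:
            continue
        if best is None or pair.fst < best[1]:
            best = (cand, pair.fst)
    if best is None:
        raise ValueError("FST undefined for every candidate pair")
    return best
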