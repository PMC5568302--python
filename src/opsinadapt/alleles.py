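"""Amino-acid allele grouping and polymorphic-site tables.

Opsin haplotypes that translate to the same protein are functionally
interchangeable (synonymous changes do not tune the pigment), so the unit
of analysis is the amino-acid allele group: the set of haplotypes sharing
one translated sequence.  This module translates coding regions, partitions
haplotypes into allele groups, labels polymorphic alignment columns as
synonymous ("s") or nonsynonymous ("n"), and tabulates allele frequencies
by species, locality or depth.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable

from .core import Alignment, Haplotype, IUPAC_CODES, GAP_CHARS

Interval = tuple[int, int]  # 1-based inclusive


def _forward_table(genetic_code: int = 1) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    fwd = dict(table.forward_table)
    for stop in table.stop_codons:
        fwd[stop] = "*"
    return fwd


def _cds_slice(sequence: str, cds_coords: list[Interval] | None) -> str:
    if cds_coords is None:
        return sequence
    parts = []
    for start, end in cds_coords:
        if not (1 <= start <= end <= len(sequence)):
            raise ValueError(f"CDS interval ({start}, {end}) outside sequence")
        parts.append(sequence[start - 1:end])  # 1-based inclusive -> 0-based half-open
    return "".join(parts)


def translate_codon(codon: str, fwd: dict[str, str]) -> str:
    """Translate one codon, resolving IUPAC ambiguity by expansion.

    If every expansion of an ambiguous codon encodes the same residue the
    residue is returned (e.g. GCN → A); otherwise 'X'.
    """
    try:
        choices = [IUPAC_CODES[b] for b in codon]
    except KeyError:
        return "X"
    residues = {fwd[a + b + c] for a, b, c in itertools.product(*choices)}
    return residues.pop() if len(residues) == 1 else "X"


def translate(sequence: str, cds_coords: list[Interval] | None = None,
              genetic_code: int = 1) -> str:
    """Translate the CDS of a nucleotide sequence to amino acids.

    ``cds_coords`` are 1-based inclusive intervals; their concatenation must
    be divisible by 3.  Gap columns within the CDS are removed with a
    warning before codon chopping.  Codons whose IUPAC expansion is
    ambiguous translate to ``X``.  An internal stop codon triggers a warning
    but translation (with ``*``) is still returned.
    """
    cds = _cds_slice(sequence.upper(), cds_coords)
    if any(ch in GAP_CHARS for ch in cds):
        warnings.warn("gap characters inside CDS removed before translation")
        cds = "".join(ch for ch in cds if ch not in GAP_CHARS)
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    fwd = _forward_table(genetic_code)
    protein = "".join(
        translate_codon(cds[i:i + 3], fwd) for i in range(0, len(cds), 3)
    )
    if "*" in protein[:-1]:
        warnings.warn("internal stop codon in translation")
    return protein


@dataclass
class AlleleGroup:
    """Haplotypes sharing one translated amino-acid sequence."""

    label: str
    protein: str
    member_ids: list[str] = field(default_factory=list)


def _compatible(protein: str, reference: str) -> bool:
    """True if `protein` (possibly containing X) can be `reference`."""
    if len(protein) != len(reference):
        return False
    return all(p == r or p == "X" for p, r in zip(protein, reference))


def group_alleles(
    haplotypes: list[Haplotype],
    cds_coords: list[Interval] | None = None,
    reference_proteins: dict[str, str] | None = None,
    genetic_code: int = 1,
) -> tuple[list[AlleleGroup], list[tuple[str, str]]]:
    """Partition haplotypes into amino-acid allele groups.

    Haplotypes are translated and grouped by exact protein identity.  When
    ``reference_proteins`` (label → protein) is given, groups matching a
    reference take its label so published allele names (H, M3, P, D, Ds, …)
    are reproduced; otherwise labels are ``A1``, ``A2``, … in order of first
    occurrence.  A haplotype whose translation contains ``X`` (ambiguity at
    a nonsynonymous site) is assigned only if exactly one reference protein
    is compatible with it; otherwise it is reported unresolved.

    Returns ``(groups, failures)`` where failures is a list of
    ``(haplotype_id, reason)``.
    """
    failures: list[tuple[str, str]] = []
    by_protein: dict[str, AlleleGroup] = {}
    order = 0

    def _label_for(protein: str) -> str:
        nonlocal order
        if reference_proteins:
            for lab, ref in reference_proteins.items():
                if protein == ref:
                    return lab
        order += 1
        return f"A{order}"

    for hap in haplotypes:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                protein = translate(hap.sequence, cds_coords, genetic_code)
        except ValueError as exc:
            failures.append((hap.id, f"translation failed: {exc}"))
            continue
        if "X" in protein:
            if reference_proteins:
                matches = [lab for lab, ref in reference_proteins.items()
                           if _compatible(protein, ref)]
                if len(matches) == 1:
                    ref = reference_proteins[matches[0]]
                    grp = by_protein.setdefault(
                        ref, AlleleGroup(matches[0], ref))
                    grp.member_ids.append(hap.id)
                    continue
            failures.append((hap.id, "ambiguous translation unresolved"))
            continue
        grp = by_protein.get(protein)
        if grp is None:
            grp = AlleleGroup(_label_for(protein), protein)
            by_protein[protein] = grp
        grp.member_ids.append(hap.id)
    return list(by_protein.values()), failures


def site_table(alignment: Alignment, cds_coords: list[Interval] | None = None,
               genetic_code: int = 1) -> pd.DataFrame:
    """Table of polymorphic alignment columns with s/n labels.

    Each polymorphic column is emitted with its 1-based position, a class —
    ``"s"`` if every observed variant leaves every overlapping observed
    codon's translation unchanged, ``"n"`` otherwise, ``"noncoding"``
    outside the CDS — and the nucleotide of each sequence.
    """
    fwd = _forward_table(genetic_code)
    # map alignment column (0-based) -> (codon positions tuple, offset)
    col_to_codon: dict[int, tuple[tuple[int, int, int], int]] = {}
    if cds_coords is not None:
        cds_cols: list[int] = []
        for start, end in cds_coords:
            cds_cols.extend(range(start - 1, end))
        if len(cds_cols) % 3 != 0:
            raise ValueError("CDS length not divisible by 3")
        for k in range(0, len(cds_cols), 3):
            codon_cols = tuple(cds_cols[k:k + 3])
            for off, c in enumerate(codon_cols):
                col_to_codon[c] = (codon_cols, off)
    else:
        if alignment.length % 3 != 0:
            raise ValueError("alignment length not divisible by 3 and no CDS given")
        for c in range(alignment.length):
            k = (c // 3) * 3
            col_to_codon[c] = ((k, k + 1, k + 2), c % 3)

    rows = []
    mat = alignment.matrix()
    for col in range(alignment.length):
        observed = set(mat[:, col])
        if len(observed) < 2:
            continue
        if col not in col_to_codon:
            cls = "noncoding"
        else:
            codon_cols, off = col_to_codon[col]
            contexts = {tuple(mat[i, list(codon_cols)]) for i in range(alignment.n)}
            synonymous = True
            for ctx in contexts:
                residues = set()
                for base in observed:
                    codon = list(ctx)
                    codon[off] = base
                    residues.add(translate_codon("".join(codon), fwd))
                if len(residues) > 1:
                    synonymous = False
                    break
            cls = "s" if synonymous else "n"
        row = {"position": col + 1, "class": cls}
        row.update({sid: mat[i, col] for i, sid in enumerate(alignment.ids)})
        rows.append(row)
    columns = ["position", "class"] + list(alignment.ids)
    return pd.DataFrame(rows, columns=columns)


def allele_frequencies(
    groups: list[AlleleGroup],
    haplotypes: list[Haplotype],
    stratify_by: str = "species",
) -> pd.DataFrame:
    """Allele counts and proportions per stratum.

    ``stratify_by`` names a :class:`Haplotype` metadata field (``species``,
    ``locality`` or ``depth_m``).  Missing metadata falls in the
    ``"unknown"`` stratum.  Proportions sum to 1 within each stratum and
    the dominant allele per stratum is flagged.
    """
    meta = {h.id: getattr(h, stratify_by, None) for h in haplotypes}
    rows = []
    for grp in groups:
        for mid in grp.member_ids:
            value = meta.get(mid)
            stratum = "unknown" if value in (None, "") else value
            rows.append({"stratum": stratum, "allele": grp.label})
    if not rows:
        return pd.DataFrame(
            columns=["stratum", "allele", "count", "frequency", "dominant"])
    df = (pd.DataFrame(rows).groupby(["stratum", "allele"]).size()
          .rename("count").reset_index())
    df["frequency"] = df["count"] / df.groupby("stratum")["count"].transform("sum")
    df["dominant"] = df.groupby("stratum")["frequency"].transform("max") == df["frequency"]
    return df.sort_values(["stratum", "allele"]).reset_index(drop=True)
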