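"""Site classification for coding and noncoding alignment columns.

Fractional synonymous / non-synonymous site counts follow Nei & Gojobori
(1986): for every reference codon all nine single-base changes are
enumerated against the standard genetic code, and each codon position
contributes the fraction of its three possible changes that are
synonymous. Changes creating a stop codon count as non-synonymous.
Counts are computed on a single designated reference row (configurable),
so class totals depend only on the reference and the annotation, never on
which other accessions are present.

"Silent" sites are synonymous coding positions plus noncoding (UTR or
intron) positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .io import AlignedLocus, BASES, GeneAnnotation

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

SITE_CLASSES = ("synonymous", "nonsynonymous", "silent", "all")

#: per-column structural labels
NONCODING = "noncoding"
CODING = "coding"
SKIPPED = "skipped"  # gap/N/? in the reference codon, or out of frame


def _translate(codon: str) -> str:
    if codon in _STANDARD.stop_codons:
        return "*"
    return _STANDARD.forward_table[codon]


def codon_syn_fractions(codon: str) -> tuple[float, float, float]:
    """Per-position synonymous fractions of a codon's nine single-base changes.

    Returns (f1, f2, f3) where f_i is the fraction of the three possible
    substitutions at codon position i that preserve the encoded amino
    acid. Reference stop codons return zeros (they are excluded upstream).
    """
    if codon in _STANDARD.stop_codons:
        return (0.0, 0.0, 0.0)
    aa = _translate(codon)
    fracs = []
    for i in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1:]
            if mut not in _STANDARD.stop_codons and _translate(mut) == aa:
                syn += 1
        fracs.append(syn / 3.0)
    return tuple(fracs)


_COMPLEMENT = str.maketrans("ACGTN?-", "TGCAN?-")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SiteClassMap:
    """Per-column site classes and fractional site counts for one locus.

    ``column_label`` holds the structural label of each alignment column
    (noncoding / coding / skipped); ``syn_weight`` holds the Nei–Gojobori
    synonymous fraction of coding columns (0 elsewhere);
    ``polymorphism_class`` labels columns by their observed variation:
    ``synonymous-eligible`` if every observed non-reference base is a
    synonymous change, ``nonsynonymous-eligible`` if every one is
    non-synonymous, ``mixed`` if both kinds occur (counted only in "all").
    """

    locus_id: str
    reference_id: str
    column_label: np.ndarray  # (L,) of {noncoding, coding, skipped}
    syn_weight: np.ndarray  # (L,) float
    polymorphism_class: np.ndarray  # (L,) of {noncoding, synonymous-eligible, ...}

    @property
    def syn_sites(self) -> float:
        return float(self.syn_weight[self.column_label == CODING].sum())

    @property
    def nonsyn_sites(self) -> float:
        coding = self.column_label == CODING
        return float((1.0 - self.syn_weight[coding]).sum())

    @property
    def noncoding_sites(self) -> int:
        return int((self.column_label == NONCODING).sum())

    @property
    def silent_sites(self) -> float:
        return self.syn_sites + self.noncoding_sites

    @property
    def all_sites(self) -> int:
        return int(self.column_label.size)

    def class_weights(self, site_class: str) -> np.ndarray:
        """Per-column site weight for a class (denominator contribution)."""
        L = self.column_label.size
        w = np.zeros(L)
        coding = self.column_label == CODING
        noncoding = self.column_label == NONCODING
        if site_class == "all":
            w[:] = 1.0
        elif site_class == "synonymous":
            w[coding] = self.syn_weight[coding]
        elif site_class == "nonsynonymous":
            w[coding] = 1.0 - self.syn_weight[coding]
        elif site_class == "silent":
            w[coding] = self.syn_weight[coding]
            w[noncoding] = 1.0
        else:
            raise ValueError(f"unknown site class {site_class!r}")
        return w

    def class_columns(self, site_class: str) -> np.ndarray:
        """Boolean mask of columns whose observed differences count in a class."""
        pc = self.polymorphism_class
        if site_class == "all":
            return np.ones(pc.size, dtype=bool)
        if site_class == "synonymous":
            return pc == "synonymous-eligible"
        if site_class == "nonsynonymous":
            return pc == "nonsynonymous-eligible"
        if site_class == "silent":
            return (pc == "synonymous-eligible") | (pc == NONCODING)
        raise ValueError(f"unknown site class {site_class!r}")


def choose_reference(locus: AlignedLocus, annotation: GeneAnnotation | None) -> str:
    """First accession whose CDS carries no gap or missing character.

    Site counting needs an intact reading frame; accessions carrying a
    frameshifting deletion cannot anchor it. Falls back to the first row
    when no row is clean.
    """
    if annotation is None or not annotation.exon_intervals():
        return locus.accession_ids[0]
    cols = annotation.exon_columns()
    for acc, seq in zip(locus.accession_ids, locus.sequences):
        if all(seq[c] not in "-N?" for c in cols):
            return acc
    return locus.accession_ids[0]


def classify_sites(
    locus: AlignedLocus,
    annotation: GeneAnnotation | None,
    reference_id: str | None = None,
) -> SiteClassMap:
    """Classify every alignment column and count fractional sites.

    Without an annotation the whole locus is noncoding. The reference row
    (default: first accession) must have no N/? inside the CDS; CDS length
    after the frame offset must be divisible by 3. Gap-containing
    reference codons are skipped (frame ambiguity); an internal stop codon
    in the reference is skipped with a warning.
    """
    import warnings

    if reference_id is None:
        reference_id = choose_reference(locus, annotation)
    ref = locus.row(reference_id)
    L = locus.length

    label = np.full(L, NONCODING, dtype=object)
    syn_w = np.zeros(L)

    if annotation is not None and annotation.exon_intervals():
        exon_cols = annotation.exon_columns()
        # UTRs are noncoding for diversity purposes; columns outside any
        # feature default to noncoding as well.
        cds_cols = [c for c in exon_cols if ref[c] != "-"]
        gap_cols = [c for c in exon_cols if ref[c] == "-"]
        label[gap_cols] = SKIPPED
        if annotation.strand == "-":
            cds_cols = cds_cols[::-1]
        cds_cols = cds_cols[annotation.cds_frame_offset:]
        for c in exon_cols:
            if ref[c] in "N?":
                raise ValueError(
                    f"{locus.locus_id}: reference {reference_id!r} has "
                    f"{ref[c]!r} inside CDS at column {c}"
                )
        if len(cds_cols) % 3 != 0:
            raise ValueError(
                f"{locus.locus_id}: CDS length {len(cds_cols)} not divisible by 3"
            )
        for k in range(0, len(cds_cols), 3):
            triple = cds_cols[k:k + 3]
            if annotation.strand == "-":
                # cds_cols already run 3'->5' on the alignment, so the codon
                # is the complement of the reference bases in that order
                codon = "".join(ref[c].translate(_COMPLEMENT) for c in triple)
            else:
                codon = "".join(ref[c] for c in triple)
            if codon in _STANDARD.stop_codons and k + 3 < len(cds_cols):
                warnings.warn(
                    f"{locus.locus_id}: internal stop codon at CDS position {k}; "
                    "codon excluded from site counting"
                )
                for c in triple:
                    label[c] = SKIPPED
                continue
            fracs = codon_syn_fractions(codon)
            for pos_in_codon, c in enumerate(triple):
                label[c] = CODING
                syn_w[c] = fracs[pos_in_codon]

    # classify observed polymorphisms column by column
    poly = np.array(label, dtype=object)
    mat = locus.matrix()
    for c in np.flatnonzero(label == CODING):
        obs = {b for b in mat[:, c] if b in BASES and b != ref[c]}
        if not obs:
            poly[c] = "synonymous-eligible" if syn_w[c] == 1.0 else (
                "nonsynonymous-eligible" if syn_w[c] == 0.0 else "monomorphic-coding"
            )
            # monomorphic coding columns carry no differences; the label is
            # irrelevant for numerators but kept distinct for clarity.
            continue
        kinds = {_change_kind(locus, annotation, ref, reference_id, c, b) for b in obs}
        if kinds == {"synonymous"}:
            poly[c] = "synonymous-eligible"
        elif kinds == {"nonsynonymous"}:
            poly[c] = "nonsynonymous-eligible"
        else:
            poly[c] = "mixed"

    return SiteClassMap(locus.locus_id, reference_id, np.array(label), syn_w, poly)


def _change_kind(locus, annotation, ref, reference_id, column, alt_base) -> str:
    """Is substituting alt_base at this column synonymous against the reference codon?"""
    exon_cols = [c for c in annotation.exon_columns() if ref[c] != "-"]
    if annotation.strand == "-":
        exon_cols = exon_cols[::-1]
    exon_cols = exon_cols[annotation.cds_frame_offset:]
    idx = exon_cols.index(column)
    k = (idx // 3) * 3
    triple = exon_cols[k:k + 3]
    if annotation.strand == "-":
        codon = "".join(ref[c].translate(_COMPLEMENT) for c in triple)
        mut = "".join(
            (alt_base if c == column else ref[c]).translate(_COMPLEMENT)
            for c in triple
        )
    else:
        codon = "".join(ref[c] for c in triple)
        mut = "".join(alt_base if c == column else ref[c] for c in triple)
    if mut in _STANDARD.stop_codons or codon in _STANDARD.stop_codons:
        return "nonsynonymous"
    return "synonymous" if _translate(mut) == _translate(codon) else "nonsynonymous"
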