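"""Readers and writers for panel data.

External representations handled here: aligned multi-FASTA per locus,
the panel metadata table (TSV), gene annotation tables (TSV), allele-rule
configuration (YAML), and haplotype reconstruction from VCF + reference.

All coordinates are 0-based half-open internally; file formats that use
1-based inclusive coordinates (VCF, annotation TSV) are converted at the
boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

#: Alignment alphabet. "N" marks unmapped and "?" low-quality nucleotides;
#: both are excluded from statistics but preserved on round-trip.
ALPHABET = frozenset("ACGTN?-")
BASES = frozenset("ACGT")

GROUP_VOCAB = (
    "aus-like",
    "indica-like",
    "wild-like",
    "admixed-weed",
    "aus",
    "indica",
    "japonica",
    "admixed-cultivar",
    "wild",
    "outgroup",
)
WEED_GROUPS = ("aus-like", "indica-like", "wild-like", "admixed-weed")

PERICARP_VOCAB = ("red", "white")
HULL_VOCAB = ("black", "straw")
AWN_VOCAB = ("present", "absent")
TILLER_ANGLE_VOCAB = ("<30", "30-60", "60-90")
SHATTERING_VOCAB = ("strong", "medium", "low", "non")

MISSING = "missing"


class RaggedAlignmentError(ValueError):
    pass


class AlphabetError(ValueError):
    pass


@dataclass
class AlignedLocus:
    """One gene or gene-fragment alignment across accessions.

    Rows are equal-length strings over ``ACGTN?-``; ``-`` is an alignment
    gap, ``N`` an unmapped site and ``?`` a low-quality site.
    """

    locus_id: str
    accession_ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.accession_ids) != len(self.sequences):
            raise ValueError("accession_ids and sequences length mismatch")
        if len(set(self.accession_ids)) != len(self.accession_ids):
            dupes = {a for a in self.accession_ids if self.accession_ids.count(a) > 1}
            raise ValueError(f"duplicate accession ids in {self.locus_id}: {sorted(dupes)}")
        if self.sequences:
            length = len(self.sequences[0])
            for acc, seq in zip(self.accession_ids, self.sequences):
                if len(seq) != length:
                    raise RaggedAlignmentError(
                        f"{self.locus_id}: record {acc!r} has length {len(seq)}, "
                        f"expected {length}"
                    )
                bad = set(seq) - ALPHABET
                if bad:
                    pos = next(i for i, c in enumerate(seq) if c in bad)
                    raise AlphabetError(
                        f"{self.locus_id}: record {acc!r} has illegal character "
                        f"{seq[pos]!r} at position {pos}"
                    )

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n(self) -> int:
        return len(self.sequences)

    def row(self, accession_id: str) -> str:
        try:
            return self.sequences[self.accession_ids.index(accession_id)]
        except ValueError:
            raise KeyError(f"{accession_id!r} not in locus {self.locus_id}") from None

    def subset(self, accession_ids: list[str]) -> "AlignedLocus":
        return AlignedLocus(
            self.locus_id, list(accession_ids), [self.row(a) for a in accession_ids]
        )

    def matrix(self) -> np.ndarray:
        """Alignment as an (n, L) array of single characters."""
        return np.array([list(s) for s in self.sequences], dtype="U1")


def read_alignment_fasta(path, locus_id: str | None = None) -> AlignedLocus:
    """Read an aligned multi-FASTA; lowercase is normalised to uppercase.

    Raises on ragged rows, duplicate headers or characters outside the
    ``ACGTN?-`` alphabet (naming the offending record / position).
    """
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if locus_id is None:
        locus_id = _stem(path)
    return AlignedLocus(locus_id, ids, seqs)


def write_alignment_fasta(locus: AlignedLocus, path) -> None:
    recs = [
        SeqRecord(Seq(s), id=a, description="")
        for a, s in zip(locus.accession_ids, locus.sequences)
    ]
    SeqIO.write(recs, str(path), "fasta-2line")


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


# ---------------------------------------------------------------------------
# Panel metadata


@dataclass
class Panel:
    """Accession-to-group map plus categorical and quantitative phenotypes.

    ``table`` is indexed by accession; controlled-vocabulary columns hold
    the string ``"missing"`` where unknown; quantitative columns hold NaN.
    Unknown extra columns from the input file are carried through untouched.
    """

    table: pd.DataFrame

    CATEGORICAL = {
        "group": GROUP_VOCAB,
        "pericarp": PERICARP_VOCAB,
        "hull": HULL_VOCAB,
        "awn": AWN_VOCAB,
        "tiller_angle_class": TILLER_ANGLE_VOCAB,
        "shattering_class": SHATTERING_VOCAB,
    }
    QUANTITATIVE = ("tiller_number", "bts_grams")

    @property
    def accessions(self) -> list[str]:
        return list(self.table.index)

    def group_of(self, accession: str) -> str:
        return self.table.at[accession, "group"]

    def members(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def groups(self) -> list[str]:
        seen = [g for g in self.table["group"].unique() if g != MISSING]
        return seen


def read_panel_table(path) -> Panel:
    """Read the panel TSV (header row; ``accession`` column unique).

    Tokens outside a column's controlled vocabulary are mapped to
    ``missing`` with a logged warning; a duplicate accession is a hard
    error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(MISSING)
    df.columns = [c.strip() for c in df.columns]
    if "accession" not in df.columns:
        raise ValueError(f"{path}: panel table needs an 'accession' column")
    df["accession"] = df["accession"].str.strip()
    if df["accession"].duplicated().any():
        dupes = df["accession"][df["accession"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate accession(s): {dupes}")
    df = df.set_index("accession")

    for col, vocab in Panel.CATEGORICAL.items():
        if col not in df.columns:
            df[col] = MISSING
            continue
        vals = df[col].str.strip()
        bad = ~vals.isin(list(vocab) + [MISSING, ""])
        if bad.any():
            for acc, tok in vals[bad].items():
                log.warning(
                    "panel %s: accession %s has unknown %s token %r; set to missing",
                    path, acc, col, tok,
                )
            vals = vals.where(~bad, MISSING)
        df[col] = vals.replace("", MISSING)

    for col in Panel.QUANTITATIVE:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col].mask(df[col] == MISSING), errors="coerce")
        else:
            df[col] = np.nan
    return Panel(df)


def write_panel_table(panel: Panel, path) -> None:
    out = panel.table.copy()
    out.to_csv(path, sep="\t", index_label="accession", na_rep=MISSING)


# ---------------------------------------------------------------------------
# Gene annotation

FEATURE_TYPES = ("UTR5", "exon", "intron", "UTR3")


@dataclass
class GeneAnnotation:
    """Gene model for one locus, in alignment coordinates (0-based half-open).

    ``features`` are (kind, start, end) sorted, non-overlapping intervals;
    exon intervals concatenated (minus frame offset) must be divisible by 3.
    """

    locus_id: str
    strand: str
    features: list[tuple[str, int, int]]
    cds_frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.locus_id}: strand must be + or -")
        if not 0 <= self.cds_frame_offset <= 2:
            raise ValueError(f"{self.locus_id}: cds_frame_offset must be 0..2")
        feats = sorted(self.features, key=lambda f: f[1])
        prev_end = -1
        for kind, start, end in feats:
            if kind not in FEATURE_TYPES:
                raise ValueError(f"{self.locus_id}: unknown feature type {kind!r}")
            if start >= end:
                raise ValueError(f"{self.locus_id}: empty interval {kind} {start}-{end}")
            if start < prev_end:
                raise ValueError(f"{self.locus_id}: overlapping features at {start}")
            prev_end = end
        self.features = feats

    def exon_intervals(self) -> list[tuple[int, int]]:
        return [(s, e) for k, s, e in self.features if k == "exon"]

    def exon_columns(self) -> np.ndarray:
        cols = np.concatenate(
            [np.arange(s, e) for s, e in self.exon_intervals()]
        ) if self.exon_intervals() else np.array([], dtype=int)
        return cols


def read_annotation_table(path) -> dict[str, GeneAnnotation]:
    """Read annotation TSV: locus, strand, feature, start, end, frame.

    File coordinates are 1-based inclusive and converted on read.
    """
    df = pd.read_csv(path, sep="\t", dtype={"locus": str, "strand": str, "feature": str})
    out: dict[str, GeneAnnotation] = {}
    for locus, sub in df.groupby("locus", sort=False):
        strand = sub["strand"].iloc[0]
        frame = int(sub["frame"].iloc[0]) if "frame" in sub.columns else 0
        feats = [
            (r.feature, int(r.start) - 1, int(r.end))
            for r in sub.itertuples()
        ]
        out[locus] = GeneAnnotation(locus, strand, feats, frame)
    return out


def write_annotation_table(annotations: dict[str, GeneAnnotation], path) -> None:
    rows = []
    for ann in annotations.values():
        for kind, start, end in ann.features:
            rows.append(
                dict(locus=ann.locus_id, strand=ann.strand, feature=kind,
                     start=start + 1, end=end, frame=ann.cds_frame_offset)
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Allele rules (schema documented in docs/methods.md)


@dataclass
class Diagnostic:
    """One diagnostic polymorphism: an indel interval or a SNP column."""

    name: str
    kind: str  # "indel" | "snp"
    start: int = 0  # alignment columns, 0-based half-open (snp: start, start+1)
    end: int = 0
    reference_state: str = ""
    alternate_states: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("indel", "snp"):
            raise ValueError(f"diagnostic {self.name}: kind must be indel or snp")
        if self.kind == "snp":
            self.end = self.start + 1
            for state in (self.reference_state, *self.alternate_states):
                if state and state not in BASES:
                    raise AlphabetError(
                        f"diagnostic {self.name}: state {state!r} not in ACGT"
                    )


@dataclass
class AlleleRule:
    """Rule set calling functional-allele classes for one gene.

    ``class_map`` entries are matched in order; each maps a pattern of
    diagnostic observations (e.g. ``{"del14": "del"}``) to a class label.
    ``profiles``, when present, trigger majority-consistent profile
    matching (used for Sdr4-style multi-SNP haplotype classes).
    """

    gene: str
    locus_id: str
    diagnostics: list[Diagnostic]
    class_map: list[tuple[dict[str, str], str]]
    fallback_class: str = "unclassified"
    profiles: list[tuple[str, dict[str, str]]] = field(default_factory=list)

    def diagnostic(self, name: str) -> Diagnostic:
        for d in self.diagnostics:
            if d.name == name:
                return d
        raise KeyError(f"rule {self.gene}: no diagnostic named {name!r}")


def read_allele_rules(path, locus_lengths: dict[str, int] | None = None) -> list[AlleleRule]:
    """Load allele rules from a YAML file; validate coordinates and states.

    Schema: top-level list of mappings with keys ``gene``, ``locus``,
    ``diagnostics`` (name, kind, start/end or column [1-based in file],
    ref, alt), ``classes`` (list of {when: {...}, call: label}),
    optional ``profiles`` and ``fallback``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        return []
    rules = []
    for entry in raw:
        diags = []
        for d in entry.get("diagnostics", []):
            kind = d["kind"]
            if kind == "snp":
                start = int(d["column"]) - 1
                end = start + 1
            else:
                start = int(d["start"]) - 1
                end = int(d["end"])
            alt = d.get("alt", [])
            if isinstance(alt, str):
                alt = [alt]
            diags.append(
                Diagnostic(d["name"], kind, start, end,
                           d.get("ref", ""), tuple(alt))
            )
        class_map = [(dict(c["when"]), c["call"]) for c in entry.get("classes", [])]
        profiles = [(p["call"], dict(p["expect"])) for p in entry.get("profiles", [])]
        rule = AlleleRule(
            entry["gene"], entry.get("locus", entry["gene"]), diags, class_map,
            entry.get("fallback", "unclassified"), profiles,
        )
        if locus_lengths and rule.locus_id in locus_lengths:
            L = locus_lengths[rule.locus_id]
            for d in rule.diagnostics:
                if not (0 <= d.start < d.end <= L):
                    raise ValueError(
                        f"rule {rule.gene}: diagnostic {d.name} interval "
                        f"[{d.start}, {d.end}) outside locus of length {L}"
                    )
        rules.append(rule)
    return rules


def write_allele_rules(rules: list[AlleleRule], path) -> None:
    out = []
    for r in rules:
        diags = []
        for d in r.diagnostics:
            item: dict = {"name": d.name, "kind": d.kind}
            if d.kind == "snp":
                item["column"] = d.start + 1
            else:
                item["start"] = d.start + 1
                item["end"] = d.end
            if d.reference_state:
                item["ref"] = d.reference_state
            if d.alternate_states:
                item["alt"] = list(d.alternate_states)
            diags.append(item)
        out.append(
            {
                "gene": r.gene,
                "locus": r.locus_id,
                "diagnostics": diags,
                "classes": [{"when": w, "call": c} for w, c in r.class_map],
                "profiles": [{"call": c, "expect": e} for c, e in r.profiles],
                "fallback": r.fallback_class,
            }
        )
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# VCF -> haplotype FASTA


def vcf_to_haplotype_fasta(
    vcf_path,
    reference_fasta,
    region: str,
    min_qual: float = 30.0,
    min_depth: int = 3,
    locus_id: str | None = None,
) -> AlignedLocus:
    """Reconstruct per-accession haplotype rows from a VCF over ``region``.

    Each row is the reference with sample alleles substituted. Sites with
    no call become ``N``; calls failing the quality/depth thresholds
    become ``?``; heterozygous calls collapse to ``N`` (inbred material —
    one haplotype per accession). Indels are padded with ``-`` so all rows
    stay equal length. Overlapping indel records are a hard error.

    ``region`` is ``chrom:start-end`` 1-based inclusive, as in samtools.
    """
    from cyvcf2 import VCF

    chrom, span = region.split(":")
    start1, end1 = (int(x) for x in span.split("-"))
    start0, end0 = start1 - 1, end1

    ref_seq = None
    for rec in SeqIO.parse(str(reference_fasta), "fasta"):
        if rec.id == chrom:
            ref_seq = str(rec.seq[start0:end0]).upper()
            break
    if ref_seq is None:
        raise ValueError(f"{reference_fasta}: contig {chrom!r} not found")

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)

    # slot i covers reference positions [slot_start[i], slot_start[i+1]);
    # per-sample allele strings are padded to the slot's max allele width.
    events = []  # (pos0_local, ref_allele, alts, per-sample allele index or None/"?")
    prev_end = -1
    # plain-text VCFs carry no tabix index, so filter records in stream
    for var in vcf:
        if var.CHROM != chrom:
            continue
        pos0 = var.POS - 1 - start0
        ref = var.REF.upper()
        if pos0 < 0 or pos0 + len(ref) > len(ref_seq):
            continue
        if pos0 < prev_end:
            raise ValueError(
                f"{vcf_path}: overlapping indel/variant records at {chrom}:{var.POS}"
            )
        prev_end = pos0 + len(ref)
        alts = [a.upper() for a in (var.ALT or [])]
        lowq = var.QUAL is not None and var.QUAL < min_qual
        depths = None
        try:
            depths = var.format("DP")
        except Exception:
            depths = None
        calls = []
        for si, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a is not None and a >= 0]
            if not alleles:
                calls.append(None)  # no call -> N
                continue
            if len(set(alleles)) > 1:
                calls.append(None)  # heterozygote collapses to N
                continue
            if lowq or (
                depths is not None
                and depths[si][0] is not None
                and int(depths[si][0]) >= 0
                and int(depths[si][0]) < min_depth
            ):
                calls.append("?")
                continue
            calls.append(alleles[0])
        events.append((pos0, ref, alts, calls))

    rows = {s: [] for s in samples}
    cursor = 0
    for pos0, ref, alts, calls in events:
        invariant = ref_seq[cursor:pos0]
        for s in samples:
            rows[s].append(invariant)
        width = max(len(ref), *(len(a) for a in alts)) if alts else len(ref)
        for s, call in zip(samples, calls):
            if call is None:
                allele = "N" * len(ref)
            elif call == "?":
                allele = "?" * len(ref)
            elif call == 0:
                allele = ref
            else:
                allele = alts[call - 1]
            rows[s].append(allele.ljust(width, "-"))
        cursor = pos0 + len(ref)
    tail = ref_seq[cursor:]
    for s in samples:
        rows[s].append(tail)

    return AlignedLocus(
        locus_id or f"{chrom}_{start1}_{end1}",
        samples,
        ["".join(rows[s]) for s in samples],
    )


# ---------------------------------------------------------------------------
# Newick / report helpers used by downstream modules


def write_tsv(df: pd.DataFrame, path, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", **kwargs)
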