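"""Functional-allele calling, amino-acid haplotypes, origin inference and
in-silico CAPS (cleaved amplified polymorphic sequence) verification.

Allele calls are rule-driven: each candidate gene ships a rule file
naming its diagnostic polymorphisms (e.g. the 14-bp exon-6 deletion that
separates the wild-type red-pericarp Rc allele from the loss-of-function
rc allele) and a mapping from diagnostic patterns to allele-class
labels. Coordinates live in the rule files, not in code, because several
diagnostics are only specified to exon resolution in the primary
literature and must be pinned to whichever reference the panel uses.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .io import AlignedLocus, AlleleRule, BASES, GeneAnnotation, Panel, WEED_GROUPS
from .trees import k2p_distance

#: observation symbols for diagnostics
DEL = "del"
REF = "ref"
MISSING_OBS = "missing"

DEFAULT_ANCESTRY_MAP = {
    "aus-like": "aus",
    "indica-like": "indica",
    "wild-like": "wild",
}


@dataclass
class AlleleCall:
    accession: str
    gene: str
    allele_class: str
    diagnostics_observed: dict[str, str]
    confidence: str  # "complete" | "partial-missing"


def observe_diagnostic(row: str, diag) -> str:
    """Read one diagnostic from an aligned row.

    Indels: ``del`` when the interval is all gaps, ``ref`` when all
    bases; a mixed gap/base interval or any N/? is ``missing``. SNPs: the
    base at the column, or ``missing`` for gap/N/?.
    """
    segment = row[diag.start:diag.end]
    if diag.kind == "indel":
        if any(c in "N?" for c in segment):
            return MISSING_OBS
        if all(c == "-" for c in segment):
            return DEL
        if all(c != "-" for c in segment):
            return REF
        return MISSING_OBS
    base = segment
    return base if base in BASES else MISSING_OBS


def classify_allele(locus: AlignedLocus, accession: str, rule: AlleleRule) -> AlleleCall:
    """Call the functional-allele class of one accession for one gene.

    Pattern entries in the rule's class map are tried in order; an entry
    matches when every named diagnostic shows the stated observation.
    When the rule carries profiles (multi-SNP haplotype classes, as for
    the seed-dormancy locus), majority-consistent profile matching is
    used instead: the profile matching strictly more of the non-missing
    diagnostics wins, provided it matches a strict majority; otherwise
    the call is the fallback class ("unclassified").
    """
    for d in rule.diagnostics:
        if not (0 <= d.start < d.end <= locus.length):
            raise ValueError(
                f"rule {rule.gene}: diagnostic {d.name} outside locus "
                f"{locus.locus_id} of length {locus.length}"
            )
    row = locus.row(accession)
    obs = {d.name: observe_diagnostic(row, d) for d in rule.diagnostics}
    confidence = "partial-missing" if MISSING_OBS in obs.values() else "complete"

    if rule.profiles:
        call = _profile_match(obs, rule)
        return AlleleCall(accession, rule.gene, call, obs, confidence)

    for pattern, label in rule.class_map:
        if all(obs.get(name) == value for name, value in pattern.items()):
            return AlleleCall(accession, rule.gene, label, obs, confidence)
    return AlleleCall(accession, rule.gene, rule.fallback_class, obs, confidence)


def _profile_match(obs: dict[str, str], rule: AlleleRule) -> str:
    """Majority-consistent profile matching.

    A profile is consistent when every observed (non-missing) diagnostic
    it names matches, and a majority of its diagnostics were observable.
    Among consistent profiles the one matching the most diagnostics wins
    (the more specific haplotype); ties and recombinant patterns fall to
    the fallback class.
    """
    scores = []
    for call, expect in rule.profiles:
        scored = [name for name in expect if obs.get(name, MISSING_OBS) != MISSING_OBS]
        matches = sum(1 for name in scored if obs[name] == expect[name])
        consistent = (
            len(scored) > 0
            and matches == len(scored)
            and len(scored) > len(expect) / 2
        )
        scores.append((call, consistent, matches))
    consistent_calls = sorted(
        (s for s in scores if s[1]), key=lambda t: -t[2]
    )
    if not consistent_calls:
        return rule.fallback_class
    if len(consistent_calls) > 1 and consistent_calls[0][2] == consistent_calls[1][2]:
        return rule.fallback_class
    return consistent_calls[0][0]


def call_alleles(
    loci: dict[str, AlignedLocus], rules: list[AlleleRule]
) -> pd.DataFrame:
    """Accession x gene allele-call matrix (long form)."""
    rows = []
    for rule in rules:
        locus = loci[rule.locus_id]
        for acc in locus.accession_ids:
            call = classify_allele(locus, acc, rule)
            rows.append(
                dict(
                    accession=acc,
                    gene=call.gene,
                    allele_class=call.allele_class,
                    confidence=call.confidence,
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Amino-acid haplotypes


@dataclass
class AaHaplotype:
    accession: str
    protein: str
    haplotype_id: int
    flags: set[str] = field(default_factory=set)


def aa_haplotype(
    locus: AlignedLocus,
    annotation: GeneAnnotation,
    accessions: list[str] | None = None,
) -> list[AaHaplotype]:
    """Translate each row's spliced CDS and assign haplotype ids.

    Identical protein strings share an id, assigned in input order.
    A frameshifting indel simply shifts the reading frame of the row's
    ungapped CDS (flagged ``frameshift`` when the ungapped length is not
    a multiple of 3); an internal stop truncates the translation and is
    flagged ``premature_stop``; N/? inside the CDS flags
    ``partial-missing`` and the affected codons translate to X.
    """
    if accessions is None:
        accessions = list(locus.accession_ids)
    exon_cols = annotation.exon_columns()
    results = []
    ids: dict[str, int] = {}
    for acc in accessions:
        row = locus.row(acc)
        cds = "".join(row[c] for c in exon_cols)
        cds = cds.replace("-", "")
        flags: set[str] = set()
        if annotation.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        cds = cds[annotation.cds_frame_offset:]
        if "N" in cds or "?" in cds:
            flags.add("partial-missing")
            cds = cds.replace("?", "N")
        if len(cds) % 3 != 0:
            flags.add("frameshift")
            cds = cds[: len(cds) - len(cds) % 3]
        protein = str(Seq(cds).translate())
        if "*" in protein[:-1]:
            flags.add("premature_stop")
            protein = protein[: protein.index("*") + 1]
        protein = protein.rstrip("*")
        if protein not in ids:
            ids[protein] = len(ids) + 1
        results.append(AaHaplotype(acc, protein, ids[protein], flags))
    return results


# ---------------------------------------------------------------------------
# Origin inference


@dataclass
class OriginCall:
    accession: str
    gene: str
    nearest_groups: list[tuple[str, float]]  # ranked (group, min distance)
    call: str  # standing_ancestral | possible_introgression | ambiguous


def infer_origin(
    locus: AlignedLocus,
    panel: Panel,
    gene: str,
    ancestry_map: dict[str, str] | None = None,
    tie_tolerance: float = 1e-9,
    exclude_groups: tuple[str, ...] = ("outgroup",),
) -> list[OriginCall]:
    """Classify each weed haplotype's origin by nearest-neighbour distance.

    For every weed accession the minimum K2P distance to each non-weed
    group's haplotypes is computed. ``standing_ancestral`` when the
    weed group's designated ancestral group attains the minimum (within
    the tie tolerance) and no non-ancestral group ties it;
    ``possible_introgression`` when a non-ancestral group is strictly
    nearest; ``ambiguous`` when ancestral and non-ancestral groups tie.
    """
    if ancestry_map is None:
        ancestry_map = DEFAULT_ANCESTRY_MAP
    donor_groups = [
        g for g in panel.groups()
        if g not in WEED_GROUPS and g not in exclude_groups
    ]
    donors = {
        g: [a for a in panel.members(g) if a in locus.accession_ids]
        for g in donor_groups
    }
    donors = {g: accs for g, accs in donors.items() if accs}
    if not donors:
        raise ValueError(f"{locus.locus_id}: no non-weed sequences available")

    calls = []
    for weed_group, ancestral in ancestry_map.items():
        for acc in panel.members(weed_group):
            if acc not in locus.accession_ids:
                continue
            row = locus.row(acc)
            dists = []
            for g, accs in donors.items():
                dmin = math.inf
                for other in accs:
                    d, _, _, comp = k2p_distance(row, locus.row(other))
                    if comp > 0 and not math.isnan(d):
                        dmin = min(dmin, d)
                if math.isfinite(dmin):
                    dists.append((g, dmin))
            if not dists:
                calls.append(OriginCall(acc, gene, [], "ambiguous"))
                continue
            dists.sort(key=lambda t: (t[1], t[0]))
            best = dists[0][1]
            nearest = {g for g, d in dists if d <= best + tie_tolerance}
            if ancestral in nearest and len(nearest) == 1:
                verdict = "standing_ancestral"
            elif ancestral in nearest:
                verdict = "ambiguous"
            else:
                verdict = "possible_introgression"
            calls.append(OriginCall(acc, gene, dists, verdict))
    return calls


# ---------------------------------------------------------------------------
# CAPS simulation

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

_RC = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _iupac_regex(site: str) -> str:
    return "".join(IUPAC[c] for c in site.upper())


def load_enzymes(path=None) -> dict[str, "Enzyme"]:
    """Load enzyme definitions from YAML (default: the packaged file)."""
    import yaml

    if path is None:
        from importlib.resources import files

        path = files("weedyrice").joinpath("data/enzymes.yaml")
        raw = yaml.safe_load(path.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return {
        name: Enzyme(name, spec["recognition_site"], int(spec["cut_offset"]))
        for name, spec in raw.items()
    }


@dataclass
class Enzyme:
    """Restriction enzyme with an IUPAC recognition site.

    ``cut_offset`` is the cut position within the recognition site,
    counted from its 5' end (ApaLI = GTGCAC cut after the G: offset 1).
    """

    name: str
    recognition_site: str
    cut_offset: int


@dataclass
class CapsAssay:
    gene: str
    forward_primer: str
    reverse_primer: str
    enzyme: Enzyme
    expected_fragment_patterns: dict[str, list[int]] = field(default_factory=dict)
    length_tolerance: int = 0


@dataclass
class CapsResult:
    gene: str
    ok: bool
    reason: str
    amplicon_length: int
    fragments: list[int]
    allele_call: str  # matched class label or "unmatched" / "failed"


def simulate_caps(template: str, assay: CapsAssay) -> CapsResult:
    """PCR-amplify and digest an ungapped template in silico.

    The amplicon is the inclusive forward-primer-start to
    reverse-primer-end span (reverse primer matched as its reverse
    complement). Each recognition-site occurrence cuts at the enzyme's
    offset; fragment lengths are reported sorted descending and matched
    against the assay's expected per-class patterns. A missing or
    multiply-matching primer is an assay failure, not an exception.
    """
    template = template.upper().replace("-", "")
    fwd = assay.forward_primer.upper()
    rev = assay.reverse_primer.upper().translate(_RC)[::-1]

    f_hits = [m.start() for m in re.finditer(re.escape(fwd), template)]
    r_hits = [m.start() for m in re.finditer(re.escape(rev), template)]
    if len(f_hits) != 1 or len(r_hits) != 1:
        reason = (
            f"forward primer hits={len(f_hits)}, reverse primer hits={len(r_hits)}"
        )
        return CapsResult(assay.gene, False, reason, 0, [], "failed")
    start = f_hits[0]
    end = r_hits[0] + len(rev)
    if start >= end:
        return CapsResult(assay.gene, False, "primers inverted", 0, [], "failed")
    amplicon = template[start:end]

    pattern = re.compile(_iupac_regex(assay.enzyme.recognition_site))
    cuts = sorted(
        m.start() + assay.enzyme.cut_offset
        for m in pattern.finditer(amplicon)
        if 0 < m.start() + assay.enzyme.cut_offset < len(amplicon)
    )
    bounds = [0] + cuts + [len(amplicon)]
    fragments = sorted(
        (b - a for a, b in zip(bounds, bounds[1:])), reverse=True
    )

    call = "unmatched"
    tol = assay.length_tolerance
    for label, expected in assay.expected_fragment_patterns.items():
        if len(expected) == len(fragments) and all(
            abs(e - f) <= tol for e, f in zip(sorted(expected, reverse=True), fragments)
        ):
            call = label
            break
    return CapsResult(assay.gene, True, "", len(amplicon), fragments, call)
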