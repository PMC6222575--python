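"""Synthetic panel generator: neutral coalescent sequences per group,
planted functional polymorphisms at group-specific frequencies, and
genotype-linked phenotypes with a configurable discordance rate.

The generator emulates a target-capture candidate-gene panel: ~100
accessions in weed / cultivar / wild / outgroup groups, ~128 aligned
loci, five of which carry diagnostic functional polymorphisms (indels
and SNPs) whose carrier frequencies differ by group. Time is scaled in
units of 2N generations, so a pair of lineages coalesces at rate 1 and
a branch of length t accumulates Poisson(theta_total/2 * t) mutations
with theta_total = theta_per_site * L; the classical neutral
expectations E[S] = theta_total * a_{n-1} and E[pi] = theta_per_site
then hold and are used as oracles in the test suite.

Every draw flows from a single integer seed through
``numpy.random.default_rng``; identical configs and seeds give
byte-identical bundles.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as wio
from .alleles import DEL as DEL_OBS, REF as REF_OBS
from .io import (
    AlignedLocus,
    AlleleRule,
    Diagnostic,
    GeneAnnotation,
    Panel,
)

BASES = np.array(["A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# Neutral coalescent


@dataclass
class Genealogy:
    """Binary coalescent tree: node i's parent and the node times.

    Leaves are nodes 0..n-1 at time 0; internal nodes n..2n-2 in
    coalescence order.
    """

    n: int
    parent: np.ndarray  # (2n-1,), -1 for the root
    time: np.ndarray  # (2n-1,)

    def branch_length(self, node: int) -> float:
        p = self.parent[node]
        return float(self.time[p] - self.time[node]) if p >= 0 else 0.0

    def leaves_below(self, node: int) -> list[int]:
        children: dict[int, list[int]] = {}
        for i, p in enumerate(self.parent):
            if p >= 0:
                children.setdefault(int(p), []).append(i)
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < self.n:
                out.append(v)
            else:
                stack.extend(children.get(v, []))
        return sorted(out)

    def total_length(self) -> float:
        return float(
            sum(self.branch_length(i) for i in range(len(self.parent)))
        )


def sample_genealogy(n: int, rng: np.random.Generator) -> Genealogy:
    """Kingman coalescent: exponential waiting times, uniform pair merges."""
    parent = np.full(2 * n - 1, -1, dtype=int)
    time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return Genealogy(n, parent, time)


def simulate_coalescent_locus(
    n: int,
    theta_per_site: float,
    L: int,
    seed: int | np.random.Generator,
    ancestral: str | None = None,
    protected_columns: set[int] | frozenset[int] = frozenset(),
) -> tuple[list[str], Genealogy]:
    """Sequences for one neutral locus plus the true genealogy.

    Mutations fall on branches as Poisson(theta_total/2 * length) and
    each takes a distinct, uniformly chosen column (infinite sites on a
    finite grid); ``protected_columns`` are never mutated. theta = 0
    returns n identical copies of the ancestral sequence.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if ancestral is None:
        ancestral = "".join(rng.choice(BASES, size=L))
    if len(ancestral) != L:
        raise ValueError("ancestral sequence length mismatch")
    gen = sample_genealogy(n, rng)
    seqs = np.array([list(ancestral)] * n, dtype="U1")

    theta_total = theta_per_site * L
    available = [c for c in range(L) if c not in protected_columns]
    rng.shuffle(available)
    used = 0
    for node in range(2 * n - 2):  # every node but the root has a branch
        bl = gen.branch_length(node)
        k = rng.poisson(theta_total / 2.0 * bl) if bl > 0 else 0
        if k == 0:
            continue
        carriers = gen.leaves_below(node)
        for _ in range(k):
            if used >= len(available):
                break  # infinite-sites grid exhausted; excess mutations dropped
            col = available[used]
            used += 1
            new = rng.choice([b for b in "ACGT" if b != ancestral[col]])
            for leaf in carriers:
                seqs[leaf, col] = new
    return ["".join(row) for row in seqs], gen


def simulate_two_deme_locus(
    n1: int,
    n2: int,
    theta_per_site: float,
    L: int,
    split_time: float,
    migration: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[list[str], list[str]]:
    """Structured coalescent for two demes.

    ``split_time`` (units of 2N) merges the demes going back in time;
    ``migration`` is the scaled rate M = 4Nm (each lineage migrates at
    rate M/2). ``split_time = inf`` with ``migration > 0`` is the
    two-deme island model, for which the generator's analytic Hudson
    F_ST expectation is 1/(1 + 2M) (see ``expected_island_fst``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = n1 + n2
    parent = np.full(2 * n - 1, -1, dtype=int)
    time = np.zeros(2 * n - 1)
    deme = {i: (0 if i < n1 else 1) for i in range(n)}
    active = list(range(n))
    t = 0.0
    nxt = n
    merged = False
    while len(active) > 1:
        if not merged and t >= split_time:
            merged = True
        by_deme = [ [a for a in active if deme[a] == 0], [a for a in active if deme[a] == 1] ]
        if merged:
            pairs = len(active) * (len(active) - 1) / 2.0
            mig_rate = 0.0
        else:
            pairs = sum(len(g) * (len(g) - 1) / 2.0 for g in by_deme)
            mig_rate = migration / 2.0 * len(active)
        total = pairs + mig_rate
        if total == 0:
            # lineages stranded in separate demes with no migration: jump
            # to the split time
            t = split_time
            merged = True
            continue
        wait = rng.exponential(1.0 / total)
        if not merged and t + wait > split_time:
            t = split_time
            merged = True
            continue
        t += wait
        if rng.random() < pairs / total:
            if merged:
                i, j = rng.choice(len(active), size=2, replace=False)
                a, b = active[i], active[j]
            else:
                weights = [len(g) * (len(g) - 1) / 2.0 for g in by_deme]
                d = 0 if rng.random() < weights[0] / sum(weights) else 1
                pool = by_deme[d]
                i, j = rng.choice(len(pool), size=2, replace=False)
                a, b = pool[i], pool[j]
            parent[a] = parent[b] = nxt
            time[nxt] = t
            deme[nxt] = deme[a]
            active = [x for x in active if x not in (a, b)] + [nxt]
            nxt += 1
        else:
            mover = active[int(rng.integers(len(active)))]
            deme[mover] = 1 - deme[mover]
    gen = Genealogy(n, parent, time)

    ancestral = "".join(rng.choice(BASES, size=L))
    seqs = np.array([list(ancestral)] * n, dtype="U1")
    theta_total = theta_per_site * L
    cols = list(range(L))
    rng.shuffle(cols)
    used = 0
    for node in range(2 * n - 2):
        bl = gen.branch_length(node)
        k = rng.poisson(theta_total / 2.0 * bl) if bl > 0 else 0
        for _ in range(k):
            if used >= L:
                break
            col = cols[used]
            used += 1
            new = rng.choice([b for b in "ACGT" if b != ancestral[col]])
            for leaf in gen.leaves_below(node):
                seqs[leaf, col] = new
    rows = ["".join(r) for r in seqs]
    return rows[:n1], rows[n1:]


def simulate_split_cluster(
    deme_sizes: dict[str, tuple[int, float]],
    split_times: dict[str, float],
    base: str,
    theta_total: float,
    L: int,
    rng: np.random.Generator,
    ancestral: str,
    protected_columns: frozenset[int] = frozenset(),
) -> dict[str, list[str]]:
    """Joint coalescent for one cluster of demes with clean splits.

    ``deme_sizes`` maps deme name -> (sample size n, relative population
    size s); within a deme a pair coalesces at rate 1/s (time in 2N_0
    units). Every non-base deme merges into ``base`` at its split time.
    Mutations fall at total rate ``theta_total/2`` per unit branch
    length. Derived groups therefore share standing variation with the
    base deme, so their haplotypes interleave with the ancestor's — the
    regime the origin-inference step is built for.
    """
    names = list(deme_sizes)
    n_total = sum(n for n, _ in deme_sizes.values())
    parent = np.full(2 * n_total - 1, -1, dtype=int)
    time = np.zeros(2 * n_total - 1)

    leaf_owner: dict[int, str] = {}
    deme_of: dict[int, str] = {}
    idx = 0
    for name in names:
        n, _ = deme_sizes[name]
        for _ in range(n):
            leaf_owner[idx] = name
            deme_of[idx] = name
            idx += 1
    active = list(range(n_total))
    pending = sorted(
        ((t, d) for d, t in split_times.items() if d in deme_sizes and d != base),
        key=lambda x: x[0],
    )
    t = 0.0
    nxt = n_total
    while len(active) > 1:
        by_deme: dict[str, list[int]] = {}
        for a in active:
            by_deme.setdefault(deme_of[a], []).append(a)
        rate = sum(
            len(g) * (len(g) - 1) / 2.0 / deme_sizes.get(d, (0, 1.0))[1]
            for d, g in by_deme.items()
        )
        wait = rng.exponential(1.0 / rate) if rate > 0 else math.inf
        if rate == 0 and not pending:
            raise ValueError(
                "stranded lineages: every non-base deme needs a split time"
            )
        if pending and t + wait >= pending[0][0]:
            t, merging = pending.pop(0)
            for a in active:
                if deme_of[a] == merging:
                    deme_of[a] = base
            continue
        t += wait
        weights = np.array([
            len(g) * (len(g) - 1) / 2.0 / deme_sizes.get(d, (0, 1.0))[1]
            for d, g in by_deme.items()
        ])
        d = list(by_deme)[int(rng.choice(len(weights), p=weights / weights.sum()))]
        pool = by_deme[d]
        i, j = rng.choice(len(pool), size=2, replace=False)
        a, b = pool[i], pool[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        deme_of[nxt] = d
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1

    gen = Genealogy(n_total, parent, time)
    seqs = np.array([list(ancestral)] * n_total, dtype="U1")
    available = [c for c in range(L) if c not in protected_columns]
    rng.shuffle(available)
    used = 0
    for node in range(2 * n_total - 2):
        bl = gen.branch_length(node)
        k = rng.poisson(theta_total / 2.0 * bl) if bl > 0 else 0
        if k == 0:
            continue
        carriers = gen.leaves_below(node)
        for _ in range(k):
            if used >= len(available):
                break
            col = available[used]
            used += 1
            new = rng.choice([b for b in "ACGT" if b != ancestral[col]])
            for leaf in carriers:
                seqs[leaf, col] = new

    out: dict[str, list[str]] = {name: [] for name in names}
    for leaf in range(n_total):
        out[leaf_owner[leaf]].append("".join(seqs[leaf]))
    return out


def expected_island_fst(M: float) -> float:
    """Hudson E[F_ST] for the symmetric two-deme island model.

    With per-lineage scaled migration M/2 (M = 4Nm), expected pairwise
    coalescence times are T_within = 2 and T_between = 2 + 1/M, giving
    1 - T_w/T_b = 1/(1 + 2M).
    """
    return 1.0 / (1.0 + 2.0 * M)


def expected_split_fst(split_time: float) -> float:
    """Hudson E[F_ST] for a clean split at time T (units of 2N): T/(1+T)."""
    return split_time / (1.0 + split_time)


# ---------------------------------------------------------------------------
# Panel configuration


@dataclass
class GroupSpec:
    name: str
    n_accessions: int
    #: target within-group per-site diversity; sets the deme's relative
    #: size as theta_per_site / theta_scale
    theta_per_site: float
    ancestral_group: str | None = None
    #: divergence cluster (the base group's name); groups in one cluster
    #: are simulated on a joint genealogy and share the fixed mutations
    #: separating clusters
    cluster: str | None = None
    #: time (units of 2N_0) at which this deme merges into the cluster's
    #: base deme going backwards; ignored for base demes
    split_time: float = 0.0


@dataclass
class Component:
    """One piece of a planted allele: a gap run or a base substitution."""

    kind: str  # "indel" | "snp"
    start: int  # 0-based alignment columns
    end: int
    alt: str = ""  # snp only


@dataclass
class PlantedAllele:
    allele_class: str
    components: list[Component]
    frequency: dict[str, float]  # group -> carrier frequency


@dataclass
class PlantedGene:
    gene: str
    locus_id: str
    wildtype_class: str
    alleles: list[PlantedAllele]
    phenotype_column: str | None = None
    expectation_map: dict[str, str] = field(default_factory=dict)


@dataclass
class LocusSpec:
    locus_id: str
    length: int
    annotation: GeneAnnotation | None = None
    #: fixed motifs (position, sequence) written into the ancestral
    #: sequence and protected from mutation (e.g. CAPS primer sites)
    motifs: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class PhenotypeModel:
    discordance_rate: float = 0.0
    levels: dict[str, tuple[str, ...]] = field(default_factory=dict)


@dataclass
class SimConfig:
    seed: int
    groups: list[GroupSpec]
    loci: list[LocusSpec]
    planted: list[PlantedGene] = field(default_factory=list)
    phenotype_model: PhenotypeModel = field(default_factory=PhenotypeModel)
    cluster_divergence: dict[str, float] = field(default_factory=dict)
    #: per-site mutation parameter of the reference-sized deme; deme
    #: sizes are theta_per_site / theta_scale
    theta_scale: float = 0.009
    #: weed groups listed here are literal copies of draws from their
    #: ancestor (for origin-inference closure tests)
    clone_weeds_from_ancestors: bool = False

    def __post_init__(self) -> None:
        for g in self.groups:
            if g.n_accessions < 1:
                raise ValueError(f"group {g.name}: need >= 1 accession")
        for locus in self.loci:
            if locus.length < 1:
                raise ValueError(f"{locus.locus_id}: length must be >= 1")
        for pg in self.planted:
            for al in pg.alleles:
                for f in al.frequency.values():
                    if not 0.0 <= f <= 1.0:
                        raise ValueError(
                            f"{pg.gene}/{al.allele_class}: frequency outside [0,1]"
                        )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


_STOPS = ("TAA", "TAG", "TGA")


def _enforce_orf(ancestral: list[str], annotation: GeneAnnotation,
                 protected: set[int]) -> None:
    """Rewrite the ancestral exon sequence so the CDS is stop-free.

    Stop codons are broken by substituting the last editable (not
    protected) base of the codon; plus-strand gene models only, which is
    what the generator emits.
    """
    cols = [c for s, e in annotation.exon_intervals() for c in range(s, e)]
    cols = cols[annotation.cds_frame_offset:]
    for k in range(0, len(cols) - len(cols) % 3, 3):
        triple = cols[k:k + 3]
        codon = "".join(ancestral[c] for c in triple)
        if codon not in _STOPS:
            continue
        for pos in (2, 1, 0):
            if triple[pos] in protected:
                continue
            for b in "CGAT":
                cand = codon[:pos] + b + codon[pos + 1:]
                if cand not in _STOPS:
                    ancestral[triple[pos]] = b
                    codon = cand
                    break
            break


# ---------------------------------------------------------------------------
# Default study configuration


def _default_annotation(locus_id: str, L: int = 900) -> GeneAnnotation:
    # 450-bp CDS in three exons; UTRs and introns around them
    return GeneAnnotation(
        locus_id,
        "+",
        [
            ("UTR5", 0, 90),
            ("exon", 90, 240),
            ("intron", 240, 330),
            ("exon", 330, 480),
            ("intron", 480, 570),
            ("exon", 570, 720),
            ("UTR3", 720, 900),
        ],
        0,
    )


#: CAPS reagents used on the synthetic Rc / Bh4 loci. Primer sequences
#: are the published assay primers; their binding sites are planted into
#: the synthetic reference so the in-silico assay runs end to end.
RC_FORWARD = "TCAATTCTTGCATTTCTTTTCCA"
RC_REVERSE = "ACGGCTTTATAGAAATAGAGGGAGT"
BH4_FORWARD = "CAATCTGGTGCATAATCAGAATGGA"
BH4_REVERSE = "CCCGAAGATCCTGACGTAGCAG"

BAN1_SITE = "GGYRCC"  # degenerate; cut after the first G
APALI_SITE = "GTGCAC"  # cut after the first G


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def default_config(
    seed: int = 0,
    n_loci: int = 128,
    locus_length: int = 900,
    discordance_rate: float = 0.06,
) -> SimConfig:
    """The default study conditions: a 101-accession panel in ten groups
    (seven of which enter the named analyses), 128 annotated loci, five
    candidate genes with planted functional polymorphisms, and
    phenotypes linked to genotype with a 6% discordance rate (about the
    rate of genotype/pericarp discrepancies seen in real panels).
    """
    groups = [
        GroupSpec("aus-like", 15, 0.0044, "aus", "aus", split_time=0.15),
        GroupSpec("indica-like", 5, 0.0048, "indica", "indica", split_time=0.006),
        GroupSpec("wild-like", 5, 0.0062, "wild", "wild", split_time=0.25),
        GroupSpec("admixed-weed", 10, 0.0050, None, "indica", split_time=0.10),
        GroupSpec("aus", 15, 0.0041, None, "aus"),
        GroupSpec("indica", 13, 0.0040, None, "indica"),
        GroupSpec("japonica", 11, 0.0030, None, "japonica"),
        GroupSpec("admixed-cultivar", 5, 0.0040, None, "indica", split_time=0.05),
        GroupSpec("wild", 18, 0.0090, None, "wild"),
        GroupSpec("outgroup", 4, 0.0030, None, "outgroup"),
    ]
    cluster_divergence = {
        "aus": 0.006,
        "indica": 0.009,
        "japonica": 0.012,
        "wild": 0.003,
        "outgroup": 0.030,
    }

    candidate = {"Rc": 0, "Bh4": 1, "sh4": 2, "PROG1": 3, "Sdr4": 4}
    loci = []
    for i in range(n_loci):
        locus_id = None
        for gene, idx in candidate.items():
            if i == idx:
                locus_id = gene
        if locus_id is None:
            locus_id = f"locus{i + 1:03d}"
        spec = LocusSpec(locus_id, locus_length,
                         _default_annotation(locus_id, locus_length))
        loci.append(spec)

    # CAPS landing sites on Rc and Bh4 (kept mutation-free)
    if candidate["Rc"] < n_loci:
        loci[candidate["Rc"]].motifs = [
            (540, RC_FORWARD),                   # forward primer, intron 2
            (600, BAN1_SITE.replace("Y", "C").replace("R", "G")),  # GGCGCC
            (760, _revcomp(RC_REVERSE)),         # reverse-primer site, UTR3
        ]
    if candidate["Bh4"] < n_loci:
        loci[candidate["Bh4"]].motifs = [
            (540, BH4_FORWARD),
            (610, APALI_SITE),
            (760, _revcomp(BH4_REVERSE)),
        ]

    def freq(**by_group):
        return by_group

    planted = [
        PlantedGene(
            "Rc", "Rc", "Rc",
            [
                PlantedAllele(
                    "rc", [Component("indel", 620, 634)],
                    {"aus": 0.07, "indica": 0.77, "japonica": 0.90,
                     "admixed-cultivar": 0.20, "aus-like": 0.0,
                     "indica-like": 0.60, "wild-like": 0.0,
                     "admixed-weed": 0.20, "wild": 0.06, "outgroup": 0.0},
                ),
                PlantedAllele(
                    "Rc-s", [Component("snp", 130, 131, "A")],
                    {"aus": 0.55, "indica": 0.0, "japonica": 0.0,
                     "admixed-cultivar": 0.0, "aus-like": 0.05,
                     "indica-like": 0.0, "wild-like": 0.0,
                     "admixed-weed": 0.0, "wild": 0.0, "outgroup": 0.0},
                ),
            ],
            "pericarp",
            {"Rc": "red", "rc": "white", "Rc-s": "white"},
        ),
        PlantedGene(
            "Bh4", "Bh4", "Bh4-wildtype",
            [
                PlantedAllele(
                    "bh4-del22", [Component("indel", 630, 652)],
                    {"aus": 0.85, "indica": 0.92, "japonica": 0.90,
                     "admixed-cultivar": 0.80, "aus-like": 0.20,
                     "indica-like": 1.0, "wild-like": 0.20,
                     "admixed-weed": 0.30, "wild": 0.15, "outgroup": 0.0},
                ),
            ],
            "hull",
            {"Bh4-wildtype": "black", "bh4-del22": "straw"},
        ),
        PlantedGene(
            "sh4", "sh4", "sh4-G",
            [
                PlantedAllele(
                    "sh4-T", [Component("snp", 150, 151, "T")],
                    {"aus": 0.95, "indica": 1.0, "japonica": 1.0,
                     "admixed-cultivar": 0.95, "aus-like": 0.90,
                     "indica-like": 0.80, "wild-like": 0.0,
                     "admixed-weed": 0.70, "wild": 0.05, "outgroup": 0.0},
                ),
            ],
            "shattering_class",
            {"sh4-G": "strong", "sh4-T": "non"},
        ),
        PlantedGene(
            "PROG1", "PROG1", "PROG1-wild",
            [
                PlantedAllele(
                    "PROG1-dom", [Component("snp", 200, 201, "T")],
                    {"aus": 0.90, "indica": 0.92, "japonica": 0.95,
                     "admixed-cultivar": 0.90, "aus-like": 0.85,
                     "indica-like": 0.85, "wild-like": 0.60,
                     "admixed-weed": 0.80, "wild": 0.30, "outgroup": 0.0},
                ),
            ],
        ),
        PlantedGene(
            "Sdr4", "Sdr4", "Sdr4-n",
            [
                PlantedAllele(
                    "Sdr4-k",
                    [Component("snp", c, c + 1, b) for c, b in
                     [(100, "T"), (120, "A"), (140, "T"), (160, "C"),
                      (350, "A"), (370, "T"), (390, "A"), (410, "C"),
                      (590, "T"), (610, "A")]]
                    + [Component("indel", 650, 653)],
                    {"aus": 0.30, "indica": 0.30, "japonica": 0.0,
                     "admixed-cultivar": 0.20, "aus-like": 0.60,
                     "indica-like": 0.60, "wild-like": 0.60,
                     "admixed-weed": 0.60, "wild": 0.55, "outgroup": 0.0},
                ),
                PlantedAllele(
                    "Sdr4-k'",
                    [Component("snp", c, c + 1, b) for c, b in
                     [(100, "T"), (120, "A"), (140, "T"), (160, "C"),
                      (350, "A"), (370, "T"), (390, "A"), (410, "C"),
                      (590, "T"), (610, "A"), (180, "G"), (430, "G")]]
                    + [Component("indel", 650, 653), Component("indel", 670, 673)],
                    {"aus": 0.10, "indica": 0.10, "japonica": 0.0,
                     "admixed-cultivar": 0.0, "aus-like": 0.15,
                     "indica-like": 0.20, "wild-like": 0.20,
                     "admixed-weed": 0.15, "wild": 0.15, "outgroup": 0.0},
                ),
            ],
        ),
    ]
    present = {l.locus_id for l in loci}
    planted = [pg for pg in planted if pg.locus_id in present]
    return SimConfig(
        seed=seed,
        groups=groups,
        loci=loci,
        planted=planted,
        phenotype_model=PhenotypeModel(
            discordance_rate,
            {
                "pericarp": ("red", "white"),
                "hull": ("black", "straw"),
                "shattering_class": ("strong", "medium", "low", "non"),
            },
        ),
        cluster_divergence=cluster_divergence,
    )


# ---------------------------------------------------------------------------
# Panel generation


def _accession_names(groups: list[GroupSpec]) -> dict[str, list[str]]:
    prefixes = {
        "aus-like": "arr", "indica-like": "irr", "wild-like": "wrr",
        "admixed-weed": "adw", "aus": "aus", "indica": "ind",
        "japonica": "jap", "admixed-cultivar": "adc", "wild": "or",
        "outgroup": "omd",
    }
    out = {}
    for g in groups:
        pre = prefixes.get(g.name, g.name[:3])
        out[g.name] = [f"{pre}{i + 1:02d}" for i in range(g.n_accessions)]
    return out


def plant_functional_polymorphisms(
    sequences: dict[str, np.ndarray],
    members_by_group: dict[str, list[str]],
    planted: PlantedGene,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Assign allele classes per group at the stated frequencies and
    rewrite the sequences accordingly.

    Carrier counts are round-half-up of frequency x group size, sampled
    without replacement; overlapping planted intervals are a hard error.
    Returns the truth table (accession, gene, true class).
    """
    spans: list[tuple[int, int, str, str]] = []
    for al in planted.alleles:
        for comp in al.components:
            key = f"{comp.kind}:{comp.start}:{comp.end}:{comp.alt}"
            for s, e, other_key, other_class in spans:
                if comp.start < e and s < comp.end and other_key != key:
                    raise ValueError(
                        f"{planted.gene}: planted interval [{comp.start},{comp.end}) "
                        f"({al.allele_class}) collides with [{s},{e}) ({other_class})"
                    )
            spans.append((comp.start, comp.end, key, al.allele_class))

    # enforce the wild-type state at every diagnostic column first
    truth_rows = []
    for group, members in members_by_group.items():
        n = len(members)
        order = list(rng.permutation(n))
        assigned: dict[str, str] = {m: planted.wildtype_class for m in members}
        cursor = 0
        for al in planted.alleles:
            f = al.frequency.get(group, 0.0)
            k = min(_round_half_up(f * n), n - cursor)
            for idx in order[cursor: cursor + k]:
                assigned[members[idx]] = al.allele_class
            cursor += k
        for m in members:
            row = sequences[m]
            for al in planted.alleles:
                carrier = assigned[m] == al.allele_class
                for comp in al.components:
                    if comp.kind == "indel":
                        if carrier:
                            row[comp.start: comp.end] = "-"
                        # non-carriers keep their (ungapped) bases
                    else:
                        if carrier:
                            row[comp.start: comp.end] = comp.alt
            truth_rows.append(
                dict(accession=m, gene=planted.gene, true_class=assigned[m])
            )
    return pd.DataFrame(truth_rows)


def _reset_diagnostic_columns(
    sequences: dict[str, np.ndarray], planted: PlantedGene, ancestral: str
) -> None:
    """Give every row the ancestral (wild-type) state at diagnostic columns
    so that background coalescent mutations never mimic a diagnostic."""
    for al in planted.alleles:
        for comp in al.components:
            for row in sequences.values():
                row[comp.start: comp.end] = list(ancestral[comp.start: comp.end])


def generate_phenotypes(
    allele_truth: pd.DataFrame,
    planted_genes: list[PlantedGene],
    model: PhenotypeModel,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phenotypes from genotype truth with discordance rate epsilon.

    Each accession gets its expected phenotype with probability
    1 - epsilon, otherwise a uniformly chosen *other* level of that
    trait. Returns (phenotypes, flip truth table).
    """
    pheno_rows: dict[str, dict[str, str]] = {}
    flips = []
    eps = model.discordance_rate
    for pg in planted_genes:
        if pg.phenotype_column is None or not pg.expectation_map:
            continue
        levels = model.levels.get(pg.phenotype_column)
        if levels is None:
            levels = tuple(sorted(set(pg.expectation_map.values())))
        sub = allele_truth[allele_truth["gene"] == pg.gene]
        for rec in sub.itertuples():
            expected = pg.expectation_map[rec.true_class]
            if eps > 0 and rng.random() < eps:
                others = [l for l in levels if l != expected]
                observed = str(rng.choice(others)) if others else expected
                flipped = observed != expected
            else:
                observed = expected
                flipped = False
            pheno_rows.setdefault(rec.accession, {})[pg.phenotype_column] = observed
            flips.append(
                dict(accession=rec.accession, trait=pg.phenotype_column,
                     expected=expected, observed=observed, flipped=flipped)
            )
    df = pd.DataFrame.from_dict(pheno_rows, orient="index")
    df.index.name = "accession"
    return df, pd.DataFrame(flips)


@dataclass
class PanelBundle:
    """In-memory result of a panel simulation."""

    config: SimConfig
    panel: Panel
    loci: dict[str, AlignedLocus]
    annotations: dict[str, GeneAnnotation]
    rules: list[AlleleRule]
    allele_truth: pd.DataFrame
    phenotype_flips: pd.DataFrame


def rules_from_planted(
    planted: list[PlantedGene], ancestral_by_locus: dict[str, str]
) -> list[AlleleRule]:
    """Derive allele-rule configuration from the generator's planted spec.

    Genes whose alleles are single diagnostics become ordered
    class-map rules with the wild-type class as fallback; genes with
    multi-diagnostic alleles (Sdr4-style haplotype classes) become
    profile rules — one profile per allele class including the wild
    type, with fallback "unclassified" for recombinant patterns.
    """
    rules = []
    for pg in planted:
        ancestral = ancestral_by_locus[pg.locus_id]
        # unique diagnostics shared across alleles
        diag_by_key: dict[str, Diagnostic] = {}
        obs_by_key: dict[str, str] = {}
        for al in pg.alleles:
            for comp in al.components:
                key = f"{comp.kind}:{comp.start}:{comp.end}:{comp.alt}"
                if key in diag_by_key:
                    continue
                name = f"d{len(diag_by_key) + 1}"
                if comp.kind == "indel":
                    diag_by_key[key] = Diagnostic(name, "indel", comp.start, comp.end)
                    obs_by_key[key] = DEL_OBS
                else:
                    diag_by_key[key] = Diagnostic(
                        name, "snp", comp.start, comp.start + 1,
                        ancestral[comp.start], (comp.alt,),
                    )
                    obs_by_key[key] = comp.alt

        multi = any(len(al.components) > 1 for al in pg.alleles)

        def pattern_of(al: PlantedAllele) -> dict[str, str]:
            out = {}
            for comp in al.components:
                key = f"{comp.kind}:{comp.start}:{comp.end}:{comp.alt}"
                out[diag_by_key[key].name] = obs_by_key[key]
            return out

        if multi:
            wt_profile = {
                d.name: (REF_OBS if d.kind == "indel" else d.reference_state)
                for d in diag_by_key.values()
            }
            profiles = [(pg.wildtype_class, wt_profile)] + [
                (al.allele_class, pattern_of(al)) for al in pg.alleles
            ]
            rules.append(
                AlleleRule(pg.gene, pg.locus_id, list(diag_by_key.values()),
                           [], "unclassified", profiles)
            )
        else:
            class_map = [(pattern_of(al), al.allele_class) for al in pg.alleles]
            rules.append(
                AlleleRule(pg.gene, pg.locus_id, list(diag_by_key.values()),
                           class_map, pg.wildtype_class, [])
            )
    return rules


def generate_panel(config: SimConfig, outdir: str | os.PathLike | None = None) -> PanelBundle:
    """Simulate a complete panel; optionally write the on-disk bundle.

    The bundle (per-locus FASTA, panel TSV, annotation TSV, allele-rule
    YAML, truth TSVs, manifest JSON) round-trips through the package's
    readers without modification.
    """
    rng = np.random.default_rng(config.seed)
    names = _accession_names(config.groups)
    group_of = {a: g.name for g in config.groups for a in names[g.name]}
    planted_by_locus = {pg.locus_id: pg for pg in config.planted}

    loci: dict[str, AlignedLocus] = {}
    annotations: dict[str, GeneAnnotation] = {}
    ancestral_by_locus: dict[str, str] = {}
    truth_frames = []

    # ancestors must be simulated before any weed group that clones them
    group_order = sorted(
        config.groups, key=lambda g: g.ancestral_group is not None
    )

    for spec in config.loci:
        L = spec.length
        ancestral = list("".join(rng.choice(BASES, size=L)))
        protected: set[int] = set()
        for pos, motif in spec.motifs:
            ancestral[pos: pos + len(motif)] = list(motif)
            protected.update(range(pos, pos + len(motif)))
        pg = planted_by_locus.get(spec.locus_id)
        if pg is not None:
            for al in pg.alleles:
                for comp in al.components:
                    protected.update(range(comp.start, comp.end))
        if spec.annotation is not None:
            _enforce_orf(ancestral, spec.annotation, protected)
        ancestral = "".join(ancestral)
        ancestral_by_locus[spec.locus_id] = ancestral

        sequences: dict[str, np.ndarray] = {}
        cluster_mut: dict[str, dict[int, str]] = {}
        free_cols = [c for c in range(L) if c not in protected]
        rng.shuffle(free_cols)
        col_cursor = 0
        for cluster, div in sorted(config.cluster_divergence.items()):
            k = rng.poisson(div * L)
            muts = {}
            for _ in range(k):
                if col_cursor >= len(free_cols):
                    break
                c = free_cols[col_cursor]
                col_cursor += 1
                muts[c] = str(rng.choice([b for b in "ACGT" if b != ancestral[c]]))
            cluster_mut[cluster] = muts

        fixed_cols: set[int] = set(protected)
        for muts in cluster_mut.values():
            fixed_cols.update(muts)

        clusters: dict[str, list[GroupSpec]] = {}
        for g in config.groups:
            clusters.setdefault(g.cluster or g.name, []).append(g)
        for cluster, cgroups in clusters.items():
            base = next(
                (g.name for g in cgroups if g.name == cluster), cgroups[0].name
            )
            deme_sizes = {
                g.name: (g.n_accessions, g.theta_per_site / config.theta_scale)
                for g in cgroups
            }
            split_times = {
                g.name: g.split_time for g in cgroups if g.name != base
            }
            by_deme = simulate_split_cluster(
                deme_sizes, split_times, base,
                config.theta_scale * L, L, rng, ancestral,
                frozenset(fixed_cols),
            )
            muts = cluster_mut.get(cluster, {})
            for g in cgroups:
                for m, row in zip(names[g.name], by_deme[g.name]):
                    arr = np.array(list(row), dtype="U1")
                    for c, b in muts.items():
                        arr[c] = b
                    sequences[m] = arr
        if config.clone_weeds_from_ancestors:
            for g in group_order:
                if g.ancestral_group is None:
                    continue
                donors = names[g.ancestral_group]
                picks = rng.integers(0, len(donors), size=len(names[g.name]))
                for m, p in zip(names[g.name], picks):
                    sequences[m] = sequences[donors[p]].copy()

        if pg is not None:
            _reset_diagnostic_columns(sequences, pg, ancestral)
            members_by_group = {g.name: names[g.name] for g in config.groups}
            truth = plant_functional_polymorphisms(
                sequences, members_by_group, pg, rng
            )
            truth_frames.append(truth)

        acc_ids = [a for g in config.groups for a in names[g.name]]
        loci[spec.locus_id] = AlignedLocus(
            spec.locus_id, acc_ids, ["".join(sequences[a]) for a in acc_ids]
        )
        if spec.annotation is not None:
            annotations[spec.locus_id] = spec.annotation

    allele_truth = (
        pd.concat(truth_frames, ignore_index=True)
        if truth_frames
        else pd.DataFrame(columns=["accession", "gene", "true_class"])
    )
    phenotypes, flips = generate_phenotypes(
        allele_truth, config.planted, config.phenotype_model, rng
    )

    # panel table: group + generated phenotypes + architecture traits
    acc_ids = [a for g in config.groups for a in names[g.name]]
    table = pd.DataFrame(index=pd.Index(acc_ids, name="accession"))
    table["group"] = [group_of[a] for a in acc_ids]
    for col in ("pericarp", "hull", "awn", "tiller_angle_class", "shattering_class"):
        table[col] = wio.MISSING
    for acc, row in phenotypes.iterrows():
        for col, val in row.items():
            table.at[acc, col] = val
    angle_by_cluster = {"wild": ["60-90", "30-60"], "outgroup": ["60-90"]}
    for g in config.groups:
        choices = angle_by_cluster.get(g.cluster, ["<30", "30-60"])
        for a in names[g.name]:
            table.at[a, "awn"] = (
                "present" if g.cluster in ("wild", "outgroup") or rng.random() < 0.3
                else "absent"
            )
            table.at[a, "tiller_angle_class"] = str(rng.choice(choices))
    tiller_mean = {"wild": 11.5, "outgroup": 11.0}
    table["tiller_number"] = [
        max(1, int(round(rng.normal(tiller_mean.get(
            next(g.cluster for g in config.groups if g.name == group_of[a]), 8.0
        ), 3.0))))
        for a in acc_ids
    ]
    bts_range = {"strong": (0.0, 10.0), "medium": (10.0, 25.0),
                 "low": (25.0, 45.0), "non": (45.0, 60.0)}
    bts = []
    for a in acc_ids:
        sc = table.at[a, "shattering_class"]
        if sc in bts_range:
            lo, hi = bts_range[sc]
            bts.append(round(float(rng.uniform(lo, hi)), 2))
        else:
            bts.append(np.nan)
    table["bts_grams"] = bts
    panel = Panel(table)

    rules = rules_from_planted(config.planted, ancestral_by_locus)
    bundle = PanelBundle(config, panel, loci, annotations, rules,
                         allele_truth, flips)
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: PanelBundle, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    loci_dir = os.path.join(outdir, "loci")
    os.makedirs(loci_dir, exist_ok=True)
    for locus_id, locus in bundle.loci.items():
        wio.write_alignment_fasta(locus, os.path.join(loci_dir, f"{locus_id}.fasta"))
    wio.write_panel_table(bundle.panel, os.path.join(outdir, "panel.tsv"))
    wio.write_annotation_table(
        bundle.annotations, os.path.join(outdir, "annotations.tsv")
    )
    wio.write_allele_rules(bundle.rules, os.path.join(outdir, "allele_rules.yaml"))
    bundle.allele_truth.to_csv(
        os.path.join(outdir, "truth_alleles.tsv"), sep="\t", index=False
    )
    bundle.phenotype_flips.to_csv(
        os.path.join(outdir, "truth_phenotype_flips.tsv"), sep="\t", index=False
    )
    manifest = dict(
        seed=bundle.config.seed,
        n_accessions=sum(g.n_accessions for g in bundle.config.groups),
        n_loci=len(bundle.loci),
        groups={g.name: g.n_accessions for g in bundle.config.groups},
        discordance_rate=bundle.config.phenotype_model.discordance_rate,
    )
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def read_bundle(outdir) -> tuple[Panel, dict[str, AlignedLocus], dict[str, GeneAnnotation], list[AlleleRule]]:
    """Load a bundle with the standard readers (no special-casing)."""
    import glob

    panel = wio.read_panel_table(os.path.join(outdir, "panel.tsv"))
    loci = {}
    for path in sorted(glob.glob(os.path.join(outdir, "loci", "*.fasta"))):
        locus = wio.read_alignment_fasta(path)
        loci[locus.locus_id] = locus
    annotations = wio.read_annotation_table(os.path.join(outdir, "annotations.tsv"))
    rules = wio.read_allele_rules(
        os.path.join(outdir, "allele_rules.yaml"),
        {lid: l.length for lid, l in loci.items()},
    )
    return panel, loci, annotations, rules
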