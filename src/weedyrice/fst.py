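"""Pairwise group differentiation (F_ST), genome-wide aggregation and the
two-standard-deviation outlier scan.

Two estimators are provided:

* ``"hudson"`` (default): the sequence-based form 1 - pi_within /
  pi_between, with pi_within the mean of the two within-group per-site
  diversities and pi_between the mean per-site difference across all
  between-group pairs (pairwise deletion).
* ``"weir-cockerham"``: the variance-components estimator on per-site
  haploid allele frequencies, combined over sites as a ratio of sums.

Negative raw values are clamped to zero in the reported value, matching
the convention of reporting F_ST on [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import _valid_mask, nucleotide_diversity_pi
from .io import AlignedLocus, Panel
from .sites import SiteClassMap, classify_sites

#: The seven weed/ancestor/cultivar population pairs analysed by default.
DEFAULT_PAIRS = (
    ("aus-like", "aus"),
    ("indica-like", "indica"),
    ("wild-like", "wild"),
    ("aus", "indica"),
    ("aus-like", "indica-like"),
    ("aus-like", "wild-like"),
    ("indica-like", "wild-like"),
)


@dataclass
class FstResult:
    locus_id: str
    pair: tuple[str, str]
    fst_raw: float
    fst: float
    n_a: int
    n_b: int
    outlier: bool = False


def _between_pi(matA: np.ndarray, matB: np.ndarray, weights: np.ndarray,
                count_cols: np.ndarray) -> float:
    validA = _valid_mask(matA)
    validB = _valid_mask(matB)
    ratios = []
    for i in range(matA.shape[0]):
        for j in range(matB.shape[0]):
            both = validA[i] & validB[j]
            comp = float(weights[both].sum())
            if comp <= 0:
                continue
            diffs = int(np.count_nonzero((matA[i] != matB[j]) & both & count_cols))
            ratios.append(diffs / comp)
    return float(np.mean(ratios)) if ratios else float("nan")


def pairwise_fst(
    locus: AlignedLocus,
    panel: Panel,
    group_a: str,
    group_b: str,
    site_map: SiteClassMap | None = None,
    site_class: str = "all",
    estimator: str = "hudson",
) -> FstResult:
    """Per-locus F_ST between two groups; NaN when undefined.

    ``pi_between == 0`` (identical groups) yields fst = 0 rather than a
    0/0 indeterminate.
    """
    members_a = [m for m in panel.members(group_a) if m in locus.accession_ids]
    members_b = [m for m in panel.members(group_b) if m in locus.accession_ids]
    n_a, n_b = len(members_a), len(members_b)
    if n_a < 2 or n_b < 2:
        return FstResult(locus.locus_id, (group_a, group_b),
                         float("nan"), float("nan"), n_a, n_b)
    if site_map is None:
        site_map = classify_sites(locus, None)

    if estimator == "hudson":
        raw = _hudson_fst(locus, members_a, members_b, site_map, site_class)
    elif estimator == "weir-cockerham":
        raw = _wc_fst(locus, members_a, members_b, site_map, site_class)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    fst = raw if math.isnan(raw) else min(max(raw, 0.0), 1.0)
    return FstResult(locus.locus_id, (group_a, group_b), raw, fst, n_a, n_b)


def _hudson_fst(locus, members_a, members_b, site_map, site_class) -> float:
    pi_a = nucleotide_diversity_pi(locus, members_a, site_map, site_class)
    pi_b = nucleotide_diversity_pi(locus, members_b, site_map, site_class)
    weights = site_map.class_weights(site_class)
    count_cols = site_map.class_columns(site_class)
    matA = locus.subset(members_a).matrix()
    matB = locus.subset(members_b).matrix()
    pi_between = _between_pi(matA, matB, weights, count_cols)
    if math.isnan(pi_between) or math.isnan(pi_a) or math.isnan(pi_b):
        return float("nan")
    if pi_between == 0.0:
        return 0.0
    pi_within = 0.5 * (pi_a + pi_b)
    return 1.0 - pi_within / pi_between


def _wc_fst(locus, members_a, members_b, site_map, site_class) -> float:
    """Weir–Cockerham theta for haploid-coded sequences, ratio of sums."""
    count_cols = site_map.class_columns(site_class)
    matA = locus.subset(members_a).matrix()
    matB = locus.subset(members_b).matrix()
    validA = _valid_mask(matA)
    validB = _valid_mask(matB)
    r = 2
    num = 0.0
    den = 0.0
    for c in np.flatnonzero(count_cols):
        colA = matA[validA[:, c], c]
        colB = matB[validB[:, c], c]
        nA, nB = colA.size, colB.size
        if nA < 2 or nB < 2:
            continue
        alleles = sorted(set(colA) | set(colB))
        if len(alleles) < 2:
            continue
        n_tot = nA + nB
        nbar = n_tot / r
        nc = (n_tot - (nA * nA + nB * nB) / n_tot) / (r - 1)
        for al in alleles:
            pA = float(np.count_nonzero(colA == al)) / nA
            pB = float(np.count_nonzero(colB == al)) / nB
            pbar = (nA * pA + nB * pB) / n_tot
            s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1) * nbar)
            # haploid analogue of WC84: between-population component a and
            # within-population component b
            a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2) / (nbar - 1))
            b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2)
            num += a
            den += a + b
    if den == 0.0:
        return 0.0
    return num / den


def genomewide_fst(
    loci: dict[str, AlignedLocus],
    panel: Panel,
    pair: tuple[str, str],
    site_maps: dict[str, SiteClassMap] | None = None,
    site_class: str = "all",
    estimator: str = "hudson",
) -> tuple[FstResult, float, float, list[FstResult]]:
    """Genome-wide F_ST for one pair: unweighted mean of per-locus clamped
    values, with the across-locus SD retained for outlier scanning.

    Returns (genome-wide result, mean, sd, per-locus results).
    """
    per_locus = []
    for locus in loci.values():
        smap = site_maps.get(locus.locus_id) if site_maps else None
        per_locus.append(
            pairwise_fst(locus, panel, pair[0], pair[1], smap, site_class, estimator)
        )
    vals = np.array([r.fst for r in per_locus if not math.isnan(r.fst)])
    if vals.size < 1:
        gw = FstResult("genome-wide", pair, float("nan"), float("nan"), 0, 0)
        return gw, float("nan"), float("nan"), per_locus
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size >= 2 else float("nan")
    gw = FstResult(
        "genome-wide", pair, mean, mean,
        max(r.n_a for r in per_locus), max(r.n_b for r in per_locus),
    )
    return gw, mean, sd, per_locus


def fst_outliers(
    per_locus_results: list[FstResult], genome_mean: float, genome_sd: float
) -> list[FstResult]:
    """Flag loci whose clamped F_ST strictly exceeds mean + 2 SD.

    With SD = 0 (or undefined), only values strictly greater than the
    mean are flagged.
    """
    if math.isnan(genome_sd):
        cutoff = genome_mean
    else:
        cutoff = genome_mean + 2.0 * genome_sd
    flagged = []
    for r in per_locus_results:
        r.outlier = (not math.isnan(r.fst)) and r.fst > cutoff
        if r.outlier:
            flagged.append(r)
    return flagged


def fst_report(
    loci: dict[str, AlignedLocus],
    panel: Panel,
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
    site_maps: dict[str, SiteClassMap] | None = None,
    site_class: str = "all",
    estimator: str = "hudson",
) -> pd.DataFrame:
    """Gene x pair F_ST matrix with a genome-wide row and outlier flags."""
    rows = []
    for pair in pairs:
        gw, mean, sd, per_locus = genomewide_fst(
            loci, panel, pair, site_maps, site_class, estimator
        )
        fst_outliers(per_locus, mean, sd)
        for r in per_locus + [gw]:
            rows.append(
                dict(
                    locus=r.locus_id,
                    pair=f"{pair[0]} vs {pair[1]}",
                    fst=r.fst,
                    fst_raw=r.fst_raw,
                    n_a=r.n_a,
                    n_b=r.n_b,
                    outlier=r.outlier,
                )
            )
    return pd.DataFrame(rows)
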