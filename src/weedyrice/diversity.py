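"""Per-locus, per-group, per-site-class diversity statistics.

pi is Nei's average pairwise nucleotide diversity per site; theta_w is
Watterson's estimator S/(a1 * L_eff); Tajima's D normalises the
difference between the mean total pairwise difference count and S/a1
with the Tajima (1989) variance constants derived from n.

Missing-data policy (configurable):

* ``"pairwise"`` (default for pi): each pair is normalised by the class
  sites at which both sequences carry an unambiguous base (pairwise
  deletion); gaps, N and ? are excluded per pair.
* ``"complete"``: only columns where every member carries an unambiguous
  base are used.

S (and hence theta_w) and the internals of Tajima's D always use
complete deletion so that the Tajima variance formula, which assumes one
set of n sequences observed at every site, stays coherent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AlignedLocus, Panel
from .sites import SITE_CLASSES, SiteClassMap, classify_sites

#: Table-style extreme-value flag thresholds
LOW_DIVERSITY_THRESHOLD = 0.0005
EXTREME_D_THRESHOLD = 2.0

_VALID = np.frompyfunc(lambda c: c in "ACGT", 1, 1)


def _valid_mask(mat: np.ndarray) -> np.ndarray:
    return (mat == "A") | (mat == "C") | (mat == "G") | (mat == "T")


def harmonic(n: int) -> float:
    """a1 = sum_{i=1}^{n-1} 1/i."""
    return float(sum(1.0 / i for i in range(1, n)))


@dataclass
class DiversityEstimate:
    locus_id: str
    group: str
    site_class: str
    n: int
    L_eff: float
    S: int
    pi: float  # per-site; NaN when undefined
    theta_w: float
    tajima_d: float  # NaN when undefined (S == 0 or n < 3)
    flags: set[str] = field(default_factory=set)

    def apply_flags(self) -> "DiversityEstimate":
        self.flags = set()
        if (not math.isnan(self.pi) and self.pi < LOW_DIVERSITY_THRESHOLD) or (
            not math.isnan(self.theta_w) and self.theta_w < LOW_DIVERSITY_THRESHOLD
        ):
            self.flags.add("low_diversity")
        if not math.isnan(self.tajima_d) and abs(self.tajima_d) > EXTREME_D_THRESHOLD:
            self.flags.add("extreme_D")
        return self


def nucleotide_diversity_pi(
    locus: AlignedLocus,
    members: list[str],
    site_map: SiteClassMap | None = None,
    site_class: str = "all",
    policy: str = "pairwise",
) -> float:
    """Mean per-site pairwise difference over all unordered member pairs.

    Differences are counted at columns whose observed polymorphism falls
    in ``site_class``; each pair is normalised by the fractional class
    site count over columns comparable for that pair. Returns NaN when no
    pair has a comparable site.
    """
    if len(members) < 2:
        return float("nan")
    sub = locus.subset(members)
    mat = sub.matrix()
    if site_map is None:
        site_map = classify_sites(locus, None)
    weights = site_map.class_weights(site_class)
    count_cols = site_map.class_columns(site_class)
    valid = _valid_mask(mat)

    if policy == "complete":
        keep = valid.all(axis=0)
        valid = valid & keep

    n = len(members)
    ratios = []
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            comp_sites = float(weights[both].sum())
            if comp_sites <= 0:
                continue
            diffs = int(np.count_nonzero((mat[i] != mat[j]) & both & count_cols))
            ratios.append(diffs / comp_sites)
    if not ratios:
        return float("nan")
    return float(np.mean(ratios))


def _complete_columns(mat: np.ndarray) -> np.ndarray:
    return _valid_mask(mat).all(axis=0)


def segregating_sites(
    locus: AlignedLocus,
    members: list[str],
    site_map: SiteClassMap | None = None,
    site_class: str = "all",
) -> tuple[int, float, float]:
    """(S, L_eff, Pi_total) under complete deletion for a site class.

    S counts class columns with >= 2 distinct bases among members
    (multi-allelic columns count once); L_eff is the fractional class
    site total over complete columns; Pi_total is the mean total pairwise
    difference count at class columns (Tajima's capital-Pi).
    """
    sub = locus.subset(members)
    mat = sub.matrix()
    if site_map is None:
        site_map = classify_sites(locus, None)
    keep = _complete_columns(mat)
    count_cols = site_map.class_columns(site_class) & keep
    weights = site_map.class_weights(site_class)
    L_eff = float(weights[keep].sum())

    n = mat.shape[0]
    S = 0
    pi_total = 0.0
    npairs = n * (n - 1) / 2
    for c in np.flatnonzero(count_cols):
        col = mat[:, c]
        _, counts = np.unique(col, return_counts=True)
        if counts.size >= 2:
            S += 1
            same = float(sum(k * (k - 1) / 2 for k in counts))
            pi_total += (npairs - same) / npairs
    return S, L_eff, pi_total


def watterson_theta(
    locus: AlignedLocus,
    members: list[str],
    site_map: SiteClassMap | None = None,
    site_class: str = "all",
) -> float:
    """Watterson's per-site estimator S / (a1 * L_eff); NaN when n < 2."""
    if len(members) < 2:
        return float("nan")
    S, L_eff, _ = segregating_sites(locus, members, site_map, site_class)
    if L_eff <= 0:
        return float("nan")
    if S == 0:
        return 0.0
    return S / (harmonic(len(members)) * L_eff)


def tajima_constants(n: int) -> tuple[float, float]:
    """(e1, e2) of Tajima (1989) for sample size n."""
    a1 = harmonic(n)
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return e1, e2


def tajimas_d(
    locus: AlignedLocus,
    members: list[str],
    site_map: SiteClassMap | None = None,
    site_class: str = "all",
) -> float:
    """Tajima's D; NaN (reported NA) when S = 0 or n < 3."""
    n = len(members)
    if n < 3:
        return float("nan")
    S, _, pi_total = segregating_sites(locus, members, site_map, site_class)
    if S == 0:
        return float("nan")
    a1 = harmonic(n)
    e1, e2 = tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi_total - S / a1) / math.sqrt(var)


def diversity_estimate(
    locus: AlignedLocus,
    group: str,
    members: list[str],
    site_map: SiteClassMap | None = None,
    site_class: str = "all",
    policy: str = "pairwise",
) -> DiversityEstimate:
    members = [m for m in members if m in locus.accession_ids]
    n = len(members)
    if n < 2:
        return DiversityEstimate(
            locus.locus_id, group, site_class, n, float("nan"), 0,
            float("nan"), float("nan"), float("nan"),
        )
    if site_map is None:
        site_map = classify_sites(locus, None)
    S, L_eff, _ = segregating_sites(locus, members, site_map, site_class)
    pi = nucleotide_diversity_pi(locus, members, site_map, site_class, policy)
    theta = watterson_theta(locus, members, site_map, site_class)
    if S == 0 and not math.isnan(pi):
        pi = 0.0 if policy == "complete" else pi
    d = tajimas_d(locus, members, site_map, site_class)
    return DiversityEstimate(
        locus.locus_id, group, site_class, n, L_eff, S, pi, theta, d
    ).apply_flags()


def summarize_diversity(
    loci: dict[str, AlignedLocus],
    panel: Panel,
    groups: list[str],
    site_classes: tuple[str, ...] = SITE_CLASSES,
    site_maps: dict[str, SiteClassMap] | None = None,
    policy: str = "pairwise",
    genomewide: str = "mean",
) -> pd.DataFrame:
    """One row per locus x group x class, plus genome-wide rows.

    The genome-wide row (``locus_id = "All loci"``) is by default the
    unweighted mean of per-locus values (``genomewide="mean"``);
    ``"concatenated"`` instead pools S, L_eff and Pi over loci and
    recomputes the statistics as if loci formed one alignment (n taken as
    the minimum per-locus n).
    """
    rows = []
    per_locus: dict[tuple[str, str], list[DiversityEstimate]] = {}
    for locus_id, locus in loci.items():
        smap = site_maps.get(locus_id) if site_maps else classify_sites(locus, None)
        for group in groups:
            members = [m for m in panel.members(group) if m in locus.accession_ids]
            for sc in site_classes:
                est = diversity_estimate(locus, group, members, smap, sc, policy)
                rows.append(est)
                per_locus.setdefault((group, sc), []).append(est)

    for (group, sc), ests in per_locus.items():
        usable = [e for e in ests if e.n >= 2]
        if not usable:
            continue
        if genomewide == "mean":
            pis = [e.pi for e in usable if not math.isnan(e.pi)]
            thetas = [e.theta_w for e in usable if not math.isnan(e.theta_w)]
            ds = [e.tajima_d for e in usable if not math.isnan(e.tajima_d)]
            gw = DiversityEstimate(
                "All loci", group, sc,
                min(e.n for e in usable),
                float(np.nansum([e.L_eff for e in usable])),
                int(sum(e.S for e in usable)),
                float(np.mean(pis)) if pis else float("nan"),
                float(np.mean(thetas)) if thetas else float("nan"),
                float(np.mean(ds)) if ds else float("nan"),
            )
        elif genomewide == "concatenated":
            n = min(e.n for e in usable)
            S = int(sum(e.S for e in usable))
            L = float(np.nansum([e.L_eff for e in usable]))
            pis = [
                (e.pi * e.L_eff, e.L_eff)
                for e in usable
                if not math.isnan(e.pi) and not math.isnan(e.L_eff)
            ]
            pi = sum(a for a, _ in pis) / sum(b for _, b in pis) if pis else float("nan")
            theta = S / (harmonic(n) * L) if n >= 2 and L > 0 else float("nan")
            # D over the pooled alignment, with pooled Pi approximated from
            # per-locus per-site pi times length
            pi_total = pi * L if not math.isnan(pi) else float("nan")
            if S > 0 and n >= 3 and not math.isnan(pi_total):
                a1 = harmonic(n)
                e1, e2 = tajima_constants(n)
                var = e1 * S + e2 * S * (S - 1)
                d = (pi_total - S / a1) / math.sqrt(var) if var > 0 else float("nan")
            else:
                d = float("nan")
            gw = DiversityEstimate("All loci", group, sc, n, L, S, pi, theta, d)
        else:
            raise ValueError(f"unknown genomewide mode {genomewide!r}")
        rows.append(gw.apply_flags())

    return pd.DataFrame(
        dict(
            locus=[r.locus_id for r in rows],
            group=[r.group for r in rows],
            site_class=[r.site_class for r in rows],
            n=[r.n for r in rows],
            L_eff=[r.L_eff for r in rows],
            S=[r.S for r in rows],
            pi=[r.pi for r in rows],
            theta_w=[r.theta_w for r in rows],
            tajima_d=[r.tajima_d for r in rows],
            flags=[",".join(sorted(r.flags)) for r in rows],
        )
    )
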