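"""Group phenotype summaries, genotype-phenotype concordance and
Kruskal-Wallis group comparisons.

Expected-phenotype maps (which allele class should produce which
phenotype, e.g. wild-type Rc -> red pericarp, rc / Rc-s -> white) are
configuration, not code: the biology is qualitative and panel-specific.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import MISSING, Panel

#: Default genotype -> expected phenotype maps for the candidate genes.
DEFAULT_EXPECTATION_MAPS = {
    "Rc": {"Rc": "red", "rc": "white", "Rc-s": "white"},
    "Bh4": {
        "Bh4-wildtype": "black",
        "bh4-del22": "straw",
        "bh4-del1": "straw",
        "bh4-stop": "straw",
    },
    # shattering-competent wild-type vs the domesticated reduced-shattering
    # allele; values are the acceptable class levels for each genotype
    "sh4": {"sh4-G": ("strong", "medium"), "sh4-T": ("low", "non")},
}

#: Breaking-tensile-strength (grams) cut-offs for shattering classes.
#: Low force = easy shattering. These defaults are package assumptions;
#: override per study.
DEFAULT_BTS_THRESHOLDS = {"strong": 10.0, "medium": 25.0, "low": 45.0}


def shattering_class(bts_grams: float, thresholds: dict[str, float] | None = None) -> str:
    if thresholds is None:
        thresholds = DEFAULT_BTS_THRESHOLDS
    if math.isnan(bts_grams):
        return MISSING
    if bts_grams < thresholds["strong"]:
        return "strong"
    if bts_grams < thresholds["medium"]:
        return "medium"
    if bts_grams < thresholds["low"]:
        return "low"
    return "non"


def trait_summary(panel: Panel, trait: str, groups: list[str] | None = None) -> pd.DataFrame:
    """Per-group summary of one trait.

    Categorical traits: count and percent per level (percent of
    non-missing). Quantitative traits: mean and sample SD (SD missing
    for single-observation groups).
    """
    if groups is None:
        groups = panel.groups()
    rows = []
    if trait in Panel.CATEGORICAL:
        levels = Panel.CATEGORICAL[trait]
        for g in groups:
            sub = panel.table.loc[panel.members(g), trait]
            non_missing = int((sub != MISSING).sum())
            row = dict(group=g, n=len(sub), n_scored=non_missing)
            for level in levels:
                k = int((sub == level).sum())
                row[f"{level}_n"] = k
                row[f"{level}_pct"] = (
                    100.0 * k / non_missing if non_missing else float("nan")
                )
            rows.append(row)
    elif trait in Panel.QUANTITATIVE:
        for g in groups:
            sub = pd.to_numeric(panel.table.loc[panel.members(g), trait], errors="coerce")
            vals = sub.dropna()
            rows.append(
                dict(
                    group=g,
                    n=len(sub),
                    n_scored=len(vals),
                    mean=float(vals.mean()) if len(vals) else float("nan"),
                    sd=float(vals.std(ddof=1)) if len(vals) >= 2 else float("nan"),
                )
            )
    else:
        raise ValueError(f"trait {trait!r} is neither categorical nor quantitative")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Concordance


@dataclass
class ConcordanceTable:
    gene: str
    expectation_map: dict[str, str]
    counts: pd.DataFrame  # phenotype x allele-class counts
    n_concordant: int
    n_discordant: int
    n_excluded: int  # partial-missing calls or missing phenotypes

    @property
    def percent_concordant(self) -> float:
        total = self.n_concordant + self.n_discordant
        return 100.0 * self.n_concordant / total if total else float("nan")


def concordance(
    allele_calls: pd.DataFrame,
    panel: Panel,
    gene: str,
    phenotype_column: str,
    expectation_map: dict[str, str],
) -> ConcordanceTable:
    """Score each accession concordant iff its phenotype equals the
    phenotype its allele class predicts.

    Map values may be a single level or a collection of acceptable
    levels (e.g. both "strong" and "medium" count as shattering-
    competent). Partial-missing calls and missing phenotypes are
    excluded and counted separately. An observed phenotype level absent
    from the map's value set is a hard error (the map must be total).
    """
    calls = allele_calls[allele_calls["gene"] == gene]
    norm_map = {
        cls: (levels,) if isinstance(levels, str) else tuple(levels)
        for cls, levels in expectation_map.items()
    }
    expected_levels = {l for levels in norm_map.values() for l in levels}
    n_con = n_dis = n_exc = 0
    counts: dict[tuple[str, str], int] = {}
    for rec in calls.itertuples():
        if rec.accession not in panel.table.index:
            continue
        pheno = panel.table.at[rec.accession, phenotype_column]
        if (
            rec.confidence != "complete"
            or pheno == MISSING
            or rec.allele_class not in expectation_map
        ):
            n_exc += 1
            continue
        if pheno not in expected_levels:
            raise ValueError(
                f"{gene}: phenotype level {pheno!r} not covered by the "
                f"expectation map {sorted(expected_levels)}"
            )
        counts[(pheno, rec.allele_class)] = counts.get((pheno, rec.allele_class), 0) + 1
        if pheno in norm_map[rec.allele_class]:
            n_con += 1
        else:
            n_dis += 1
    phenos = sorted({p for p, _ in counts} | expected_levels)
    classes = sorted(expectation_map)
    mat = pd.DataFrame(0, index=phenos, columns=classes)
    for (p, c), k in counts.items():
        mat.at[p, c] = k
    return ConcordanceTable(gene, expectation_map, mat, n_con, n_dis, n_exc)


# ---------------------------------------------------------------------------
# Kruskal-Wallis


@dataclass
class KWResult:
    trait: str
    groups: list[str]
    H: float
    df: int
    p_value: float
    post_hoc: dict[str, str] = field(default_factory=dict)  # group -> letters


def kruskal_wallis(
    values_by_group: dict[str, np.ndarray | list[float]],
    trait: str = "",
    post_hoc: bool = False,
    alpha: float = 0.05,
) -> KWResult:
    """Tie-corrected Kruskal-Wallis test with chi-square p-value.

    H = [12/(N(N+1))] * sum R_i^2/n_i - 3(N+1), divided by the tie
    correction 1 - sum(t^3 - t)/(N^3 - N) over tied-value run lengths t.
    All-identical values give H = 0, p = 1. Optional post hoc: all
    pairwise two-sided Mann-Whitney tests, Holm-corrected, summarised as
    a compact letter display.
    """
    groups = [g for g, v in values_by_group.items() if len(v) > 0]
    samples = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(samples)
    N = pooled.size
    if N < 2:
        raise ValueError("need at least two observations")
    df = len(groups) - 1

    ranks = stats.rankdata(pooled)
    H = 0.0
    idx = 0
    for s in samples:
        r = ranks[idx: idx + s.size]
        H += r.sum() ** 2 / s.size
        idx += s.size
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(tie_counts**3 - tie_counts)) / (N**3 - N)
    if correction <= 0:  # every value identical
        return KWResult(trait, groups, 0.0, df, 1.0)
    H /= correction
    H = max(H, 0.0)
    p = float(stats.chi2.sf(H, df))

    result = KWResult(trait, groups, float(H), df, p)
    if post_hoc and len(groups) >= 2:
        result.post_hoc = _letter_display(groups, samples, alpha)
    return result


def _letter_display(groups, samples, alpha) -> dict[str, str]:
    pairs = list(itertools.combinations(range(len(groups)), 2))
    pvals = []
    for i, j in pairs:
        if np.all(samples[i] == samples[i][0]) and np.all(
            samples[j] == samples[j][0]
        ) and samples[i][0] == samples[j][0]:
            pvals.append(1.0)
            continue
        _, p = stats.mannwhitneyu(samples[i], samples[j], alternative="two-sided")
        pvals.append(float(p))
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    differ = {pair for pair, rej in zip(pairs, reject) if rej}

    # greedy compact-letter display: assign letters so that two groups
    # share a letter iff they are not significantly different
    letters: list[set[int]] = []
    for g in range(len(groups)):
        placed = False
        for members in letters:
            if all((min(g, m), max(g, m)) not in differ for m in members):
                members.add(g)
                placed = True
        if not placed:
            letters.append({g})
    out = {name: "" for name in groups}
    for li, members in enumerate(letters):
        ch = chr(ord("a") + li)
        for m in sorted(members):
            out[groups[m]] += ch
    return out
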