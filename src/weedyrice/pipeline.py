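"""End-to-end orchestration: load a panel bundle, compute site classes,
diversity, F_ST, haplotype trees, allele calls, origin calls and
concordance, and write the report bundle.

Every stage writes a TSV (or Newick) and the run ends with a
machine-readable manifest recording the seed and every estimator switch,
so any stage can be reproduced by calling the module functions with the
recorded settings.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .alleles import call_alleles, infer_origin
from .diversity import summarize_diversity
from .fst import DEFAULT_PAIRS, fst_report
from .io import Panel, WEED_GROUPS, write_tsv
from .simulate import read_bundle
from .sites import SITE_CLASSES, classify_sites
from .traits import DEFAULT_EXPECTATION_MAPS, concordance, kruskal_wallis, trait_summary
from .trees import bootstrap_support, root_with_outgroup

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    seed: int
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS
    site_classes: tuple[str, ...] = SITE_CLASSES
    bootstrap_reps: int = 1000
    fst_estimator: str = "hudson"
    fst_site_class: str = "all"
    missing_policy: str = "pairwise"
    genomewide: str = "mean"
    tree_genes: tuple[str, ...] | None = None  # default: loci with allele rules
    outgroup: tuple[str, ...] = ("omd01", "omd02")
    expectation_maps: dict = field(default_factory=lambda: dict(DEFAULT_EXPECTATION_MAPS))
    concordance_traits: dict = field(
        default_factory=lambda: {"Rc": "pericarp", "Bh4": "hull", "sh4": "shattering_class"}
    )


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the manifest dict.

    A stage failure aborts the run with the stage name and offending
    locus; outputs written so far stay on disk next to a FAILED marker.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "input_dir": str(config.input_dir),
        "switches": {
            "fst_estimator": config.fst_estimator,
            "fst_site_class": config.fst_site_class,
            "missing_policy": config.missing_policy,
            "genomewide": config.genomewide,
            "bootstrap_reps": config.bootstrap_reps,
        },
        "stages": {},
    }
    stage = "load"
    try:
        t0 = time.time()
        panel, loci, annotations, rules = read_bundle(config.input_dir)
        manifest["stages"]["load"] = round(time.time() - t0, 2)

        stage = "site_classification"
        t0 = time.time()
        site_maps = {}
        for locus_id, locus in loci.items():
            ann = annotations.get(locus_id)
            site_maps[locus_id] = classify_sites(locus, ann)
        manifest["stages"][stage] = round(time.time() - t0, 2)

        stage = "trait_summary"
        t0 = time.time()
        groups = [g for g in panel.groups() if g != "outgroup"]
        cat_frames = []
        for trait in ("pericarp", "hull", "tiller_angle_class"):
            df = trait_summary(panel, trait, groups)
            df.insert(0, "trait", trait)
            cat_frames.append(df)
        write_tsv(pd.concat(cat_frames, ignore_index=True),
                  os.path.join(config.output_dir, "table1_categorical_traits.tsv"))
        quant_frames = []
        kw_rows = []
        for trait in ("tiller_number", "bts_grams"):
            df = trait_summary(panel, trait, groups)
            df.insert(0, "trait", trait)
            quant_frames.append(df)
            by_group = {
                g: panel.table.loc[panel.members(g), trait].dropna().to_numpy()
                for g in groups
            }
            by_group = {g: v for g, v in by_group.items() if len(v) >= 2}
            if len(by_group) >= 2:
                kw = kruskal_wallis(by_group, trait, post_hoc=True)
                kw_rows.append(
                    dict(trait=trait, H=kw.H, df=kw.df, p_value=kw.p_value,
                         letters=";".join(f"{g}={l}" for g, l in kw.post_hoc.items()))
                )
        write_tsv(pd.concat(quant_frames, ignore_index=True),
                  os.path.join(config.output_dir, "table2_quantitative_traits.tsv"))
        write_tsv(pd.DataFrame(kw_rows),
                  os.path.join(config.output_dir, "table2_kruskal_wallis.tsv"))
        manifest["stages"][stage] = round(time.time() - t0, 2)

        stage = "diversity"
        t0 = time.time()
        div = summarize_diversity(
            loci, panel, groups, config.site_classes, site_maps,
            config.missing_policy, config.genomewide,
        )
        write_tsv(div, os.path.join(config.output_dir, "table4_diversity.tsv"))
        manifest["stages"][stage] = round(time.time() - t0, 2)

        stage = "fst"
        t0 = time.time()
        fst = fst_report(loci, panel, config.pairs, site_maps,
                         config.fst_site_class, config.fst_estimator)
        write_tsv(fst, os.path.join(config.output_dir, "table5_fst.tsv"))
        outliers = fst[(fst["outlier"]) & (fst["locus"] != "genome-wide")]
        write_tsv(outliers, os.path.join(config.output_dir, "fst_outliers.tsv"))
        manifest["stages"][stage] = round(time.time() - t0, 2)

        stage = "alleles"
        t0 = time.time()
        calls = call_alleles(loci, rules)
        calls = calls.merge(
            panel.table["group"], left_on="accession", right_index=True, how="left"
        )
        write_tsv(calls, os.path.join(config.output_dir, "allele_calls.tsv"))
        manifest["stages"][stage] = round(time.time() - t0, 2)

        stage = "trees"
        t0 = time.time()
        tree_genes = config.tree_genes
        if tree_genes is None:
            tree_genes = tuple(r.locus_id for r in rules)
        for gene in tree_genes:
            locus = loci[gene]
            tree = bootstrap_support(
                locus, None, config.bootstrap_reps, config.seed
            )
            present_og = [o for o in config.outgroup if o in locus.accession_ids]
            if present_og:
                tree = root_with_outgroup(tree, present_og)
            tree.write_newick(os.path.join(config.output_dir, f"tree_{gene}.nwk"))
            leaf_ann = calls[calls["gene"].isin(
                [r.gene for r in rules if r.locus_id == gene]
            )][["accession", "allele_class", "group"]]
            write_tsv(leaf_ann,
                      os.path.join(config.output_dir, f"tree_{gene}_leaves.tsv"))
        manifest["stages"][stage] = round(time.time() - t0, 2)

        stage = "origin"
        t0 = time.time()
        origin_rows = []
        for rule in rules:
            locus = loci[rule.locus_id]
            for call in infer_origin(locus, panel, rule.gene):
                origin_rows.append(
                    dict(
                        accession=call.accession,
                        gene=call.gene,
                        call=call.call,
                        nearest=";".join(
                            f"{g}:{d:.5f}" for g, d in call.nearest_groups[:3]
                        ),
                    )
                )
        write_tsv(pd.DataFrame(origin_rows),
                  os.path.join(config.output_dir, "origin_calls.tsv"))
        manifest["stages"][stage] = round(time.time() - t0, 2)

        stage = "concordance"
        t0 = time.time()
        conc_rows = []
        for gene, trait in config.concordance_traits.items():
            if gene not in {r.gene for r in rules}:
                continue
            emap = config.expectation_maps.get(gene)
            if emap is None:
                continue
            table = concordance(calls, panel, gene, trait, emap)
            write_tsv(
                table.counts.reset_index(names="phenotype"),
                os.path.join(config.output_dir, f"table3_{gene}_counts.tsv"),
            )
            conc_rows.append(
                dict(gene=gene, trait=trait,
                     n_concordant=table.n_concordant,
                     n_discordant=table.n_discordant,
                     n_excluded=table.n_excluded,
                     percent_concordant=table.percent_concordant)
            )
        write_tsv(pd.DataFrame(conc_rows),
                  os.path.join(config.output_dir, "concordance_summary.tsv"))
        manifest["stages"][stage] = round(time.time() - t0, 2)
    except Exception as exc:
        with open(os.path.join(config.output_dir, "FAILED"), "w") as fh:
            fh.write(f"stage={stage}\nerror={exc!r}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(os.path.join(config.output_dir, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
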