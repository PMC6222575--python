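import numpy as np
import pytest

from weedyrice import simulate as sim
from weedyrice.io import AlignedLocus, GeneAnnotation, Panel


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic panel: all 10 groups, 8 loci (5 candidate genes)."""
    cfg = sim.default_config(seed=11, n_loci=8)
    return sim.generate_panel(cfg)


@pytest.fixture
def toy_locus():
    return AlignedLocus(
        "toy",
        ["a", "b", "c"],
        ["ACGTACGTAC", "ACGTACGTAC", "ACGTACTTAC"],
    )


@pytest.fixture
def coding_annotation():
    # 9-bp locus, all one exon, frame 0
    return GeneAnnotation("toy", "+", [("exon", 0, 9)], 0)


def make_locus(rows, ids=None, locus_id="t"):
    if ids is None:
        ids = [f"s{i}" for i in range(len(rows))]
    return AlignedLocus(locus_id, ids, rows)


@pytest.fixture
def make_panel():
    def _make(groups: dict[str, list[str]], **phenos):
        import pandas as pd

        accs = [a for members in groups.values() for a in members]
        table = pd.DataFrame(index=pd.Index(accs, name="accession"))
        table["group"] = [
            g for g, members in groups.items() for _ in members
        ]
        for col in ("pericarp", "hull", "awn", "tiller_angle_class",
                    "shattering_class"):
            table[col] = phenos.get(col, "missing")
        for col in ("tiller_number", "bts_grams"):
            table[col] = phenos.get(col, np.nan)
        return Panel(table)

    return _make
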