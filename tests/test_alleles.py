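"""Functional-allele calls, amino-acid haplotypes, origin inference, CAPS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from weedyrice.alleles import (
    CapsAssay,
    Enzyme,
    aa_haplotype,
    classify_allele,
    infer_origin,
    load_enzymes,
    simulate_caps,
)
from weedyrice.io import AlignedLocus, AlleleRule, Diagnostic, GeneAnnotation


def rc_rule():
    return AlleleRule(
        "Rc", "Rc",
        [
            Diagnostic("del14", "indel", 20, 34),
            Diagnostic("rcs", "snp", 5, 6, "C", ("A",)),
        ],
        [({"del14": "del"}, "rc"), ({"rcs": "A"}, "Rc-s")],
        "Rc",
    )


def base_row(length=60, fill="T"):
    return list(fill * length)


class TestClassifyAllele:
    def _locus(self, rows, ids=None):
        ids = ids or [f"s{i}" for i in range(len(rows))]
        return AlignedLocus("Rc", ids, rows)

    def test_fourteen_gap_interval_called_rc(self):
        row = base_row()
        row[20:34] = "-" * 14
        locus = self._locus(["".join(row)])
        call = classify_allele(locus, "s0", rc_rule())
        assert call.allele_class == "rc"
        assert call.confidence == "complete"

    def test_point_mutation_without_deletion_called_rc_s(self):
        row = base_row()
        row[5] = "A"
        locus = self._locus(["".join(row)])
        call = classify_allele(locus, "s0", rc_rule())
        assert call.allele_class == "Rc-s"

    def test_reference_states_fall_back_to_wildtype(self):
        locus = self._locus(["".join(base_row())])
        assert classify_allele(locus, "s0", rc_rule()).allele_class == "Rc"

    def test_mixed_gap_base_interval_is_partial_missing(self):
        row = base_row()
        row[20:27] = "-" * 7  # half the diagnostic interval
        locus = self._locus(["".join(row)])
        call = classify_allele(locus, "s0", rc_rule())
        assert call.confidence == "partial-missing"
        assert call.allele_class == "Rc"  # fallback

    def test_missing_snp_column_partial_missing(self):
        row = base_row()
        row[5] = "N"
        locus = self._locus(["".join(row)])
        call = classify_allele(locus, "s0", rc_rule())
        assert call.confidence == "partial-missing"

    def test_coordinates_outside_locus_rejected(self):
        locus = AlignedLocus("Rc", ["s0"], ["TTTT"])
        with pytest.raises(ValueError, match="outside locus"):
            classify_allele(locus, "s0", rc_rule())

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_non_diagnostic_columns(self, data):
        """Randomly mutating non-diagnostic columns never changes the call."""
        row = base_row()
        locus = self._locus(["".join(row)])
        before = classify_allele(locus, "s0", rc_rule()).allele_class
        diag_cols = set(range(20, 34)) | {5}
        free = [c for c in range(60) if c not in diag_cols]
        cols = data.draw(st.lists(st.sampled_from(free), max_size=10))
        bases = data.draw(
            st.lists(st.sampled_from("ACG-N?"), min_size=len(cols),
                     max_size=len(cols))
        )
        for c, b in zip(cols, bases):
            row[c] = b
        mutated = self._locus(["".join(row)])
        assert classify_allele(mutated, "s0", rc_rule()).allele_class == before


def sdr4_rule():
    snp_cols = [2, 6, 10, 14]
    diags = [Diagnostic(f"s{i}", "snp", c, c + 1, "A", ("T",))
             for i, c in enumerate(snp_cols)]
    diags.append(Diagnostic("ind", "indel", 20, 23))
    diags.append(Diagnostic("kp1", "snp", 26, 27, "A", ("G",)))
    k = {f"s{i}": "T" for i in range(4)} | {"ind": "del"}
    kp = dict(k) | {"kp1": "G"}
    n = {f"s{i}": "A" for i in range(4)} | {"ind": "ref", "kp1": "A"}
    return AlleleRule(
        "Sdr4", "Sdr4", diags, [], "unclassified",
        [("Sdr4-n", n), ("Sdr4-k", k), ("Sdr4-k'", kp)],
    )


class TestProfileMatching:
    def _call(self, row):
        locus = AlignedLocus("Sdr4", ["x"], ["".join(row)])
        return classify_allele(locus, "x", sdr4_rule())

    def test_wildtype_profile(self):
        assert self._call(base_row(30, "A")).allele_class == "Sdr4-n"

    def test_k_profile(self):
        row = base_row(30, "A")
        for c in (2, 6, 10, 14):
            row[c] = "T"
        row[20:23] = "---"
        assert self._call(row).allele_class == "Sdr4-k"

    def test_k_prime_wins_as_more_specific(self):
        row = base_row(30, "A")
        for c in (2, 6, 10, 14):
            row[c] = "T"
        row[20:23] = "---"
        row[26] = "G"
        assert self._call(row).allele_class == "Sdr4-k'"

    def test_recombinant_pattern_unclassified(self):
        row = base_row(30, "A")
        row[2] = "T"  # only one of the four k SNPs
        assert self._call(row).allele_class == "unclassified"


class TestAaHaplotype:
    def _locus_ann(self, rows):
        ids = [f"s{i}" for i in range(len(rows))]
        locus = AlignedLocus("g", ids, rows)
        ann = GeneAnnotation("g", "+", [("exon", 0, len(rows[0]))], 0)
        return locus, ann

    def test_synonymous_rows_share_haplotype_id(self):
        locus, ann = self._locus_ann(["ATGGGATAA"[:9], "ATGGGCTAA"[:9]])
        haps = aa_haplotype(locus, ann)
        assert haps[0].haplotype_id == haps[1].haplotype_id
        assert haps[0].protein == haps[1].protein == "MG"

    def test_nonsynonymous_snp_distinct_id(self):
        locus, ann = self._locus_ann(["ATGGGATAA"[:9], "ATGCGATAA"[:9]])
        haps = aa_haplotype(locus, ann)
        assert haps[0].haplotype_id != haps[1].haplotype_id

    def test_frameshifting_deletion_flagged_and_divergent(self):
        # 9-codon toy CDS hand-translated: MKTAYIAKQ
        cds = "ATGAAAACCGCATATATAGCAAAACAA"
        shifted = cds[:4] + "-" + cds[5:]  # 1-bp deletion in codon 2
        locus, ann = self._locus_ann([cds, shifted])
        haps = aa_haplotype(locus, ann)
        assert haps[0].protein == "MKTAYIAKQ"
        assert "frameshift" in haps[1].flags
        assert haps[1].protein != haps[0].protein

    def test_premature_stop_truncates_with_flag(self):
        locus, ann = self._locus_ann(["ATGTAAGGGAAA"[:12]])
        haps = aa_haplotype(locus, ann)
        assert "premature_stop" in haps[0].flags
        assert haps[0].protein == "M"


class TestInferOrigin:
    def _setup(self, make_panel, weed_row, aus_rows, indica_rows):
        groups = {
            "aus-like": ["w1"],
            "aus": [f"a{i}" for i in range(len(aus_rows))],
            "indica": [f"i{i}" for i in range(len(indica_rows))],
        }
        panel = make_panel(groups)
        ids = ["w1"] + groups["aus"] + groups["indica"]
        rows = [weed_row] + aus_rows + indica_rows
        locus = AlignedLocus("Rc", ids, rows)
        return locus, panel

    def test_identical_to_ancestor_is_standing_variation(self, make_panel):
        locus, panel = self._setup(
            make_panel, "AAAAAAAA", ["AAAAAAAA", "AAAACCCC"],
            ["GGGGAAAA", "GGGGCCCC"],
        )
        (call,) = infer_origin(locus, panel, "Rc")
        assert call.call == "standing_ancestral"
        assert call.nearest_groups[0] == ("aus", 0.0)

    def test_strictly_nearest_non_ancestor_is_introgression(self, make_panel):
        locus, panel = self._setup(
            make_panel, "GGGGAAAA", ["AAAACCCC", "AAAATTTT"],
            ["GGGGAAAA", "GGGGCCCC"],
        )
        (call,) = infer_origin(locus, panel, "Rc")
        assert call.call == "possible_introgression"

    def test_equal_distance_tie_is_ambiguous(self, make_panel):
        locus, panel = self._setup(
            make_panel, "AAAAAAAA", ["AAAAAAAA"], ["AAAAAAAA"]
        )
        (call,) = infer_origin(locus, panel, "Rc")
        assert call.call == "ambiguous"

    def test_no_donor_sequences_is_error(self, make_panel):
        panel = make_panel({"aus-like": ["w1"]})
        locus = AlignedLocus("Rc", ["w1"], ["ACGT"])
        with pytest.raises(ValueError, match="no non-weed"):
            infer_origin(locus, panel, "Rc")

    def test_cloned_weeds_all_standing(self, make_panel):
        rng = np.random.default_rng(0)
        aus_rows = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(4)]
        ind_rows = [
            "".join(rng.choice(list("ACGT"), 10)) + r[10:] for r in aus_rows
        ]
        groups = {
            "aus-like": ["w1", "w2"],
            "aus": [f"a{i}" for i in range(4)],
            "indica": [f"i{i}" for i in range(4)],
        }
        panel = make_panel(groups)
        ids = ["w1", "w2"] + groups["aus"] + groups["indica"]
        rows = [aus_rows[0], aus_rows[2]] + aus_rows + ind_rows
        locus = AlignedLocus("Rc", ids, rows)
        calls = infer_origin(locus, panel, "Rc")
        assert all(c.call == "standing_ancestral" for c in calls)


def toy_template(rng=None, length=600):
    rng = rng or np.random.default_rng(9)
    t = list("".join(rng.choice(list("AT"), size=length)))  # no GC: no GTGCAC
    return t


class TestCaps:
    FWD = "ACCGGTTACCGGTT"
    REV = "TTGGCCAATTGGCC"

    def _assay(self, patterns=None):
        return CapsAssay(
            "Bh4", self.FWD, self.REV,
            Enzyme("ApaLI", "GTGCAC", 1),
            patterns or {},
        )

    def _template(self, cut_at=None, amplicon=500):
        rng = np.random.default_rng(9)
        t = toy_template(rng)
        # forward primer at 50; reverse-primer site so amplicon = 500
        t[50:50 + len(self.FWD)] = list(self.FWD)
        rc_rev = "GGCCAATTGGCCAA"  # revcomp of REV
        end = 50 + amplicon
        t[end - len(rc_rev):end] = list(rc_rev)
        if cut_at is not None:
            # enzyme cuts after G: site start so cut lands at `cut_at`
            t[50 + cut_at - 1:50 + cut_at + 5] = list("GTGCAC")
        return "".join(t)

    def test_single_cut_fragment_lengths(self):
        res = simulate_caps(self._template(cut_at=200), self._assay())
        assert res.ok
        assert res.amplicon_length == 500
        assert res.fragments == [300, 200]

    def test_fragments_sum_to_amplicon(self):
        for cut in (100, 200, 333):
            res = simulate_caps(self._template(cut_at=cut), self._assay())
            assert sum(res.fragments) == res.amplicon_length

    def test_deletion_spanning_site_leaves_uncut_and_calls_allele(self):
        template = self._template(cut_at=200)
        # 22-bp deletion removing the recognition site
        deleted = template[:50 + 190] + template[50 + 212:]
        assay = self._assay({"wildtype": [300, 200], "del22": [478]})
        res = simulate_caps(deleted, assay)
        assert res.fragments == [478]
        assert res.allele_call == "del22"
        wt = simulate_caps(template, assay)
        assert wt.allele_call == "wildtype"

    def test_gapped_rows_accepted(self):
        template = self._template(cut_at=200)
        gapped = template[:100] + "--" + template[100:]
        res = simulate_caps(gapped, self._assay())
        assert res.ok and res.amplicon_length == 500

    def test_missing_primer_is_assay_failure_not_exception(self):
        res = simulate_caps("ATATATAT" * 50, self._assay())
        assert not res.ok
        assert res.allele_call == "failed"

    def test_multiple_primer_hits_fail(self):
        t = self._template()
        t = t + t  # both primers twice
        res = simulate_caps(t, self._assay())
        assert not res.ok

    def test_degenerate_site_matching(self):
        # BanI GGYRCC must match GGCACC (Y=C, R=A)
        assay = CapsAssay("Rc", self.FWD, self.REV, Enzyme("BanI", "GGYRCC", 1))
        rng = np.random.default_rng(9)
        t = toy_template(rng)
        t[50:50 + len(self.FWD)] = list(self.FWD)
        t[544:550] = list("GGCACC")
        rc_rev = "GGCCAATTGGCCAA"  # revcomp of REV
        t[584:598] = list(rc_rev)
        res = simulate_caps("".join(t), assay)
        assert res.ok
        assert len(res.fragments) == 2

    def test_packaged_enzyme_definitions_load(self):
        enz = load_enzymes()
        assert enz["ApaLI"].recognition_site == "GTGCAC"
        assert enz["BanI"].recognition_site == "GGYRCC"
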