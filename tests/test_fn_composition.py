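"""Hierarchical report parsing, merging, and FN-set composition."""

import numpy as np
import pytest

from hrrbench.fn_composition import (
    ancestry_balance,
    fn_truth_composition,
    merge_reports,
    parse_report,
    serialize_report,
    summarize_fn_composition,
)
from hrrbench.read_fate import FnReadSet, classify_fates
from hrrbench.removers import SimulatedRemoverParams, simulated_remove
from hrrbench.sequence_io import ProvenanceLabel, SourceClass

REPORT = (
    "20.00\t20\t20\tU\t0\tunclassified\n"
    "80.00\t80\t5\tR\t1\troot\n"
    "45.00\t45\t10\tD\t2\t  Bacteria\n"
    "35.00\t35\t35\tS\t1280\t    Staphylococcus aureus\n"
    "30.00\t30\t0\tD\t2759\t  Eukaryota\n"
    "30.00\t30\t30\tS\t9606\t    Homo sapiens\n"
)


def build_tree():
    return parse_report(REPORT)


class TestParse:
    def test_toy_report_structure(self):
        tree = build_tree()
        assert tree.unclassified_reads == 20
        assert len(tree.roots) == 1
        root = tree.roots[0]
        assert root.taxid == 1 and root.clade_reads == 80
        assert [c.taxid for c in root.children] == [2, 2759]
        staph = root.children[0].children[0]
        assert (staph.taxid, staph.clade_reads, staph.depth) == (1280, 35, 2)

    def test_empty_report(self):
        tree = parse_report("")
        assert tree.roots == [] and tree.total_reads == 0

    def test_clade_sum_violation_detected(self):
        bad = REPORT.replace("80.00\t80\t5", "80.00\t80\t6")
        with pytest.raises(ValueError, match="clade-sum"):
            parse_report(bad)

    def test_indentation_jump_rejected(self):
        bad = (
            "0.00\t1\t1\tR\t1\troot\n"
            "0.00\t1\t1\tS\t5\t      too-deep\n"
        )
        with pytest.raises(ValueError, match="indentation"):
            parse_report(bad)

    def test_parse_serialize_roundtrip(self):
        tree = build_tree()
        again = parse_report(serialize_report(tree))
        assert again.unclassified_reads == tree.unclassified_reads
        assert again.flat_counts() == tree.flat_counts()
        assert [n.depth for n in again.walk()] == [n.depth for n in tree.walk()]


class TestMerge:
    def test_identity_with_empty(self):
        tree = build_tree()
        merged = merge_reports([tree, parse_report("")])
        assert merged.flat_counts() == tree.flat_counts()
        assert merged.unclassified_reads == tree.unclassified_reads

    def test_self_merge_doubles_counts(self):
        tree = build_tree()
        merged = merge_reports([tree, tree])
        for taxid, (direct, clade) in tree.flat_counts().items():
            d2, c2 = merged.flat_counts()[taxid]
            assert (d2, c2) == (2 * direct, 2 * clade)
        assert merged.unclassified_reads == 2 * tree.unclassified_reads
        for root in merged.roots:
            root.check_clade_sums()

    def test_merge_matches_flat_sum_oracle(self, rng):
        """Random subtree samples merge to the brute-force taxid-wise sums."""
        trees = []
        for k in range(5):
            scale = int(rng.integers(1, 5))
            rep = (
                f"0.00\t{20*scale}\t{20*scale}\tU\t0\tunclassified\n"
                f"0.00\t{80*scale}\t{5*scale}\tR\t1\troot\n"
                f"0.00\t{45*scale}\t{10*scale}\tD\t2\t  Bacteria\n"
                f"0.00\t{35*scale}\t{35*scale}\tS\t1280\t    Staphylococcus aureus\n"
                f"0.00\t{30*scale}\t{0}\tD\t2759\t  Eukaryota\n"
                f"0.00\t{30*scale}\t{30*scale}\tS\t9606\t    Homo sapiens\n"
            )
            trees.append(parse_report(rep))
        merged = merge_reports(trees)
        oracle = {}
        for t in trees:
            for taxid, (d, c) in t.flat_counts().items():
                od, oc = oracle.get(taxid, (0, 0))
                oracle[taxid] = (od + d, oc + c)
        assert merged.flat_counts() == oracle

    def test_merge_associative_commutative(self):
        other = (
            "10.00\t10\t10\tU\t0\tunclassified\n"
            "90.00\t90\t10\tR\t1\troot\n"
            "40.00\t40\t40\tD\t2\t  Bacteria\n"
            "40.00\t40\t0\tD\t2759\t  Eukaryota\n"
            "40.00\t40\t40\tS\t9606\t    Homo sapiens\n"
        )
        a, b = build_tree(), parse_report(other)
        ab = merge_reports([a, b]).flat_counts()
        ba = merge_reports([b, a]).flat_counts()
        assert ab == ba

    def test_conflicting_identity_rejected(self):
        other = REPORT.replace("Staphylococcus aureus", "Renamed taxon")
        with pytest.raises(ValueError, match="conflicting"):
            merge_reports([build_tree(), parse_report(other)])


class TestComposition:
    def test_worked_breakdown(self):
        """100 FN reads: 50 bacterial, 30 human clade, 20 unclassified."""
        rep = (
            "20.00\t20\t20\tU\t0\tunclassified\n"
            "80.00\t80\t0\tR\t1\troot\n"
            "50.00\t50\t50\tD\t2\t  Bacteria\n"
            "30.00\t30\t0\tD\t2759\t  Eukaryota\n"
            "30.00\t30\t30\tS\t9606\t    Homo sapiens\n"
        )
        summary = summarize_fn_composition(parse_report(rep))
        assert (summary.n_microbial, summary.n_human_classified, summary.n_unclassified) == (
            50, 30, 20,
        )
        assert summary.pct_microbial == pytest.approx(50.0)
        assert summary.n_fn_total == 100

    def test_all_unclassified(self):
        rep = "100.00\t40\t40\tU\t0\tunclassified\n"
        summary = summarize_fn_composition(parse_report(rep))
        assert summary.pct_microbial == 0.0 and summary.n_unclassified == 40

    def test_nested_human_taxids_not_double_counted(self):
        rep = (
            "0.00\t10\t0\tR\t1\troot\n"
            "0.00\t10\t4\tG\t9605\t  Homo\n"
            "0.00\t6\t6\tS\t9606\t    Homo sapiens\n"
        )
        summary = summarize_fn_composition(parse_report(rep), human_taxids={9605, 9606})
        assert summary.n_human_classified == 10
        assert summary.n_microbial == 0

    def test_fn_set_enriched_for_contaminants_matches_label_oracle(
        self, viral_pool, donor_pools
    ):
        """Remover sparing contaminants: FN truth census equals a direct label count."""
        pairs = viral_pool[:100] + donor_pools["D01"] + donor_pools["D02"]
        params = SimulatedRemoverParams(
            sensitivity=0.9, false_positive_rate=0.0, contaminant_removal_rate=0.0, seed=4
        )
        res = simulated_remove(pairs, params)
        _, fn_set = classify_fates(res, pairs, count_singletons_as_removed=True)
        comp = fn_truth_composition(fn_set)
        # label-truth oracle, bypassing any classifier
        oracle = {"host": 0, "contaminant": 0}
        for p in pairs:
            cls = p.label.source_class
            if cls is SourceClass.TARGET:
                continue
            for mate in (1, 2):
                if res.fate_of(p.qname, mate) == "retained":
                    oracle["host" if cls is SourceClass.HOST else "contaminant"] += 1
        assert comp == oracle
        # contaminants never flagged: every retained contaminant read is an FN
        assert comp["contaminant"] > 0


class TestAncestryBalance:
    def _fn_set(self, donor_counts):
        reads = []
        i = 0
        for donor, n in donor_counts.items():
            for _ in range(n):
                reads.append(
                    (f"r{i}", 1, ProvenanceLabel(SourceClass.HOST, donor, f"c:{i}-{i+1}"))
                )
                i += 1
        return FnReadSet(cell=None, reads=reads)

    def test_empty_fn_set(self):
        assert ancestry_balance(self._fn_set({}), {"D1": "AFR"}) is None

    def test_statistic_matches_hand_formula(self):
        # all 270 FNs from one donor of 27; groups = donors themselves
        donors = {f"d{i:02d}": f"d{i:02d}" for i in range(27)}
        fn = self._fn_set({"d00": 270})
        res = ancestry_balance(fn, donors)
        # expected 10 per group: chi2 = (270-10)^2/10 + 26*(0-10)^2/10
        assert res.statistic == pytest.approx((260**2) / 10 + 26 * 10)

    def test_unmapped_donor_rejected(self):
        with pytest.raises(ValueError, match="no group"):
            ancestry_balance(self._fn_set({"dX": 5}), {"d0": "AFR"})

    def test_null_calibration_monte_carlo(self, rng):
        """Type-I error of the Monte-Carlo test ≈ alpha over 500 simulations."""
        donors = {f"d{i}": ["g1", "g2", "g3"][i % 3] for i in range(9)}
        donor_list = list(donors)
        rejects = 0
        reps = 500
        for rep in range(reps):
            picks = rng.choice(donor_list, size=12)
            counts = {}
            for d in picks:
                counts[d] = counts.get(d, 0) + 1
            res = ancestry_balance(
                self._fn_set(counts), donors, n_simulations=400, seed=int(rng.integers(2**31))
            )
            if res.p_value <= 0.05:
                rejects += 1
        assert rejects / reps < 0.09  # conservative discrete test, never wildly above alpha
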