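"""Counting driver: (n/m)/k weights, normalisation, stats, end-to-end runs."""

import pandas as pd
import pytest

from conftest import assert_counts_equal, engine_assign, scenario_features
from srnacount import fixtures, formats_io, interval_index, quantify, rule_engine
from srnacount.formats_io import Alignment, InputError, RunConfig
from srnacount.quantify import (LibraryStats, assign_alignment,
                                normalize_library)


def make_index(features, rules, gffless=False):
    cands = rule_engine.stage1_select(features, rules, bypass_filters=gffless)
    lengths = {}
    for f in features:
        lengths[f.ref_name] = max(lengths.get(f.ref_name, 0), f.end + 100)
    return interval_index.build_index(cands, lengths)


def feat(fid, start, end, strand="+", ftype="gene"):
    return formats_io.FeatureRecord(feature_id=fid, source="s", type=ftype,
                                    ref_name="chrI", start=start, end=end,
                                    strand=strand, attributes={"ID": [fid]})


def rule(**kw):
    from test_rule_engine import rule as _rule
    return _rule(**kw)


def aln(start, end, n=1, m=1, strand="+", nt5="A", nm=0):
    return Alignment(read_id="r", seq_count=n, ref_name="chrI", start=start,
                     end=end, strand=strand, five_prime_nt=nt5,
                     length=end - start, mismatches=nm, n_alignments=m)


class TestAssignAlignment:
    """(n/m)/k weight formula with optional m and k factors."""

    def setup_method(self):
        # three stacked features all passing one Partial wildcard rule
        self.features = [feat(f"f{i}", 100, 200) for i in range(3)]
        self.rules = [rule()]
        self.index = make_index(self.features, self.rules)

    @pytest.mark.parametrize("n, m", [(6, 2), (10, 5)])
    def test_nmk_formula(self, n, m):
        rows = assign_alignment(aln(120, 142, n=n, m=m), self.index, self.rules)
        assert len(rows) == 3  # k = 3 stacked features
        assert all(w == (n / m) / 3 for _, _, w in rows)

    def test_k1_case(self):
        index = make_index(self.features[:1], self.rules)
        (row,) = assign_alignment(aln(120, 142, n=4, m=1), index, self.rules)
        assert row[2] == 4.0

    def test_optional_factors(self):
        a = aln(120, 142, n=6, m=2)
        rows = assign_alignment(a, self.index, self.rules,
                                normalize_by_features=False)
        assert all(w == 3.0 for _, _, w in rows)  # k := 1, each gets n/m
        rows = assign_alignment(a, self.index, self.rules,
                                normalize_by_alignments=False)
        assert all(w == 2.0 for _, _, w in rows)  # m := 1, (n/1)/3
        rows = assign_alignment(a, self.index, self.rules,
                                normalize_by_alignments=False,
                                normalize_by_features=False)
        assert all(w == 6.0 for _, _, w in rows)

    def test_single_feature_two_tied_rules_split_evenly(self):
        # one feature passing two minimum-hierarchy rules: (n/m)/k split over
        # the rules so feature totals are rule-set independent
        rules = [rule(index=0, classify="a"), rule(index=1, classify="b")]
        index = make_index(self.features[:1], rules)
        rows = assign_alignment(aln(120, 142, n=4, m=1), index, rules)
        assert sorted(w for _, _, w in rows) == [2.0, 2.0]
        assert sum(w for _, _, w in rows) == 4.0

    def test_unassigned_returns_empty(self):
        assert assign_alignment(aln(300, 322), self.index, self.rules) == []


class TestFig1Semantics:
    def test_hierarchy_and_strand_routing(self, rrna_vs_sirna):
        """Sense rRNA fragments match both rules but go wholly to the
        hierarchy-1 rRNA rule; antisense reads are strand-incompatible with
        it and fall through to the siRNA rule."""
        scenario, _ = rrna_vs_sirna
        counts, _ = engine_assign(scenario)
        rules = scenario.rules
        by_class = {}
        for (fid, ridx), w in counts.items():
            by_class.setdefault(rules[ridx].classifier, 0.0)
            by_class[rules[ridx].classifier] += w
        sense = sum(r.copies for r in scenario.reads if r.note == "rRNA")
        anti = sum(r.copies for r in scenario.reads if r.note == "siRNA")
        assert by_class["rRNA"] == pytest.approx(sense)
        assert by_class["siRNA"] == pytest.approx(anti)


class TestCountLibrary:
    def test_single_rule_conservation(self, tmp_path):
        sc, paths = fixtures.make_scenario("gffless", 7, tmp_path)
        cfg = RunConfig(samples=str(paths["samples"]), rules=str(paths["rules"]),
                        out_dir=str(tmp_path / "o"), collapsed_format="count",
                        timestamp=False)
        out = quantify.run(cfg)
        stats = pd.read_csv(out / "summary_stats.csv", index_col=0)
        for lib in stats.columns:
            assert float(stats.loc["Assigned Reads", lib]) + \
                float(stats.loc["Unassigned Mapped Reads", lib]) == \
                pytest.approx(float(stats.loc["Mapped Reads", lib]))

    def test_multimapper_partial_assignment(self, multimapper):
        """n=6, m=2 with one assigning locus: 3.0 to the feature, 3.0
        unassigned read-equivalents."""
        scenario, _ = multimapper
        counts, unassigned = engine_assign(scenario)
        rules = scenario.rules
        read1 = next(r for r in scenario.reads if r.idx == 1)
        assert read1.copies == 6 and len(read1.alignments) == 2
        total_locA = sum(w for (fid, _), w in counts.items() if fid == "locA")
        # locA gets read0's first locus (4/2 = 2.0) plus read1's (6/2 = 3.0)
        assert total_locA == pytest.approx(5.0)
        assert unassigned == pytest.approx(3.0)

    def test_nt_len_distribution_counts_raw_assigned_reads(self, tmp_path):
        sc, paths = fixtures.make_scenario("g22_g26", 7, tmp_path)
        cfg = RunConfig(samples=str(paths["samples"]), rules=str(paths["rules"]),
                        gff=str(paths["gff"]), out_dir=str(tmp_path / "o"),
                        collapsed_format="count", timestamp=False)
        out = quantify.run(cfg)
        bf = fixtures.brute_force_assign(sc)
        for lib in (1, 2):
            table = pd.read_csv(out / f"nt_len_lib{lib}.csv", index_col=0)
            expected = {}
            for r in sc.reads:
                if r.lib != lib or not r.mapped:
                    continue
                if r.collapsed_id in bf.per_read:  # assigned to >=1 feature
                    key = (r.seq[0], len(r.seq))
                    expected[key] = expected.get(key, 0) + r.copies
            for (nt, ln), n in expected.items():
                assert int(table.loc[nt, str(ln)]) == n
            assert int(table.values.sum()) == sum(expected.values())


class TestNormalization:
    def _stats(self, mapped=2_000_000, factor=None):
        return LibraryStats(name="lib", mapped_reads=mapped,
                            custom_factor=factor)

    def test_rpm(self):
        col = pd.Series([50.0, 0.0])
        out = normalize_library(col, self._stats(), "rpm")
        assert out.tolist() == [25.0, 0.0]

    def test_rpm_zero_mapped_errors(self):
        with pytest.raises(InputError):
            normalize_library(pd.Series([1.0]), self._stats(mapped=0), "rpm")

    def test_custom_identity_and_missing(self):
        col = pd.Series([3.0])
        assert normalize_library(col, self._stats(factor=1.0), "custom").tolist() == [3.0]
        with pytest.raises(InputError):
            normalize_library(col, self._stats(), "custom")

    def test_rpm_class_totals_scale(self, tmp_path):
        """After rpm scaling, summed class totals = 1e6 * assigned/mapped."""
        sc, paths = fixtures.make_scenario("rrna_vs_sirna", 5, tmp_path)
        cfg = RunConfig(samples=str(paths["samples"]), rules=str(paths["rules"]),
                        gff=str(paths["gff"]), out_dir=str(tmp_path / "o"),
                        collapsed_format="count", timestamp=False, rpm=True)
        out = quantify.run(cfg)
        classes = pd.read_csv(out / "class_totals.csv", index_col=0)
        stats = pd.read_csv(out / "summary_stats.csv", index_col=0)
        for lib in classes.columns:
            expected = 1e6 * float(stats.loc["Assigned Reads", lib]) / \
                float(stats.loc["Mapped Reads", lib])
            assert classes[lib].sum() == pytest.approx(expected)


class TestRunProperties:
    def test_feature_total_invariant_under_rule_splitting(self):
        """Splitting one rule into mutually exclusive same-hierarchy rules
        must not change feature-level totals."""
        sc, _ = fixtures.make_scenario("g22_g26", 7)
        merged = sc.rules_rows[:1]
        merged[0] = dict(merged[0])
        merged[0]["Length"] = "22,26"
        merged[0]["Classify as..."] = "siRNA"
        split_counts, _ = engine_assign(sc)
        sc_merged = fixtures.Scenario(sc.name, sc.seed, sc.genome, sc.features,
                                      merged, sc.reads)
        merged_counts, _ = engine_assign(sc_merged)

        def per_feature(counts):
            tot = {}
            for (fid, _), w in counts.items():
                tot[fid] = tot.get(fid, 0.0) + w
            return tot

        assert per_feature(split_counts) == pytest.approx(per_feature(merged_counts))

    def test_catch_all_rule_closes_unassigned(self):
        """A maximal-hierarchy Partial wildcard rule captures every read that
        overlaps any feature."""
        sc, _ = fixtures.make_scenario("mirna_isomir", 7)
        _, unassigned_before = engine_assign(sc)
        assert unassigned_before > 0
        rows = sc.rules_rows + [fixtures._rule_row(
            "Type", "miRNA", "other", 99, "Any", "Any", "Any", "Partial")]
        sc2 = fixtures.Scenario(sc.name, sc.seed, sc.genome, sc.features,
                                rows, sc.reads)
        counts, unassigned_after = engine_assign(sc2)
        overlapping_mass = 0.0
        for a in sc.alignments():
            if any(f.start < a.end and a.start < f.end for f in sc.features):
                overlapping_mass += a.seq_count / a.n_alignments
        # no read overlapping a feature stays unassigned
        total_mass = sum(a.seq_count / a.n_alignments for a in sc.alignments())
        assert sum(counts.values()) + unassigned_after == pytest.approx(total_mass)
        assert unassigned_after == pytest.approx(total_mass - overlapping_mass)

    def test_outputs_deterministic_under_sam_record_permutation(self, tmp_path):
        sc, paths = fixtures.make_scenario("rrna_vs_sirna", 7, tmp_path / "a")
        sam = paths["lib1_collapsed"]
        lines = sam.read_text().splitlines(keepends=True)
        header = [l for l in lines if l.startswith("@")]
        body = [l for l in lines if not l.startswith("@")]
        shuffled = tmp_path / "a" / "lib1_shuffled.sam"
        shuffled.write_text("".join(header + body[::-1]))
        sheet = tmp_path / "a" / "samples_shuffled.csv"
        sheet.write_text("file,name,norm_factor\n"
                         f"{sam.name},lib1,\n")
        sheet2 = tmp_path / "a" / "samples_shuffled2.csv"
        sheet2.write_text("file,name,norm_factor\n"
                          f"{shuffled.name},lib1,\n")
        outs = []
        for sp, od in ((sheet, "o1"), (sheet2, "o2")):
            cfg = RunConfig(samples=str(sp), rules=str(paths["rules"]),
                            gff=str(paths["gff"]), out_dir=str(tmp_path / od),
                            collapsed_format="count", timestamp=False)
            outs.append(quantify.run(cfg))
        for name in ("feature_counts.csv", "class_totals.csv", "rule_totals.csv"):
            assert (outs[0] / name).read_bytes() == (outs[1] / name).read_bytes()

    def test_run_writes_effective_config_and_log(self, tmp_path):
        sc, paths = fixtures.make_scenario("multimapper", 7, tmp_path)
        cfg = RunConfig(samples=str(paths["samples"]), rules=str(paths["rules"]),
                        gff=str(paths["gff"]), out_dir=str(tmp_path / "o"),
                        collapsed_format="count", timestamp=False, trace=True)
        out = quantify.run(cfg)
        assert (out / "config.effective.yml").exists()
        assert (out / "run.log").exists()
        assert (out / "trace_lib1.tsv").read_text().startswith("read_id\t")
        reloaded = formats_io.load_config(out / "config.effective.yml")
        assert reloaded.rules == cfg.rules

    def test_gffless_run_counts_per_reference(self, tmp_path):
        sc, paths = fixtures.make_scenario("gffless", 7, tmp_path)
        cfg = RunConfig(samples=str(paths["samples"]), rules=str(paths["rules"]),
                        out_dir=str(tmp_path / "o"), collapsed_format="count",
                        timestamp=False)
        out = quantify.run(cfg)
        counts = pd.read_csv(out / "feature_counts.csv", index_col=[0, 1])
        bf = fixtures.brute_force_assign(sc)
        for (fid, cls), w in bf.counts.items():
            assert counts.loc[(fid, cls)].sum() == pytest.approx(w)
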