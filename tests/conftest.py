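import pytest

from srnacount import fixtures, formats_io, interval_index, rule_engine
from srnacount.quantify import assign_alignment


def scenario_features(scenario):
    """Features as the engine sees them (reference sequences in GFF-less mode)."""
    if scenario.gffless:
        return [
            formats_io.FeatureRecord(feature_id=ref, source=".", type=".",
                                     ref_name=ref, start=0, end=len(seq),
                                     strand="+")
            for ref, seq in scenario.genome.items()]
    return scenario.features


def engine_assign(scenario, libs=None, normalize_by_alignments=True,
                  normalize_by_features=True):
    """Run the staged engine + interval index over a scenario in memory.

    Returns ((feature_id, rule_index) -> weight, unassigned read-equivalents).
    """
    rules = scenario.rules
    candidates = rule_engine.stage1_select(
        scenario_features(scenario), rules, bypass_filters=scenario.gffless)
    index = interval_index.build_index(candidates, scenario.axis_lengths)
    counts, unassigned = {}, 0.0
    for aln in scenario.alignments(libs=libs):
        rows = assign_alignment(
            aln, index, rules,
            normalize_by_alignments=normalize_by_alignments,
            normalize_by_features=normalize_by_features)
        if not rows:
            unassigned += aln.seq_count / aln.n_alignments
        for fid, ridx, w in rows:
            counts[(fid, ridx)] = counts.get((fid, ridx), 0.0) + w
    return counts, unassigned


def assert_counts_equal(engine_counts, oracle_counts, tol=1e-9):
    keys = set(engine_counts) | set(oracle_counts)
    for key in keys:
        a, b = engine_counts.get(key, 0.0), oracle_counts.get(key, 0.0)
        assert a == pytest.approx(b, abs=tol), f"mismatch at {key}: {a} vs {b}"


@pytest.fixture(scope="session", params=fixtures.SCENARIO_NAMES)
def any_scenario(request, tmp_path_factory):
    out = tmp_path_factory.mktemp(f"sc_{request.param}")
    scenario, paths = fixtures.make_scenario(request.param, seed=7, out_dir=out)
    return scenario, paths


def _named(name):
    @pytest.fixture(scope="session")
    def fixture(tmp_path_factory):
        out = tmp_path_factory.mktemp(f"sc_{name}")
        return fixtures.make_scenario(name, seed=7, out_dir=out)
    return fixture


mirna_isomir = _named("mirna_isomir")
rrna_vs_sirna = _named("rrna_vs_sirna")
g22_g26 = _named("g22_g26")
promoter = _named("promoter")
multimapper = _named("multimapper")
gffless = _named("gffless")
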