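"""Operon colocalization screen: parsing, filtering, pair detection, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fapcore as fc
from fapcore.operon import ParseError, gene_gap

from conftest import random_hits

TSV_HEADER = "protein_id\tcomponent\tassembly_id\tcontig_id\tstart\tend\tstrand\ttaxon"


def mk(component, start, end, contig="c1", pid=None, assembly="a1", taxon=""):
    return fc.HomologHit(
        protein_id=pid or f"{component}_{start}", component=component,
        assembly_id=assembly, contig_id=contig, start=start, end=end, taxon=taxon,
    )


# ---------------------------------------------------------------------------
# independent brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_screen(hits, max_gap=5000, min_components=4):
    """Reference implementation: test the second-nearest-neighbor rule for
    every hit, then exhaustively merge retained hits into connected
    components under the max_gap relation."""

    def gap(a, b):
        return max(0, max(a.start, b.start) - min(a.end, b.end) - 1)

    groups = {}
    for h in hits:
        groups.setdefault((h.assembly_id, h.contig_id), []).append(h)
    out = []
    for _key, group in groups.items():
        kept = [h for h in group
                if sum(1 for o in group if o is not h and gap(h, o) < max_gap) >= 2]
        # exhaustive merging: repeat until no two clusters can merge
        clusters = [[h] for h in kept]
        merged = True
        while merged:
            merged = False
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    if any(gap(a, b) < max_gap for a in clusters[i] for b in clusters[j]):
                        clusters[i] += clusters.pop(j)
                        merged = True
                        break
                if merged:
                    break
        for cl in clusters:
            if len({h.component for h in cl}) >= min_components:
                out.append(frozenset((h.protein_id, h.start, h.end) for h in cl))
    return set(out)


def calls_as_sets(calls):
    return {frozenset((m.protein_id, m.start, m.end) for m in c.members) for c in calls}


_interval = st.tuples(st.integers(1, 10_000), st.integers(1, 3_000))


@given(_interval, _interval)
@settings(max_examples=200, derandomize=True, deadline=None)
def test_gene_gap_symmetric_and_zero_on_overlap(a, b):
    ha = mk("FapA", a[0], a[0] + a[1] - 1)
    hb = mk("FapB", b[0], b[0] + b[1] - 1)
    assert gene_gap(ha, hb) == gene_gap(hb, ha)
    overlap = not (ha.end < hb.start or hb.end < ha.start)
    if overlap:
        assert gene_gap(ha, hb) == 0
    else:
        assert gene_gap(ha, hb) >= 0


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

class TestParseHits:
    def test_tsv_identity(self):
        rows = [TSV_HEADER]
        for k, comp in enumerate(fc.COMPONENTS):
            rows.append(f"P{k}\t{comp}\tA1\tc1\t{1000 * (k + 1)}\t{1000 * (k + 1) + 500}\t+\tPseudomonas")
        hits = fc.parse_hits("\n".join(rows), format="tsv")
        assert [h.component for h in hits] == list(fc.COMPONENTS)
        assert hits[0].start == 1000 and hits[0].end == 1500
        assert hits[0].strand == "+" and hits[0].taxon == "Pseudomonas"

    def test_gff3_one_based_passthrough(self):
        line = "ctg7\tscreen\tgene\t1000\t2000\t.\t+\t.\tID=XP1;fap_component=fapC;assembly_id=A9"
        (hit,) = fc.parse_hits(line, format="gff3")
        assert (hit.start, hit.end) == (1000, 2000)
        assert hit.component == "FapC"
        assert hit.contig_id == "ctg7" and hit.assembly_id == "A9"

    def test_unknown_component_rejected_with_identifier(self):
        table = TSV_HEADER + "\nP1\tFapX\tA1\tc1\t10\t20\t+\t"
        with pytest.raises(ParseError, match="FapX"):
            fc.parse_hits(table, format="tsv")

    def test_malformed_row_names_line_number(self):
        table = TSV_HEADER + "\nP1\tFapA\tA1\tc1\t10\t20\t+\tx\nP2\tFapB\tA1\tc1\tNaN\t30\t+\tx"
        with pytest.raises(ParseError, match="line 3"):
            fc.parse_hits(table, format="tsv")

    def test_duplicate_rows_deduplicated(self):
        row = "P1\tFapA\tA1\tc1\t10\t20\t+\tx"
        hits = fc.parse_hits("\n".join([TSV_HEADER, row, row]), format="tsv")
        assert len(hits) == 1


# ---------------------------------------------------------------------------
# colocalization filter
# ---------------------------------------------------------------------------

class TestFilterOperonHits:
    def test_six_gene_operon_single_call(self):
        hits, pos = [], 1
        for comp in fc.COMPONENTS:
            hits.append(mk(comp, pos, pos + 999))
            pos += 1200  # 200 bp intergenic gaps
        calls = fc.filter_operon_hits(hits)
        assert len(calls) == 1
        assert len(calls[0].members) == 6
        assert calls[0].distinct_components == frozenset(fc.COMPONENTS)
        assert calls_as_sets(calls) == brute_force_screen(hits)

    def test_empty_input(self):
        assert fc.filter_operon_hits([]) == []

    def test_three_components_insufficient(self):
        hits = [mk("FapB", 1000, 1500), mk("FapC", 1700, 2200), mk("FapE", 2400, 2900)]
        assert fc.filter_operon_hits(hits) == []
        assert brute_force_screen(hits) == set()

    def test_lone_hit_excluded_by_second_nearest_rule(self):
        hits = [mk("FapC", 100_000, 101_000),
                mk("FapA", 1, 500), mk("FapB", 600, 1100), mk("FapD", 1200, 1700),
                mk("FapE", 1800, 2300)]
        calls = fc.filter_operon_hits(hits)
        assert len(calls) == 1
        assert all(m.component != "FapC" for m in calls[0].members)

    def test_count_raw_hits_flag(self):
        # two FapC fragments + FapA + FapB: 4 raw hits, 3 distinct components
        hits = [mk("FapA", 1, 500), mk("FapB", 600, 1100),
                mk("FapC", 1200, 1700, pid="x1"), mk("FapC", 1800, 2300, pid="x2")]
        assert fc.filter_operon_hits(hits) == []
        assert len(fc.filter_operon_hits(hits, count_raw_hits=True)) == 1

    def test_midpoint_metric_flag(self):
        a, b = mk("FapA", 1, 9001), mk("FapB", 9500, 9600)
        assert gene_gap(a, b, "edge") == 498
        assert gene_gap(a, b, "midpoint") == pytest.approx(5049.0)

    def test_oracle_equivalence_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            hits = random_hits(rng)
            assert calls_as_sets(fc.filter_operon_hits(hits)) == brute_force_screen(hits)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        hits = random_hits(rng, n_max=15)
        ref = calls_as_sets(fc.filter_operon_hits(hits))
        for _ in range(5):
            rng.shuffle(hits)
            assert calls_as_sets(fc.filter_operon_hits(list(hits))) == ref

    def test_monotonicity_in_max_gap_and_min_components(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            hits = random_hits(rng, n_max=15)
            small = fc.filter_operon_hits(hits, max_gap=3000)
            large = fc.filter_operon_hits(hits, max_gap=6000)
            members_small = {m for c in small for m in
                             ((x.protein_id, x.start, x.end) for x in c.members)}
            members_large = {m for c in large for m in
                             ((x.protein_id, x.start, x.end) for x in c.members)}
            assert members_small <= members_large
            lo = calls_as_sets(fc.filter_operon_hits(hits, min_components=3))
            hi = calls_as_sets(fc.filter_operon_hits(hits, min_components=4))
            assert hi <= lo


class TestColocalizedPairs:
    def test_pair_within_gap(self):
        d, f = mk("FapD", 1000, 2000), mk("FapF", 2500, 4000)
        pairs = fc.detect_colocalized_pairs([d, f])
        assert pairs == [(d, f)]
        assert gene_gap(d, f) == 499

    def test_gap_too_large(self):
        hits = [mk("FapD", 1000, 2000), mk("FapF", 8001, 9000)]
        assert fc.detect_colocalized_pairs(hits) == []

    def test_different_contigs(self):
        hits = [mk("FapD", 1000, 2000, contig="c1"), mk("FapF", 2500, 4000, contig="c2")]
        assert fc.detect_colocalized_pairs(hits) == []

    def test_symmetry_in_component_order(self):
        hits = [mk("FapD", 1000, 2000), mk("FapF", 2500, 4000)]
        fwd = fc.detect_colocalized_pairs(hits, "FapD", "FapF")
        rev = fc.detect_colocalized_pairs(hits, "FapF", "FapD")
        assert [(a.protein_id, b.protein_id) for a, b in fwd] == \
               [(a.protein_id, b.protein_id) for a, b in rev]


class TestPresenceMatrix:
    def _operon(self, comps, assembly, taxon, contig):
        hits, pos = [], 1
        for comp in comps:
            hits.append(mk(comp, pos, pos + 999, contig=contig, assembly=assembly,
                           taxon=taxon, pid=f"{assembly}{comp}"))
            pos += 1200
        return hits

    def test_component_counts_per_genus(self):
        hits = (self._operon(fc.COMPONENTS, "a1", "GenusA", "c1")
                + self._operon(fc.COMPONENTS[:5], "a2", "GenusB", "c2"))
        calls = fc.filter_operon_hits(hits)
        pm = fc.presence_matrix(calls)
        assert pm.table.loc["GenusA"].sum() == 6
        assert pm.table.loc["GenusB"].sum() == 5
        assert not pm.table.loc["GenusB", "FapF"]

    def test_no_calls_empty_matrix(self):
        pm = fc.presence_matrix([])
        assert pm.table.shape[0] == 0

    def test_strain_counts_distinct_assemblies(self):
        hits = (self._operon(fc.COMPONENTS[:4], "a1", "GenusA", "c1")
                + self._operon(fc.COMPONENTS[:4], "a2", "GenusA", "c2"))
        pm = fc.presence_matrix(fc.filter_operon_hits(hits))
        assert pm.strain_counts["GenusA"] == 2

    def test_taxonomy_mapping_with_unclassified_fallback(self):
        hits = self._operon(fc.COMPONENTS[:4], "a1", "", "c1")
        calls = fc.filter_operon_hits(hits)
        assert fc.presence_matrix(calls).table.index.tolist() == ["unclassified"]
        pm = fc.presence_matrix(calls, {"a1": "Azotobacter"})
        assert pm.table.index.tolist() == ["Azotobacter"]
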