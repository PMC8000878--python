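import numpy as np
import pytest

from mirsite import (
    PlantSpec,
    alternatives,
    duplex,
    effective_sites,
    find_clusters,
    find_clusters_by_gene,
    plant_sites,
    random_mirnas,
    scan,
    scan_all,
    scenario_gastric_like,
)
from mirsite.sequence_io import read_mirna_fasta, read_transcripts


class TestRandomMirnas:
    def test_deterministic_under_seed(self):
        a = random_mirnas(10, (20, 25), 0.5, seed=7)
        b = random_mirnas(10, (20, 25), 0.5, seed=7)
        assert [m.seq for m in a] == [m.seq for m in b]
        assert all(20 <= m.length <= 25 for m in a)

    def test_gc_extremes(self):
        pure_gc = random_mirnas(5, (20, 20), 1.0, seed=1)
        assert all(set(m.seq) <= set("GC") for m in pure_gc)
        pure_au = random_mirnas(5, (20, 20), 0.0, seed=1)
        assert all(set(m.seq) <= set("AU") for m in pure_au)

    def test_n_validation(self):
        with pytest.raises(ValueError):
            random_mirnas(0, (20, 25), 0.5, seed=1)


class TestPlantSites:
    mirnas = random_mirnas(3, (22, 24), 0.55, seed=11)

    def test_perfect_plant_recovered(self):
        t, recs = plant_sites("G", 400, (100, 200, 100),
                              [PlantSpec(self.mirnas[0].id, 50)],
                              self.mirnas, seed=5)
        assert recs[0].realized_paired_pct == 100.0
        sites = scan(self.mirnas[0], t)
        assert any(s.start == 50 and s.ratio_pct == 100.0 for s in sites)

    def test_degraded_plant_below_threshold(self):
        """An 85%-paired plant stays in the truth ledger but is not a
        site at a 90% scan threshold."""
        t, recs = plant_sites("G", 400, (100, 200, 100),
                              [PlantSpec(self.mirnas[1].id, 80,
                                         target_ratio_pct=85.0)],
                              self.mirnas, seed=5)
        L = self.mirnas[1].length
        assert recs[0].realized_paired_pct == pytest.approx(
            100 * (L - round(L * 0.15)) / L
        )
        assert not any(
            s.start == 80 for s in scan(self.mirnas[1], t, threshold_pct=90)
        )

    def test_realized_matches_duplex_recomputation(self):
        t, recs = plant_sites("G", 400, (100, 200, 100),
                              [PlantSpec(self.mirnas[0].id, 120,
                                         target_ratio_pct=92.0)],
                              self.mirnas, seed=9)
        m = self.mirnas[0]
        window = t.seq[119 : 119 + m.length]
        sch = duplex(m.seq, window)
        assert recs[0].realized_dG == pytest.approx(sch.dG)
        assert recs[0].realized_bonds_pct == pytest.approx(
            100 * sch.dG / sch.dGm
        )

    def test_plant_outside_transcript_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            plant_sites("G", 100, (0, 100, 0),
                        [PlantSpec(self.mirnas[0].id, 95)],
                        self.mirnas, seed=1)

    def test_overlapping_plants_overwrite_in_order(self):
        specs = [PlantSpec(self.mirnas[0].id, 50),
                 PlantSpec(self.mirnas[1].id, 55)]
        t, recs = plant_sites("G", 400, (100, 200, 100), specs,
                              self.mirnas, seed=5)
        # the later plant survives intact; the earlier one is damaged
        assert recs[1].realized_paired_pct == 100.0
        assert recs[0].realized_paired_pct < 100.0


class TestScenario:
    def test_seed_reproducibility_byte_identical(self, truth, tmp_path):
        again = scenario_gastric_like(seed=7)
        truth.write(tmp_path / "a")
        again.write(tmp_path / "b")
        for name in ("mirnas.fa", "transcripts.fa", "regions.tsv", "truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_written_cosmos_reloads(self, truth, tmp_path):
        truth.write(tmp_path)
        mirnas = read_mirna_fasta(tmp_path / "mirnas.fa")
        transcripts = read_transcripts(
            tmp_path / "transcripts.fa", tmp_path / "regions.tsv"
        )
        assert [m.seq for m in mirnas] == [m.seq for m in truth.mirnas]
        assert [t.seq for t in transcripts] == [t.seq for t in truth.transcripts]

    def test_recovery_of_high_quality_plants(self, truth, scenario_sites):
        found = {(s.mirna_id, s.gene, s.start) for s in scenario_sites}
        strong = [p for p in truth.plants if p.realized_bonds_pct >= 90]
        assert strong, "scenario must contain recoverable plants"
        assert all((p.mirna_id, p.gene, p.start) in found for p in strong)

    def test_no_recovery_of_weak_plants(self, truth, scenario_sites):
        found = {(s.mirna_id, s.gene, s.start) for s in scenario_sites}
        weak = [p for p in truth.plants if p.realized_bonds_pct < 85]
        assert weak, "scenario must contain sub-threshold plants"
        assert not any((p.mirna_id, p.gene, p.start) in found for p in weak)

    def test_alternatives_structure(self, truth, scenario_sites):
        filtered = effective_sites(scenario_sites)
        mirna_recs, gene_recs = alternatives(filtered)
        assert any(r.n_genes >= 6 for r in mirna_recs)
        assert any(g.n_mirnas >= 6 for g in gene_recs)

    def test_contains_compact_cluster(self, truth, scenario_sites):
        clusters = find_clusters_by_gene(scenario_sites)
        assert any(c.compaction >= 4 for c in clusters)
        assert all(c.compaction >= 1 for c in clusters)

    def test_truth_cluster_matches_ledger_arithmetic(self, truth):
        """Planted tiling intervals in one 5'UTR form a single cluster
        whose compaction equals direct sum/span arithmetic on the ledger."""
        from mirsite.scan import BindingSite

        g01 = [p for p in truth.plants if p.gene == "G01" and p.region == "5UTR"]
        sites = [
            BindingSite(mirna_id=p.mirna_id, gene=p.gene, start=p.start,
                        length=p.length, dG=p.realized_dG, dGm=p.realized_dG,
                        ratio_pct=p.realized_bonds_pct, region="5UTR")
            for p in g01
        ]
        clusters = find_clusters(sites)
        assert len(clusters) == 1
        c = clusters[0]
        span = max(p.end for p in g01) - min(p.start for p in g01) + 1
        total = sum(p.length for p in g01)
        assert c.compaction == pytest.approx(total / span)
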