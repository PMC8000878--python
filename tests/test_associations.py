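import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirsite.associations import (
    alternatives,
    competition_rank,
    effective_sites,
    nx_site_report,
    suppression,
    suppression_from_ratio,
)
from mirsite.clusters import find_clusters
from mirsite.scan import BindingSite
from mirsite.sequence_io import Transcript


def _site(mirna="m1", gene="G1", start=10, dG=-120.0, region="3UTR", length=22):
    return BindingSite(mirna_id=mirna, gene=gene, start=start, length=length,
                       dG=dG, dGm=-150.0, ratio_pct=92.0, region=region)


class TestEffectiveSites:
    def test_region_cutoffs(self):
        sites = [
            _site(dG=-134, region="5UTR"),   # strong enough for the leader
            _site(dG=-125, region="5UTR"),   # too weak there
            _site(dG=-119, region="3UTR"),   # clears the laxer trailer cutoff
            _site(dG=-110, region="3UTR"),
        ]
        kept = effective_sites(sites)
        assert [s.dG for s in kept] == [-134, -119]

    def test_boundary_inclusive(self):
        assert effective_sites([_site(dG=-130.0, region="CDS")])

    def test_positive_threshold_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            effective_sites([_site()], {"3UTR": 115.0})

    def test_loosening_never_removes(self):
        sites = [_site(dG=-100 - 5 * i, region="3UTR") for i in range(10)]
        strict = {s.dG for s in effective_sites(sites, {"3UTR": -120.0})}
        loose = {s.dG for s in effective_sites(sites, {"3UTR": -105.0})}
        assert strict <= loose


class TestAlternatives:
    def _cosmos(self):
        sites = []
        for g in ("G1", "G2", "G3", "G4", "G5", "G6"):
            sites.append(_site(mirna="hub", gene=g))
        for m in ("m1", "m2", "m3"):
            sites.append(_site(mirna=m, gene="G1", start=50))
        sites.append(_site(mirna="lonely", gene="G9"))
        return sites

    def test_counts_and_exclusion(self):
        mirna_recs, gene_recs = alternatives(self._cosmos())
        by_mirna = {r.mirna_id: r for r in mirna_recs}
        assert by_mirna["hub"].n_genes == 6
        assert "lonely" not in by_mirna and "m1" not in by_mirna
        by_gene = {r.gene: r for r in gene_recs}
        assert by_gene["G1"].n_mirnas == 4  # hub + m1..m3
        assert "G9" not in by_gene

    def test_order_invariance_and_witness(self):
        sites = self._cosmos()
        rng = np.random.default_rng(3)
        shuffled = list(sites)
        rng.shuffle(shuffled)
        assert alternatives(sites) == alternatives(shuffled)
        pairs = {(s.mirna_id, s.gene) for s in sites}
        mirna_recs, _ = alternatives(sites)
        for rec in mirna_recs:
            for g in rec.genes:
                assert (rec.mirna_id, g) in pairs


class TestSuppression:
    @pytest.mark.parametrize(
        "ratio,expected", [(1.0, 50.0), (0.1, 100 / 11), (10.0, 1000 / 11)]
    )
    def test_occupancy_values(self, ratio, expected):
        assert suppression_from_ratio(ratio) == pytest.approx(expected)

    def test_printed_round_figures(self):
        """1:10 sits at ~10% suppression and 10:1 at ~90%."""
        assert suppression(1, 10) == pytest.approx(10, abs=1)
        assert suppression(10, 1) == pytest.approx(90, abs=1)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=200, deadline=None)
    def test_complementarity_identity(self, r):
        assert suppression_from_ratio(r) + suppression_from_ratio(1 / r) == (
            pytest.approx(100.0)
        )

    def test_input_validation(self):
        with pytest.raises(ValueError):
            suppression(-1, 1)
        with pytest.raises(ValueError):
            suppression(1, 0)


class TestCompetitionRank:
    def _cluster(self, specs):
        sites = [
            _site(mirna=m, start=10 + i, dG=dg, length=22)
            for i, (m, dg) in enumerate(specs)
        ]
        return find_clusters(sites)[0]

    def test_expression_can_beat_energy(self):
        """A 4.8x more abundant miRNA outranks a slightly stronger one."""
        c = self._cluster([("strong", -121.0), ("abundant", -117.0)])
        ranked = competition_rank(c, {"abundant": 4.8})
        assert [m for m, _ in ranked] == ["abundant", "strong"]
        assert ranked[0][1] == pytest.approx(4.8 * 117)

    def test_equal_expression_energy_decides(self):
        c = self._cluster([("weak", -110.0), ("strong", -125.0)])
        assert [m for m, _ in competition_rank(c)] == ["strong", "weak"]

    def test_singleton(self):
        c = self._cluster([("only", -120.0)])
        assert [m for m, _ in competition_rank(c)] == ["only"]


class TestNxReport:
    def _transcripts(self):
        return [
            Transcript(gene="HI", seq="A" * 90, utr5_len=30, cds_len=30,
                       utr3_len=30, nx=25.2),
            Transcript(gene="LO", seq="A" * 90, utr5_len=30, cds_len=30,
                       utr3_len=30, nx=2.0),
            Transcript(gene="NA", seq="A" * 90, utr5_len=30, cds_len=30,
                       utr3_len=30),
        ]

    def test_single_site_gene_row(self):
        df = nx_site_report(self._transcripts(), [_site(gene="HI", start=5)])
        row = df[df["gene"] == "HI"].iloc[0]
        assert (row["nx"], row["n_sites"], row["n_multi_clusters"]) == (25.2, 1, 0)

    def test_multi_member_cluster_counted(self):
        sites = [_site(gene="LO", mirna=f"m{i}", start=10 + i) for i in range(5)]
        df = nx_site_report(self._transcripts(), sites)
        assert df[df["gene"] == "LO"]["n_multi_clusters"].iloc[0] == 1

    def test_sorted_by_nx_desc_missing_last(self):
        df = nx_site_report(self._transcripts(), [])
        assert list(df["gene"]) == ["HI", "LO", "NA"]
        assert (df["n_sites"] == 0).all()
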