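"""Synthetic community generator: profiles, genomes, SAG sampling."""

import dataclasses

import numpy as np
import pytest

from sagkit.community import (evolve_ssu, make_reference_taxonomy,
                              make_taxon_profile, sample_sag,
                              simulate_community, synthesize_genome)
from sagkit.constants import MARKER_SET
from sagkit.cosort import marker_census


class TestProfiles:
    def test_deterministic_for_same_inputs(self):
        a = make_taxon_profile("Other-Bacteria", "standard", 7)
        b = make_taxon_profile("Other-Bacteria", "standard", 7)
        assert a.ssu_ref == b.ssu_ref
        assert np.array_equal(a.cog_distribution, b.cog_distribution)
        assert a.target_coding_density == b.target_coding_density

    def test_patesci_preset_contract(self):
        p = make_taxon_profile("Patescibacteria", "patesci_like", 7)
        assert p.etc_complement == {}
        assert p.o2red_genes == ()
        assert p.genetic_code in (11, 25)

    def test_unknown_style_rejected(self):
        with pytest.raises(ValueError):
            make_taxon_profile("Patescibacteria", "weird", 7)

    def test_mean_coding_density_near_configured(self):
        dens = [make_taxon_profile("Other-Bacteria", "standard", s)
                .target_coding_density for s in range(100)]
        assert abs(np.mean(dens) - 0.90) < 0.02

    def test_cog_distribution_depletion(self):
        pa = make_taxon_profile("Patescibacteria", "patesci_like", 3)
        st = make_taxon_profile("Other-Bacteria", "standard", 3)
        from sagkit.constants import COG_CATEGORIES
        for cat in "CEHP":
            i = COG_CATEGORIES.index(cat)
            assert pa.cog_distribution[i] < st.cog_distribution[i]


class TestEvolveSsu:
    def test_zero_divergence_identity(self):
        s = "ACGT" * 400
        assert evolve_ssu(s, 0.0, 5) == s

    def test_divergence_within_binomial_bounds(self):
        refs = make_reference_taxonomy()
        s = refs["Patescibacteria"]
        out = evolve_ssu(s, 0.1, 3)
        assert len(out) == len(s)
        d = sum(a != b for a, b in zip(s, out)) / len(s)
        assert 0.07 <= d <= 0.13

    def test_deterministic_and_range_checked(self):
        s = "ACGT" * 400
        assert evolve_ssu(s, 0.1, 9) == evolve_ssu(s, 0.1, 9)
        with pytest.raises(ValueError):
            evolve_ssu(s, 0.5, 1)


class TestSynthesizeGenome:
    def test_realized_density_near_target(self):
        prof = make_taxon_profile("Other-Bacteria", "standard", 21)
        prof = dataclasses.replace(prof, target_coding_density=0.90,
                                   genome_length=200_000)
        g = synthesize_genome(prof, 22)
        coding = sum(f.end - f.start for f in g.gene_map if f.kind != "ssu")
        assert abs(coding / len(g.sequence) - 0.90) < 0.03

    def test_code11_genome_has_no_inframe_tga(self, genome_pool):
        g = next(g for g in genome_pool if g.profile.genetic_code == 11)
        for f in g.gene_map:
            if f.kind == "ssu":
                continue
            nt = g.sequence[f.start:f.end]
            if f.strand == "-":
                nt = nt.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            body = [nt[i:i+3] for i in range(3, len(nt) - 3, 3)]
            assert "TGA" not in body, f.protein_id

    def test_code25_genomes_use_tga_in_many_cds(self, genome_pool):
        g = next(g for g in genome_pool if g.profile.genetic_code == 25)
        n_cds = n_tga = 0
        for f in g.gene_map:
            if f.kind == "ssu":
                continue
            nt = g.sequence[f.start:f.end]
            if f.strand == "-":
                nt = nt.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            body = [nt[i:i+3] for i in range(3, len(nt) - 3, 3)]
            n_cds += 1
            n_tga += "TGA" in body
        assert n_tga / n_cds >= 0.30

    def test_full_genome_marker_census_complete(self, genome_pool):
        g = genome_pool[0]
        markers = [r["marker_id"] for r in g.annotations if r["marker_id"]]
        census = marker_census(markers)
        assert census.completeness_pct == 100.0
        assert census.contamination_pct == 0.0

    def test_embedded_ssu_matches_profile(self, genome_pool):
        g = genome_pool[0]
        f = next(f for f in g.gene_map if f.kind == "ssu")
        nt = g.sequence[f.start:f.end]
        if f.strand == "-":
            nt = nt.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert nt == g.profile.ssu_ref

    def test_too_small_genome_rejected(self):
        prof = make_taxon_profile("Other-Bacteria", "standard", 2)
        prof = dataclasses.replace(prof, genome_length=30_000)
        with pytest.raises(ValueError):
            synthesize_genome(prof, 2)


class TestSampleSag:
    def test_identity_case(self, genome_pool):
        g = genome_pool[0]
        sag = sample_sag([g], 1.0, 1, "AG-001", 9, sag_id="S1")
        assert list(sag.contigs.values()) == [g.sequence]
        assert sag.truth["admixture"] is False

    def test_completeness_recovered_from_contigs(self, genome_pool):
        g = genome_pool[3]
        for seed in range(5):
            sag = sample_sag([g], 0.3, 5, "AG-001", seed, sag_id=f"S{seed}")
            frac = sag.assembly_length / len(g.sequence)
            assert 0.25 <= frac <= 0.35

    def test_admixture_marker_retention(self, genome_pool):
        g1, g2 = genome_pool[3], genome_pool[4]
        counts = []
        for seed in range(40):
            sag = sample_sag([g1, g2], [0.6, 0.6], 4, "AG-002", seed,
                             sag_id=f"X{seed}")
            assert sag.truth["admixture"] is True
            per_source = {}
            for r in sag.annotations:
                if r["marker_id"]:
                    src = r["protein_id"].split("|")[0]
                    per_source[src] = per_source.get(src, 0) + 1
            counts.extend(per_source.values())
        mean_frac = np.mean(counts) / len(MARKER_SET)
        assert abs(mean_frac - 0.6) < 0.08

    def test_invalid_completeness_rejected(self, genome_pool):
        with pytest.raises(ValueError):
            sample_sag([genome_pool[0]], 0.0, 1, "AG-001", 1)

    def test_annotations_subset_of_source(self, genome_pool):
        g = genome_pool[0]
        sag = sample_sag([g], 0.4, 3, "AG-001", 77, sag_id="S77")
        src_pids = {r["protein_id"] for r in g.annotations}
        assert {r["protein_id"] for r in sag.annotations} <= src_pids
        # every retained gene lies fully inside its contig
        for f in sag.gene_map:
            assert 0 <= f.start < f.end <= len(sag.contigs[f.contig_id])


class TestSimulateCommunity:
    def test_determinism(self):
        a = simulate_community(n_taxa=3, n_sags=6, seed=5)
        b = simulate_community(n_taxa=3, n_sags=6, seed=5)
        assert [s.sag_id for s in a.sags] == [s.sag_id for s in b.sags]
        assert all(x.contigs == y.contigs for x, y in zip(a.sags, b.sags))

    def test_cosort_rate_and_truth(self, small_community):
        adm = [s for s in small_community.sags if s.truth["admixture"]]
        for s in adm:
            assert len(s.truth["source_taxa"]) == 2
        for s in small_community.sags:
            assert s.truth["admixture"] == (len(s.truth["source_taxa"]) == 2)

    def test_min_contig_length(self, small_community):
        for s in small_community.sags:
            for c in s.contigs.values():
                assert len(c) >= 2000
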