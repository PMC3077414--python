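import numpy as np
import pytest

from chipfrag.composition_stats import at_content, window_profile
from chipfrag.motif_engine import IUPACPattern, expand_iupac, scan
from chipfrag.synthetic_data import (
    SimulationConfig,
    plant_motifs,
    simulate_fragments,
    simulate_gene_models,
    simulate_genome,
    simulate_qpcr,
)


def small_config(**kw):
    defaults = dict(seed=7, chrom_lengths=(60_000, 30_000), n_fragments=20,
                    fragment_length_range=(105, 1848))
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGenome:
    def test_single_component_mean_recovered(self):
        config = SimulationConfig(
            seed=3, chrom_lengths=(1_000_000,), at_mixture=((1.0, 0.59, 0.0),)
        )
        g = simulate_genome(config)
        prof = window_profile(g)
        assert abs(float(np.mean(prof.values)) - 0.59) < 0.01

    def test_clamping_keeps_at_above_floor(self):
        config = small_config(at_mixture=((1.0, 0.0, 0.0),))
        prof = window_profile(simulate_genome(config))
        assert all(v >= 0.0 for v in prof.values)
        # windows target the 0.05 clamp, not 0
        assert float(np.mean(prof.values)) == pytest.approx(0.05, abs=0.01)

    def test_seed_determinism(self):
        c = small_config()
        assert simulate_genome(c) == simulate_genome(c)

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            small_config(at_mixture=((0.5, 0.5, 0.05),))


class TestPlantMotifs:
    PATTERNS = expand_iupac(
        [IUPACPattern("ATATTCGCGAWWATT"), IUPACPattern("ATATTGCGCAWWATT")]
    )

    def test_density_zero_leaves_genome_unchanged(self):
        c = small_config()
        g = simulate_genome(c)
        g2, truth = plant_motifs(g, self.PATTERNS, 0.0, c)
        assert g2 == g and truth == []

    def test_every_plant_recovered_by_scan(self):
        c = small_config(seed=11, chrom_lengths=(200_000,))
        g = simulate_genome(c)
        g2, truth = plant_motifs(g, self.PATTERNS, 100.0, c)
        assert truth  # Poisson(20) plants expected
        rep = scan(g2, self.PATTERNS)
        found = {(m.sequence_id, m.start) for m in rep.matches}
        assert {(c_, p) for c_, p, _ in truth} <= found

    def test_ground_truth_variants_in_place(self):
        c = small_config(seed=5)
        g2, truth = plant_motifs(simulate_genome(c), self.PATTERNS, 50.0, c)
        seqs = {r.id: r.sequence for r in g2}
        for chrom, pos, var in truth:
            assert seqs[chrom][pos : pos + 15] == var

    def test_seed_determinism(self):
        c = small_config()
        g = simulate_genome(c)
        assert plant_motifs(g, self.PATTERNS, 30.0, c) == plant_motifs(g, self.PATTERNS, 30.0, c)

    def test_infeasible_density_rejected(self):
        c = small_config(chrom_lengths=(1000,))
        g = simulate_genome(c)
        with pytest.raises(ValueError, match="density"):
            plant_motifs(g, self.PATTERNS, 100_000.0, c)


class TestFragments:
    def test_counts_and_length_range(self):
        c = small_config(n_fragments=49)
        g = simulate_genome(c)
        frags, loci = simulate_fragments(g, c)
        assert len(frags) == 49 and len(loci) == 49
        for f, l in zip(frags, loci):
            assert 105 <= f.length <= 1848
            assert f.length == l.end - l.start
            assert g.get(l.chrom).sequence[l.start : l.end] == f.sequence

    def test_positive_shift_raises_fragment_at(self):
        hits = 0
        for seed in range(20):
            c = small_config(seed=seed, n_fragments=30, fragment_at_shift=0.06)
            g = simulate_genome(c)
            frags, _ = simulate_fragments(g, c)
            genome_mean = float(np.mean(window_profile(g).values)) * 100
            frag_mean = float(np.mean([at_content(f.sequence) for f in frags]))
            hits += frag_mean > genome_mean
        assert hits >= 19

    def test_zero_shift_unbiased(self):
        # under the null the fragment-vs-genome rank-sum p is not systematically small
        from chipfrag.composition_stats import compare_fragments_to_genome

        ps = []
        for seed in range(20):
            c = small_config(seed=seed, n_fragments=25, fragment_at_shift=0.0)
            g = simulate_genome(c)
            frags, _ = simulate_fragments(g, c)
            ps.append(compare_fragments_to_genome(frags, g).result_greater.p_two_sided)
        assert 0.05 < np.mean(ps) < 0.95
        assert sum(p < 0.05 for p in ps) <= 4

    def test_seed_determinism(self):
        c = small_config()
        g = simulate_genome(c)
        assert simulate_fragments(g, c) == simulate_fragments(g, c)


class TestGeneModels:
    def test_invariants_across_seeds(self):
        for seed in range(25):
            c = small_config(seed=seed, gene_density=20.0)
            g = simulate_genome(c)
            genes = simulate_gene_models(g, c)
            by_chrom: dict[str, list] = {}
            for gene in genes:
                assert gene.exons == tuple(sorted(gene.exons))
                assert len(gene.introns) == len(gene.exons) - 1
                assert gene.span[1] <= g.get(gene.chrom).length
                by_chrom.setdefault(gene.chrom, []).append(gene.span)
            for spans in by_chrom.values():
                spans.sort()
                for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                    assert e1 <= s2  # non-overlapping

    def test_zero_density_gives_no_genes(self):
        c = small_config(gene_density=0.0)
        assert simulate_gene_models(simulate_genome(c), c) == []

    def test_seed_determinism(self):
        c = small_config()
        g = simulate_genome(c)
        assert simulate_gene_models(g, c) == simulate_gene_models(g, c)


class TestQpcr:
    def test_sd_zero_closed_form(self):
        c = small_config(qpcr_delta_ct_mean=6.97, qpcr_delta_ct_sd=0.0)
        from chipfrag.chip_quant import fold_enrichment

        for s in simulate_qpcr(c):
            assert fold_enrichment(s).fold == pytest.approx(2**6.97)

    def test_mean_zero_clusters_at_one(self):
        c = small_config(qpcr_delta_ct_mean=0.0, qpcr_delta_ct_sd=0.1)
        from chipfrag.chip_quant import fold_enrichment

        folds = [fold_enrichment(s).fold for s in simulate_qpcr(c)]
        assert all(0.5 < f < 2.0 for f in folds)

    def test_seed_determinism(self):
        c = small_config()
        assert simulate_qpcr(c) == simulate_qpcr(c)
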