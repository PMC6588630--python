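import numpy as np
import pytest

from chemorep.io import HitRow, SequenceRecord
from chemorep.mining import (
    GeneModel,
    build_gene_model,
    classify_gene,
    merge_hits,
    mine_genome,
    search_homologs,
    verify_family_membership,
)
from chemorep.simulate import simulate_receptor_genome
from conftest import AAS, random_nt


def _hit(contig="c1", strand="+", sstart=100, send=400, bits=100.0,
         query="q1") -> HitRow:
    return HitRow(query, contig, 95.0, (send - sstart) // 3, 5, 0, 0, 100,
                  sstart, send, strand, 1e-30, bits)


class TestSearch:
    def test_planted_identical_copy_found(self, seed_protein):
        contigs, truth = simulate_receptor_genome(
            seed_protein, 1, 0, 0, divergence=0.0, contig_len=3000, seed=2
        )
        hits = search_homologs(contigs, [seed_protein])
        assert hits
        best = max(hits, key=lambda h: h.bitscore)
        assert best.evalue <= 1e-10
        assert (best.qend - best.qstart) / len(seed_protein.residues) >= 0.95

    def test_minus_strand_forward_coordinates(self, seed_protein):
        for seed in range(6):
            contigs, truth = simulate_receptor_genome(
                seed_protein, 1, 0, 0, 0.0, 3000, seed=seed
            )
            (gene,) = truth.genes
            if gene.strand == "-":
                break
        hits = search_homologs(contigs, [seed_protein])
        best = max(hits, key=lambda h: h.bitscore)
        assert best.strand == "-"
        assert best.sstart < best.send
        assert best.sstart >= gene.start - 3 and best.send <= gene.end + 3

    def test_random_sequence_no_hits(self, seed_protein):
        clean = 0
        for seed in range(20):
            rng = np.random.default_rng(9000 + seed)
            contig = SequenceRecord("r", random_nt(rng, 100_000))
            hits = search_homologs([contig], [seed_protein])
            clean += not hits
        assert clean >= 19

    def test_imported_mode_filters(self):
        rows = [_hit(), _hit(sstart=500, send=800)]
        rows[1].evalue = 1e-5
        out = search_homologs([], [], e_cutoff=1e-10, mode="imported",
                              imported_hits=rows)
        assert len(out) == 1

    def test_unknown_mode_rejected(self, seed_protein):
        with pytest.raises(ValueError):
            search_homologs([], [seed_protein], mode="blast")


class TestMergeHits:
    def test_overlapping_hits_merge(self):
        loci = merge_hits([_hit(sstart=100, send=400),
                           _hit(sstart=350, send=800)])
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (100, 800)

    def test_opposite_strands_stay_separate(self):
        loci = merge_hits([_hit(sstart=100, send=400, strand="+"),
                           _hit(sstart=350, send=800, strand="-")])
        assert len(loci) == 2

    def test_short_locus_discarded(self):
        loci = merge_hits([_hit(sstart=100, send=250)])
        assert loci == []

    def test_gap_boundary(self):
        # gap of 5100 > max_gap keeps loci apart; 4900 merges them
        far = merge_hits([_hit(sstart=100, send=400),
                          _hit(sstart=5500, send=5900)], max_gap=5000)
        assert len(far) == 2
        near = merge_hits([_hit(sstart=100, send=400),
                           _hit(sstart=5300, send=5700)], max_gap=5000)
        assert len(near) == 1 and near[0].end == 5700

    def test_disjoint_per_contig_strand(self):
        rng = np.random.default_rng(0)
        hits = [_hit(sstart=int(s), send=int(s) + 300)
                for s in rng.integers(0, 50_000, 40)]
        loci = merge_hits(hits, max_gap=1000)
        loci = sorted(loci, key=lambda l: l.start)
        for a, b in zip(loci, loci[1:]):
            assert a.end + 1000 < b.start  # pairwise disjoint with margin

    def test_best_query_by_bitscore(self):
        loci = merge_hits([_hit(bits=50.0, query="weak"),
                           _hit(sstart=150, send=450, bits=90.0,
                                query="strong")])
        assert loci[0].best_query == "strong"


class TestGeneModel:
    def test_intact_gene_full_coverage_no_disruptions(self, seed_protein):
        contigs, truth = simulate_receptor_genome(
            seed_protein, 1, 0, 0, 0.1, 4000, seed=5
        )
        hits = search_homologs(contigs, [seed_protein])
        (locus,) = merge_hits(hits)
        model = build_gene_model(locus, {c.id: c.residues for c in contigs},
                                 seed_protein, flank=1000)
        assert model.coverage >= 0.95
        assert model.disruptions == []
        assert classify_gene(model) == "intact"

    def test_nonsense_disruption_within_one_codon(self, seed_protein):
        found = 0
        for seed in range(12):
            contigs, truth = simulate_receptor_genome(
                seed_protein, 0, 0, 1, 0.05, 4000, seed=seed
            )
            (gene,) = truth.genes
            kinds = {d.kind for d in gene.disruptions}
            if kinds != {"nonsense"}:
                continue
            hits = search_homologs(contigs, [seed_protein])
            (locus,) = merge_hits(hits)
            model = build_gene_model(
                locus, {c.id: c.residues for c in contigs}, seed_protein,
                flank=1000,
            )
            assert model is not None
            nons = [p for k, p in model.disruptions if k == "nonsense"]
            assert nons, "planted nonsense not recovered"
            planted = gene.disruptions[0].position
            assert min(abs(p - planted) for p in nons) <= 3
            found += 1
        assert found >= 3

    def test_truncated_gene_clipped_flagged(self, seed_protein):
        contigs, truth = simulate_receptor_genome(
            seed_protein, 0, 1, 0, 0.05, 4000, seed=11
        )
        anns = mine_genome(contigs, [seed_protein], flank=1000)
        assert len(anns) == 1
        assert anns[0].model.coverage < 1.0
        assert anns[0].model.contig_edge
        assert anns[0].status == "truncated"


class TestClassify:
    def _model(self, coverage, disruptions, edge):
        locus = merge_hits([_hit(sstart=100, send=700)])[0]
        return GeneModel(locus, 100, 700, "M" * 200, coverage, disruptions,
                         edge, False, 500.0)

    def test_full_coverage_clean_is_intact(self):
        assert classify_gene(self._model(1.0, [], False)) == "intact"

    def test_any_disruption_is_pseudogene(self):
        m = self._model(1.0, [("frameshift", 300)], False)
        assert classify_gene(m) == "pseudogene"

    def test_partial_with_edge_is_truncated(self):
        assert classify_gene(self._model(0.6, [], True)) == "truncated"

    def test_total_function(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = self._model(
                float(rng.random()),
                [("nonsense", 3)] if rng.random() < 0.5 else [],
                bool(rng.random() < 0.5),
            )
            assert classify_gene(m) in {"intact", "truncated", "pseudogene"}


class TestVerifyFamily:
    def _panel(self):
        rng = np.random.default_rng(1)
        target = "M" + "".join(AAS[i] for i in rng.integers(0, 20, 199))
        decoy = "M" + "".join(AAS[i] for i in rng.integers(0, 20, 199))
        refs = [SequenceRecord("t1", target), SequenceRecord("d1", decoy)]
        return refs, {"t1": "target", "d1": "decoy"}, target, decoy

    def test_mutated_target_accepted(self):
        refs, fam, target, _ = self._panel()
        rng = np.random.default_rng(2)
        s = list(target)
        for pos in rng.integers(0, 200, 20):
            s[pos] = AAS[rng.integers(20)]
        assert verify_family_membership("".join(s), refs, fam)

    def test_decoy_rejected(self):
        refs, fam, _, decoy = self._panel()
        assert not verify_family_membership(decoy, refs, fam)

    def test_tie_rejected(self):
        refs = [SequenceRecord("t1", "MAAAA"), SequenceRecord("d1", "MAAAA")]
        fam = {"t1": "target", "d1": "decoy"}
        assert not verify_family_membership("MAAAA", refs, fam)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            verify_family_membership("MAAA", [], {})


class TestEndToEnd:
    def test_status_recovery_on_planted_genomes(self, seed_protein):
        """>= 95% of planted genes recovered with the exact planted status
        (divergence 0.1, scaled seed count; full scale in acceptance)."""
        total, exact = 0, 0
        for seed in range(10):
            contigs, truth = simulate_receptor_genome(
                seed_protein, 2, 1, 2, 0.1, 4000, seed=seed
            )
            anns = mine_genome(contigs, [seed_protein], flank=1500)
            by_contig = {a.model.locus.contig: a for a in anns}
            for g in truth.genes:
                total += 1
                a = by_contig.get(g.contig)
                if a is not None and a.status == g.status:
                    exact += 1
        assert exact / total >= 0.95
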