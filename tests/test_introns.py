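"""Splice inference, intron-site arithmetic, homologization, categories."""

import numpy as np
import pandas as pd
import pytest

from _oracles import intron_category_oracle
from cadtrace.introns import (
    CATEGORIES,
    IntronSiteMatrix,
    SpliceInferenceError,
    classify_sites,
    coding_sites,
    infer_gene_structure,
    intron_protein_sites,
    project_sites,
    summarize_conservation,
)
from cadtrace.records import (
    GeneModel,
    MultipleAlignment,
    NucleotideRecord,
    ValidationError,
)
from cadtrace.simulate import (
    FamilyConfig,
    GeneSpec,
    SitePlan,
    build_gene,
    default_blueprint,
    generate_family,
    generate_protein,
)


def _nt(id_, seq, kind="genomic"):
    return NucleotideRecord(id=id_, sequence=seq, kind=kind)


class TestInference:
    def test_identical_sequences_single_exon(self):
        record, _ = generate_protein(default_blueprint("IVa", seed=1), "g")
        genomic, transcript, *_ = build_gene(record, [], seed=1)
        assert genomic.sequence == transcript.sequence
        model = infer_gene_structure(transcript, genomic)
        assert len(model.exons) == 1
        assert model.spliced_sequence(genomic) == transcript.sequence

    def test_five_planted_introns_recovered_exactly(self):
        record, _ = generate_protein(default_blueprint("IVa", seed=2), "g")
        plan = [(100, 0), (300, 1), (500, 2), (700, 0), (900, 1)]
        genomic, transcript, model, sites = build_gene(record, plan, seed=2)
        inferred = infer_gene_structure(transcript, genomic)
        assert inferred.exons == model.exons  # all 10 boundaries
        for s, e in inferred.introns():
            assert genomic.sequence[s - 1 : s + 1] == "GT"
            assert genomic.sequence[e - 2 : e] == "AG"

    def test_unreconstructable_transcript_reports_interval(self):
        genomic = _nt("g", "ATG" + "C" * 200)
        transcript = _nt("t", "ATG" + "C" * 50 + "TTTTTAAAAATTTTT" * 3,
                         kind="transcript")
        with pytest.raises(SpliceInferenceError) as err:
            infer_gene_structure(transcript, genomic, find_cds=False)
        start, end = err.value.unplaced
        assert 0 <= start < end <= len(transcript.sequence)

    def test_idempotent_on_own_output(self):
        record, _ = generate_protein(default_blueprint("IVa", seed=3), "g")
        plan = [(150, 2), (600, 0)]
        genomic, transcript, _, _ = build_gene(record, plan, seed=3)
        m1 = infer_gene_structure(transcript, genomic)
        spliced = _nt("t2", m1.spliced_sequence(genomic), kind="transcript")
        m2 = infer_gene_structure(spliced, genomic)
        assert m2.exons == m1.exons


class TestSiteArithmetic:
    def _model(self, coding_offset):
        # one intron after `coding_offset` coding bases; 60 nt UTRs
        utr = 60
        first = utr + coding_offset
        return GeneModel(
            gene_id="g", seq_id="s", strand="+",
            exons=[(1, first), (first + 101, first + 100 + 600 - coding_offset
                    + utr)],
            cds_start_offset=utr, cds_length=600,
        )

    def test_intron_between_codons_is_phase0_next_codon(self):
        (site,) = coding_sites(intron_protein_sites(self._model(300)))
        assert (site.protein_position, site.phase) == (101, 0)

    def test_intron_after_first_base_is_phase1_same_codon(self):
        (site,) = coding_sites(intron_protein_sites(self._model(298)))
        assert (site.protein_position, site.phase) == (100, 1)

    def test_intron_after_second_base_is_phase2(self):
        (site,) = coding_sites(intron_protein_sites(self._model(299)))
        assert (site.protein_position, site.phase) == (100, 2)

    def test_utr_intron_flagged_and_excluded(self):
        utr_model = GeneModel(
            gene_id="g", seq_id="s", strand="+",
            exons=[(1, 30), (131, 800)], cds_start_offset=60, cds_length=600,
        )
        sites = intron_protein_sites(utr_model)
        assert len(sites) == 1 and sites[0].in_utr
        assert coding_sites(sites) == []

    def test_noncanonical_rejected_unless_allowed(self):
        record, _ = generate_protein(default_blueprint("IVa", seed=4), "g")
        genomic, transcript, model, _ = build_gene(record, [(200, 0)], seed=4)
        broken = _nt("g", genomic.sequence[: model.exons[0][1]] + "CC" +
                     genomic.sequence[model.exons[0][1] + 2 :])
        with pytest.raises(ValidationError, match="non-canonical"):
            intron_protein_sites(model, broken)
        sites = intron_protein_sites(model, broken, allow_noncanonical=True)
        assert sites[0].noncanonical

    def test_planted_pairs_recovered_over_50_genes(self):
        rng = np.random.default_rng(77)
        bp = default_blueprint("III", seed=0, ec_count=14)
        record, _ = generate_protein(bp, "g")
        L = len(record.sequence)
        for trial in range(50):
            n = int(rng.integers(5, 41))
            pos = np.sort(rng.choice(np.arange(15, L - 15, 12), n,
                                     replace=False))
            plan = [(int(p), int(rng.integers(0, 3))) for p in pos]
            genomic, transcript, _, _ = build_gene(
                record, plan, seed=int(rng.integers(2**31 - 1)),
                gene_id=f"g{trial}",
            )
            inferred = infer_gene_structure(transcript, genomic)
            got = [(s.protein_position, s.phase)
                   for s in coding_sites(intron_protein_sites(inferred,
                                                              genomic))]
            assert got == plan


class TestProjection:
    def test_shared_site_single_key(self):
        aln = MultipleAlignment(rows=[("a", "MKVLAW"), ("b", "MKVLAW")])
        sites = {
            "a": intron_protein_sites(GeneModel(
                gene_id="a", seq_id="s", strand="+",
                exons=[(1, 9), (110, 118)], cds_start_offset=0,
                cds_length=18)),
            "b": intron_protein_sites(GeneModel(
                gene_id="b", seq_id="s", strand="+",
                exons=[(1, 9), (210, 218)], cds_start_offset=0,
                cds_length=18)),
        }
        matrix = project_sites(sites, aln)
        assert matrix.site_keys == [(4, 0)]
        assert matrix.presence.loc["a", (4, 0)]
        assert matrix.presence.loc["b", (4, 0)]

    def test_same_column_different_phase_distinct_keys(self):
        aln = MultipleAlignment(rows=[("a", "MKVLAW"), ("b", "MKVLAW")])
        model_a = GeneModel(gene_id="a", seq_id="s", strand="+",
                            exons=[(1, 9), (110, 118)], cds_start_offset=0,
                            cds_length=18)
        model_b = GeneModel(gene_id="b", seq_id="s", strand="+",
                            exons=[(1, 10), (111, 118)], cds_start_offset=0,
                            cds_length=18)
        matrix = project_sites(
            {"a": intron_protein_sites(model_a),
             "b": intron_protein_sites(model_b)}, aln,
        )
        assert sorted(matrix.site_keys) == [(4, 0), (4, 1)]

    def test_gap_alignment_separates_non_homologous_sites(self):
        aln = MultipleAlignment(rows=[("a", "MKV-LAW"), ("b", "MKVQLAW")])
        model = GeneModel(gene_id="x", seq_id="s", strand="+",
                          exons=[(1, 12), (113, 121)], cds_start_offset=0,
                          cds_length=21)
        ma = GeneModel(gene_id="a", seq_id="s", strand="+", exons=model.exons,
                       cds_start_offset=0, cds_length=21)
        matrix = project_sites(
            {"a": intron_protein_sites(ma),
             "b": intron_protein_sites(
                 GeneModel(gene_id="b", seq_id="s", strand="+",
                           exons=model.exons, cds_start_offset=0,
                           cds_length=21))},
            aln,
        )
        # residue 5 of a sits in column 6; residue 5 of b in column 5
        assert sorted(matrix.site_keys) == [(5, 0), (6, 0)]


def _random_matrix(rng, genes):
    n_sites = int(rng.integers(1, 9))
    keys = [(int(c), int(rng.integers(0, 3)))
            for c in rng.choice(np.arange(1, 200), n_sites, replace=False)]
    data = {}
    for key in keys:
        col = rng.random(len(genes)) < 0.5
        if not col.any():
            col[rng.integers(0, len(genes))] = True
        data[key] = col
    presence = pd.DataFrame(data, index=genes)
    presence.columns = pd.Index(keys)
    return IntronSiteMatrix(presence=presence)


class TestCategories:
    GROUPS = {
        "sp1": "spider", "sp2": "spider",
        "cent": "arthropod_typeIII", "mite": "arthropod_typeIII",
        "fly": "arthropod_typeIV", "shrimp": "arthropod_typeIV",
        "snail": "non_arthropod", "urchin": "non_arthropod",
    }

    def _single_site(self, carriers):
        genes = list(self.GROUPS)
        presence = pd.DataFrame({(10, 0): [g in carriers for g in genes]},
                                index=genes)
        presence.columns = pd.Index([(10, 0)])
        return classify_sites(IntronSiteMatrix(presence=presence),
                              self.GROUPS)

    def test_two_spiders_only_is_unshared_with_note(self):
        m = self._single_site({"sp1", "sp2"})
        assert m.categories[(10, 0)] == "unshared"
        assert "lineage" in m.notes[(10, 0)]

    def test_spider_fly_snail_is_broadly_shared(self):
        m = self._single_site({"sp1", "fly", "snail"})
        assert m.categories[(10, 0)] == "broadly_shared"

    def test_missing_group_rejected(self):
        genes = ["sp1", "mystery"]
        presence = pd.DataFrame({(1, 0): [True, True]}, index=genes)
        presence.columns = pd.Index([(1, 0)])
        with pytest.raises(ValidationError, match="mystery"):
            classify_sites(IntronSiteMatrix(presence=presence),
                           {"sp1": "spider"})

    def test_random_matrices_match_rule_oracle(self):
        rng = np.random.default_rng(123)
        genes = list(self.GROUPS)
        for _ in range(300):
            matrix = classify_sites(_random_matrix(rng, genes), self.GROUPS)
            for key in matrix.site_keys:
                present = [g for g in genes if matrix.presence.loc[g, key]]
                want = intron_category_oracle([self.GROUPS[g] for g in present])
                assert matrix.categories[key] == want

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(5)
        matrix = _random_matrix(rng, list(self.GROUPS))
        m1 = classify_sites(matrix, self.GROUPS)
        shuffled = IntronSiteMatrix(
            presence=matrix.presence.iloc[::-1]
        )
        m2 = classify_sites(shuffled, self.GROUPS)
        assert m1.categories == m2.categories

    def test_category_counts_partition_sites(self):
        rng = np.random.default_rng(6)
        matrix = classify_sites(_random_matrix(rng, list(self.GROUPS)),
                                self.GROUPS)
        summary = summarize_conservation(matrix)
        assert sum(summary["per_category"].values()) == summary["n_sites"]
        assert set(summary["per_category"]) == set(CATEGORIES)


class TestSummaries:
    def test_single_gene_all_shared_by_one(self):
        presence = pd.DataFrame({(1, 0): [True], (2, 1): [True]}, index=["g"])
        presence.columns = pd.Index([(1, 0), (2, 1)])
        m = IntronSiteMatrix(presence=presence)
        s = summarize_conservation(m, k=1)
        assert s["shared_by_k"] == 2 and s["per_gene"]["g"] == 2

    def test_planted_shared_and_unique_tallies(self):
        cfg = FamilyConfig(
            genes=[
                GeneSpec(name="a", group="spider", divergence=0.1),
                GeneSpec(name="b", group="spider", divergence=0.1,
                         n_unique_sites=5),
            ],
            sites=[SitePlan(carriers="all") for _ in range(10)],
            parent_ec_count=14,
        )
        sim = generate_family(cfg, seed=40)
        sites_by_gene = {}
        for name in sim.gene_models:
            model = infer_gene_structure(sim.transcripts[name],
                                         sim.genomics[name])
            sites_by_gene[name] = intron_protein_sites(model,
                                                       sim.genomics[name])
        matrix = project_sites(sites_by_gene, sim.alignment)
        shared = summarize_conservation(matrix, k=2)["shared_by_k"]
        assert shared == 10
        assert len(matrix.site_keys) == 15

    def test_subset_restriction(self):
        presence = pd.DataFrame(
            {(1, 0): [True, True, False], (5, 2): [True, True, True]},
            index=["a", "b", "c"],
        )
        presence.columns = pd.Index([(1, 0), (5, 2)])
        m = IntronSiteMatrix(presence=presence)
        assert summarize_conservation(m, k=2, subset=["b", "c"])[
            "shared_by_k"] == 1
        with pytest.raises(ValidationError):
            summarize_conservation(m, subset=["a", "zzz"])
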