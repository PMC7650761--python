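"""Generator contracts: determinism, planted structure, recoverability."""

import numpy as np
import pandas as pd
import pytest

from termite_virome import abundance as ab
from termite_virome import orf_codes as oc
from termite_virome import pipeline
from termite_virome import synthetic_data as sd
from termite_virome.io_formats import (
    read_count_matrix,
    read_domain_table,
    read_fasta,
    read_homology_table,
    read_library_metadata,
    read_reference_table,
)


class TestConfigValidation:
    def test_bad_fraction_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.SimulationConfig(procedure_split=1.5)

    def test_zero_libraries_rejected(self):
        with pytest.raises(sd.ConfigurationError):
            sd.SimulationConfig(n_libraries=0)

    def test_hop_fraction_must_be_removable(self):
        with pytest.raises(sd.ConfigurationError, match="removable"):
            sd.SimulationConfig(n_index_hops=1, index_hop_fraction=0.002)

    def test_tier_mix_must_sum_to_one(self):
        with pytest.raises(sd.ConfigurationError):
            sd.SimulationConfig(abundance_tier_mix=(0.5, 0.5, 0.5))


class TestDeterminism:
    def test_same_seed_byte_identical_bundle(self, tmp_path):
        cfg = sd.SimulationConfig(seed=5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        sd.simulate_virome(cfg).write(d1)
        sd.simulate_virome(cfg).write(d2)
        for p1 in sorted(d1.iterdir()):
            p2 = d2 / p1.name
            assert p1.read_bytes() == p2.read_bytes(), p1.name

    def test_different_seed_differs(self):
        b1 = sd.simulate_virome(sd.SimulationConfig(seed=1))
        b2 = sd.simulate_virome(sd.SimulationConfig(seed=2))
        assert [c.sequence for c in b1.contigs] != [c.sequence for c in b2.contigs]


class TestEmptySurvey:
    def test_no_viruses_means_no_hits_and_all_nonviral(self):
        b = sd.simulate_virome(
            sd.SimulationConfig(n_viruses=0, n_endogenous=0, n_index_hops=0, seed=3)
        )
        assert b.homology_hits == []
        assert set(b.truth.contig_labels.values()) == {"non-viral"}
        assert len(b.count_matrix) == 0


class TestBundleStructure:
    def test_outputs_parse_with_io_readers(self, bundle, tmp_path):
        paths = bundle.write(tmp_path / "bundle")
        contigs = read_fasta(paths["contigs"])
        hits = read_homology_table(paths["homology"])
        domains = read_domain_table(paths["domains"])
        counts = read_count_matrix(paths["counts"])
        meta = read_library_metadata(paths["metadata"])
        refs = read_reference_table(paths["references"])
        assert len(contigs) == len(bundle.contigs)
        assert len(hits) == len(bundle.homology_hits)
        assert len(domains) == len(bundle.domain_hits)
        pd.testing.assert_frame_equal(counts, bundle.count_matrix.astype("int64"))
        assert meta == bundle.library_meta
        assert set(refs) == set(bundle.reference_table)

    def test_every_contig_has_exactly_one_label(self, bundle):
        labels = bundle.truth.contig_labels
        assert set(labels) == {c.contig_id for c in bundle.contigs}
        allowed = {"exogenous-viral", "endogenous", "non-viral", "contaminant-blacklist"}
        assert set(labels.values()) <= allowed

    def test_exogenous_genomes_have_significant_hits(self, bundle):
        best = {}
        for h in bundle.homology_hits:
            best[h.query_id] = min(best.get(h.query_id, 1.0), h.evalue)
        for cid, label in bundle.truth.contig_labels.items():
            if label == "exogenous-viral":
                assert best[cid] < 1e-5

    def test_planted_abundances_fall_in_their_tier(self, bundle):
        totals = {m.library_id: m.total_reads for m in bundle.library_meta}
        t = bundle.truth
        hop_sources = set(t.exogenous_viruses[: bundle.config.n_index_hops])
        for key, origin in t.detections.items():
            virus, lib = key.split("|")
            if origin != "resident" or virus not in t.exogenous_viruses:
                continue
            count = bundle.count_matrix.loc[virus, lib]
            pct = 100.0 * count / totals[lib]
            tier = ab.classify_abundance(pct)
            if virus in hop_sources:
                assert tier == "high"
            else:
                # all of a virus's resident detections share one tier
                others = [
                    ab.classify_abundance(
                        100.0 * bundle.count_matrix.loc[virus, l2] / totals[l2]
                    )
                    for k2, o2 in t.detections.items()
                    if o2 == "resident"
                    for v2, l2 in [k2.split("|")]
                    if v2 == virus
                ]
                assert len(set(others)) == 1

    def test_column_sums_match_metadata_viral_fraction(self, bundle):
        totals = {m.library_id: m.total_reads for m in bundle.library_meta}
        for lib, frac in bundle.truth.viral_fraction.items():
            assert bundle.count_matrix[lib].sum() == pytest.approx(
                frac * totals[lib], abs=0.5
            )

    def test_variant_code_genomes_need_uga_trp(self, bundle):
        seq_of = {c.contig_id: c.sequence for c in bundle.contigs}
        t = bundle.truth
        contig_of = {v: k for k, v in t.virus_of_contig.items()}
        span_of = {h.query_id: (h.align_start, h.align_end) for h in bundle.homology_hits}
        for virus, code in t.virus_code.items():
            if virus not in t.exogenous_viruses:
                continue
            cid = contig_of[virus]
            best, cov = oc.best_code_for_contig(
                seq_of[cid], homology_span=span_of[cid]
            )
            if code != 1:
                assert best in (3, 4, 5) and cov > 0.9
            else:
                assert best == 1 and cov > 0.9


class TestPlantEndogenousCopy:
    def _genome(self, seed=0, length=2400):
        rng = np.random.default_rng(seed)
        return sd.make_viral_genome(rng, length)

    def test_single_indel_degrades_orf_under_all_codes(self):
        """One mid-span frameshift splits the ORF; the longest surviving
        ORF keeps one flank plus stop-readthrough, so it lands below 0.7
        of the original (half is not reachable with a single indel)."""
        seq, span, _ = self._genome()
        original = oc.find_orfs(seq, 1, min_len_codons=1)[0].length_codons
        broken = sd.plant_endogenous_copy(seq, 1, seed=9, homology_span=span)
        for code in (1, 5):
            orfs = oc.find_orfs(broken, code, min_len_codons=1)
            assert orfs[0].length_codons < 0.7 * original
        interrupted, _ = oc.detect_interrupted_orf(
            span, oc.find_orfs(broken, 1, min_len_codons=30)
        )
        assert interrupted

    def test_three_indels_destroy_most_of_the_orf(self):
        seq, span, _ = self._genome(5)
        original = oc.find_orfs(seq, 1, min_len_codons=1)[0].length_codons
        broken = sd.plant_endogenous_copy(seq, 3, seed=9, homology_span=span)
        assert oc.find_orfs(broken, 1, min_len_codons=1)[0].length_codons < 0.7 * original

    def test_reproducible_given_seed(self):
        seq, span, _ = self._genome(1)
        a = sd.plant_endogenous_copy(seq, 3, seed=4, homology_span=span)
        b = sd.plant_endogenous_copy(seq, 3, seed=4, homology_span=span)
        assert a == b

    def test_length_changes_by_at_most_n_indels(self):
        seq, span, _ = self._genome(2)
        out = sd.plant_endogenous_copy(seq, 3, seed=5, homology_span=span)
        assert abs(len(out) - len(seq)) <= 3

    def test_zero_indels_rejected(self):
        seq, span, _ = self._genome(3)
        with pytest.raises(ValueError, match="n_indels"):
            sd.plant_endogenous_copy(seq, 0, seed=1, homology_span=span)

    def test_no_gene_sized_orf_rejected(self):
        rng = np.random.default_rng(6)
        junk = "".join(rng.choice(list("ACGT"), 900))
        if oc.find_orfs(junk, 1, min_len_codons=200):  # vanishingly unlikely
            pytest.skip("random sequence accidentally contains a long ORF")
        with pytest.raises(ValueError, match="gene-sized"):
            sd.plant_endogenous_copy(junk, 1, seed=1)


class TestPlantIndexHop:
    def _m(self):
        return pd.DataFrame(
            [[180_000, 0]], index=["v"], columns=["src", "dst"]
        )

    def test_hop_arithmetic(self):
        out = sd.plant_index_hop(self._m(), "v", "src", "dst", 0.0005)
        assert out.loc["v", "dst"] == 90
        assert out.loc["v", "src"] == 180_000

    def test_minimum_one_read(self):
        m = pd.DataFrame([[1000, 0]], index=["v"], columns=["src", "dst"])
        out = sd.plant_index_hop(m, "v", "src", "dst", 0.0001)
        assert out.loc["v", "dst"] == 1

    def test_zero_fraction_rejected(self):
        with pytest.raises(ValueError):
            sd.plant_index_hop(self._m(), "v", "src", "dst", 0.0)

    def test_zero_source_rejected(self):
        m = pd.DataFrame([[0, 0]], index=["v"], columns=["src", "dst"])
        with pytest.raises(ValueError):
            sd.plant_index_hop(m, "v", "src", "dst", 0.0005)


class TestRecovery:
    def test_triage_recovers_exactly_the_planted_exogenous_set(
        self, bundle, pipeline_result
    ):
        assert pipeline_result.final_names == set(bundle.truth.exogenous_viruses)

    def test_precision_one_no_nonviral_retained(self, bundle, pipeline_result):
        nonviral = {
            cid for cid, lab in bundle.truth.contig_labels.items() if lab == "non-viral"
        }
        retained_contigs = {c for r in pipeline_result.final_records for c in r.contig_ids}
        assert retained_contigs & nonviral == set()

    def test_endogenous_copies_flagged(self, bundle, pipeline_result):
        flagged = {r.virus_name for r in pipeline_result.records if r.endogenous}
        assert flagged == set(bundle.truth.endogenous_viruses)

    def test_contamination_filter_removes_exactly_planted_hops(self):
        b = sd.simulate_virome(
            sd.SimulationConfig(n_index_hops=2, index_hop_fraction=0.0005, seed=21)
        )
        res = pipeline.run_on_bundle(b)
        removed = {(r.virus_name, r.library_id) for r in res.removals}
        planted = {
            tuple(k.split("|"))
            for k, v in b.truth.detections.items()
            if v == "index-hop"
        }
        assert removed == planted and len(removed) == 2
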