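"""Species clustering, host rules, clade summaries, alignment oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from termite_virome import taxonomy_host as th
from termite_virome.abundance import VirusDetection
from termite_virome.io_formats import LibraryMeta, ReferenceVirus
from termite_virome.triage import VirusRecord

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP = -4.0


def _identity_of_columns(cols):
    lo, hi = 0, len(cols)
    while lo < hi and "-" in cols[lo]:
        lo += 1
    while hi > lo and "-" in cols[hi - 1]:
        hi -= 1
    inner = cols[lo:hi]
    if not inner:
        return 0.0
    matches = sum(1 for x, y in inner if x == y and x != "-")
    return 100.0 * matches / len(inner)


def nw_oracle(a, b):
    """Textbook Needleman-Wunsch with linear gaps.  Enumerates every
    co-optimal traceback and returns (score, set of identities%) — an
    independent brute-force oracle for short strings."""
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        score[i, 0] = i * GAP
    for j in range(1, m + 1):
        score[0, j] = j * GAP
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            score[i, j] = max(
                score[i - 1, j - 1] + BLOSUM62[a[i - 1], b[j - 1]],
                score[i - 1, j] + GAP,
                score[i, j - 1] + GAP,
            )
    identities = set()

    def walk(i, j, cols):
        if i == 0 and j == 0:
            identities.add(_identity_of_columns(cols[::-1]))
            return
        if i > 0 and j > 0 and np.isclose(
            score[i, j], score[i - 1, j - 1] + BLOSUM62[a[i - 1], b[j - 1]]
        ):
            walk(i - 1, j - 1, cols + [(a[i - 1], b[j - 1])])
        if i > 0 and np.isclose(score[i, j], score[i - 1, j] + GAP):
            walk(i - 1, j, cols + [(a[i - 1], "-")])
        if j > 0 and np.isclose(score[i, j], score[i, j - 1] + GAP):
            walk(i, j - 1, cols + [("-", b[j - 1])])

    walk(n, m, [])
    return score[n, m], identities


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert th.pairwise_identity("MKV" * 33 + "M", "MKV" * 33 + "M") == 100.0

    def test_five_substitutions_in_100(self):
        a = "ACDEFGHIKLMNPQRSTVWY" * 5
        b = list(a)
        for pos, sub in zip((3, 23, 47, 68, 91), "WWWWW"):
            b[pos] = sub
        assert th.pairwise_identity(a, "".join(b)) == pytest.approx(95.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            th.pairwise_identity("", "MKV")

    @given(st.integers(0, 400))
    @settings(max_examples=40)
    def test_matches_dp_oracle_on_short_strings(self, seed):
        """Identity agrees with an exhaustive dynamic-programming oracle
        on random <=12-aa strings under the same scoring."""
        rng = np.random.default_rng(seed)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        a = "".join(rng.choice(list(aas), int(rng.integers(3, 13))))
        b = "".join(rng.choice(list(aas), int(rng.integers(3, 13))))
        oracle_score, identities = nw_oracle(a, b)
        got = th.pairwise_identity(a, b)
        # the optimal score is unique; identity must match one of the
        # co-optimal alignments enumerated by the oracle
        assert th._ALIGNER.score(a, b) == pytest.approx(oracle_score)
        assert any(got == pytest.approx(i) for i in identities)


class TestClusterSpecies:
    def _matrix(self, names, pairs):
        m = pd.DataFrame(0.0, index=names, columns=names)
        np.fill_diagonal(m.values, 100.0)
        for a, b, v in pairs:
            m.loc[a, b] = m.loc[b, a] = v
        return m

    def test_pair_above_threshold_is_one_species(self):
        m = self._matrix(["a", "b"], [("a", "b", 96.0)])
        c = th.cluster_species(m)
        assert c["a"] == c["b"]

    def test_exactly_95_is_two_species(self):
        m = self._matrix(["a", "b"], [("a", "b", 95.0)])
        c = th.cluster_species(m)
        assert c["a"] != c["b"]

    def test_single_linkage_chain(self):
        m = self._matrix(
            ["A", "B", "C"], [("A", "B", 96), ("B", "C", 96), ("A", "C", 80)]
        )
        c = th.cluster_species(m)
        assert c["A"] == c["B"] == c["C"]
        # oracle: connected components by brute force over the edge list
        edges = {(a, b) for a, b in itertools.combinations("ABC", 2) if m.loc[a, b] > 95}
        assert edges == {("A", "B"), ("B", "C")}

    def test_threshold_boundaries(self):
        m = self._matrix(["a", "b", "c"], [("a", "b", 50), ("b", "c", 10)])
        assert len(set(th.cluster_species(m, threshold=0).values())) == 1
        assert len(set(th.cluster_species(m, threshold=100).values())) == 3

    def test_asymmetric_matrix_rejected(self):
        m = self._matrix(["a", "b"], [])
        m.iloc[0, 1] = 50.0
        with pytest.raises(ValueError, match="symmetric"):
            th.cluster_species(m)


def _meta(lib, procedure):
    return LibraryMeta(lib, "T. sp.", "Termitidae", "Australia", "Wood",
                       procedure, 500_000)


def _ref(host, clade="Sobemo-like", group="Luteo-Sobemo"):
    return ReferenceVirus("R1", "rel virus", host, 3000, clade, group, "RNA")


def _rec(name, clade, group, host):
    return VirusRecord(
        virus_name=name, contig_ids=("c",), library_ids=("lib01",),
        clade=clade, group=group, genome_length=3000,
        closest_relative=_ref(host, clade, group),
        percent_identity_to_relative=33.0, completeness_ratio=0.95,
    )


def _det(name, lib, pct, tier):
    return VirusDetection(name, lib, 100, 3000, 1e5, pct, tier)


META = {"wb": _meta("wb", "whole-body"), "ho": _meta("ho", "head-only")}

ARCHETYPES = [
    # (record, detections, expected category)
    (_rec("v_bact", "Leviviridae", "Narna-Levi", "bacteria"),
     [_det("v_bact", "wb", 0.0005, "low")], "Bacteria"),
    (_rec("v_fungi", "Mitovirus-like", "Narna-Levi", "fungi"),
     [_det("v_fungi", "wb", 0.003, "moderate")], "Fungus-associated"),
    (_rec("v_plant", "Idaeovirus-like", "Hepe-Virga", "plant"),
     [_det("v_plant", "wb", 0.0087, "moderate")], "Plant"),
    (_rec("v_symb", "Picobirna-like A", "Partiti-Picobirna", "vertebrate"),
     [_det("v_symb", "wb", 0.0005, "low")], "Symbiont"),
    (_rec("v_term", "Negev-like", "Hepe-Virga", "arthropod"),
     [_det("v_term", "ho", 0.54, "high")], "Termite"),
    (_rec("v_none", "Narna-like", "Narna-Levi", "mixed"),
     [_det("v_none", "wb", 0.1, "high")], "No inference"),
]


class TestHostRules:
    @pytest.mark.parametrize("rec,dets,expected",
                             ARCHETYPES, ids=[a[2] for a in ARCHETYPES])
    def test_archetype_recovers_planted_category(self, rec, dets, expected):
        pred = th.infer_host(rec, dets, META)
        assert pred.category == expected

    def test_head_only_detection_raises_confidence(self):
        rec = _rec("v", "Negev-like", "Hepe-Virga", "arthropod")
        pred_ho = th.infer_host(rec, [_det("v", "ho", 0.54, "high")], META)
        pred_wb = th.infer_host(rec, [_det("v", "wb", 0.54, "high")], META)
        assert pred_ho.confidence == "suggested"
        assert pred_wb.confidence == "cautious"

    def test_unknown_clade_warns_and_abstains(self):
        rec = _rec("v", "Totally-new-clade", "Narna-Levi", "arthropod")
        with pytest.warns(UserWarning, match="unknown clade"):
            pred = th.infer_host(rec, [], META)
        assert pred.category == "No inference"

    def test_order_deterministic_under_permutation(self):
        dets = [d for _, ds, _ in ARCHETYPES for d in ds]
        preds1 = [th.infer_host(r, dets, META).category for r, _, _ in ARCHETYPES]
        preds2 = [th.infer_host(r, dets[::-1], META).category for r, _, _ in ARCHETYPES]
        assert preds1 == preds2


class TestRounding:
    @pytest.mark.parametrize(
        "x,sig,expected",
        [(0.135, 2, 0.14), (0.165, 2, 0.17), (0.0087, 2, 0.0087),
         (0.57, 2, 0.57), (0.000975, 2, 0.00098), (0.0, 2, 0.0)],
    )
    def test_two_sig_figs_half_away_from_zero(self, x, sig, expected):
        assert th.round_sig_half_up(x, sig) == expected

    def test_one_decimal_half_up(self):
        assert th.round_decimal_half_up(38.14, 1) == 38.1
        assert th.round_decimal_half_up(38.15, 1) == 38.2


class TestCladeSummaries:
    def test_mean_abundance_over_detections_reproduces_printed_cells(self):
        """Two-library detections at (0.10, 0.17)% and (0.2, 0.13)% give
        clade means 0.14 and 0.17 after 2-sig-fig rounding."""
        recs = [
            _rec("narna_v", "Narna-like", "Narna-Levi", "mixed"),
            _rec("lispi_v", "Lispi-like", "Mono-Chu", "arthropod"),
        ]
        dets = [
            _det("narna_v", "wb", 0.10, "high"), _det("narna_v", "ho", 0.17, "high"),
            _det("lispi_v", "wb", 0.2, "high"), _det("lispi_v", "ho", 0.13, "high"),
        ]
        by_clade = {s.clade: s for s in th.summarize_clades(recs, dets)}
        assert by_clade["Narna-like"].mean_abundance == 0.14
        assert by_clade["Lispi-like"].mean_abundance == 0.17

    def test_singleton_clade_identity_one_decimal(self):
        rec = _rec("flavi_v", "Flaviviridae", "Flaviviridae", "vertebrate")
        rec.percent_identity_to_relative = 38.1
        (summary,) = th.summarize_clades([rec], [_det("flavi_v", "ho", 0.13, "high")])
        assert summary.mean_identity == 38.1
        assert summary.n_novel_viruses == 1
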