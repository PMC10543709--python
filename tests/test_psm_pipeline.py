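"""PSM collapse, target-decoy q-values, filters, isobaric novelty, assignment."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hervantigen.psm_pipeline import (
    CollapsedPeptide,
    DbIndex,
    PsmRecord,
    assign_category,
    assign_source_herv,
    check_novelty,
    collapse_to_peptides,
    compute_qvalues,
    expand_leu_ile,
    filter_identifications,
)
from hervantigen.search_db import SearchDbEntry


def brute_force_qvalues(target_scores, decoy_scores):
    """O(n^2) enumeration: q(s) = min over thresholds t <= s of D>=t / T>=t."""
    t = np.asarray(target_scores, dtype=float)
    d = np.asarray(decoy_scores, dtype=float)
    thresholds = np.unique(np.concatenate([t, d]))
    n_t = (t[None, :] >= thresholds[:, None]).sum(axis=1)
    n_d = (d[None, :] >= thresholds[:, None]).sum(axis=1)
    fdr = np.where(n_t > 0, n_d / np.maximum(n_t, 1), np.inf)
    return [float(min(1.0, fdr[thresholds <= s].min())) for s in t]


def _rows(target_scores, decoy_scores):
    rows = [
        CollapsedPeptide(f"T{i}", s, False, frozenset({"tumor"}))
        for i, s in enumerate(target_scores)
    ]
    rows += [
        CollapsedPeptide(f"D{i}", s, True, frozenset({"tumor"}))
        for i, s in enumerate(decoy_scores)
    ]
    return rows


class TestCollapse:
    def test_best_score_is_max(self):
        psms = [
            PsmRecord("LYDTVTHTF", s, False, "tumor") for s in (2.1, 3.0, 2.5)
        ]
        (row,) = collapse_to_peptides(psms)
        assert row.best_score == 3.0

    def test_empty_input(self):
        assert collapse_to_peptides([]) == []

    def test_samples_unioned(self):
        psms = [
            PsmRecord("AYAAAAAAF", 1.0, False, "tumor"),
            PsmRecord("AYAAAAAAF", 2.0, False, "normal"),
        ]
        (row,) = collapse_to_peptides(psms)
        assert row.samples == frozenset({"tumor", "normal"})

    def test_target_and_decoy_kept_separate(self):
        psms = [
            PsmRecord("AYAAAAAAF", 1.0, False, "tumor"),
            PsmRecord("AYAAAAAAF", 2.0, True, "tumor"),
        ]
        assert len(collapse_to_peptides(psms)) == 2


class TestQValues:
    @pytest.mark.parametrize(
        "targets,decoys,expected",
        [
            ([3, 2], [1], {"T0": 0.0, "T1": 0.0}),
            ([3, 1], [2], {"T0": 0.0, "T1": 0.5}),
            ([1], [2], {"T0": 1.0}),  # capped at 1
        ],
    )
    def test_examples(self, targets, decoys, expected):
        assert compute_qvalues(_rows(targets, decoys)) == expected

    def test_no_targets_raises(self):
        with pytest.raises(ValueError, match="target"):
            compute_qvalues(_rows([], [1.0]))

    @given(st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_t = int(rng.integers(1, 40))
        n_d = int(rng.integers(0, 40))
        # integer scores force ties across and within target/decoy lists
        t = rng.integers(0, 10, size=n_t).astype(float)
        d = rng.integers(0, 10, size=n_d).astype(float)
        got = compute_qvalues(_rows(t, d))
        expected = brute_force_qvalues(t, d)
        for i, e in enumerate(expected):
            assert got[f"T{i}"] == pytest.approx(e)

    @given(st.integers(0, 10_000))
    def test_monotone_in_score(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.normal(1, 1, size=30)
        d = rng.normal(0, 1, size=30)
        q = compute_qvalues(_rows(t, d))
        order = np.argsort(t)
        qs = [q[f"T{i}"] for i in order]
        assert all(a >= b for a, b in zip(qs, qs[1:]))


class TestFilter:
    def test_length_and_q_gates(self):
        rows = _rows([5.0, 4.0, 3.0], [3.5])
        rows[0] = CollapsedPeptide("AYAAAAF", 5.0, False, frozenset({"t"}))   # 7-mer
        rows[1] = CollapsedPeptide("GYISPYFINTSK", 4.0, False, frozenset({"t"}))  # 12-mer
        rows[2] = CollapsedPeptide("AYAAAAAAF", 3.0, False, frozenset({"t"}))  # q=1/1
        q = compute_qvalues(rows)
        idents = filter_identifications(rows, q, q_max=0.01)
        assert [i.peptide for i in idents] == ["GYISPYFINTSK"]

    def test_decoys_never_reported(self):
        rows = _rows([5.0] , [1.0])
        rows[0] = CollapsedPeptide("AYAAAAAAF", 5.0, False, frozenset({"t"}))
        q = compute_qvalues(rows)
        idents = filter_identifications(rows, q)
        assert all(not getattr(i, "is_decoy", False) for i in idents)
        assert len(idents) == 1


class TestLeuIle:
    def test_single_site_both_modes(self):
        assert expand_leu_ile("LYDTVTHTF", "combinatorial") == {
            "LYDTVTHTF",
            "IYDTVTHTF",
        }
        assert expand_leu_ile("LYDTVTHTF", "swap_all") == {
            "LYDTVTHTF",
            "IYDTVTHTF",
        }

    def test_no_sites(self):
        assert expand_leu_ile("AAAA") == {"AAAA"}

    def test_three_sites(self):
        combi = expand_leu_ile("LIL", "combinatorial")
        assert combi == {"LLL", "LLI", "LIL", "LII", "ILL", "ILI", "IIL", "III"}
        assert expand_leu_ile("LIL", "swap_all") == {"LIL", "ILI"}

    def test_combinatorial_cap(self):
        with pytest.raises(ValueError, match="cap"):
            expand_leu_ile("L" * 13, "combinatorial")


class TestNovelty:
    PROTEOME = [["AAAAGYISPYFAAAA", "CCCCCCCC"]]

    def test_copied_peptide_not_novel(self):
        assert not check_novelty("GYISPYF", self.PROTEOME)

    def test_isobaric_variant_blocks_novelty(self):
        # the peptide itself is absent but its I-variant matches
        proteome = [["AAAIYDTVTHTFAAA"]]
        assert not check_novelty("LYDTVTHTF", proteome)

    def test_unrelated_peptide_novel(self):
        assert check_novelty("WWWWWWWW", self.PROTEOME)

    def test_invariant_under_li_substitution(self):
        proteome = [["AAAIYDTVTHTFAAA"]]
        for variant in expand_leu_ile("LYDTVTHTF", "combinatorial"):
            assert check_novelty(variant, proteome) == check_novelty(
                "LYDTVTHTF", proteome
            )

    def test_empty_proteome_raises(self):
        with pytest.raises(ValueError, match="proteome"):
            check_novelty("AAAA", [[]])


def _db():
    return [
        SearchDbEntry("canonical|P1", "canonical", "AAAGYISPYFAAA", {"source_id": "P1"}),
        SearchDbEntry("mutanome|G2|A5W", "mutanome", "CCCWCCC", {"source_id": "P2"}),
        SearchDbEntry(
            "herv_orf|h1|f0:0-30", "herv_orf", "MGYISPYFLYDTVTHTF",
            {"source_id": "h1", "nt_length": 54, "frame": 0, "start_nt": 0, "end_nt": 54},
        ),
        SearchDbEntry(
            "herv_orf|h2|f0:0-30", "herv_orf", "MLYDTVTHTFW",
            {"source_id": "h2", "nt_length": 36, "frame": 0, "start_nt": 0, "end_nt": 36},
        ),
    ]


class TestAssignment:
    def test_canonical_precedence_over_herv(self):
        assert assign_category("GYISPYF", _db()) == "canonical"

    def test_herv_only(self):
        assert assign_category("LYDTVTHTF", _db()) == "herv_orf"

    def test_mutanome_only(self):
        assert assign_category("CCWCC", _db()) == "mutanome"

    def test_unmatched_raises(self):
        with pytest.raises(ValueError, match="no search-database entry"):
            assign_category("KKKKKKKK", _db())

    def test_source_herv_highest_tpm(self):
        expr = {"h1": {"tumor": 5.0}, "h2": {"tumor": 3.0}}
        assigned, candidates = assign_source_herv("LYDTVTHTF", _db(), expr, "tumor")
        assert assigned == "h1"
        assert candidates == ("h1", "h2")

    def test_source_herv_tie_lexicographic(self):
        expr = {"h1": {"tumor": 2.0}, "h2": {"tumor": 2.0}}
        assigned, _ = assign_source_herv("LYDTVTHTF", _db(), expr, "tumor")
        assert assigned == "h1"

    def test_single_candidate(self):
        index = DbIndex(_db())
        assigned, candidates = assign_source_herv(
            "MLYDTVTHTFW", index, {"h2": {"tumor": 0.5}}, "tumor"
        )
        assert assigned == "h2"
        assert candidates == ("h2",)
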