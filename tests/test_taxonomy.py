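"""Alignment identity and cutoff-based taxonomic assignment."""

from functools import lru_cache

import numpy as np
import pytest

from afmock import (
    AnnotationParams,
    ReferenceDB,
    ReferenceRecord,
    Taxon,
    assign_taxonomy,
    pairwise_identity,
)
from conftest import random_dna

MATCH, MISMATCH, GAP = 1, -1, -2


def optimal_identities(a, b):
    """Exhaustive DP oracle: identities of every optimal global alignment.

    Returns the set of 100 * matches / columns values achievable by
    alignments attaining the optimal score under the package's default
    scoring.  Small inputs only.
    """

    @lru_cache(maxsize=None)
    def score(i, j):
        if i == 0 and j == 0:
            return 0
        best = -10**9
        if i > 0 and j > 0:
            best = max(best, score(i - 1, j - 1)
                       + (MATCH if a[i - 1] == b[j - 1] else MISMATCH))
        if i > 0:
            best = max(best, score(i - 1, j) + GAP)
        if j > 0:
            best = max(best, score(i, j - 1) + GAP)
        return best

    @lru_cache(maxsize=None)
    def outcomes(i, j):
        """Set of (matches, columns) over optimal alignments of prefixes."""
        if i == 0 and j == 0:
            return frozenset({(0, 0)})
        out = set()
        s = score(i, j)
        if i > 0 and j > 0:
            step = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            if score(i - 1, j - 1) + step == s:
                out.update((m + (step == MATCH), c + 1)
                           for m, c in outcomes(i - 1, j - 1))
        if i > 0 and score(i - 1, j) + GAP == s:
            out.update((m, c + 1) for m, c in outcomes(i - 1, j))
        if j > 0 and score(i, j - 1) + GAP == s:
            out.update((m, c + 1) for m, c in outcomes(i, j - 1))
        return frozenset(out)

    return {100.0 * m / c for m, c in outcomes(len(a), len(b))}


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        seq = random_dna(np.random.default_rng(0), 150)
        assert pairwise_identity(seq, seq) == pytest.approx(100.0)

    def test_single_substitution_on_150mer(self):
        seq = random_dna(np.random.default_rng(1), 150)
        other = seq[:75] + ("A" if seq[75] != "A" else "C") + seq[76:]
        assert pairwise_identity(seq, other) == pytest.approx(100 * 149 / 150, abs=1e-9)
        assert round(pairwise_identity(seq, other), 2) == 99.33

    def test_internal_indel_counts_gap_column(self):
        a = "ACGTACGTAC"
        b = a[:4] + "T" + a[4:]  # 11-mer: a with one internal insertion
        # ten matched columns plus one gap column
        assert pairwise_identity(a, b) == pytest.approx(100 * 10 / 11, abs=1e-9)
        # deletion instead: nine matched columns of ten
        assert pairwise_identity(a, a[:4] + a[5:]) == pytest.approx(90.0, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b = random_dna(rng, 30), random_dna(rng, 25)
            assert pairwise_identity(a, b) == pytest.approx(
                pairwise_identity(b, a), abs=1e-9)

    def test_agrees_with_exhaustive_dp_on_small_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(120):
            a = random_dna(rng, int(rng.integers(1, 13)))
            b = random_dna(rng, int(rng.integers(1, 13)))
            got = pairwise_identity(a, b)
            assert any(got == pytest.approx(x, abs=1e-9)
                       for x in optimal_identities(a, b)), (a, b)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_semiglobal_ignores_flank_truncation(self):
        rng = np.random.default_rng(4)
        ref = random_dna(rng, 400)
        query = ref[100:250]
        assert pairwise_identity(query, ref, mode="semiglobal") == pytest.approx(100.0)
        assert pairwise_identity(query, ref, mode="global") < 60.0


def mutated(seq, n_subs, rng):
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


@pytest.fixture(scope="module")
def small_db():
    rng = np.random.default_rng(5)
    return ReferenceDB([
        ReferenceRecord("ref_a", random_dna(rng, 400), Taxon("GenusA", "GenusA_1")),
        ReferenceRecord("ref_b", random_dna(rng, 420), Taxon("GenusB", "GenusB_1")),
    ])


class TestAssignTaxonomy:
    def test_db_member_returns_own_taxon_at_100(self, small_db):
        for rec in small_db.records:
            taxon, identity, ref_id = assign_taxonomy(rec.sequence, small_db)
            assert (taxon, identity, ref_id) == (rec.taxon, pytest.approx(100.0),
                                                 rec.ref_id)

    def test_query_between_cutoffs_gets_genus_only(self, small_db):
        rng = np.random.default_rng(6)
        ref = small_db.records[0]
        query = mutated(ref.sequence, 16, rng)  # 96% identity to nearest
        taxon, identity, ref_id = assign_taxonomy(query, small_db)
        assert 95 < identity <= 98
        assert taxon == Taxon("GenusA", None)
        assert ref_id == "ref_a"

    def test_query_below_genus_cutoff_is_na(self, small_db):
        rng = np.random.default_rng(7)
        query = random_dna(rng, 400)  # unrelated, far below 90.5%
        taxon, identity, _ = assign_taxonomy(query, small_db)
        assert identity < 90.5
        assert taxon == Taxon(None, None)

    def test_raising_cutoffs_never_adds_labels(self, small_db):
        rng = np.random.default_rng(8)
        ref = small_db.records[0]
        rank = {2: 0, 1: 1, 0: 2}  # labels count -> coarseness order

        def n_labels(taxon):
            return (taxon.genus is not None) + (taxon.clade is not None)

        for n_subs in (0, 4, 8, 12, 16, 25, 60):
            query = mutated(ref.sequence, n_subs, rng) if n_subs else ref.sequence
            previous = 2
            for clade_cut, genus_cut in ((90.0, 85.0), (95.0, 92.0), (98.0, 95.0),
                                         (99.5, 99.0)):
                params = AnnotationParams(clade_cutoff=clade_cut,
                                          genus_cutoff=genus_cut)
                taxon, _, _ = assign_taxonomy(query, small_db, params)
                assert n_labels(taxon) <= previous
                previous = n_labels(taxon)

    def test_clade_implies_genus(self):
        with pytest.raises(ValueError):
            Taxon(None, "clade_without_genus")

    def test_db_fasta_roundtrip(self, small_db, tmp_path):
        path = tmp_path / "db.fasta"
        small_db.to_fasta(path)
        back = ReferenceDB.from_fasta(path)
        assert [(r.ref_id, r.sequence, r.taxon) for r in back.records] == \
            [(r.ref_id, r.sequence, r.taxon) for r in small_db.records]
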