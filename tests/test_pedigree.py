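import numpy as np
import pandas as pd
import pytest

from nivalis.pedigree import (
    Pedigree,
    PedigreeError,
    a_inverse,
    additive_relationship,
    generation_time,
    inbreeding_coefficients,
    validate_pedigree,
)


def ped_frame(rows):
    return pd.DataFrame(rows, columns=["id", "sire", "dam", "sex", "cohort"])


TRIO = ped_frame(
    [("s", "", "", "M", 2000), ("d", "", "", "F", 2000), ("o", "s", "d", "F", 2001)]
)


def random_pedigree(n, seed=0, n_founders=10, start=2000):
    """Random overlapping-generations pedigree for oracle tests."""
    rng = np.random.default_rng(seed)
    rows = []
    males, females = [], []
    for i in range(n):
        iid = f"i{i}"
        sex = "M" if rng.random() < 0.5 else "F"
        if i < n_founders or not males or not females:
            rows.append((iid, "", "", sex, start))
        else:
            cohort = start + 1 + i // max(n // 8, 1)
            rows.append((iid, rng.choice(males), rng.choice(females), sex, cohort))
        (males if sex == "M" else females).append(iid)
    return validate_pedigree(ped_frame(rows))


# ---------------------------------------------------------------- validation
class TestValidation:
    def test_trio_is_valid_with_expected_counts(self):
        ped = validate_pedigree(TRIO)
        assert len(ped) == 3
        assert ped.n_maternities == 1
        assert ped.n_paternities == 1
        assert ped.max_depth == 2

    def test_parents_sorted_before_offspring(self):
        shuffled = TRIO.iloc[[2, 0, 1]].reset_index(drop=True)
        ped = validate_pedigree(shuffled)
        assert ped.index["o"] > max(ped.index["s"], ped.index["d"])

    def test_cycle_raises_naming_an_individual(self):
        bad = ped_frame(
            [("a", "b", "", "M", 2000), ("b", "a", "", "M", 2000), ("m", "", "", "F", 2000)]
        )
        with pytest.raises(PedigreeError, match="cycle"):
            validate_pedigree(bad)

    def test_sex_inconsistent_parentage(self):
        bad = ped_frame(
            [("s", "", "", "F", 2000), ("d", "", "", "F", 2000), ("o", "s", "d", "M", 2001)]
        )
        with pytest.raises(PedigreeError, match="sex-inconsistent.*s"):
            validate_pedigree(bad)

    def test_parent_born_after_offspring_rejected(self):
        bad = ped_frame(
            [("s", "", "", "M", 2005), ("d", "", "", "F", 2000), ("o", "s", "d", "M", 2001)]
        )
        with pytest.raises(PedigreeError, match="born after"):
            validate_pedigree(bad)

    def test_same_cohort_parentage_allowed(self):
        ok = ped_frame(
            [("s", "", "", "M", 2000), ("d", "", "", "F", 2001), ("o", "s", "d", "M", 2001)]
        )
        assert len(validate_pedigree(ok)) == 3

    def test_unknown_parent_tokens(self):
        frame = ped_frame(
            [("s", "NA", None, "M", 2000), ("d", "", "*", "F", 2000),
             ("o", "s", "d", "M", 2001)]
        )
        ped = validate_pedigree(frame)
        assert ped.founders.sum() == 2

    def test_missing_parent_record_rejected(self):
        bad = ped_frame([("o", "ghost", "", "M", 2001)])
        with pytest.raises(PedigreeError, match="ghost"):
            validate_pedigree(bad)

    def test_generator_link_counts_match_truth_ledger(self, small_dataset):
        ped = small_dataset.pedigree
        n_juv = len(small_dataset.truth.growth)
        assert ped.n_maternities == n_juv
        assert ped.n_paternities == n_juv


# ------------------------------------------------------- relationship matrix
class TestAdditiveRelationship:
    def test_unrelated_founders_identity(self):
        ped = validate_pedigree(
            ped_frame([("a", "", "", "M", 2000), ("b", "", "", "F", 2000)])
        )
        assert np.allclose(additive_relationship(ped), np.eye(2))

    def test_parent_offspring_half(self):
        ped = validate_pedigree(TRIO)
        A = additive_relationship(ped)
        o, s = ped.index["o"], ped.index["s"]
        assert A[o, s] == pytest.approx(0.5)
        assert A[o, o] == pytest.approx(1.0)

    def test_full_sib_mating_inbreeding(self):
        rows = [
            ("s", "", "", "M", 2000), ("d", "", "", "F", 2000),
            ("b1", "s", "d", "M", 2001), ("b2", "s", "d", "F", 2001),
            ("x", "b1", "b2", "M", 2002),
        ]
        ped = validate_pedigree(ped_frame(rows))
        A = additive_relationship(ped)
        x = ped.index["x"]
        assert A[x, x] == pytest.approx(1.25)
        assert inbreeding_coefficients(ped)[x] == pytest.approx(0.25)

    def test_matches_gene_dropping_allele_sharing(self):
        """A entries equal expected allele-sharing from dropped alleles."""
        ped = random_pedigree(50, seed=3)
        A = additive_relationship(ped)
        rng = np.random.default_rng(0)
        n, reps = len(ped), 60000
        # two allele copies per individual; founders unique, offspring inherit
        alleles = np.zeros((n, 2, reps), dtype=np.int32)
        counter = 1
        for i in range(n):
            for side, p in enumerate((ped.sire[i], ped.dam[i])):
                if p < 0:
                    alleles[i, side] = counter
                    counter += 1
                else:
                    pick = rng.integers(0, 2, reps)
                    alleles[i, side] = alleles[p, pick, np.arange(reps)]
        # check a sample of pairs incl. diagonal
        pairs = [(i, i) for i in range(0, n, 7)] + [
            (i, j) for i in range(0, n, 11) for j in range(0, n, 13) if i != j
        ]
        for i, j in pairs:
            share = np.zeros(reps)
            for ai in range(2):
                for aj in range(2):
                    share += alleles[i, ai] == alleles[j, aj]
            est = share.mean() / 2.0
            se = share.std() / 2.0 / np.sqrt(reps)
            assert abs(est - A[i, j]) < max(3 * se, 1e-3), (i, j)

    def test_inbreeding_matches_recursive_kinship(self):
        """diag(A) - 1 equals F from an independent kinship recursion."""
        ped = random_pedigree(40, seed=5)
        from functools import lru_cache

        @lru_cache(maxsize=None)
        def kinship(i, j):
            if i > j:
                i, j = j, i
            if i == j:
                s, d = ped.sire[i], ped.dam[i]
                extra = kinship(s, d) if (s >= 0 and d >= 0) else 0.0
                return 0.5 * (1.0 + extra)
            # j is never an ancestor of i when i < j (topological order)
            s, d = ped.sire[j], ped.dam[j]
            val = 0.0
            if s >= 0:
                val += 0.5 * kinship(i, s)
            if d >= 0:
                val += 0.5 * kinship(i, d)
            return val

        F = inbreeding_coefficients(ped)
        for i in range(len(ped)):
            s, d = ped.sire[i], ped.dam[i]
            expected = kinship(s, d) if (s >= 0 and d >= 0) else 0.0
            assert F[i] == pytest.approx(expected, abs=1e-12)

    def test_psd_on_generated_pedigree(self, small_dataset):
        A = additive_relationship(small_dataset.pedigree)
        assert np.allclose(A, A.T)
        w = np.linalg.eigvalsh(A)
        assert w.min() > -1e-8
        assert np.all(np.diag(A) >= 1.0 - 1e-12)
        assert A.max() <= 2.0 + 1e-12


# ---------------------------------------------------------------- A inverse
class TestAInverse:
    def test_trio_inverse(self):
        ped = validate_pedigree(TRIO)
        A = additive_relationship(ped)
        Ainv = a_inverse(ped).toarray()
        assert np.allclose(Ainv @ A, np.eye(3), atol=1e-10)

    def test_founders_only_identity(self):
        ped = validate_pedigree(
            ped_frame([("a", "", "", "M", 2000), ("b", "", "", "F", 2000)])
        )
        assert np.allclose(a_inverse(ped).toarray(), np.eye(2))

    @pytest.mark.parametrize("n,seed", [(100, 1), (300, 2)])
    def test_matches_dense_inverse_on_inbred_pedigree(self, n, seed):
        ped = random_pedigree(n, seed=seed, n_founders=8)
        assert inbreeding_coefficients(ped).max() > 0  # inbreeding present
        A = additive_relationship(ped)
        Ainv = a_inverse(ped).toarray()
        assert np.allclose(Ainv, np.linalg.inv(A), atol=1e-8)
        assert np.abs(Ainv @ A - np.eye(n)).max() < 1e-8


# ------------------------------------------------------------ generation time
class TestGenerationTime:
    def test_all_age_one(self):
        assert generation_time(validate_pedigree(TRIO)) == pytest.approx(1.0)

    def test_mixed_parent_ages(self):
        rows = [
            ("s", "", "", "M", 2000), ("d", "", "", "F", 2000),
            ("o1", "s", "d", "M", 2001), ("o2", "s", "d", "F", 2002),
        ]
        ped = validate_pedigree(ped_frame(rows))
        assert generation_time(ped) == pytest.approx(1.5)

    def test_no_links_raises(self):
        ped = validate_pedigree(ped_frame([("a", "", "", "M", 2000)]))
        with pytest.raises(PedigreeError, match="no parent links"):
            generation_time(ped)


class TestRandomPedigreeInvariants:
    """Structural invariants over randomly generated pedigrees."""

    from hypothesis import given, settings, strategies as st

    @given(seed=st.integers(0, 10_000), n=st.integers(5, 60))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_relationship_matrix_invariants(self, seed, n):
        ped = random_pedigree(n, seed=seed, n_founders=max(4, n // 5))
        A = additive_relationship(ped)
        assert np.allclose(A, A.T)
        assert np.all(np.diag(A) >= 1.0 - 1e-12)
        assert A.min() >= 0.0 and A.max() <= 2.0 + 1e-12
        assert np.linalg.eigvalsh(A).min() > -1e-8
        Ainv = a_inverse(ped)
        assert np.abs(Ainv @ A - np.eye(len(ped))).max() < 1e-8
        # individuals with both parents unknown are mutually unrelated
        founders = np.where(ped.founders)[0]
        off = A[np.ix_(founders, founders)] - np.eye(len(founders))
        assert np.abs(off).max() == 0.0


def test_csv_roundtrip(tmp_path, small_dataset):
    ped = small_dataset.pedigree
    path = tmp_path / "ped.csv"
    ped.to_csv(path)
    back = Pedigree.from_csv(path)
    assert back.ids == ped.ids
    assert np.array_equal(back.sire, ped.sire)
    assert np.array_equal(back.cohort, ped.cohort)
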