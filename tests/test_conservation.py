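"""BLOSUM45 loading, per-position scoring and the differential statistic."""

import numpy as np
import pytest

from dirpscan.alignment import MultipleAlignment
from dirpscan.conservation import (
    SubstitutionMatrix,
    differential_profile,
    load_substitution_matrix,
    map_to_reference,
    pair_position_score,
    set_conservation,
    significant_positions,
)


def _ncbi_text(matrix):
    head = "   " + " ".join(matrix.residues)
    body = "\n".join(
        r + " " + " ".join(f"{matrix.scores[i, j]:g}" for j in range(len(matrix.residues)))
        for i, r in enumerate(matrix.residues)
    )
    return head + "\n" + body + "\n"


class TestSubstitutionMatrix:
    def test_ncbi_roundtrip_matches_canonical_blosum45(self, b45):
        parsed = load_substitution_matrix(_ncbi_text(b45), name="BLOSUM45")
        assert parsed.residues == b45.residues
        assert np.array_equal(parsed.scores, b45.scores)
        assert parsed.score("W", "W") == 15
        assert parsed.score("A", "W") == parsed.score("W", "A")

    def test_asymmetric_matrix_rejected(self):
        text = "   A R\nA 4 -1\nR -2 5\n"
        with pytest.raises(ValueError, match="symmetric"):
            load_substitution_matrix(text)

    def test_missing_residue_lookup_names_residue(self, b45):
        small = SubstitutionMatrix(("A", "R"), np.array([[4.0, -2.0], [-2.0, 7.0]]))
        with pytest.raises(KeyError, match="'B'"):
            small.score("A", "B")

    def test_diagonal_dominates_rows(self, b45):
        # a defining property of BLOSUM-style matrices
        s = b45.scores[:20, :20]
        off_max = np.where(np.eye(20, dtype=bool), -np.inf, s).max(axis=1)
        assert (np.diag(s) >= off_max).all()


class TestPairPositionScore:
    def test_matched_leucines(self, b45):
        msa = MultipleAlignment({"a": "L", "b": "L"}, reference_id="a")
        assert pair_position_score(msa, "a", "b", 0, b45) == b45.score("L", "L")

    def test_gap_is_not_scorable(self, b45):
        msa = MultipleAlignment({"a": "L-", "b": "LL"}, reference_id="a")
        assert pair_position_score(msa, "a", "b", 1, b45) is None

    def test_identity_scores_above_substitution(self, b45):
        assert b45.score("A", "A") > b45.score("A", "W")


class TestSetConservation:
    def test_identical_column_gives_diagonal(self, b45):
        msa = MultipleAlignment({"a": "W", "b": "W", "c": "W"}, reference_id="a")
        means, cov = set_conservation(msa, msa.pairs(), b45)
        assert means[0] == b45.score("W", "W") and cov[0] == 1.0

    def test_mean_of_two_pairs(self, b45):
        msa = MultipleAlignment({"a": "A", "b": "A", "c": "W", "d": "W"}, reference_id="a")
        means, _ = set_conservation(msa, [("a", "b"), ("a", "c")], b45)
        assert means[0] == (b45.score("A", "A") + b45.score("A", "W")) / 2

    def test_matches_hand_computed_means(self, b45):
        rows = {
            "r1": "ACDEFGHIKL",
            "r2": "ACDEFGHIKV",
            "r3": "ACDE-GHIKL",
            "r4": "PCDEFGHIKL",
            "r5": "ACDWFGHIKL",
            "r6": "ACDEFGHI-L",
        }
        msa = MultipleAlignment(rows, reference_id="r1")
        pairs = [("r1", "r2"), ("r3", "r4"), ("r5", "r6")]
        means, cov = set_conservation(msa, pairs, b45)
        # column 0: A/A, A/P, A/A ; column 3: E/E, E/E, W/E ; column 4: F/F, -/F -> 2 scorable
        assert means[0] == pytest.approx((5 + (-1) + 5) / 3)
        assert means[3] == pytest.approx((6 + 6 + (-3)) / 3)
        assert cov[4] == pytest.approx(2 / 3)
        assert means[4] == pytest.approx((8 + 8) / 2)

    def test_low_coverage_unscored(self, b45):
        msa = MultipleAlignment({"a": "A-", "b": "A-", "c": "AA", "d": "AA"}, reference_id="c")
        means, cov = set_conservation(msa, [("a", "b"), ("a", "c"), ("b", "d")], b45)
        assert np.isnan(means[1]) and cov[1] == pytest.approx(0.0)


class TestMapToReference:
    def test_gap_skipping_count(self):
        msa = MultipleAlignment({"ref": "M-TE", "x": "MATE"}, reference_id="ref")
        assert map_to_reference(msa, 2) == "T2"

    def test_reference_gap_not_mappable(self):
        msa = MultipleAlignment({"ref": "M-TE", "x": "MATE"}, reference_id="ref")
        with pytest.raises(ValueError, match="not mappable"):
            map_to_reference(msa, 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_covers_reference_exactly_once(self, seed):
        rng = np.random.default_rng(seed)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        ref = "".join(rng.choice(list(aas + "------"), size=30))
        if ref.strip("-") == "":
            ref = "A" + ref[1:]
        msa = MultipleAlignment({"ref": ref, "x": "A" * 30}, reference_id="ref")
        labels = [map_to_reference(msa, c) for c in msa.reference_columns()]
        numbers = [int(l[1:]) for l in labels]
        assert numbers == list(range(1, len(ref.replace("-", "")) + 1))
        assert [l[0] for l in labels] == [c for c in ref if c != "-"]


def _profile_msa(rng, n_rows=20, length=24):
    aas = "ACDEFGHIKLMNPQRSTVWY"
    rows = {
        f"s{i:02d}": "".join(rng.choice(list(aas), size=length)) for i in range(n_rows)
    }
    return rows


class TestDifferentialProfile:
    def test_whole_msa_set_has_zero_delta(self, b45):
        rng = np.random.default_rng(0)
        msa = MultipleAlignment(_profile_msa(rng), reference_id="s00")
        prof = differential_profile(msa, msa.pairs(), None, b45, n_random_sets=10, seed=1)
        assert prof.table["delta"].abs().max() == 0.0

    def test_planted_conserved_column_has_max_delta(self, b45):
        rng = np.random.default_rng(1)
        rows = _profile_msa(rng)
        ids = sorted(rows)
        pair_set = [(ids[i], ids[i + 1]) for i in range(0, 12, 2)]
        for a, b in pair_set:  # column 5 invariant within the planted pairs
            rows[a] = rows[a][:5] + "H" + rows[a][6:]
            rows[b] = rows[b][:5] + "H" + rows[b][6:]
        msa = MultipleAlignment(rows, reference_id=ids[0])
        prof = differential_profile(msa, pair_set, None, b45, n_random_sets=50, seed=2)
        table = prof.scored()
        top = table.loc[table["delta"].idxmax()]
        assert top["column"] == 5 and top["direction"] == "conserved"

    def test_planted_variable_column_negative_delta(self, b45):
        rng = np.random.default_rng(2)
        rows = {k: "W" + v[1:] for k, v in _profile_msa(rng).items()}
        ids = sorted(rows)
        pair_set = [(ids[i], ids[i + 1]) for i in range(0, 12, 2)]
        for a, _ in pair_set:  # break the conserved column inside the set
            rows[a] = "C" + rows[a][1:]
        msa = MultipleAlignment(rows, reference_id=ids[0])
        prof = differential_profile(msa, pair_set, None, b45, n_random_sets=50, seed=3)
        row = prof.scored().set_index("column").loc[0]
        assert row["delta"] < 0 and row["direction"] == "variable"

    def test_constant_matrix_shift_leaves_delta_unchanged(self, b45):
        rng = np.random.default_rng(3)
        msa = MultipleAlignment(_profile_msa(rng), reference_id="s00")
        pair_set = msa.pairs()[:6]
        shifted = SubstitutionMatrix(b45.residues, b45.scores + 7.0, name="shifted")
        sets = [msa.pairs()[i : i + 6] for i in range(0, 60, 6)]
        p1 = differential_profile(msa, pair_set, sets, b45)
        p2 = differential_profile(msa, pair_set, sets, shifted)
        assert np.allclose(p1.table["delta"], p2.table["delta"])
        assert np.allclose(p1.table["p"], p2.table["p"])


class TestSignificantPositions:
    def test_planted_columns_recovered_with_directions(self, b45):
        rng = np.random.default_rng(4)
        rows = _profile_msa(rng, n_rows=24, length=30)
        ids = sorted(rows)
        pair_set = [(ids[i], ids[i + 1]) for i in range(0, 16, 2)]

        def put(col, char, members):
            for m in members:
                rows[m] = rows[m][:col] + char + rows[m][col + 1 :]

        for col in (3, 11, 19):  # conserved within the set
            for a, b in pair_set:
                put(col, "H", [a, b])
        put(25, "W", ids)  # variable within the set
        put(25, "C", [a for a, _ in pair_set])
        msa = MultipleAlignment(rows, reference_id=ids[0])
        prof = differential_profile(msa, pair_set, None, b45, n_random_sets=199, seed=5)
        hits = significant_positions(prof, alpha=0.01)
        assert sorted(hits["column"]) == [3, 11, 19, 25]
        directions = dict(zip(hits["column"], hits["direction"]))
        assert directions[25] == "variable"
        assert all(directions[c] == "conserved" for c in (3, 11, 19))

    def test_alpha_one_returns_every_scored_position(self, b45):
        rng = np.random.default_rng(6)
        msa = MultipleAlignment(_profile_msa(rng), reference_id="s00")
        prof = differential_profile(msa, msa.pairs()[:5], None, b45, n_random_sets=20, seed=7)
        hits = significant_positions(prof, alpha=1.0)
        assert len(hits) == len(prof.scored())

    def test_unattainable_alpha_warns(self, b45):
        rng = np.random.default_rng(7)
        msa = MultipleAlignment(_profile_msa(rng), reference_id="s00")
        prof = differential_profile(msa, msa.pairs()[:5], None, b45, n_random_sets=20, seed=8)
        with pytest.warns(UserWarning, match="resolution"):
            significant_positions(prof, alpha=0.01)

    def test_power_at_moderate_effect_sizes(self, b45):
        # planted pairs agree only up to similar residues (score ~2-3 above
        # background): recovery power >= 90% with 20 pairs
        rng = np.random.default_rng(9)
        similar = [("I", "V"), ("K", "R"), ("D", "E"), ("S", "T"), ("F", "Y")]
        hits = 0
        n_rep = 25
        for _ in range(n_rep):
            rows = _profile_msa(rng, n_rows=40, length=20)
            ids = sorted(rows)
            pair_set = [(ids[i], ids[i + 1]) for i in range(0, 40, 2)]
            for a, b in pair_set:
                ra, rb = similar[int(rng.integers(len(similar)))]
                rows[a] = rows[a][:4] + ra + rows[a][5:]
                rows[b] = rows[b][:4] + rb + rows[b][5:]
            msa = MultipleAlignment(rows, reference_id=ids[0])
            prof = differential_profile(
                msa, pair_set, None, b45, n_random_sets=100,
                seed=int(rng.integers(2**31 - 1)),
            )
            sig = significant_positions(prof, alpha=0.01)
            if 4 in set(sig["column"]):
                hits += 1
        assert hits / n_rep >= 0.9
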