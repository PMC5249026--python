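import numpy as np
import pytest

from snoscout.folding import (
    CANONICAL_PAIRS,
    MIN_HAIRPIN,
    UNPAIRED,
    StructureParseError,
    ensemble_stats,
    fold,
    get_engine,
    is_single_stemloop,
    local_fold,
    make_constraint,
    parse_structure,
)

from conftest import random_rna

ORDER = str.maketrans("(.)", "012")  # lexicographic order '(' < '.' < ')'


def enumerate_best_structure(seq):
    """Exhaustive enumeration oracle: all nested structures (min hairpin 3,
    Watson-Crick + G.U pairs), maximum pairs, lexicographically smallest."""
    n = len(seq)
    memo = {}

    def structures(i, j):
        if (i, j) in memo:
            return memo[(i, j)]
        if j - i <= 0:
            return [""]
        out = ["." + s for s in structures(i + 1, j)]
        for k in range(i + MIN_HAIRPIN + 1, j):
            if (seq[i], seq[k]) in CANONICAL_PAIRS:
                for inner in structures(i + 1, k):
                    for rest in structures(k + 1, j):
                        out.append("(" + inner + ")" + rest)
        memo[(i, j)] = out
        return out

    all_structs = structures(0, n)
    best_pairs = max(s.count("(") for s in all_structs)
    candidates = [s for s in all_structs if s.count("(") == best_pairs]
    return min(candidates, key=lambda s: s.translate(ORDER)), best_pairs


class TestMaxPairEngine:
    def test_hairpin(self, maxpair):
        result = maxpair.fold("GGGAAACCC")
        assert result.structure == "(((...)))"
        assert result.mfe == -3.0

    def test_too_short_to_pair(self, maxpair):
        result = maxpair.fold("ACGU")
        assert result.structure == "...."
        assert result.mfe == 0.0

    def test_matches_enumeration_oracle(self, maxpair):
        rng = np.random.default_rng(17)
        for _ in range(500):
            seq = random_rna(rng, int(rng.integers(5, 15)))
            expected_struct, expected_pairs = enumerate_best_structure(seq)
            got = maxpair.fold(seq)
            assert got.mfe == -expected_pairs, seq
            assert got.structure == expected_struct, seq

    def test_local_fold_finds_embedded_hairpin(self, maxpair):
        seq = "A" * 10 + "GGGG" + "AAAA" + "CCCC" + "A" * 32
        hits = local_fold(maxpair, seq, 120)
        assert len(hits) == 1
        assert hits[0][0] == 10

    def test_local_fold_poly_a_empty(self, maxpair):
        assert local_fold(maxpair, "A" * 50, 120) == []

    def test_local_fold_respects_span(self, maxpair):
        rng = np.random.default_rng(3)
        for _ in range(30):
            seq = random_rna(rng, 80)
            for start, end, _s, _e in local_fold(maxpair, seq, 20):
                assert end - start <= 20 + 1


class TestConstraints:
    @pytest.mark.parametrize("engine_name", ["vienna", "maxpair"])
    def test_unpaired_positions_stay_unpaired(self, engine_name):
        engine = get_engine(engine_name)
        rng = np.random.default_rng(29)
        for _ in range(40):
            seq = random_rna(rng, 40, p=[0.2, 0.3, 0.3, 0.2])
            pos = rng.choice(40, size=5, replace=False)
            constraint = make_constraint(40, pos)
            result = fold(engine, seq, constraint)
            for p in pos:
                assert result.structure[p] == "."
            # balanced
            parse_structure(result.structure)

    def test_first_position_constraint(self, vienna):
        result = fold(vienna, "GGGGGAAAACCCCC", make_constraint(14, [0]))
        assert result.structure[0] == "."

    def test_constraint_never_improves_energy(self, vienna):
        rng = np.random.default_rng(31)
        for _ in range(20):
            seq = random_rna(rng, 60)
            free = fold(vienna, seq).mfe
            constrained = fold(vienna, seq, make_constraint(60, range(10, 30))).mfe
            assert constrained >= free - 1e-9


class TestParseStructure:
    def test_plain_hairpin(self):
        d = parse_structure("(((...)))")
        assert len(d.pairs) == 3
        assert d.hairpin_loops == [((2, 6), 3)]
        assert d.interior_elements == []
        assert d.external_unpaired == 0

    def test_interior_loop(self):
        d = parse_structure("((..((...))..))")
        assert d.pairs == [(0, 14), (1, 13), (4, 10), (5, 9)]
        assert d.interior_elements == [((1, 13), (4, 10), 2, 2)]
        assert d.hairpin_loops == [((5, 9), 3)]
        assert len(d.helices) == 2

    def test_all_unpaired(self):
        d = parse_structure("......")
        assert d.pairs == []
        assert d.external_unpaired == 6

    def test_unbalanced_raises_with_position(self):
        with pytest.raises(StructureParseError, match="position"):
            parse_structure("((..)")
        with pytest.raises(StructureParseError):
            parse_structure(")(")

    def test_position_classification_is_a_partition(self):
        rng = np.random.default_rng(41)
        engine = get_engine("maxpair")
        for _ in range(100):
            seq = random_rna(rng, int(rng.integers(10, 60)))
            d = parse_structure(engine.fold(seq).structure)
            paired = 2 * len(d.pairs)
            hairpin = sum(n for _, n in d.hairpin_loops)
            interior = sum(l + r for _, _, l, r in d.interior_elements)
            assert paired + hairpin + interior + d.external_unpaired == d.length


class TestSingleStemloop:
    @pytest.mark.parametrize(
        "structure,min_bp,expected",
        [
            ("(((...)))", 3, True),
            ("(((...)))(((...)))", 3, False),
            ("((...))", 3, False),
            ("((..((...))..))", 3, True),
            ("((..((...))..((...))..))", 3, False),  # multiloop
        ],
    )
    def test_cases(self, structure, min_bp, expected):
        assert is_single_stemloop(parse_structure(structure), min_bp) is expected


class TestEnsembleStats:
    def test_homopolymer_has_zero_sd_and_zscore(self, maxpair):
        stats = ensemble_stats(maxpair, "A" * 30, 10, seed=1)
        assert stats.e_stdv == 0.0
        assert stats.zscore == 0.0

    def test_deterministic_under_seed(self, vienna):
        seq = "GGGGGAAAACCCCCAAGGGCCAAACC"
        a = ensemble_stats(vienna, seq, 20, seed=7)
        b = ensemble_stats(vienna, seq, 20, seed=7)
        assert (a.e_avg, a.e_stdv, a.zscore) == (b.e_avg, b.e_stdv, b.zscore)

    def test_structured_hairpin_scores_negative_z(self, maxpair):
        stats = ensemble_stats(maxpair, "GGGGGAAAACCCCC", 200, seed=3)
        assert stats.zscore < 0

    def test_requires_two_shuffles(self, maxpair):
        with pytest.raises(ValueError):
            ensemble_stats(maxpair, "ACGUACGU", 1, seed=0)


def test_vienna_local_fold_span_property(vienna):
    rng = np.random.default_rng(53)
    for _ in range(20):
        seq = random_rna(rng, 150)
        for start, end, struct, energy in local_fold(vienna, seq, 40):
            assert end - start <= 40 + 3
            parse_structure(struct)
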