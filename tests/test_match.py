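import random
from functools import lru_cache

import edlib
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amplitrim import (
    AmpliconPanel,
    AmpliconPrimer,
    MatchModel,
    MatchParams,
    SeedRole,
    build_index,
    dynamic_model_match,
    hamming_distance,
    kmer_model_match,
    locate_primer,
    nw_align,
)
from amplitrim.panel import bases_match

from conftest import random_seq

dna = st.text(alphabet="ACGT", min_size=1, max_size=10)


def prefix_edit_distance(primer: str, text: str) -> int:
    """Independent oracle: minimum edit distance between the whole primer
    and any prefix of ``text``, by exhaustive recursion over edit scripts."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == len(primer):
            return 0  # remaining text is a free suffix
        options = [1 + rec(i + 1, j)]  # consume primer base against a gap
        if j < len(text):
            options.append((primer[i] != text[j]) + rec(i + 1, j + 1))
            options.append(1 + rec(i, j + 1))  # consume text base against a gap
        return min(options)

    return rec(0, 0)


class TestHamming:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("ACGT", "ACGT", 0), ("ACGT", "ACGA", 1), ("NNNN", "ACGT", 0), ("ACGT", "NCGT", 1)],
    )
    def test_examples(self, a, b, expected):
        assert hamming_distance(a, b) == expected

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            hamming_distance("ACGT", "ACG")

    @settings(derandomize=True)
    @given(st.data())
    def test_matches_positional_brute_force(self, data):
        n = data.draw(st.integers(1, 30))
        a = data.draw(st.text(alphabet="ACGTN", min_size=n, max_size=n))
        b = data.draw(st.text(alphabet="ACGTN", min_size=n, max_size=n))
        brute = sum(1 for x, y in zip(a, b) if not bases_match(x, y))
        assert hamming_distance(a, b) == brute


class TestNwAlign:
    @pytest.mark.parametrize(
        "primer,text,score,end",
        [
            ("ACGT", "ACGTTTTT", 0, 4),
            ("ACGT", "AGTTTT", -1, 3),
            ("AAAA", "TTTT", -4, 0),  # 4 deletions tie 4 substitutions; earliest end wins
        ],
    )
    def test_examples(self, primer, text, score, end):
        got_score, got_end = nw_align(primer, text)
        assert got_score == score
        assert got_end == end

    @settings(derandomize=True, max_examples=200)
    @given(dna, dna)
    def test_score_is_minus_prefix_edit_distance(self, primer, text):
        score, end = nw_align(primer, text)
        assert score == -prefix_edit_distance(primer, text)
        # the reported end realises the reported score
        if end > 0:
            assert edlib.align(primer, text[:end], mode="NW")["editDistance"] == -score

    @settings(derandomize=True, max_examples=200)
    @given(dna, dna)
    def test_agrees_with_edlib_prefix_mode(self, primer, text):
        score, _ = nw_align(primer, text)
        assert -score == edlib.align(primer, text, mode="SHW")["editDistance"]


@pytest.fixture
def exact_read(small_panel):
    rng = random.Random(5)
    fwd = small_panel.primers[0].forward_seq
    return fwd + random_seq(rng, 130 - len(fwd)), fwd


class TestKmerModel:
    def test_exact_read_matches_at_zero(self, small_panel, small_index, match_params, exact_read):
        read, fwd = exact_read
        m = kmer_model_match(read, small_index, small_panel, match_params)
        assert m is not None
        assert (m.read_start, m.read_end, m.cost) == (0, len(fwd), 0)
        assert m.model is MatchModel.KMERS
        assert m.role is SeedRole.FORWARD_5P

    def test_junk_prefix_shifts_placement(self, small_panel, small_index, match_params):
        fwd = small_panel.primers[0].forward_seq
        read = "GG" + fwd + "TTTTACGGATTTCAGGACCA"
        m = kmer_model_match(read, small_index, small_panel, match_params)
        assert m is not None
        assert (m.read_start, m.read_end, m.cost) == (2, 2 + len(fwd), 0)
        # brute-force placement scan agrees that this is the only zero-cost placement
        zero_cost = [
            s
            for s in range(len(read) - len(fwd) + 1)
            if hamming_distance(fwd, read[s : s + len(fwd)]) == 0
        ]
        assert zero_cost == [2]

    def test_all_windows_errored_and_zero_allowance(self, small_panel, small_index):
        fwd = small_panel.primers[0].forward_seq
        # substitute every 8th base so every k=8 window holds >=1 error
        bases = list(fwd)
        for pos in range(0, len(fwd), 8):
            bases[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[bases[pos]]
        read = "".join(bases) + "ACGGATTTCAGGACCATTGG"
        params = MatchParams(k=8, max_mismatch=0)
        assert kmer_model_match(read, small_index, small_panel, params) is None

    def test_cost_equals_whole_primer_hamming(self, small_panel, small_index, match_params):
        fwd = small_panel.primers[0].forward_seq
        mutated = fwd[:10] + ("A" if fwd[10] != "A" else "C") + fwd[11:]
        read = mutated + "ACGGATTTCAGGACCATTGG"
        m = kmer_model_match(read, small_index, small_panel, match_params)
        assert m is not None
        assert m.cost == hamming_distance(fwd, read[: len(fwd)]) == 1


class TestDynamicModel:
    def test_deletion_matched_by_dynamic(self, small_panel, small_index, match_params):
        fwd = small_panel.primers[0].forward_seq
        deleted = fwd[:10] + fwd[11:]  # 1-bp deletion mid-primer
        read = deleted + "ACGGATTTCAGGACCATTGG"
        assert kmer_model_match(read, small_index, small_panel, match_params) is None
        m = dynamic_model_match(read, small_index, small_panel, match_params)
        assert m is not None
        assert m.model is MatchModel.DYNAMIC
        assert m.cost == 1
        assert m.read_end == len(deleted)

    def test_random_read_has_no_candidates(self, small_panel, small_index, match_params, rng):
        read = random_seq(rng, 150)
        assert dynamic_model_match(read, small_index, small_panel, match_params) is None

    def test_exact_primer_direct_invocation(self, small_panel, small_index, match_params):
        fwd = small_panel.primers[0].forward_seq
        read = fwd + "ACGGATTTCAGGACCATTGG"
        m = dynamic_model_match(read, small_index, small_panel, match_params)
        assert m is not None
        assert (m.cost, m.read_end) == (0, len(fwd))


class TestLocatePrimer:
    def test_prefers_kmers_model(self, small_panel, small_index, match_params, exact_read):
        read, _ = exact_read
        m = locate_primer(read, small_index, small_panel, match_params)
        assert m.model is MatchModel.KMERS

    def test_falls_back_to_dynamic_on_indel(self, small_panel, small_index, match_params):
        fwd = small_panel.primers[0].forward_seq
        read = fwd[:10] + fwd[11:] + "ACGGATTTCAGGACCATTGG"
        m = locate_primer(read, small_index, small_panel, match_params)
        assert m is not None and m.model is MatchModel.DYNAMIC

    def test_primer_free_read_unmatched(self, small_panel, small_index, match_params, rng):
        assert locate_primer(random_seq(rng, 150), small_index, small_panel, match_params) is None

    def test_match_count_monotone_in_allowance(self, small_panel, small_index, rng):
        """Raising the mismatch allowance never unmatches a read."""
        fwd = small_panel.primers[0].forward_seq
        reads = []
        for _ in range(40):
            bases = list(fwd)
            for pos in rng.sample(range(len(fwd)), rng.randint(0, 4)):
                bases[pos] = rng.choice([b for b in "ACGT" if b != bases[pos]])
            reads.append("".join(bases) + random_seq(rng, 120))
        counts = []
        for mm in range(0, 6):
            params = MatchParams(k=8, max_mismatch=mm)
            counts.append(
                sum(
                    locate_primer(r, small_index, small_panel, params) is not None
                    for r in reads
                )
            )
        assert counts == sorted(counts)
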