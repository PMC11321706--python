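import numpy as np
import pytest

from cdstore.channel import ChannelParams, simulate_counts_array
from cdstore.experiments import build_error_fixture
from cdstore.rscode import get_codec
from cdstore.softdecode import (
    BlockEvidence,
    SearchLimits,
    SoftDecodeResult,
    derrick_cp_decode,
    position_alternatives,
    rank_candidate_positions,
    validate_against_library,
)


def make_fixture(toy_code, seed, e):
    alphabet, library, spec, params = toy_code
    codec = get_codec(spec)
    rng = np.random.default_rng(seed)
    info = [int(x) for x in rng.integers(0, spec.field_order, spec.k_info)]
    truth = np.asarray(codec.encode(info), dtype=np.int64)
    counts, err_pos = build_error_fixture(truth, alphabet, library, params, e, rng)
    evidence = BlockEvidence.from_counts(counts, alphabet, params.p_error)
    return truth, counts, err_pos, evidence


def test_rank_positions_tie_break_on_index(toy_code):
    alphabet, _, _, _ = toy_code
    counts = np.tile([30, 0, 0, 0], (7, 1))
    ev = BlockEvidence.from_counts(counts, alphabet, 0.01)
    assert rank_candidate_positions(ev, 3) == [0, 1, 2]


def test_perturbed_position_ranks_first(toy_code):
    alphabet, _, _, _ = toy_code
    counts = np.tile([30, 0, 0, 0], (7, 1))
    counts[4] = [18, 12, 0, 0]
    ev = BlockEvidence.from_counts(counts, alphabet, 0.01)
    assert rank_candidate_positions(ev, 1)[0] == 4


def test_ranking_matches_sort_oracle(toy_code, rng):
    alphabet, _, _, params = toy_code
    symbols = rng.integers(0, len(alphabet), 7)
    counts = simulate_counts_array(symbols, alphabet, params, rng=rng)
    ev = BlockEvidence.from_counts(counts, alphabet, params.p_error)
    expected = sorted(range(7), key=lambda i: (-ev.distances[i], i))
    assert rank_candidate_positions(ev, 7) == expected
    with pytest.raises(ValueError):
        rank_candidate_positions(ev, 0)


def test_noiseless_block_decodes_without_soft_loop(toy_code):
    alphabet, library, spec, params = toy_code
    truth, counts, _, evidence = make_fixture(toy_code, seed=10, e=0)
    res = derrick_cp_decode(evidence, library, spec)
    assert res.status == "decoded"
    assert res.codeword == [int(s) for s in truth]
    assert res.substitutions == []
    assert not res.used_soft_search


def test_soft_never_degrades_hard(toy_code, rng):
    """Any hard-decodable block is returned identically, 0 substitutions."""
    alphabet, library, spec, params = toy_code
    codec = get_codec(spec)
    for seed in range(5):
        truth, counts, err_pos, evidence = make_fixture(toy_code, seed=seed, e=2)
        hard = codec.decode([int(s) for s in evidence.symbols])
        assert hard is not None  # 2 errors: inside the hard bound
        soft = derrick_cp_decode(evidence, library, spec)
        assert soft.status == "decoded"
        assert soft.codeword == hard[0] == [int(s) for s in truth]
        assert soft.substitutions == []


def test_three_errors_beyond_hard_bound_decoded(toy_code):
    """3 > t = 2 constructed errors: recovered via library-guided substitution."""
    alphabet, library, spec, _ = toy_code
    truth, _, err_pos, evidence = make_fixture(toy_code, seed=11, e=3)
    assert np.any(evidence.symbols[err_pos] != truth[err_pos])
    res = derrick_cp_decode(
        evidence, library, spec, SearchLimits(max_positions=7), validate_m=2
    )
    assert res.status == "decoded"
    assert res.codeword == [int(s) for s in truth]
    subs_pos = {p for p, _, _ in res.substitutions}
    assert subs_pos <= set(int(i) for i in err_pos)


def test_search_completeness_on_toy_code(toy_code):
    """Errors inside the candidate ranking with the truth in the alternative
    sets are always reachable: the true codeword is found once wrong valid
    codewords (which the tiny RS(7,3) space makes frequent) are excluded,
    mirroring the matrix-level retry loop."""
    alphabet, library, spec, _ = toy_code
    limits = SearchLimits(max_positions=7, max_iterations=10**6)
    for seed in (20, 21, 22, 23):
        for e in (3, 4):
            truth, _, _, evidence = make_fixture(toy_code, seed=seed, e=e)
            excluded = set()
            for _ in range(10):
                res = derrick_cp_decode(
                    evidence, library, spec, limits,
                    excluded=excluded, validate_m=2,
                )
                assert res.status == "decoded"
                if res.codeword == [int(s) for s in truth]:
                    break
                excluded.add(tuple(res.codeword))
                excluded |= res.excluded_solutions
            else:
                pytest.fail("true codeword never reached")


def test_iteration_budget_respected(toy_code):
    alphabet, library, spec, _ = toy_code
    truth, _, _, evidence = make_fixture(toy_code, seed=30, e=5)
    limits = SearchLimits(max_iterations=3)
    res = derrick_cp_decode(evidence, library, spec, limits)
    assert res.iterations_used <= 3
    if res.status == "exhausted":
        assert res.codeword is None


def test_validation_accepts_identity(toy_code):
    alphabet, library, spec, _ = toy_code
    truth, _, _, evidence = make_fixture(toy_code, seed=10, e=0)
    res = derrick_cp_decode(evidence, library, spec)
    assert validate_against_library(res, evidence, library, 2)
    with pytest.raises(ValueError):
        bad = SoftDecodeResult("exhausted", None, [], 1, False)
        validate_against_library(bad, evidence, library, 2)


def test_miscorrection_detected_and_retried(toy_code):
    """A 3-error pattern that hard-decodes to a wrong codeword: the
    membership check rejects it, and exclusion-and-retry (the decoder-error
    handling loop) restores the true codeword."""
    alphabet, library, spec, _ = toy_code
    from cdstore.softdecode import decode_block_validated

    codec = get_codec(spec)
    truth, _, _, evidence = make_fixture(toy_code, seed=2, e=3)
    hard = codec.decode([int(s) for s in evidence.symbols])
    assert hard is not None and hard[0] != [int(s) for s in truth]  # miscorrection
    wrong = SoftDecodeResult("decoded", hard[0], [], 1, False)
    assert not validate_against_library(wrong, evidence, library, 2)
    # the wrong-but-valid codewords of the tiny RS(7,3) space are pruned by
    # successive exclusion, exactly as a CRC failure would drive it
    excluded = set()
    limits = SearchLimits(max_positions=7, max_block_passes=8)
    for _ in range(10):
        res = decode_block_validated(evidence, library, spec, limits, excluded)
        assert res.status == "decoded"
        if res.codeword == [int(s) for s in truth]:
            break
        excluded |= res.excluded_solutions
        excluded.add(tuple(res.codeword))
    else:
        pytest.fail("true codeword never restored")


def test_excluded_solution_is_skipped(toy_code):
    alphabet, library, spec, _ = toy_code
    truth, _, _, evidence = make_fixture(toy_code, seed=10, e=0)
    first = derrick_cp_decode(evidence, library, spec)
    res = derrick_cp_decode(
        evidence, library, spec, excluded={tuple(first.codeword)}
    )
    assert res.codeword != first.codeword


def test_alternative_sets_rank_truth_first_near_boundary(toy_code):
    alphabet, library, spec, _ = toy_code
    truth, _, err_pos, evidence = make_fixture(toy_code, seed=11, e=3)
    alts = position_alternatives(evidence, library, 2)
    for pos in err_pos:
        assert int(truth[pos]) in [a for a, _ in alts[int(pos)]]
    # scores are sorted descending
    for row in alts:
        scores = [s for _, s in row]
        assert scores == sorted(scores, reverse=True)


def test_evidence_length_must_match_block(toy_code):
    alphabet, library, spec, params = toy_code
    counts = np.tile([30, 0, 0, 0], (6, 1))
    ev = BlockEvidence.from_counts(counts, alphabet, 0.01)
    with pytest.raises(ValueError):
        derrick_cp_decode(ev, library, spec)
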