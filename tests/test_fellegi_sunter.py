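import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from securelink import fellegi_sunter as fs
from securelink import synthdata
from tests.conftest import simulate_pattern_counts

FIELDS = ("family_name", "first_name", "birth_date")


# --- agreement patterns ------------------------------------------------------

def test_agreement_pattern_worked_pair():
    a = {"family_name": "Dupont", "first_name": "François", "birth_date": "29/01/1940"}
    b = {"family_name": "Dupont", "first_name": "François", "birth_date": "29/03/1940"}
    assert fs.agreement_pattern(a, b, FIELDS) == (1, 1, 0)
    assert fs.agreement_pattern(a, a, FIELDS) == (1, 1, 1)


def test_agreement_pattern_identical_on_hashed_values():
    # comparison is plain equality, so hashed variants give the same pattern
    from securelink.pseudonymize import HashKey, hash_value
    k = HashKey.from_text("k", "s")
    a = {"family_name": "Dupont", "first_name": "François", "birth_date": "29/01/1940"}
    b = {"family_name": "Dupont", "first_name": "François", "birth_date": "29/03/1940"}
    ha = {f: hash_value(str(v), k).hex for f, v in a.items()}
    hb = {f: hash_value(str(v), k).hex for f, v in b.items()}
    assert fs.agreement_pattern(ha, hb, FIELDS) == fs.agreement_pattern(a, b, FIELDS)


def test_agreement_pattern_missing_field_handling():
    a = {"family_name": "Dupont", "first_name": "", "birth_date": None}
    b = {"family_name": "Dupont", "first_name": "Jean", "birth_date": "29/01/1940"}
    assert fs.agreement_pattern(a, b, FIELDS) == (1, None, None)
    assert fs.agreement_pattern(a, b, FIELDS, missing_is_disagreement=True) == (1, 0, 0)


def test_agreement_pattern_absent_field_is_config_error():
    with pytest.raises(fs.LinkageConfigError):
        fs.agreement_pattern({"x": 1}, {"x": 1}, ("x", "y"))


# --- weights -----------------------------------------------------------------

def test_unit_weights_symmetric_case_and_base2():
    params = fs.FSParameters(m=(0.5, 0.9), u=(0.5, 0.1), p=0.1)
    wt = fs.unit_weights(params, log_base=2)
    assert wt.agree[0] == pytest.approx(0.0)
    assert wt.disagree[0] == pytest.approx(0.0)
    # oracle: log2(9) = 3.1699...
    assert wt.agree[1] == pytest.approx(math.log2(9))
    assert wt.disagree[1] == pytest.approx(-math.log2(9))


def test_unit_weight_signs_when_m_exceeds_u():
    params = fs.FSParameters(m=(0.95, 0.8), u=(0.05, 0.3), p=0.02)
    wt = fs.unit_weights(params)
    assert all(w > 0 for w in wt.agree)
    assert all(w < 0 for w in wt.disagree)


def test_agree_weight_monotone_in_m():
    last = -np.inf
    for m in (0.5, 0.7, 0.9, 0.99):
        w = fs.unit_weights(fs.FSParameters(m=(m,), u=(0.1,), p=0.1)).agree[0]
        assert w > last
        last = w


@pytest.mark.parametrize("pattern, expected", [
    ((1, 1, 1), 24.4),
    ((0, 1, 1), 13.2),
    ((1, 1, 0), 11.0),
    ((0, 0, 0), -9.4),
])
def test_compound_weight_published_configurations(pattern, expected, published_weights):
    assert fs.compound_weight(pattern, published_weights) == pytest.approx(expected)


def test_compound_weight_skips_missing_and_checks_length(published_weights):
    assert fs.compound_weight((1, None, 0), published_weights) == pytest.approx(8.4 - 3.1)
    with pytest.raises(fs.LinkageConfigError):
        fs.compound_weight((1, 1), published_weights)


@settings(derandomize=True, max_examples=100)
@given(bits=st.lists(st.sampled_from([0, 1]), min_size=3, max_size=3))
def test_compound_weight_is_additive(bits):
    wt = fs.UnitWeightTable.from_values((8.4, 5.7, 10.3), (-2.8, -3.5, -3.1))
    manual = sum(wt.agree[i] if b else wt.disagree[i] for i, b in enumerate(bits))
    assert fs.compound_weight(tuple(bits), wt) == pytest.approx(manual)


# --- classification ----------------------------------------------------------

@pytest.mark.parametrize("weight, expected", [
    (24.4, "matched"),
    (-9.4, "unmatched"),
    (13.0, "indecision"),
    (15.0, "matched"),     # tie on the upper threshold goes up
    (12.0, "indecision"),  # tie on the lower threshold goes up
    (11.999, "unmatched"),
])
def test_classify_with_boundary_rule(weight, expected):
    assert fs.classify(weight, lower=12, upper=15) == expected


def test_classify_rejects_inverted_thresholds():
    with pytest.raises(fs.LinkageConfigError):
        fs.classify(0, lower=5, upper=1)


# --- EM ----------------------------------------------------------------------

def test_em_recovers_generating_parameters_small():
    m, u, p = (0.95, 0.9, 0.98), (0.05, 0.1, 0.01), 0.05
    counts = simulate_pattern_counts(m, u, p, 200_000, seed=7)
    fit = fs.em_fit(counts)
    assert fit.converged
    assert max(abs(a - b) for a, b in zip(fit.m, m)) < 0.03
    assert max(abs(a - b) for a, b in zip(fit.u, u)) < 0.03
    assert abs(fit.p - p) < 0.02


def test_em_loglik_ascends_every_iteration():
    counts = simulate_pattern_counts((0.9, 0.85), (0.2, 0.1), 0.1, 50_000, seed=3)
    fit = fs.em_fit(counts)
    diffs = np.diff(fit.loglik)
    assert (diffs >= -1e-8).all()


def test_em_infinite_tol_returns_init():
    counts = {(1, 1): 50, (0, 0): 950}
    init = fs.FSParameters(m=(0.8, 0.8), u=(0.2, 0.2), p=0.05)
    fit = fs.em_fit(counts, init=init, tol=float("inf"))
    assert fit.m == init.m and fit.u == init.u and fit.p == init.p
    assert fit.converged


def test_em_canonicalizes_label_switching():
    # initialize with the classes swapped; the fit must come back with m > u
    counts = simulate_pattern_counts((0.95, 0.9), (0.05, 0.1), 0.1, 100_000, seed=5)
    swapped = fs.FSParameters(m=(0.1, 0.1), u=(0.9, 0.9), p=0.9)
    fit = fs.em_fit(counts, init=swapped)
    assert all(mi > ui for mi, ui in zip(fit.m, fit.u))


def test_em_single_field_matches_grid_search_oracle():
    # counts exactly at the mixture proportions of (m,u,p)=(0.8,0.2,0.3)
    counts = {(1,): 380, (0,): 620}
    fit = fs.em_fit(counts)
    grid = np.linspace(0.025, 0.975, 20)
    best = -np.inf
    for mm in grid:
        for uu in grid:
            for pp in grid:
                p1 = pp * mm + (1 - pp) * uu
                best = max(best, 380 * np.log(p1) + 620 * np.log(1 - p1))
    assert fit.loglik[-1] >= best - 1e-9
    # analytic supremum of the (non-identifiable) one-field mixture
    analytic = 380 * np.log(0.38) + 620 * np.log(0.62)
    assert fit.loglik[-1] == pytest.approx(analytic, abs=1e-6)


def test_em_degenerate_inputs_rejected():
    with pytest.raises(fs.EstimationError):
        fs.em_fit({(1, 1): 100})
    with pytest.raises(fs.EstimationError):
        fs.em_fit({(1, 1): 100, (0, 0): 0})


def test_em_nonconvergence_flagged_not_raised():
    counts = simulate_pattern_counts((0.9, 0.8), (0.1, 0.2), 0.1, 10_000, seed=9)
    fit = fs.em_fit(counts, tol=0.0, max_iter=3)
    assert not fit.converged
    assert fit.n_iter == 3


# --- diagnostics -------------------------------------------------------------

def test_pattern_diagnostics_posteriors(published_weights):
    params = fs.FSParameters(m=(0.95, 0.9, 0.98), u=(0.05, 0.1, 0.01), p=0.01)
    counts = simulate_pattern_counts(params.m, params.u, params.p, 100_000, seed=13)
    diag = fs.pattern_diagnostics(counts, params)
    assert np.allclose(diag["p_match"] + diag["p_unmatch"], 1.0)
    # monotonicity oracle: direct Bayes computation over all patterns,
    # sorted by compound weight
    assert (np.diff(diag.sort_values("weight")["p_match"]) >= -1e-12).all()
    # weight column consistent with compound_weight
    wt = fs.unit_weights(params)
    for _, row in diag.iterrows():
        pat = tuple(int(c) for c in row["pattern"])
        assert row["weight"] == pytest.approx(fs.compound_weight(pat, wt))


def test_thresholds_from_posteriors():
    params = fs.FSParameters(m=(0.95, 0.9, 0.98), u=(0.05, 0.1, 0.01), p=0.01)
    counts = simulate_pattern_counts(params.m, params.u, params.p, 100_000, seed=13)
    diag = fs.pattern_diagnostics(counts, params)
    lower, upper = fs.thresholds_from_posteriors(diag, 0.9, 0.9)
    assert lower <= upper
    sure_match = diag.loc[diag["weight"] >= upper, "p_match"]
    assert (sure_match >= 0.9).all()


# --- blocking and deterministic linkage --------------------------------------

def _files_with_ids(n, seed):
    pop = synthdata.generate_population(n, seed=seed)
    a, b, truth = synthdata.make_producer_files(
        pop, synthdata.ErrorConfig(overlap=0.5), seed=seed)
    a["birth_year"] = a["birth_date"].str[-4:]
    b["birth_year"] = b["birth_date"].str[-4:]
    return a, b, truth


def test_block_pairs_single_shared_value_is_cartesian():
    a = pd.DataFrame({"seq": [1, 2], "sex": [1, 1]})
    b = pd.DataFrame({"seq": [1, 2, 3], "sex": [1, 1, 1]})
    pairs = fs.block_pairs(a, b, [["sex"]])
    assert len(pairs) == 6


def test_block_pairs_union_monotone():
    a, b, _ = _files_with_ids(80, 21)
    one = fs.block_pairs(a, b, [["sex"]])
    two = fs.block_pairs(a, b, [["sex"], ["birth_year"]])
    set_one = set(map(tuple, one.to_numpy()))
    set_two = set(map(tuple, two.to_numpy()))
    assert set_one <= set_two
    assert not two.duplicated().any()


def test_block_pairs_matches_exhaustive_enumeration():
    a, b, _ = _files_with_ids(60, 22)
    pairs = fs.block_pairs(a, b, [["birth_year"]])
    # oracle: brute-force filter over the full cartesian product
    oracle = {(ra["seq"], rb["seq"])
              for _, ra in a.iterrows() for _, rb in b.iterrows()
              if ra["birth_year"] == rb["birth_year"]}
    assert set(map(tuple, pairs.to_numpy())) == oracle


def test_block_pairs_empty_plan_warns_above_cap():
    a = pd.DataFrame({"seq": range(30)})
    b = pd.DataFrame({"seq": range(30)})
    with pytest.warns(UserWarning, match="cartesian"):
        pairs = fs.block_pairs(a, b, [], pair_cap=100)
    assert len(pairs) == 900


def test_deterministic_link_basic_cases():
    a = pd.DataFrame({"seq": [1, 2, 3], "nir": ["x", "y", "z"]})
    b = pd.DataFrame({"seq": [10, 11], "nir": ["q", "r"]})
    assert fs.deterministic_link(a, b, "nir").empty

    b2 = pd.DataFrame({"seq": [10], "nir": ["y"]})
    link = fs.deterministic_link(a, b2, "nir")
    assert link.to_dict("records") == [{"id_a": 2, "id_b": 10, "multi": False}]

    a2 = pd.DataFrame({"seq": [1, 2], "nir": ["y", "y"]})
    link2 = fs.deterministic_link(a2, b2, "nir")
    assert len(link2) == 2
    assert link2["multi"].all()


def test_deterministic_link_contained_in_block_pairs():
    a, b, _ = _files_with_ids(60, 23)
    det = fs.deterministic_link(a, b, "nir")
    blocked = fs.block_pairs(a, b, [["nir"]])
    det_pairs = set(zip(det["id_a"], det["id_b"]))
    block_set = set(map(tuple, blocked.to_numpy()))
    assert det_pairs <= block_set


# --- full pipeline -----------------------------------------------------------

def test_probabilistic_link_error_free_files(clean_files):
    file_a, file_b, truth = clean_files
    cfg = fs.LinkageConfig(
        compare_fields=("family_name", "first_name", "birth_date", "nir"),
        blocking_plan=(("sex",),), lower=0.0, upper=5.0)
    result = fs.probabilistic_link(file_a, file_b, cfg)
    matched = result.decisions[result.decisions["category"] == "matched"]
    assert set(zip(matched["id_a"], matched["id_b"])) == \
        set(zip(truth["seq_a"], truth["seq_b"]))


def test_probabilistic_link_replay_published_weights(published_weights):
    # fixed weights, EM skipped: compound weights reproduce the published sums
    a = pd.DataFrame({"seq": [1], "family_name": ["Dupont"],
                      "first_name": ["François"], "birth_date": ["29/01/1940"]})
    b = pd.DataFrame({"seq": [1, 2], "family_name": ["Dupont", "Dupont"],
                      "first_name": ["François", "François"],
                      "birth_date": ["29/01/1940", "29/03/1940"]})
    cfg = fs.LinkageConfig(compare_fields=FIELDS, blocking_plan=(("family_name",),),
                           lower=12, upper=15, fixed_weights=published_weights)
    result = fs.probabilistic_link(a, b, cfg)
    by_pair = result.decisions.set_index(["id_a", "id_b"])
    assert by_pair.loc[(1, 1), "compound_weight"] == pytest.approx(24.4)
    assert by_pair.loc[(1, 2), "compound_weight"] == pytest.approx(11.0)
    assert by_pair.loc[(1, 1), "category"] == "matched"
    assert by_pair.loc[(1, 2), "category"] == "unmatched"
    assert result.params is None


def test_probabilistic_link_empty_files():
    empty = pd.DataFrame(columns=["seq", "family_name", "first_name", "birth_date"])
    cfg = fs.LinkageConfig(compare_fields=FIELDS, blocking_plan=())
    result = fs.probabilistic_link(empty, empty, cfg)
    assert result.decisions.empty


def test_probabilistic_link_decisions_sorted_lexicographically(clean_files):
    file_a, file_b, _ = clean_files
    cfg = fs.LinkageConfig(
        compare_fields=("family_name", "first_name", "birth_date", "nir"),
        blocking_plan=(("sex",),), lower=0.0, upper=5.0)
    dec = fs.probabilistic_link(file_a, file_b, cfg).decisions
    keys = list(zip(dec["id_a"], dec["id_b"]))
    assert keys == sorted(keys)
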