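"""Fellegi–Sunter probabilistic record linkage, plus deterministic linkage
and blocking.

The model
---------

Record pairs drawn from two files split into two latent classes: M, the
pairs whose records belong to the same individual, and U, the pairs whose
records belong to different individuals. For each comparison field *i* two
probabilities govern agreement:

* ``m_i`` — probability that the field agrees given the pair is in M;
* ``u_i`` — probability that the field agrees given the pair is in U.

A field that agrees contributes the unit weight ``log(m_i / u_i)``
(positive when ``m_i > u_i``); a field that disagrees contributes
``log((1 - m_i) / (1 - u_i))`` (negative). Because unit weights are log
likelihood ratios under conditional independence given the class, they sum
across fields into a *compound weight* — the linkage decision statistic.
Two thresholds partition the compound-weight axis into "unmatched",
"indecision" and "matched" zones.

``m_i``, ``u_i`` and the match-class proportion ``p`` are unknown in
practice and are estimated from the observed agreement-pattern counts by
the EM algorithm for a two-class latent model with conditionally
independent binary indicators.

Comparison is binary equality per field, which works identically on
cleartext and on (keyed-)hashed values — the property that makes the
method usable on pseudonymized files, where edit distances are
unavailable.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FSParameters",
    "UnitWeightTable",
    "LinkageConfig",
    "LinkageResult",
    "EstimationError",
    "LinkageConfigError",
    "MATCHED",
    "INDECISION",
    "UNMATCHED",
    "agreement_pattern",
    "unit_weights",
    "compound_weight",
    "classify",
    "em_fit",
    "pattern_diagnostics",
    "thresholds_from_posteriors",
    "block_pairs",
    "deterministic_link",
    "probabilistic_link",
]

MATCHED = "matched"
INDECISION = "indecision"
UNMATCHED = "unmatched"

_CLAMP = 1e-6  # keeps every unit weight finite


class EstimationError(ValueError):
    """EM cannot be run on the supplied pattern counts."""


class LinkageConfigError(ValueError):
    """Invalid linkage configuration (thresholds, fields, weights)."""


# --- parameters and weights --------------------------------------------------

@dataclass(frozen=True)
class FSParameters:
    """Per-field match/unmatch agreement probabilities and class proportion.

    ``m[i] > u[i]`` must hold after a converged fit — agreement is more
    likely among true matches; a violation on most fields indicates label
    switching, which :func:`em_fit` canonicalizes away.
    """

    m: tuple[float, ...]
    u: tuple[float, ...]
    p: float
    converged: bool = True
    n_iter: int = 0
    loglik: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not (len(self.m) == len(self.u) >= 1):
            raise EstimationError("m and u must be non-empty and equal length")
        probs = (*self.m, *self.u, self.p)
        if not all(0.0 < x < 1.0 for x in probs):
            raise EstimationError("all probabilities must lie strictly inside (0, 1)")

    @property
    def k(self) -> int:
        return len(self.m)


@dataclass(frozen=True)
class UnitWeightTable:
    """Per-field agreement and disagreement weights, in log units."""

    agree: tuple[float, ...]
    disagree: tuple[float, ...]
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if len(self.agree) != len(self.disagree):
            raise LinkageConfigError("agree/disagree weight vectors differ in length")

    @property
    def k(self) -> int:
        return len(self.agree)

    @classmethod
    def from_values(cls, agree: Sequence[float], disagree: Sequence[float],
                    log_base: float = 2.0) -> "UnitWeightTable":
        """Build a table from externally supplied weights (e.g. a published fit)."""
        return cls(tuple(agree), tuple(disagree), log_base)


def unit_weights(params: FSParameters, log_base: float = 2.0) -> UnitWeightTable:
    """Unit weights ``log(m/u)`` (agreement) and ``log((1-m)/(1-u))`` (disagreement).

    Base 2 is the record-linkage convention; any base > 1 only rescales every
    weight by a common factor and leaves the classification unchanged as long
    as thresholds are expressed in the same base.
    """
    if log_base <= 1.0:
        raise LinkageConfigError("log base must be > 1")
    m = np.asarray(params.m)
    u = np.asarray(params.u)
    if np.any(m <= _CLAMP / 2) or np.any(m >= 1 - _CLAMP / 2) or \
       np.any(u <= _CLAMP / 2) or np.any(u >= 1 - _CLAMP / 2):
        raise EstimationError("probability at the clamping boundary; weights unreliable")
    scale = np.log(log_base)
    agree = np.log(m / u) / scale
    disagree = np.log((1 - m) / (1 - u)) / scale
    return UnitWeightTable(tuple(agree.tolist()), tuple(disagree.tolist()), log_base)


# --- patterns and weights per pair -------------------------------------------

def agreement_pattern(rec_a: Mapping[str, object], rec_b: Mapping[str, object],
                      fields: Sequence[str], *,
                      missing_is_disagreement: bool = False) -> tuple[int | None, ...]:
    """Binary agreement vector over the comparison fields for one record pair.

    Bit i is 1 iff the two field values are identical — which applies
    unchanged to hashed values, equal fingerprints standing in for equal
    cleartext. A missing value on either side yields ``None`` for that field
    (contributing weight 0 downstream) unless ``missing_is_disagreement``.
    """
    bits: list[int | None] = []
    for f in fields:
        if f not in rec_a or f not in rec_b:
            raise LinkageConfigError(f"comparison field {f!r} absent from record schema")
        va, vb = rec_a[f], rec_b[f]
        if _is_missing(va) or _is_missing(vb):
            bits.append(0 if missing_is_disagreement else None)
        else:
            bits.append(1 if va == vb else 0)
    return tuple(bits)


def _is_missing(v: object) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and np.isnan(v):
        return True
    return isinstance(v, str) and v == ""


def compound_weight(pattern: Sequence[int | None], weights: UnitWeightTable) -> float:
    """Sum of per-field unit weights selected by the agreement pattern."""
    if len(pattern) != weights.k:
        raise LinkageConfigError(
            f"pattern length {len(pattern)} != weight table length {weights.k}")
    total = 0.0
    for bit, aw, dw in zip(pattern, weights.agree, weights.disagree):
        if bit is None:
            continue
        total += aw if bit else dw
    return total


def classify(weight: float, lower: float, upper: float) -> str:
    """Three-way linkage decision from the compound weight.

    ``weight >= upper`` → matched; ``weight >= lower`` → indecision;
    below ``lower`` → unmatched. A weight exactly on a threshold goes to
    the higher category.
    """
    if lower > upper:
        raise LinkageConfigError(f"lower threshold {lower} exceeds upper {upper}")
    if weight >= upper:
        return MATCHED
    if weight >= lower:
        return INDECISION
    return UNMATCHED


# --- EM estimation -----------------------------------------------------------

def _pattern_matrix(pattern_counts: Mapping[tuple, int]):
    pats = sorted(pattern_counts, key=lambda t: tuple(-1 if b is None else b for b in t))
    k = len(pats[0])
    if any(len(p) != k for p in pats):
        raise EstimationError("patterns of unequal length")
    gamma = np.array([[0 if b is None else b for b in p] for p in pats], dtype=float)
    obs = np.array([[b is not None for b in p] for p in pats], dtype=float)
    n = np.array([pattern_counts[p] for p in pats], dtype=float)
    return pats, gamma, obs, n


def _class_loglik(gamma: np.ndarray, obs: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """log P(pattern | class) per pattern, skipping unobserved fields."""
    return (obs * (gamma * np.log(probs) + (1 - gamma) * np.log(1 - probs))).sum(axis=1)


def _loglik(gamma, obs, n, m, u, p) -> float:
    la = _class_loglik(gamma, obs, m)
    lb = _class_loglik(gamma, obs, u)
    mix = np.logaddexp(np.log(p) + la, np.log(1 - p) + lb)
    return float((n * mix).sum())


def em_fit(pattern_counts: Mapping[tuple, int],
           init: FSParameters | None = None,
           tol: float = 1e-6,
           max_iter: int = 500) -> FSParameters:
    """Fit (m, u, p) to agreement-pattern counts by EM.

    Two-class latent mixture with conditionally independent binary
    indicators. The E-step computes each pattern's posterior probability of
    belonging to the match class from the current parameters; the M-step
    re-estimates ``p`` as the posterior-weighted match fraction and each
    ``m_i`` / ``u_i`` as the posterior-weighted agreement rate within its
    class. Probabilities are clamped to ``[1e-6, 1 - 1e-6]`` every M-step so
    that unit weights stay finite.

    Iteration stops when a full E+M cycle improves the observed-data
    log-likelihood by less than ``tol`` (the pre-cycle parameters are
    returned, so ``tol = inf`` returns the initialization after one cycle)
    or when ``max_iter`` cycles have run, in which case the result carries
    ``converged=False`` rather than raising.

    If most fields end with ``m_i < u_i`` the two classes have swapped
    labels (the likelihood is symmetric under (m, u, p) → (u, m, 1-p));
    the result is canonicalized so the match class is the high-agreement one.
    """
    counts = {p: c for p, c in pattern_counts.items() if c > 0}
    if len(counts) < 2:
        raise EstimationError("need at least 2 distinct patterns with positive counts")
    pats, gamma, obs, n = _pattern_matrix(counts)
    k = gamma.shape[1]

    if init is None:
        init = FSParameters(m=(0.9,) * k, u=(0.1,) * k, p=0.01)
    if init.k != k:
        raise EstimationError(f"init has {init.k} fields, patterns have {k}")

    m = np.asarray(init.m, dtype=float)
    u = np.asarray(init.u, dtype=float)
    p = float(init.p)
    trace = [_loglik(gamma, obs, n, m, u, p)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: posterior match probability per pattern
        la = np.log(p) + _class_loglik(gamma, obs, m)
        lb = np.log(1 - p) + _class_loglik(gamma, obs, u)
        g = np.exp(la - np.logaddexp(la, lb))
        # M-step
        wm = n * g
        wu = n * (1 - g)
        p_new = float(wm.sum() / n.sum())
        m_new = (wm[:, None] * gamma * obs).sum(axis=0) / (wm[:, None] * obs).sum(axis=0)
        u_new = (wu[:, None] * gamma * obs).sum(axis=0) / (wu[:, None] * obs).sum(axis=0)
        m_new = np.clip(m_new, _CLAMP, 1 - _CLAMP)
        u_new = np.clip(u_new, _CLAMP, 1 - _CLAMP)
        p_new = float(np.clip(p_new, _CLAMP, 1 - _CLAMP))
        ll = _loglik(gamma, obs, n, m_new, u_new, p_new)
        if ll - trace[-1] < tol:
            converged = True
            break
        m, u, p = m_new, u_new, p_new
        trace.append(ll)

    if (m < u).sum() > k / 2:  # label switching: swap classes
        m, u, p = u, m, 1 - p
    return FSParameters(m=tuple(m.tolist()), u=tuple(u.tolist()), p=p,
                        converged=converged, n_iter=it, loglik=tuple(trace))


def pattern_diagnostics(pattern_counts: Mapping[tuple, int],
                        params: FSParameters,
                        log_base: float = 2.0,
                        weights: UnitWeightTable | None = None) -> pd.DataFrame:
    """Per-pattern diagnostics table: count, compound weight and posteriors.

    One row per observed pattern, sorted by compound weight, with
    ``P(match | pattern)`` and its complement computed by Bayes' rule from
    the fitted parameters. This is the table threshold choice is based on.
    """
    if weights is None:
        weights = unit_weights(params, log_base)
    pats, gamma, obs, n = _pattern_matrix(dict(pattern_counts))
    m = np.asarray(params.m)
    u = np.asarray(params.u)
    la = np.log(params.p) + _class_loglik(gamma, obs, m)
    lb = np.log(1 - params.p) + _class_loglik(gamma, obs, u)
    post_m = np.exp(la - np.logaddexp(la, lb))
    rows = []
    for i, pat in enumerate(pats):
        rows.append({
            "pattern": "".join("?" if b is None else str(b) for b in pat),
            "count": int(n[i]),
            "weight": compound_weight(pat, weights),
            "p_match": float(post_m[i]),
            "p_unmatch": float(1 - post_m[i]),
        })
    return (pd.DataFrame(rows)
            .sort_values("weight", kind="stable")
            .reset_index(drop=True))


def thresholds_from_posteriors(diagnostics: pd.DataFrame,
                               p_match_min: float = 0.95,
                               p_unmatch_min: float = 0.95) -> tuple[float, float]:
    """Derive (lower, upper) thresholds from target posterior probabilities.

    ``upper`` is the smallest observed compound weight whose pattern has
    ``P(match) >= p_match_min``; ``lower`` is the smallest weight whose
    pattern fails ``P(unmatch) >= p_unmatch_min`` (i.e. the bottom of the
    zone where "unmatched" can no longer be declared with confidence).
    """
    d = diagnostics.sort_values("weight")
    upper_cand = d.loc[d["p_match"] >= p_match_min, "weight"]
    lower_cand = d.loc[d["p_unmatch"] < p_unmatch_min, "weight"]
    if upper_cand.empty:
        raise EstimationError(f"no pattern reaches P(match) >= {p_match_min}")
    upper = float(upper_cand.min())
    lower = float(lower_cand.min()) if not lower_cand.empty else upper
    return min(lower, upper), upper


# --- candidate generation ----------------------------------------------------

def block_pairs(file_a: pd.DataFrame, file_b: pd.DataFrame,
                plan: Sequence[Sequence[str]],
                id_a: str = "seq", id_b: str = "seq",
                pair_cap: int = 10_000_000) -> pd.DataFrame:
    """Candidate record pairs from successive blocking passes.

    Each pass is a set of blocking fields; it contributes every cross-file
    pair agreeing *exactly* on all of the pass's fields. Passes are
    unioned (deduplicated), so adding a pass can only add candidates —
    running a second pass on, say, birth year recovers true pairs that a
    first pass on an unreliable sex field missed. An empty plan degenerates
    to the full cartesian product, with a warning once it exceeds
    ``pair_cap``.

    Returns a DataFrame with columns ``id_a``/``id_b`` (the neutral
    identifiers), sorted lexicographically for reproducibility.
    """
    out_frames = []
    if not list(plan):
        total = len(file_a) * len(file_b)
        if total > pair_cap:
            warnings.warn(
                f"empty blocking plan: full cartesian product of {total} pairs "
                f"exceeds the cap of {pair_cap}", stacklevel=2)
        pairs = file_a[[id_a]].rename(columns={id_a: "id_a"}).merge(
            file_b[[id_b]].rename(columns={id_b: "id_b"}), how="cross")
        out_frames.append(pairs)
    for pass_fields in plan:
        pass_fields = list(pass_fields)
        for f in pass_fields:
            if f not in file_a.columns or f not in file_b.columns:
                raise LinkageConfigError(f"blocking field {f!r} missing from a file")
        left = file_a[[id_a] + pass_fields].rename(columns={id_a: "id_a"}).dropna(
            subset=pass_fields)
        right = file_b[[id_b] + pass_fields].rename(columns={id_b: "id_b"}).dropna(
            subset=pass_fields)
        merged = left.merge(right, on=pass_fields)[["id_a", "id_b"]]
        out_frames.append(merged)
    if not out_frames:
        return pd.DataFrame(columns=["id_a", "id_b"])
    pairs = pd.concat(out_frames, ignore_index=True).drop_duplicates()
    return pairs.sort_values(["id_a", "id_b"], kind="stable").reset_index(drop=True)


def deterministic_link(file_a: pd.DataFrame, file_b: pd.DataFrame,
                       id_field: str,
                       id_a: str = "seq", id_b: str = "seq") -> pd.DataFrame:
    """Strict deterministic linkage: equality join on one identifier field.

    The classical case is a join on a (doubly hashed) national identifier —
    the hashed values of the same person under the same keys are equal, so
    an ordinary equality join links the files. Pairs whose identifier value
    occurs more than once in either file are kept and flagged
    (``multi=True``) rather than resolved.
    """
    left = file_a[[id_a, id_field]].rename(columns={id_a: "id_a"}).dropna(subset=[id_field])
    right = file_b[[id_b, id_field]].rename(columns={id_b: "id_b"}).dropna(subset=[id_field])
    merged = left.merge(right, on=id_field)
    if merged.empty:
        return pd.DataFrame(columns=["id_a", "id_b", "multi"])
    sizes = merged.groupby(id_field)["id_a"].transform("size")
    merged["multi"] = sizes > 1
    return (merged[["id_a", "id_b", "multi"]]
            .sort_values(["id_a", "id_b"], kind="stable")
            .reset_index(drop=True))


# --- full probabilistic pipeline ---------------------------------------------

@dataclass(frozen=True)
class LinkageConfig:
    """Configuration of a probabilistic linkage run."""

    compare_fields: tuple[str, ...]
    blocking_plan: tuple[tuple[str, ...], ...] = ()
    lower: float = 0.0
    upper: float = 0.0
    log_base: float = 2.0
    fixed_weights: UnitWeightTable | None = None  # skip EM, replay given weights
    em_init: FSParameters | None = None
    em_tol: float = 1e-6
    em_max_iter: int = 500
    missing_is_disagreement: bool = False
    id_a: str = "seq"
    id_b: str = "seq"

    def __post_init__(self) -> None:
        if not self.compare_fields:
            raise LinkageConfigError("at least one comparison field is required")
        if self.lower > self.upper:
            raise LinkageConfigError("lower threshold exceeds upper threshold")


@dataclass
class LinkageResult:
    decisions: pd.DataFrame      # id_a, id_b, pattern, compound_weight, category
    diagnostics: pd.DataFrame    # pattern, count, weight, p_match, p_unmatch
    params: FSParameters | None  # None when fixed weights were replayed
    weights: UnitWeightTable
    converged: bool


def _pair_patterns(file_a: pd.DataFrame, file_b: pd.DataFrame,
                   pairs: pd.DataFrame, cfg: LinkageConfig) -> np.ndarray:
    """Agreement matrix (n_pairs × k) with -1 encoding 'missing'."""
    fields = list(cfg.compare_fields)
    a = file_a.set_index(cfg.id_a).loc[pairs["id_a"], fields].to_numpy()
    b = file_b.set_index(cfg.id_b).loc[pairs["id_b"], fields].to_numpy()
    missing_a = pd.isna(a) | (a == "")
    missing_b = pd.isna(b) | (b == "")
    agree = (a == b).astype(int)
    missing = missing_a | missing_b
    if cfg.missing_is_disagreement:
        agree[missing] = 0
    else:
        agree[missing] = -1
    return agree


def probabilistic_link(file_a: pd.DataFrame, file_b: pd.DataFrame,
                       config: LinkageConfig) -> LinkageResult:
    """Run the full probabilistic pipeline on two record files.

    Stages: blocking → per-pair agreement patterns → EM fit on the pattern
    counts (or replay of externally supplied unit weights) → compound
    weights → dual-threshold classification. Returns per-pair decisions
    plus the per-pattern diagnostics table; EM non-convergence is carried
    as a flag, never an exception.
    """
    for f in config.compare_fields:
        if f not in file_a.columns or f not in file_b.columns:
            raise LinkageConfigError(f"comparison field {f!r} missing from a file")
    pairs = block_pairs(file_a, file_b, config.blocking_plan,
                        id_a=config.id_a, id_b=config.id_b)
    if pairs.empty:
        empty = pd.DataFrame(columns=["id_a", "id_b", "pattern", "compound_weight",
                                      "category"])
        diag = pd.DataFrame(columns=["pattern", "count", "weight", "p_match",
                                     "p_unmatch"])
        wt = config.fixed_weights or UnitWeightTable(
            (0.0,) * len(config.compare_fields), (0.0,) * len(config.compare_fields),
            config.log_base)
        return LinkageResult(empty, diag, None, wt, converged=True)

    agree = _pair_patterns(file_a, file_b, pairs, config)
    pattern_tuples = [tuple(None if v == -1 else int(v) for v in row) for row in agree]
    counts = Counter(pattern_tuples)

    params: FSParameters | None = None
    if config.fixed_weights is not None:
        weights = config.fixed_weights
        converged = True
    else:
        params = em_fit(counts, init=config.em_init, tol=config.em_tol,
                        max_iter=config.em_max_iter)
        weights = unit_weights(params, config.log_base)
        converged = params.converged

    weight_by_pattern = {pat: compound_weight(pat, weights) for pat in counts}
    w = np.array([weight_by_pattern[pat] for pat in pattern_tuples])
    categories = np.where(w >= config.upper, MATCHED,
                          np.where(w >= config.lower, INDECISION, UNMATCHED))
    decisions = pairs.copy()
    decisions["pattern"] = ["".join("?" if b is None else str(b) for b in pat)
                            for pat in pattern_tuples]
    decisions["compound_weight"] = w
    decisions["category"] = categories
    decisions = (decisions.sort_values(["id_a", "id_b"], kind="stable")
                 .reset_index(drop=True))

    if params is not None:
        diag = pattern_diagnostics(counts, params, config.log_base, weights)
    else:
        rows = [{"pattern": "".join("?" if b is None else str(b) for b in pat),
                 "count": c, "weight": weight_by_pattern[pat],
                 "p_match": np.nan, "p_unmatch": np.nan}
                for pat, c in counts.items()]
        diag = (pd.DataFrame(rows).sort_values("weight", kind="stable")
                .reset_index(drop=True))
    return LinkageResult(decisions, diag, params, weights, converged)
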