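"""Two-sample differential testing with a permutation-based FDR.

Per protein the statistic is a (optionally variance-moderated) pooled
two-sample t:

    t = (mean_T - mean_C) / (s_pooled * sqrt(1/n1 + 1/n2) + s0)

Raw p-values come from the t reference distribution with n1+n2-2 degrees
of freedom.  q-values come from condition-label permutations: for every
balanced relabeling of the samples the full vector of null statistics is
recomputed and pooled over proteins, and

    q(i) = median over relabelings of  #{null |t| >= |t_i|} / #{observed |t| >= |t_i|}

clipped to [0, 1] and made monotone non-increasing in |t|.  The identity
partition (observed labeling and its swap) is excluded from the null
pool, since it would contribute a ratio of exactly 1 for every protein.

The moderation constant ``s0`` (the SAM fudge factor) stabilises the
denominator of low-variance proteins; with only a handful of replicates
the plain t statistic (s0 = 0) has very heavy null tails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .quant import CONTROL, TREATMENT, QuantMatrix

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
NON_RESPONDER = "non_responder"


class ConfigurationError(ValueError):
    pass


@dataclass
class TestParams:
    alpha: float = 0.05
    strict_alpha: float = 0.01
    fdr_target: float = 0.05
    n_permutations: int = 250
    s0: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.strict_alpha < 1):
            raise ValueError("alpha levels must be in (0, 1)")
        if not (0 < self.fdr_target < 1):
            raise ValueError("fdr_target must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")


@dataclass
class DiffResult:
    """Per-protein differential result table.

    ``table`` columns: protein_id (index), log2fc, t, p, q, class.
    """

    table: pd.DataFrame

    @property
    def class_counts(self) -> dict[str, int]:
        counts = self.table["class"].value_counts().to_dict()
        return {k: int(counts.get(k, 0)) for k in (POSITIVE, NEGATIVE, NON_RESPONDER)}


def _t_statistics(values: np.ndarray, treat_mask: np.ndarray, s0: float) -> np.ndarray:
    """Pooled-variance two-sample t for every row, treatment minus control."""
    a = values[:, ~treat_mask]
    b = values[:, treat_mask]
    n1, n2 = a.shape[1], b.shape[1]
    diff = b.mean(axis=1) - a.mean(axis=1)
    ss = a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)
    sp = np.sqrt(ss / (n1 + n2 - 2))
    den = sp * np.sqrt(1.0 / n1 + 1.0 / n2) + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / den
        # 0/0 (constant identical groups) -> no evidence; x/0 -> infinite
        t = np.where(den == 0, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    return t


def _balanced_relabelings(
    n_samples: int, n_treat: int, n_max: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Index sets acting as pseudo-treatment, excluding the identity partition.

    For balanced designs relabelings are deduplicated up to a group swap
    (the |t| vector is invariant).  All distinct relabelings are
    enumerated when there are at most ``n_max``; otherwise ``n_max``
    random ones are drawn.
    """
    identity = frozenset(range(n_samples - n_treat, n_samples))
    identity_swap = frozenset(range(n_samples - n_treat))
    all_sets = [frozenset(c) for c in combinations(range(n_samples), n_treat)]
    if n_treat * 2 == n_samples:
        # keep one representative per {S, complement(S)} pair
        seen: set[frozenset] = set()
        dedup = []
        for s in all_sets:
            comp = frozenset(set(range(n_samples)) - s)
            if s not in seen and comp not in seen:
                seen.add(s)
                dedup.append(s)
        all_sets = dedup
    all_sets = [s for s in all_sets if s != identity and s != identity_swap]
    if len(all_sets) < 2:
        raise ConfigurationError(
            "fewer than 2 distinct permutations possible for this design"
        )
    if len(all_sets) > n_max:
        idx = rng.choice(len(all_sets), size=n_max, replace=False)
        all_sets = [all_sets[i] for i in sorted(idx)]
    return [np.array(sorted(s)) for s in all_sets]


def differential_test(matrix: QuantMatrix, params: TestParams | None = None) -> DiffResult:
    """Compute per-protein log2FC, t, raw p and permutation q.

    Requires a complete (imputed) log2 matrix.  Sample order is
    canonicalised to controls first so that permutation enumeration is
    independent of column order.
    """
    params = params or TestParams()
    if not matrix.log2_transformed:
        raise ConfigurationError("differential_test expects log2 intensities")
    if matrix.values.isna().any(axis=None):
        raise ConfigurationError("matrix contains missing values; impute first")

    ctrl = matrix.samples(CONTROL)
    treat = matrix.samples(TREATMENT)
    cols = ctrl + treat
    values = matrix.values[cols].to_numpy(dtype=float)
    n1, n2 = len(ctrl), len(treat)
    treat_mask = np.zeros(n1 + n2, dtype=bool)
    treat_mask[n1:] = True

    t_obs = _t_statistics(values, treat_mask, params.s0)
    log2fc = values[:, treat_mask].mean(axis=1) - values[:, ~treat_mask].mean(axis=1)
    df = n1 + n2 - 2
    p = 2.0 * stats.t.sf(np.abs(t_obs), df)

    rng = np.random.default_rng(params.seed)
    relabelings = _balanced_relabelings(n1 + n2, n2, params.n_permutations, rng)

    abs_obs = np.abs(t_obs)
    sorted_obs = np.sort(abs_obs)
    n = len(abs_obs)
    r_obs = n - np.searchsorted(sorted_obs, abs_obs, side="left")  # #obs |t| >= |t_i|
    ratios = np.empty((len(relabelings), n))
    for j, idx in enumerate(relabelings):
        mask = np.zeros(n1 + n2, dtype=bool)
        mask[idx] = True
        null_abs = np.sort(np.abs(_t_statistics(values, mask, params.s0)))
        v = n - np.searchsorted(null_abs, abs_obs, side="left")
        ratios[j] = v / r_obs
    q = np.clip(np.median(ratios, axis=0), 0.0, 1.0)

    # monotone non-increasing in |t|; ties broken by protein id for determinism
    ids = matrix.values.index.to_numpy()
    order = np.lexsort((ids, -abs_obs))
    q_sorted = np.maximum.accumulate(q[order])
    q_mono = np.empty_like(q)
    q_mono[order] = q_sorted

    table = pd.DataFrame(
        {"log2fc": log2fc, "t": t_obs, "p": p, "q": q_mono,
         "class": NON_RESPONDER},
        index=matrix.values.index,
    )
    table.index.name = "protein_id"
    return DiffResult(table)


def classify_responders(
    result: DiffResult, params: TestParams | None = None, strict: bool = False
) -> DiffResult:
    """Assign positive/negative/non-responder classes by sign of log2FC and raw p.

    ``strict=True`` uses the secondary ``strict_alpha`` level.  The
    permutation q column is left untouched so that a q-based selection
    can be reported alongside.
    """
    params = params or TestParams()
    level = params.strict_alpha if strict else params.alpha
    t = result.table.copy()
    sig = t["p"] < level
    t["class"] = NON_RESPONDER
    t.loc[sig & (t["log2fc"] > 0), "class"] = POSITIVE
    t.loc[sig & (t["log2fc"] < 0), "class"] = NEGATIVE
    out = DiffResult(t)
    logger.info("classify_responders (p<%g): %s", level, out.class_counts)
    return out
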