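"""Permutation test for antagonistic arrangement of linked interval effects.

If adjacent introgression intervals carry effects of opposite sign
(repulsion-phase linkage), the cumulative phenotypes of the NIL ladder
stay close together and their variance is small.  The test asks whether
the observed variance of the ladder phenotypes is smaller than expected
were the same effects randomly ordered along the chromosome: effects are
shuffled among the intervals, the cumulative phenotypes rebuilt, and the
variance recomputed for each shuffle.
"""

from __future__ import annotations

import math
from itertools import permutations as _iter_permutations

import numpy as np

from .datatypes import ArrangementResult, EffectLadder, NILLadder, ValidationError


def _effect_array(effects, trait: str = "N") -> np.ndarray:
    if isinstance(effects, EffectLadder):
        return effects.trait_effects(trait)
    return np.asarray(effects, dtype=float).ravel()


def cumulative_phenotypes(effects, ladder: NILLadder, trait: str = "N") -> np.ndarray:
    """Per-strain phenotypes implied by the interval effects.

    Strain k carries the k right-most intervals, so its phenotype is the
    sum of those effects: the all-N2 strain sits at zero and the
    all-CB4856 strain at the sum of all effects.
    """
    e = _effect_array(effects, trait)
    if e.size != ladder.n_intervals:
        raise ValidationError(
            f"{e.size} effects inconsistent with {ladder.n_intervals} intervals"
        )
    return np.concatenate([[0.0], np.cumsum(e[::-1])])


def variance_statistic(phenotypes: np.ndarray) -> float:
    """Sample variance (n - 1 denominator) of the strain phenotypes."""
    ph = np.asarray(phenotypes, dtype=float)
    if ph.size < 2:
        raise ValidationError("need at least 2 phenotypes")
    return float(np.var(ph, ddof=1))


def _null_variances(effect_rows: np.ndarray) -> np.ndarray:
    """Ladder-phenotype variance for each row of interval effects.

    Vectorized over rows: cumulative phenotypes are the reversed cumsum
    plus the implicit leading zero of the all-N2 strain, so with
    m + 1 strains,  V = (sum(c^2) - sum(c)^2 / (m + 1)) / m  where c are
    the m cumulative sums.
    """
    rows = np.atleast_2d(np.asarray(effect_rows, dtype=float))
    m = rows.shape[1]
    csum = np.cumsum(rows[:, ::-1], axis=1)
    s1 = csum.sum(axis=1)
    s2 = (csum**2).sum(axis=1)
    return (s2 - s1**2 / (m + 1)) / m


def order_permutation_test(
    effects,
    ladder: NILLadder | None = None,
    n_perm: int = 100_000,
    seed: int | None = None,
    trait: str = "N",
    two_sided: bool = False,
) -> ArrangementResult:
    """Monte-Carlo arrangement test over uniform random interval orders.

    One-sided by default with small variance as the alternative
    (antagonistic arrangement): p = (1 + #{V_perm <= V_obs}) / (1 + n_perm).
    The two-sided variant doubles the smaller tail.  Orders are drawn
    uniformly with replacement; the full null sample is retained.
    """
    e = _effect_array(effects, trait)
    m = e.size
    if m < 2:
        raise ValidationError("arrangement test needs at least 2 intervals")
    if ladder is not None and ladder.n_intervals != m:
        raise ValidationError("ladder interval count does not match effects")
    if n_perm < 999:
        raise ValidationError("need at least 999 permutations")
    v_obs = float(_null_variances(e[None, :])[0])
    rng = np.random.default_rng(seed)
    shuffled = rng.permuted(np.tile(e, (n_perm, 1)), axis=1)
    null = _null_variances(shuffled)
    tol = 1e-12 + 1e-9 * v_obs
    n_low = int((null <= v_obs + tol).sum())
    p_low = (1 + n_low) / (1 + n_perm)
    if two_sided:
        n_high = int((null >= v_obs - tol).sum())
        p_high = (1 + n_high) / (1 + n_perm)
        p = min(1.0, 2 * min(p_low, p_high))
    else:
        p = p_low
    return ArrangementResult(
        observed_variance=v_obs,
        null_variances=null,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
        two_sided=two_sided,
    )


def exhaustive_arrangement_test(
    effects, ladder: NILLadder | None = None, trait: str = "N"
) -> tuple[float, np.ndarray]:
    """Exact arrangement test by enumerating all m! interval orders.

    Tied effects are handled naturally: duplicate orderings are counted
    with their multiplicity.  Returns (exact one-sided p, the m! null
    variances).  Bounded at m <= 8; use the Monte-Carlo test beyond.
    """
    e = _effect_array(effects, trait)
    m = e.size
    if m < 2:
        raise ValidationError("arrangement test needs at least 2 intervals")
    if m > 8:
        raise ValidationError("exhaustive enumeration bounded at 8 intervals; use the Monte-Carlo test")
    if ladder is not None and ladder.n_intervals != m:
        raise ValidationError("ladder interval count does not match effects")
    orders = np.array(list(_iter_permutations(e)), dtype=float)
    null = _null_variances(orders)
    v_obs = float(_null_variances(e[None, :])[0])
    tol = 1e-12 + 1e-9 * v_obs
    p = float((null <= v_obs + tol).sum()) / math.factorial(m)
    return p, null
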