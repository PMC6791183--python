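"""Near-isogenic line interval dissection.

Raw well records are first reduced to one adjusted phenotype per
independently passaged replicate population (strain x day x passage) by
univariate variance-components models that absorb assay day, plate
(nested in day) and well position; the replicate population's predicted
value (grand mean + its BLUP) is the adjusted phenotype.  Strain is
deliberately absent from the model, so genetic signal flows into the
replicate BLUPs.  Each of the ladder's intervals is then tested by a
two-strain multivariate analysis of variance between the adjacent
strains that differ only in that interval, with permutation p-values
from shuffling strain labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    EffectLadder,
    IntervalTestTable,
    NILLadder,
    TRAITS,
    ValidationError,
    WellRecord,
    wells_to_frame,
)
from . import mstats


@dataclass(frozen=True)
class ReplicatePhenotypes:
    """One adjusted [S, M, N] observation per replicate population."""

    table: pd.DataFrame  # columns: strain, day, passage, S, M, N

    def __post_init__(self) -> None:
        required = {"strain", "day", "passage", *TRAITS}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"replicate table missing columns {sorted(missing)}")

    def for_strain(self, strain: str) -> np.ndarray:
        sub = self.table[self.table["strain"] == strain]
        return sub[list(TRAITS)].to_numpy(dtype=float)

    @property
    def strains(self) -> list[str]:
        return list(dict.fromkeys(self.table["strain"]))


class MixedModelError(RuntimeError):
    """A variance-components fit failed to converge or was singular."""


def extract_replicate_phenotypes(wells: Sequence[WellRecord]) -> ReplicatePhenotypes:
    """Adjusted replicate-population phenotypes from raw wells.

    For each trait separately, fits a variance-components model with
    random intercepts for assay day, plate (nested in day), well
    position, and replicate population (strain x day x passage).  The
    adjusted phenotype of a replicate population is the fixed grand mean
    plus that population's BLUP.  BLUP shrinkage toward the grand mean
    is accepted; with the default assay design it is small because each
    population is measured on ~10 wells.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    df = wells_to_frame(list(wells))
    df["plate_uid"] = df["day"].str.cat(df["plate"], sep="|")
    df["rep_uid"] = df["strain"].str.cat([df["day"], df["passage"]], sep="|")
    for factor in ("day", "plate_uid", "well", "rep_uid"):
        if df[factor].nunique() < 2:
            raise ValidationError(f"nuisance factor {factor!r} has fewer than 2 levels")
    df["_grp"] = 1

    vc = {
        "day": "0 + C(day)",
        "plate": "0 + C(plate_uid)",
        "well": "0 + C(well)",
        "rep": "0 + C(rep_uid)",
    }
    rep_levels = sorted(df["rep_uid"].unique())
    adjusted = pd.DataFrame(index=rep_levels, columns=list(TRAITS), dtype=float)
    for trait in TRAITS:
        model = sm.MixedLM.from_formula(
            f"{trait} ~ 1", groups="_grp", vc_formula=vc, re_formula="0", data=df
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            try:
                fit = model.fit(reml=True, method="lbfgs")
                if not np.isfinite(fit.params).all():
                    raise ValueError("non-finite parameter estimates")
            except Exception:
                try:
                    fit = model.fit(reml=True, method="cg")
                except Exception as e:  # noqa: BLE001 - re-raise with trait context
                    raise MixedModelError(
                        f"variance-components fit failed for trait {trait!r}: {e}"
                    ) from e
        grand_mean = float(fit.fe_params.iloc[0])
        blups = _vc_blups(model, fit, "rep")
        for level in rep_levels:
            adjusted.loc[level, trait] = grand_mean + blups.get(level, 0.0)

    meta = df.drop_duplicates("rep_uid").set_index("rep_uid")[["strain", "day", "passage"]]
    out = meta.loc[rep_levels].reset_index(drop=True)
    out[list(TRAITS)] = adjusted.loc[rep_levels].to_numpy()
    return ReplicatePhenotypes(table=out)


def _vc_blups(model, fit, component: str) -> dict[str, float]:
    """Per-level BLUPs of one variance component from a MixedLM fit.

    Level names are recovered from the variance-component design labels,
    which have the form ``C(factor)[level]``.
    """
    re_all = fit.random_effects
    (group_re,) = re_all.values()  # single all-encompassing group
    names = model.exog_vc.names
    out: dict[str, float] = {}
    for label, value in group_re.items():
        s = str(label)
        if not s.startswith(component + "["):
            continue
        # labels look like "rep[C(rep_uid)[LEVEL]]": take the innermost bracket
        start = s.rindex("[") + 1
        level = s[start : s.index("]", start)] if "[" in s else s
        out[level] = float(value)
    if not out:
        raise MixedModelError(f"no BLUPs recovered for component {component!r} (labels: {names})")
    return out


# ---------------------------------------------------------------------------
# pairwise tests
# ---------------------------------------------------------------------------

def _two_groups(
    reps: ReplicatePhenotypes, strain_a: str, strain_b: str
) -> tuple[np.ndarray, np.ndarray]:
    Ya = reps.for_strain(strain_a)
    Yb = reps.for_strain(strain_b)
    if len(Ya) < 3 or len(Yb) < 3:
        raise ValidationError(
            f"need >= 3 observations per strain ({strain_a}: {len(Ya)}, {strain_b}: {len(Yb)})"
        )
    return Ya, Yb


def pairwise_multivariate_test(
    reps: ReplicatePhenotypes, strain_a: str, strain_b: str, statistic: str = "wilks"
) -> mstats.MultivariateTest:
    """Two-strain MANOVA on the three traits (parametric p-value)."""
    Ya, Yb = _two_groups(reps, strain_a, strain_b)
    Y = np.vstack([Ya, Yb])
    n = len(Y)
    group = np.r_[np.zeros(len(Ya)), np.ones(len(Yb))]
    X_full = np.column_stack([np.ones(n), group])
    X_red = np.ones((n, 1))
    return mstats.wilks_test(Y, X_full, X_red, statistic=statistic)


def _two_group_lambda_batch(
    Y: np.ndarray, masks: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Wilks' Lambda and per-trait F for many 2-group label assignments.

    ``masks`` is (n_assignments x n) boolean, True marking group A.  The
    group sizes are constant across rows.  Uses the rank-1 identity
    Lambda = 1 - c * delta' T^{-1} delta with c = n_a n_b / n and
    delta the group-mean difference; T is the total (centered) SSCP.
    """
    n, p = Y.shape
    n_a = int(masks[0].sum())
    n_b = n - n_a
    c = n_a * n_b / n
    Yc = Y - Y.mean(axis=0)
    T = Yc.T @ Yc
    Tinv = np.linalg.pinv(T)
    sums_a = masks @ Y  # (B, p)
    total = Y.sum(axis=0)
    delta = sums_a / n_a - (total - sums_a) / n_b
    quad = np.einsum("bi,ij,bj->b", delta, Tinv, delta)
    lam = np.clip(1.0 - c * quad, 1e-12, 1.0)
    # univariate one-way F with the same assignments
    H_tt = c * delta**2
    E_tt = np.diag(T)[None, :] - H_tt
    F = H_tt / (E_tt / (n - 2))
    return lam, F


def permutation_pvalue(
    reps: ReplicatePhenotypes,
    strain_a: str,
    strain_b: str,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, dict[str, float]]:
    """Label-permutation p-values for the pairwise comparison.

    Strain labels are shuffled among the pooled observations; the same
    permutation draws feed the multivariate statistic and the three
    univariate F statistics.  p = (1 + #{perm >= observed extremeness})
    / (1 + n_perm), so p is never zero.
    """
    if n_perm < 99:
        raise ValidationError("need at least 99 permutations")
    Ya, Yb = _two_groups(reps, strain_a, strain_b)
    Y = np.vstack([Ya, Yb])
    n, n_a = len(Y), len(Ya)
    obs_mask = np.zeros((1, n), dtype=bool)
    obs_mask[0, :n_a] = True
    lam_obs, F_obs = _two_group_lambda_batch(Y, obs_mask)

    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm, n), dtype=bool)
    for b in range(n_perm):
        masks[b, rng.choice(n, size=n_a, replace=False)] = True
    lam_perm, F_perm = _two_group_lambda_batch(Y, masks)

    tol = 1e-12
    p_multi = (1 + int((lam_perm <= lam_obs[0] + tol).sum())) / (1 + n_perm)
    p_uni = {
        t: (1 + int((F_perm[:, k] >= F_obs[0, k] - tol).sum())) / (1 + n_perm)
        for k, t in enumerate(TRAITS)
    }
    return p_multi, p_uni


# ---------------------------------------------------------------------------
# ladder-level results
# ---------------------------------------------------------------------------

def interval_effect_ladder(reps: ReplicatePhenotypes, ladder: NILLadder) -> EffectLadder:
    """Per-interval CB4856-direction effect vectors from strain means.

    The effect of interval i is the mean adjusted phenotype of the
    strain carrying the introgression up to and including i, minus that
    of the strain lacking only i.  The effects telescope: they sum to
    the difference between the all-CB4856 and all-N2 parental strains.
    """
    present = set(reps.strains)
    missing = [s for s in ladder.strains if s not in present]
    if missing:
        raise ValidationError(f"ladder strains absent from replicate data: {missing}")
    means = {s: reps.for_strain(s).mean(axis=0) for s in ladder.strains}
    effects = np.zeros((ladder.n_intervals, 3))
    for i in range(ladder.n_intervals):
        k_without, k_with = ladder.carriers_of(i)
        effects[i] = means[ladder.strains[k_with]] - means[ladder.strains[k_without]]
    return EffectLadder(effects=effects, labels=ladder.interval_labels)


def bonferroni_flags(
    p_values: Sequence[float], family_alpha: float = 0.05
) -> tuple[np.ndarray, float]:
    """Family-wise flags: significant iff p <= family_alpha / m."""
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValidationError("need at least one p-value")
    threshold = family_alpha / p.size
    return p <= threshold, threshold


def test_intervals(
    reps: ReplicatePhenotypes,
    ladder: NILLadder,
    n_perm: int = 10_000,
    seed: int | None = None,
    family_alpha: float = 0.05,
) -> IntervalTestTable:
    """Test every ladder interval by adjacent-strain comparison.

    Each interval gets the two-strain Wilks' Lambda, its label-permutation
    p-value, per-trait univariate permutation p-values, the interval's
    CB4856-direction effect vector, and a Bonferroni flag over the family
    of intervals.  Permutations for interval i use substream i of the seed.
    """
    effects = interval_effect_ladder(reps, ladder)
    rows = []
    for i in range(ladder.n_intervals):
        k_without, k_with = ladder.carriers_of(i)
        s_lo, s_hi = ladder.strains[k_without], ladder.strains[k_with]
        test = pairwise_multivariate_test(reps, s_lo, s_hi)
        sub_seed = np.random.SeedSequence(seed, spawn_key=(i,)).generate_state(1)[0] % (2**31)
        p_multi, p_uni = permutation_pvalue(reps, s_lo, s_hi, n_perm=n_perm, seed=int(sub_seed))
        rows.append(
            {
                "interval": ladder.interval_labels[i],
                "strain_lo": s_lo,
                "strain_hi": s_hi,
                "wilks_lambda": test.statistic,
                "p_perm": p_multi,
                "p_perm_S": p_uni["S"],
                "p_perm_M": p_uni["M"],
                "p_perm_N": p_uni["N"],
                "effect_S": effects.effects[i, 0],
                "effect_M": effects.effects[i, 1],
                "effect_N": effects.effects[i, 2],
            }
        )
    df = pd.DataFrame(rows)
    flags, threshold = bonferroni_flags(df["p_perm"].to_numpy(), family_alpha)
    df["bonferroni_significant"] = flags
    df = df[list(IntervalTestTable.COLUMNS)]
    return IntervalTestTable(table=df, family_alpha=family_alpha, bonferroni_threshold=threshold)


def parental_test(
    reps: ReplicatePhenotypes,
    ladder: NILLadder,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, dict[str, float]]:
    """Permutation comparison of the all-N2 and all-CB4856 parental strains."""
    return permutation_pvalue(
        reps, ladder.strains[0], ladder.strains[-1], n_perm=n_perm, seed=seed
    )
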