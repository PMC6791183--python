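"""Multivariate QTL mapping in RIAILs.

The mapping procedure is multivariate marker regression: at each marker,
the three demography traits are regressed jointly on the genotype code
(plus any markers already retained as covariates) and the marker's
contribution is tested with Wilks' Lambda.  Genome-wide significance is
assessed by a permutation-based residual empirical threshold: residuals
from the current covariate model are permuted against the genotypes and
the genome-wide maximum score recorded for each permutation.  A forward
search adds the strongest marker whenever it clears the threshold and
rescans with it as a covariate, stopping when no marker clears.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    GenotypeMatrix,
    PhenotypeTable,
    QTLModel,
    ScanProfile,
    TRAITS,
    ValidationError,
)
from . import mstats


@dataclass(frozen=True)
class PermutationSettings:
    """Controls for the permutation-based genome-wide threshold."""

    n_permutations: int = 1000
    genomewide_alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValidationError("need at least 100 permutations")
        if not 0 < self.genomewide_alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class EffectEstimate:
    """Joint additive multivariate fit at a set of retained markers."""

    markers: tuple[str, ...]
    effects: np.ndarray  # n_qtl x n_traits, CB4856-direction
    r_squared: dict[str, float]
    univariate_p: np.ndarray  # n_qtl x n_traits


# ---------------------------------------------------------------------------
# phenotype preparation
# ---------------------------------------------------------------------------

def adjust_for_assay_day(
    raw: PhenotypeTable, day_labels: dict[str, str]
) -> PhenotypeTable:
    """Residuals of a multivariate regression of traits on assay day.

    Regressing on a single factor is per-day centering: within each day
    each trait's residuals sum to zero.  Every line needs a label and
    every day at least two lines.
    """
    missing = [ln for ln in raw.lines if ln not in day_labels]
    if missing:
        raise ValidationError(f"no day label for lines {missing[:5]}")
    days = np.asarray([day_labels[ln] for ln in raw.lines])
    resid = raw.values.copy()
    for day in dict.fromkeys(days):
        idx = np.flatnonzero(days == day)
        if idx.size < 2:
            raise ValidationError(f"assay day {day!r} has a single line; residual degenerate")
        resid[idx] -= resid[idx].mean(axis=0)
    return PhenotypeTable(lines=raw.lines, values=resid, scale="residual")


def filter_low_fecundity(
    raw: PhenotypeTable, progeny_per_founder_max_excluded: float = 5
) -> PhenotypeTable:
    """Drop lines with progeny per founder at or below the cutoff.

    Lines that fail to thrive ("five or fewer progeny per initial worm")
    carry no usable demography signal; they are removed before mapping.
    Order of the remaining lines is preserved.
    """
    if raw.scale != "raw":
        raise ValidationError("fecundity filter applies to raw-scale phenotypes")
    keep = raw.values[:, 2] > progeny_per_founder_max_excluded
    return PhenotypeTable(
        lines=tuple(ln for ln, k in zip(raw.lines, keep) if k),
        values=raw.values[keep],
        scale=raw.scale,
    )


# ---------------------------------------------------------------------------
# marker scan
# ---------------------------------------------------------------------------

def _align(Y: PhenotypeTable, G: GenotypeMatrix) -> np.ndarray:
    """Phenotype rows in genotype line order (sets must agree)."""
    if set(Y.lines) != set(G.lines):
        raise ValidationError("phenotype and genotype line sets differ")
    pos = {ln: i for i, ln in enumerate(Y.lines)}
    order = np.array([pos[ln] for ln in G.lines])
    return Y.values[order]


def _trait_columns(traits: tuple[str, ...]) -> list[int]:
    bad = [t for t in traits if t not in TRAITS]
    if bad:
        raise ValidationError(f"unknown traits {bad}")
    return [TRAITS.index(t) for t in traits]


def _covariate_design(G: GenotypeMatrix, covariate_idx: list[int]) -> np.ndarray:
    n = G.n_lines
    return np.column_stack([np.ones(n)] + [G.calls[:, j] for j in covariate_idx])


def marker_scan(
    Y: PhenotypeTable,
    G: GenotypeMatrix,
    covariate_markers: list[str] | None = None,
    statistic: str = "wilks",
    traits: tuple[str, ...] = TRAITS,
) -> ScanProfile:
    """Multivariate marker regression at every non-covariate marker.

    For each focal marker, fits traits ~ intercept + covariates + focal
    genotype and tests the focal coefficient with Wilks' Lambda (exact F
    for this rank-1 hypothesis; Pillai's trace gives the identical F
    here and is available for reporting).  Monomorphic markers, markers
    collinear with the covariates, and the covariates themselves are
    flagged and carry no statistic.  Lines with a missing covariate call
    are excluded throughout; lines missing the focal call are excluded
    marker-wise.
    """
    if statistic not in ("wilks", "pillai"):
        raise ValidationError(f"unknown statistic {statistic!r}")
    covariate_markers = covariate_markers or []
    cov_idx = [G.markers.marker_id.index(m) for m in covariate_markers]
    Yv = _align(Y, G)[:, _trait_columns(traits)]
    p = Yv.shape[1]
    X0_all = _covariate_design(G, cov_idx)
    rows_ok = ~np.isnan(X0_all).any(axis=1)
    X0 = X0_all[rows_ok]
    Yv = Yv[rows_ok]
    calls = G.calls[rows_ok]
    n = int(rows_ok.sum())
    q0 = np.linalg.matrix_rank(X0)
    if n < q0 + 1 + p:
        raise ValidationError(f"only {n} usable lines for a model with {q0 + 1} parameters")

    m = G.n_markers
    lam = np.full(m, np.nan)
    Fv = np.full(m, np.nan)
    pv = np.full(m, np.nan)
    flagged = np.zeros(m, dtype=bool)
    flagged[cov_idx] = True
    scan_targets = np.setdiff1d(np.arange(m), np.asarray(cov_idx, dtype=int))
    complete = ~np.isnan(calls).any(axis=0)
    batch = scan_targets[complete[scan_targets]]
    loop = scan_targets[~complete[scan_targets]]

    v = n - q0 - 1
    if batch.size:
        Y_r = mstats.residualize(Yv, X0)
        G_r = mstats.residualize(calls[:, batch], X0)
        lam_b, F_b, p_b, df1, df2 = mstats.rank_one_wilks_batch(Y_r, G_r, v)
        lam[batch], Fv[batch], pv[batch] = lam_b, F_b, p_b
        flagged[batch[np.isnan(lam_b)]] = True
    else:
        df1, df2 = float(p), float(v - p + 1)
    for j in loop:
        x = calls[:, j]
        sub = ~np.isnan(x)
        n_j = int(sub.sum())
        q0_j = np.linalg.matrix_rank(X0[sub])
        v_j = n_j - q0_j - 1
        if v_j < p:
            flagged[j] = True
            continue
        Y_r = mstats.residualize(Yv[sub], X0[sub])
        G_r = mstats.residualize(x[sub, None], X0[sub])
        lam_j, F_j, p_j, _, _ = mstats.rank_one_wilks_batch(Y_r, G_r, v_j)
        if np.isnan(lam_j[0]):
            flagged[j] = True
        else:
            lam[j], Fv[j], pv[j] = lam_j[0], F_j[0], p_j[0]

    stat = 1.0 - lam if statistic == "pillai" else lam
    table = pd.DataFrame(
        {
            "marker_id": list(G.markers.marker_id),
            "wilks_lambda": lam,
            "F": Fv,
            "df1": df1,
            "df2": df2,
            "p": pv,
            "neglog10_p": mstats.neglog10(pv),
            "flagged": flagged,
        }
    )
    if statistic == "pillai":
        table["pillai_trace"] = stat
    return ScanProfile(table=table)


def residual_empirical_threshold(
    Y: PhenotypeTable,
    G: GenotypeMatrix,
    covariate_markers: list[str] | None = None,
    settings: PermutationSettings = PermutationSettings(),
    traits: tuple[str, ...] = TRAITS,
    rng: np.random.Generator | None = None,
) -> float:
    """Genome-wide -log10(p) threshold by permuting current-model residuals.

    Residuals of the traits on the covariate model are permuted jointly
    (each line's trait triple stays together) against the genotypes; the
    score of a permutation is the genome-wide maximum -log10(p) over the
    scanned markers, and the threshold is the empirical (1 - alpha)
    quantile (order statistic, ceiling index) of those maxima.  Lines
    with any missing call among the scanned markers or covariates are
    excluded here so every permutation scans an identical line set.
    """
    covariate_markers = covariate_markers or []
    cov_idx = [G.markers.marker_id.index(m) for m in covariate_markers]
    Yv = _align(Y, G)[:, _trait_columns(traits)]
    p = Yv.shape[1]
    X0_all = _covariate_design(G, cov_idx)
    scan_targets = np.setdiff1d(np.arange(G.n_markers), np.asarray(cov_idx, dtype=int))
    rows_ok = ~np.isnan(X0_all).any(axis=1) & ~np.isnan(G.calls[:, scan_targets]).any(axis=1)
    X0 = X0_all[rows_ok]
    Yv = Yv[rows_ok]
    calls = G.calls[rows_ok][:, scan_targets]
    n = int(rows_ok.sum())
    q0 = np.linalg.matrix_rank(X0)
    v = n - q0 - 1
    if v < p:
        raise ValidationError("too few usable lines for the permutation scan")

    if rng is None:
        rng = np.random.default_rng(settings.seed)
    P0 = np.linalg.pinv(X0)
    R = Yv - X0 @ (P0 @ Yv)  # residuals of the covariate model
    G_r = calls - X0 @ (P0 @ calls)
    maxima = np.empty(settings.n_permutations)
    for b in range(settings.n_permutations):
        perm = rng.permutation(n)
        Yp = R[perm]
        Yp_r = Yp - X0 @ (P0 @ Yp)
        _, _, pvals, _, _ = mstats.rank_one_wilks_batch(Yp_r, G_r, v)
        with np.errstate(divide="ignore"):
            maxima[b] = np.nanmax(-np.log10(pvals))
    k = math.ceil((1 - settings.genomewide_alpha) * settings.n_permutations)
    return float(np.sort(maxima)[k - 1])


def forward_search(
    Y: PhenotypeTable,
    G: GenotypeMatrix,
    settings: PermutationSettings = PermutationSettings(),
    statistic: str = "wilks",
    traits: tuple[str, ...] = TRAITS,
    max_qtl: int = 20,
    return_profiles: bool = False,
) -> QTLModel | tuple[QTLModel, list[ScanProfile]]:
    """Iterative marker-regression model building.

    Scan all non-covariate markers given the current covariates; if the
    strongest marker (ties broken by lowest marker index) exceeds that
    scan's permutation threshold, retain it as a covariate and rescan;
    otherwise stop.  A hard cap of ``max_qtl`` retained markers bounds
    runtime.  Permutation draws for scan i come from a fixed substream i
    of the settings seed, so the search is deterministic given the data.
    """
    retained: list[str] = []
    thresholds: list[float] = []
    profiles: list[ScanProfile] = []
    while len(retained) < max_qtl:
        profile = marker_scan(Y, G, retained, statistic=statistic, traits=traits)
        profiles.append(profile)
        scores = profile.table["neglog10_p"].to_numpy()
        scores = np.where(profile.table["flagged"].to_numpy(), -np.inf, scores)
        if not np.isfinite(scores).any():
            break
        best = int(np.nanargmax(scores))  # argmax takes the lowest index on ties
        rng = np.random.default_rng(
            np.random.SeedSequence(settings.seed, spawn_key=(len(retained),))
        )
        thr = residual_empirical_threshold(
            Y, G, retained, settings, traits=traits, rng=rng
        )
        thresholds.append(thr)
        if scores[best] > thr:
            retained.append(G.markers.marker_id[best])
        else:
            break

    if retained:
        est = estimate_effects(Y, G, retained, traits=traits)
        effects3 = _embed_traits(est.effects, traits)
        r2 = {t: est.r_squared[t] for t in traits}
        uni = {
            t: tuple(bool(x) for x in (est.univariate_p[:, k] < 0.05))
            for k, t in enumerate(traits)
        }
    else:
        effects3 = np.empty((0, 3))
        r2 = {t: 0.0 for t in traits}
        uni = {t: () for t in traits}
    model = QTLModel(
        markers=tuple(retained),
        effects=effects3,
        thresholds=tuple(thresholds),
        r_squared=r2,
        univariate_significant=uni,
        statistic=statistic,
        alpha=settings.genomewide_alpha,
        n_permutations=settings.n_permutations,
        seed=settings.seed,
    )
    return (model, profiles) if return_profiles else model


def _embed_traits(effects: np.ndarray, traits: tuple[str, ...]) -> np.ndarray:
    """Place per-trait effect columns into the full [S, M, N] layout."""
    out = np.zeros((effects.shape[0], 3))
    for k, t in enumerate(traits):
        out[:, TRAITS.index(t)] = effects[:, k]
    return out


def estimate_effects(
    Y: PhenotypeTable,
    G: GenotypeMatrix,
    qtl_markers: list[str],
    traits: tuple[str, ...] = TRAITS,
) -> EffectEstimate:
    """Joint additive multivariate fit at the retained markers.

    Effect vectors are the coefficients of the CB4856 genotype code;
    per-trait R-squared comes from the same joint fit.  Monomorphic or
    pairwise-collinear markers are rejected by name.
    """
    idx = [G.markers.marker_id.index(m) for m in qtl_markers]
    Yv = _align(Y, G)[:, _trait_columns(traits)]
    X = _covariate_design(G, idx)
    rows_ok = ~np.isnan(X).any(axis=1)
    X, Yv = X[rows_ok], Yv[rows_ok]
    n, k = X.shape[0], len(idx)
    for col, name in enumerate(qtl_markers):
        if np.ptp(X[:, col + 1]) == 0:
            raise ValidationError(f"marker {name!r} is monomorphic in the usable lines")
    if np.linalg.matrix_rank(X) < k + 1:
        for a in range(k):
            for b in range(a + 1, k):
                sub = X[:, [0, a + 1, b + 1]]
                if np.linalg.matrix_rank(sub) < 3:
                    raise ValidationError(
                        f"markers {qtl_markers[a]!r} and {qtl_markers[b]!r} are collinear"
                    )
        raise ValidationError("retained markers are jointly collinear")
    beta, *_ = np.linalg.lstsq(X, Yv, rcond=None)
    fitted = X @ beta
    resid = Yv - fitted
    ss_res = (resid**2).sum(axis=0)
    ss_tot = ((Yv - Yv.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1 - ss_res / ss_tot, 0.0)
    dof = n - (k + 1)
    sigma2 = ss_res / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.outer(np.diag(xtx_inv)[1:], sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta[1:] / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    return EffectEstimate(
        markers=tuple(qtl_markers),
        effects=beta[1:],
        r_squared={t: float(r2[j]) for j, t in enumerate(traits)},
        univariate_p=pvals,
    )


def epistasis_test(
    Y: PhenotypeTable,
    G: GenotypeMatrix,
    qtl_markers: list[str],
    traits: tuple[str, ...] = TRAITS,
) -> tuple[float, float]:
    """Multivariate tests for interaction among retained QTL.

    Compares the purely additive model against (i) the model with all
    pairwise products of QTL genotype codes and (ii) the model with all
    higher-order products as well, via Wilks' Lambda with Rao's F.
    Returns (pairwise p, higher-order p).
    """
    if len(qtl_markers) < 2:
        raise ValidationError("epistasis test needs at least two retained markers")
    idx = [G.markers.marker_id.index(m) for m in qtl_markers]
    Yv = _align(Y, G)[:, _trait_columns(traits)]
    X_add = _covariate_design(G, idx)
    rows_ok = ~np.isnan(X_add).any(axis=1)
    X_add, Yv = X_add[rows_ok], Yv[rows_ok]
    k = len(idx)
    cols = [X_add[:, 1 + j] for j in range(k)]

    from itertools import combinations

    pair_cols = [cols[a] * cols[b] for a, b in combinations(range(k), 2)]
    X_pair = np.column_stack([X_add] + pair_cols)
    high_cols = []
    for order in range(3, k + 1):
        for combo in combinations(range(k), order):
            prod = np.ones(X_add.shape[0])
            for j in combo:
                prod = prod * cols[j]
            high_cols.append(prod)
    X_high = np.column_stack([X_pair] + high_cols) if high_cols else X_pair

    test_pair = mstats.wilks_test(Yv, X_pair, X_add)
    if np.linalg.matrix_rank(X_high) > np.linalg.matrix_rank(X_pair):
        test_high = mstats.wilks_test(Yv, X_high, X_add)
        p_high = test_high.p_value
    else:
        p_high = test_pair.p_value  # no estimable higher-order terms beyond pairs
    return test_pair.p_value, p_high
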