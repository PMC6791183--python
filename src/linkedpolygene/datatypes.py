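"""Shared domain types for the inbred-panel quantitative-genetics pipeline.

The experimental system is a cross between the C. elegans strains N2 and
CB4856.  Genotypes are homozygous biallelic calls (0 = N2 allele,
1 = CB4856 allele) on panels of inbred lines: recombinant inbred advanced
intercross lines (RIAILs) with mosaic genomes, and a ladder of near-isogenic
lines (NILs) whose CB4856 introgressions share a common right end.

The phenotype throughout is the three-dimensional "demography" vector
[S, M, N]: the proportion of sorted animals in the small (<90 um) and
medium (90-200 um) body-length bins, and the number of progeny per
founding L4 hermaphrodite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

TRAITS = ("S", "M", "N")

#: sentinel for a missing genotype call in on-disk files
MISSING_CODE = "NA"

SIMPLEX_TOL = 1e-9


class ValidationError(ValueError):
    """A record or table violates a domain-type invariant."""


@dataclass(frozen=True)
class MarkerMap:
    """Genetic and physical positions of the genotyped markers.

    Markers are listed in map order: within each chromosome both the
    genetic position (cM) and the physical position (bp, 1-based) must be
    non-decreasing.
    """

    marker_id: tuple[str, ...]
    chromosome: tuple[str, ...]
    genetic_pos: np.ndarray  # cM, float
    physical_pos: np.ndarray  # bp, int

    def __post_init__(self) -> None:
        n = len(self.marker_id)
        if not (len(self.chromosome) == len(self.genetic_pos) == len(self.physical_pos) == n):
            raise ValidationError("marker map fields have inconsistent lengths")
        if len(set(self.marker_id)) != n:
            raise ValidationError("marker ids are not unique")
        gp = np.asarray(self.genetic_pos, dtype=float)
        pp = np.asarray(self.physical_pos, dtype=np.int64)
        if np.any(gp < 0):
            raise ValidationError("genetic positions must be non-negative")
        if np.any(pp < 0):
            raise ValidationError("physical positions must be non-negative")
        for chrom in dict.fromkeys(self.chromosome):
            idx = [i for i, c in enumerate(self.chromosome) if c == chrom]
            if np.any(np.diff(gp[idx]) < 0) or np.any(np.diff(pp[idx]) < 0):
                raise ValidationError(
                    f"markers on chromosome {chrom!r} are not sorted by position"
                )
        object.__setattr__(self, "genetic_pos", gp)
        object.__setattr__(self, "physical_pos", pp)

    def __len__(self) -> int:
        return len(self.marker_id)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        return list(dict.fromkeys(self.chromosome))

    def chromosome_slices(self) -> dict[str, slice]:
        """Contiguous index slice for each chromosome (map order)."""
        out: dict[str, slice] = {}
        chrom = np.asarray(self.chromosome)
        for c in self.chromosomes:
            idx = np.flatnonzero(chrom == c)
            out[c] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chromosome": self.chromosome,
                "genetic_pos_cM": self.genetic_pos,
                "physical_pos_bp": self.physical_pos,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerMap":
        return cls(
            marker_id=tuple(str(m) for m in df["marker_id"]),
            chromosome=tuple(str(c) for c in df["chromosome"]),
            genetic_pos=df["genetic_pos_cM"].to_numpy(dtype=float),
            physical_pos=df["physical_pos_bp"].to_numpy(dtype=np.int64),
        )


@dataclass(frozen=True)
class GenotypeMatrix:
    """Homozygous biallelic calls for a panel of inbred lines.

    ``calls`` is lines x markers, float, with 0.0 = N2 allele,
    1.0 = CB4856 allele, and NaN for a missing call.  Heterozygote codes
    are rejected: the panels are fully inbred.
    """

    lines: tuple[str, ...]
    markers: MarkerMap
    calls: np.ndarray

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls, dtype=float)
        if calls.shape != (len(self.lines), len(self.markers)):
            raise ValidationError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(self.lines)} lines x {len(self.markers)} markers"
            )
        if len(set(self.lines)) != len(self.lines):
            raise ValidationError("line ids are not unique")
        ok = np.isnan(calls) | (calls == 0.0) | (calls == 1.0)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValidationError(
                f"invalid genotype code {calls[i, j]!r} for line "
                f"{self.lines[i]!r}, marker {self.markers.marker_id[j]!r} "
                "(expected 0, 1 or missing)"
            )
        object.__setattr__(self, "calls", calls)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=list(self.lines), columns=list(self.markers.marker_id))


@dataclass(frozen=True)
class TraitVector:
    """One [S, M, N] demography observation.

    On the raw scale S and M are bin proportions (S + M <= 1) and N is a
    non-negative progeny count per founding L4.  Residual-scale vectors
    (e.g. after assay-day adjustment) relax those bounds and must be
    flagged via ``residual_scale=True``.
    """

    S: float
    M: float
    N: float
    residual_scale: bool = False

    def __post_init__(self) -> None:
        for name in TRAITS:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValidationError(f"trait {name} is not finite: {v!r}")
        if not self.residual_scale:
            if not (-SIMPLEX_TOL <= self.S <= 1 + SIMPLEX_TOL):
                raise ValidationError(f"S out of [0, 1]: {self.S}")
            if not (-SIMPLEX_TOL <= self.M <= 1 + SIMPLEX_TOL):
                raise ValidationError(f"M out of [0, 1]: {self.M}")
            if self.S + self.M > 1 + SIMPLEX_TOL:
                raise ValidationError(f"S + M = {self.S + self.M} exceeds 1")
            if self.N < 0:
                raise ValidationError(f"N negative: {self.N}")

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.M, self.N], dtype=float)


@dataclass(frozen=True)
class PhenotypeTable:
    """Per-line [S, M, N] phenotypes, raw or residual scale."""

    lines: tuple[str, ...]
    values: np.ndarray  # n_lines x 3
    scale: str = "raw"  # "raw" | "residual"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape != (len(self.lines), 3):
            raise ValidationError(
                f"values shape {values.shape} inconsistent with {len(self.lines)} lines x 3 traits"
            )
        if len(set(self.lines)) != len(self.lines):
            raise ValidationError("line ids are not unique")
        if self.scale not in ("raw", "residual"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if not np.isfinite(values).all():
            raise ValidationError("phenotype table contains non-finite values")
        if self.scale == "raw":
            S, M, N = values[:, 0], values[:, 1], values[:, 2]
            bad = (
                (S < -SIMPLEX_TOL)
                | (M < -SIMPLEX_TOL)
                | (S + M > 1 + SIMPLEX_TOL)
                | (N < 0)
            )
            if bad.any():
                line = self.lines[int(np.flatnonzero(bad)[0])]
                raise ValidationError(f"raw-scale trait invariant violated for line {line!r}")
        object.__setattr__(self, "values", values)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.lines), columns=list(TRAITS))


@dataclass(frozen=True)
class WellRecord:
    """One sorter assay well: design factors plus the raw trait vector."""

    strain: str
    day: str
    plate: str  # nested in day
    well: str  # well position on the plate
    passage: str  # passaging replicate, nested in strain x day
    traits: TraitVector

    def __post_init__(self) -> None:
        for name in ("strain", "day", "plate", "well", "passage"):
            if not str(getattr(self, name)):
                raise ValidationError(f"empty factor level for {name}")
        if self.traits.residual_scale:
            raise ValidationError("well records must carry raw-scale traits")


def wells_to_frame(wells: Sequence[WellRecord]) -> pd.DataFrame:
    """Tabulate well records (one row per well, fixed column order)."""
    return pd.DataFrame(
        {
            "strain": [w.strain for w in wells],
            "day": [w.day for w in wells],
            "plate": [w.plate for w in wells],
            "well": [w.well for w in wells],
            "passage": [w.passage for w in wells],
            "S": [w.traits.S for w in wells],
            "M": [w.traits.M for w in wells],
            "N": [w.traits.N for w in wells],
        }
    )


# ---------------------------------------------------------------------------
# NIL ladder
# ---------------------------------------------------------------------------

def _interval_labels(n: int) -> tuple[str, ...]:
    """Interval labels a, b, c, ... (aa, ab, ... beyond 26)."""
    labels = []
    for i in range(n):
        if i < 26:
            labels.append(chr(ord("a") + i))
        else:
            labels.append(chr(ord("a") + i // 26 - 1) + chr(ord("a") + i % 26))
    return tuple(labels)


@dataclass(frozen=True)
class NILLadder:
    """A near-isogenic line ladder with a common right introgression end.

    Strain k (k = 0 .. n_intervals) carries the CB4856 allele in exactly
    the k right-most intervals, so adjacent strains differ in exactly one
    interval.  Intervals are labelled a, b, ... left to right.
    """

    n_intervals: int
    strains: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_intervals < 1:
            raise ValidationError("a ladder needs at least one interval")
        if not self.strains:
            object.__setattr__(
                self,
                "strains",
                tuple(f"NIL{k:02d}" for k in range(self.n_intervals + 1)),
            )
        if len(self.strains) != self.n_intervals + 1:
            raise ValidationError(
                f"{len(self.strains)} strains inconsistent with {self.n_intervals} intervals"
            )
        if len(set(self.strains)) != len(self.strains):
            raise ValidationError("strain ids are not unique")

    @property
    def interval_labels(self) -> tuple[str, ...]:
        return _interval_labels(self.n_intervals)

    def membership(self) -> np.ndarray:
        """(n_strains x n_intervals) 0/1 matrix of carried CB4856 intervals.

        Column i is interval i counted from the left; strain k carries the
        k right-most intervals.
        """
        m = self.n_intervals
        out = np.zeros((m + 1, m), dtype=int)
        for k in range(m + 1):
            if k:
                out[k, m - k :] = 1
        return out

    def carriers_of(self, interval_index: int) -> tuple[int, int]:
        """(strain lacking only this interval, strain carrying up to it).

        ``interval_index`` counts from the left (0-based).  The returned
        pair of ladder ranks differs in exactly that interval.
        """
        m = self.n_intervals
        if not 0 <= interval_index < m:
            raise IndexError(interval_index)
        k_with = m - interval_index
        return k_with - 1, k_with


@dataclass(frozen=True)
class EffectLadder:
    """Signed per-interval effect vectors for a NIL ladder, left to right.

    Effects are in the CB4856 direction: the phenotypic change caused by
    substituting the CB4856 allele into that interval.  ``effects`` is
    (n_intervals x 3) for the full [S, M, N] vector; a univariate ladder
    for a chosen trait is obtained with :meth:`trait_effects`.
    """

    effects: np.ndarray  # n_intervals x 3
    labels: tuple[str, ...] = ()
    orientation: str = "right-anchored"

    def __post_init__(self) -> None:
        eff = np.atleast_2d(np.asarray(self.effects, dtype=float))
        if eff.shape[1] != 3:
            raise ValidationError("effect ladder must hold 3-d [S, M, N] effect vectors")
        if not self.labels:
            object.__setattr__(self, "labels", _interval_labels(eff.shape[0]))
        if len(self.labels) != eff.shape[0]:
            raise ValidationError("label count does not match effect count")
        object.__setattr__(self, "effects", eff)

    @property
    def n_intervals(self) -> int:
        return self.effects.shape[0]

    def trait_effects(self, trait: str = "N") -> np.ndarray:
        """The scalar effect sequence for one trait (default progeny number)."""
        if trait not in TRAITS:
            raise ValidationError(f"unknown trait {trait!r}")
        return self.effects[:, TRAITS.index(trait)].copy()


# ---------------------------------------------------------------------------
# Result containers (filled by the analysis modules)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanProfile:
    """Per-marker multivariate marker-regression statistics for one scan."""

    table: pd.DataFrame
    # columns: marker_id, wilks_lambda, F, df1, df2, p, neglog10_p, flagged

    COLUMNS = ("marker_id", "wilks_lambda", "F", "df1", "df2", "p", "neglog10_p", "flagged")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValidationError(f"scan profile missing columns {sorted(missing)}")


@dataclass(frozen=True)
class QTLModel:
    """Forward-search result: retained markers and the joint additive fit."""

    markers: tuple[str, ...]  # in order of retention
    effects: np.ndarray  # n_qtl x 3, CB4856-direction effect vectors
    thresholds: tuple[float, ...]  # -log10 p threshold used at each accepted scan
    r_squared: dict[str, float]  # per-trait variance explained by the joint model
    univariate_significant: dict[str, tuple[bool, ...]]  # trait -> per-QTL nominal flags
    statistic: str = "wilks"
    alpha: float = 0.05
    n_permutations: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        eff = np.asarray(self.effects, dtype=float).reshape(len(self.markers), 3)
        if len(set(self.markers)) != len(self.markers):
            raise ValidationError("retained markers are not distinct")
        if any(t <= 0 for t in self.thresholds):
            raise ValidationError("thresholds must be positive")
        for t, r2 in self.r_squared.items():
            if not -1e-12 <= r2 <= 1 + 1e-12:
                raise ValidationError(f"R^2 for {t} out of [0, 1]: {r2}")
        object.__setattr__(self, "effects", eff)

    @property
    def n_qtl(self) -> int:
        return len(self.markers)


@dataclass(frozen=True)
class IntervalTestTable:
    """Per-interval pairwise MANOVA results for a NIL ladder."""

    table: pd.DataFrame
    family_alpha: float = 0.05
    bonferroni_threshold: float | None = None

    COLUMNS = (
        "interval",
        "strain_lo",
        "strain_hi",
        "wilks_lambda",
        "p_perm",
        "bonferroni_significant",
        "p_perm_S",
        "p_perm_M",
        "p_perm_N",
        "effect_S",
        "effect_M",
        "effect_N",
    )

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValidationError(f"interval table missing columns {sorted(missing)}")


@dataclass(frozen=True)
class ArrangementResult:
    """Outcome of the interval-effect arrangement permutation test."""

    observed_variance: float
    null_variances: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None
    two_sided: bool = False

    def __post_init__(self) -> None:
        if self.observed_variance < 0:
            raise ValidationError("variance cannot be negative")
        if not 0 < self.p_value <= 1:
            raise ValidationError(f"p-value out of (0, 1]: {self.p_value}")
        object.__setattr__(
            self, "null_variances", np.asarray(self.null_variances, dtype=float)
        )


@dataclass(frozen=True)
class PolygenySummary:
    """Distribution of simulated across-line phenotypic variances."""

    variances: np.ndarray  # one per simulation
    mean_variance: float
    observed_variance: float | None = None
    mean_ratio: float | None = None
    fraction_at_or_below_observed: float | None = None
    n_qtl: int | None = None
    h2: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        var = np.asarray(self.variances, dtype=float)
        if np.any(var < 0):
            raise ValidationError("simulated variances must be non-negative")
        object.__setattr__(self, "variances", var)


def dataclass_to_jsonable(obj):
    """Recursively convert a result dataclass to JSON-serializable data."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: dataclass_to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: dataclass_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [dataclass_to_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    return obj
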