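"""Synthetic study generator.

Emulates the three data layers the analyses consume, so the whole
pipeline is testable without any raw sorter data:

* RIAIL genotypes — mosaic N2/CB4856 genomes simulated as a first-order
  Markov chain along each chromosome with Haldane recombination
  fractions and a map-expansion multiplier for the advanced-intercross
  history (the panel accumulates extra crossovers relative to an F2 map).
* the NIL ladder — 16 strains whose CB4856 introgressions share a common
  right end, defining 15 nested intervals.
* well-level phenotypes — the [S, M, N] demography vector with random
  effects for assay day, plate (nested in day), well position and
  passaging replicate, on a latent scale mapped into the (S, M)
  proportion simplex by an inverse additive-log-ratio transform.

All generators take explicit integer seeds; independent substreams are
derived with fixed spawn keys so adding one generator never perturbs
another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    EffectLadder,
    GenotypeMatrix,
    MarkerMap,
    NILLadder,
    PhenotypeTable,
    TraitVector,
    ValidationError,
    WellRecord,
)

#: baseline (S, M, L) composition of a well under no genetic or nuisance effect
BASELINE_COMPOSITION = (0.25, 0.35, 0.40)
#: baseline progeny per founding L4
BASELINE_PROGENY = 45.0

_CHROM_NAMES = ("I", "II", "III", "IV", "V", "X")


def _rng(seed: int | None, *spawn_key: int) -> np.random.Generator:
    """A generator on a fixed substream of ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


# ---------------------------------------------------------------------------
# effect distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalEffects:
    """i.i.d. normal effect sizes, parameterized by mean and variance."""

    mean: float = -0.1
    variance: float = 8.6

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValidationError("variance must be non-negative")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.normal(self.mean, np.sqrt(self.variance), size=size)


@dataclass(frozen=True)
class UniformEffects:
    low: float = -5.0
    high: float = 5.0

    def __post_init__(self) -> None:
        if self.high < self.low:
            raise ValidationError("require low <= high")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.uniform(self.low, self.high, size=size)


@dataclass(frozen=True)
class ResampleEffects:
    """Resample effect sizes (with replacement) from an observed pool."""

    pool: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.pool) == 0:
            raise ValidationError("resampling pool is empty")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(np.asarray(self.pool, dtype=float), size=size, replace=True)


EffectDistribution = NormalEffects | UniformEffects | ResampleEffects


# ---------------------------------------------------------------------------
# marker maps and RIAIL genotypes
# ---------------------------------------------------------------------------

def default_marker_map(
    n_markers: int = 1000,
    n_chromosomes: int = 6,
    chrom_length_cM: float = 50.0,
    chrom_length_bp: int = 17_000_000,
) -> MarkerMap:
    """An evenly spaced placeholder map: six 50 cM chromosomes by default.

    The real panel's map is not part of this package's inputs; this map
    only has to carry realistic linkage structure for simulations.
    """
    if n_chromosomes > len(_CHROM_NAMES):
        names = tuple(f"chr{i + 1}" for i in range(n_chromosomes))
    else:
        names = _CHROM_NAMES[:n_chromosomes]
    per = [n_markers // n_chromosomes] * n_chromosomes
    for i in range(n_markers % n_chromosomes):
        per[i] += 1
    ids, chroms, gpos, ppos = [], [], [], []
    for c, k in zip(names, per):
        g = np.linspace(0.0, chrom_length_cM, k)
        p = np.linspace(1, chrom_length_bp, k).astype(np.int64)
        for j in range(k):
            ids.append(f"{c}_{j + 1:04d}")
            chroms.append(c)
            gpos.append(g[j])
            ppos.append(int(p[j]))
    return MarkerMap(
        marker_id=tuple(ids),
        chromosome=tuple(chroms),
        genetic_pos=np.array(gpos),
        physical_pos=np.array(ppos, dtype=np.int64),
    )


def unlinked_marker_map(n_markers: int) -> MarkerMap:
    """Every marker on its own chromosome: no linkage at all."""
    return MarkerMap(
        marker_id=tuple(f"u{j + 1:05d}" for j in range(n_markers)),
        chromosome=tuple(f"chr{j + 1}" for j in range(n_markers)),
        genetic_pos=np.zeros(n_markers),
        physical_pos=np.ones(n_markers, dtype=np.int64),
    )


@dataclass(frozen=True)
class RIAILPanelSpec:
    """Parameters of a simulated RIAIL genotype panel."""

    n_lines: int = 282
    marker_map: MarkerMap = field(default_factory=default_marker_map)
    map_expansion: float = 5.0  # advanced-intercross map expansion, lambda >= 1
    founder_allele_freq: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValidationError("need at least one line")
        if self.map_expansion < 1:
            raise ValidationError("map expansion must be >= 1")
        if not 0 < self.founder_allele_freq < 1:
            raise ValidationError("founder allele frequency must be in (0, 1)")


def simulate_riail_genotypes(spec: RIAILPanelSpec) -> GenotypeMatrix:
    """Simulate inbred mosaic genotypes as a Markov chain per chromosome.

    The first marker of each chromosome is CB4856 with probability
    ``founder_allele_freq``; between adjacent markers at genetic distance
    d cM the genotype switches with the Haldane recombination fraction
    under map expansion lambda, r = (1 - exp(-2 * lambda * d / 100)) / 2.
    Chromosomes and lines are independent.
    """
    mm = spec.marker_map
    rng = _rng(spec.seed, 0)
    calls = np.empty((spec.n_lines, len(mm)), dtype=float)
    for chrom, sl in mm.chromosome_slices().items():
        g = mm.genetic_pos[sl]
        d = np.diff(g)
        r = 0.5 * (1.0 - np.exp(-2.0 * spec.map_expansion * d / 100.0))
        k = len(g)
        first = (rng.random(spec.n_lines) < spec.founder_allele_freq).astype(int)
        if k > 1:
            switches = rng.random((spec.n_lines, k - 1)) < r
            states = (first[:, None] + np.concatenate(
                [np.zeros((spec.n_lines, 1), dtype=int), np.cumsum(switches, axis=1)],
                axis=1,
            )) % 2
        else:
            states = first[:, None]
        calls[:, sl] = states
    lines = tuple(f"RIAIL{i + 1:03d}" for i in range(spec.n_lines))
    return GenotypeMatrix(lines=lines, markers=mm, calls=calls)


def make_nil_ladder(n_intervals: int = 15) -> NILLadder:
    """A NIL ladder with ``n_intervals + 1`` strains sharing a right end."""
    return NILLadder(n_intervals=n_intervals)


# ---------------------------------------------------------------------------
# effect sets and genetic values
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSet:
    """Effects assigned to a subset of markers of a genotype panel."""

    marker_indices: np.ndarray  # distinct indices, int
    effects: np.ndarray  # (n,) scalar or (n, 3) [S, M, N] effects
    distribution: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.marker_indices, dtype=int)
        eff = np.asarray(self.effects, dtype=float)
        if len(np.unique(idx)) != idx.size:
            raise ValidationError("effect marker indices must be distinct")
        if eff.shape[0] != idx.size:
            raise ValidationError("effect count must equal index count")
        object.__setattr__(self, "marker_indices", idx)
        object.__setattr__(self, "effects", eff)

    @property
    def n_qtl(self) -> int:
        return self.marker_indices.size


def draw_effects(
    genotypes: GenotypeMatrix,
    n_qtl: int,
    distribution: EffectDistribution,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EffectSet:
    """Assign i.i.d. effects to ``n_qtl`` distinct markers chosen uniformly."""
    m = genotypes.n_markers
    if n_qtl > m:
        raise ValidationError(f"cannot place {n_qtl} QTL on {m} markers")
    if rng is None:
        rng = _rng(seed, 1)
    idx = rng.choice(m, size=n_qtl, replace=False) if n_qtl else np.empty(0, dtype=int)
    eff = distribution.draw(rng, n_qtl)
    return EffectSet(
        marker_indices=np.sort(idx),
        effects=eff,
        distribution=repr(distribution),
        seed=seed,
    )


def genetic_values(genotypes: GenotypeMatrix, effects: EffectSet) -> np.ndarray:
    """Additive genetic values: value(line) = sum_j effect_j * call(line, j).

    Lines with a missing call at any effect marker are flagged by NaN.
    Returns shape (n_lines,) for scalar effects, (n_lines, 3) for
    [S, M, N] effect vectors.
    """
    idx = effects.marker_indices
    if idx.size and idx.max() >= genotypes.n_markers:
        raise ValidationError("effect marker index out of range")
    sub = genotypes.calls[:, idx]
    incomplete = np.isnan(sub).any(axis=1)
    if effects.effects.ndim == 1:
        vals = np.where(incomplete, np.nan, np.nansum(sub * effects.effects, axis=1))
        if idx.size == 0:
            vals = np.zeros(genotypes.n_lines)
            vals[incomplete] = np.nan
        return vals
    vals = np.nan_to_num(sub) @ effects.effects
    vals[incomplete] = np.nan
    return vals


def add_environment(
    values: np.ndarray, h2: float, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Add i.i.d. Gaussian noise so expected broad-sense heritability is h2.

    Noise variance is Vg * (1 - h2) / h2 per column, with Vg the sample
    variance of the genetic values; h2 = 1 returns the values unchanged.
    """
    values = np.asarray(values, dtype=float)
    if not 0 < h2 <= 1:
        raise ValidationError(f"heritability out of (0, 1]: {h2}")
    if values.shape[0] < 2:
        raise ValidationError("need at least 2 lines")
    if h2 == 1:
        return values.copy()
    vg = np.var(values, axis=0, ddof=1)
    if np.any(vg <= 0):
        raise ValidationError("zero genetic variance: cannot target h2 < 1")
    if rng is None:
        rng = _rng(seed, 2)
    sd = np.sqrt(vg * (1 - h2) / h2)
    return values + rng.normal(0.0, sd, size=values.shape)


# ---------------------------------------------------------------------------
# latent -> observable trait mapping
# ---------------------------------------------------------------------------

def latent_to_traits(latent: np.ndarray) -> np.ndarray:
    """Map latent [S, M, N] values onto the observable trait scale.

    The latent S and M components are additive-log-ratio coordinates
    (relative to the large bin) around the baseline composition; the
    inverse transform guarantees S, M >= 0 and S + M <= 1 with no
    truncation.  The latent N is an offset from the baseline progeny
    count, clamped at zero.
    """
    latent = np.atleast_2d(np.asarray(latent, dtype=float))
    bS, bM, bL = BASELINE_COMPOSITION
    zS = np.log(bS / bL) + latent[:, 0]
    zM = np.log(bM / bL) + latent[:, 1]
    denom = 1.0 + np.exp(zS) + np.exp(zM)
    out = np.empty_like(latent)
    out[:, 0] = np.exp(zS) / denom
    out[:, 1] = np.exp(zM) / denom
    out[:, 2] = np.maximum(BASELINE_PROGENY + latent[:, 2], 0.0)
    return out


# ---------------------------------------------------------------------------
# NIL assay simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssayDesign:
    """Layout and nuisance structure of a sorter assay of the NIL panel.

    Nuisance standard deviations are per trait on the latent scale
    (additive-log-ratio units for S and M, progeny for N).  Defaults give
    day-to-day shifts that dominate plate/well effects, as is typical of
    multi-day sorter experiments.
    """

    n_days: int = 3
    n_strains: int = 16
    n_passage_reps: int = 5
    n_plates_per_day: int = 10
    sd_day: tuple[float, float, float] = (0.15, 0.15, 4.0)
    sd_plate: tuple[float, float, float] = (0.05, 0.05, 1.5)
    sd_well: tuple[float, float, float] = (0.05, 0.05, 1.5)
    sd_passage: tuple[float, float, float] = (0.10, 0.10, 2.0)
    sd_resid: tuple[float, float, float] = (0.20, 0.20, 6.0)
    emulate_missingness: bool = False
    n_target: int = 2293  # retained wells when missingness is emulated
    n_well_positions: int = 96
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_days", "n_strains", "n_passage_reps", "n_plates_per_day"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("sd_day", "sd_plate", "sd_well", "sd_passage", "sd_resid"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValidationError(f"{name} must give one sd per trait")
            if np.any(v < 0):
                raise ValidationError(f"{name} must be non-negative")

    @property
    def n_wells(self) -> int:
        return self.n_days * self.n_strains * self.n_passage_reps * self.n_plates_per_day


def simulate_nil_assay(
    ladder: NILLadder,
    true_effects: EffectLadder,
    design: AssayDesign,
) -> list[WellRecord]:
    """Simulate raw well records for a NIL ladder assay.

    Each strain's latent mean is the cumulative sum of its carried
    interval effects.  Each well adds day, plate, well-position,
    passaging-replicate and residual Gaussian draws, then maps the
    latent values onto the observable scale.  Within a day, each
    (strain, passage) replicate occupies a fixed random well position
    replicated across that day's plates, mirroring the replicated-layout
    design of the assay.
    """
    if true_effects.n_intervals != ladder.n_intervals:
        raise ValidationError(
            f"{true_effects.n_intervals} effects inconsistent with "
            f"{ladder.n_intervals} ladder intervals"
        )
    if design.n_strains != ladder.n_intervals + 1:
        raise ValidationError("design n_strains must equal ladder strain count")
    rng = _rng(design.seed, 3)
    strain_means = ladder.membership() @ true_effects.effects  # (n_strains, 3)

    sd_day = np.asarray(design.sd_day, float)
    sd_plate = np.asarray(design.sd_plate, float)
    sd_well = np.asarray(design.sd_well, float)
    sd_pass = np.asarray(design.sd_passage, float)
    sd_res = np.asarray(design.sd_resid, float)

    n_pos = design.n_well_positions
    well_eff = rng.normal(0.0, sd_well, size=(n_pos, 3))

    records: list[WellRecord] = []
    n_units = design.n_strains * design.n_passage_reps
    for di in range(design.n_days):
        day_label = f"d{di + 1}"
        day_eff = rng.normal(0.0, sd_day, size=3)
        plate_eff = rng.normal(0.0, sd_plate, size=(design.n_plates_per_day, 3))
        # one well position per (strain, passage), layout shared across plates
        if n_units <= n_pos:
            positions = rng.choice(n_pos, size=n_units, replace=False)
        else:
            positions = rng.integers(0, n_pos, size=n_units)
        pass_eff = rng.normal(0.0, sd_pass, size=(n_units, 3))
        for pi in range(design.n_plates_per_day):
            resid = rng.normal(0.0, sd_res, size=(n_units, 3))
            unit = 0
            for si in range(design.n_strains):
                for ri in range(design.n_passage_reps):
                    latent = (
                        strain_means[si]
                        + day_eff
                        + plate_eff[pi]
                        + well_eff[positions[unit]]
                        + pass_eff[unit]
                        + resid[unit]
                    )
                    s, m, n = latent_to_traits(latent)[0]
                    records.append(
                        WellRecord(
                            strain=ladder.strains[si],
                            day=day_label,
                            plate=f"{day_label}p{pi + 1:02d}",
                            well=f"w{positions[unit] + 1:02d}",
                            passage=f"r{ri + 1}",
                            traits=TraitVector(S=s, M=m, N=n),
                        )
                    )
                    unit += 1
    if design.emulate_missingness:
        records = _apply_missingness(records, ladder, design, rng)
    return records


def _apply_missingness(
    records: list[WellRecord],
    ladder: NILLadder,
    design: AssayDesign,
    rng: np.random.Generator,
) -> list[WellRecord]:
    """Drop one strain on the last day, then subsample to the target count.

    Emulates the retained shape of a real multi-day assay: one strain
    present on only a subset of days, plus scattered excluded wells.
    """
    drop_strain = ladder.strains[1]
    drop_day = f"d{design.n_days}"
    kept = [r for r in records if not (r.strain == drop_strain and r.day == drop_day)]
    if len(kept) > design.n_target:
        keep_idx = np.sort(rng.choice(len(kept), size=design.n_target, replace=False))
        kept = [kept[i] for i in keep_idx]
    return kept


# ---------------------------------------------------------------------------
# RIAIL phenotype simulation (per-line, single assay each)
# ---------------------------------------------------------------------------

def simulate_riail_phenotypes(
    genotypes: GenotypeMatrix,
    effects: EffectSet,
    n_days: int = 10,
    sd_day: tuple[float, float, float] = (0.15, 0.15, 4.0),
    sd_resid: tuple[float, float, float] = (0.25, 0.25, 7.0),
    n_low_fecundity: int = 10,
    seed: int | None = None,
) -> tuple[PhenotypeTable, dict[str, str]]:
    """Raw per-line [S, M, N] phenotypes with assay-day structure.

    Each line is assayed once on one of ``n_days`` assay days.  The
    latent phenotype is genetic value + day effect + residual; a random
    subset of ``n_low_fecundity`` lines is set to <= 5 progeny per
    founder, emulating lines that fail to thrive and are filtered before
    mapping.  Returns the raw phenotype table plus per-line day labels.
    """
    rng = _rng(seed, 4)
    gv = genetic_values(genotypes, effects)
    if gv.ndim == 1:
        latent_g = np.zeros((genotypes.n_lines, 3))
        latent_g[:, 2] = gv
    else:
        latent_g = gv
    day_idx = rng.integers(0, n_days, size=genotypes.n_lines)
    day_eff = rng.normal(0.0, np.asarray(sd_day, float), size=(n_days, 3))
    resid = rng.normal(0.0, np.asarray(sd_resid, float), size=(genotypes.n_lines, 3))
    latent = latent_g + day_eff[day_idx] + resid
    traits = latent_to_traits(latent)
    if n_low_fecundity:
        low = rng.choice(genotypes.n_lines, size=n_low_fecundity, replace=False)
        traits[low, 2] = rng.uniform(0.0, 5.0, size=n_low_fecundity)
    table = PhenotypeTable(lines=genotypes.lines, values=traits, scale="raw")
    labels = {line: f"d{day_idx[i] + 1}" for i, line in enumerate(genotypes.lines)}
    return table, labels
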