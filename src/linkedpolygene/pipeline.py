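"""End-to-end orchestration: config handling, fixtures, and the full run.

A run is configured by a flat TOML file; every stochastic stage gets an
explicit seed at config resolution (derived from the master seed when
not set), so the same config always yields bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as lpio
from .datatypes import EffectLadder, ValidationError
from .arrangement import order_permutation_test
from .nil import extract_replicate_phenotypes, test_intervals
from .polygeny import PolygenicModelSpec, simulate_variance_distribution
from .scan import (
    PermutationSettings,
    adjust_for_assay_day,
    filter_low_fecundity,
    forward_search,
)
from .simulate import (
    AssayDesign,
    NormalEffects,
    RIAILPanelSpec,
    default_marker_map,
    draw_effects,
    make_nil_ladder,
    simulate_nil_assay,
    simulate_riail_genotypes,
    simulate_riail_phenotypes,
)

logger = logging.getLogger("linkedpolygene")


@dataclass
class RunConfig:
    """Resolved configuration for a pipeline run."""

    out_dir: str = "linkedpolygene_run"
    seed: int = 0

    # stage toggles
    run_fixtures: bool = True
    run_scan: bool = True
    run_nil: bool = True
    run_arrangement: bool = True
    run_polygeny: bool = True

    # optional user-supplied inputs (synthetic generation used when absent)
    genotypes_path: str | None = None
    marker_map_path: str | None = None
    phenotypes_path: str | None = None
    day_labels_path: str | None = None
    wells_path: str | None = None

    # synthetic study parameters
    n_lines: int = 282
    n_markers: int = 1000
    n_chromosomes: int = 6
    map_expansion: float = 5.0
    n_riail_qtl: int = 8
    riail_effect_sd: float = 4.0
    n_nil_intervals: int = 15
    nil_effect_sd: float = 2.9
    n_plates_per_day: int = 10

    # scan parameters
    scan_alpha: float = 0.05
    scan_n_permutations: int = 1000
    scan_seed: int | None = None

    # NIL test parameters
    nil_n_perm: int = 10_000
    nil_family_alpha: float = 0.05
    nil_seed: int | None = None

    # arrangement test parameters
    arrangement_trait: str = "N"
    arrangement_n_perm: int = 100_000
    arrangement_two_sided: bool = False
    arrangement_seed: int | None = None

    # polygeny simulation parameters
    polygeny_n_qtl: int = 600
    polygeny_mu: float = -0.1
    polygeny_sigma2: float = 8.6
    polygeny_h2: float | None = None
    polygeny_n_sims: int = 10_000
    polygeny_observed_var: float | None = None
    polygeny_seed: int | None = None

    def __post_init__(self) -> None:
        problems = []
        for name in ("scan_alpha", "nil_family_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                problems.append(f"{name} out of (0, 1): {v}")
        if self.polygeny_h2 is not None and not 0 < self.polygeny_h2 <= 1:
            problems.append(f"polygeny_h2 out of (0, 1]: {self.polygeny_h2}")
        if self.arrangement_trait not in ("S", "M", "N"):
            problems.append(f"arrangement_trait must be S, M or N: {self.arrangement_trait}")
        for name in ("n_lines", "n_markers", "n_nil_intervals", "scan_n_permutations",
                     "nil_n_perm", "arrangement_n_perm", "polygeny_n_sims"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be positive")
        if problems:
            raise ValidationError("; ".join(problems))
        # every stochastic stage gets an explicit seed
        root = np.random.SeedSequence(self.seed)
        derived = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(5)]
        if self.scan_seed is None:
            self.scan_seed = derived[0]
        if self.nil_seed is None:
            self.nil_seed = derived[1]
        if self.arrangement_seed is None:
            self.arrangement_seed = derived[2]
        if self.polygeny_seed is None:
            self.polygeny_seed = derived[3]
        self.fixtures_seed = derived[4]

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_FIELD_NAMES = {f.name for f in dataclasses.fields(RunConfig)}


def validate_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Parse and validate a TOML config file; fill defaults.

    Unknown keys and out-of-range values are rejected with every problem
    listed.  An empty (or absent) file yields the all-defaults synthetic
    run.  Keyword overrides take precedence over the file.
    """
    data: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    flat: dict = {}
    for key, value in data.items():
        if isinstance(value, dict):  # allow [section] grouping: section_key
            for sub, v in value.items():
                flat[f"{key}_{sub}"] = v
        else:
            flat[key] = value
    flat.update({k: v for k, v in overrides.items() if v is not None})
    unknown = sorted(set(flat) - _FIELD_NAMES)
    if unknown:
        raise ValidationError(f"unknown config keys: {unknown}")
    cfg = RunConfig(**flat)
    logger.info("resolved config (hash %s): %s", cfg.config_hash(), dataclasses.asdict(cfg))
    return cfg


def make_fixtures(cfg: RunConfig) -> dict[str, str]:
    """Write a complete synthetic study into the output directory.

    Emits RIAIL genotypes + marker map, raw RIAIL phenotypes + day
    labels, the NIL ladder and its raw well records, and the true
    simulated effect ladder (for reference).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.fixtures_seed
    mm = default_marker_map(n_markers=cfg.n_markers, n_chromosomes=cfg.n_chromosomes)
    geno = simulate_riail_genotypes(
        RIAILPanelSpec(
            n_lines=cfg.n_lines, marker_map=mm, map_expansion=cfg.map_expansion, seed=seed
        )
    )
    qtl_effects = draw_effects(
        geno, cfg.n_riail_qtl, NormalEffects(mean=0.0, variance=cfg.riail_effect_sd**2),
        seed=seed,
    )
    phen, day_labels = simulate_riail_phenotypes(geno, qtl_effects, seed=seed)

    ladder = make_nil_ladder(cfg.n_nil_intervals)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    signs = rng.choice([-1.0, 1.0], size=cfg.n_nil_intervals)
    mag = np.abs(rng.normal(0.0, cfg.nil_effect_sd, size=cfg.n_nil_intervals))
    nil_effects = np.zeros((cfg.n_nil_intervals, 3))
    nil_effects[:, 2] = signs * mag
    nil_effects[:, 0] = rng.normal(0.0, 0.05, size=cfg.n_nil_intervals)
    nil_effects[:, 1] = rng.normal(0.0, 0.05, size=cfg.n_nil_intervals)
    true_ladder = EffectLadder(effects=nil_effects)
    design = AssayDesign(
        n_strains=cfg.n_nil_intervals + 1,
        n_plates_per_day=cfg.n_plates_per_day,
        seed=seed,
    )
    wells = simulate_nil_assay(ladder, true_ladder, design)

    paths = {
        "genotypes": str(out / "riail_genotypes.tsv"),
        "marker_map": str(out / "marker_map.tsv"),
        "phenotypes": str(out / "riail_phenotypes.csv"),
        "day_labels": str(out / "riail_day_labels.csv"),
        "wells": str(out / "nil_wells.csv"),
        "nil_ladder": str(out / "nil_ladder.json"),
        "true_effect_ladder": str(out / "true_effect_ladder.json"),
    }
    lpio.write_genotypes(geno, paths["genotypes"], paths["marker_map"])
    lpio.write_phenotypes(phen, paths["phenotypes"])
    lpio.write_day_labels(day_labels, paths["day_labels"])
    lpio.write_well_records(wells, paths["wells"])
    lpio.write_results(ladder, paths["nil_ladder"])
    lpio.write_results(true_ladder, paths["true_effect_ladder"])
    logger.info("fixtures written to %s", out)
    return paths


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages and return a structured run report.

    Stage order: fixtures -> RIAIL scan -> NIL pipeline -> arrangement
    test -> polygeny simulation.  Intermediate artifacts are written
    into the output directory; a failing stage halts the run with the
    stage named, retaining earlier outputs.
    """
    logging.basicConfig(
        stream=sys.stderr, level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": [],
        "stage_seeds": {
            "scan": cfg.scan_seed,
            "nil": cfg.nil_seed,
            "arrangement": cfg.arrangement_seed,
            "polygeny": cfg.polygeny_seed,
            "fixtures": cfg.fixtures_seed,
        },
    }
    paths = {
        "genotypes": cfg.genotypes_path,
        "marker_map": cfg.marker_map_path,
        "phenotypes": cfg.phenotypes_path,
        "day_labels": cfg.day_labels_path,
        "wells": cfg.wells_path,
        "nil_ladder": None,
    }

    def _stage(name):
        logger.info("stage %s", name)
        report["stages"].append(name)

    try:
        if cfg.run_fixtures:
            _stage("fixtures")
            fixture_paths = make_fixtures(cfg)
            for k, v in fixture_paths.items():
                if paths.get(k) is None:
                    paths[k] = v

        geno = phen_resid = None
        if cfg.run_scan or cfg.run_polygeny:
            if not (paths["genotypes"] and paths["marker_map"]):
                raise ValidationError("genotypes required; enable fixtures or supply paths")
            geno = lpio.read_genotypes(paths["genotypes"], paths["marker_map"])

        if cfg.run_scan:
            _stage("scan")
            phen = lpio.read_phenotypes(paths["phenotypes"])
            day_labels = lpio.read_day_labels(paths["day_labels"])
            phen = filter_low_fecundity(phen)
            geno_kept = _subset_lines(geno, phen.lines)
            phen_resid = adjust_for_assay_day(phen, day_labels)
            settings = PermutationSettings(
                n_permutations=cfg.scan_n_permutations,
                genomewide_alpha=cfg.scan_alpha,
                seed=cfg.scan_seed,
            )
            model, profiles = forward_search(
                phen_resid, geno_kept, settings, return_profiles=True
            )
            lpio.write_results(model, out / "qtl_model.json")
            for i, prof in enumerate(profiles):
                lpio.write_results(prof, out / f"scan_profile_{i}.tsv")
            report["scan"] = {
                "n_lines": phen_resid.n_lines,
                "n_qtl": model.n_qtl,
                "markers": list(model.markers),
                "r_squared": model.r_squared,
            }

        ladder = effect_ladder = None
        if cfg.run_nil:
            _stage("nil")
            wells = lpio.read_well_records(paths["wells"])
            ladder = (
                lpio.read_nil_ladder(paths["nil_ladder"])
                if paths.get("nil_ladder")
                else make_nil_ladder(cfg.n_nil_intervals)
            )
            reps = extract_replicate_phenotypes(wells)
            table = test_intervals(
                reps, ladder, n_perm=cfg.nil_n_perm, seed=cfg.nil_seed,
                family_alpha=cfg.nil_family_alpha,
            )
            from .nil import interval_effect_ladder

            effect_ladder = interval_effect_ladder(reps, ladder)
            lpio.write_results(table, out / "interval_tests.tsv")
            lpio.write_results(effect_ladder, out / "effect_ladder.json")
            report["nil"] = {
                "n_wells": len(wells),
                "n_replicates": len(reps.table),
                "n_bonferroni_significant": int(
                    table.table["bonferroni_significant"].sum()
                ),
                "bonferroni_threshold": table.bonferroni_threshold,
            }

        if cfg.run_arrangement:
            _stage("arrangement")
            if effect_ladder is None:
                el_path = out / "effect_ladder.json"
                if not el_path.exists():
                    raise ValidationError("arrangement stage needs the NIL stage's effect ladder")
                effect_ladder = lpio.read_effect_ladder(el_path)
            if ladder is None:
                ladder = make_nil_ladder(effect_ladder.n_intervals)
            result = order_permutation_test(
                effect_ladder, ladder, n_perm=cfg.arrangement_n_perm,
                seed=cfg.arrangement_seed, trait=cfg.arrangement_trait,
                two_sided=cfg.arrangement_two_sided,
            )
            lpio.write_results(result, out / "arrangement_result.json")
            report["arrangement"] = {
                "trait": cfg.arrangement_trait,
                "observed_variance": result.observed_variance,
                "p_value": result.p_value,
            }

        if cfg.run_polygeny:
            _stage("polygeny")
            spec = PolygenicModelSpec(
                n_qtl=cfg.polygeny_n_qtl,
                distribution=NormalEffects(mean=cfg.polygeny_mu, variance=cfg.polygeny_sigma2),
                h2=cfg.polygeny_h2,
                n_sims=cfg.polygeny_n_sims,
                seed=cfg.polygeny_seed,
            )
            observed = cfg.polygeny_observed_var
            if observed is None and phen_resid is not None:
                observed = float(np.var(phen_resid.values[:, 2], ddof=1))
            summary = simulate_variance_distribution(geno, spec, observed)
            lpio.write_results(summary, out / "polygeny_summary.json")
            report["polygeny"] = {
                "n_qtl": spec.n_qtl,
                "mean_variance": summary.mean_variance,
                "observed_variance": summary.observed_variance,
                "mean_ratio": summary.mean_ratio,
                "fraction_at_or_below_observed": summary.fraction_at_or_below_observed,
            }
    except Exception as e:
        failing = report["stages"][-1] if report["stages"] else "setup"
        raise RuntimeError(f"pipeline halted in stage {failing!r}: {e}") from e

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("run complete: %s", out / "run_report.json")
    return report


def _subset_lines(geno, lines):
    from .datatypes import GenotypeMatrix

    keep = [i for i, ln in enumerate(geno.lines) if ln in set(lines)]
    return GenotypeMatrix(
        lines=tuple(geno.lines[i] for i in keep),
        markers=geno.markers,
        calls=geno.calls[keep],
    )
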