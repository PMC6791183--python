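"""Shared fixtures: small synthetic panels generated at test time."""

import numpy as np
import pytest

import linkedpolygene as lp
from linkedpolygene.datatypes import EffectLadder
from linkedpolygene.simulate import AssayDesign, make_nil_ladder


@pytest.fixture(scope="session")
def small_genotypes() -> lp.GenotypeMatrix:
    """60 lines x 40 unlinked balanced markers, no missing calls."""
    rng = np.random.default_rng(101)
    calls = (rng.random((60, 40)) < 0.5).astype(float)
    return lp.GenotypeMatrix(
        lines=tuple(f"L{i:03d}" for i in range(60)),
        markers=lp.unlinked_marker_map(40),
        calls=calls,
    )


@pytest.fixture(scope="session")
def nil_study():
    """A small NIL study: ladder, true effects, wells, extracted replicates.

    Session-scoped because the variance-components extraction is the
    slowest single step in the suite.
    """
    ladder = make_nil_ladder(5)
    rng = np.random.default_rng(207)
    effects = np.zeros((5, 3))
    effects[:, 2] = np.array([3.0, -2.5, 0.0, 2.0, -3.5])
    effects[:, 0] = rng.normal(0, 0.08, 5)
    effects[:, 1] = rng.normal(0, 0.08, 5)
    true_ladder = EffectLadder(effects=effects)
    design = AssayDesign(
        n_days=3,
        n_strains=6,
        n_passage_reps=4,
        n_plates_per_day=6,
        sd_day=(0.05, 0.05, 2.0),
        sd_plate=(0.02, 0.02, 0.8),
        sd_well=(0.02, 0.02, 0.8),
        sd_passage=(0.03, 0.03, 1.0),
        sd_resid=(0.08, 0.08, 3.0),
        n_well_positions=24,  # = units/day, so positions recur across days
        seed=207,
    )
    wells = lp.simulate_nil_assay(ladder, true_ladder, design)
    reps = lp.extract_replicate_phenotypes(wells)
    return {
        "ladder": ladder,
        "true_effects": true_ladder,
        "design": design,
        "wells": wells,
        "reps": reps,
    }
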