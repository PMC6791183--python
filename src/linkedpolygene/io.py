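"""Readers and writers for the on-disk representations.

Formats: genotype calls as TSV (lines x markers, header row of marker ids,
first column of line ids, missing = "NA"); marker maps as TSV; well
records and phenotype tables as CSV with fixed headers; tabular results
(scan profiles, interval tables) as TSV; nested results as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ArrangementResult,
    EffectLadder,
    GenotypeMatrix,
    IntervalTestTable,
    MarkerMap,
    MISSING_CODE,
    NILLadder,
    PhenotypeTable,
    PolygenySummary,
    QTLModel,
    ScanProfile,
    TraitVector,
    ValidationError,
    WellRecord,
    wells_to_frame,
)

WELL_HEADER = ["strain", "day", "plate", "well", "passage", "S", "M", "N"]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


# ---------------------------------------------------------------------------
# genotypes + marker map
# ---------------------------------------------------------------------------

def read_marker_map(path: str | Path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chromosome": str})
    required = {"marker_id", "chromosome", "genetic_pos_cM", "physical_pos_bp"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"marker map {path} missing columns {sorted(required - set(df.columns))}"
        )
    return MarkerMap.from_frame(df)


def write_marker_map(markers: MarkerMap, path: str | Path) -> None:
    markers.to_frame().to_csv(path, sep="\t", index=False)


def read_genotypes(path_calls: str | Path, path_map: str | Path) -> GenotypeMatrix:
    """Read a lines x markers call matrix plus its marker map.

    Marker order follows the map file; a marker-id mismatch between the
    two files is a reconciliation error.  Valid codes are 0, 1 and the
    missing sentinel "NA".
    """
    markers = read_marker_map(path_map)
    df = pd.read_csv(path_calls, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    if set(df.columns) != set(markers.marker_id):
        extra = sorted(set(df.columns) - set(markers.marker_id))
        missing = sorted(set(markers.marker_id) - set(df.columns))
        raise FormatError(
            f"marker ids disagree between calls and map (calls-only: {extra[:5]}, "
            f"map-only: {missing[:5]})"
        )
    df = df[list(markers.marker_id)]
    flat = pd.Series(df.to_numpy().ravel(), dtype="string").str.strip()
    mapping = {MISSING_CODE: np.nan, "0": 0.0, "0.0": 0.0, "1": 1.0, "1.0": 1.0}
    vals = flat.map(mapping)
    bad = vals.isna().to_numpy() & (flat != MISSING_CODE).to_numpy()
    if bad.any():
        k = int(np.flatnonzero(bad)[0])
        i, j = divmod(k, df.shape[1])
        raise FormatError(
            f"invalid genotype code {flat.iloc[k]!r} at line {df.index[i]!r}, "
            f"marker {df.columns[j]!r}"
        )
    calls = vals.to_numpy(dtype=float).reshape(df.shape)
    return GenotypeMatrix(lines=tuple(df.index), markers=markers, calls=calls)


def write_genotypes(geno: GenotypeMatrix, path_calls: str | Path, path_map: str | Path) -> None:
    write_marker_map(geno.markers, path_map)
    out = pd.DataFrame(index=list(geno.lines), columns=list(geno.markers.marker_id), dtype=object)
    calls = geno.calls
    codes = np.where(np.isnan(calls), MISSING_CODE, calls.astype(object))
    for j in range(calls.shape[1]):
        col = codes[:, j]
        out.iloc[:, j] = [MISSING_CODE if c == MISSING_CODE else str(int(c)) for c in col]
    out.to_csv(path_calls, sep="\t", index_label="line")


# ---------------------------------------------------------------------------
# well records + phenotype tables
# ---------------------------------------------------------------------------

def read_well_records(path: str | Path) -> list[WellRecord]:
    """Read raw assay wells; every row must satisfy the trait invariants."""
    df = pd.read_csv(path, dtype={c: str for c in WELL_HEADER[:5]})
    if list(df.columns) != WELL_HEADER:
        raise FormatError(f"well record file must have header {','.join(WELL_HEADER)}")
    records = []
    for i, row in df.iterrows():
        try:
            tv = TraitVector(S=float(row["S"]), M=float(row["M"]), N=float(row["N"]))
            records.append(
                WellRecord(
                    strain=row["strain"],
                    day=row["day"],
                    plate=row["plate"],
                    well=row["well"],
                    passage=row["passage"],
                    traits=tv,
                )
            )
        except ValidationError as e:
            raise ValidationError(f"row {i}: {e}") from e
    return records


def write_well_records(wells: Sequence[WellRecord], path: str | Path) -> None:
    wells_to_frame(wells).to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, dtype={"line": str})
    required = {"line", "S", "M", "N"}
    if not required.issubset(df.columns):
        raise FormatError(f"phenotype file missing columns {sorted(required - set(df.columns))}")
    scale = "raw"
    if "scale" in df.columns:
        scales = set(df["scale"])
        if len(scales) != 1:
            raise FormatError("mixed scale flags in phenotype file")
        scale = scales.pop()
    return PhenotypeTable(
        lines=tuple(df["line"]),
        values=df[["S", "M", "N"]].to_numpy(dtype=float),
        scale=scale,
    )


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    df = table.to_frame().reset_index(names="line")
    df["scale"] = table.scale
    df.to_csv(path, index=False)


def read_day_labels(path: str | Path) -> dict[str, str]:
    """Per-line assay-day labels: CSV with header line,day."""
    df = pd.read_csv(path, dtype=str)
    if not {"line", "day"}.issubset(df.columns):
        raise FormatError("day label file must have columns line,day")
    return dict(zip(df["line"], df["day"]))


def write_day_labels(labels: dict[str, str], path: str | Path) -> None:
    pd.DataFrame({"line": list(labels), "day": list(labels.values())}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# result types (dispatching writer + per-type readers)
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"  # round-trip target: 12 significant digits


def write_results(result, path: str | Path) -> None:
    """Write any pipeline result: TSV for tabular types, JSON for nested."""
    path = Path(path)
    if isinstance(result, ScanProfile):
        result.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    elif isinstance(result, IntervalTestTable):
        df = result.table.copy()
        df.attrs = {}
        with open(path, "w") as fh:
            fh.write(f"# family_alpha={result.family_alpha!r}\t")
            fh.write(f"bonferroni_threshold={result.bonferroni_threshold!r}\n")
            df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)
    elif isinstance(result, QTLModel):
        _dump_json(
            {
                "kind": "QTLModel",
                "markers": list(result.markers),
                "effects": result.effects.tolist(),
                "thresholds": list(result.thresholds),
                "r_squared": result.r_squared,
                "univariate_significant": {
                    k: list(v) for k, v in result.univariate_significant.items()
                },
                "statistic": result.statistic,
                "alpha": result.alpha,
                "n_permutations": result.n_permutations,
                "seed": result.seed,
            },
            path,
        )
    elif isinstance(result, EffectLadder):
        _dump_json(
            {
                "kind": "EffectLadder",
                "labels": list(result.labels),
                "effects": result.effects.tolist(),
                "orientation": result.orientation,
            },
            path,
        )
    elif isinstance(result, ArrangementResult):
        _dump_json(
            {
                "kind": "ArrangementResult",
                "observed_variance": result.observed_variance,
                "p_value": result.p_value,
                "n_perm": result.n_perm,
                "seed": result.seed,
                "two_sided": result.two_sided,
                "null_variances": result.null_variances.tolist(),
            },
            path,
        )
    elif isinstance(result, PolygenySummary):
        _dump_json(
            {
                "kind": "PolygenySummary",
                "mean_variance": result.mean_variance,
                "observed_variance": result.observed_variance,
                "mean_ratio": result.mean_ratio,
                "fraction_at_or_below_observed": result.fraction_at_or_below_observed,
                "n_qtl": result.n_qtl,
                "h2": result.h2,
                "seed": result.seed,
                "variances": result.variances.tolist(),
            },
            path,
        )
    elif isinstance(result, NILLadder):
        _dump_json(
            {
                "kind": "NILLadder",
                "n_intervals": result.n_intervals,
                "strains": list(result.strains),
            },
            path,
        )
    else:
        raise TypeError(f"don't know how to write a {type(result).__name__}")


def _dump_json(obj: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
        fh.write("\n")


def read_scan_profile(path: str | Path) -> ScanProfile:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str})
    df["flagged"] = df["flagged"].astype(bool)
    for col in ("wilks_lambda", "F", "df1", "df2", "p", "neglog10_p"):
        df[col] = df[col].astype(float)
    return ScanProfile(table=df)


def read_interval_table(path: str | Path) -> IntervalTestTable:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise FormatError("interval table missing metadata header line")
        meta = dict(item.split("=", 1) for item in header[1:].strip().split("\t"))
        df = pd.read_csv(fh, sep="\t", dtype={"interval": str, "strain_lo": str, "strain_hi": str})
    df["bonferroni_significant"] = df["bonferroni_significant"].astype(bool)
    thr = meta.get("bonferroni_threshold", "None")
    return IntervalTestTable(
        table=df,
        family_alpha=float(meta["family_alpha"]),
        bonferroni_threshold=None if thr == "None" else float(thr),
    )


def _load_json(path: str | Path, kind: str) -> dict:
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("kind") != kind:
        raise FormatError(f"{path} holds a {obj.get('kind')!r}, expected {kind!r}")
    return obj


def read_qtl_model(path: str | Path) -> QTLModel:
    obj = _load_json(path, "QTLModel")
    return QTLModel(
        markers=tuple(obj["markers"]),
        effects=np.asarray(obj["effects"], dtype=float).reshape(len(obj["markers"]), 3),
        thresholds=tuple(obj["thresholds"]),
        r_squared=obj["r_squared"],
        univariate_significant={k: tuple(v) for k, v in obj["univariate_significant"].items()},
        statistic=obj["statistic"],
        alpha=obj["alpha"],
        n_permutations=obj["n_permutations"],
        seed=obj["seed"],
    )


def read_effect_ladder(path: str | Path) -> EffectLadder:
    obj = _load_json(path, "EffectLadder")
    return EffectLadder(
        effects=np.asarray(obj["effects"], dtype=float),
        labels=tuple(obj["labels"]),
        orientation=obj["orientation"],
    )


def read_arrangement_result(path: str | Path) -> ArrangementResult:
    obj = _load_json(path, "ArrangementResult")
    return ArrangementResult(
        observed_variance=obj["observed_variance"],
        null_variances=np.asarray(obj["null_variances"], dtype=float),
        p_value=obj["p_value"],
        n_perm=obj["n_perm"],
        seed=obj["seed"],
        two_sided=obj["two_sided"],
    )


def read_polygeny_summary(path: str | Path) -> PolygenySummary:
    obj = _load_json(path, "PolygenySummary")
    return PolygenySummary(
        variances=np.asarray(obj["variances"], dtype=float),
        mean_variance=obj["mean_variance"],
        observed_variance=obj["observed_variance"],
        mean_ratio=obj["mean_ratio"],
        fraction_at_or_below_observed=obj["fraction_at_or_below_observed"],
        n_qtl=obj["n_qtl"],
        h2=obj["h2"],
        seed=obj["seed"],
    )


def read_nil_ladder(path: str | Path) -> NILLadder:
    obj = _load_json(path, "NILLadder")
    return NILLadder(n_intervals=obj["n_intervals"], strains=tuple(obj["strains"]))
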