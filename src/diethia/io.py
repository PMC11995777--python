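"""Delimited-text input/output for assessment bundles.

File layout (one directory per bundle, comma-separated UTF-8, header row,
period decimal separator; floats are written with ``repr`` precision so a
write/read cycle is bit-exact):

- ``population.csv``: age, sex, count, total_mortality
- ``newborns.csv``: sex, count
- ``disease_<id>.csv``: age, sex, incidence, prevalence, excess_mortality,
  acute_fatal_fraction
- ``exposure_<group>.csv``: age, sex, category, prevalence
- ``rr_<group>_<disease>.csv``: category, age_low, age_high, sex, rr,
  ci_low, ci_high
- ``exposure_<group>_categories.csv``: category, intake, adherent
- ``guidelines.csv`` (optional): food_group, rule_kind, lower, upper
- run configuration: a JSON document mirroring :class:`SimulationConfig`
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    AGE_MAX,
    N_AGES,
    N_SEXES,
    SEXES,
    DiseaseEpidemiology,
    ExposureCategory,
    ExposureModel,
    GuidelineComponent,
    InputBundle,
    PopulationStructure,
    RelativeRiskTable,
    RuleKind,
    SimulationConfig,
    validate_bundle,
)

__all__ = ["read_inputs", "write_bundle", "read_config", "write_config"]

_SEX_INDEX = {s: i for i, s in enumerate(SEXES)}


class SchemaError(ValueError):
    """A file is missing, malformed, or incomplete (names the offending cell)."""


class ValidationError(ValueError):
    """A structurally well-formed bundle violates a domain invariant."""


def _check_complete(df: pd.DataFrame, path: Path, extra_keys: list[str] | None = None) -> None:
    """Require every (age 0..95, sex) combination exactly once (per extra key)."""
    keys = ["age", "sex"] + (extra_keys or [])
    seen = set(map(tuple, df[keys].itertuples(index=False)))
    extras = sorted({t[2:] for t in seen}) if extra_keys else [()]
    for age in range(N_AGES):
        for sex in SEXES:
            for rest in extras:
                if (age, sex, *rest) not in seen:
                    raise SchemaError(
                        f"{path.name}: missing row for age {age}, sex {sex}"
                        + (f", {extra_keys[0]} {rest[0]}" if rest else "")
                    )
    if len(seen) != len(df):
        raise SchemaError(f"{path.name}: duplicate age/sex rows")


def _pivot_age_sex(df: pd.DataFrame, column: str) -> np.ndarray:
    out = np.zeros((N_AGES, N_SEXES))
    out[df["age"].to_numpy(), df["sex"].map(_SEX_INDEX).to_numpy()] = df[column].to_numpy(float)
    return out


def _read_csv(path: Path, columns: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"missing input file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
    if "sex" in df.columns:
        bad = set(df["sex"]) - set(SEXES)
        if bad:
            raise SchemaError(f"{path.name}: unknown sex values {sorted(bad)}")
    return df


def read_inputs(directory: str | Path, config: SimulationConfig | None = None) -> InputBundle:
    """Read and validate a complete input bundle from ``directory``.

    Raises :class:`SchemaError` for missing/malformed files and
    :class:`ValidationError` when the typed bundle violates an invariant.
    """
    directory = Path(directory)

    pop_df = _read_csv(directory / "population.csv", ["age", "sex", "count", "total_mortality"])
    _check_complete(pop_df, directory / "population.csv")
    nb_df = _read_csv(directory / "newborns.csv", ["sex", "count"])
    newborns = np.zeros(N_SEXES)
    newborns[nb_df["sex"].map(_SEX_INDEX).to_numpy()] = nb_df["count"].to_numpy(float)
    population = PopulationStructure(
        count=_pivot_age_sex(pop_df, "count"),
        newborns=newborns,
        total_mortality=_pivot_age_sex(pop_df, "total_mortality"),
    )

    diseases: dict[str, DiseaseEpidemiology] = {}
    for path in sorted(directory.glob("disease_*.csv")):
        disease_id = path.stem[len("disease_") :]
        df = _read_csv(
            path,
            ["age", "sex", "incidence", "prevalence", "excess_mortality", "acute_fatal_fraction"],
        )
        _check_complete(df, path)
        acute_frac = _pivot_age_sex(df, "acute_fatal_fraction")
        diseases[disease_id] = DiseaseEpidemiology(
            disease_id=disease_id,
            incidence=_pivot_age_sex(df, "incidence"),
            prevalence=_pivot_age_sex(df, "prevalence"),
            excess_mortality=_pivot_age_sex(df, "excess_mortality"),
            acute_fatal_fraction=acute_frac,
            acute=bool(np.any(acute_frac > 0)),
        )

    guidelines: dict[str, GuidelineComponent] = {}
    gpath = directory / "guidelines.csv"
    if gpath.exists():
        gdf = _read_csv(gpath, ["food_group", "rule_kind", "lower", "upper"])
        for row in gdf.itertuples(index=False):
            guidelines[row.food_group] = GuidelineComponent(
                food_group=row.food_group,
                rule_kind=RuleKind(row.rule_kind),
                lower=None if pd.isna(row.lower) else float(row.lower),
                upper=None if pd.isna(row.upper) else float(row.upper),
            )

    exposures: dict[str, ExposureModel] = {}
    for path in sorted(directory.glob("exposure_*.csv")):
        if path.stem.endswith("_categories"):
            continue
        group = path.stem[len("exposure_") :]
        cat_path = directory / f"exposure_{group}_categories.csv"
        cdf = _read_csv(cat_path, ["category", "intake", "adherent"])
        categories = [
            ExposureCategory(label=str(r.category), intake=float(r.intake), adherent=bool(r.adherent))
            for r in cdf.itertuples(index=False)
        ]
        labels = [c.label for c in categories]
        df = _read_csv(path, ["age", "sex", "category", "prevalence"])
        df["category"] = df["category"].astype(str)
        bad = set(df["category"]) - set(labels)
        if bad:
            raise SchemaError(f"{path.name}: unknown categories {sorted(bad)}")
        _check_complete(df, path, ["category"])
        prev = np.zeros((N_AGES, N_SEXES, len(labels)))
        idx = {lab: i for i, lab in enumerate(labels)}
        prev[
            df["age"].to_numpy(),
            df["sex"].map(_SEX_INDEX).to_numpy(),
            df["category"].map(idx).to_numpy(),
        ] = df["prevalence"].to_numpy(float)
        exposures[group] = ExposureModel(food_group=group, categories=categories, prevalence=prev)

    rr_tables: dict[tuple[str, str], RelativeRiskTable] = {}
    for path in sorted(directory.glob("rr_*.csv")):
        stem = path.stem[len("rr_") :]
        group = next((g for g in exposures if stem.startswith(g + "_")), None)
        if group is None:
            raise SchemaError(f"{path.name}: no matching exposure model")
        disease_id = stem[len(group) + 1 :]
        df = _read_csv(path, ["category", "age_low", "age_high", "sex", "rr", "ci_low", "ci_high"])
        df["category"] = df["category"].astype(str)
        labels = [c.label for c in exposures[group].categories]
        bands = sorted(set(zip(df["age_low"].astype(int), df["age_high"].astype(int))))
        band_idx = {b: i for i, b in enumerate(bands)}
        shape = (len(labels), len(bands), N_SEXES)
        rr = np.full(shape, np.nan)
        lo = np.full(shape, np.nan)
        hi = np.full(shape, np.nan)
        cat_idx = {lab: i for i, lab in enumerate(labels)}
        for row in df.itertuples(index=False):
            if row.category not in cat_idx:
                raise SchemaError(f"{path.name}: unknown category '{row.category}'")
            c = cat_idx[row.category]
            b = band_idx[(int(row.age_low), int(row.age_high))]
            s = _SEX_INDEX[row.sex]
            rr[c, b, s], lo[c, b, s], hi[c, b, s] = row.rr, row.ci_low, row.ci_high
        if np.any(np.isnan(rr)):
            c, b, s = map(int, np.argwhere(np.isnan(rr))[0])
            raise SchemaError(
                f"{path.name}: missing row for category '{labels[c]}', "
                f"band {bands[b]}, sex {SEXES[s]}"
            )
        reference = next(
            (lab for lab in labels if np.allclose(rr[cat_idx[lab]], 1) and np.allclose(hi[cat_idx[lab]], 1)),
            labels[0],
        )
        rr_tables[(group, disease_id)] = RelativeRiskTable(
            food_group=group,
            disease_id=disease_id,
            category_labels=labels,
            bands=bands,
            rr=rr,
            ci_low=lo,
            ci_high=hi,
            reference_category=reference,
        )

    bundle = InputBundle(
        population=population,
        diseases=diseases,
        exposures=exposures,
        rr_tables=rr_tables,
        guidelines=guidelines,
    )
    problems = validate_bundle(bundle)
    if problems:
        raise ValidationError("invalid input bundle:\n" + "\n".join(problems))
    return bundle



def _to_csv(df: pd.DataFrame, path: Path) -> None:
    """Write with ``repr`` float formatting so values round-trip bit-exactly."""
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def _age_sex_frame(**arrays: np.ndarray) -> pd.DataFrame:
    rows = []
    for age in range(N_AGES):
        for s, sex in enumerate(SEXES):
            rows.append({"age": age, "sex": sex, **{k: v[age, s] for k, v in arrays.items()}})
    return pd.DataFrame(rows)


def write_bundle(bundle: InputBundle, directory: str | Path) -> None:
    """Write a bundle to ``directory`` in the documented CSV layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pop = bundle.population
    _to_csv(
        _age_sex_frame(count=pop.count, total_mortality=pop.total_mortality),
        directory / "population.csv",
    )
    _to_csv(pd.DataFrame({"sex": list(SEXES), "count": pop.newborns}), directory / "newborns.csv")
    for disease_id, dis in bundle.diseases.items():
        _to_csv(
            _age_sex_frame(
                incidence=dis.incidence,
                prevalence=dis.prevalence,
                excess_mortality=dis.excess_mortality,
                acute_fatal_fraction=dis.acute_fatal_fraction,
            ),
            directory / f"disease_{disease_id}.csv",
        )
    for group, exp in bundle.exposures.items():
        _to_csv(
            pd.DataFrame(
                {
                    "category": [c.label for c in exp.categories],
                    "intake": [c.intake for c in exp.categories],
                    "adherent": [c.adherent for c in exp.categories],
                }
            ),
            directory / f"exposure_{group}_categories.csv",
        )
        rows = []
        for age in range(N_AGES):
            for s, sex in enumerate(SEXES):
                for k, cat in enumerate(exp.categories):
                    rows.append(
                        {"age": age, "sex": sex, "category": cat.label, "prevalence": exp.prevalence[age, s, k]}
                    )
        _to_csv(pd.DataFrame(rows), directory / f"exposure_{group}.csv")
    for (group, disease_id), table in bundle.rr_tables.items():
        rows = []
        for c, lab in enumerate(table.category_labels):
            for b, (lo_age, hi_age) in enumerate(table.bands):
                for s, sex in enumerate(SEXES):
                    rows.append(
                        {
                            "category": lab,
                            "age_low": lo_age,
                            "age_high": hi_age,
                            "sex": sex,
                            "rr": table.rr[c, b, s],
                            "ci_low": table.ci_low[c, b, s],
                            "ci_high": table.ci_high[c, b, s],
                        }
                    )
        _to_csv(pd.DataFrame(rows), directory / f"rr_{group}_{disease_id}.csv")
    if bundle.guidelines:
        _to_csv(
            pd.DataFrame(
                [
                    {
                        "food_group": g.food_group,
                        "rule_kind": g.rule_kind.value,
                        "lower": g.lower,
                        "upper": g.upper,
                    }
                    for g in bundle.guidelines.values()
                ]
            ),
            directory / "guidelines.csv",
        )


def read_config(path: str | Path) -> SimulationConfig:
    with open(path, encoding="utf-8") as fh:
        return SimulationConfig.model_validate(json.load(fh))


def write_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(config.model_dump(), fh, indent=2)
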