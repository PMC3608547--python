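"""Data model and ingestion for comparative effect-size tables.

One row of a dataset is one reported effect size together with its
taxonomic position (class / family / species / study), two-level study
moderators, and species-level covariates (multiple paternity, cost and
benefit effect sizes, proportion of male care).  Taxonomy must nest: a
species belongs to exactly one family and a family to one class.

Design matrices follow the coding used throughout the analyses:
two-level factors become -1/+1 columns, covariates are Z-transformed
(mean 0, SD 1 over the observed values) with missing cells imputed to 0
on the standardised scale, and interaction columns are products of the
coded main-effect columns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .effects import EffectSize, TestStatistic, statistic_to_r, two_tailed_p, zr_variance

__all__ = [
    "EffectRecord",
    "DesignMatrixBundle",
    "CSV_COLUMNS",
    "MODERATORS",
    "COVARIATES",
    "load_dataset",
    "records_from_dataframe",
    "records_to_dataframe",
    "build_design",
    "species_summary",
    "dataset_profile",
]

logger = logging.getLogger(__name__)

#: canonical CSV schema, one row per effect size
CSV_COLUMNS = [
    "effect_id", "study_id", "species", "family", "class",
    "stat_kind", "stat_value", "df1", "df2", "n", "sign", "r_reported",
    "care_measure", "design", "genetic", "female_access", "competitor",
    "test_scope", "outcome_measure",
    "multiple_paternity_pct", "pct_epo", "zr_cost", "zr_benefit",
    "prop_male_care",
]

#: two-level moderators (-1/+1 coded) and the three-level outcome factor
MODERATORS = {
    "care_measure": ("amount", "probability"),
    "design": ("experimental", "observational"),
    "genetic": ("no", "yes"),
    "female_access": ("no", "yes"),
    "competitor": ("no", "yes"),
    "test_scope": ("across", "within"),
    "outcome_measure": None,  # three-level, indicator coded
}

#: species-level covariates, standardised before modelling
COVARIATES = ("multiple_paternity", "pct_epo", "zr_cost", "zr_benefit", "prop_male_care")

DATASETS = ("adjust", "cost", "benefit")


@dataclass
class EffectRecord:
    """One dataset row: an effect size plus labels, moderators, covariates."""

    effect: EffectSize
    effect_id: str
    study_id: str
    species: str
    family: str
    tax_class: str
    dataset: str = "adjust"
    moderators: Dict[str, str] = field(default_factory=dict)
    covariates: Dict[str, Optional[float]] = field(default_factory=dict)
    statistic: Optional[TestStatistic] = None

    def __post_init__(self) -> None:
        if self.dataset not in DATASETS:
            raise ValueError(f"dataset must be one of {DATASETS}")
        mp = self.covariates.get("multiple_paternity")
        if mp is not None and not (0.0 <= mp <= 100.0):
            raise ValueError("multiple_paternity must be a percentage in [0, 100]")


@dataclass
class DesignMatrixBundle:
    """Aligned response, measurement variances, fixed-effect design and
    random-effect grouping indices ready for the Gibbs sampler."""

    response: np.ndarray
    meas_var: np.ndarray
    X: np.ndarray
    columns: List[str]
    coding: Dict[str, dict]
    groups: Dict[str, np.ndarray]
    group_labels: Dict[str, List[str]]

    @property
    def n_obs(self) -> int:
        return self.response.shape[0]

    def __post_init__(self) -> None:
        n = self.response.shape[0]
        if self.meas_var.shape[0] != n or self.X.shape[0] != n:
            raise ValueError("response, meas_var and X must have equal row counts")
        for name, idx in self.groups.items():
            if idx.shape[0] != n:
                raise ValueError(f"grouping '{name}' misaligned with response")


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    return pd.isna(value)


def _row_effect(row: pd.Series, index) -> Tuple[EffectSize, Optional[TestStatistic]]:
    """Build the EffectSize for a row from its statistic or reported r."""
    n = row.get("n")
    if _is_missing(n):
        raise ValueError(f"row {index}: sample size n is required")
    n = int(n)
    stat = None
    if not _is_missing(row.get("stat_kind")):
        sign = None if _is_missing(row.get("sign")) else int(row["sign"])
        stat = TestStatistic(
            kind=str(row["stat_kind"]),
            value=float(row["stat_value"]),
            df1=None if _is_missing(row.get("df1")) else int(row["df1"]),
            df2=None if _is_missing(row.get("df2")) else int(row["df2"]),
            n=n,
            sign=sign,
        )
        r = statistic_to_r(stat)
    elif not _is_missing(row.get("r_reported")):
        r = float(row["r_reported"])
        stat = TestStatistic(kind="r", value=r, n=n)
    else:
        raise ValueError(f"row {index}: either a test statistic or r_reported is required")
    return EffectSize.from_r(r, n), stat


def records_from_dataframe(df: pd.DataFrame, dataset: str = "adjust") -> List[EffectRecord]:
    """Convert a schema-conforming DataFrame to EffectRecords.

    Rows whose effect size cannot be constructed (n <= 3, missing
    statistic and r, unusable conversion) are dropped with a logged
    reason.  Inconsistent taxonomy nesting raises.
    """
    required = {"effect_id", "study_id", "species", "family", "class", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")

    records: List[EffectRecord] = []
    for index, row in df.iterrows():
        try:
            eff, stat = _row_effect(row, index)
        except ValueError as exc:
            logger.warning("rejecting row %s: %s", index, exc)
            continue
        moderators = {
            key: str(row[key])
            for key in MODERATORS
            if key in df.columns and not _is_missing(row.get(key))
        }
        covariates: Dict[str, Optional[float]] = {}
        for cov in COVARIATES:
            col = "multiple_paternity_pct" if cov == "multiple_paternity" else cov
            if col in df.columns:
                covariates[cov] = None if _is_missing(row.get(col)) else float(row[col])
        records.append(
            EffectRecord(
                effect=eff,
                effect_id=str(row["effect_id"]),
                study_id=str(row["study_id"]),
                species=str(row["species"]),
                family=str(row["family"]),
                tax_class=str(row["class"]),
                dataset=dataset,
                moderators=moderators,
                covariates=covariates,
                statistic=stat,
            )
        )
    validate_taxonomy(records)
    return records


def load_dataset(path, dataset: str = "adjust") -> List[EffectRecord]:
    """Read a canonical CSV and return validated EffectRecords."""
    df = pd.read_csv(path)
    return records_from_dataframe(df, dataset=dataset)


def records_to_dataframe(records: Sequence[EffectRecord]) -> pd.DataFrame:
    """Serialise records back to the canonical CSV schema."""
    rows = []
    for rec in records:
        stat = rec.statistic
        row = {
            "effect_id": rec.effect_id,
            "study_id": rec.study_id,
            "species": rec.species,
            "family": rec.family,
            "class": rec.tax_class,
            "stat_kind": stat.kind if stat is not None else None,
            "stat_value": stat.value if stat is not None else None,
            "df1": stat.df1 if stat is not None else None,
            "df2": stat.df2 if stat is not None else None,
            "n": rec.effect.n,
            "sign": stat.sign if stat is not None else None,
            "r_reported": rec.effect.r,
        }
        for key in MODERATORS:
            row[key] = rec.moderators.get(key)
        for cov in COVARIATES:
            col = "multiple_paternity_pct" if cov == "multiple_paternity" else cov
            row[col] = rec.covariates.get(cov)
        rows.append(row)
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def validate_taxonomy(records: Sequence[EffectRecord]) -> None:
    """Ensure species nest in exactly one family and families in one class."""
    offenders = []
    sp_fam: Dict[str, str] = {}
    fam_cls: Dict[str, str] = {}
    for rec in records:
        prev = sp_fam.setdefault(rec.species, rec.family)
        if prev != rec.family:
            offenders.append(f"species {rec.species!r} under families {prev!r} and {rec.family!r}")
        prev = fam_cls.setdefault(rec.family, rec.tax_class)
        if prev != rec.tax_class:
            offenders.append(f"family {rec.family!r} under classes {prev!r} and {rec.tax_class!r}")
    if offenders:
        raise ValueError("inconsistent taxonomy nesting: " + "; ".join(sorted(set(offenders))))


TermSpec = Union[str, Tuple[str, str]]


def _parse_term(term: TermSpec) -> Tuple[str, ...]:
    if isinstance(term, str):
        parts = tuple(p.strip() for p in term.split(":"))
    else:
        parts = tuple(term)
    if not 1 <= len(parts) <= 2:
        raise ValueError(f"terms must be main effects or pairwise interactions, got {term!r}")
    return parts


def _main_effect_columns(
    records: Sequence[EffectRecord], name: str
) -> Tuple[List[np.ndarray], List[str], dict]:
    """Coded column(s) for one moderator or covariate plus coding metadata."""
    n = len(records)
    if name in MODERATORS and MODERATORS[name] is not None:
        lo, hi = MODERATORS[name]
        values = []
        for rec in records:
            level = rec.moderators.get(name)
            if level is None:
                raise ValueError(f"moderator {name!r} missing for effect {rec.effect_id}")
            if level not in (lo, hi):
                raise ValueError(f"moderator {name!r} has unknown level {level!r}")
            values.append(-1.0 if level == lo else 1.0)
        meta = {"type": "factor2", "levels": {lo: -1.0, hi: 1.0}}
        return [np.asarray(values)], [name], meta
    if name in MODERATORS:  # three-level factor: indicator vs alphabetical reference
        levels = sorted({rec.moderators.get(name, "") for rec in records})
        if "" in levels:
            raise ValueError(f"moderator {name!r} missing for some records")
        ref, rest = levels[0], levels[1:]
        cols = []
        for level in rest:
            cols.append(
                np.asarray([1.0 if rec.moderators[name] == level else 0.0 for rec in records])
            )
        meta = {"type": "factor_indicator", "reference": ref, "levels": levels}
        return cols, [f"{name}[{lvl}]" for lvl in rest], meta
    if name in COVARIATES:
        raw = np.array(
            [np.nan if rec.covariates.get(name) is None else rec.covariates[name] for rec in records],
            dtype=float,
        )
        observed = ~np.isnan(raw)
        if observed.sum() < 2:
            raise ValueError(f"covariate {name!r} has fewer than 2 observed values")
        mean = float(raw[observed].mean())
        sd = float(raw[observed].std(ddof=0))
        if sd == 0:
            raise ValueError(f"covariate {name!r} is constant; cannot standardise")
        col = np.zeros(n)
        col[observed] = (raw[observed] - mean) / sd
        meta = {
            "type": "covariate",
            "mean": mean,
            "sd": sd,
            "n_imputed": int((~observed).sum()),
            "imputed_mask": (~observed).tolist(),
        }
        return [col], [name], meta
    raise ValueError(f"unknown model term {name!r}")


def build_design(
    records: Sequence[EffectRecord],
    terms: Iterable[TermSpec] = (),
) -> DesignMatrixBundle:
    """Assemble the fixed-effect design and random-effect groupings.

    The model always carries an intercept.  Interaction terms
    (``"a:b"`` or ``("a", "b")``) are products of the coded/standardised
    main-effect columns; missing covariate cells are imputed to zero
    *before* products are formed, so models with and without the
    interaction stay comparable on the same rows.
    """
    if not records:
        raise ValueError("no records")
    validate_taxonomy(records)
    n = len(records)
    cols: List[np.ndarray] = [np.ones(n)]
    names: List[str] = ["intercept"]
    coding: Dict[str, dict] = {}

    main_cache: Dict[str, Tuple[List[np.ndarray], List[str]]] = {}

    def main(name: str) -> Tuple[List[np.ndarray], List[str]]:
        if name not in main_cache:
            cs, ns, meta = _main_effect_columns(records, name)
            coding[name] = meta
            main_cache[name] = (cs, ns)
        return main_cache[name]

    parsed = [_parse_term(t) for t in terms]
    for parts in parsed:
        if len(parts) == 1:
            cs, ns = main(parts[0])
            cols.extend(cs)
            names.extend(ns)
    for parts in parsed:
        if len(parts) == 2:
            (ca, na), (cb, nb) = main(parts[0]), main(parts[1])
            for col_a, name_a in zip(ca, na):
                for col_b, name_b in zip(cb, nb):
                    cols.append(col_a * col_b)
                    names.append(f"{name_a}:{name_b}")

    groups: Dict[str, np.ndarray] = {}
    group_labels: Dict[str, List[str]] = {}
    for level, attr in (
        ("class", "tax_class"),
        ("family", "family"),
        ("species", "species"),
        ("study", "study_id"),
    ):
        labels = sorted({getattr(rec, attr) for rec in records})
        lut = {lab: i for i, lab in enumerate(labels)}
        groups[level] = np.asarray([lut[getattr(rec, attr)] for rec in records], dtype=np.intp)
        group_labels[level] = labels

    return DesignMatrixBundle(
        response=np.asarray([rec.effect.zr for rec in records], dtype=float),
        meas_var=np.asarray([rec.effect.var_zr for rec in records], dtype=float),
        X=np.column_stack(cols),
        columns=names,
        coding=coding,
        groups=groups,
        group_labels=group_labels,
    )


def species_summary(records: Sequence[EffectRecord]) -> pd.DataFrame:
    """Inverse-variance weighted mean Fisher-Z per species with SE and the
    number of distinct contributing studies."""
    rows = {}
    for rec in records:
        rows.setdefault(rec.species, []).append(rec)
    out = []
    for species in sorted(rows):
        recs = rows[species]
        w = np.array([r.effect.weight for r in recs])
        z = np.array([r.effect.zr for r in recs])
        mean = float((w * z).sum() / w.sum())
        out.append(
            {
                "species": species,
                "family": recs[0].family,
                "class": recs[0].tax_class,
                "mean_zr": mean,
                "se": float(math.sqrt(1.0 / w.sum())),
                "k_effects": len(recs),
                "k_studies": len({r.study_id for r in recs}),
            }
        )
    return pd.DataFrame(out)


def dataset_profile(records: Sequence[EffectRecord], alpha: float = 0.05) -> dict:
    """Composition counts and vote-counting style summaries.

    Returns effect/study/species/family/class counts, the fraction of
    species whose (weighted and unweighted) mean Fisher-Z is positive,
    and the fraction of effects — and of studies with at least one
    effect — significant at ``alpha`` (two-tailed p reconstructed from
    the stored statistic).
    """
    summary = species_summary(records)
    unweighted = {}
    for rec in records:
        unweighted.setdefault(rec.species, []).append(rec.effect.zr)
    frac_pos_unweighted = float(
        np.mean([np.mean(v) > 0 for v in unweighted.values()])
    )
    sig_flags: List[bool] = []
    study_sig: Dict[str, bool] = {}
    for rec in records:
        if rec.statistic is None:
            continue
        p = two_tailed_p(rec.statistic)
        sig = p < alpha
        sig_flags.append(sig)
        study_sig[rec.study_id] = study_sig.get(rec.study_id, False) or sig
    return {
        "effects": len(records),
        "studies": len({r.study_id for r in records}),
        "species": len({r.species for r in records}),
        "families": len({r.family for r in records}),
        "classes": len({r.tax_class for r in records}),
        "frac_species_positive": float((summary["mean_zr"] > 0).mean()),
        "frac_species_positive_unweighted": frac_pos_unweighted,
        "frac_effects_significant": float(np.mean(sig_flags)) if sig_flags else float("nan"),
        "frac_studies_significant": (
            float(np.mean(list(study_sig.values()))) if study_sig else float("nan")
        ),
    }
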