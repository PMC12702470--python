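"""Audit reports and conversion to the analysis-ready patient dataset.

The final product of a phenotyping run is a delimited file with one row
per screened patient: a key column plus a 0/1 column per condition. A
condition is flagged present when at least one of the patient's mentions
carries a category in the configured *present* set — by default only
``ACUTE_PRESENT`` (an acute, index-admission phenotype); the *ever*
preset adds ``HISTORICAL_CHRONIC``. Negated, different-meaning and
ambiguous mentions map to absent. Patients screened but never matched
appear with flag 0 — they are the true-negative denominator for any
downstream sensitivity/specificity analysis.

Audit reports expose every instance with its context, category and the
rule that fired, optionally as a seeded uniform sample, so any exported
flag can be traced back to the exact note text that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from notepheno.context_library import CategoryLabel
from notepheno.errors import ConfigurationError
from notepheno.search import IntermediateDB

#: display order of categories in audit reports
_CATEGORY_ORDER = [
    CategoryLabel.ACUTE_PRESENT,
    CategoryLabel.HISTORICAL_CHRONIC,
    CategoryLabel.NEGATED,
    CategoryLabel.UNDER_EVALUATION,
    CategoryLabel.DIFFERENT_MEANING,
    CategoryLabel.UNCATEGORIZED,
]

_FORBIDDEN_PRESENT = {
    CategoryLabel.NEGATED,
    CategoryLabel.DIFFERENT_MEANING,
    CategoryLabel.UNCATEGORIZED,
}


@dataclass(frozen=True)
class ExportConfig:
    """How mention categories collapse to per-patient binary flags."""

    present_categories: frozenset[CategoryLabel] = frozenset({CategoryLabel.ACUTE_PRESENT})
    include_patients: str = "all"  # all screened | positive only
    audit_sample_fraction: float = 1.0
    audit_seed: int = 0
    #: map UNCATEGORIZED to absent instead of refusing to export
    uncategorized_as_absent: bool = False

    def __post_init__(self):
        bad = self.present_categories & _FORBIDDEN_PRESENT
        if bad:
            raise ConfigurationError(
                f"present_categories may not contain {sorted(c.value for c in bad)}"
            )
        if not 0.0 <= self.audit_sample_fraction <= 1.0:
            raise ConfigurationError(
                f"audit_sample_fraction must be in [0, 1], got {self.audit_sample_fraction}"
            )
        if self.include_patients not in ("all", "positive"):
            raise ConfigurationError(
                f"include_patients must be all|positive, got {self.include_patients!r}"
            )


#: acute index-admission phenotype (default)
ACUTE_CONFIG = ExportConfig()
#: "ever had the condition" phenotype
EVER_CONFIG = ExportConfig(
    present_categories=frozenset(
        {CategoryLabel.ACUTE_PRESENT, CategoryLabel.HISTORICAL_CHRONIC}
    )
)


@dataclass
class PatientPhenotype:
    """Binary flags for one patient with per-category supporting counts."""

    patient_id: str
    flags: dict[str, int] = field(default_factory=dict)
    support: dict[str, dict[str, int]] = field(default_factory=dict)


def audit_report(db: IntermediateDB, cfg: ExportConfig) -> pd.DataFrame:
    """Per-instance audit table grouped by category, optionally sampled.

    Sampling is uniform without replacement, driven by ``cfg.audit_seed``,
    so an audit is exactly reproducible. Uncategorized instances sort
    last and are flagged in the ``needs_review`` column.
    """
    rows = [
        {
            "category": x.category.value,
            "patient_id": x.patient_id,
            "note_id": x.note_id,
            "note_type": x.note_type,
            "condition": x.condition_name,
            "surface": x.surface,
            "context": " ".join(x.left_context)
            + " [" + x.surface + "] "
            + " ".join(x.right_context),
            "rule_id": x.fired_rule_id or "",
            "needs_review": x.category is CategoryLabel.UNCATEGORIZED,
            "instance_id": x.instance_id,
        }
        for x in db.instances
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "category", "patient_id", "note_id", "note_type", "condition",
            "surface", "context", "rule_id", "needs_review", "instance_id",
        ],
    )
    if cfg.audit_sample_fraction < 1.0 and len(df):
        n_keep = int(round(cfg.audit_sample_fraction * len(df)))
        rng = np.random.default_rng(cfg.audit_seed)
        keep = np.sort(rng.choice(len(df), size=n_keep, replace=False))
        df = df.iloc[keep]
    order = {c.value: i for i, c in enumerate(_CATEGORY_ORDER)}
    df = df.assign(_ord=df["category"].map(order)).sort_values(
        ["_ord", "patient_id", "note_id", "instance_id"], kind="mergesort"
    )
    return df.drop(columns="_ord").reset_index(drop=True)


def aggregate_patients(
    dbs: IntermediateDB | Sequence[IntermediateDB],
    cfg: ExportConfig,
    screened_patient_ids: Iterable[str],
) -> list[PatientPhenotype]:
    """Collapse categorized instances to one phenotype row per patient.

    Every screened patient appears exactly once; patients without any
    instance get flag 0 for every condition. Refuses to run while
    uncategorized instances remain unless ``cfg.uncategorized_as_absent``
    explicitly maps them to absent.
    """
    if isinstance(dbs, IntermediateDB):
        dbs = [dbs]
    screened = sorted(set(screened_patient_ids))
    screened_set = set(screened)
    conditions = sorted({db.condition_name for db in dbs})
    pheno = {
        pid: PatientPhenotype(
            patient_id=pid,
            flags={c: 0 for c in conditions},
            support={c: {} for c in conditions},
        )
        for pid in screened
    }
    for db in dbs:
        pending = db.uncategorized_ids()
        if pending and not cfg.uncategorized_as_absent:
            raise ConfigurationError(
                f"{len(pending)} uncategorized instances remain for "
                f"{db.condition_name!r}: finish the review, or set "
                "uncategorized_as_absent=True to map them to absent"
            )
        for x in db.instances:
            if x.patient_id not in screened_set:
                raise ConfigurationError(
                    f"instance patient {x.patient_id!r} not in the screened set"
                )
            p = pheno[x.patient_id]
            sup = p.support[x.condition_name]
            sup[x.category.value] = sup.get(x.category.value, 0) + 1
            if x.category in cfg.present_categories:
                p.flags[x.condition_name] = 1
    out = [pheno[pid] for pid in screened]
    if cfg.include_patients == "positive":
        out = [p for p in out if any(p.flags.values())]
    return out


def phenotype_frame(phenotypes: Sequence[PatientPhenotype]) -> pd.DataFrame:
    """Phenotypes as a DataFrame: key column then conditions, lexicographic."""
    conditions = sorted({c for p in phenotypes for c in p.flags})
    rows = [
        {"patient_id": p.patient_id, **{c: p.flags.get(c, 0) for c in conditions}}
        for p in phenotypes
    ]
    return pd.DataFrame(rows, columns=["patient_id", *conditions])


def write_dataset(
    phenotypes: Sequence[PatientPhenotype], path: str | Path
) -> pd.DataFrame:
    """Write the binary dataset (header + one row per patient) and return it."""
    df = phenotype_frame(phenotypes)
    df.to_csv(path, index=False, lineterminator="\n")
    return df


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read a binary flag dataset written by :func:`write_dataset`."""
    return pd.read_csv(path, dtype={"patient_id": str})


def merge_datasets(*frames: pd.DataFrame) -> pd.DataFrame:
    """Outer-join flag datasets on the patient key (column union).

    A patient missing from one input gets 0 for that input's conditions.
    """
    if not frames:
        raise ValueError("need at least one dataset")
    out = frames[0]
    for df in frames[1:]:
        overlap = (set(out.columns) & set(df.columns)) - {"patient_id"}
        if overlap:
            raise ConfigurationError(
                f"condition columns present in both inputs: {sorted(overlap)}"
            )
        out = out.merge(df, on="patient_id", how="outer", sort=False)
    cols = ["patient_id", *sorted(c for c in out.columns if c != "patient_id")]
    out = out[cols].sort_values("patient_id", kind="mergesort").reset_index(drop=True)
    flag_cols = [c for c in cols if c != "patient_id"]
    out[flag_cols] = out[flag_cols].fillna(0).astype(int)
    return out


def flags_from_frame(df: pd.DataFrame, condition: str) -> dict[str, int]:
    """Extract one condition's flag map (patient id → 0/1) from a dataset."""
    if condition not in df.columns:
        raise ConfigurationError(f"condition column {condition!r} not in dataset")
    return dict(zip(df["patient_id"].astype(str), df[condition].astype(int)))
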