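"""Per-patient molecular features and the analysis-ready patient table.

Derives CRLF2 qPCR positivity by relative quantification (2^-ddCt against
GAPDH, positive at >= 0.1% of reference-gene expression), IKZF1/CDKN2A/B
deletion and codeletion status from MLPA calls, ingests per-gene mutation
flags, joins everything with the expression-signature calls, and runs the
feature-vs-signature association report through the tests in
:mod:`phlike.stats`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cluster import PH_LIKE, SignatureCall
from .stats import ContingencyTable, TestResult, choose_test, mood_median_test

__all__ = [
    "QpcrMeasurement",
    "Crlf2Call",
    "LesionProfile",
    "PatientRecord",
    "ddct_ratio",
    "derive_codeletion",
    "assemble_patient_table",
    "feature_association_report",
    "CRLF2_POSITIVITY_PCT",
    "MRD_POSITIVITY_PCT",
]

#: CRLF2 relative expression (% of GAPDH) at or above which a sample is positive
CRLF2_POSITIVITY_PCT = 0.1
#: MRD level (%) at or above which flow-cytometry MRD is positive
MRD_POSITIVITY_PCT = 0.01

CLINICAL_COLUMNS = [
    "patient_id", "age", "sex", "wbc_e9_l", "pb_blasts_pct", "bm_blasts_pct",
    "mrd_induction", "mrd_consolidation", "os_time_years", "os_event",
    "dfs_time_years", "dfs_event", "cir_time_years", "cir_cause",
    "crlf2_ct", "gapdh_ct", "ikzf1_del", "cdkn2ab_del",
]


@dataclass(frozen=True)
class QpcrMeasurement:
    """Cycle thresholds for the target (CRLF2) and reference (GAPDH) genes."""

    ct_target: float
    ct_reference: float
    calibrator_dct: Optional[float] = None

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not math.isfinite(v) or v <= 0:
                raise ValueError("Ct values must be finite and > 0")
        if self.calibrator_dct is not None and not math.isfinite(self.calibrator_dct):
            raise ValueError("calibrator dCt must be finite")


@dataclass(frozen=True)
class Crlf2Call:
    relative_expression_pct: float
    positive: bool


@dataclass(frozen=True)
class LesionProfile:
    ikzf1_deleted: Optional[bool]
    cdkn2ab_deleted: Optional[bool]
    codeletion: Optional[bool] = None


@dataclass
class PatientRecord:
    patient_id: str
    label: str  # PH_LIKE / NON_PH_LIKE
    crlf2: Optional[Crlf2Call] = None
    lesions: Optional[LesionProfile] = None
    mutations: dict[str, bool] = field(default_factory=dict)
    mutation_annotations: dict[str, str] = field(default_factory=dict)
    mrd_induction: Optional[str] = None  # "positive" / "negative" / None
    mrd_consolidation: Optional[str] = None
    clinical: dict[str, float | str | None] = field(default_factory=dict)
    outcomes: dict[str, tuple[float, int]] = field(default_factory=dict)  # endpoint -> (time, cause)


def ddct_ratio(q: QpcrMeasurement) -> Crlf2Call:
    """Relative expression by 2^-ddCt, as a percentage of the reference gene.

    dCt = Ct_target - Ct_reference; with a calibrator, ddCt = dCt -
    dCt_calibrator, otherwise ddCt = dCt.  Relative expression is
    ``100 * 2^-ddCt`` percent and the call is positive at >= 0.1%
    (boundary inclusive).
    """
    dct = q.ct_target - q.ct_reference
    ddct = dct if q.calibrator_dct is None else dct - q.calibrator_dct
    pct = 100.0 * 2.0 ** (-ddct)
    return Crlf2Call(relative_expression_pct=pct, positive=pct >= CRLF2_POSITIVITY_PCT)


def derive_codeletion(p: LesionProfile) -> LesionProfile:
    """Fill the codeletion flag: both deleted -> True; missing propagates."""
    if p.ikzf1_deleted is None or p.cdkn2ab_deleted is None:
        co: Optional[bool] = None
    else:
        co = p.ikzf1_deleted and p.cdkn2ab_deleted
    return LesionProfile(p.ikzf1_deleted, p.cdkn2ab_deleted, co)


def _mrd_status(value) -> Optional[str]:
    """Normalize an MRD entry: status string or numeric % level."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("positive", "pos", "+"):
            return "positive"
        if v in ("negative", "neg", "-"):
            return "negative"
        if v in ("", "na", "nan", "missing"):
            return None
        value = float(v)
    return "positive" if float(value) >= MRD_POSITIVITY_PCT else "negative"


def _opt_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("", "na", "nan", "missing"):
            return None
        return v in ("1", "true", "yes", "del", "deleted")
    return bool(value)


def assemble_patient_table(
    calls: list[SignatureCall],
    clinical_tsv: str | Path,
    mutations_tsv: str | Path | None = None,
) -> tuple[list[PatientRecord], dict]:
    """Join signature calls with the clinical table and the mutation table.

    One record per patient present in the signature calls; patients in one
    source but not another are listed in the join report.  Duplicate
    patient ids in any file are an error.
    """
    clin = pd.read_csv(clinical_tsv, sep="\t", dtype={"patient_id": str})
    if clin["patient_id"].duplicated().any():
        raise ValueError("duplicate patient id in clinical table")
    clin = clin.set_index("patient_id")
    call_ids = [c.sample_id for c in calls]
    if len(set(call_ids)) != len(call_ids):
        raise ValueError("duplicate patient id in signature calls")

    mut_flags: dict[str, dict[str, bool]] = {}
    mut_ann: dict[str, dict[str, str]] = {}
    if mutations_tsv is not None:
        mut = pd.read_csv(mutations_tsv, sep="\t", dtype={"patient_id": str})
        if mut.duplicated(subset=["patient_id", "gene"]).any():
            raise ValueError("duplicate patient/gene pair in mutations table")
        for row in mut.itertuples(index=False):
            mut_flags.setdefault(row.patient_id, {})[row.gene] = bool(row.flag)
            ann = getattr(row, "annotation", None)
            if isinstance(ann, str) and ann:
                mut_ann.setdefault(row.patient_id, {})[row.gene] = ann

    records: list[PatientRecord] = []
    report = {
        "calls_without_clinical": [],
        "clinical_without_calls": sorted(set(clin.index) - set(call_ids)),
    }
    for call in calls:
        pid = call.sample_id
        if pid not in clin.index:
            report["calls_without_clinical"].append(pid)
            continue
        row = clin.loc[pid]
        rec = PatientRecord(patient_id=pid, label=call.label)
        ct_t, ct_r = row.get("crlf2_ct"), row.get("gapdh_ct")
        if pd.notna(ct_t) and pd.notna(ct_r):
            rec.crlf2 = ddct_ratio(QpcrMeasurement(float(ct_t), float(ct_r)))
        rec.lesions = derive_codeletion(
            LesionProfile(_opt_bool(row.get("ikzf1_del")), _opt_bool(row.get("cdkn2ab_del")))
        )
        rec.mutations = mut_flags.get(pid, {})
        rec.mutation_annotations = mut_ann.get(pid, {})
        rec.mrd_induction = _mrd_status(row.get("mrd_induction"))
        rec.mrd_consolidation = _mrd_status(row.get("mrd_consolidation"))
        for col in ("age", "wbc_e9_l", "pb_blasts_pct", "bm_blasts_pct"):
            v = row.get(col)
            rec.clinical[col] = float(v) if pd.notna(v) else None
        rec.clinical["sex"] = row.get("sex") if pd.notna(row.get("sex")) else None
        for endpoint, tcol, ccol in (
            ("os", "os_time_years", "os_event"),
            ("dfs", "dfs_time_years", "dfs_event"),
            ("cir", "cir_time_years", "cir_cause"),
        ):
            tv, cv = row.get(tcol), row.get(ccol)
            if pd.notna(tv) and pd.notna(cv):
                rec.outcomes[endpoint] = (float(tv), int(cv))
        records.append(rec)
    return records, report


def _binary_feature_table(values: list[Optional[bool]], phlike: list[bool]) -> Optional[ContingencyTable]:
    rows = [(v, p) for v, p in zip(values, phlike) if v is not None]
    if not rows:
        return None
    a = sum(1 for v, p in rows if p and v)
    b = sum(1 for v, p in rows if p and not v)
    c = sum(1 for v, p in rows if not p and v)
    d = sum(1 for v, p in rows if not p and not v)
    return ContingencyTable.from_cells(
        a, b, c, d,
        row_labels=("PH_LIKE", "NON_PH_LIKE"),
        col_labels=("feature+", "feature-"),
    )


def feature_association_report(records: list[PatientRecord]) -> pd.DataFrame:
    """Association of each molecular/clinical feature with the signature.

    Binary features give a 2x2 table against the Ph-like label tested with
    :func:`phlike.stats.choose_test`; quantitative features use Mood's
    median test.  Missing values are excluded per feature; features with
    no non-missing values are skipped with a warning.
    """
    labelled = [r for r in records if r.label]
    if len(labelled) < 2:
        raise ValueError("need >= 2 records with a signature label")
    phlike = [r.label == PH_LIKE for r in labelled]

    binary: dict[str, list[Optional[bool]]] = {
        "crlf2_positive": [r.crlf2.positive if r.crlf2 else None for r in labelled],
        "ikzf1_del": [r.lesions.ikzf1_deleted if r.lesions else None for r in labelled],
        "cdkn2ab_del": [r.lesions.cdkn2ab_deleted if r.lesions else None for r in labelled],
        "ikzf1_cdkn2ab_codeletion": [r.lesions.codeletion if r.lesions else None for r in labelled],
        "mrd_induction_positive": [
            None if r.mrd_induction is None else r.mrd_induction == "positive" for r in labelled
        ],
        "mrd_consolidation_positive": [
            None if r.mrd_consolidation is None else r.mrd_consolidation == "positive"
            for r in labelled
        ],
    }
    genes = sorted({g for r in labelled for g in r.mutations})
    for gene in genes:
        binary[f"mut_{gene}"] = [r.mutations.get(gene) for r in labelled]

    out = []
    for name, vals in binary.items():
        table = _binary_feature_table(vals, phlike)
        if table is None:
            warnings.warn(f"feature {name!r} all-missing; skipped")
            continue
        res: TestResult = choose_test(table)
        out.append(
            {
                "feature": name,
                "kind": "binary",
                "n": int(table.total),
                "method": res.method,
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
        )
    for name in ("wbc_e9_l", "pb_blasts_pct", "bm_blasts_pct", "age"):
        pairs = [(r.clinical.get(name), p) for r, p in zip(labelled, phlike)]
        pairs = [(v, p) for v, p in pairs if v is not None]
        g1 = [v for v, p in pairs if p]
        g0 = [v for v, p in pairs if not p]
        if not g1 or not g0:
            warnings.warn(f"feature {name!r} missing in a group; skipped")
            continue
        res = mood_median_test([g1, g0])
        out.append(
            {
                "feature": name,
                "kind": "quantitative",
                "n": len(pairs),
                "method": res.method,
                "statistic": res.statistic,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(out)
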