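"""Targeted expression-panel I/O, normalization, and QC.

The classification pipeline starts from a gene × sample matrix of raw
amplicon read counts for a 42-gene panel (38 informative genes plus four
candidate housekeeping controls: GUSB, JUN, PBGD, TBP).  This module turns
raw counts into the housekeeping-normalized matrix that downstream
clustering consumes:

    counts → RPM (reads per million) → gene/sample QC →
    housekeeping selection → per-sample division by the housekeeping gene.

Normalizing each sample to its own housekeeping value makes every later
step invariant to sequencing depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "PanelDefinition",
    "ExpressionMatrix",
    "QcReport",
    "read_counts",
    "compute_rpm",
    "filter_genes",
    "filter_samples",
    "select_housekeeping",
    "normalize_to_housekeeping",
    "DEFAULT_PANEL",
]

#: default gene/sample QC thresholds
DEFAULT_MIN_MEDIAN_RPM = 5.0
DEFAULT_MIN_TOTAL_READS = 50_000

# The 38 informative genes of the targeted panel, alphabetical.
_TARGET_GENES = (
    "ABCA9 ARHGEF12 BMPR1B CA6 CD99 CHN2 CRLF2 DCTN4 DENND3 ECM1 ENAM GAB1 "
    "GBP5 GPR110 IFITM1 IGJ IL7R LDB3 MDFIC MMP28 MUC4 NRXN3 PON2 RBM47 "
    "RNF157 S100Z SEMA6A SCHIP1 SH2B3 SLC2A5 SLC37A3 SOC2 SPATS2L TAF5L "
    "TMEM154 TP53INP1 TTYH2 WNT9A"
).split()
_HOUSEKEEPING = ("GUSB", "JUN", "PBGD", "TBP")


class PanelError(ValueError):
    """Raised for malformed panel inputs or QC-emptied matrices."""


@dataclass(frozen=True)
class PanelDefinition:
    """The gene panel: target genes, housekeeping candidates and markers.

    ``markers_up`` are genes overexpressed in the BCR-ABL1-like (Ph-like)
    subgroup; ``markers_down`` are underexpressed there.
    """

    panel_genes: tuple[str, ...]
    housekeeping_candidates: frozenset[str] = frozenset(_HOUSEKEEPING)
    markers_up: frozenset[str] = frozenset({"ECM1", "ENAM", "IGJ", "CRLF2"})
    markers_down: frozenset[str] = frozenset({"MDFIC"})

    def __post_init__(self) -> None:
        genes = set(self.panel_genes)
        if len(genes) != len(self.panel_genes):
            raise PanelError("duplicate gene in panel definition")
        if not self.housekeeping_candidates <= genes:
            raise PanelError("housekeeping candidates must be panel genes")
        if self.markers_up & self.markers_down:
            raise PanelError("a gene cannot be both an up- and a down-marker")
        if not (self.markers_up | self.markers_down) <= genes:
            raise PanelError("marker genes must be panel genes")

    @classmethod
    def default(cls) -> "PanelDefinition":
        return cls(panel_genes=tuple(_TARGET_GENES) + _HOUSEKEEPING)

    @classmethod
    def from_json(cls, path: str | Path) -> "PanelDefinition":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return cls(
            panel_genes=tuple(raw["panel_genes"]),
            housekeeping_candidates=frozenset(raw["housekeeping_candidates"]),
            markers_up=frozenset(raw["markers_up"]),
            markers_down=frozenset(raw["markers_down"]),
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "panel_genes": list(self.panel_genes),
            "housekeeping_candidates": sorted(self.housekeeping_candidates),
            "markers_up": sorted(self.markers_up),
            "markers_down": sorted(self.markers_down),
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


DEFAULT_PANEL = PanelDefinition.default()


@dataclass
class ExpressionMatrix:
    """Gene × sample matrix with a processing-stage tag.

    ``stage`` is one of ``counts`` (raw integer reads), ``rpm`` (each sample
    scaled to one million panel reads) or ``normalized`` (each sample divided
    by its housekeeping-gene value).
    """

    values: pd.DataFrame  # genes in rows, samples in columns
    stage: str

    _STAGES = ("counts", "rpm", "normalized", "log")

    def __post_init__(self) -> None:
        if self.stage not in self._STAGES:
            raise PanelError(f"unknown stage {self.stage!r}")
        if self.values.index.has_duplicates:
            raise PanelError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise PanelError("duplicate sample ids")
        if self.stage != "log" and (self.values.to_numpy() < 0).any():
            raise PanelError("negative expression values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


@dataclass
class QcReport:
    """Machine-readable record of everything QC removed and why."""

    dropped_genes: list[dict] = field(default_factory=list)
    dropped_samples: list[dict] = field(default_factory=list)
    flagged: list[dict] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def merged_with(self, other: "QcReport") -> "QcReport":
        return QcReport(
            dropped_genes=self.dropped_genes + other.dropped_genes,
            dropped_samples=self.dropped_samples + other.dropped_samples,
            flagged=self.flagged + other.flagged,
            thresholds={**self.thresholds, **other.thresholds},
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "dropped_genes": self.dropped_genes,
                    "dropped_samples": self.dropped_samples,
                    "flagged": self.flagged,
                    "thresholds": self.thresholds,
                },
                indent=2,
            ),
            encoding="utf-8",
        )


# ---------------------------------------------------------------------------
# reading


def read_counts(path: str | Path, panel: PanelDefinition) -> ExpressionMatrix:
    """Read a counts TSV (genes in rows, header of sample ids).

    The matrix is restricted to panel genes in panel order.  A panel gene
    missing from the file, a duplicated gene row, negative or non-integer
    cells, or an empty matrix are all errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise PanelError("empty count matrix")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise PanelError(f"duplicate gene row(s): {dups}")
    missing = [g for g in panel.panel_genes if g not in df.index]
    if missing:
        raise PanelError(f"panel gene absent from counts file: {missing}")
    df = df.loc[list(panel.panel_genes)]
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise PanelError("non-numeric cell in counts file")
    if (arr < 0).any():
        raise PanelError("negative count")
    if not np.allclose(arr, np.round(arr)):
        raise PanelError("non-integer count")
    return ExpressionMatrix(values=df.astype(np.int64), stage="counts")


# ---------------------------------------------------------------------------
# RPM and QC


def compute_rpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample column so panel reads total one million (RPM)."""
    if counts.stage != "counts":
        raise PanelError(f"expected counts stage, got {counts.stage}")
    totals = counts.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise PanelError(f"all-zero sample column(s): {list(zero.index)}")
    rpm = counts.values.astype(float) * 1e6 / totals
    return ExpressionMatrix(values=rpm, stage="rpm")


def filter_genes(
    rpm: ExpressionMatrix,
    panel: PanelDefinition,
    min_median_rpm: float = DEFAULT_MIN_MEDIAN_RPM,
) -> tuple[ExpressionMatrix, QcReport]:
    """Drop genes whose across-sample median RPM falls below the threshold.

    Housekeeping candidates are exempt from removal (they are needed for
    normalization) but are flagged in the report if they fail the threshold.
    """
    if min_median_rpm < 0:
        raise PanelError("min_median_rpm must be >= 0")
    report = QcReport(thresholds={"min_median_rpm": min_median_rpm})
    medians = rpm.values.median(axis=1)
    keep: list[str] = []
    for gene in rpm.gene_ids:
        low = medians[gene] < min_median_rpm
        if low and gene not in panel.housekeeping_candidates:
            report.dropped_genes.append(
                {"gene": gene, "reason": "low_median_rpm", "median_rpm": float(medians[gene])}
            )
        else:
            keep.append(gene)
            if low:
                report.flagged.append(
                    {
                        "gene": gene,
                        "reason": "housekeeping_below_median_rpm_threshold",
                        "median_rpm": float(medians[gene]),
                    }
                )
    if not [g for g in keep if g not in panel.housekeeping_candidates]:
        raise PanelError("empty panel after QC: all non-housekeeping genes removed")
    return ExpressionMatrix(values=rpm.values.loc[keep], stage=rpm.stage), report


def filter_samples(
    rpm: ExpressionMatrix,
    counts: ExpressionMatrix,
    min_total_reads: int = DEFAULT_MIN_TOTAL_READS,
) -> tuple[ExpressionMatrix, QcReport]:
    """Drop samples whose total raw panel reads fall below the threshold."""
    if set(rpm.sample_ids) != set(counts.sample_ids):
        raise PanelError("rpm and counts matrices must share sample ids")
    report = QcReport(thresholds={"min_total_reads": min_total_reads})
    totals = counts.values.sum(axis=0)
    keep = []
    for sample in rpm.sample_ids:
        if totals[sample] < min_total_reads:
            report.dropped_samples.append(
                {"sample": sample, "reason": "low_total_reads", "total_reads": int(totals[sample])}
            )
        else:
            keep.append(sample)
    if not keep:
        raise PanelError("all samples removed by QC")
    return ExpressionMatrix(values=rpm.values[keep], stage=rpm.stage), report


# ---------------------------------------------------------------------------
# housekeeping selection and normalization


def _profile_score(rpm: pd.DataFrame, candidate: str, non_candidates: list[str]) -> float:
    # mean pairwise inter-sample Spearman rho of candidate-normalized profiles
    norm = rpm.loc[non_candidates] / rpm.loc[candidate]
    rho = _sps.spearmanr(norm.to_numpy(), axis=0).statistic
    n = norm.shape[1]
    if n == 2:  # spearmanr returns a scalar for two columns
        return float(rho)
    iu = np.triu_indices(n, k=1)
    return float(np.asarray(rho)[iu].mean())


def _depth_score(rpm: pd.DataFrame, candidate: str, counts_totals: pd.Series) -> float:
    # Spearman rho of the candidate's raw profile against per-sample depth
    rho = _sps.spearmanr(rpm.loc[candidate].to_numpy(), counts_totals.to_numpy()).statistic
    return float(rho)


def select_housekeeping(
    rpm: ExpressionMatrix,
    candidates: Iterable[str] | None = None,
    panel: PanelDefinition = DEFAULT_PANEL,
    score: str = "profile",
    counts: ExpressionMatrix | None = None,
) -> tuple[str, pd.DataFrame]:
    """Pick the housekeeping gene that best harmonizes patient profiles.

    For each candidate the matrix is normalized by that candidate and the
    mean of all pairwise inter-sample Spearman correlations of the
    normalized profiles (over non-candidate genes) is the candidate's score
    (``score="profile"``, default).  ``score="depth"`` instead correlates
    the candidate's raw row with per-sample total reads.  The argmax wins;
    ties break by panel order.  A candidate with a zero value in any sample
    is unusable and scored ``-inf``.
    """
    if candidates is None:
        candidates = panel.housekeeping_candidates
    cand = [g for g in panel.panel_genes if g in set(candidates)]
    if not cand:
        raise PanelError("no housekeeping candidates supplied")
    missing = [g for g in cand if g not in rpm.gene_ids]
    if missing:
        raise PanelError(f"candidate gene(s) absent from matrix: {missing}")
    if len(rpm.sample_ids) < 3:
        raise PanelError("housekeeping selection needs at least 3 samples")
    if score not in ("profile", "depth"):
        raise PanelError(f"unknown hk score {score!r}")
    if score == "depth":
        if counts is None:
            raise PanelError("depth scoring requires the raw counts matrix")
        counts_totals = counts.values.sum(axis=0)[rpm.sample_ids]
    non_cand = [g for g in rpm.gene_ids if g not in set(cand)]
    rows = []
    for g in cand:
        usable = bool((rpm.values.loc[g] > 0).all())
        if not usable:
            s = -np.inf
        elif score == "profile":
            s = _profile_score(rpm.values, g, non_cand)
        else:
            s = _depth_score(rpm.values, g, counts_totals)
        rows.append({"gene": g, "score": s, "usable": usable})
    table = pd.DataFrame(rows).set_index("gene")
    if not table["usable"].any():
        raise PanelError("all housekeeping candidates unusable (zero values)")
    best = table["score"].idxmax()  # first occurrence wins -> panel order
    return str(best), table


def normalize_to_housekeeping(rpm: ExpressionMatrix, hk: str) -> ExpressionMatrix:
    """Divide every sample column by that sample's housekeeping value."""
    if hk not in rpm.gene_ids:
        raise PanelError(f"housekeeping gene {hk!r} not in matrix")
    hk_row = rpm.values.loc[hk]
    zero = hk_row[hk_row == 0]
    if len(zero):
        raise PanelError(
            f"housekeeping gene {hk!r} is zero in sample(s) {list(zero.index)}; "
            "drop the sample(s) or choose another housekeeping gene"
        )
    return ExpressionMatrix(values=rpm.values / hk_row, stage="normalized")
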