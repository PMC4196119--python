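"""Sample-by-feature containers, delimited-text I/O, and cohort preprocessing.

The pipeline operates on gene-level expression and copy-number matrices
(samples as rows) joined to a clinical table carrying follow-up time in
years, an event indicator, and optional per-patient covariates.  The
preprocessing steps here — robust linear scaling to the 2%/98% quantiles,
stacking of expression and copy-number blocks into one high-dimensional
vector per sample, and removal of samples censored before a minimum
follow-up — put heterogeneous molecular features on a comparable [0, 1]
scale before feature selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXPRESSION = "expression"
COPY_NUMBER = "copy_number"
_VALID_SOURCES = (EXPRESSION, COPY_NUMBER)


@dataclass
class SampleMatrix:
    """A samples x features real matrix with per-feature provenance.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Real-valued measurements; must be finite.
    sample_ids : list of str
        Unique sample identifiers, one per row.
    feature_ids : list of str
        Unique feature identifiers, one per column.
    feature_source : list of str
        Per-feature provenance tag, ``"expression"`` or ``"copy_number"``.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    feature_source: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, j = self.values.shape
        if n < 2 or j < 1:
            raise ValueError(f"need at least 2 samples and 1 feature, got {n}x{j}")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if len(self.feature_ids) != j:
            raise ValueError("feature_ids length does not match column count")
        for name, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise ValueError(f"duplicate {name} ids: {dupes}")
        if self.feature_source is None:
            self.feature_source = [EXPRESSION] * j
        self.feature_source = list(self.feature_source)
        if len(self.feature_source) != j:
            raise ValueError("feature_source length does not match column count")
        bad = sorted({s for s in self.feature_source if s not in _VALID_SOURCES})
        if bad:
            raise ValueError(f"unknown feature_source tags: {bad}")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def select_source(self, source: str) -> "SampleMatrix":
        """Slice out the columns of one provenance block."""
        idx = [i for i, s in enumerate(self.feature_source) if s == source]
        if not idx:
            raise ValueError(f"no features with source {source!r}")
        return SampleMatrix(
            self.values[:, idx],
            list(self.sample_ids),
            [self.feature_ids[i] for i in idx],
            [source] * len(idx),
        )

    def write_tsv(self, path, delimiter: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=delimiter, index_label="sample_id")


@dataclass
class ClinicalTable:
    """Per-sample survival outcomes and optional covariates.

    ``time`` is follow-up in years, ``event`` is 1 for an observed event and
    0 for right censoring.  ``covariates`` may hold named real columns
    (histological grade, molecular grade, mutation rate, age, ...) with
    missing values allowed; ``annotation`` is an optional display-only
    subtype label (e.g. PAM50) that no computation consumes.
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame | None = None
    annotation: list[str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length does not match sample_ids")
        if pd.Index(self.sample_ids).has_duplicates:
            raise ValueError("duplicate sample ids in clinical table")
        if np.any(self.time < 0):
            raise ValueError("survival times must be >= 0")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")
        if self.covariates is not None:
            self.covariates = self.covariates.set_axis(self.sample_ids, axis=0)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, keep: np.ndarray) -> "ClinicalTable":
        keep = np.asarray(keep)
        ids = [s for s, k in zip(self.sample_ids, keep) if k]
        return ClinicalTable(
            ids,
            self.time[keep],
            self.event[keep],
            self.covariates.loc[ids] if self.covariates is not None else None,
            [a for a, k in zip(self.annotation, keep) if k] if self.annotation else None,
        )


def read_sample_matrix(path, delimiter: str = "\t", source: str = EXPRESSION) -> SampleMatrix:
    """Read a delimited sample-by-feature matrix.

    The header row holds feature ids and the first column sample ids.
    Non-numeric cells (including NA) are rejected with the offending
    row/column named; duplicate ids raise.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)[1:]
    dupes = pd.Index(header)[pd.Index(header).duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate feature ids in {path}: {dupes}")
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, keep_default_na=False)
    df.columns = header
    if df.index.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    values = np.empty(df.shape, dtype=float)
    for jcol, col in enumerate(df.columns):
        try:
            values[:, jcol] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = df.index[np.nonzero(np.isnan(bad.to_numpy()))[0][0]]
            raise ValueError(
                f"non-numeric cell at sample {row!r}, feature {col!r} in {path}"
            ) from None
    return SampleMatrix(values, df.index.tolist(), df.columns.tolist(), [source] * df.shape[1])


def read_clinical_table(path, delimiter: str = "\t") -> ClinicalTable:
    """Read a clinical table with columns sample_id, time, event, <covariates...>."""
    df = pd.read_csv(path, sep=delimiter)
    required = {"sample_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    annotation = df["annotation"].astype(str).tolist() if "annotation" in df.columns else None
    cov_cols = [c for c in df.columns if c not in required and c != "annotation"]
    covariates = df[cov_cols].astype(float) if cov_cols else None
    return ClinicalTable(
        df["sample_id"].astype(str).tolist(),
        df["time"].to_numpy(float),
        df["event"].to_numpy(int),
        covariates,
        annotation,
    )


def robust_scale(m: SampleMatrix, q_low: float = 0.02, q_high: float = 0.98) -> SampleMatrix:
    """Robust linear scaling: per feature, map the ``q_low`` quantile to 0 and
    the ``q_high`` quantile to 1, then clip to [0, 1].

    Quantiles use linear interpolation of order statistics.  Clipping removes
    the influence of outliers beyond the anchor quantiles.  A constant
    feature has no scale and is mapped to all zeros (with a warning).
    """
    if not q_low < q_high:
        raise ValueError("q_low must be < q_high")
    lo = np.quantile(m.values, q_low, axis=0)
    hi = np.quantile(m.values, q_high, axis=0)
    span = hi - lo
    degenerate = span <= 0
    if degenerate.any():
        names = [m.feature_ids[i] for i in np.nonzero(degenerate)[0][:10]]
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) constant between quantile anchors, "
            f"mapped to all zeros (e.g. {names})",
            UserWarning,
        )
    safe = np.where(degenerate, 1.0, span)
    scaled = np.clip((m.values - lo) / safe, 0.0, 1.0)
    scaled[:, degenerate] = 0.0
    return SampleMatrix(scaled, list(m.sample_ids), list(m.feature_ids), list(m.feature_source))


def stack_features(expr: SampleMatrix, cna: SampleMatrix) -> SampleMatrix:
    """Stack an expression and a copy-number block into one matrix per sample.

    Samples are aligned by id (the copy-number block is reordered to the
    expression order); feature ids are prefixed by source so a gene symbol
    present in both blocks stays unique.
    """
    expr_ids, cna_ids = set(expr.sample_ids), set(cna.sample_ids)
    if expr_ids != cna_ids:
        only_expr = sorted(expr_ids - cna_ids)
        only_cna = sorted(cna_ids - expr_ids)
        raise ValueError(
            f"sample ids do not match: only in expression {only_expr}, "
            f"only in copy-number {only_cna}"
        )
    order = [cna.sample_ids.index(s) for s in expr.sample_ids]
    values = np.hstack([expr.values, cna.values[order]])
    ids = [f"expr:{f}" for f in expr.feature_ids] + [f"cna:{f}" for f in cna.feature_ids]
    source = [EXPRESSION] * expr.n_features + [COPY_NUMBER] * cna.n_features
    return SampleMatrix(values, list(expr.sample_ids), ids, source)


def filter_short_followup(
    m: SampleMatrix,
    clinical: ClinicalTable,
    min_years: float = 10.0,
    drop_all_short: bool = False,
) -> tuple[SampleMatrix, ClinicalTable]:
    """Drop samples whose follow-up is too short to inform survival endpoints.

    By default only censored samples with ``time < min_years`` are removed:
    a patient censored early carries almost no endpoint information, whereas
    a death at any time is informative.  ``drop_all_short=True`` applies the
    stricter rule of removing every sample with ``time < min_years``.
    """
    pos = {s: i for i, s in enumerate(clinical.sample_ids)}
    missing = [s for s in m.sample_ids if s not in pos]
    if missing:
        raise ValueError(f"samples missing from clinical table: {missing[:10]}")
    order = np.array([pos[s] for s in m.sample_ids])
    time, event = clinical.time[order], clinical.event[order]
    if drop_all_short:
        keep = time >= min_years
    else:
        keep = (event == 1) | (time >= min_years)
    if not keep.any() or keep.sum() < 2:
        raise ValueError("no samples survive censoring filter")
    logger.info("censoring filter removed %d of %d samples", int((~keep).sum()), len(keep))
    kept_ids = [s for s, k in zip(m.sample_ids, keep) if k]
    m_out = SampleMatrix(
        m.values[keep], kept_ids, list(m.feature_ids), list(m.feature_source)
    )
    clin_aligned = ClinicalTable(
        [clinical.sample_ids[i] for i in order],
        time,
        event,
        clinical.covariates.iloc[order] if clinical.covariates is not None else None,
        [clinical.annotation[i] for i in order] if clinical.annotation else None,
    )
    return m_out, clin_aligned.subset(keep)


def cna_frequency(cna: SampleMatrix) -> np.ndarray:
    """Per-sample copy-number alteration burden: the sum over genes of the
    absolute alteration magnitude (amplifications and deletions both count),
    with 0 meaning copy-neutral."""
    bad = sorted({s for s in cna.feature_source if s != COPY_NUMBER})
    if bad:
        raise ValueError(f"cna_frequency requires copy-number features only, found {bad}")
    return np.abs(cna.values).sum(axis=1)
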