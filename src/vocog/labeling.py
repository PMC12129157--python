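"""MMSE-based binary labels and subject manifests.

The Mini-Mental State Examination (MMSE, 0-30) is the single source of
truth for the training label: a score of 23 or lower marks the subject
as cognitively declined (label 1, CD), 24 or higher as cognitively
normal (label 0, CN).  Labels are always recomputed from the score; a
label column in a manifest is only cross-checked, never trusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

MMSE_CD_CUTOFF = 23  # score <= cutoff -> cognitively declined


class ManifestError(ValueError):
    """Raised for malformed or inconsistent subject manifests."""


@dataclass
class SubjectRecord:
    subject_id: str
    mmse: int
    label: int  # 0 = CN, 1 = CD, always derived from mmse
    wav_path: str = ""
    diagnosis: str = ""
    age: float | None = None
    sex: str | None = None
    education_years: float | None = None
    cdr: float | None = None


def label_from_mmse(mmse: int) -> int:
    """1 (CD) iff the MMSE score is 23 or lower, else 0 (CN)."""
    import numbers

    if isinstance(mmse, bool) or not isinstance(mmse, numbers.Number):
        raise TypeError(f"MMSE must be a numeric score, got {type(mmse).__name__}")
    if not float(mmse).is_integer():
        raise ValueError(f"MMSE must be an integer score, got {mmse!r}")
    mmse = int(mmse)
    if not 0 <= mmse <= 30:
        raise ValueError(f"MMSE score out of range 0-30: {mmse}")
    return 1 if mmse <= MMSE_CD_CUTOFF else 0


_OPTIONAL_COLS = ("diagnosis", "age", "sex", "education_years", "cdr")


def load_manifest(path: str | Path) -> list[SubjectRecord]:
    """Read a subject manifest CSV into records with derived labels.

    Required columns: ``subject_id``, ``wav_path``, ``mmse``.  Rows with
    missing MMSE are rejected (with their row numbers); a ``label``
    column, if present, must agree with the MMSE rule.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ManifestError(f"empty manifest: {path}") from exc
    if len(df) == 0:
        raise ManifestError(f"manifest has a header but no rows: {path}")
    required = {"subject_id", "wav_path", "mmse"}
    missing = required - set(df.columns)
    if missing:
        raise ManifestError(f"manifest {path} missing columns: {sorted(missing)}")

    bad = df.index[df["mmse"].isna()].tolist()
    if bad:
        rows = [i + 2 for i in bad]  # 1-based, counting the header line
        raise ManifestError(f"rows with missing MMSE in {path}: {rows}")

    dupes = df["subject_id"][df["subject_id"].duplicated()].unique().tolist()
    if dupes:
        raise ManifestError(f"duplicate subject_id values in {path}: {dupes}")

    labels = [label_from_mmse(m) for m in df["mmse"]]
    if "label" in df.columns:
        stated = df["label"].astype(int).tolist()
        wrong = [i + 2 for i, (a, b) in enumerate(zip(stated, labels)) if a != b]
        if wrong:
            raise ManifestError(
                f"label column inconsistent with the MMSE 23/24 rule in {path}, rows: {wrong}"
            )

    records = []
    for i, row in df.iterrows():
        extras = {}
        for col in _OPTIONAL_COLS:
            if col in df.columns and pd.notna(row[col]):
                extras[col] = row[col]
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                mmse=int(row["mmse"]),
                label=labels[i],
                wav_path=str(row["wav_path"]),
                **extras,
            )
        )
    return records
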