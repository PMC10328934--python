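"""Label space: three-character ICD-10 prefix grouping and chronicity flags.

Full ICD-10 codes are grouped under their three-character prefixes (all of
I25.x becomes the single label I25), and codes whose leading letter denotes
symptoms, external causes or health-status factors (R, U, V, W, X, Y, Z) are
excluded from the label space entirely. Each retained label is designated
chronic or acute via a Chronic Condition Indicator style mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "EXCLUDED_LETTERS",
    "group_code",
    "LabelMatrix",
    "build_label_matrix",
    "annotate_chronicity",
]

EXCLUDED_LETTERS = frozenset("RUVWXYZ")


def group_code(code: str) -> str | None:
    """Three-character prefix of a full ICD-10 code, or ``None`` if excluded.

    Dots are removed before truncation and the result is upper-cased, so
    "I25.10" -> "I25" and "a00" -> "A00". Codes starting with an excluded
    letter return ``None``. Malformed codes (no leading A-Z letter, or fewer
    than three characters after dot removal) raise ``ValueError``.
    """
    if not isinstance(code, str) or not code.strip():
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    c = code.strip().upper().replace(".", "")
    if not c[0].isalpha() or not c[0].isascii():
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    if len(c) < 3:
        raise ValueError(f"malformed ICD-10 code (too short): {code!r}")
    if c[0] in EXCLUDED_LETTERS:
        return None
    return c[:3]


@dataclass
class LabelMatrix:
    """Binary encounter-by-label matrix with aligned, ordered indices."""

    encounter_ids: list[str]
    label_ids: list[str]   # lexicographically ordered
    matrix: sp.csr_matrix  # binary
    n_dropped_rows: int = 0

    @property
    def prevalence(self) -> pd.Series:
        dense = np.asarray(self.matrix.mean(axis=0)).ravel()
        return pd.Series(dense, index=self.label_ids)

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()


def label_universe(frequent: set[str]) -> list[str]:
    """Grouped frequent codes minus excluded letters, lexicographic."""
    groups = set()
    for code in frequent:
        g = group_code(code)
        if g is not None:
            groups.add(g)
    return sorted(groups)


def build_label_matrix(
    encounter_ids: list[str],
    diagnoses: pd.DataFrame,
    labels: list[str],
    frequent: set[str] | None = None,
) -> LabelMatrix:
    """Binary matrix: entry (e, l) = 1 iff encounter e carries a frequent code
    grouped under label l.

    Rows whose labels are all zero (the encounter's only codes group to
    excluded letters) are dropped and counted in ``n_dropped_rows``.
    """
    labels = sorted(labels)
    lab_idx = {l: i for i, l in enumerate(labels)}
    dx = diagnoses[diagnoses["encounter_id"].isin(set(encounter_ids))]
    if frequent is not None:
        dx = dx[dx["icd10_code"].isin(frequent)]

    grouped = dx["icd10_code"].map(lambda c: group_code(c))
    keep = grouped.notna() & grouped.isin(lab_idx)
    pairs = pd.DataFrame(
        {"encounter_id": dx.loc[keep, "encounter_id"], "label": grouped[keep]}
    ).drop_duplicates()

    row_idx = {e: i for i, e in enumerate(encounter_ids)}
    rows = pairs["encounter_id"].map(row_idx).to_numpy()
    cols = pairs["label"].map(lab_idx).to_numpy()
    mat = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(encounter_ids), len(labels)),
    ).tocsr()
    mat.data[:] = 1.0

    nonzero = np.asarray(mat.sum(axis=1)).ravel() > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("dropping %d encounters with no retained label", n_dropped)
        kept_ids = [e for e, nz in zip(encounter_ids, nonzero) if nz]
        mat = mat[np.flatnonzero(nonzero)]
    else:
        kept_ids = list(encounter_ids)
    return LabelMatrix(kept_ids, labels, mat, n_dropped)


def annotate_chronicity(
    labels: list[str],
    cci: pd.DataFrame,
    observed_codes: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Map each label to ``"chronic"``, ``"acute"`` or ``"unknown"``.

    ``cci`` has columns (code, chronic_flag) and may contain prefixes or
    full codes. A prefix entry wins directly. Otherwise the flag is the
    majority over the cohort's observed constituent full codes
    (``observed_codes``: DataFrame with an ``icd10_code`` column, one row
    per observed event), ties resolving to chronic. Labels with no mapping
    are flagged unknown and logged — never silently defaulted.
    """
    from .labels import group_code as _gc  # self-import keeps mypy quiet

    norm = cci.copy()
    norm["code"] = norm["code"].str.upper().str.replace(".", "", regex=False)
    norm["chronic_flag"] = norm["chronic_flag"].str.lower()
    flag_by_code = dict(zip(norm["code"], norm["chronic_flag"]))

    counts: dict[str, dict[str, int]] = {}
    if observed_codes is not None:
        obs = observed_codes["icd10_code"].str.upper().str.replace(".", "", regex=False)
        for full, n in obs.value_counts().items():
            if full[0] in EXCLUDED_LETTERS:
                continue
            prefix = full[:3]
            flag = flag_by_code.get(full)
            if flag in ("chronic", "acute"):
                counts.setdefault(prefix, {"chronic": 0, "acute": 0})[flag] += int(n)

    out: dict[str, str] = {}
    for label in labels:
        direct = flag_by_code.get(label)
        if direct in ("chronic", "acute"):
            out[label] = direct
        elif label in counts:
            c = counts[label]
            out[label] = "chronic" if c["chronic"] >= c["acute"] else "acute"
        else:
            logger.warning("label %s absent from CCI mapping; flagged unknown", label)
            out[label] = "unknown"
    return out
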