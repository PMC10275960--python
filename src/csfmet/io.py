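"""Data model and TSV I/O for feature tables and injection metadata.

Two tables drive the whole pipeline:

* a **feature table** — features x injections intensity matrix, each feature
  annotated with m/z (Da), retention time (s) and ion mode, on either the raw
  or the log2 scale;
* an **injection metadata** table — one row per injection (study sample, QC,
  blank or dilution-series injection) carrying cohort, phenotype group,
  run order, demographics and longitudinal annotations.

Both are stored as plain TSV.  Missing intensities are encoded as empty
cells or ``NA`` on disk, never as ``0``: a genuine zero in a blank is
informative and must survive a round-trip.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ION_MODES = ("positive", "negative")
SAMPLE_TYPES = ("study", "qc", "blank", "dilution")
GROUPS = ("HC", "RRMS", "PMS", "TRANSITIONING")
SCALES = ("raw", "log2")

#: fixed feature-annotation columns preceding the per-injection columns
FEATURE_COLS = ("feature_id", "mz", "rt", "ion_mode")

META_COLS = (
    "injection_id",
    "subject_id",
    "cohort",
    "group",
    "sample_type",
    "dilution_volume",
    "injection_order",
    "age",
    "sex",
    "timepoint_months",
    "treated",
)


class ValidationError(ValueError):
    """A table violates one of the documented invariants."""


@dataclass
class FeatureTable:
    """Features x injections intensity matrix with feature annotations.

    Parameters
    ----------
    features
        DataFrame indexed by ``feature_id`` with columns ``mz`` (Da, > 0),
        ``rt`` (seconds, >= 0) and ``ion_mode`` (``positive``/``negative``).
    values
        DataFrame indexed by ``feature_id`` (same order as ``features``),
        one column per injection id; ``NaN`` marks a missing measurement.
    scale
        ``"raw"`` (non-negative intensities) or ``"log2"``.
    """

    features: pd.DataFrame
    values: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        if not self.features.index.is_unique:
            dupes = self.features.index[self.features.index.duplicated()].unique()
            raise ValidationError(f"duplicate feature_id: {', '.join(map(str, dupes))}")
        if list(self.features.index) != list(self.values.index):
            raise ValidationError("features and values indexed differently")
        bad_mode = set(self.features["ion_mode"]) - set(ION_MODES)
        if bad_mode:
            raise ValidationError(f"unknown ion mode(s): {sorted(bad_mode)}")
        if (self.features["mz"] <= 0).any():
            bad = self.features.index[self.features["mz"] <= 0][0]
            raise ValidationError(f"non-positive m/z for feature {bad}")
        if (self.features["rt"] < 0).any():
            bad = self.features.index[self.features["rt"] < 0][0]
            raise ValidationError(f"negative retention time for feature {bad}")
        if self.scale == "raw":
            vals = self.values.to_numpy(dtype=float)
            if np.any(vals[np.isfinite(vals)] < 0):
                raise ValidationError("raw-scale table contains negative intensities")

    # -- convenience -----------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def injection_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def select_features(self, ids: Iterable[str]) -> "FeatureTable":
        ids = list(ids)
        return FeatureTable(self.features.loc[ids], self.values.loc[ids], self.scale)

    def select_injections(self, ids: Iterable[str]) -> "FeatureTable":
        ids = list(ids)
        return FeatureTable(self.features, self.values[ids], self.scale)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.features.copy(), self.values.copy(), self.scale)

    def check_against_meta(self, meta: "InjectionMeta") -> None:
        """Require column ids to exactly match the metadata injection set."""
        cols = set(self.injection_ids)
        known = set(meta.df.index)
        if cols != known:
            missing = sorted(cols - known)[:5]
            extra = sorted(known - cols)[:5]
            raise ValidationError(
                f"injection ids disagree with metadata (unmatched columns: {missing}, "
                f"unmatched metadata rows: {extra})"
            )


@dataclass
class InjectionMeta:
    """Per-injection annotations, indexed by ``injection_id``.

    ``group`` is present iff ``sample_type == 'study'``; ``dilution_volume``
    (µL) iff ``sample_type == 'dilution'``; ``injection_order`` is 1-based and
    unique within each cohort.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.df
        if not df.index.is_unique:
            dupes = df.index[df.index.duplicated()].unique()
            raise ValidationError(f"duplicate injection_id: {', '.join(map(str, dupes))}")
        bad_type = set(df["sample_type"]) - set(SAMPLE_TYPES)
        if bad_type:
            raise ValidationError(f"unknown sample_type(s): {sorted(bad_type)}")
        bad_cohort = set(df["cohort"]) - {1, 2}
        if bad_cohort:
            raise ValidationError(f"cohort must be 1 or 2, got {sorted(bad_cohort)}")

        is_study = df["sample_type"] == "study"
        no_group = df.loc[is_study, "group"].isna()
        if no_group.any():
            bad = df.index[is_study][no_group][0]
            raise ValidationError(f"study injection {bad} lacks a phenotype group")
        bad_group = set(df.loc[is_study, "group"].dropna()) - set(GROUPS)
        if bad_group:
            raise ValidationError(f"unknown group(s): {sorted(bad_group)}")
        if df.loc[~is_study, "group"].notna().any():
            bad = df.index[~is_study][df.loc[~is_study, "group"].notna()][0]
            raise ValidationError(f"non-study injection {bad} carries a group")

        is_dil = df["sample_type"] == "dilution"
        if df.loc[is_dil, "dilution_volume"].isna().any():
            bad = df.index[is_dil][df.loc[is_dil, "dilution_volume"].isna()][0]
            raise ValidationError(f"dilution injection {bad} lacks dilution_volume")
        if df.loc[~is_dil, "dilution_volume"].notna().any():
            bad = df.index[~is_dil][df.loc[~is_dil, "dilution_volume"].notna()][0]
            raise ValidationError(f"non-dilution injection {bad} carries dilution_volume")

        for cohort, sub in df.groupby("cohort"):
            order = sub["injection_order"]
            if order.isna().any() or (order < 1).any():
                raise ValidationError(f"cohort {cohort}: injection_order must be >= 1")
            if order.duplicated().any():
                dup = int(order[order.duplicated()].iloc[0])
                raise ValidationError(
                    f"cohort {cohort}: duplicate injection_order {dup}"
                )

    # -- selectors -------------------------------------------------------
    def _of(self, sample_type: str, cohort: int | None) -> pd.DataFrame:
        sub = self.df[self.df["sample_type"] == sample_type]
        if cohort is not None:
            sub = sub[sub["cohort"] == cohort]
        return sub

    def study(self, cohort: int | None = None, groups: Sequence[str] | None = None) -> pd.DataFrame:
        sub = self._of("study", cohort)
        if groups is not None:
            sub = sub[sub["group"].isin(groups)]
        return sub

    def qc(self, cohort: int | None = None) -> pd.DataFrame:
        return self._of("qc", cohort)

    def blank(self, cohort: int | None = None) -> pd.DataFrame:
        return self._of("blank", cohort)

    def dilution(self, cohort: int | None = None) -> pd.DataFrame:
        return self._of("dilution", cohort)

    def subset(self, injection_ids: Iterable[str]) -> "InjectionMeta":
        return InjectionMeta(self.df.loc[list(injection_ids)].copy())


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

def _header_comment(fh, extra: dict | None) -> None:
    if extra:
        items = " ".join(f"{k}={v}" for k, v in extra.items())
        fh.write(f"# {items}\n")


def write_feature_table(table: FeatureTable, path: str | Path, provenance: dict | None = None) -> None:
    """Write a feature table as TSV (``feature_id mz rt ion_mode`` + one
    column per injection); missing entries become empty cells."""
    path = Path(path)
    out = table.features.copy()
    out.index.name = "feature_id"
    out = out.reset_index()[list(FEATURE_COLS)]
    out = pd.concat([out, table.values.reset_index(drop=True)], axis=1)
    with open(path, "w") as fh:
        _header_comment(fh, {"scale": table.scale, **(provenance or {})})
        out.to_csv(fh, sep="\t", index=False, na_rep="")


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a TSV feature table written by :func:`write_feature_table`.

    The first comment line may carry ``scale=...``; otherwise the scale
    defaults to ``raw``.  Empty cells and ``NA`` parse as missing (never 0).
    """
    path = Path(path)
    scale = "raw"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if tok.startswith("scale="):
                    scale = tok.split("=", 1)[1]
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(_io.StringIO(body), sep="\t", dtype={"feature_id": str},
                     na_values=["NA", ""], keep_default_na=False)
    missing = [c for c in FEATURE_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    inj_cols = [c for c in df.columns if c not in FEATURE_COLS]
    for c in inj_cols:
        try:
            df[c] = pd.to_numeric(df[c], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: non-numeric intensity in column {c}: {exc}") from None
    features = df[list(FEATURE_COLS)].set_index("feature_id")
    values = df[inj_cols].astype(float)
    values.index = features.index
    return FeatureTable(features, values, scale)


def write_injection_meta(meta: InjectionMeta, path: str | Path, provenance: dict | None = None) -> None:
    path = Path(path)
    out = meta.df.copy()
    out.index.name = "injection_id"
    out = out.reset_index()[list(META_COLS)]
    with open(path, "w") as fh:
        _header_comment(fh, provenance)
        out.to_csv(fh, sep="\t", index=False, na_rep="")


def read_injection_meta(path: str | Path, table: FeatureTable | None = None) -> InjectionMeta:
    """Read and validate injection metadata; optionally cross-check that the
    injection ids exactly cover a feature table's columns."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"injection_id": str, "subject_id": str, "group": str, "sex": str},
                     na_values=["NA", ""], keep_default_na=False)
    missing = [c for c in META_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    df = df.set_index("injection_id")
    df["cohort"] = df["cohort"].astype(int)
    df["injection_order"] = df["injection_order"].astype(int)
    df["dilution_volume"] = pd.to_numeric(df["dilution_volume"])
    df["age"] = pd.to_numeric(df["age"])
    df["timepoint_months"] = pd.to_numeric(df["timepoint_months"])
    df["treated"] = df["treated"].astype(str).str.lower().isin(("true", "1"))
    meta = InjectionMeta(df)
    if table is not None:
        table.check_against_meta(meta)
    return meta


def write_results_tsv(df: pd.DataFrame, path: str | Path, provenance: dict | None = None,
                      index: bool = False) -> None:
    """Write a results table with a leading comment line recording provenance
    (config hash, seed) so every output is self-describing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        _header_comment(fh, provenance)
        df.to_csv(fh, sep="\t", index=index, na_rep="NA")
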