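"""Domain types and tab-separated readers/writers for every table the pipeline touches.

All files are UTF-8, tab-delimited, with ``#`` comment lines ignored.  The
formats covered here are

* FPKM expression matrices (features x replicate samples),
* per-replicate-pair differential tables in the Cuffdiff 2.x ``.diff`` dialect,
* TF -> target regulation tables with evidence labels (YEASTRACT-export style),
* flat gene -> GO-slim mappings, and
* strain physiology tables (growth rate, uptake rate, product yields).

Feature identifiers are treated as opaque strings throughout; collapsing
transcripts to genes, when needed, is a user-supplied mapping applied before
the TF and GO stages (see :func:`apply_feature_mapping`).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError, TableValueError

#: Evidence labels accepted in regulation tables.
EVIDENCE_LABELS = frozenset({"documented-direct", "documented-indirect", "potential"})

#: Default evidence filter: only documented (direct or indirect) regulations.
DOCUMENTED_EVIDENCE = frozenset({"documented-direct", "documented-indirect"})

DIRECTIONS = ("up", "down", "none")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """FPKM values for a set of features across replicate samples.

    Parameters
    ----------
    values
        DataFrame of nonnegative FPKM values, rows indexed by feature id,
        columns by sample (replicate) id.  Row/column order is meaningful and
        preserved on round-trips.
    condition_of
        Mapping from each sample id to its condition label.  Every sample
        must be assigned exactly one condition.
    """

    values: pd.DataFrame
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            raise FormatError("duplicate feature ids in expression matrix")
        if cols.has_duplicates:
            raise FormatError("duplicate sample ids in expression matrix")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise TableValueError("expression matrix contains non-numeric values")
        if np.isnan(arr).any():
            raise TableValueError("expression matrix contains missing values")
        if (arr < 0).any():
            raise TableValueError("FPKM values must be nonnegative")
        missing = [s for s in cols if s not in self.condition_of]
        if missing:
            raise DesignError(f"samples missing from condition map: {missing}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        """Distinct condition labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.condition_of[s], None)
        return list(seen)

    def samples_of(self, condition: str) -> list[str]:
        """Sample ids belonging to ``condition``, in column order."""
        out = [s for s in self.sample_ids if self.condition_of[s] == condition]
        if not out:
            raise DesignError(f"unknown condition label: {condition!r}")
        return out


@dataclass
class PairwiseDETable:
    """Differential calls from one control-replicate vs experiment-replicate
    comparison.

    ``direction`` follows a single convention: ``up`` means the feature's
    expression *increased in the experimental replicate* relative to the
    control replicate.  ``direction == "none"`` exactly when ``significant``
    is false.
    """

    pair_label: tuple[str, str]  # (control replicate id, experiment replicate id)
    records: pd.DataFrame  # feature_id, value_control, value_experiment,
    # log2_fold_change, p_value, q_value (nullable), significant, direction

    REQUIRED = (
        "feature_id",
        "value_control",
        "value_experiment",
        "log2_fold_change",
        "p_value",
        "significant",
        "direction",
    )

    def __post_init__(self) -> None:
        r = self.records
        for col in self.REQUIRED:
            if col not in r.columns:
                raise FormatError(f"pairwise DE table missing column {col!r}")
        if "q_value" not in r.columns:
            self.records = r = r.assign(q_value=np.nan)
        if r["feature_id"].duplicated().any():
            raise FormatError("duplicate feature ids in pairwise DE table")
        p = r["p_value"].to_numpy(dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise TableValueError("p_value outside [0, 1]")
        bad_dir = ~r["direction"].isin(DIRECTIONS)
        if bad_dir.any():
            raise TableValueError("direction must be one of up/down/none")
        none_mismatch = (r["direction"] == "none") != (~r["significant"])
        if none_mismatch.any():
            raise TableValueError("direction is 'none' iff not significant")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.records["feature_id"])

    def significant_features(self) -> pd.DataFrame:
        return self.records[self.records["significant"]]


@dataclass
class RegulationTable:
    """A set of documented TF -> target-gene regulation edges."""

    edges: pd.DataFrame  # tf, target, evidence

    def __post_init__(self) -> None:
        e = self.edges
        for col in ("tf", "target", "evidence"):
            if col not in e.columns:
                raise FormatError(f"regulation table missing column {col!r}")
        if len(e):
            if (e["tf"].astype(str) == "").any() or (e["target"].astype(str) == "").any():
                raise TableValueError("empty tf or target name")
            unknown = set(e["evidence"]) - EVIDENCE_LABELS
            if unknown:
                raise FormatError(f"unknown evidence label(s): {sorted(unknown)}")
            if e.duplicated(["tf", "target", "evidence"]).any():
                self.edges = e.drop_duplicates(["tf", "target", "evidence"]).reset_index(drop=True)

    @property
    def tfs(self) -> list[str]:
        return sorted(set(self.edges["tf"]))

    def targets_of(self, tf: str) -> set[str]:
        return set(self.edges.loc[self.edges["tf"] == tf, "target"])

    def targets_by_tf(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for tf, grp in self.edges.groupby("tf", sort=False):
            out[str(tf)] = set(grp["target"])
        return out


@dataclass
class GOMapping:
    """Flat gene -> GO-slim term mapping.  A gene may map to zero terms; such
    genes fall into the "Un-identified" bucket of the summary stage."""

    entries: pd.DataFrame  # gene, go_id, go_description

    def __post_init__(self) -> None:
        e = self.entries
        for col in ("gene", "go_id", "go_description"):
            if col not in e.columns:
                raise FormatError(f"GO mapping missing column {col!r}")
        if len(e) and (e["go_id"].astype(str) == "").any():
            raise TableValueError("empty GO id")

    def terms_of(self, gene: str) -> set[tuple[str, str]]:
        sub = self.entries[self.entries["gene"] == gene]
        return set(zip(sub["go_id"], sub["go_description"]))


PHYSIOLOGY_METRICS = ("mu", "q_xylose", "y_xylitol", "y_glycerol", "y_acetate", "y_etoh")


@dataclass
class PhysiologyTable:
    """Strain physiology: specific growth rate ``mu`` (1/h), specific xylose
    uptake ``q_xylose`` (mmol/gDCW/h) and product yields (g/g), each with a
    stated +/- uncertainty (carried, not propagated)."""

    records: pd.DataFrame  # index strain; columns metric and metric_sd pairs

    def __post_init__(self) -> None:
        r = self.records
        for m in PHYSIOLOGY_METRICS:
            if m not in r.columns or f"{m}_sd" not in r.columns:
                raise FormatError(f"physiology table missing metric column {m!r}")
            if (r[m].to_numpy(dtype=float) < 0).any():
                raise TableValueError(f"negative point value for {m}")
        if r.index.has_duplicates:
            raise FormatError("duplicate strain names in physiology table")

    @property
    def strains(self) -> list[str]:
        return list(self.records.index)

    def value(self, strain: str, metric: str) -> float:
        if metric not in PHYSIOLOGY_METRICS:
            raise KeyError(f"unknown metric {metric!r}")
        if strain not in self.records.index:
            raise KeyError(f"unknown strain {strain!r}")
        return float(self.records.loc[strain, metric])


# ---------------------------------------------------------------------------
# Low-level helpers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", encoding="utf-8", **kwargs)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_expression_table(
    path: str | Path, condition_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Read a features x samples FPKM table.

    The file has a header row of sample ids and feature ids in the first
    column.  Every sample in the file must appear in ``condition_map``.
    """
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise TableValueError(f"non-numeric expression value: {exc}") from exc
    return ExpressionMatrix(values=df, condition_of=dict(condition_map))


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


_DIFF_LFC_SPELLINGS = ("log2(fold_change)", "log2_fold_change")


def read_cuffdiff_diff(
    path: str | Path, alpha: float = 0.05, *, use_q_value: bool = False
) -> PairwiseDETable:
    """Read a Cuffdiff 2.x ``.diff`` file as one replicate-pair comparison.

    A record is significant iff the file flags it ``yes`` *and* its p-value
    is at most ``alpha`` (the conjunction is a documented choice; set
    ``use_q_value`` to threshold the q-value instead when present).
    Direction is derived from the sign of the log2 fold change, ``up``
    meaning higher in the experimental sample (``value_2``).
    """
    df = _read_tsv(path)
    lfc_col = next((c for c in _DIFF_LFC_SPELLINGS if c in df.columns), None)
    if lfc_col is None:
        raise FormatError(
            "diff file must contain a 'log2(fold_change)' or 'log2_fold_change' column"
        )
    for col in ("test_id", "value_1", "value_2", "p_value", "significant"):
        if col not in df.columns:
            raise FormatError(f"diff file missing mandatory column {col!r}")
    p = df["p_value"].to_numpy(dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise TableValueError("p_value outside [0, 1] in diff file")
    has_q = "q_value" in df.columns
    if use_q_value and not has_q:
        raise FormatError("use_q_value requested but diff file has no q_value column")
    stat = df["q_value"].to_numpy(dtype=float) if use_q_value else p
    flagged = df["significant"].astype(str).str.strip().str.lower() == "yes"
    lfc = df[lfc_col].to_numpy(dtype=float)
    significant = flagged.to_numpy() & (stat <= alpha)
    direction = np.where(~significant, "none", np.where(lfc > 0, "up", "down"))
    sample_1 = df["sample_1"].iloc[0] if "sample_1" in df.columns and len(df) else "control"
    sample_2 = df["sample_2"].iloc[0] if "sample_2" in df.columns and len(df) else "experiment"
    records = pd.DataFrame(
        {
            "feature_id": df["test_id"].astype(str),
            "value_control": df["value_1"].astype(float),
            "value_experiment": df["value_2"].astype(float),
            "log2_fold_change": lfc,
            "p_value": p,
            "q_value": df["q_value"].astype(float) if has_q else np.nan,
            "significant": significant,
            "direction": direction,
        }
    )
    return PairwiseDETable(pair_label=(str(sample_1), str(sample_2)), records=records)


def read_regulation_table(
    path: str | Path, evidence_filter: Iterable[str] = DOCUMENTED_EVIDENCE
) -> RegulationTable:
    """Read a 3-column (tf, target, evidence) regulation table, keeping only
    edges whose evidence label is in ``evidence_filter``."""
    df = _read_tsv(path, header=0)
    if df.empty:
        df = pd.DataFrame(columns=["tf", "target", "evidence"])
    df.columns = [str(c).strip().lower() for c in df.columns]
    table = RegulationTable(edges=df)
    keep = table.edges["evidence"].isin(set(evidence_filter))
    return RegulationTable(edges=table.edges[keep].reset_index(drop=True))


def write_regulation_table(table: RegulationTable, path: str | Path) -> None:
    table.edges.to_csv(path, sep="\t", index=False)


def read_go_mapping(path: str | Path) -> GOMapping:
    df = _read_tsv(path, header=0, dtype=str)
    if df.empty:
        df = pd.DataFrame(columns=["gene", "go_id", "go_description"])
    df.columns = [str(c).strip().lower() for c in df.columns]
    return GOMapping(entries=df.reset_index(drop=True))


def write_go_mapping(mapping: GOMapping, path: str | Path) -> None:
    mapping.entries.to_csv(path, sep="\t", index=False)


def read_physiology_table(path: str | Path) -> PhysiologyTable:
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    return PhysiologyTable(records=df.astype(float))


def write_physiology_table(table: PhysiologyTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index_label="strain")


def apply_feature_mapping(
    features: Iterable[str], mapping: Mapping[str, str] | None
) -> list[str]:
    """Collapse transcript ids to gene ids via a user-supplied mapping.

    Features absent from the mapping keep their own id (feature ids double
    as gene ids when no mapping is given).  Duplicates after collapsing are
    removed, first occurrence wins.
    """
    if mapping is None:
        mapped = list(features)
    else:
        mapped = [mapping.get(f, f) for f in features]
    seen: dict[str, None] = {}
    for g in mapped:
        seen.setdefault(g, None)
    return list(seen)
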