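"""Domain containers and tabular readers/writers.

Every downstream module consumes these four containers:

* :class:`OmicMatrix` — one molecular layer, features in rows.
* :class:`ClinicalTable` — per-sample clinical annotation.
* :class:`GeneSetCollection` — GMT-style gene-set collections.
* :class:`SignatureMatrix` — cell-type reference profiles for deconvolution.

All on-disk formats are plain UTF-8 tab-separated text with "." decimals.
Missing values are represented explicitly as NaN, never as 0; only the
proteomics retention filter (:mod:`snfomics.preprocess`) removes them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OmicMatrix",
    "ClinicalTable",
    "GeneSet",
    "GeneSetCollection",
    "SignatureMatrix",
    "read_omic_matrix",
    "write_omic_matrix",
    "read_gmt",
    "write_gmt",
    "read_clinical_table",
    "write_clinical_table",
    "read_signature_matrix",
    "write_signature_matrix",
    "align_cohort",
]

#: columns a clinical table must provide
CLINICAL_REQUIRED = (
    "sample_id",
    "age",
    "sex",
    "location",
    "braf_status",
    "pfs_time",
    "pfs_event",
)


def _check_unique(ids, what: str) -> None:
    counts = pd.Index(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise ValueError(f"duplicate {what}: {', '.join(map(str, dups.index[:5]))}")


@dataclass
class OmicMatrix:
    """One molecular layer: a features x samples numeric matrix.

    Parameters
    ----------
    layer_name:
        Label such as ``"mrna"``, ``"protein"`` or ``"methylation"``.
    values:
        Features-in-rows DataFrame; NaN marks missing measurements.
    is_log:
        True when values are already on a log (or otherwise variance
        stabilised) scale; methylation beta values keep ``is_log=False``.
    """

    layer_name: str
    values: pd.DataFrame
    is_log: bool = True

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values = self.values.astype(float)
        _check_unique(self.values.index, f"feature ids in layer '{self.layer_name}'")
        _check_unique(self.values.columns, f"sample ids in layer '{self.layer_name}'")
        # beta-value range applies to the raw scale only, not to derived
        # (z-scored) methylation matrices
        if self.layer_name == "methylation" and not self.is_log:
            vals = self.values.to_numpy()
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("methylation beta values must lie in [0, 1]")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "OmicMatrix":
        return OmicMatrix(self.layer_name, self.values.loc[:, list(sample_ids)].copy(), self.is_log)

    def subset_features(self, feature_ids) -> "OmicMatrix":
        return OmicMatrix(self.layer_name, self.values.loc[list(feature_ids), :].copy(), self.is_log)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation (one row per sample).

    Required columns: sample_id, age (years), sex, location, braf_status,
    pfs_time (months), pfs_event (0/1). A ``group`` column is optional and
    extra columns are preserved untouched. Categorical columns are
    normalised to lower case on construction.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"clinical table missing required column(s): {', '.join(missing)}")
        df["sample_id"] = df["sample_id"].astype(str).str.strip()
        _check_unique(df["sample_id"], "sample ids in clinical table")
        for col in ("sex", "location", "braf_status"):
            df[col] = df[col].astype(str).str.strip().str.lower()
        if "group" in df.columns:
            df["group"] = df["group"].astype(str).str.strip().str.lower()
        df["age"] = df["age"].astype(float)
        df["pfs_time"] = df["pfs_time"].astype(float)
        if (df["pfs_time"] < 0).any():
            raise ValueError("pfs_time must be non-negative")
        events = df["pfs_event"].astype(float)
        if not events.isin([0.0, 1.0]).all():
            bad = sorted(set(events[~events.isin([0.0, 1.0])]))
            raise ValueError(f"pfs_event must be 0 or 1, got {bad}")
        df["pfs_event"] = events.astype(int)
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def __len__(self) -> int:
        return len(self.data)

    def subset_samples(self, sample_ids) -> "ClinicalTable":
        wanted = list(sample_ids)
        sub = self.data.set_index("sample_id").loc[wanted].reset_index()
        return ClinicalTable(sub)


@dataclass
class GeneSet:
    name: str
    description: str
    members: list[str]


@dataclass
class GeneSetCollection:
    """An ordered collection of named gene sets (GMT semantics)."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique([s.name for s in self.sets], "gene-set names")
        for s in self.sets:
            if not s.members:
                raise ValueError(f"gene set '{s.name}' has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


@dataclass
class SignatureMatrix:
    """Cell-type reference profiles (features x cell types), non-negative."""

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        self.profiles = self.profiles.astype(float)
        _check_unique(self.profiles.index, "signature feature ids")
        _check_unique(self.profiles.columns, "cell-type labels")
        vals = self.profiles.to_numpy()
        if np.nanmin(vals) < 0:
            raise ValueError("signature profiles must be non-negative")
        zero_cols = self.profiles.columns[(vals == 0).all(axis=0)]
        if len(zero_cols):
            raise ValueError(f"all-zero signature column(s): {', '.join(zero_cols)}")

    @property
    def cell_types(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.profiles.index)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_numeric_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for j, col in enumerate(df.columns):
        raw = df[col].str.strip()
        blank = raw.isin(["", "NA", "NaN", "nan", "na"])
        parsed = pd.to_numeric(raw.where(~blank), errors="coerce")
        bad = parsed.isna() & ~blank
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric value {raw.iloc[i]!r} at row '{df.index[i]}' "
                f"(row {i + 2}), column '{col}' (column {j + 2}) in {path}"
            )
        out[col] = parsed
    return out


def read_omic_matrix(path, layer_name: str, is_log: bool = True, transpose: bool = False) -> OmicMatrix:
    """Read a tab-separated features x samples matrix.

    First column holds feature ids, header row holds sample ids. Empty or
    "NA" cells become NaN (missing), never zero. ``transpose=True`` accepts
    samples-in-rows files.
    """
    df = _read_numeric_table(path)
    if transpose:
        df = df.T
    return OmicMatrix(layer_name=layer_name, values=df, is_log=is_log)


def write_omic_matrix(matrix: OmicMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id", na_rep="NA")


def read_gmt(path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name, description, members per line."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno} has {len(fields)} field(s); need >= 3")
            name, description = fields[0].strip(), fields[1].strip()
            members, seen = [], set()
            for m in fields[2:]:
                m = m.strip()
                if not m:
                    continue
                if m in seen:
                    logger.warning("gene set '%s': duplicate member '%s' dropped", name, m)
                    continue
                seen.add(m)
                members.append(m)
            sets.append(GeneSet(name, description, members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def read_clinical_table(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = df.columns.str.strip()
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing required column(s): {', '.join(missing)}")
    return ClinicalTable(df)


def write_clinical_table(table: ClinicalTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_signature_matrix(path) -> SignatureMatrix:
    return SignatureMatrix(_read_numeric_table(path))


def write_signature_matrix(sig: SignatureMatrix, path) -> None:
    sig.profiles.to_csv(path, sep="\t", index_label="feature_id", na_rep="NA")


def align_cohort(matrices, clinical: ClinicalTable | None = None):
    """Restrict all layers (and clinical table) to the shared samples.

    The shared sample order is the order of appearance in the first matrix.
    Returns ``(matrices, clinical)``; ``clinical`` may be None.
    """
    if not matrices:
        raise ValueError("align_cohort needs at least one matrix")
    shared = [s.strip() for s in matrices[0].sample_ids]
    for m in matrices[1:]:
        ids = {s.strip() for s in m.sample_ids}
        shared = [s for s in shared if s in ids]
    if clinical is not None:
        ids = {s.strip() for s in clinical.sample_ids}
        shared = [s for s in shared if s in ids]
    if not shared:
        raise ValueError("no samples shared across all inputs")
    logger.info("align_cohort: %d shared sample(s)", len(shared))
    out_matrices = [m.subset_samples(shared) for m in matrices]
    out_clinical = clinical.subset_samples(shared) if clinical is not None else None
    return out_matrices, out_clinical
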