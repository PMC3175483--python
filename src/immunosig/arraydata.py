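"""Immunosignature intensity data: containers, I/O, normalization, descriptives.

An immunosignature experiment produces, for each serum sample, a microarray
of thousands of random-sequence peptides whose fluorescence (RFU, 16-bit,
0-65,500) measures antibody binding.  This module holds the ground data
format (:class:`IntensityMatrix`), the per-slide median normalization with
log10 transform used before all downstream modelling, and pooled per-group
descriptive statistics.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IntensityMatrix",
    "NormalizedMatrix",
    "GroupDescriptives",
    "read_intensity_table",
    "read_gpr",
    "write_intensity_table",
    "median_normalize_log10",
    "describe_groups",
    "descriptives_frame",
]

RFU_CEILING = 65500.0

class FormatError(ValueError):
    """Malformed input table (duplicate ids, missing columns, bad header)."""

class ValidationError(ValueError):
    """Well-formed table containing invalid values (negative, non-numeric)."""


@dataclass
class IntensityMatrix:
    """Raw samples x peptides fluorescence matrix with metadata.

    Parameters
    ----------
    values : (n_samples, n_peptides) array of raw RFU, finite and >= 0.
    sample_ids, peptide_ids : unique string identifiers.
    group_labels : per-sample group (e.g. normal / single_tumor / second_tumor).
    peptide_sequences : optional per-peptide amino-acid sequence.
    empty_spot : boolean mask of printed positions carrying no peptide,
        used to gauge array background; excluded from testing and factoring.
    """

    values: np.ndarray
    sample_ids: list[str]
    group_labels: list[str]
    peptide_ids: list[str]
    peptide_sequences: list[str] | None = None
    empty_spot: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.peptide_ids = [str(p) for p in self.peptide_ids]
        self.group_labels = [str(g) for g in self.group_labels]
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D samples x peptides matrix")
        n, v = self.values.shape
        if n < 2 or v < 3:
            raise ValidationError(
                f"need at least 2 samples and 3 peptides, got {n} x {v}"
            )
        if len(self.sample_ids) != n:
            raise FormatError("sample_ids length does not match matrix rows")
        if len(self.peptide_ids) != v:
            raise FormatError("peptide_ids length does not match matrix columns")
        if len(self.group_labels) != n:
            raise FormatError("group_labels length does not match matrix rows")
        if len(set(self.sample_ids)) != n:
            raise FormatError("duplicate sample ids")
        if len(set(self.peptide_ids)) != v:
            raise FormatError("duplicate peptide ids")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite intensity at sample {self.sample_ids[i]!r}, "
                f"peptide {self.peptide_ids[j]!r}"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative intensity at sample {self.sample_ids[i]!r}, "
                f"peptide {self.peptide_ids[j]!r}"
            )
        if self.empty_spot is None:
            self.empty_spot = np.zeros(v, dtype=bool)
        else:
            self.empty_spot = np.asarray(self.empty_spot, dtype=bool)
            if self.empty_spot.shape != (v,):
                raise FormatError("empty_spot length does not match peptide count")
        if self.peptide_sequences is not None and len(self.peptide_sequences) != v:
            raise FormatError("peptide_sequences length does not match peptide count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_peptides(self) -> int:
        return self.values.shape[1]

    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        return list(dict.fromkeys(self.group_labels))

    def group_mask(self, group: str) -> np.ndarray:
        mask = np.array([g == group for g in self.group_labels])
        if not mask.any():
            raise ValueError(f"no samples in group {group!r}")
        return mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.peptide_ids)


@dataclass
class NormalizedMatrix:
    """log10 median-normalized intensities.

    Each raw array (sample row) is divided by its own median and rescaled by
    the grand median of the per-sample medians, which removes global
    per-slide intensity bias while keeping values on the RFU scale, then
    log10 is applied.  ``normalization_constant[i]`` is the multiplier
    applied to row i before the log; the provenance matrix is kept so the
    transform is invertible.
    """

    values: np.ndarray
    provenance: IntensityMatrix
    normalization_constant: np.ndarray
    zero_offset: float = 0.0

    @property
    def sample_ids(self) -> list[str]:
        return self.provenance.sample_ids

    @property
    def peptide_ids(self) -> list[str]:
        return self.provenance.peptide_ids

    @property
    def group_labels(self) -> list[str]:
        return self.provenance.group_labels

    @property
    def empty_spot(self) -> np.ndarray:
        return self.provenance.empty_spot

    def groups(self) -> list[str]:
        return self.provenance.groups()

    def group_mask(self, group: str) -> np.ndarray:
        return self.provenance.group_mask(group)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.peptide_ids)

    def backtransform(self) -> np.ndarray:
        """Undo the log and per-sample rescaling: recover raw RFU."""
        raw = 10.0 ** self.values / self.normalization_constant[:, None]
        return raw - self.zero_offset


@dataclass
class GroupDescriptives:
    """Raw-RFU descriptive statistics pooled over every spot of a group."""

    group: str
    n_samples: int
    mean: float
    minimum: float
    maximum: float
    std_deviation: float
    variance: float
    range: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.range is None:
            self.range = self.maximum - self.minimum


def _validate_numeric(df: pd.DataFrame, path: str) -> np.ndarray:
    arr = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(arr))
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"{path}: non-numeric intensity at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    return arr


def read_intensity_table(
    path,
    format: str = "tsv",
    label_map=None,
    empty_token: str = "empty",
    signal_column: str = "F635 Median",
) -> IntensityMatrix:
    """Read an intensity table into a validated :class:`IntensityMatrix`.

    ``tsv``/``csv``: one table, first column sample id, remaining columns
    peptides.  ``gpr``: *path* is a list of GenePix-results files (or a
    directory of ``.gpr`` files), one array per sample.  ``label_map`` maps
    sample id to group label (dict or two-column TSV path); samples missing
    from the map get group ``"unknown"``.

    Peptides whose name contains *empty_token* (case-insensitive) are
    flagged as empty spots.
    """
    label_map = _load_label_map(label_map)
    if format == "gpr":
        return read_gpr(path, label_map=label_map, empty_token=empty_token,
                        signal_column=signal_column)
    if format not in ("tsv", "csv"):
        raise FormatError(f"unknown format {format!r}")
    sep = "\t" if format == "tsv" else ","
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        dup = next(h for i, h in enumerate(header) if h in header[:i])
        raise FormatError(f"{path}: duplicate peptide id {dup!r}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate peptide id {dup!r}")
    values = _validate_numeric(df, str(path))
    peptide_ids = [str(c) for c in df.columns]
    sample_ids = [str(s) for s in df.index]
    groups = [label_map.get(s, "unknown") for s in sample_ids]
    empty = np.array([empty_token.lower() in p.lower() for p in peptide_ids])
    return IntensityMatrix(values, sample_ids, groups, peptide_ids, empty_spot=empty)


def _load_label_map(label_map) -> dict:
    if label_map is None:
        return {}
    if isinstance(label_map, dict):
        return {str(k): str(v) for k, v in label_map.items()}
    df = pd.read_csv(label_map, sep=None, engine="python", header=None, comment="#")
    if df.shape[1] < 2:
        raise FormatError("label map needs two columns: sample id, group")
    if str(df.iloc[0, 0]).lower() in ("sample", "sample_id", "id"):
        df = df.iloc[1:]
    return {str(r[0]): str(r[1]) for r in df.itertuples(index=False)}


def _read_one_gpr(path: str, signal_column: str) -> pd.Series:
    """Parse a minimal GenePix results dialect: ATF-style header lines, then
    a tab-delimited table with Block/Row/Column/Name/ID and signal columns."""
    with open(path) as fh:
        lines = fh.readlines()
    header_idx = None
    for i, line in enumerate(lines):
        cols = [c.strip().strip('"') for c in line.rstrip("\n").split("\t")]
        if "Block" in cols and "Name" in cols and "ID" in cols:
            header_idx = i
            break
    if header_idx is None:
        raise FormatError(f"{path}: no GPR column header (Block/Name/ID) found")
    table = pd.read_csv(io.StringIO("".join(lines[header_idx:])), sep="\t")
    table.columns = [str(c).strip().strip('"') for c in table.columns]
    required = {"Block", "Row", "Column", "Name", "ID", signal_column}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"{path}: missing GPR columns {sorted(missing)}")
    ids = table["ID"].astype(str).str.strip('"')
    if ids.duplicated().any():
        raise FormatError(f"{path}: duplicate peptide id {ids[ids.duplicated()].iloc[0]!r}")
    sig = pd.to_numeric(table[signal_column], errors="coerce")
    if sig.isna().any():
        row = table.loc[sig.isna()].iloc[0]
        raise ValidationError(
            f"{path}: non-numeric {signal_column!r} at spot "
            f"Block {row['Block']} Row {row['Row']} Column {row['Column']}"
        )
    names = table["Name"].astype(str).str.strip('"')
    out = pd.Series(sig.to_numpy(dtype=float), index=ids)
    out.attrs["names"] = names.to_numpy()
    return out


def read_gpr(
    paths,
    label_map=None,
    empty_token: str = "empty",
    signal_column: str = "F635 Median",
) -> IntensityMatrix:
    """Read one GPR file per sample; sample id is the file stem."""
    label_map = _load_label_map(label_map)
    if isinstance(paths, (str, os.PathLike)):
        d = str(paths)
        if os.path.isdir(d):
            paths = sorted(
                os.path.join(d, f) for f in os.listdir(d) if f.endswith(".gpr")
            )
        else:
            paths = [d]
    series, sample_ids = [], []
    for p in paths:
        s = _read_one_gpr(str(p), signal_column)
        series.append(s)
        sample_ids.append(os.path.splitext(os.path.basename(str(p)))[0])
    ref = series[0]
    for p, s in zip(paths, series[1:], strict=False):
        if not s.index.equals(ref.index):
            raise FormatError(f"{p}: peptide ids differ from first array")
    values = np.vstack([s.to_numpy() for s in series])
    peptide_ids = [str(i) for i in ref.index]
    names = ref.attrs.get("names", np.array(peptide_ids))
    empty = np.array(
        [empty_token.lower() in str(nm).lower() or empty_token.lower() in pid.lower()
         for nm, pid in zip(names, peptide_ids)]
    )
    groups = [label_map.get(s, "unknown") for s in sample_ids]
    return IntensityMatrix(values, sample_ids, groups, peptide_ids, empty_spot=empty)


def write_intensity_table(x, path, format: str = "tsv") -> None:
    """Write an :class:`IntensityMatrix` or :class:`NormalizedMatrix` as TSV/CSV."""
    sep = "\t" if format == "tsv" else ","
    x.to_frame().to_csv(path, sep=sep, index_label="sample_id")


def median_normalize_log10(x: IntensityMatrix, zero_offset: float = 1.0) -> NormalizedMatrix:
    """Per-slide median normalization followed by log10.

    Each sample row is divided by its own median and multiplied by the grand
    median of per-sample medians, so after normalization every array has the
    same median on the raw RFU scale; then log10.  *zero_offset* (RFU) is
    added to every value first so occasional zero spots survive the log;
    background runs ~150-300 RFU so this leaves real signal untouched.
    """
    vals = x.values + zero_offset
    if np.any(vals <= 0):
        i = int(np.argwhere((vals <= 0).any(axis=1))[0][0])
        raise ValueError(
            f"sample {x.sample_ids[i]!r} has non-positive intensity after "
            f"zero_offset={zero_offset}; cannot log-transform"
        )
    med = np.median(vals, axis=1)
    if np.any(med == 0):
        i = int(np.argwhere(med == 0)[0][0])
        raise ValueError(f"sample {x.sample_ids[i]!r} has zero median; cannot scale")
    grand = np.median(med)
    const = grand / med
    return NormalizedMatrix(
        values=np.log10(vals * const[:, None]),
        provenance=x,
        normalization_constant=const,
        zero_offset=zero_offset,
    )


def describe_groups(x: IntensityMatrix) -> list[GroupDescriptives]:
    """Pooled raw-RFU descriptives per disease group.

    Statistics pool every spot of every sample in the group (ddof=1), on raw
    intensities: the 16-bit magnitudes (backgrounds of a few hundred RFU,
    ceilings near 65,500) are only meaningful on that scale.
    """
    out = []
    for g in x.groups():
        mask = x.group_mask(g)
        pooled = x.values[mask].ravel()
        out.append(
            GroupDescriptives(
                group=g,
                n_samples=int(mask.sum()),
                mean=float(pooled.mean()),
                minimum=float(pooled.min()),
                maximum=float(pooled.max()),
                std_deviation=float(pooled.std(ddof=1)),
                variance=float(pooled.var(ddof=1)),
            )
        )
    return out


def descriptives_frame(descs: list[GroupDescriptives]) -> pd.DataFrame:
    """Tabular layout: Group / Mean / Minimum / Maximum / Std. Deviation / Variance / Range."""
    return pd.DataFrame(
        {
            "Group": [d.group for d in descs],
            "Mean": [d.mean for d in descs],
            "Minimum": [d.minimum for d in descs],
            "Maximum": [d.maximum for d in descs],
            "Std. Deviation": [d.std_deviation for d in descs],
            "Variance": [d.variance for d in descs],
            "Range": [d.range for d in descs],
        }
    )
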