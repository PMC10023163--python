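"""Reading, validation, filtering and windowing of localization tables.

Single-molecule localization microscopy produces one record per *blink*: a
single fluorophore emission event localized to nanometer accuracy.  The
canonical on-disk format is a delimited text table with header columns
``x_nm, y_nm, z_nm, photons, frame, precision_nm, probe``.  Vendor exports
with different column names or units are mapped onto this schema through a
:class:`Dialect`.

All downstream geometry is 2D: the z coordinate is discarded with
:func:`flatten_z` before analysis (axial chromatic aberration makes z
unreliable for multi-color comparisons).  Per-synapse analysis windows are
defined by :func:`segment_rois`, which centers a fixed window on each
fiducial (dense-projection marker) cluster along the nerve cord.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_PROBES",
    "Dialect",
    "DIALECTS",
    "LocalizationSet",
    "SynapseROI",
    "FormatError",
    "read_localizations",
    "write_localizations",
    "filter_precision",
    "flatten_z",
    "segment_rois",
]

#: Probe labels recognised by default.  Extend per experiment.
DEFAULT_PROBES = frozenset(
    {"CaV1", "CaV2", "RyR", "ELKS", "UNC13", "UNC13L", "UNC13S"}
)

REQUIRED_COLUMNS = ("x_nm", "y_nm", "photons", "probe")
OPTIONAL_COLUMNS = ("z_nm", "frame", "precision_nm")


class FormatError(ValueError):
    """A localization table does not conform to its declared dialect."""


@dataclass(frozen=True)
class Dialect:
    """Column mapping from a vendor export onto the canonical schema.

    Parameters
    ----------
    columns
        Mapping of canonical name -> column name in the file.  Must cover
        at least ``x_nm, y_nm, photons, probe``.
    length_unit
        Unit of the coordinate/precision columns in the file; one of
        ``"nm"`` or ``"um"``.  Values are coerced to nm on read.
    sep
        Field separator.
    """

    columns: dict[str, str]
    length_unit: str = "nm"
    sep: str = ","

    def __post_init__(self) -> None:
        if self.length_unit not in ("nm", "um"):
            raise ValueError(f"length_unit must be 'nm' or 'um', got {self.length_unit!r}")
        missing = [c for c in REQUIRED_COLUMNS if c not in self.columns]
        if missing:
            raise FormatError(f"dialect missing required column mapping(s): {missing}")


#: Registry of known dialects.  The canonical dialect is the identity
#: mapping; add entries here when a new vendor export is encountered.
DIALECTS: dict[str, Dialect] = {
    "canonical": Dialect(
        columns={c: c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS},
    ),
}


@dataclass
class LocalizationSet:
    """Per-blink localization records for one field of view or ROI.

    Wraps a :class:`pandas.DataFrame` with canonical columns
    ``x_nm, y_nm, photons, probe`` and optionally ``z_nm, frame,
    precision_nm``; unknown columns are carried through untouched.
    """

    data: pd.DataFrame
    probes: frozenset[str] = field(default=DEFAULT_PROBES)

    def __post_init__(self) -> None:
        df = self.data
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"missing required column: {col}")
        for col in ("x_nm", "y_nm", "z_nm", "precision_nm", "photons"):
            if col in df.columns and len(df):
                vals = df[col].to_numpy()
                if not np.issubdtype(vals.dtype, np.number):
                    raise FormatError(f"column {col!r} is not numeric")
                if col != "z_nm" and not np.isfinite(vals).all():
                    bad = int(np.flatnonzero(~np.isfinite(vals))[0])
                    raise FormatError(f"non-finite value in column {col!r} at row {bad}")
        if len(df):
            if (df["photons"].to_numpy() < 0).any():
                raise FormatError("negative photon counts")
            if "precision_nm" in df.columns and (df["precision_nm"].to_numpy() <= 0).any():
                raise FormatError("non-positive localization precision")
            unknown = set(df["probe"].unique()) - self.probes
            if unknown:
                raise FormatError(f"unknown probe label(s): {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_z(self) -> bool:
        return "z_nm" in self.data.columns

    def xy(self) -> np.ndarray:
        """(n, 2) array of x/y coordinates in nm."""
        return self.data[["x_nm", "y_nm"]].to_numpy(dtype=float)

    def select_probe(self, probe: str) -> "LocalizationSet":
        return LocalizationSet(
            self.data[self.data["probe"] == probe].reset_index(drop=True),
            probes=self.probes,
        )


@dataclass
class SynapseROI:
    """One synapse's analysis window.

    The window is centered on a fiducial (dense-projection marker) cluster
    center; every member localization, of any probe, lies within
    ``half_width`` of that center.
    """

    roi_id: int
    fiducial: str
    center: tuple[float, float]
    half_width: float
    members: LocalizationSet

    def probe(self, label: str) -> LocalizationSet:
        return self.members.select_probe(label)


def read_localizations(
    path,
    dialect: Dialect | str = "canonical",
    probes: frozenset[str] = DEFAULT_PROBES,
) -> LocalizationSet:
    """Read a delimited localization table.

    Coordinates and precision are coerced to nm according to the dialect's
    declared unit.  Columns not named in the dialect are preserved as
    opaque attributes of the table.
    """
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    df = pd.read_csv(path, sep=dialect.sep)
    rename = {src: dst for dst, src in dialect.columns.items() if src in df.columns}
    missing = [
        dst for dst, src in dialect.columns.items()
        if dst in REQUIRED_COLUMNS and src not in df.columns
    ]
    if missing:
        raise FormatError(f"file {path} missing required column(s): {missing}")
    df = df.rename(columns=rename)
    for col in ("x_nm", "y_nm", "z_nm", "precision_nm"):
        if col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                # +2: one for the header line, one for 1-based numbering
                line = int(bad.idxmax()) + 2
                raise FormatError(f"non-numeric value in column {col!r} at line {line}")
            df[col] = coerced
            if dialect.length_unit == "um":
                df[col] = df[col] * 1000.0
    return LocalizationSet(df.reset_index(drop=True), probes=probes)


def write_localizations(locs: LocalizationSet, path, sep: str = ",") -> None:
    """Write a table in the canonical dialect (all lengths in nm)."""
    locs.data.to_csv(path, sep=sep, index=False, float_format="%.6f")


def filter_precision(locs: LocalizationSet, max_precision: float = 80.0) -> LocalizationSet:
    """Drop records localized worse than ``max_precision`` nm (CRLB).

    The threshold is inclusive: a record at exactly the threshold is kept.
    Record order is preserved; the operation is idempotent.
    """
    if "precision_nm" not in locs.data.columns:
        raise FormatError("filter_precision requires a precision_nm column")
    keep = locs.data["precision_nm"].to_numpy() <= max_precision
    return replace(locs, data=locs.data[keep].reset_index(drop=True))


def flatten_z(locs: LocalizationSet) -> LocalizationSet:
    """Discard the z coordinate; x/y are untouched.

    A no-op for tables without z.  All downstream geometry is 2D.
    """
    if not locs.has_z:
        return locs
    return replace(locs, data=locs.data.drop(columns=["z_nm"]))


def segment_rois(
    locs: LocalizationSet,
    fiducial: str,
    half_width: float = 700.0,
    gap_nm: float = 250.0,
    min_cluster_size: int = 20,
) -> list[SynapseROI]:
    """Cut a field of view into per-synapse windows around fiducial clusters.

    Fiducial clusters are detected along the cord axis (see
    :func:`synaptoscope.clustergeom.detect_cord_clusters`); every
    localization of every probe within ``half_width`` nm of a fiducial
    cluster center is assigned to that cluster's ROI.  A localization
    within range of two centers goes to the nearer one; exact ties break
    toward the lower ``roi_id``.
    """
    from .clustergeom import detect_cord_clusters

    fid = locs.select_probe(fiducial)
    if len(fid) == 0:
        warnings.warn(f"no localizations for fiducial probe {fiducial!r}; no ROIs")
        return []
    cord = detect_cord_clusters(fid, gap_nm=gap_nm, min_cluster_size=min_cluster_size)
    centers = cord.centers
    if len(centers) == 0:
        warnings.warn("no fiducial clusters detected; no ROIs")
        return []

    xy = locs.xy()
    # distance of every localization to every fiducial cluster center
    d = np.linalg.norm(xy[:, None, :] - centers[None, :, :], axis=2)
    nearest = np.argmin(d, axis=1)  # argmin takes the lowest index on ties
    within = d[np.arange(len(xy)), nearest] <= half_width

    rois = []
    for i, center in enumerate(centers):
        mask = within & (nearest == i)
        members = LocalizationSet(
            locs.data[mask].reset_index(drop=True), probes=locs.probes
        )
        if len(members.select_probe(fiducial)) == 0:
            continue
        rois.append(
            SynapseROI(
                roi_id=len(rois),
                fiducial=fiducial,
                center=(float(center[0]), float(center[1])),
                half_width=half_width,
                members=members,
            )
        )
    return rois
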