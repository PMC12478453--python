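"""Spectra, metadata and protein-panel I/O.

The canonical interchange format for spectra is a long CSV with header
``sample_id,point_index,wavenumber_cm1,intensity`` (one row per channel
per acquisition point).  Per-point two-column text files are also
accepted, with sample id and point index parsed from the filename
(``<sample>_<point>.txt``).  Metadata and protein panels are plain CSVs.

All readers validate at the boundary and fail atomically: either every
record in a file is returned, or an exception names the offending row.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from seraman.exceptions import (
    AxisError,
    DuplicateRecordError,
    ExtrapolationError,
    SpectraParseError,
)

#: Minimum number of channels in a usable point spectrum (one
#: Savitzky-Golay window of the widest default configuration).
MIN_CHANNELS = 33

GROUPS = ("healthy", "PDAC", "CP", "LARC_pre", "LARC_post")


@dataclass
class PointSpectrum:
    """One acquisition point: a wavenumber axis plus raw intensities."""

    sample_id: str
    point_index: int
    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape:
            raise AxisError(
                f"{self.sample_id}/{self.point_index}: axis and intensity "
                f"lengths differ ({self.wavenumbers.size} vs {self.intensities.size})"
            )
        if self.wavenumbers.size < MIN_CHANNELS:
            raise AxisError(
                f"{self.sample_id}/{self.point_index}: spectrum has "
                f"{self.wavenumbers.size} channels, need >= {MIN_CHANNELS}"
            )
        if not np.all(np.isfinite(self.wavenumbers)) or not np.all(
            np.isfinite(self.intensities)
        ):
            raise SpectraParseError(
                f"{self.sample_id}/{self.point_index}: non-finite values"
            )
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise AxisError(
                f"{self.sample_id}/{self.point_index}: wavenumbers not "
                "strictly increasing (duplicate or unsorted channels)"
            )

    def copy(self) -> "PointSpectrum":
        return PointSpectrum(
            self.sample_id,
            self.point_index,
            self.wavenumbers.copy(),
            self.intensities.copy(),
        )


@dataclass
class SampleSpectra:
    """All acquisition points of one serum sample."""

    sample_id: str
    points: list[PointSpectrum]
    common_axis: np.ndarray | None = None

    def __post_init__(self) -> None:
        for p in self.points:
            if p.sample_id != self.sample_id:
                raise AxisError(
                    f"point {p.point_index} belongs to {p.sample_id!r}, "
                    f"not {self.sample_id!r}"
                )

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class CohortMetadata:
    """Group label, response score and exclusion flags of one sample."""

    sample_id: str
    group: str
    nar_score: float | None = None
    jaundice: bool = False
    matched_pair_id: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SpectraParseError(
                f"{self.sample_id}: unknown group {self.group!r}; "
                f"expected one of {GROUPS}"
            )
        if self.nar_score is not None and not self.group.startswith("LARC"):
            raise SpectraParseError(
                f"{self.sample_id}: NAR score given for non-LARC group "
                f"{self.group!r}"
            )


@dataclass
class ProteinPanel:
    """Analyte name -> nonnegative concentration/abundance for one sample."""

    sample_id: str
    values: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# spectra


def _spectra_from_frame(df: pd.DataFrame, source: str) -> list[SampleSpectra]:
    dup = df.duplicated(subset=["sample_id", "point_index", "wavenumber_cm1"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise DuplicateRecordError(
            f"{source}: duplicate record for sample {row['sample_id']!r} "
            f"point {int(row['point_index'])} at {row['wavenumber_cm1']} cm-1"
        )
    samples: list[SampleSpectra] = []
    for sid, sdf in df.groupby("sample_id", sort=True):
        points = []
        for pidx, pdf in sdf.groupby("point_index", sort=True):
            pdf = pdf.sort_values("wavenumber_cm1")
            points.append(
                PointSpectrum(
                    sample_id=str(sid),
                    point_index=int(pidx),
                    wavenumbers=pdf["wavenumber_cm1"].to_numpy(),
                    intensities=pdf["intensity"].to_numpy(),
                )
            )
        samples.append(SampleSpectra(sample_id=str(sid), points=points))
    return samples


def read_spectra(path: str | Path, dialect: str = "long_csv") -> list[SampleSpectra]:
    """Read spectra grouped by sample and acquisition point.

    Parameters
    ----------
    path
        For ``long_csv``: one CSV file.  For ``two_column``: a directory of
        ``<sample>_<point>.txt`` files (whitespace- or comma-delimited,
        wavenumber then intensity).
    dialect
        ``"long_csv"`` (canonical) or ``"two_column"``.
    """
    path = Path(path)
    if dialect == "long_csv":
        df = pd.read_csv(path, dtype=str)
        required = ["sample_id", "point_index", "wavenumber_cm1", "intensity"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SpectraParseError(f"{path}: missing columns {missing}")
        for col in ["point_index", "wavenumber_cm1", "intensity"]:
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            if bad.any():
                # +2: header line plus 1-based numbering
                line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
                raise SpectraParseError(
                    f"{path}: line {line}: cannot parse {col}="
                    f"{df[col].iloc[line - 2]!r} as a number"
                )
            if converted.isna().any():
                line = int(np.flatnonzero(converted.isna().to_numpy())[0]) + 2
                raise SpectraParseError(f"{path}: line {line}: missing {col}")
            # numpy's parser is correctly rounded; pandas' fast path is not
            df[col] = df[col].to_numpy(dtype="U32").astype(float)
        return _spectra_from_frame(df, str(path))
    if dialect == "two_column":
        frames = []
        files = sorted(path.glob("*.txt")) if path.is_dir() else [path]
        if not files:
            raise SpectraParseError(f"{path}: no .txt point files found")
        pat = re.compile(r"^(?P<sample>.+)_(?P<point>\d+)$")
        for f in files:
            m = pat.match(f.stem)
            if m is None:
                raise SpectraParseError(
                    f"{f}: filename must look like <sample>_<point>.txt"
                )
            try:
                arr = np.loadtxt(f, delimiter=None if "," not in f.read_text(
                ).splitlines()[0] else ",", ndmin=2)
            except ValueError as exc:
                raise SpectraParseError(f"{f}: {exc}") from exc
            if arr.shape[1] != 2:
                raise SpectraParseError(f"{f}: expected two columns")
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": m.group("sample"),
                        "point_index": int(m.group("point")),
                        "wavenumber_cm1": arr[:, 0],
                        "intensity": arr[:, 1],
                    }
                )
            )
        return _spectra_from_frame(pd.concat(frames, ignore_index=True), str(path))
    raise SpectraParseError(f"unknown dialect {dialect!r}")


def write_spectra(samples: Iterable[SampleSpectra], path: str | Path) -> None:
    """Write spectra as the canonical long CSV (full float precision)."""
    rows = []
    for s in samples:
        for p in s.points:
            rows.append(
                pd.DataFrame(
                    {
                        "sample_id": s.sample_id,
                        "point_index": p.point_index,
                        "wavenumber_cm1": p.wavenumbers,
                        "intensity": p.intensities,
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )


def harmonize_axis(
    sample: SampleSpectra,
    grid: tuple[float, float, float] = (600.0, 1800.0, 1.0),
) -> SampleSpectra:
    """Linearly interpolate every point spectrum onto a shared grid.

    The default grid, 600-1800 cm-1 at 1 cm-1, covers the serum
    fingerprint region with margin around every panel peak.  The grid
    must lie inside every point's native range; no extrapolation.
    """
    start, stop, step = grid
    axis = np.arange(start, stop + step / 2, step, dtype=float)
    new_points = []
    for p in sample.points:
        if axis[0] < p.wavenumbers[0] - 1e-9 or axis[-1] > p.wavenumbers[-1] + 1e-9:
            raise ExtrapolationError(
                f"{sample.sample_id}/{p.point_index}: grid "
                f"[{axis[0]}, {axis[-1]}] exceeds native range "
                f"[{p.wavenumbers[0]}, {p.wavenumbers[-1]}]"
            )
        new_points.append(
            PointSpectrum(
                sample_id=p.sample_id,
                point_index=p.point_index,
                wavenumbers=axis.copy(),
                intensities=np.interp(axis, p.wavenumbers, p.intensities),
            )
        )
    return SampleSpectra(sample.sample_id, new_points, common_axis=axis)


# ---------------------------------------------------------------------------
# metadata


def apply_exclusions(
    metadata: Sequence[CohortMetadata], longitudinal: bool = False
) -> list[CohortMetadata]:
    """Apply the cohort exclusion rules.

    Jaundiced samples are always removed (jaundice biases serum biomarker
    discovery in pancreatic cancer).  With ``longitudinal=True``, matched
    pre/post treatment pairs contribute only their pre-treatment record,
    so no patient is counted twice in a cross-sectional comparison.
    Idempotent.
    """
    kept = [m for m in metadata if not m.jaundice]
    if longitudinal:
        paired = {}
        for m in kept:
            if m.matched_pair_id is not None:
                paired.setdefault(m.matched_pair_id, []).append(m)
        drop = set()
        for pid, members in paired.items():
            if len(members) > 1:
                pre = [m for m in members if m.group == "LARC_pre"]
                keep_ids = {m.sample_id for m in (pre or members[:1])}
                drop |= {m.sample_id for m in members} - keep_ids
        kept = [m for m in kept if m.sample_id not in drop]
    return kept


def read_metadata(path: str | Path) -> list[CohortMetadata]:
    df = pd.read_csv(path, dtype={"sample_id": str, "matched_pair_id": str})
    ids = df["sample_id"]
    if ids.duplicated().any():
        raise DuplicateRecordError(
            f"{path}: duplicate sample_id {ids[ids.duplicated()].iloc[0]!r}"
        )
    out = []
    for _, row in df.iterrows():
        nar = row.get("nar_score")
        nar = None if pd.isna(nar) else float(nar)
        if nar is not None and nar < 0:
            raise SpectraParseError(
                f"{path}: {row['sample_id']}: negative NAR score {nar}"
            )
        pair = row.get("matched_pair_id")
        pair = None if pd.isna(pair) else str(pair)
        out.append(
            CohortMetadata(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                nar_score=nar,
                jaundice=bool(row.get("jaundice", False)),
                matched_pair_id=pair,
            )
        )
    return out


def write_metadata(metadata: Sequence[CohortMetadata], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metadata],
            "group": [m.group for m in metadata],
            "nar_score": [m.nar_score for m in metadata],
            "jaundice": [m.jaundice for m in metadata],
            "matched_pair_id": [m.matched_pair_id for m in metadata],
        }
    ).to_csv(path, index=False)


def metadata_frame(metadata: Sequence[CohortMetadata]) -> pd.DataFrame:
    """Metadata as a DataFrame indexed by sample_id."""
    df = pd.DataFrame(
        {
            "group": [m.group for m in metadata],
            "nar_score": [
                np.nan if m.nar_score is None else m.nar_score for m in metadata
            ],
            "jaundice": [m.jaundice for m in metadata],
            "matched_pair_id": [m.matched_pair_id for m in metadata],
        },
        index=pd.Index([m.sample_id for m in metadata], name="sample_id"),
    )
    return df


# ---------------------------------------------------------------------------
# protein panels


def read_protein_panel(path: str | Path) -> pd.DataFrame:
    """Read a wide protein CSV (``sample_id,<analyte>,...``).

    Returns a DataFrame indexed by sample_id; values must be finite and
    nonnegative.
    """
    df = pd.read_csv(path, index_col="sample_id")
    if df.index.duplicated().any():
        raise DuplicateRecordError(f"{path}: duplicate sample_id rows")
    vals = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise SpectraParseError(f"{path}: non-finite analyte values")
    if np.any(vals < 0):
        raise SpectraParseError(f"{path}: negative analyte values")
    return df.astype(float)


def write_protein_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, index_label="sample_id", float_format="%.17g")
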