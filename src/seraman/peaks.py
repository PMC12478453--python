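"""Metabolite peak panel and ratiometric quantification.

The panel holds the 40 tentative serum metabolite assignments used
throughout the analysis (fingerprint region, 621-1682 cm-1).  Processed
point spectra are averaged per sample, a peak value is read off the mean
spectrum as the windowed maximum around each nominal position, and every
value is divided by the 1448 cm-1 lipid/protein CH-deformation band of
the same sample.  The resulting dimensionless samples x peaks table is
the currency of all downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from seraman.exceptions import (
    AxisError,
    DegenerateDataError,
    ParameterError,
    RatiometricError,
)
from seraman.preprocess import ProcessedSpectrum

# (wavenumber cm-1, metabolite, vibrational mode)
_PANEL_ROWS: list[tuple[int, str, str]] = [
    (621, "Phenylalanine", "C–C twisting mode"),
    (643, "Proline", "C–C twisting mode, skeletal stretching vibration"),
    (671, "DNA bases", "C–S stretching mode"),
    (701, "Cholesterol", "Choline group, CH2 rocking, cholesterol ring deformation"),
    (719, "Phosphatidylcholine (PC)/sphingomyelin",
     "Symmetric stretch vibration of choline group"),
    (744, "Thymine (DNA base)", "Backbone vibrations, deformation of the ring"),
    (757, "Tryptophan", "Symmetric breathing of tryptophan, sigma(ring)"),
    (805, "DNA/RNA", "C'–O–P–O–C'3 phosphodiester stretching"),
    (828, "Tyrosine", "Out-of-plane ring breathing"),
    (852, "Sugars (glucose, glycerol)", "C–O–C skeletal stretching"),
    (878, "Glutamic acid", "COOH deformation"),
    (898, "Glycine", "C–C stretching"),
    (938, "Citric acid, Succinic acid",
     "v(OH...O) out of plane wagging vibration of hydrogen bonds"),
    (957, "Fatty acid", "C–H bending"),
    (992, "Arginine", "C–N stretching, C–C stretching"),
    (1002, "Phenylalanine", "Symmetric in-plane ring breathing"),
    (1011, "Carbohydrates", "C–O–C ring, C–O–H bending"),
    (1031, "Phenylalanine", "C–H in-plane bending, ring in-plane bending"),
    (1051, "Glucose/glycerol", "C–O stretching"),
    (1063, "Lipids", "Chain C–C stretching"),
    (1082, "Lipids", "Chain C–C stretching"),
    (1103, "Mannose", "sigma(CH2) twisting vibrations"),
    (1126, "Glucose", "C–C stretching, C–O stretching, C–O–H in-plane bending"),
    (1155, "Carotenoids", "C–C stretching, C–H stretching"),
    (1172, "Saturated long-chain fatty acids", "C–C stretching"),
    (1207, "Amino acids", "NH3 asymmetric rocking"),
    (1249, "Amide III", "Asymmetric O–P–O stretching"),
    (1257, "Unsaturated lipids, fatty acids", "CH3/CH2 twisting and wagging"),
    (1268, "Unsaturated lipids, fatty acids", "CH3/CH2 twisting and wagging"),
    (1314, "Histidine", "NH3+ asymmetric rocking, C–C–H stretching"),
    (1338, "Threonine", "C–H deformation"),
    (1448, "Lipids and proteins",
     "CH2 and CH2CH3 bending, scissoring, and deformation"),
    (1518, "Carotenoids", "C–C stretching and C=C stretching"),
    (1552, "Tryptophan", "Indole ring stretching, C=C stretching"),
    (1575, "DNA & NADH", "Ring breathing modes"),
    (1585, "Phenylalanine", "C–C bending"),
    (1605, "Phenylalanine", "C=O stretching, C=C in-plane bending"),
    (1615, "Tyrosine", "C=C stretching"),
    (1657, "Unsaturated lipids, PC, phosphatidylethanolamine", "C=C stretching"),
    (1682, "Amide I", "C=O stretching"),
]

#: Ratiometric reference band.  The methods text quotes 1447 cm-1 while the
#: assignment table lists 1448; with a +/-5 cm-1 extraction window the
#: 1 cm-1 discrepancy is immaterial.  1448 is used as the nominal position.
DEFAULT_DENOMINATOR = 1448.0


@dataclass(frozen=True)
class PeakAssignment:
    """A nominal band position with its tentative metabolite assignment."""

    wavenumber_cm1: float
    metabolite: str
    vibrational_mode: str = ""

    @property
    def label(self) -> str:
        return f"{self.wavenumber_cm1:g} {self.metabolite}"


@dataclass
class PeakPanel:
    """Ordered collection of peak assignments plus quantification policy."""

    assignments: list[PeakAssignment]
    denominator_wavenumber: float = DEFAULT_DENOMINATOR
    half_window: float = 5.0

    def __post_init__(self) -> None:
        if self.half_window <= 0:
            raise ParameterError("half_window must be > 0")
        positions = [a.wavenumber_cm1 for a in self.assignments]
        if len(set(positions)) != len(positions):
            raise ParameterError("panel positions must be unique")

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.wavenumber_cm1 for a in self.assignments])

    @property
    def labels(self) -> list[str]:
        return [a.label for a in self.assignments]

    def label_for(self, wavenumber: float) -> str:
        for a in self.assignments:
            if a.wavenumber_cm1 == wavenumber:
                return a.label
        raise KeyError(f"no panel peak at {wavenumber} cm-1")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "wavenumber_cm1": [a.wavenumber_cm1 for a in self.assignments],
                "metabolite": [a.metabolite for a in self.assignments],
                "vibrational_mode": [a.vibrational_mode for a in self.assignments],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "PeakPanel":
        df = pd.read_csv(path)
        return cls(
            [
                PeakAssignment(
                    float(r["wavenumber_cm1"]),
                    str(r["metabolite"]),
                    str(r.get("vibrational_mode", "")),
                )
                for _, r in df.iterrows()
            ],
            **kwargs,
        )


def default_panel() -> PeakPanel:
    """The 40-band serum metabolite panel (621-1682 cm-1)."""
    return PeakPanel(
        [PeakAssignment(float(w), m, v) for w, m, v in _PANEL_ROWS]
    )


@dataclass
class PeakTable:
    """Samples x peaks matrix of ratiometric peak values."""

    frame: pd.DataFrame  # index sample_id, columns panel labels
    panel: PeakPanel = field(default_factory=default_panel)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def column(self, wavenumber: float) -> pd.Series:
        """The ratiometric values of one panel peak, by nominal position."""
        return self.frame[self.panel.label_for(wavenumber)]

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path: str | Path, panel: PeakPanel | None = None) -> "PeakTable":
        return cls(pd.read_csv(path, index_col="sample_id"), panel or default_panel())


# ---------------------------------------------------------------------------


def extract_peak(
    wavenumbers: np.ndarray,
    intensities: np.ndarray,
    position: float,
    half_window: float = 5.0,
) -> float:
    """Peak value: maximum intensity within ``position +/- half_window``.

    The windowed maximum is robust to calibration drift of a few cm-1,
    and local: channels outside the window never affect the value.
    """
    lo, hi = position - half_window, position + half_window
    if lo < wavenumbers[0] - 1e-9 or hi > wavenumbers[-1] + 1e-9:
        raise AxisError(
            f"window [{lo}, {hi}] cm-1 outside spectrum range "
            f"[{wavenumbers[0]}, {wavenumbers[-1]}]"
        )
    mask = (wavenumbers >= lo - 1e-9) & (wavenumbers <= hi + 1e-9)
    return float(np.max(intensities[mask]))


def mean_spectrum(points: Sequence[ProcessedSpectrum]) -> tuple[np.ndarray, np.ndarray]:
    """Average processed point spectra on their common grid."""
    axis0 = points[0].wavenumbers
    for p in points[1:]:
        if not np.array_equal(p.wavenumbers, axis0):
            raise AxisError("point spectra are not on a common grid")
    return axis0, np.mean([p.intensities for p in points], axis=0)


def build_peak_table(
    cohort: Iterable[tuple[str, Sequence[ProcessedSpectrum]]] | dict,
    panel: PeakPanel | None = None,
) -> PeakTable:
    """Quantify every panel peak for every sample, ratiometrically.

    Per sample the processed point spectra are averaged first (maximising
    SNR), peaks are extracted from the mean spectrum, and each value is
    divided by the denominator-band value of the same sample.  The
    denominator column is therefore identically 1.

    Before the division, the per-spectrum mean removed by SNV is restored
    (mean ``snv_offset`` over the points): a constant added to both
    numerator and denominator would otherwise bias every ratio toward 1,
    while the SNV scale cancels in the ratio regardless.
    """
    panel = panel or default_panel()
    if isinstance(cohort, dict):
        cohort = cohort.items()
    rows = {}
    for sample_id, points in cohort:
        if len(points) < 1:
            raise DegenerateDataError(f"{sample_id}: no processed point spectra")
        axis, mean = mean_spectrum(points)
        offset = float(np.mean([getattr(p, "snv_offset", 0.0) for p in points]))
        mean = mean + offset
        denom = extract_peak(
            axis, mean, panel.denominator_wavenumber, panel.half_window
        )
        if denom <= 0:
            raise RatiometricError(
                f"{sample_id}: denominator peak at "
                f"{panel.denominator_wavenumber} cm-1 is {denom:.4g} <= 0"
            )
        rows[sample_id] = [
            extract_peak(axis, mean, a.wavenumber_cm1, panel.half_window) / denom
            for a in panel.assignments
        ]
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=panel.labels)
    frame.index.name = "sample_id"
    return PeakTable(frame, panel)
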