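"""Synthetic serum Raman cohorts with a full ground-truth record.

A sample's fingerprint spectrum is generated as

    intensity(v) = baseline(v) + sum_k a_k * shape(v - v_k; FWHM) + noise + spikes

with the 40 panel bands as narrow pseudo-Voigt peaks riding on a smooth,
strictly positive polynomial fluorescence background that dominates the
peaks several-fold, shot-like Gaussian channel noise, and sporadic
cosmic-ray spikes of 1-3 channels.  Group structure enters as
multiplicative effects on selected peak amplitudes; biological
variability is lognormal on each amplitude (default cv 15%).

Protein panels are linear in the standardized true peak ratios through a
configurable loading matrix (plus an optional loading on the sample's
standardized NAR score, so response classes can carry protein signal of
their own), and NAR scores follow a linear model on the standardized
ratios, truncated at zero.

Everything drawn is logged in a :class:`GroundTruth` so recovery tests
can compute every expected statistic independently of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from seraman.exceptions import ConfigError
from seraman.io import (
    CohortMetadata,
    PointSpectrum,
    SampleSpectra,
    write_metadata,
    write_protein_panel,
    write_spectra,
)
from seraman.peaks import DEFAULT_DENOMINATOR, default_panel

#: Analytes treated as DNA-damage-response markers (lymphocyte panel);
#: everything else in a generated protein panel is a cytokine/chemokine.
DDR_ANALYTES = ("ATR", "CHK1", "CHK2", "MDM2", "H2AX", "p21", "p53")

CYTOKINE_ANALYTES = (
    "IL-1b", "IL-1ra", "IL-2", "IL-4", "IL-6", "IL-8", "IL-10", "IL-13",
    "IL-17", "IFN-g", "IP-10", "MCP-1", "MIP-1a", "MIP-1b", "PDGF-bb",
)


def default_base_amplitudes() -> dict[float, float]:
    """Baseline peak amplitudes for a healthy serum-like spectrum.

    The 1448 cm-1 lipid/protein CH-deformation band dominates serum
    fingerprint spectra (amplitude 1.0, the ratiometric reference); the
    sharp 1002 cm-1 phenylalanine ring-breathing mode and the 1657 cm-1
    amide/lipid band are the next strongest; the remaining bands are
    typically 10-35% of the reference and cycle through 0.10-0.35 here.
    """
    panel = default_panel()
    amps = {}
    for i, a in enumerate(panel.assignments):
        amps[a.wavenumber_cm1] = 0.10 + 0.25 * ((i * 7) % 10) / 9.0
    amps[1448.0] = 1.0
    amps[1002.0] = 0.60
    amps[1657.0] = 0.45
    return amps


@dataclass
class SyntheticConfig:
    """Generative parameters of a synthetic cohort.

    Amplitude units are arbitrary; the noise sd and cosmic amplitudes are
    expressed relative to the denominator-band amplitude so configs stay
    meaningful under rescaling.
    """

    seed: int
    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"healthy": 6, "PDAC": 6}
    )
    grid: tuple[float, float, float] = (600.0, 1800.0, 1.0)
    peak_shape: str = "pseudo_voigt"  # gaussian | lorentzian | pseudo_voigt
    peak_fwhm: float = 8.0
    base_amplitudes: dict[float, float] = field(
        default_factory=default_base_amplitudes
    )
    group_effects: dict[str, dict[float, float]] = field(default_factory=dict)
    baseline_degree: int = 6
    baseline_level: tuple[float, float] = (5.0, 20.0)  # x denominator amplitude
    noise_sd: float = 0.01  # fraction of denominator amplitude
    cosmic_rate: float = 0.05  # spikes per point spectrum
    cosmic_amplitude: tuple[float, float] = (20.0, 100.0)  # x absolute noise sd
    cosmic_width: tuple[int, int] = (1, 3)  # channels
    n_points: int = 25
    amplitude_cv: float = 0.15
    protein_loadings: pd.DataFrame | None = None  # analytes x panel wavenumbers
    protein_nar_loading: dict[str, float] = field(default_factory=dict)
    protein_noise_sd: float = 1.0
    protein_offset: float = 6.0
    nar_groups: tuple[str, ...] = ()
    nar_beta0: float = 11.0
    nar_betas: dict[float, float] = field(default_factory=dict)
    nar_noise_sd: float = 3.0
    nar_from_latent: tuple[str, ...] = ()  # groups whose NAR ignores their peaks

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.peak_shape not in ("gaussian", "lorentzian", "pseudo_voigt"):
            raise ConfigError(f"unknown peak shape {self.peak_shape!r}")
        if self.peak_fwhm <= 0 or self.amplitude_cv < 0 or self.noise_sd < 0:
            raise ConfigError("widths, cv and noise sd must be nonnegative")
        if any(a <= 0 for a in self.base_amplitudes.values()):
            raise ConfigError("base amplitudes must be > 0")
        panel_wn = set(self.base_amplitudes)
        for g, eff in self.group_effects.items():
            extra = set(eff) - panel_wn
            if extra:
                raise ConfigError(f"group {g!r} effects on unknown peaks {extra}")
        if self.baseline_degree < 0 or self.baseline_degree > 9:
            raise ConfigError("baseline degree must be within the 0..9 range")

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.array(sorted(self.base_amplitudes))

    @property
    def axis(self) -> np.ndarray:
        start, stop, step = self.grid
        return np.arange(start, stop + step / 2, step, dtype=float)


@dataclass
class GroundTruth:
    """Everything the generator drew, for independent recomputation."""

    amplitudes: pd.DataFrame  # samples x wavenumbers (true a_k)
    ratios: pd.DataFrame  # samples x wavenumbers (a_k / a_denominator)
    baseline_coeffs: dict[str, np.ndarray]  # per sample, monomial on [-1,1]
    spikes: pd.DataFrame  # sample, point, channel, width, amplitude
    group_effects: dict[str, dict[float, float]]
    noise_sd_abs: pd.Series  # per sample, absolute channel-noise sd
    nar_betas: dict[float, float]
    nar_beta0: float
    nar_noise_sd: float
    protein_loadings: pd.DataFrame | None
    peak_z: pd.DataFrame | None = None  # standardized ratios used for proteins/NAR

    def fold_change(self, case: str, reference: str, wavenumber: float) -> float:
        """Configured (true) group fold change at one band."""
        e_case = self.group_effects.get(case, {}).get(wavenumber, 1.0)
        e_ref = self.group_effects.get(reference, {}).get(wavenumber, 1.0)
        return e_case / e_ref


# ---------------------------------------------------------------------------
# low-level pieces


def peak_profile(x: np.ndarray, fwhm: float, shape: str = "pseudo_voigt") -> np.ndarray:
    """Unit-height line shape centred at zero with the given FWHM."""
    g = np.exp(-4.0 * np.log(2.0) * (x / fwhm) ** 2)
    l = 1.0 / (1.0 + 4.0 * (x / fwhm) ** 2)
    if shape == "gaussian":
        return g
    if shape == "lorentzian":
        return l
    return 0.5 * g + 0.5 * l


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 lognormal multiplicative noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)


def draw_baseline_coeffs(config: SyntheticConfig, rng: np.random.Generator,
                         denom_amp: float) -> np.ndarray:
    """Monomial coefficients (on a [-1,1] axis) of a strictly positive
    background dominating the peaks ``baseline_level`` times."""
    lo, hi = config.baseline_level
    c0 = rng.uniform(lo, hi) * denom_amp
    coeffs = np.zeros(config.baseline_degree + 1)
    coeffs[0] = c0
    if config.baseline_degree >= 1:
        # bounded so that the curve stays >= c0/2 > 0 on [-1,1]
        coeffs[1:] = rng.uniform(-1, 1, config.baseline_degree) * (
            c0 / (2.0 * config.baseline_degree)
        )
    return coeffs


def _baseline_curve(coeffs: np.ndarray, axis: np.ndarray) -> np.ndarray:
    t = 2.0 * (axis - axis[0]) / (axis[-1] - axis[0]) - 1.0
    return np.polynomial.polynomial.polyval(t, coeffs)


def render_clean_spectrum(
    config: SyntheticConfig,
    amplitudes: dict[float, float],
    baseline_coeffs: np.ndarray,
) -> np.ndarray:
    """Noise- and spike-free analytic spectrum on the config grid."""
    axis = config.axis
    y = _baseline_curve(baseline_coeffs, axis)
    for wn, a in amplitudes.items():
        y = y + a * peak_profile(axis - wn, config.peak_fwhm, config.peak_shape)
    return y


def generate_point_spectrum(
    config: SyntheticConfig,
    amplitudes: dict[float, float],
    baseline_coeffs: np.ndarray,
    rng: np.random.Generator,
    sample_id: str = "S",
    point_index: int = 0,
) -> tuple[PointSpectrum, list[dict]]:
    """One acquisition point: clean spectrum + channel noise + spikes.

    Returns the spectrum and the list of injected spike records
    ``{"sample_id", "point_index", "channel", "width", "amplitude"}``.
    """
    axis = config.axis
    y = render_clean_spectrum(config, amplitudes, baseline_coeffs)
    noise_abs = config.noise_sd * amplitudes[DEFAULT_DENOMINATOR]
    if noise_abs > 0:
        y = y + rng.normal(0.0, noise_abs, axis.size)
    spikes: list[dict] = []
    if config.cosmic_rate > 0 and rng.random() < config.cosmic_rate:
        w_lo, w_hi = config.cosmic_width
        width = int(rng.integers(w_lo, w_hi + 1))
        channel = int(rng.integers(0, axis.size - width))
        amp = rng.uniform(*config.cosmic_amplitude) * max(noise_abs, 1e-12)
        y[channel : channel + width] += amp
        spikes.append(
            {
                "sample_id": sample_id,
                "point_index": point_index,
                "channel": channel,
                "width": width,
                "amplitude": amp,
            }
        )
    return (
        PointSpectrum(sample_id, point_index, axis.copy(), y),
        spikes,
    )


# ---------------------------------------------------------------------------
# cohort generation


def _draw_sample_amplitudes(
    config: SyntheticConfig, group: str, rng: np.random.Generator
) -> dict[float, float]:
    effects = config.group_effects.get(group, {})
    wns = config.wavenumbers
    factors = _lognormal_factor(rng, config.amplitude_cv, wns.size)
    return {
        float(wn): config.base_amplitudes[wn] * effects.get(wn, 1.0) * f
        for wn, f in zip(wns, factors)
    }


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[SampleSpectra], list[CohortMetadata], pd.DataFrame | None, GroundTruth]:
    """Generate spectra, metadata, an optional protein panel, and truth.

    Requires >= 2 groups with >= 3 samples each.  All randomness flows
    from ``config.seed``.
    """
    if len(config.n_per_group) < 2:
        raise ConfigError("need >= 2 groups")
    if min(config.n_per_group.values()) < 3:
        raise ConfigError("need >= 3 samples per group")
    rng = np.random.default_rng(config.seed)
    wns = config.wavenumbers
    denom = DEFAULT_DENOMINATOR

    sample_ids: list[str] = []
    groups: list[str] = []
    amp_rows: list[list[float]] = []
    baseline_coeffs: dict[str, np.ndarray] = {}
    samples: list[SampleSpectra] = []
    spike_records: list[dict] = []
    noise_abs: dict[str, float] = {}

    for group, n in config.n_per_group.items():
        for i in range(n):
            sid = f"{group}_{i:03d}"
            sample_ids.append(sid)
            groups.append(group)
            amps = _draw_sample_amplitudes(config, group, rng)
            amp_rows.append([amps[wn] for wn in wns])
            coeffs = draw_baseline_coeffs(config, rng, amps[denom])
            baseline_coeffs[sid] = coeffs
            noise_abs[sid] = config.noise_sd * amps[denom]
            points = []
            for j in range(config.n_points):
                spec, spikes = generate_point_spectrum(
                    config, amps, coeffs, rng, sample_id=sid, point_index=j
                )
                points.append(spec)
                spike_records.extend(spikes)
            samples.append(
                SampleSpectra(sid, points, common_axis=config.axis)
            )

    amplitudes = pd.DataFrame(
        amp_rows, index=pd.Index(sample_ids, name="sample_id"), columns=wns
    )
    ratios = amplitudes.div(amplitudes[denom], axis=0)
    group_s = pd.Series(groups, index=amplitudes.index, name="group")

    # standardized true ratios, the latent drivers of proteins and NAR
    z = (ratios - ratios.mean()) / ratios.std(ddof=1).replace(0.0, 1.0)

    # NAR scores: linear in z over nar_betas, truncated at 0
    nar = pd.Series(np.nan, index=amplitudes.index, name="nar_score")
    z_nar = pd.Series(0.0, index=amplitudes.index)
    if config.nar_groups:
        for sid in amplitudes.index:
            g = group_s[sid]
            if g not in config.nar_groups:
                continue
            if g in config.nar_from_latent:
                # response class decoupled from this sample's spectrum
                contrib = sum(
                    b * rng.normal() for b in config.nar_betas.values()
                )
            else:
                contrib = sum(
                    b * z.loc[sid, wn] for wn, b in config.nar_betas.items()
                )
            score = config.nar_beta0 + contrib + rng.normal(0, config.nar_noise_sd)
            nar[sid] = max(score, 0.0)
        observed = nar.dropna()
        if len(observed) > 1 and observed.std(ddof=1) > 0:
            z_nar.loc[observed.index] = (
                observed - observed.mean()
            ) / observed.std(ddof=1)

    # protein panel: L @ z + optional NAR loading + noise, shifted positive
    proteins = None
    if config.protein_loadings is not None:
        L = config.protein_loadings
        missing = set(L.columns) - set(wns)
        if missing:
            raise ConfigError(f"protein loadings on unknown peaks {missing}")
        raw = z[list(L.columns)].to_numpy() @ L.to_numpy().T
        raw = raw + rng.normal(0, config.protein_noise_sd, raw.shape)
        for j, analyte in enumerate(L.index):
            g = config.protein_nar_loading.get(str(analyte), 0.0)
            if g:
                raw[:, j] += g * z_nar.to_numpy()
        proteins = pd.DataFrame(
            np.clip(raw + config.protein_offset, 0.0, None),
            index=amplitudes.index,
            columns=L.index,
        )

    metadata = [
        CohortMetadata(
            sample_id=sid,
            group=group_s[sid],
            nar_score=None if pd.isna(nar[sid]) else float(nar[sid]),
        )
        for sid in amplitudes.index
    ]
    truth = GroundTruth(
        amplitudes=amplitudes,
        ratios=ratios,
        baseline_coeffs=baseline_coeffs,
        spikes=pd.DataFrame(
            spike_records,
            columns=["sample_id", "point_index", "channel", "width", "amplitude"],
        ),
        group_effects=config.group_effects,
        noise_sd_abs=pd.Series(noise_abs, name="noise_sd_abs"),
        nar_betas=config.nar_betas,
        nar_beta0=config.nar_beta0,
        nar_noise_sd=config.nar_noise_sd,
        protein_loadings=config.protein_loadings,
        peak_z=z,
    )
    return samples, metadata, proteins, truth


def draw_ratio_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Draw true ratiometric peak values for a cohort without rendering
    spectra — the amplitude model only (group effects x lognormal
    biological variation, ratioed against the denominator band).

    Useful for statistical calibration studies where the spectral
    rendering and preprocessing stages are not under test.
    """
    rng = np.random.default_rng(config.seed)
    wns = config.wavenumbers
    rows, ids, groups = [], [], []
    for group, n in config.n_per_group.items():
        for i in range(n):
            amps = _draw_sample_amplitudes(config, group, rng)
            rows.append([amps[wn] for wn in wns])
            ids.append(f"{group}_{i:03d}")
            groups.append(group)
    amplitudes = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"),
                              columns=wns)
    ratios = amplitudes.div(amplitudes[DEFAULT_DENOMINATOR], axis=0)
    return ratios, pd.Series(groups, index=amplitudes.index, name="group")


# ---------------------------------------------------------------------------
# presets


def preset_pdac_vs_cp(
    seed: int,
    n_healthy: int = 48,
    n_pdac: int = 18,
    n_cp: int = 20,
    n_points: int = 25,
    **overrides,
) -> SyntheticConfig:
    """Diagnosis cohort: healthy vs pancreatic cancer vs pancreatitis.

    Cancer shows elevated sugar/glucose and aromatic amino-acid bands and
    depressed carotenoid, short fatty-acid and unsaturated-lipid bands.
    The sugar (852), tyrosine (828) and DNA/RNA (805) bands separate
    cancer from pancreatitis; carotenoid and glucose changes are shared
    by both diseases.
    """
    pdac = {
        852.0: 1.8, 828.0: 1.65, 805.0: 1.6,
        1126.0: 1.2, 1011.0: 1.2, 1031.0: 1.15, 1585.0: 1.15, 1605.0: 1.15,
        757.0: 1.15, 1552.0: 1.15, 1615.0: 1.15, 1575.0: 1.15,
        1257.0: 1.2, 1268.0: 1.2,
        957.0: 0.85, 1657.0: 0.85, 938.0: 0.85, 1155.0: 0.8, 1518.0: 0.8,
    }
    cp = {
        1126.0: 1.2, 1011.0: 1.15, 1063.0: 1.1, 1082.0: 1.1,
        1155.0: 0.8, 1518.0: 0.8, 957.0: 0.9, 938.0: 0.9,
    }
    kwargs = dict(
        seed=seed,
        n_per_group={"healthy": n_healthy, "PDAC": n_pdac, "CP": n_cp},
        group_effects={"PDAC": pdac, "CP": cp},
        n_points=n_points,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


def default_protein_loadings() -> pd.DataFrame:
    """Loading matrix linking cytokines/DDR markers to peak ratios.

    Encodes the qualitative correlation structure seen in serum studies:
    IL-8 loads on arginine (992) and sugars (852); IL-1b loads negatively
    on the aromatic amino-acid bands; MDM2/p53 load on DNA (671, 744) and
    NADH (1575); ATR/CHK1/CHK2 load on membrane lipids (701, 719) and the
    957 fatty-acid band.
    """
    analytes = list(CYTOKINE_ANALYTES) + list(DDR_ANALYTES)
    peaks = [671.0, 744.0, 701.0, 719.0, 757.0, 828.0, 852.0, 878.0,
             898.0, 938.0, 957.0, 992.0, 1155.0, 1575.0, 1615.0]
    L = pd.DataFrame(0.0, index=analytes, columns=peaks)
    L.loc["IL-8", [992.0, 852.0]] = [0.7, 0.6]
    L.loc["IL-1b", [878.0, 757.0, 828.0, 1615.0]] = -0.5
    L.loc["IL-2", [992.0, 938.0]] = [0.5, -0.5]
    L.loc["IL-17", [898.0]] = -0.4
    L.loc["MCP-1", [852.0]] = 0.5
    L.loc["MDM2", [671.0, 744.0, 1575.0]] = 0.6
    L.loc["p53", [671.0, 744.0, 1575.0]] = 0.6
    L.loc["ATR", [701.0, 719.0, 957.0]] = 0.6
    L.loc["CHK1", [701.0, 719.0, 957.0]] = 0.5
    L.loc["CHK2", [701.0, 719.0, 957.0]] = 0.5
    return L


def preset_larc_response(
    seed: int,
    n_pre: int = 30,
    n_post: int = 85,
    n_points: int = 25,
    **overrides,
) -> SyntheticConfig:
    """Treatment-response cohort: rectal cancer pre/post chemoradiation.

    NAR scores are generated from the pre-treatment peak ratios (glycine,
    sugars and carotenoid bands load positively — worse prognosis; the
    amino-acid 1207 and saturated fatty-acid 1257 bands negatively), so
    poor responders show elevated 852 sugars by construction.  For
    post-treatment samples the spectral group effects are reset toward
    healthy and the NAR score derives from an independent latent draw:
    the metabolome no longer tracks the score after therapy.
    """
    nar_betas = {
        898.0: 4.0, 852.0: 3.0, 1155.0: 2.5, 1518.0: 2.5,
        1207.0: -3.0, 1257.0: -2.5,
    }
    pre = {852.0: 1.3, 643.0: 1.25, 805.0: 0.85, 898.0: 1.2}
    kwargs = dict(
        seed=seed,
        n_per_group={"LARC_pre": n_pre, "LARC_post": n_post},
        group_effects={"LARC_pre": pre},
        nar_groups=("LARC_pre", "LARC_post"),
        nar_from_latent=("LARC_post",),
        nar_betas=nar_betas,
        nar_beta0=11.0,
        nar_noise_sd=3.0,
        protein_loadings=default_protein_loadings(),
        protein_nar_loading={a: 1.2 for a in DDR_ANALYTES},
        n_points=n_points,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


def preset_null(seed: int, n_each: int = 10, n_points: int = 25,
                **overrides) -> SyntheticConfig:
    """Two groups with identical distributions and no protein structure."""
    kwargs = dict(
        seed=seed,
        n_per_group={"healthy": n_each, "PDAC": n_each},
        group_effects={},
        n_points=n_points,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


PRESETS = {
    "pdac-vs-cp": preset_pdac_vs_cp,
    "larc-response": preset_larc_response,
    "null": preset_null,
}


# ---------------------------------------------------------------------------
# fixtures on disk


def write_fixture(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a cohort and write it out as plain CSV files.

    Emits ``spectra.csv`` (long format), ``metadata.csv``,
    ``proteins.csv`` (if configured), ``truth_amplitudes.csv``,
    ``truth_spikes.csv`` and ``config.txt``.  Byte-stable for a fixed
    seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples, metadata, proteins, truth = generate_cohort(config)
    paths = {}
    paths["spectra"] = out / "spectra.csv"
    write_spectra(samples, paths["spectra"])
    paths["metadata"] = out / "metadata.csv"
    write_metadata(metadata, paths["metadata"])
    if proteins is not None:
        paths["proteins"] = out / "proteins.csv"
        write_protein_panel(proteins, paths["proteins"])
    paths["truth_amplitudes"] = out / "truth_amplitudes.csv"
    truth.amplitudes.to_csv(paths["truth_amplitudes"])
    paths["truth_spikes"] = out / "truth_spikes.csv"
    truth.spikes.to_csv(paths["truth_spikes"], index=False)
    paths["config"] = out / "config.txt"
    lines = []
    for key, value in vars(config).items():
        if isinstance(value, pd.DataFrame):
            value = "<matrix>"
        lines.append(f"{key} = {value!r}")
    paths["config"].write_text("\n".join(lines) + "\n")
    return paths
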