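"""End-to-end analysis runs with manifests.

Three orchestrated workflows mirror the study designs the package
supports:

* :func:`run_diagnosis` — healthy vs pancreatic cancer vs pancreatitis:
  preprocessing, peak table, volcano plots per comparison, per-peak ROC
  for cancer-vs-pancreatitis, PCA and PCA-tSNE embeddings, group-mean
  difference spectra.
* :func:`run_response` — rectal cancer pre/post chemoradiation:
  NAR responder stratification, peak-NAR correlations per timepoint,
  pre-vs-post volcano within responder classes, per-peak ROC for
  poor-vs-(complete+partial).
* :func:`run_integration` — peaks + cytokines + DDR markers:
  cross-block correlation matrices, protein rank metrics and
  differential calls, and a PCA+SVM leave-one-out comparison of nested
  feature sets.

Every run writes tidy CSVs plus a ``manifest.txt`` (config hash, seed,
version, outputs) sufficient to reproduce the outputs bit-for-bit.
Inputs are never mutated; reruns into a clean directory are byte-stable.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from seraman import __version__ as _version
from seraman.exceptions import ConfigError
from seraman.io import (
    apply_exclusions,
    harmonize_axis,
    metadata_frame,
    read_metadata,
    read_protein_panel,
    read_spectra,
)
from seraman.peaks import PeakPanel, build_peak_table, default_panel, mean_spectrum
from seraman.preprocess import PreprocessParams, ProcessedSpectrum, preprocess_sample
from seraman import gsea, stats
from seraman.simulate import DDR_ANALYTES, PRESETS, generate_cohort

logger = logging.getLogger("seraman")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    out_dir: Path
    seed: int = 0
    # either a simulation preset ...
    preset: str | None = None
    preset_kwargs: dict = field(default_factory=dict)
    # ... or input files
    spectra_path: Path | None = None
    metadata_path: Path | None = None
    proteins_path: Path | None = None
    # processing
    grid: tuple[float, float, float] = (600.0, 1800.0, 1.0)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    panel: PeakPanel = field(default_factory=default_panel)
    longitudinal: bool = False
    # analysis
    comparisons: list[tuple[str, str]] | None = None  # (case, reference)
    c_grid: list[int] = field(default_factory=lambda: list(range(1, 101)))
    n_boot: int = 2000

    def content_hash(self) -> str:
        blob = repr(
            {
                k: (v.frame.to_csv() if hasattr(v, "frame") else repr(v))
                for k, v in sorted(vars(self).items())
                if k != "out_dir"
            }
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_cohort(config: RunConfig, default_preset: str):
    """Simulate or read the cohort, harmonize axes, apply exclusions."""
    t0 = time.perf_counter()
    if config.spectra_path is not None:
        samples = read_spectra(config.spectra_path)
        metadata = (
            read_metadata(config.metadata_path) if config.metadata_path else []
        )
        proteins = (
            read_protein_panel(config.proteins_path)
            if config.proteins_path
            else None
        )
        truth = None
        samples = [harmonize_axis(s, config.grid) for s in samples]
    else:
        preset = config.preset or default_preset
        if preset not in PRESETS:
            raise ConfigError(f"unknown preset {preset!r}")
        sim_config = PRESETS[preset](seed=config.seed, **config.preset_kwargs)
        samples, metadata, proteins, truth = generate_cohort(sim_config)
    metadata = apply_exclusions(metadata, longitudinal=config.longitudinal)
    kept = {m.sample_id for m in metadata}
    dropped = [s.sample_id for s in samples if s.sample_id not in kept]
    if dropped:
        logger.warning("excluded %d samples: %s", len(dropped), dropped)
    samples = [s for s in samples if s.sample_id in kept]
    logger.info("cohort loaded (%d samples) in %.2fs",
                len(samples), time.perf_counter() - t0)
    return samples, metadata, proteins, truth


def _peak_table(samples, config: RunConfig):
    t0 = time.perf_counter()
    processed = {
        s.sample_id: preprocess_sample(s, config.preprocess) for s in samples
    }
    for sid, pts in processed.items():
        bad = [p.point_index for p in pts if not p.qc.get("baseline_converged")]
        if bad:
            logger.warning("%s: baseline not converged for points %s", sid, bad)
    table = build_peak_table(processed, config.panel)
    logger.info("preprocessing + quantification in %.2fs",
                time.perf_counter() - t0)
    return processed, table


def _group_mean_spectra(processed: dict, meta: pd.DataFrame):
    """Cohort-mean processed spectrum per group (mean of sample means)."""
    out = {}
    for group, ids in meta.groupby("group").groups.items():
        means = []
        axis = None
        for sid in ids:
            if sid in processed:
                axis, m = mean_spectrum(processed[sid])
                means.append(m)
        if means:
            out[group] = ProcessedSpectrum(
                sample_id=str(group), point_index=0, wavenumbers=axis,
                intensities=np.mean(means, axis=0), baseline=np.zeros_like(axis),
            )
    return out


def _write_manifest(config: RunConfig, out: Path, outputs: list[str]) -> None:
    lines = [
        f"config_hash = {config.content_hash()}",
        f"seed = {config.seed}",
        f"seraman_version = {_version}",
    ] + [f"output = {name}" for name in sorted(outputs)]
    (out / "manifest.txt").write_text("\n".join(lines) + "\n")


def _roc_table(table_frame, mask_pos, mask_neg, seed, n_boot):
    rows = []
    for i, col in enumerate(table_frame.columns):
        scores = pd.concat([table_frame.loc[mask_pos, col],
                            table_frame.loc[mask_neg, col]])
        labels = np.r_[np.ones(int(mask_pos.sum())), np.zeros(int(mask_neg.sum()))]
        r = stats.roc_auc(scores.to_numpy(), labels, n_boot=n_boot,
                          seed=seed + i)
        rows.append((col, r.auc, r.ci_low, r.ci_high, r.n_pos, r.n_neg))
    return pd.DataFrame(
        rows, columns=["feature", "auc", "ci_low", "ci_high", "n_pos", "n_neg"]
    )


# ---------------------------------------------------------------------------


def run_diagnosis(config: RunConfig) -> dict:
    """Diagnosis workflow (healthy / PDAC / CP).  Returns result objects."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples, metadata, _, truth = _load_cohort(config, "pdac-vs-cp")
    meta = metadata_frame(metadata)
    groups_present = set(meta["group"])
    if "healthy" not in groups_present or not (
        {"PDAC", "CP"} & groups_present
    ):
        raise ConfigError(
            f"diagnosis run needs healthy plus PDAC and/or CP, have {groups_present}"
        )
    processed, table = _peak_table(samples, config)
    outputs = ["peak_table.csv"]
    table.to_csv(out / "peak_table.csv")

    comparisons = config.comparisons or [
        (case, ref)
        for case, ref in [("PDAC", "healthy"), ("CP", "healthy"), ("PDAC", "CP")]
        if case in groups_present and ref in groups_present
    ]
    results = {"table": table, "meta": meta, "truth": truth, "volcano": {}}
    for case, ref in comparisons:
        v = stats.volcano(table, meta["group"], case, ref)
        name = f"volcano_{case}_vs_{ref}.csv"
        v.to_csv(out / name, index=False)
        outputs.append(name)
        results["volcano"][(case, ref)] = v

    if {"PDAC", "CP"} <= groups_present:
        roc = _roc_table(
            table.frame,
            meta["group"] == "PDAC",
            meta["group"] == "CP",
            config.seed,
            config.n_boot,
        )
        roc.to_csv(out / "roc_PDAC_vs_CP.csv", index=False)
        outputs.append("roc_PDAC_vs_CP.csv")
        results["roc"] = roc

    emb = stats.pca(table.frame, k=2)
    emb.coordinates.assign(group=meta["group"]).to_csv(out / "pca.csv")
    outputs.append("pca.csv")
    results["pca"] = emb
    if table.frame.shape[0] >= 8:
        tsne = stats.pca_tsne(table.frame, seed=config.seed)
        tsne.coordinates.assign(group=meta["group"]).to_csv(out / "tsne.csv")
        outputs.append("tsne.csv")
        results["tsne"] = tsne

    gm = _group_mean_spectra(processed, meta)
    for case, ref in comparisons:
        if case in gm and ref in gm:
            d = stats.difference_spectrum(gm[case], gm[ref])
            name = f"difference_{case}_vs_{ref}.csv"
            pd.DataFrame(
                {"wavenumber_cm1": d.wavenumbers, "difference": d.intensities}
            ).to_csv(out / name, index=False)
            outputs.append(name)
    _write_manifest(config, out, outputs)
    return results


def run_response(config: RunConfig) -> dict:
    """Treatment-response workflow (LARC pre/post with NAR scores)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples, metadata, proteins, truth = _load_cohort(config, "larc-response")
    meta = metadata_frame(metadata)
    larc = meta[meta["group"].str.startswith("LARC")]
    if larc.empty or larc["nar_score"].notna().sum() == 0:
        raise ConfigError("response run needs LARC samples with NAR scores")
    processed, table = _peak_table(samples, config)
    outputs = ["peak_table.csv", "stratification.csv"]
    table.to_csv(out / "peak_table.csv")

    strata = stats.stratify_nar_series(meta["nar_score"])
    strat = pd.DataFrame(
        {"group": meta["group"], "nar_score": meta["nar_score"],
         "responder_class": strata}
    )
    strat.to_csv(out / "stratification.csv")
    counts = strata.dropna().value_counts()
    if len(counts) == 1:
        logger.warning("all NAR-scored samples fall in one stratum: %s",
                       counts.index[0])
    results = {"table": table, "meta": meta, "strata": strata, "truth": truth,
               "proteins": proteins, "nar_corr": {}, "volcano": {}, "roc": {}}

    for tp, group in [("pre", "LARC_pre"), ("post", "LARC_post")]:
        ids = meta.index[(meta["group"] == group)]
        scored = meta.loc[ids, "nar_score"].dropna()
        skipped = set(ids) - set(scored.index)
        if skipped:
            logger.warning("%s: no NAR score, excluded from correlation: %s",
                           tp, sorted(skipped))
        if len(scored) < 3:
            continue
        r = stats.pearson_matrix(
            table.frame.loc[scored.index], scored.to_frame("NAR")
        )
        name = f"corr_nar_{tp}.csv"
        r.to_csv(out / name)
        outputs.append(name)
        results["nar_corr"][tp] = r["NAR"]

    timepoint = meta["group"].map(
        {"LARC_pre": "pre", "LARC_post": "post"}
    )
    for cls in ("complete", "partial", "poor"):
        in_cls = strata == cls
        n_pre = int((in_cls & (timepoint == "pre")).sum())
        n_post = int((in_cls & (timepoint == "post")).sum())
        if min(n_pre, n_post) < 2:
            continue
        sub = table.frame.loc[in_cls]
        v = stats.volcano(sub, timepoint.loc[in_cls], "post", "pre")
        name = f"volcano_post_vs_pre_{cls}.csv"
        v.to_csv(out / name, index=False)
        outputs.append(name)
        results["volcano"][cls] = v

    for tp in ("pre", "post"):
        in_tp = timepoint == tp
        pos = in_tp & (strata == "poor")
        neg = in_tp & strata.isin(["complete", "partial"])
        if pos.sum() >= 2 and neg.sum() >= 2:
            roc = _roc_table(table.frame, pos, neg, config.seed, config.n_boot)
            name = f"roc_poor_vs_rest_{tp}.csv"
            roc.to_csv(out / name, index=False)
            outputs.append(name)
            results["roc"][tp] = roc
    _write_manifest(config, out, outputs)
    return results


def run_integration(config: RunConfig) -> dict:
    """Peaks + cytokines + DDR integration workflow."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples, metadata, proteins, truth = _load_cohort(config, "larc-response")
    if proteins is None:
        raise ConfigError("integration run needs a protein panel")
    meta = metadata_frame(metadata)
    processed, table = _peak_table(samples, config)
    strata = stats.stratify_nar_series(meta["nar_score"])

    ddr_cols = [c for c in proteins.columns if c in DDR_ANALYTES]
    cyt_cols = [c for c in proteins.columns if c not in DDR_ANALYTES]
    common = table.frame.index.intersection(proteins.index)
    # classification compares complete vs poor responders after therapy
    # when post-treatment samples exist; otherwise whatever is aligned
    if (meta.loc[common, "group"] == "LARC_post").sum() >= 6:
        common = common[meta.loc[common, "group"] == "LARC_post"]
    binary = strata.loc[common].isin(["complete", "poor"])
    cohort_ids = common[binary]
    labels = strata.loc[cohort_ids]
    if len(cohort_ids) < 6 or labels.value_counts().min() < 3:
        raise ConfigError(
            "integration needs >= 6 aligned samples with >= 3 complete "
            "and >= 3 poor responders"
        )
    outputs = ["peak_table.csv"]
    table.to_csv(out / "peak_table.csv")

    results = {"table": table, "meta": meta, "proteins": proteins,
               "truth": truth, "cv": {}}
    for name, X, Y in [
        ("corr_peaks_cytokines", table.frame, proteins[cyt_cols]),
        ("corr_peaks_ddr", table.frame, proteins[ddr_cols]),
        ("corr_cytokines_ddr", proteins[cyt_cols], proteins[ddr_cols]),
    ]:
        if Y.shape[1] == 0:
            continue
        r = stats.pearson_matrix(X, Y)
        r.to_csv(out / f"{name}.csv")
        outputs.append(f"{name}.csv")
        results[name] = r

    calls = gsea.metrics_from_groups(proteins.loc[cohort_ids], labels)
    calls.to_csv(out / "protein_calls.csv", index=False)
    gsea.write_rnk(calls, out / "proteins.rnk")
    outputs += ["protein_calls.csv", "proteins.rnk"]
    results["calls"] = calls

    feature_sets = {
        "RS": table.frame.loc[cohort_ids],
        "RS+cytokines": pd.concat(
            [table.frame.loc[cohort_ids], proteins.loc[cohort_ids, cyt_cols]],
            axis=1,
        ),
        "RS+cytokines+DDR": pd.concat(
            [table.frame.loc[cohort_ids], proteins.loc[cohort_ids]], axis=1
        ),
    }
    rows = []
    for fname, X in feature_sets.items():
        t0 = time.perf_counter()
        report = stats.pca_svm_loocv(
            X, labels, c_grid=config.c_grid, feature_set=fname
        )
        logger.info("LOOCV %s: accuracy %.3f (C=%d) in %.2fs", fname,
                    report.loocv_accuracy, report.chosen_C,
                    time.perf_counter() - t0)
        rows.append((fname, report.loocv_accuracy, report.chosen_C))
        results["cv"][fname] = report
    acc = pd.DataFrame(rows, columns=["feature_set", "loocv_accuracy", "chosen_C"])
    acc.to_csv(out / "svm_accuracy.csv", index=False)
    outputs.append("svm_accuracy.csv")
    results["accuracy_table"] = acc
    _write_manifest(config, out, outputs)
    return results
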