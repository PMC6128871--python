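"""End-to-end workflow: measure -> screen -> calibrate -> predict -> analyze.

A declarative YAML config drives the run so that every exclusion (fresh-wood
core sections, silicate-bearing depths) is auditable, and a JSON manifest
records the config hash, seed, and the fate of every input sample.  Inputs
can be real files (per-sample CSVs plus a metadata table, or a standards
workbook) or the synthetic generators, selected in the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import (
    CalibrationStandard, calibrate_from_standards, save_models,
)
from .peaks import (
    PeakHeightTransformer, SilicateThresholds, default_peak_definitions,
    load_peak_definitions, measurements_table,
)
from .spectra import SampleRecord, Spectrum, read_spectrum
from .synthetic import TransectParams, generate_calibration_set, generate_transect
from .trends import (
    build_composition_table, fit_external_vectors, latitudinal_regression,
    loess_profile, pca_spectra, pooled_t_test, surface_summary,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_full_pipeline"]


class PipelineError(RuntimeError):
    """Stage failure; message names the stage (and sample where relevant)."""


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_yaml``)."""

    seed: int
    standards: dict
    samples: dict
    output_dir: Path
    peaks_file: Path | None = None
    exclusions: dict[str, str] = field(default_factory=dict)
    silicate_thresholds: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, output_dir: str | Path | None = None) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        if "seed" not in raw:
            raise PipelineError("config: a seed is mandatory")
        out = Path(output_dir or raw.get("output", "peatspec_report"))
        cfg = cls(
            seed=int(raw["seed"]),
            standards=raw.get("standards", {"synthetic": {}}),
            samples=raw.get("samples", {"synthetic_transect": {}}),
            output_dir=out,
            peaks_file=Path(raw["peaks"]) if raw.get("peaks") else None,
            exclusions=dict(raw.get("exclusions") or {}),
            silicate_thresholds=dict(raw.get("silicate_thresholds") or {}),
            analysis=dict(raw.get("analysis") or {}),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for label, section, key in (
            ("standards workbook", self.standards, "workbook"),
            ("sample spectra directory", self.samples, "spectra_dir"),
            ("sample metadata table", self.samples, "metadata"),
        ):
            p = section.get(key)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"config: {label} not found: {p}")
        if self.peaks_file is not None and not self.peaks_file.exists():
            raise PipelineError(f"config: peaks file not found: {self.peaks_file}")


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(
        {k: str(v) for k, v in vars(cfg).items() if k != "output_dir"},
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_standards(cfg: RunConfig) -> list[CalibrationStandard]:
    if "synthetic" in cfg.standards:
        params = dict(cfg.standards["synthetic"])
        params.setdefault("seed", cfg.seed)
        return generate_calibration_set(**params)
    if "workbook" in cfg.standards:
        df = pd.read_excel(cfg.standards["workbook"], engine="openpyxl")
        required = {
            "sample_id", "standard_class", "carb_height", "arom15_height",
            "arom16_height", "pct_cellulose_hemicellulose", "pct_klason_lignin",
        }
        missing = required - set(df.columns)
        if missing:
            raise PipelineError(f"standards workbook missing columns: {sorted(missing)}")
        return [CalibrationStandard(**{k: row[k] for k in required})
                for _, row in df.iterrows()]
    raise PipelineError("config: standards must specify 'synthetic' or 'workbook'")


def _load_samples(cfg: RunConfig) -> tuple[list[Spectrum], list[SampleRecord]]:
    if "synthetic_transect" in cfg.samples:
        params = dict(cfg.samples["synthetic_transect"])
        params.setdefault("seed", cfg.seed)
        return generate_transect(TransectParams(**params))
    if "spectra_dir" in cfg.samples:
        meta = pd.read_csv(cfg.samples["metadata"])
        spectra, records = [], []
        for _, row in meta.iterrows():
            sid = str(row["sample_id"])
            spectra.append(read_spectrum(
                Path(cfg.samples["spectra_dir"]) / f"{sid}.csv", sample_id=sid,
            ))
            records.append(SampleRecord(
                sample_id=sid,
                material=row.get("material", "peat"),
                site=str(row.get("site", "")),
                category=str(row.get("category", "")),
                depth_cm=_opt_float(row.get("depth_cm")),
                latitude_deg=_opt_float(row.get("latitude_deg")),
                mean_annual_temp_C=_opt_float(row.get("mean_annual_temp_C")),
            ))
        return spectra, records
    raise PipelineError(
        "config: samples must specify 'synthetic_transect' or 'spectra_dir'"
    )


def _opt_float(v) -> float | None:
    return None if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)


def run_full_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full workflow; returns the manifest dict.

    Writes models.json, measurements.csv, composition.csv, surface_summary
    /regressions/t_tests/loess/pca_scores/pca_loadings/vector_fits CSVs and
    manifest.json under ``config.output_dir``.  Any stage error aborts with
    the stage name and removes partial outputs.  Byte-identical outputs for
    identical inputs and seed.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        p = out / name
        df.to_csv(p, index=False, float_format="%.12g")
        written.append(p)

    stage = "load"
    try:
        standards = _load_standards(config)
        spectra, records = _load_samples(config)

        stage = "exclude"
        for r in records:
            if r.sample_id in config.exclusions:
                r.excluded = True
                r.exclusion_reason = config.exclusions[r.sample_id]

        stage = "measure"
        peaks = (load_peak_definitions(config.peaks_file)
                 if config.peaks_file else default_peak_definitions())
        thresholds = SilicateThresholds(**config.silicate_thresholds) \
            if config.silicate_thresholds else None
        ph = PeakHeightTransformer(
            peaks=peaks, screen_silicates=True, silicate_thresholds=thresholds,
        ).fit(spectra)
        heights = ph.transform(spectra)
        emit("measurements.csv", measurements_table(spectra, peaks))

        stage = "calibrate"
        models = calibrate_from_standards(standards)
        save_models(models, out / "models.json")
        written.append(out / "models.json")

        stage = "predict"
        comp = build_composition_table(heights, records, models)
        emit("composition.csv", comp.reset_index())

        stage = "analyze"
        opts = config.analysis
        max_depth = float(opts.get("surface_max_depth_cm", 50.0))
        lat_split = float(opts.get("latitude_split_deg", 45.0))
        n_perm = int(opts.get("n_perm", 999))
        included = comp[~comp["excluded"].astype(bool)]
        peat = included[included["material"] == "peat"].copy()
        peat["core_id"] = peat["site"]
        plants = included[included["material"] == "plant"]

        summ = surface_summary(peat, max_depth=max_depth)
        lat_by_core = peat.groupby("site")[["latitude_deg", "mean_annual_temp_C"]].first()
        summ = summ.merge(lat_by_core, left_on="core_id", right_index=True)
        emit("surface_summary.csv", summ)

        reg_rows = []
        for cov in ("latitude_deg", "mean_annual_temp_C"):
            for resp in ("mean_carbohydrates_est", "mean_aromatics_est"):
                r = latitudinal_regression(summ, cov, resp)
                reg_rows.append({"covariate": cov, "response": resp, **vars(r)})
        emit("regressions.csv", pd.DataFrame(reg_rows))

        t_rows = []
        lo_pl = plants[plants["latitude_deg"] < lat_split]
        hi_pl = plants[plants["latitude_deg"] >= lat_split]
        for resp in ("carbohydrates_est", "aromatics_est"):
            t, dof, p = pooled_t_test(hi_pl[resp], lo_pl[resp])
            t_rows.append({"contrast": "plants_high_vs_low_latitude",
                           "response": resp, "t": t, "df": dof, "p": p})
        emit("t_tests.csv", pd.DataFrame(t_rows))

        lo_curves = []
        for resp in ("carbohydrates_est", "aromatics_est", "aliphatic_rel_abund"):
            if resp not in peat.columns:
                continue
            c = loess_profile(
                peat, resp, latitude_split=lat_split,
                degree=int(opts.get("loess_degree", 2)),
                span=float(opts.get("loess_span", 0.75)),
            )
            c.insert(0, "response", resp)
            lo_curves.append(c)
        emit("loess.csv", pd.concat(lo_curves, ignore_index=True))

        stage = "ordination"
        incl_ids = set(included.index)
        pca_spec = [s for s in spectra if s.sample_id in incl_ids]
        pca = pca_spectra(pca_spec, n_components=5)
        emit("pca_scores.csv", pca.scores_.reset_index())
        emit("pca_loadings.csv", pd.DataFrame(
            pca.loadings_.T, columns=pca.scores_.columns,
        ).assign(wavenumber=pca.common_grid_))
        ext = included.reindex(pca.scores_.index)
        variables = pd.DataFrame({
            "carbohydrates_est": ext["carbohydrates_est"],
            "aromatics_est": ext["aromatics_est"],
            "aliphatic_rel_abund": ext.get("aliphatic_rel_abund"),
            # depth/latitude/temperature fitted on peat rows only
            "depth": ext["depth_cm"].where(ext["material"] == "peat"),
            "latitude": ext["latitude_deg"].where(ext["material"] == "peat"),
            "temperature": ext["mean_annual_temp_C"].where(ext["material"] == "peat"),
        })
        vec = fit_external_vectors(pca.scores_, variables, n_perm=n_perm,
                                   seed=config.seed)
        emit("vector_fits.csv", vec)

        stage = "manifest"
        manifest = {
            "peatspec_version": __version__,
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "n_standards": len(standards),
            "n_samples": len(records),
            "n_included": int((~comp["excluded"].astype(bool)).sum()),
            "n_excluded": int(comp["excluded"].astype(bool).sum()),
            "n_peat_in_pca": int((ext["material"] == "peat").sum()),
            "n_plant_in_pca": int((ext["material"] == "plant").sum()),
            "samples": {
                r.sample_id: ({"status": "excluded", "reason": r.exclusion_reason}
                              if r.excluded else {"status": "included"})
                for r in records
            },
            "outputs": [p.name for p in written] + ["manifest.json"],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        (out / "models.json").unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
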