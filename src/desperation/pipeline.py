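"""End-to-end orchestration: simulate -> preprocess -> fit -> dispersion ->
describe -> report.

``run_pipeline`` executes every stage on a generated (or user-supplied)
panel, writes each stage's tables under an output directory, and records a
manifest with the seed, configuration and a SHA-256 per output file, so a
run is reproducible byte-for-byte from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from desperation import descriptives, dispersion, models, preprocess
from desperation.panel import GeneratorConfig, generate_panel, validate_generator

__all__ = ["RunConfig", "run_pipeline", "load_panel_csv"]

logger = logging.getLogger(__name__)

RESOURCE_VARS = ("objective_resources", "subjective_resources")


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    seed: int = 0
    panel_csv: str | None = None  # if set, skip the generator
    generator_overrides: dict = field(default_factory=dict)
    resource_vars: tuple = RESOURCE_VARS
    max_degree: int = 5
    grid: str = "percentile"
    n_grid: int = 199
    min_side: int = 20
    sweep_pmin: float = 1.0
    sweep_pmax: float = 50.0
    tail_pct: float = 5.0

    @staticmethod
    def from_file(path: str) -> "RunConfig":
        """Flat ``key = value`` text config; unknown keys are an error."""
        cfg = {}
        valid = {f.name for f in dataclasses.fields(RunConfig)}
        gen_valid = {f.name for f in dataclasses.fields(GeneratorConfig)}
        overrides = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key.startswith("generator."):
                gkey = key[len("generator.") :]
                if gkey not in gen_valid:
                    raise ValueError(f"{path}:{lineno}: unknown generator field {gkey!r}")
                overrides[gkey] = _parse_value(val)
            elif key in valid:
                cfg[key] = _parse_value(val)
            else:
                raise ValueError(f"{path}:{lineno}: unknown config field {key!r}")
        if "resource_vars" in cfg:
            cfg["resource_vars"] = tuple(str(cfg["resource_vars"]).split(","))
        cfg["generator_overrides"] = overrides
        return RunConfig(**cfg)


def _parse_value(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    return s


def load_panel_csv(path: str) -> pd.DataFrame:
    """Read a raw panel CSV in the documented schema (see docs/schema.md)."""
    df = pd.read_csv(path)
    from desperation.preprocess import REQUIRED_COLUMNS

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel CSV is missing required column(s): {missing}")
    return df


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index=True):
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format="%.6g")


def _segmented_summary(seg: models.SegmentedFit) -> dict:
    return {
        "cp": seg.cp,
        "beta0": seg.beta0,
        "beta1": seg.beta1,
        "beta2": seg.beta2,
        "se": seg.se,
        "pvalues": seg.pvalues,
        "scaled": seg.scaled,
        "controls": seg.controls,
        "deviance": seg.deviance,
        "share_below": seg.share_below,
    }


def run_pipeline(cfg: RunConfig = RunConfig()) -> dict:
    """Run all stages; returns the manifest (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if cfg.panel_csv is not None:
            raw = load_panel_csv(cfg.panel_csv)
            gen_cfg = None
        else:
            gen_cfg = GeneratorConfig(seed=cfg.seed, **cfg.generator_overrides)
            raw = generate_panel(gen_cfg)
        _write_csv(raw, out / "panel_raw.csv", index=False)
        diag = validate_generator(raw)

        stage = "preprocess"
        proc = preprocess.preprocess_panel(raw)
        _write_csv(proc, out / "panel_processed.csv", index=False)

        stage = "fit"
        fit_results = {}
        for var in cfg.resource_vars:
            comparison = models.compare_polynomials(proc, var, cfg.max_degree)
            seg = models.fit_segmented_mixed(
                proc, var, grid=cfg.grid, n_points=cfg.n_grid, min_side=cfg.min_side
            )
            _write_csv(comparison.aic_table, out / f"poly_aic_{var}.csv")
            _write_csv(seg.profile, out / f"deviance_profile_{var}.csv", index=False)
            fit_results[var] = {
                "poly_selected_degree": comparison.selected_degree,
                "poly_aic": comparison.aic_table["aic"].to_dict(),
                "lrt_vs_linear": (
                    comparison.lrt_table.to_dict("index")
                    if len(comparison.lrt_table)
                    else {}
                ),
                "segmented": _segmented_summary(seg),
            }

        stage = "dispersion"
        family = dispersion.dispersion_family(proc)
        _write_csv(family, out / "dispersion_family.csv", index=False)
        disp_results = {"family": family.to_dict("records")}
        for var in cfg.resource_vars:
            sweep = dispersion.variance_sweep(
                proc, var, pmin=cfg.sweep_pmin, pmax=cfg.sweep_pmax
            )
            _write_csv(sweep.table, out / f"variance_sweep_{var}.csv", index=False)
            stab = dispersion.within_person_stability(proc, var)
            disp_results[var] = {
                "sweep_min_ratio": float(sweep.table["ratio"].min()),
                "stability_slope": stab.slope,
                "stability_p": stab.p,
            }
        disp_results["icc_risk_count"] = dispersion.icc(proc, "risk_count")

        stage = "describe"
        prevalence = descriptives.extreme_prevalence_table(proc, cfg.tail_pct)
        by_count = descriptives.mean_resources_by_count(proc)
        strain = descriptives.strain_group_summary(proc)
        discount = descriptives.discounting_contrast(proc, cfg.tail_pct)
        consist = descriptives.consistency_by_resources(proc)
        for name, df in [
            ("extreme_prevalence", prevalence),
            ("mean_resources_by_count", by_count),
            ("strain_summary", strain),
            ("discounting_contrast", discount),
            ("consistency", consist),
        ]:
            _write_csv(df, out / f"{name}.csv")

        stage = "report"
        report = {
            "seed": cfg.seed,
            "n_rows": int(len(proc)),
            "generator_diagnostics": dataclasses.asdict(diag) if diag else None,
            "fits": fit_results,
            "dispersion": disp_results,
        }
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": cfg.seed,
        "config": {
            k: (v if not isinstance(v, tuple) else list(v))
            for k, v in dataclasses.asdict(cfg).items()
        },
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.suffix in (".csv", ".json")
            and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
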