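"""End-to-end orchestration: simulate -> extract -> correlate -> model -> rank.

A run is described by a :class:`RunConfig` (YAML round-trippable). Stages
communicate only through tidy CSV files in the run directory, and a JSON
manifest records the seed, a config hash, and every artifact, so a rerun with
the same config is seed-identical. With ``resume=True`` stages whose outputs
already exist are skipped.

Stage outputs
-------------
``simulate``       ears.csv, ground_truth.csv, abr_growth.csv, dpoae_io.csv
``extract-efr``    efr_measures.csv (trial sets are regenerated in-memory
                   from per-ear seeds rather than persisted; a full cohort of
                   raw trial matrices would be several GB)
``extract-abr``    abr_summary.csv
``extract-dpoae``  dpoae_summary.csv
``correlate``      analysis_table.csv, correlations.csv
``model``          cv_results.csv
``compare-aicc``   aicc_all.csv, aicc_excluding_acute.csv
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as _cohort
from .abr import ABRGrowth, abr_summary
from .cohort import EFR_STIMULI, CohortConfig, generate_cohort
from .dpoae import DPOAEIO, dpoae_summary
from .models import (
    CVConfig,
    ModelSpec,
    build_analysis_table,
    repeated_grouped_cv,
)
from .selection import compare_models_aicc
from .stats import correlation_screen, screen_to_frame

__all__ = ["RunConfig", "run_pipeline", "default_model_grid", "load_real_table"]

log = logging.getLogger("synaptometry")

#: headline EFR metric used for the default model grid (magnitude at the
#: modulation frequency, no noise-floor correction)
DEFAULT_EFR_METHOD = "f0"


def default_model_grid(efr_method: str = DEFAULT_EFR_METHOD) -> list[ModelSpec]:
    """Six evoked options x four OHC adjustments (24 models): no evoked
    measure, ABR wave-1 at 80 dB SPL, and the four EFR conditions."""
    evoked_options: list[tuple] = [
        (),
        ("abr_80",),
        (f"sam_110_{efr_method}",),
        (f"sam_1000_{efr_method}",),
        (f"ram_110_{efr_method}",),
        (f"ram_1000_{efr_method}",),
    ]
    adjustments = [None, "dpoae_threshold", "dpoae_40", "dpoae_55"]
    return [ModelSpec(evoked=ev, dpoae=adj) for ev in evoked_options for adj in adjustments]


@dataclass
class RunConfig:
    """Full pipeline configuration (serializable to/from YAML)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    efr_mode: str = "trials"  # "trials" (full bootstrap) or "fast"
    efr_n_draws: int = 100
    efr_method: str = DEFAULT_EFR_METHOD
    output_dir: str = "run"
    log_level: str = "INFO"

    def model_grid(self) -> list[ModelSpec]:
        return default_model_grid(self.efr_method)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # YAML-safe group_loss keys
        d["cohort"]["group_loss"] = {
            f"{g}@{int(f)}": v for (g, f), v in self.cohort.group_loss.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        c = dict(d.pop("cohort", {}))
        if "group_loss" in c:
            c["group_loss"] = {
                (k.split("@")[0], float(k.split("@")[1])): v
                for k, v in c["group_loss"].items()
            }
        if "ohc_loss_db" in c:
            c["ohc_loss_db"] = {k: tuple(v) for k, v in c["ohc_loss_db"].items()}
        for key in ("frequencies", "abr_levels", "dpoae_l2_levels"):
            if key in c:
                c[key] = tuple(c[key])
        if "baseline_synapses" in c:
            c["baseline_synapses"] = {float(k): v for k, v in c["baseline_synapses"].items()}
        if "harmonic_weights" in c:
            c["harmonic_weights"] = {k: tuple(v) for k, v in c["harmonic_weights"].items()}
        cv = dict(d.pop("cv", {}))
        return cls(cohort=CohortConfig(**c), cv=CVConfig(**cv), **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Hash of the scientific configuration (where the run is written and
        how it logs do not change what it computes)."""
        d = self.to_dict()
        d.pop("output_dir", None)
        d.pop("log_level", None)
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages


def _outputs_exist(outdir: Path, names: list[str]) -> bool:
    return all((outdir / n).exists() for n in names)


def stage_simulate(config: RunConfig, outdir: Path) -> None:
    ears, truth = generate_cohort(config.cohort)
    pd.DataFrame(
        {
            "ear_id": [e.ear_id for e in ears],
            "group": [e.group for e in ears],
            "sex": [e.sex for e in ears],
            "index": [e.index for e in ears],
            "missing_1k_32k": [e.missing_1k_32k for e in ears],
        }
    ).to_csv(outdir / "ears.csv", index=False)
    truth.to_csv(outdir / "ground_truth.csv", index=False)

    growth_rows, io_rows = [], []
    for ear in ears:
        for f in config.cohort.frequencies:
            g = _cohort.simulate_abr_growth(ear, f, config.cohort)
            for lvl, amp in zip(g.levels, g.wave1_uv):
                growth_rows.append(
                    {"ear_id": ear.ear_id, "frequency_hz": f,
                     "level_db_spl": lvl, "wave1_uv": amp}
                )
            io = _cohort.simulate_dpoae_io(ear, f, config.cohort)
            for l2, dp in zip(io.l2_levels, io.dp_level_db_spl):
                io_rows.append(
                    {"ear_id": ear.ear_id, "f2_hz": f, "l2_db_spl": l2,
                     "dp_level_db_spl": dp}
                )
    pd.DataFrame(growth_rows).to_csv(outdir / "abr_growth.csv", index=False)
    pd.DataFrame(io_rows).to_csv(outdir / "dpoae_io.csv", index=False)


def stage_extract_efr(config: RunConfig, outdir: Path) -> None:
    ears_df = pd.read_csv(outdir / "ears.csv")
    truth = pd.read_csv(outdir / "ground_truth.csv")
    ears = _ears_from_frames(ears_df, truth, config.cohort)
    rows = []
    for ear in ears:
        for f in config.cohort.frequencies:
            if config.efr_mode == "trials":
                vals = _cohort._efr_measures_trials_all(
                    ear, f, config.cohort, config.efr_n_draws
                )
            else:
                vals = {}
                for stim in EFR_STIMULI:
                    rng = np.random.default_rng(
                        [config.cohort.seed, ear.index,
                         _cohort._EVOKED_KEYS.index(stim), int(f), 29]
                    )
                    vals.update(
                        _cohort._efr_measures_fast(ear, f, stim, config.cohort, rng)
                    )
            if ear.missing_1k_32k and f == 32000.0:
                vals = {
                    k: (np.nan if k.startswith(("sam_1000", "ram_1000")) else v)
                    for k, v in vals.items()
                }
            rows.append({"ear_id": ear.ear_id, "frequency_hz": f, **vals})
    pd.DataFrame(rows).to_csv(outdir / "efr_measures.csv", index=False)


def _ears_from_frames(ears_df, truth, cohort_cfg) -> list:
    """Rebuild Ear objects from the simulate-stage CSVs (nuisance factors are
    regenerated deterministically from the seed via generate_cohort)."""
    ears, _ = generate_cohort(cohort_cfg)
    recorded = set(ears_df["ear_id"])
    return [e for e in ears if e.ear_id in recorded]


def stage_extract_abr(config: RunConfig, outdir: Path) -> None:
    growth = pd.read_csv(outdir / "abr_growth.csv")
    rows = []
    for (ear_id, f), sub in growth.groupby(["ear_id", "frequency_hz"]):
        sub = sub.sort_values("level_db_spl")
        g = ABRGrowth(ear_id, f, sub["level_db_spl"].values, sub["wave1_uv"].values)
        s = abr_summary(g, noise_uv=config.cohort.noise_sd["abr_uv"])
        rows.append(
            {"ear_id": ear_id, "frequency_hz": f, "abr_80": s.amp80,
             "abr_70": s.amp70, "abr_60": s.amp60, "slope_2": s.slope2,
             "slope_4": s.slope4, "slope_all": s.slope_all,
             "abr_threshold": s.threshold_db}
        )
    pd.DataFrame(rows).to_csv(outdir / "abr_summary.csv", index=False)


def stage_extract_dpoae(config: RunConfig, outdir: Path) -> None:
    io = pd.read_csv(outdir / "dpoae_io.csv")
    rows = []
    for (ear_id, f2), sub in io.groupby(["ear_id", "f2_hz"]):
        sub = sub.sort_values("l2_db_spl")
        d = dpoae_summary(
            DPOAEIO(ear_id, f2, sub["l2_db_spl"].values, sub["dp_level_db_spl"].values)
        )
        rows.append(
            {"ear_id": ear_id, "frequency_hz": f2,
             "dpoae_threshold": d.threshold_db, "dpoae_40": d.level_at_40,
             "dpoae_55": d.level_at_55}
        )
    pd.DataFrame(rows).to_csv(outdir / "dpoae_summary.csv", index=False)


def _load_analysis_table(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(outdir / "analysis_table.csv")


def stage_correlate(config: RunConfig, outdir: Path) -> None:
    truth = pd.read_csv(outdir / "ground_truth.csv")
    tables = [
        pd.read_csv(outdir / n)
        for n in ("abr_summary.csv", "dpoae_summary.csv", "efr_measures.csv")
    ]
    table = build_analysis_table(truth, *tables,
                                 frequencies=tuple(config.cohort.frequencies))
    table.to_csv(outdir / "analysis_table.csv", index=False)

    m = config.efr_method
    measures = ["abr_80", f"sam_110_{m}", f"sam_1000_{m}", f"ram_110_{m}", f"ram_1000_{m}"]
    targets = ["synapses"] + list(DPOAE := ["dpoae_threshold", "dpoae_40", "dpoae_55"])
    pairs = [(meas, tgt) for meas in measures for tgt in targets]
    frames = []
    for excl in (None, config.cv.test_group):
        res = correlation_screen(table, pairs, exclude_group=excl)
        frames.append(screen_to_frame(res))
    pd.concat(frames, ignore_index=True).to_csv(outdir / "correlations.csv", index=False)


def stage_model(config: RunConfig, outdir: Path) -> None:
    table = _load_analysis_table(outdir)
    rows = []
    for spec in config.model_grid():
        cv = repeated_grouped_cv(spec, table, config.cv)
        rows.append(
            {"model": spec.name,
             "evoked": "+".join(spec.evoked) if spec.evoked else "none",
             "adjustment": spec.dpoae or "none",
             "mean_val": cv.mean_val, "sem_val": cv.sem_val,
             "mean_test": cv.mean_test, "sem_test": cv.sem_test,
             "n_complete": cv.n_complete}
        )
    pd.DataFrame(rows).to_csv(outdir / "cv_results.csv", index=False)


def stage_compare_aicc(config: RunConfig, outdir: Path) -> None:
    table = _load_analysis_table(outdir)
    grid = config.model_grid()
    for scope, name in (("all", "aicc_all.csv"),
                        ("excluding_acute", "aicc_excluding_acute.csv")):
        cmp = compare_models_aicc(grid, table, scope=scope,
                                  exclude_group=config.cv.test_group)
        out = cmp.table.copy()
        out["n_ears"] = cmp.n_ears
        out.to_csv(outdir / name, index=False)


STAGES = [
    ("simulate", stage_simulate,
     ["ears.csv", "ground_truth.csv", "abr_growth.csv", "dpoae_io.csv"]),
    ("extract-efr", stage_extract_efr, ["efr_measures.csv"]),
    ("extract-abr", stage_extract_abr, ["abr_summary.csv"]),
    ("extract-dpoae", stage_extract_dpoae, ["dpoae_summary.csv"]),
    ("correlate", stage_correlate, ["analysis_table.csv", "correlations.csv"]),
    ("model", stage_model, ["cv_results.csv"]),
    ("compare-aicc", stage_compare_aicc,
     ["aicc_all.csv", "aicc_excluding_acute.csv"]),
]


def run_pipeline(config: RunConfig, resume: bool = False,
                 stages: list[str] | None = None) -> Path:
    """Run the pipeline end to end; returns the run directory.

    With ``resume=True``, stages whose outputs already exist are skipped.
    ``stages`` restricts execution to the named stages (their inputs must
    already exist).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest = {
        "seed": config.cohort.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    config.to_yaml(outdir / "config.yaml")
    _write_data_dictionary(outdir)
    for name, fn, outputs in STAGES:
        if stages is not None and name not in stages:
            continue
        if resume and _outputs_exist(outdir, outputs):
            log.info("stage %s: outputs present, skipped (resume)", name)
            manifest["stages"][name] = {"outputs": outputs, "skipped": True}
            continue
        t0 = time.time()
        log.info("stage %s: running", name)
        fn(config, outdir)
        log.info("stage %s: done in %.1fs", name, time.time() - t0)
        manifest["stages"][name] = {"outputs": outputs, "skipped": False}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def _write_data_dictionary(outdir: Path) -> None:
    (outdir / "data_dictionary.md").write_text(
        "# Run-directory data dictionary\n\n"
        "- ears.csv: ear_id, group, sex, index, missing_1k_32k\n"
        "- ground_truth.csv: ear_id, group, sex, frequency_hz, synapses_per_ihc, ohc_loss_db\n"
        "- abr_growth.csv: ear_id, frequency_hz, level_db_spl, wave1_uv\n"
        "- dpoae_io.csv: ear_id, f2_hz, l2_db_spl, dp_level_db_spl\n"
        "- efr_measures.csv: ear_id, frequency_hz, <stimulus>_<metric> columns "
        "(metrics: f0, f0_4, f0_snr, f0_4_snr, f0_4_power[, plv]; dB re 1 uV "
        "or dB; plv unitless)\n"
        "- abr_summary.csv: ear_id, frequency_hz, abr_80/70/60 (uV), "
        "slope_2/4/all (uV/dB), abr_threshold (dB SPL, empty = not reached)\n"
        "- dpoae_summary.csv: ear_id, frequency_hz, dpoae_threshold (dB SPL), "
        "dpoae_40, dpoae_55 (dB SPL)\n"
        "- analysis_table.csv: long (ear_id x frequency_hz) join of the above "
        "with ground-truth synapses\n"
        "- correlations.csv: measure, target, r, ci_low, ci_high, "
        "conf_level_pct, n, significant, excluded_group\n"
        "- cv_results.csv: model, evoked, adjustment, mean_val, sem_val, "
        "mean_test, sem_test, n_complete (RMSE in synapses/IHC)\n"
        "- aicc_all.csv / aicc_excluding_acute.csv: model, evoked, adjustment, "
        "aicc, k, n_obs, delta_aicc, tier, n_ears\n"
    )


def load_real_table(path) -> pd.DataFrame:
    """Load a long-format per-ear CSV of real measurements.

    Expected columns match the synthetic analysis table: ear_id, group,
    frequency_hz, synapses, evoked-measure columns, and DPOAE covariates.
    The same model grid, CV, and AICc machinery then apply unchanged.
    """
    table = pd.read_csv(path)
    required = {"ear_id", "frequency_hz", "synapses"}
    missing = required - set(table.columns)
    if missing:
        raise KeyError(f"real-data table missing columns: {sorted(missing)}")
    return table
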