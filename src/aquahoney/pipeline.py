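"""Full study replay: configuration, orchestration and report bundling.

``run_study`` executes the whole analysis on synthetic or user-provided
spectra: outlier screen -> range cut -> general PCA-LDA pretreatment
optimization -> PCA display models (reusing the general best
pretreatments) -> detailed PCA-LDA (8 per honey type) -> PLSR (general +
detailed) -> subtraction spectra -> wavelength voting -> aquagram
coordinate selection -> 24 aquagrams -> HMF statistics. Everything is
deterministic per seed.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hmf as hmf_stats
from .aquagram import (
    DEFAULT_TOP_K,
    classic_aquagram,
    collect_votes,
    default_wamacs,
    render_radar,
    select_coordinates,
)
from .exceptions import ConfigError
from .models import (
    DEFAULT_MAX_LVS,
    DEFAULT_PC_CANDIDATES,
    ModelTask,
    detailed_tasks,
    fit_pca,
    optimize_pretreatment,
    subtraction_spectra,
)
from .outliers import detect_outliers
from .pretreat import apply_pretreatment, enumerate_grid, parse_spec
from .simulate import (
    DEFAULT_PARAMS,
    SynthParams,
    generate_design,
    generate_hmf,
    generate_spectra,
)
from .spectra import CONTROL, HONEY_TYPES, TEMPERATURES, TIMES, SpectraSet, cut_range, read_spectra_csv

__all__ = ["RunConfig", "StudyReport", "run_study", "make_fixtures"]

log = logging.getLogger("aquahoney")


@dataclass
class RunConfig:
    """Validated configuration of a study replay."""

    seed: int = 0
    honey_types: tuple[str, ...] = HONEY_TYPES
    spectra_csv: str | None = None  # None -> simulate
    hmf_csv: str | None = None
    range_nm: tuple[float, float] = (1300.0, 1600.0)
    #: "full" = the 41-combination optimization grid; "fast" = a 6-spec
    #: subset for quick replays (one representative per pipeline shape)
    grid_choice: str = "full"
    outlier_alpha: float = 0.999
    top_k: int = DEFAULT_TOP_K
    pc_candidates: tuple[int, ...] = DEFAULT_PC_CANDIDATES
    max_lvs: int = DEFAULT_MAX_LVS
    control_temperature: float = 25.0
    render: bool = True
    output_dir: str = "study_output"

    def __post_init__(self):
        self.honey_types = tuple(self.honey_types)
        self.range_nm = tuple(float(v) for v in self.range_nm)
        if len(self.range_nm) != 2 or self.range_nm[0] >= self.range_nm[1]:
            raise ConfigError(f"range_nm must be (lo, hi) with lo < hi: {self.range_nm}")
        if not self.honey_types:
            raise ConfigError("honey_types must be non-empty")
        self.pc_candidates = tuple(int(k) for k in self.pc_candidates)
        if not self.pc_candidates or min(self.pc_candidates) < 1:
            raise ConfigError("pc_candidates must be positive")
        if not 0 < self.outlier_alpha <= 1:
            raise ConfigError("outlier_alpha must lie in (0, 1]")
        if self.max_lvs < 1 or self.top_k < 1:
            raise ConfigError("max_lvs and top_k must be >= 1")
        if self.grid_choice not in ("full", "fast"):
            raise ConfigError("grid_choice must be 'full' or 'fast'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class StudyReport:
    """Everything the replay produced, plus a file manifest."""

    config: RunConfig
    outlier_counts: dict
    general_best: dict  # (honey, family) -> pretreatment codec
    classification: pd.DataFrame  # one row per PCA-LDA model
    regression: pd.DataFrame  # one row per PLSR model
    coordinates: dict  # honey -> AquagramSpec
    aquagrams: dict  # (honey, kind, level) -> Aquagram
    hmf: dict  # honey -> dict of HMF stage outputs
    files: list = field(default_factory=list)

    @property
    def n_aquagrams(self) -> int:
        return len(self.aquagrams)


def _load_or_simulate(config: RunConfig):
    if config.spectra_csv:
        spectra = read_spectra_csv(config.spectra_csv)
        hmf_df = pd.read_csv(config.hmf_csv) if config.hmf_csv else None
        if hmf_df is not None:
            hmf_df["temperature_C"] = hmf_df["temperature_C"].map(
                lambda v: CONTROL if str(v) == CONTROL else int(float(v))
            )
        return spectra, hmf_df
    params = DEFAULT_PARAMS.with_seed(config.seed)
    design = generate_design(config.honey_types)
    return generate_spectra(design, params), generate_hmf(design, params)


def run_study(config: RunConfig) -> StudyReport:
    """Execute the full replay; writes CSV/PNG outputs under
    ``config.output_dir`` and returns the in-memory report."""
    t0 = _time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    if config.grid_choice == "full":
        grid = enumerate_grid()
    else:
        grid = [
            parse_spec(c)
            for c in ("raw", "snv", "msc", "deTr", "sgol@2-21-0_snv",
                      "sgol@2-13-0_sgol@2-13-2")
        ]
    wamacs = default_wamacs()

    spectra_all, hmf_df = _load_or_simulate(config)
    spectra_all = spectra_all.exclude_water_refs()
    log.info("input: %d spectra", spectra_all.n_spectra)

    outlier_counts = {}
    kept_parts = []
    for h in config.honey_types:
        sub = spectra_all.subset(honey_type=h)
        rep = detect_outliers(sub, alpha=config.outlier_alpha)
        outlier_counts[h] = rep.n_flagged
        kept_parts.append(sub.select(rep.keep_mask))
        rep.to_frame(sub).to_csv(out / f"outliers_{h}.csv", index=False)
        files.append(f"outliers_{h}.csv")
        log.info("outlier screen %s: flagged %d/%d", h, rep.n_flagged, sub.n_spectra)
    spectra_all = _concat(kept_parts)
    spectra = cut_range(spectra_all, *config.range_nm)

    general_best: dict = {}
    class_rows = []
    reg_rows = []
    coordinates = {}
    aquagrams = {}
    hmf_out = {}

    for h in config.honey_types:
        sources = []
        # --- general PCA-LDA with pretreatment optimization
        for family in ("general_temperature", "general_time"):
            task = ModelTask(family, h)
            best, report = optimize_pretreatment(
                spectra, task, grid, "validation_accuracy", config.pc_candidates
            )
            general_best[(h, family)] = best.format()
            row = report.loc[report["pretreatment"] == best.format()].iloc[0]
            class_rows.append(
                {"honey_type": h, "task": task.describe(), "family": family,
                 **row.to_dict()}
            )
            report.to_csv(out / f"pcalda_grid_{h}_{family}.csv", index=False)
            files.append(f"pcalda_grid_{h}_{family}.csv")
            # PCA display model reusing the general best pretreatment
            sub = task.select(spectra)
            _, Xt = apply_pretreatment(best, sub.absorbance, wavelengths=sub.wavelengths)
            pca = fit_pca(Xt, 2, sub.wavelengths)
            sources.append((f"{h}/pca_{family}", pca))
            log.info("%s %s: best=%s val=%.1f%%", h, family, best.format(), row["validation"])

        # --- detailed PCA-LDA (8 per type)
        for task in detailed_tasks(h):
            best, report = optimize_pretreatment(
                spectra, task, grid, "validation_accuracy", config.pc_candidates
            )
            row = report.loc[report["pretreatment"] == best.format()].iloc[0]
            class_rows.append(
                {"honey_type": h, "task": task.describe(), "family": task.family,
                 **row.to_dict()}
            )
            from .models import PCALDAModel

            res = PCALDAModel(spectra, task, best, n_pcs=int(row["n_components"])).fit()
            sources.append((f"{h}/pcalda_{task.describe()}", res))
            log.info("%s %s: best=%s val=%.1f%%", h, task.describe(), best.format(),
                     row["validation"])

        # --- PLSR general + detailed
        plsr_tasks = [ModelTask("general_temperature", h), ModelTask("general_time", h)]
        plsr_tasks += detailed_tasks(h)
        for task in plsr_tasks:
            best, report = optimize_pretreatment(
                spectra, task, grid, "R2CV", max_lvs=config.max_lvs
            )
            row = report.loc[report["pretreatment"] == best.format()].iloc[0]
            reg_rows.append(
                {"honey_type": h, "task": task.describe(), "family": task.family,
                 **row.to_dict()}
            )
            from .models import cv_plsr

            rep = cv_plsr(spectra, task, best, config.max_lvs, config.control_temperature)
            sub = task.select(spectra)
            sources.append((f"{h}/plsr_{task.describe()}", (sub.wavelengths, rep)))
            log.info("%s PLSR %s: best=%s R2CV=%.2f", h, task.describe(), best.format(),
                     rep.R2CV)

        # --- subtraction spectra (two display variants, both groupings)
        hsub = spectra.subset(honey_type=h)
        for m in TIMES:
            comp = hsub.subset(time_min=[0, m])
            for variant in ("msc", "sgol_d2"):
                diffs = subtraction_spectra(comp, "temperature_C", variant)
                sources.append((f"{h}/diff_{variant}_within_{m}min", diffs))
        for t in TEMPERATURES:
            comp = hsub.subset(temperature_C=[CONTROL, t])
            for variant in ("msc", "sgol_d2"):
                diffs = subtraction_spectra(comp, "time_min", variant)
                sources.append((f"{h}/diff_{variant}_within_{t}C", diffs))

        # --- votes -> coordinates -> aquagrams
        votes = _collect_all_votes(sources, config.top_k)
        aqspec = select_coordinates(votes, wamacs)
        coordinates[h] = aqspec
        for m in TIMES:
            comp = hsub.subset(time_min=[0, m])
            a = classic_aquagram(comp, aqspec, "temperature_C",
                                 title=f"{h}: temperature pattern within {m} min")
            aquagrams[(h, "temperature_pattern", m)] = a
            _emit_aquagram(a, out, f"aquagram_{h}_temp_within_{m}min", files, config.render)
        for t in TEMPERATURES:
            comp = hsub.subset(temperature_C=[CONTROL, t])
            a = classic_aquagram(comp, aqspec, "time_min",
                                 title=f"{h}: time pattern within {t} degC")
            aquagrams[(h, "time_pattern", t)] = a
            _emit_aquagram(a, out, f"aquagram_{h}_time_within_{t}C", files, config.render)

        # --- HMF stage
        if hmf_df is not None:
            hmf_out[h] = _hmf_stage(hmf_df[hmf_df["honey_type"] == h], out, h, files)

    classification = pd.DataFrame(class_rows)
    regression = pd.DataFrame(reg_rows)
    classification.to_csv(out / "classification_models.csv", index=False)
    regression.to_csv(out / "regression_models.csv", index=False)
    files += ["classification_models.csv", "regression_models.csv"]
    config.to_yaml(out / "config.yaml")
    manifest = {
        "seed": config.seed,
        "n_spectra": int(spectra.n_spectra),
        "n_aquagrams": len(aquagrams),
        "runtime_s": round(_time.time() - t0, 1),
        "files": files + ["config.yaml"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    report = StudyReport(
        config, outlier_counts, general_best, classification, regression,
        coordinates, aquagrams, hmf_out, files + ["config.yaml", "manifest.json"],
    )
    missing = [f for f in report.files if not (out / f).exists()]
    if missing:
        raise ConfigError(f"bundle incomplete, missing: {missing}")
    return report


def _collect_all_votes(sources, top_k):
    votes = []
    for sid, item in sources:
        if isinstance(item, tuple):  # (wavelengths, PLSRReport)
            wl, rep = item
            votes += collect_votes([(sid, rep)], wavelengths=wl, top_k=top_k)
        else:
            votes += collect_votes([(sid, item)], top_k=top_k)
    return votes


def _emit_aquagram(a, out: Path, stem: str, files: list, render: bool):
    a.to_frame().to_csv(out / f"{stem}.csv")
    files.append(f"{stem}.csv")
    if render and len(a.coordinates) >= 3:
        render_radar(a, out / f"{stem}.png")
        files.append(f"{stem}.png")


def _hmf_stage(df: pd.DataFrame, out: Path, h: str, files: list) -> dict:
    res: dict = {}
    normality, levene_p = hmf_stats.check_assumptions(
        df, ["temperature_C", "time_min"]
    )
    res["normality"] = normality
    res["levene_p"] = levene_p
    homogeneous = levene_p >= hmf_stats.ALPHA
    res["anova"] = hmf_stats.two_way_anova(df)
    df = df.copy()
    df["level"] = df["temperature_C"].astype(str) + "/" + df["time_min"].astype(str)
    res["stars"] = hmf_stats.control_comparison(
        df, f"{CONTROL}/0", homogeneous=homogeneous, by="level"
    )
    letters = {}
    ph_all = hmf_stats.posthoc(df, homogeneous=homogeneous, by="level")
    for m in TIMES:  # capital letters: temperatures within one time
        levels = [f"{t}/{m}" for t in TEMPERATURES]
        sub = ph_all.pairs[
            ph_all.pairs["group_a"].isin(levels) & ph_all.pairs["group_b"].isin(levels)
        ]
        letters[f"within_{m}min"] = hmf_stats.letter_display(
            hmf_stats.PosthocResult(sub, ph_all.method), levels
        )
    for t in TEMPERATURES:  # lowercase letters: times within one temperature
        levels = [f"{t}/{m}" for m in TIMES]
        sub = ph_all.pairs[
            ph_all.pairs["group_a"].isin(levels) & ph_all.pairs["group_b"].isin(levels)
        ]
        letters[f"within_{t}C"] = hmf_stats.letter_display(
            hmf_stats.PosthocResult(sub, ph_all.method), levels
        )
    res["letters"] = letters
    res["anova"].to_csv(out / f"hmf_anova_{h}.csv", index=False)
    res["stars"].to_csv(out / f"hmf_stars_{h}.csv", index=False)
    files += [f"hmf_anova_{h}.csv", f"hmf_stars_{h}.csv"]
    return res


def _concat(parts: list[SpectraSet]) -> SpectraSet:
    grid = parts[0].grid
    X = np.vstack([p.absorbance for p in parts])
    meta = pd.concat([p.meta for p in parts], ignore_index=True)
    return SpectraSet(grid, X, meta)


def make_fixtures(scale: str = "tiny", seed: int = 0, out_dir=None) -> dict:
    """Seed-stable fixture bundles.

    ``tiny``: one honey type, 2 replicates, 2 fills x 2 scans — fast enough
    for unit tests and CI. ``default``: the full 153-sample design.
    """
    params = DEFAULT_PARAMS.with_seed(seed)
    if scale == "tiny":
        from dataclasses import replace

        params = replace(params, n_fills=2, n_scans=2)
        design = generate_design(("sunflower",), ("R1", "R2"))
    elif scale == "default":
        design = generate_design()
    else:
        raise ConfigError(f"unknown fixture scale {scale!r}")
    spectra = generate_spectra(design, params)
    hmf_df = generate_hmf(design, params)
    bundle = {"design": design, "spectra": spectra, "hmf": hmf_df, "params": params}
    if out_dir is not None:
        from .spectra import write_spectra_csv

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_spectra_csv(spectra, out / "spectra.csv")
        hmf_df.to_csv(out / "hmf.csv", index=False)
        pdict = asdict(params)
        pdict["archetypes"] = [asdict(a) for a in params.archetypes]
        with open(out / "params.yaml", "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(pdict)), fh, sort_keys=True)
        bundle["paths"] = {
            "spectra": str(out / "spectra.csv"),
            "hmf": str(out / "hmf.csv"),
            "params": str(out / "params.yaml"),
        }
    return bundle
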