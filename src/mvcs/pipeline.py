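"""End-to-end orchestration: data -> SI table -> mixed models -> report.

``run_pipeline`` takes a :class:`PipelineConfig` that either embeds a
synthetic-study generator configuration or points at a study directory,
runs the full analysis (preprocessing, MVCS similarity indices for the
three run pairings, behavioral block measures, per-ROI mixed models with
BH-FDR across ROIs, follow-up contrasts), and returns a
:class:`StudyReport` that can be written to disk deterministically.

``calibrate`` is the batch mode: repeated synthetic studies with
aggregated fixed-effect rejection rates, used for type-I error and power
experiments.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import block_performance
from .exceptions import ConfigError, MvcsError
from .pairings import PreprocessSettings, assemble_pairings
from .stats import fdr_bh, fit_lmm_behavior, fit_lmm_si, followup_contrast
from .synthetic import (
    CONDITIONS,
    PAIRINGS,
    GeneratorConfig,
    SiEffects,
    SyntheticStudy,
    generate_experiment,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "StudyReport",
    "run_pipeline",
    "build_si_table",
    "build_behavior_table",
    "validate_inputs",
    "calibrate",
]

_RUNS_FOR_PAIRING = {
    "early_late": ("task",),
    "rs_pre_post": ("pre", "post"),
    "task_rs_post": ("task", "post"),
}


@dataclass
class PipelineConfig:
    """Everything one analysis run needs, reproducible from seed + config."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    data_dir: str | None = None  # if set, load instead of generate
    settings: PreprocessSettings = field(default_factory=PreprocessSettings)
    pairings: tuple[str, ...] = PAIRINGS
    rois: tuple[str, ...] | None = None  # None = all ROIs in the study
    fit_behavior: bool = True
    fdr_q: float = 0.05
    seed: int | None = None  # overrides generator.seed when given
    log_level: str = "WARNING"

    def validate(self) -> None:
        self.generator.validate()
        if self.log_level.upper() not in (
            "DEBUG", "INFO", "WARNING", "ERROR", "CRITICAL"
        ):
            raise ConfigError(f"unknown log_level {self.log_level!r}")
        for p in self.pairings:
            if p not in PAIRINGS:
                raise ConfigError(f"unknown pairing {p!r}")
        for name in ("fd_threshold_mm", "highpass_hz", "n_tissue_pcs",
                     "min_volumes"):
            if getattr(self.settings, name) <= 0:
                raise ConfigError(f"settings.{name} must be positive")
        if self.data_dir is not None and not Path(self.data_dir).exists():
            raise ConfigError(f"data_dir {self.data_dir!r} does not exist")

    def to_dict(self) -> dict:
        return {
            "generator": self.generator.to_dict(),
            "data_dir": self.data_dir,
            "settings": {
                k: getattr(self.settings, k)
                for k in ("fd_threshold_mm", "highpass_hz", "gm_threshold",
                          "n_tissue_pcs", "min_volumes",
                          "include_task_rest_blocks")
            },
            "pairings": list(self.pairings),
            "rois": list(self.rois) if self.rois else None,
            "fit_behavior": self.fit_behavior,
            "fdr_q": self.fdr_q,
            "seed": self.seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "generator" in d:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        if "settings" in d and isinstance(d["settings"], dict):
            d["settings"] = PreprocessSettings(**d["settings"])
        if d.get("pairings") is not None:
            d["pairings"] = tuple(d["pairings"])
        if d.get("rois") is not None:
            d["rois"] = tuple(d["rois"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def demo(cls) -> "PipelineConfig":
        """A small study (8 subjects, 2 ROIs) for quick end-to-end runs."""
        gen = GeneratorConfig(
            n_subjects=8, rois={"dlpfc": 60, "hippocampus": 60}
        )
        return cls(generator=gen)


@dataclass
class StudyReport:
    """All tables one pipeline run produces, plus provenance.

    Every omitted run pair appears in ``exclusions`` with its reason, and
    ``usage`` carries the exact volume accounting (input = used +
    censored + trimmed) per run and pairing.
    """

    si_table: pd.DataFrame
    lmm_tables: dict[tuple[str, str], pd.DataFrame]  # (pairing, roi)
    contrast_table: pd.DataFrame
    behavior_blocks: pd.DataFrame
    behavior_anova: dict[str, pd.DataFrame]
    usage: pd.DataFrame
    exclusions: pd.DataFrame
    provenance: dict
    errors: list[str] = field(default_factory=list)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        kw = dict(sep="\t", index=False, float_format="%.10g",
                  lineterminator="\n")
        self.si_table.to_csv(out / "si_table.tsv", **kw)
        for (pairing, roi), table in sorted(self.lmm_tables.items()):
            table.to_csv(out / f"lmm_{pairing}_{roi}.tsv", **kw)
        self.contrast_table.to_csv(out / "contrasts.tsv", **kw)
        if len(self.behavior_blocks):
            self.behavior_blocks.to_csv(out / "behavior_blocks.tsv", **kw)
        for response, table in sorted(self.behavior_anova.items()):
            table.to_csv(out / f"behavior_lmm_{response}.tsv", **kw)
        self.usage.to_csv(out / "volume_usage.tsv", **kw)
        self.exclusions.to_csv(out / "exclusions.tsv", **kw)
        with open(out / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=1, sort_keys=True)
        if self.errors:
            with open(out / "errors.txt", "w") as fh:
                fh.write("\n".join(self.errors) + "\n")


def _load_or_generate(config: PipelineConfig) -> SyntheticStudy:
    if config.data_dir is not None:
        from .io import read_study

        return read_study(config.data_dir)
    gen = config.generator
    if config.seed is not None:
        gen = replace(gen, seed=config.seed)
    needed_runs = sorted(
        {r for p in config.pairings for r in _RUNS_FOR_PAIRING[p]}
    )
    return generate_experiment(
        gen, runs=tuple(needed_runs), include_behavior=config.fit_behavior
    )


def build_si_table(
    study: SyntheticStudy,
    settings: PreprocessSettings | None = None,
    pairings: tuple[str, ...] = PAIRINGS,
    rois: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Similarity records for every subject x condition x ROI x pairing.

    Returns ``(si_table, usage, exclusions)`` as long-format frames.
    """
    settings = settings or PreprocessSettings()
    design = study.design.set_index(["subject", "condition"])
    roi_list = tuple(rois) if rois else tuple(study.config.rois)
    records, usage, exclusions = [], [], []
    for (subject, condition), cd in sorted(study.data.items()):
        meta_row = design.loc[(subject, condition)]
        meta = dict(
            subject=subject, condition=condition,
            visit=int(meta_row["visit"]),
            stimulation=meta_row["stimulation"], task=meta_row["task"],
        )
        for roi in roi_list:
            gm = study.gm_prob[(subject, roi)]
            result = assemble_pairings(
                cd.pre, cd.task, cd.post, roi=roi, gm_prob=gm, meta=meta,
                settings=settings, pairings=pairings,
            )
            records.extend(result.records)
            usage.extend(result.usage)
            exclusions.extend(result.exclusions)
    si_cols = ["subject", "condition", "visit", "stimulation", "task",
               "roi", "pairing", "si", "n_voxels", "n_volumes"]
    si_table = pd.DataFrame(
        [[getattr(r, c) for c in si_cols] for r in records], columns=si_cols
    )
    usage_cols = ["subject", "condition", "roi", "pairing", "role",
                  "n_input", "n_censored", "n_trimmed", "n_used"]
    usage_df = pd.DataFrame(
        [[getattr(u, c) for c in usage_cols] for u in usage],
        columns=usage_cols,
    )
    excl_cols = ["subject", "condition", "roi", "pairing", "reason"]
    excl_df = pd.DataFrame(
        [[getattr(e, c) for c in excl_cols] for e in exclusions],
        columns=excl_cols,
    )
    return si_table, usage_df, excl_df


def build_behavior_table(study: SyntheticStudy) -> pd.DataFrame:
    """Block-level speed/accuracy per subject x condition."""
    design = study.design.set_index(["subject", "condition"])
    frames = []
    for (subject, condition), cd in sorted(study.data.items()):
        if cd.keypresses is None:
            continue
        perf = block_performance(cd.keypresses)
        meta_row = design.loc[(subject, condition)]
        perf.insert(0, "subject", subject)
        perf.insert(1, "condition", condition)
        perf.insert(2, "visit", int(meta_row["visit"]))
        perf.insert(3, "stimulation", meta_row["stimulation"])
        perf.insert(4, "task", meta_row["task"])
        frames.append(perf)
    if not frames:
        return pd.DataFrame(
            columns=["subject", "condition", "visit", "stimulation", "task",
                     "block", "mean_rt_correct", "accuracy", "n_correct"]
        )
    return pd.concat(frames, ignore_index=True)


def _fdr_across_rois(
    lmm_tables: dict[tuple[str, str], pd.DataFrame], q: float
) -> None:
    """Append a BH-adjusted p column per pairing x effect across ROIs."""
    pairings = sorted({k[0] for k in lmm_tables})
    for pairing in pairings:
        rois = sorted(k[1] for k in lmm_tables if k[0] == pairing)
        if not rois:
            continue
        effects = lmm_tables[(pairing, rois[0])]["effect"].tolist()
        for effect in effects:
            pvals = {}
            for roi in rois:
                tab = lmm_tables[(pairing, roi)]
                sel = tab["effect"] == effect
                if sel.any():
                    pvals[roi] = float(tab.loc[sel, "p"].iloc[0])
            res = fdr_bh(pvals, q)
            for roi in pvals:
                tab = lmm_tables[(pairing, roi)]
                sel = tab["effect"] == effect
                lmm_tables[(pairing, roi)].loc[sel, "p_fdr"] = res.adjusted[roi]


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path | None = None
) -> StudyReport:
    """Run the full analysis described by ``config``.

    Deterministic given the configuration (including its seed): rerunning
    writes byte-identical tables.  Stage failures are collected in the
    report's ``errors`` rather than aborting the whole run.
    """
    config.validate()
    errors: list[str] = []
    study = _load_or_generate(config)
    roi_list = tuple(config.rois) if config.rois else tuple(study.config.rois)

    si_table, usage, exclusions = build_si_table(
        study, config.settings, config.pairings, roi_list
    )

    lmm_tables: dict[tuple[str, str], pd.DataFrame] = {}
    contrast_rows = []
    for pairing in config.pairings:
        for roi in roi_list:
            sub = si_table[
                (si_table["pairing"] == pairing) & (si_table["roi"] == roi)
            ]
            if sub["subject"].nunique() < 2:
                errors.append(
                    f"lmm skipped for {pairing}/{roi}: not enough subjects"
                )
                continue
            try:
                res = fit_lmm_si(sub)
            except MvcsError as exc:
                errors.append(f"lmm failed for {pairing}/{roi}: {exc}")
                continue
            tab = res.anova.copy()
            tab.insert(0, "roi", roi)
            tab.insert(0, "pairing", pairing)
            tab["p_fdr"] = np.nan
            tab["converged"] = res.converged
            lmm_tables[(pairing, roi)] = tab
            for cell_a, cell_b in (("cSEQ", "cRND"), ("iSEQ", "iRND")):
                try:
                    fc = followup_contrast(res, cell_a, cell_b)
                except MvcsError as exc:
                    errors.append(
                        f"contrast {cell_a}-{cell_b} failed for "
                        f"{pairing}/{roi}: {exc}"
                    )
                    continue
                contrast_rows.append(
                    (pairing, roi, f"{cell_a}-{cell_b}", fc.estimate, fc.f,
                     fc.df_num, fc.df_den, fc.p)
                )
    _fdr_across_rois(lmm_tables, config.fdr_q)
    contrast_table = pd.DataFrame(
        contrast_rows,
        columns=["pairing", "roi", "contrast", "estimate", "F", "df_num",
                 "df_den", "p"],
    )

    behavior_blocks = build_behavior_table(study) if config.fit_behavior \
        else pd.DataFrame()
    behavior_anova: dict[str, pd.DataFrame] = {}
    if config.fit_behavior and len(behavior_blocks):
        for response in ("mean_rt_correct", "accuracy"):
            try:
                res = fit_lmm_behavior(
                    behavior_blocks, response=response,
                    n_blocks=study.config.n_blocks,
                )
                tab = res.anova.copy()
                tab["converged"] = res.converged
                behavior_anova[response] = tab
            except MvcsError as exc:
                errors.append(f"behavior lmm failed for {response}: {exc}")

    provenance = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed if config.seed is not None
        else config.generator.seed,
        "n_si_records": int(len(si_table)),
        "n_exclusions": int(len(exclusions)),
        "censored_fraction_by_pairing": _censored_fractions(usage),
    }
    report = StudyReport(
        si_table=si_table, lmm_tables=lmm_tables,
        contrast_table=contrast_table, behavior_blocks=behavior_blocks,
        behavior_anova=behavior_anova, usage=usage, exclusions=exclusions,
        provenance=provenance, errors=errors,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report


def _censored_fractions(usage: pd.DataFrame) -> dict:
    if not len(usage):
        return {}
    out = {}
    for pairing, grp in usage.groupby("pairing"):
        out[pairing] = round(
            float(grp["n_censored"].sum() / grp["n_input"].sum()), 6
        )
    return out


def validate_inputs(study_dir: str | Path) -> dict:
    """Check a study directory for format and completeness problems.

    Returns ``{"errors": [...], "warnings": [...]}``; hard format
    violations are errors, per-subject missing cells (which the mixed
    models tolerate) are warnings.
    """
    from .io import read_motion_tsv, read_timeseries_tsv

    root = Path(study_dir)
    errors: list[str] = []
    warnings: list[str] = []
    design_path = root / "design.tsv"
    if not design_path.exists():
        return {"errors": [f"missing design table {design_path}"],
                "warnings": []}
    design = pd.read_csv(design_path, sep="\t")
    needed = {"subject", "visit", "stimulation", "task", "condition"}
    if not needed <= set(design.columns):
        errors.append(
            f"design table missing columns {sorted(needed - set(design.columns))}"
        )
        return {"errors": errors, "warnings": warnings}
    dup = design.duplicated(subset=["subject", "condition"])
    if dup.any():
        errors.append(
            "duplicate subject x condition rows in design: "
            + ", ".join(
                f"{r.subject}/{r.condition}"
                for r in design[dup].itertuples()
            )
        )
    config_path = root / "config.yaml"
    rois: list[str] = []
    if config_path.exists():
        with open(config_path) as fh:
            cfg = yaml.safe_load(fh)
        rois = list((cfg or {}).get("rois", {}))
    else:
        warnings.append("no config.yaml; ROI completeness not checked")
    for row in design.itertuples():
        cdir = root / str(row.subject) / str(row.condition)
        if not cdir.exists():
            warnings.append(f"missing session directory {cdir}")
            continue
        for role in ("pre", "task", "post"):
            ts_files = sorted(cdir.glob(f"{role}_roi-*.tsv"))
            motion = cdir / f"{role}_motion.tsv"
            if not ts_files:
                warnings.append(
                    f"{row.subject}/{row.condition}: no {role} run data"
                )
                continue
            if not motion.exists():
                errors.append(
                    f"{row.subject}/{row.condition}: missing motion file "
                    f"{motion.name}"
                )
                continue
            try:
                mot = read_motion_tsv(motion)
                for f in ts_files:
                    ts = read_timeseries_tsv(f)
                    if ts.n_volumes != mot.n_volumes:
                        errors.append(
                            f"{f}: {ts.n_volumes} volumes but motion has "
                            f"{mot.n_volumes}"
                        )
            except (ConfigError, ValueError) as exc:
                errors.append(str(exc))
            for roi in rois:
                if not (cdir / f"{role}_roi-{roi}.tsv").exists():
                    warnings.append(
                        f"{row.subject}/{row.condition}: {role} run missing "
                        f"ROI {roi}"
                    )
    return {"errors": errors, "warnings": warnings}


def calibrate(
    config: PipelineConfig,
    n_reps: int = 100,
    pairing: str = "early_late",
    roi: str | None = None,
    alpha: float = 0.05,
    seed: int = 0,
    effects: tuple[str, ...] = ("task", "stimulation", "stimulation:task"),
) -> pd.DataFrame:
    """Repeated synthetic studies with aggregated rejection rates.

    Each repetition generates a fresh study (only the runs the chosen
    pairing needs), computes its SI table, fits the SI mixed model for
    one ROI, and records each effect's p-value and the cSEQ-cRND
    follow-up estimate.  Returns the long-format results; aggregate with
    ``df.groupby("effect")["reject"].mean()``.
    """
    config.validate()
    if pairing not in PAIRINGS:
        raise ConfigError(f"unknown pairing {pairing!r}")
    roi = roi or next(iter(config.generator.rois))
    runs = _RUNS_FOR_PAIRING[pairing]
    rows = []
    for rep in range(n_reps):
        gen = replace(config.generator, seed=int(seed) + rep)
        study = generate_experiment(gen, runs=runs, include_behavior=False)
        si_table, _, _ = build_si_table(
            study, config.settings, (pairing,), (roi,)
        )
        sub = si_table[si_table["pairing"] == pairing]
        res = fit_lmm_si(sub)
        fc = followup_contrast(res, "cSEQ", "cRND")
        for effect in effects:
            row = res.effect(effect)
            rows.append(
                (rep, effect, float(row["F"]), float(row["p"]),
                 bool(row["p"] < alpha), fc.estimate, res.converged)
            )
    return pd.DataFrame(
        rows,
        columns=["rep", "effect", "F", "p", "reject", "contrast_cseq_crnd",
                 "converged"],
    )


def _early_late_batch(
    config: PipelineConfig, roi: str, rho_el: float, n_studies: int,
    seed: int, si_effects: SiEffects,
) -> pd.DataFrame:
    """SI tables of a batch of studies with a given early/late persistence."""
    frames = []
    for i in range(n_studies):
        gen = replace(
            config.generator,
            seed=int(seed) + i,
            persistence_rho={
                **dict(config.generator.persistence_rho), "early_late": rho_el
            },
            si_effects=si_effects,
        )
        study = generate_experiment(gen, runs=("task",),
                                    include_behavior=False)
        si_table, _, _ = build_si_table(
            study, config.settings, ("early_late",), (roi,)
        )
        si_table["study"] = i
        frames.append(si_table)
    return pd.concat(frames, ignore_index=True)


def recover_interaction(
    config: PipelineConfig,
    n_reps: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    effect_sd: float = 1.0,
    pilot_studies: int = 8,
) -> dict:
    """Power experiment: inject a stimulation-by-task persistence
    interaction of ``effect_sd`` within-cell SDs on the early/late SI and
    measure how often the mixed model detects it with the right sign.

    The persistence-scale effect is calibrated from null pilot batches:
    the within-cell SI standard deviation and the local slope of mean SI
    in rho fix the rho shift that moves each condition cell by
    ``effect_sd / 2`` SDs (a standardized interaction of ``effect_sd``).
    The follow-up contrast checks that cSEQ - cRND carries the injected
    (negative) sign.
    """
    config.validate()
    roi = next(iter(config.generator.rois))
    base_rho = dict(config.generator.persistence_rho)["early_late"]
    lo_rho, hi_rho = base_rho - 0.15, base_rho + 0.15
    lo = _early_late_batch(config, roi, lo_rho, pilot_studies,
                           seed + 100_000, SiEffects())
    hi = _early_late_batch(config, roi, hi_rho, pilot_studies,
                           seed + 200_000, SiEffects())
    slope = (hi["si"].mean() - lo["si"].mean()) / (hi_rho - lo_rho)
    cell_sd = float(
        pd.concat([lo, hi]).groupby(["study", "condition"])["si"]
        .std(ddof=1).mean()
    )
    delta = 2.0 * effect_sd * cell_sd / slope
    # cells shift by +/- delta/4 on the rho scale; keep rho in range
    delta = float(min(delta, 4.0 * min(base_rho, 1.0 - base_rho) * 0.95))
    effects = SiEffects(interaction=-delta)
    detected, signs, rows = 0, 0, []
    for rep in range(n_reps):
        gen = replace(config.generator, seed=seed + rep, si_effects=effects)
        study = generate_experiment(gen, runs=("task",),
                                    include_behavior=False)
        si_table, _, _ = build_si_table(
            study, config.settings, ("early_late",), (roi,)
        )
        res = fit_lmm_si(si_table)
        fc = followup_contrast(res, "cSEQ", "cRND")
        p_int = float(res.effect("stimulation:task")["p"])
        hit = p_int < alpha
        detected += hit
        if hit:
            signs += fc.estimate < 0
        rows.append((rep, p_int, fc.estimate, hit))
    return {
        "power": detected / n_reps,
        "sign_rate": signs / detected if detected else np.nan,
        "delta_rho": delta,
        "cell_sd": cell_sd,
        "slope": float(slope),
        "n_reps": n_reps,
        "results": pd.DataFrame(
            rows, columns=["rep", "p_interaction", "contrast", "detected"]
        ),
    }
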