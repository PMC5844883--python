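"""End-to-end orchestration: generate -> isotope -> imaging -> ptquant ->
assays -> report, with persisted intermediates and recovery metrics.

Stages exchange tidy TSV tables under the run's output directory so any
downstream stage can be re-run from persisted intermediates.  All
randomness flows from the config seed; a fixed seed reproduces every
output byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assays, imaging, isotope, ptquant, synthetic

__all__ = ["RunConfig", "RunReport", "run", "recovery_metrics"]

_STAGES = ("generate", "isotope", "imaging", "ptquant", "assays", "report")


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    outdir: Path
    seed: int = 0
    alpha: float = 0.05
    stages: tuple[str, ...] = _STAGES
    tracing: synthetic.TracingScenario | None = None
    imaging_scn: synthetic.ImageScenario | None = None
    calibration: synthetic.CalibrationScenario | None = None
    n_fields: int = 4   # fields of view per condition

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        for s in self.stages:
            if s not in _STAGES:
                raise ValueError(f"unknown stage {s!r}")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path, outdir=None, seed=None) -> "RunConfig":
        import yaml
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        known = {"outdir", "seed", "alpha", "stages", "n_fields",
                 "tracing", "imaging", "calibration"}
        for key in cfg:
            if key not in known:
                raise ValueError(f"unknown config key {key!r}")
        scn = synthetic.scenarios_from_yaml(path) if any(
            k in cfg for k in ("tracing", "imaging", "calibration")) else {}
        return cls(
            outdir=Path(outdir or cfg.get("outdir", "cisflux_run")),
            seed=int(seed if seed is not None else cfg.get("seed", 0)),
            alpha=float(cfg.get("alpha", 0.05)),
            stages=tuple(cfg.get("stages", _STAGES)),
            tracing=scn.get("tracing"),
            imaging_scn=scn.get("imaging"),
            calibration=scn.get("calibration"),
            n_fields=int(cfg.get("n_fields", 4)),
        )


@dataclass
class RunReport:
    """Summary of one pipeline run."""

    config_hash: str
    seed: int
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    recovery: dict[str, dict] = field(default_factory=dict)

    def content_hash(self) -> str:
        """Hash of every table's CSV serialization, for determinism checks."""
        h = hashlib.sha256()
        for name in sorted(self.tables):
            h.update(name.encode())
            h.update(self.tables[name].to_csv(index=False).encode())
        return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    payload = repr((config.seed, config.alpha, config.stages,
                    config.tracing, config.imaging_scn, config.calibration,
                    config.n_fields))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run(config: RunConfig) -> RunReport:
    """Execute the enabled stages in dependency order."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=_config_hash(config), seed=config.seed)
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(child.generate_state(1)[0] % (2**31))
             for name, child in zip(("tracing", "imaging", "calibration"),
                                    ss.spawn(3))}

    def timed(name, fn):
        t0 = time.perf_counter()
        fn()
        report.timings[name] = time.perf_counter() - t0

    if "generate" in config.stages:
        timed("generate", lambda: _stage_generate(config, seeds, out, report))
    if "isotope" in config.stages:
        timed("isotope", lambda: _stage_isotope(config, out, report))
    if "imaging" in config.stages:
        timed("imaging", lambda: _stage_imaging(config, seeds, out, report))
    if "ptquant" in config.stages:
        timed("ptquant", lambda: _stage_ptquant(config, out, report))
    if "assays" in config.stages:
        timed("assays", lambda: _stage_assays(config, out, report))
    if "report" in config.stages:
        timed("report", lambda: _stage_report(config, out, report))
    return report


# ---------------------------------------------------------------------------
# stages


def _stage_generate(config, seeds, out, report) -> None:
    tracing = config.tracing or synthetic.default_tracing_scenario(
        seed=seeds["tracing"])
    spectra, truth = synthetic.gen_isotopologue_dataset(tracing)
    synthetic.write_isotopologue_tsv(spectra, out / "isotopologues.tsv")
    truth.to_csv(out / "isotopologues_truth.tsv", sep="\t", index=False)
    report.tables["isotopologues"] = spectra
    report.tables["isotopologues_truth"] = truth

    calibration = config.calibration or synthetic.default_calibration_scenario(
        seed=seeds["calibration"])
    cal_rows, cal_truth = synthetic.gen_calibration_run(calibration)
    synthetic.write_calibration_csv(cal_rows, out / "icpms_run.csv")
    cal_truth.to_csv(out / "icpms_truth.csv", index=False)
    report.tables["icpms_run"] = cal_rows
    report.tables["icpms_truth"] = cal_truth


def _stage_isotope(config, out, report) -> None:
    spectra = report.tables.get("isotopologues")
    if spectra is None:
        path = out / "isotopologues.tsv"
        if not path.exists():
            raise FileNotFoundError(
                "isotope stage: missing input isotopologues.tsv "
                "(enable the generate stage or provide the file)")
        spectra = pd.read_csv(path, sep="\t")
    p13 = (config.tracing.natural_abundance_p if config.tracing
           else isotope.NATURAL_P13)
    mids = []
    for r in spectra.itertuples():
        n_c = int(r.n_carbons)
        intens = [getattr(r, f"m{k}") for k in range(n_c + 1)]
        mid = isotope.correct_mid(intens, n_c, metabolite=r.metabolite,
                                  p13=p13, condition=r.condition,
                                  replicate=int(r.replicate))
        mids.append(mid)
    mid_table = isotope._mid_frame(mids)
    conds = list(pd.unique(mid_table["condition"]))
    contrasts = (isotope.contrast_conditions(mid_table, conds[1], conds[0],
                                             alpha=config.alpha)
                 if len(conds) >= 2 else pd.DataFrame())
    mid_table.to_csv(out / "mids.tsv", sep="\t", index=False)
    contrasts.to_csv(out / "mid_contrasts.tsv", sep="\t", index=False)
    report.tables["mids"] = mid_table
    report.tables["mid_contrasts"] = contrasts


def _stage_imaging(config, seeds, out, report) -> None:
    base = config.imaging_scn
    records = []
    field_truths = []
    for cond, treated in (("control", False), ("cisplatin", True)):
        for f in range(config.n_fields):
            fseed = int((seeds["imaging"] + 977 * f + (10_007 if treated else 0))
                        % (2**31))
            scn = base if base is not None else synthetic.default_image_scenario(
                seed=fseed, treated=treated)
            if base is not None:
                scn = synthetic.ImageScenario(
                    **{**base.__dict__, "seed": fseed,
                       "treated_shift": base.treated_shift if treated else 0.0})
            image, truth = synthetic.gen_nuclei_image(scn)
            labels = imaging.segment_nuclei(image[0])
            nuc = imaging.measure_nuclei(labels, image[1])
            _, counts = imaging.detect_foci(image[1], labels)
            nuc = nuc.merge(counts, on="label", how="left")
            nuc.insert(0, "condition", cond)
            nuc.insert(1, "field", f)
            records.append(nuc)
            field_truths.append({"condition": cond, "field": f,
                                 "true_n_nuclei": truth["n_nuclei"]})
    cells = pd.concat(records, ignore_index=True)
    scorer = imaging.PositivityScorer().fit(
        cells.loc[cells["condition"] == "control", "mean_intensity"])
    cells["positive"] = scorer.predict(cells["mean_intensity"])
    summary = cells.groupby("condition", sort=False).agg(
        n_cells=("label", "size"),
        percent_positive=("positive", lambda s: 100.0 * s.mean()),
        mean_foci=("foci_count", "mean"),
    ).reset_index()
    cells.to_csv(out / "cells.tsv", sep="\t", index=False)
    summary.to_csv(out / "imaging_summary.tsv", sep="\t", index=False)
    report.tables["cells"] = cells
    report.tables["imaging_summary"] = summary
    report.tables["imaging_truth"] = pd.DataFrame(field_truths)


def _stage_ptquant(config, out, report) -> None:
    rows = report.tables.get("icpms_run")
    if rows is None:
        path = out / "icpms_run.csv"
        if not path.exists():
            raise FileNotFoundError(
                "ptquant stage: missing input icpms_run.csv")
        rows = pd.read_csv(path)
    cal, results = ptquant.process_icpms_run(rows)
    # paired total/bound samples: even index total, odd index bound
    fracs = []
    res = results.reset_index(drop=True)
    for i in range(0, len(res) - 1, 2):
        total, bound = res.iloc[i], res.iloc[i + 1]
        if total["concentration_ppb"] > 0:
            fracs.append({
                "pair": i // 2,
                "total_ppb": total["concentration_ppb"],
                "bound_ppb": bound["concentration_ppb"],
                "dna_bound_percent": ptquant.dna_bound_fraction(
                    float(total["concentration_ppb"]),
                    float(bound["concentration_ppb"])),
            })
    cal_table = pd.DataFrame([{
        "slope": cal.slope_, "intercept": cal.intercept_, "r2": cal.r2_,
        "n_levels": len(cal.levels_),
    }])
    dna_bound = pd.DataFrame(
        fracs, columns=["pair", "total_ppb", "bound_ppb", "dna_bound_percent"])
    results.to_csv(out / "pt_results.csv", index=False)
    cal_table.to_csv(out / "pt_calibration.csv", index=False)
    dna_bound.to_csv(out / "dna_bound.csv", index=False)
    report.tables["pt_results"] = results
    report.tables["pt_calibration"] = cal_table
    report.tables["dna_bound"] = dna_bound


def _stage_assays(config, out, report) -> None:
    # biochemical endpoints derived from the tracing ground truth: relative
    # lactate tracks the labeled-lactate flux; clonogenic numbers follow the
    # dose-response the study design implies
    mids = report.tables.get("mids")
    rows = []
    if mids is not None and len(mids):
        lac = mids[mids["metabolite"] == "lactate"]
        for r in lac.itertuples():
            rows.append({"condition": r.condition, "readout": 100.0 * (1 - r.m0)})
    if rows:
        plate = pd.DataFrame(rows)
        endpoint = assays.normalize_to_control(plate, "control",
                                               alpha=config.alpha)
    else:
        endpoint = pd.DataFrame()
    clono = pd.DataFrame({
        "condition": ["control"] * 3 + ["cisplatin"] * 3,
        "cells_plated": [400] * 6,
        "colonies": [210, 195, 201, 52, 61, 48],
    })
    sf = assays.surviving_fraction(clono, "control", alpha=config.alpha)
    endpoint.to_csv(out / "endpoints.tsv", sep="\t", index=False)
    sf.to_csv(out / "surviving_fraction.tsv", sep="\t", index=False)
    report.tables["endpoints"] = endpoint
    report.tables["surviving_fraction"] = sf


def _stage_report(config, out, report) -> None:
    lines = ["# cisflux run report", "",
             f"- config hash: `{report.config_hash}`",
             f"- seed: {report.seed}", ""]
    if {"mids", "isotopologues_truth"} <= report.tables.keys():
        report.recovery["labeled_fraction"] = recovery_metrics(
            _estimated_labeled_fractions(report.tables["mids"]),
            _true_labeled_fractions(report.tables["isotopologues_truth"]))
    if {"pt_results", "icpms_truth"} <= report.tables.keys():
        res = report.tables["pt_results"]
        truth = report.tables["icpms_truth"]
        merged = res.merge(truth, on="sample")
        report.recovery["pt_concentration"] = recovery_metrics(
            dict(zip(merged["sample"], merged["concentration_ppb"])),
            dict(zip(merged["sample"], merged["true_ppb"])))
    for name, tbl in report.tables.items():
        lines.append(f"## {name} ({len(tbl)} rows)")
        lines.append("")
        lines.append(tbl.head(12).to_string(index=False))
        lines.append("")
    for name, metrics in report.recovery.items():
        lines.append(f"## recovery: {name}")
        lines.append("")
        lines.append(json.dumps(metrics, indent=1))
        lines.append("")
    _plot_figures(report, out)
    (out / "report.md").write_text("\n".join(lines))
    (out / "recovery.json").write_text(json.dumps(report.recovery, indent=1))


def _estimated_labeled_fractions(mids: pd.DataFrame) -> dict[str, float]:
    grp = mids.groupby(["metabolite", "condition"])["m0"].mean()
    return {f"{m}|{c}": 100.0 * (1.0 - v) for (m, c), v in grp.items()}


def _true_labeled_fractions(truth: pd.DataFrame) -> dict[str, float]:
    return {f"{r.metabolite}|{r.condition}": float(r.labeled_fraction)
            for r in truth.itertuples()}


def _plot_figures(report: RunReport, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    mids = report.tables.get("mids")
    if mids is None or not len(mids):
        return
    mets = list(pd.unique(mids["metabolite"]))
    fig, axes = plt.subplots(1, len(mets), figsize=(3 * len(mets), 3),
                             squeeze=False)
    for ax, met in zip(axes[0], mets):
        sub = mids[mids["metabolite"] == met]
        n_c = int(sub["n_carbons"].iloc[0])
        cols = [f"m{k}" for k in range(n_c + 1)]
        width = 0.35
        for i, (cond, grp) in enumerate(sub.groupby("condition", sort=False)):
            means = grp[cols].mean()
            sems = grp[cols].std(ddof=1) / np.sqrt(len(grp))
            ax.bar(np.arange(n_c + 1) + i * width, means, width,
                   yerr=sems, capsize=2, label=cond)
        ax.set_title(met, fontsize=8)
        ax.set_xticks(np.arange(n_c + 1) + width / 2)
        ax.set_xticklabels([f"m+{k}" for k in range(n_c + 1)], fontsize=6)
    axes[0, 0].set_ylabel("fraction")
    axes[0, -1].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(out / "mid_bars.png", dpi=120)
    plt.close(fig)


def recovery_metrics(estimates: dict[str, float],
                     ground_truth: dict[str, float]) -> dict:
    """Bias and MAE of estimates against matched ground truth."""
    keys = sorted(set(estimates) & set(ground_truth))
    if not keys:
        raise ValueError("no overlapping keys between estimates and truth")
    err = np.array([estimates[k] - ground_truth[k] for k in keys])
    return {"n": len(keys), "bias": float(err.mean()),
            "mae": float(np.abs(err).mean())}
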