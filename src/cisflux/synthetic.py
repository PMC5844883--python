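"""Seeded generators for every input the pipeline consumes, with ground truth.

Three generators emulate the study's data-producing instruments:

* **Tracing** — isotopologue intensity tables for U-13C6-glucose labeling of
  glycolytic, PPP and TCA intermediates.  True tracer MIDs per condition are
  forward-convolved with the natural-abundance distribution, scaled by a
  metabolite pool size, and perturbed by multiplicative lognormal noise
  (intensities are positive and errors are CV-stable, as for SRM peak
  areas).  Lactate's true MID is a mixture of the pyruvate MID with an
  unlabeled media-pyruvate pool: with pyruvate 90% labeled and a dilution
  fraction of 5/18 the generated lactate is 65% labeled, the pattern the
  study observed.
* **Imaging** — two-channel fields (DAPI, gamma-H2AX): non-overlapping
  disk nuclei, per-nucleus base gamma-H2AX intensity drawn from a
  condition-dependent normal, symmetric 2-D Gaussian foci, additive
  background noise, clipped at zero.
* **Calibration** — Pt/Ir ratios at serial-dilution standard levels with
  noise SD proportional to concentration (the heteroscedasticity that makes
  1/x^2 weighting appropriate), plus samples at known true ppb.

All randomness flows from one top-level seed, split per sub-draw via
``numpy.random.SeedSequence``; the same scenario and seed reproduce
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .isotope import NATURAL_P13, natural_abundance_matrix
from .ptquant import CALIBRATION_LEVELS_PPB

__all__ = [
    "TracingScenario",
    "ImageScenario",
    "CalibrationScenario",
    "gen_isotopologue_dataset",
    "gen_nuclei_image",
    "gen_calibration_run",
    "default_tracing_scenario",
    "default_image_scenario",
    "default_calibration_scenario",
    "write_isotopologue_tsv",
    "write_image_tiff",
    "write_calibration_csv",
    "write_ground_truth_json",
    "scenarios_from_yaml",
]


# ---------------------------------------------------------------------------
# scenarios


@dataclass
class TracingScenario:
    """Ground-truth description of a 13C-glucose labeling experiment.

    ``true_mids`` maps condition -> metabolite -> fraction vector (length
    n_carbons + 1, summing to 1).  ``dilution_fraction`` is the share of the
    lactate pool fed by unlabeled media pyruvate rather than glycolytic
    (labeled) pyruvate; it is applied to ``dilution_target`` using
    ``dilution_source``'s MID.
    """

    metabolites: list[tuple[str, int]]
    true_mids: dict[str, dict[str, np.ndarray]]
    dilution_fraction: float = 0.0
    dilution_source: str = "pyruvate"
    dilution_target: str = "lactate"
    natural_abundance_p: float = NATURAL_P13
    noise_cv: float = 0.05
    n_replicates: int = 3
    total_pool: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dilution_fraction <= 1.0:
            raise ValueError("dilution_fraction must be in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        n_by_met = dict(self.metabolites)
        for cond, mids in self.true_mids.items():
            for met, vec in mids.items():
                vec = np.asarray(vec, dtype=float)
                if met not in n_by_met:
                    raise ValueError(f"true MID for unknown metabolite {met!r}")
                if vec.size != n_by_met[met] + 1:
                    raise ValueError(
                        f"MID length mismatch for {met!r} in {cond!r}")
                if np.any(vec < 0) or abs(vec.sum() - 1.0) > 1e-9:
                    raise ValueError(
                        f"true MID for {met!r} in {cond!r} must be a "
                        "non-negative vector summing to 1")
                mids[met] = vec


@dataclass
class ImageScenario:
    """Parameters of a synthetic two-channel immunofluorescence field."""

    n_nuclei: int = 30
    radius_range: tuple[int, int] = (8, 14)
    control_intensity: tuple[float, float] = (300.0, 60.0)  # mean, sd (a.u.)
    treated_shift: float = 0.0        # added to mean intensity (a.u.)
    foci_per_nucleus: tuple[str, float] = ("poisson", 3.0)
    focus_amplitude: float = 900.0    # peak above nucleus base (a.u.)
    focus_sigma: float = 1.5          # pixels
    focus_min_separation: float = 6.0  # px between focus centers
    background_sd: float = 12.0       # additive Gaussian noise sd (a.u.)
    dapi_intensity: float = 3000.0    # disk value in the DAPI channel (a.u.)
    image_size: tuple[int, int] = (512, 512)
    margin: int = 4                   # min gap between nucleus borders, px
    max_placement_tries: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        lo, hi = self.radius_range
        if lo < 1 or hi < lo:
            raise ValueError("radius_range must satisfy 1 <= lo <= hi")


@dataclass
class CalibrationScenario:
    """Parameters of a synthetic ICP-MS calibration + sample run."""

    true_slope: float = 0.02          # ratio per ppb
    true_intercept: float = 0.0       # ratio
    standard_levels: tuple[float, ...] = CALIBRATION_LEVELS_PPB
    relative_noise_sd: float = 0.0    # noise sd = this * concentration
    sample_concentrations: tuple[float, ...] = ()
    ir_counts: float = 1e5            # internal-standard counts per run
    seed: int = 0

    def __post_init__(self) -> None:
        levels = np.asarray(self.standard_levels, dtype=float)
        if np.any(levels <= 0) or np.any(np.diff(levels) <= 0):
            raise ValueError(
                "standard levels must be strictly positive and increasing")


# ---------------------------------------------------------------------------
# tracing generator


def _mixture_mid(scn: TracingScenario, cond: str, met: str) -> np.ndarray:
    mids = scn.true_mids[cond]
    vec = mids[met]
    if met == scn.dilution_target and scn.dilution_fraction > 0:
        src = mids[scn.dilution_source]
        if src.size != vec.size:
            raise ValueError(
                "dilution source and target have mismatched carbon counts")
        unlabeled = np.zeros_like(src)
        unlabeled[0] = 1.0
        d = scn.dilution_fraction
        return (1.0 - d) * src + d * unlabeled
    return vec


def gen_isotopologue_dataset(
        scn: TracingScenario) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate raw isotopologue spectra plus their ground-truth MIDs.

    Returns ``(spectra, truth)``: spectra rows are metabolite, n_carbons,
    condition, replicate, m0...mN raw intensities; truth rows carry the
    effective (post-mixture) true MID and its labeled fraction per
    metabolite/condition.
    """
    rng = np.random.default_rng(np.random.SeedSequence(scn.seed))
    n_by_met = dict(scn.metabolites)
    mats = {n: natural_abundance_matrix(n, scn.natural_abundance_p)
            if scn.natural_abundance_p > 0 else np.eye(n + 1)
            for n in set(n_by_met.values())}
    # lognormal with unit mean: mu = -sigma^2/2
    sigma = np.sqrt(np.log1p(scn.noise_cv**2)) if scn.noise_cv > 0 else 0.0
    spec_rows, truth_rows = [], []
    for cond in scn.true_mids:
        for met, n_c in scn.metabolites:
            if met not in scn.true_mids[cond]:
                continue
            true = _mixture_mid(scn, cond, met)
            observed = mats[n_c] @ true
            truth_rows.append({
                "metabolite": met, "n_carbons": n_c, "condition": cond,
                **{f"m{k}": float(v) for k, v in enumerate(true)},
                "labeled_fraction": 100.0 * (1.0 - float(true[0])),
            })
            for rep in range(1, scn.n_replicates + 1):
                noise = (np.exp(rng.normal(-sigma**2 / 2, sigma, n_c + 1))
                         if sigma > 0 else np.ones(n_c + 1))
                intens = scn.total_pool * observed * noise
                spec_rows.append({
                    "metabolite": met, "n_carbons": n_c, "condition": cond,
                    "replicate": rep,
                    **{f"m{k}": float(v) for k, v in enumerate(intens)},
                })
    max_n = max(n_by_met.values())
    cols = ["metabolite", "n_carbons", "condition", "replicate"] + [
        f"m{k}" for k in range(max_n + 1)]
    spectra = pd.DataFrame(spec_rows).reindex(columns=cols)
    truth = pd.DataFrame(truth_rows)
    return spectra, truth


def default_tracing_scenario(seed: int = 0, noise_cv: float = 0.05,
                             n_replicates: int = 3,
                             lactate_suppression: float = 0.35,
                             ) -> TracingScenario:
    """Study-condition scenario: U-13C6 glucose, control vs cisplatin.

    Control labeling mirrors the study's observations: pyruvate ~90%
    labeled (m+3), lactate diluted to ~65% by unlabeled media pyruvate
    (dilution fraction 5/18), alpha-ketoglutarate <20% labeled, PPP
    intermediates 40-50% labeled.  Cisplatin suppresses the labeled-lactate
    flux by ``lactate_suppression`` (moving that mass to m+0) and shunts
    carbon into citrate m+2/m+4 and ribose-5-phosphate labeling.
    """
    def mid(n: int, **kv: float) -> np.ndarray:
        v = np.zeros(n + 1)
        for key, val in kv.items():
            v[int(key[1:])] = val
        v[0] = 1.0 - v[1:].sum()
        if v[0] < -1e-12:
            raise ValueError("labeled fractions exceed 1")
        v[0] = max(v[0], 0.0)
        return v

    s = lactate_suppression
    metabolites = [("pyruvate", 3), ("lactate", 3), ("citrate", 6),
                   ("alpha-ketoglutarate", 5), ("ribose-5-phosphate", 5),
                   ("glucose-6-phosphate", 6)]
    control = {
        "pyruvate": mid(3, m3=0.90),
        "lactate": mid(3, m3=0.90),          # diluted to 65% by the mixture
        "citrate": mid(6, m2=0.14, m4=0.04, m5=0.02),
        "alpha-ketoglutarate": mid(5, m2=0.12, m4=0.04),
        "ribose-5-phosphate": mid(5, m5=0.45),
        "glucose-6-phosphate": mid(6, m6=0.80),
    }
    treated = {
        "pyruvate": mid(3, m3=0.90 * (1 - s)),
        "lactate": mid(3, m3=0.90 * (1 - s)),
        "citrate": mid(6, m2=0.22, m4=0.08, m5=0.03),
        "alpha-ketoglutarate": mid(5, m2=0.12, m4=0.04),
        "ribose-5-phosphate": mid(5, m5=0.55),
        "glucose-6-phosphate": mid(6, m6=0.80),
    }
    return TracingScenario(
        metabolites=metabolites,
        true_mids={"control": control, "cisplatin": treated},
        dilution_fraction=5.0 / 18.0,   # 0.9 * (1 - 5/18) = 0.65
        noise_cv=noise_cv,
        n_replicates=n_replicates,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# imaging generator


def _draw_count(rng: np.random.Generator, dist: tuple[str, float]) -> int:
    kind, param = dist
    if kind == "poisson":
        return int(rng.poisson(param))
    if kind == "fixed":
        return int(param)
    raise ValueError(f"unknown foci distribution {kind!r}")


def gen_nuclei_image(scn: ImageScenario) -> tuple[np.ndarray, dict]:
    """Generate a two-channel field (DAPI, gamma-H2AX) with ground truth.

    Returns ``(image, truth)`` where ``image`` has shape (2, H, W), channel
    0 = DAPI, channel 1 = gamma-H2AX, dtype float64 (>= 0), and ``truth``
    lists every nucleus (center, radius, base intensity, foci coordinates).

    Raises ``RuntimeError`` if the requested nuclei cannot be placed
    without overlap within the retry budget — never silently truncates.
    """
    rng = np.random.default_rng(np.random.SeedSequence(scn.seed))
    h, w = scn.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    dapi = np.zeros((h, w))
    gh2ax = np.zeros((h, w))
    placed: list[tuple[float, float, float]] = []
    nuclei = []
    tries = 0
    while len(placed) < scn.n_nuclei:
        if tries >= scn.max_placement_tries:
            raise RuntimeError(
                f"could not place {scn.n_nuclei} non-overlapping nuclei in a "
                f"{h}x{w} field after {tries} tries")
        tries += 1
        r = float(rng.uniform(*scn.radius_range))
        cy = float(rng.uniform(r + 1, h - r - 1))
        cx = float(rng.uniform(r + 1, w - r - 1))
        if any((cy - py) ** 2 + (cx - px) ** 2 < (r + pr + scn.margin) ** 2
               for py, px, pr in placed):
            continue
        placed.append((cy, cx, r))
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        dapi[mask] = scn.dapi_intensity
        mean, sd = scn.control_intensity
        base = max(0.0, float(rng.normal(mean + scn.treated_shift, sd)))
        gh2ax[mask] += base
        n_foci = _draw_count(rng, scn.foci_per_nucleus)
        foci = []
        for _ in range(n_foci):
            # keep foci inside the nucleus, away from its rim; separation
            # from earlier foci is best-effort within a bounded retry budget
            for _attempt in range(200):
                rho = r * 0.7 * np.sqrt(rng.uniform())
                theta = rng.uniform(0, 2 * np.pi)
                fy, fx = cy + rho * np.sin(theta), cx + rho * np.cos(theta)
                if all(np.hypot(fy - f["y"], fx - f["x"])
                       >= scn.focus_min_separation for f in foci):
                    break
            gh2ax += scn.focus_amplitude * np.exp(
                -((yy - fy) ** 2 + (xx - fx) ** 2) / (2 * scn.focus_sigma**2))
            foci.append({"y": float(fy), "x": float(fx)})
        nuclei.append({"center_y": cy, "center_x": cx, "radius": r,
                       "base_intensity": base, "foci": foci,
                       "n_foci": n_foci})
    if scn.background_sd > 0:
        dapi += rng.normal(0, scn.background_sd, (h, w))
        gh2ax += rng.normal(0, scn.background_sd, (h, w))
    image = np.stack([np.clip(dapi, 0, None), np.clip(gh2ax, 0, None)])
    truth = {"n_nuclei": len(nuclei), "nuclei": nuclei,
             "image_size": [h, w]}
    return image, truth


def default_image_scenario(seed: int = 0, n_nuclei: int = 30,
                           treated: bool = False) -> ImageScenario:
    """One field of view: ~30 nuclei; treated fields shift gamma-H2AX up."""
    return ImageScenario(n_nuclei=n_nuclei,
                         treated_shift=250.0 if treated else 0.0,
                         foci_per_nucleus=("poisson", 5.0 if treated else 1.5),
                         seed=seed)


# ---------------------------------------------------------------------------
# calibration generator


def gen_calibration_run(
        scn: CalibrationScenario) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an ICP-MS run table plus ground truth.

    Returns ``(rows, truth)``.  ``rows`` columns: sample, role, pt194,
    pt195, pt196, ir193, nominal_ppb; Pt counts are split across the three
    monitored masses so that their sum over Ir equals the generated ratio.
    Negative noisy ratios clip to 0 and are flagged in ``truth``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(scn.seed))
    # natural Pt isotope pattern across 194/195/196, renormalized
    mass_split = np.array([0.3286, 0.3378, 0.2521])
    mass_split = mass_split / mass_split.sum()

    def rows_for(concs, role):
        recs, truths = [], []
        for i, c in enumerate(concs):
            ratio = scn.true_slope * c + scn.true_intercept
            if scn.relative_noise_sd > 0:
                ratio += rng.normal(0, scn.relative_noise_sd * c)
            clipped = ratio < 0
            ratio = max(ratio, 0.0)
            pt = ratio * scn.ir_counts * mass_split
            name = f"{role}_{i + 1}"
            recs.append({"sample": name, "role": role,
                         "pt194": pt[0], "pt195": pt[1], "pt196": pt[2],
                         "ir193": scn.ir_counts,
                         "nominal_ppb": c if role == "standard" else np.nan})
            truths.append({"sample": name, "true_ppb": c,
                           "true_ratio": scn.true_slope * c + scn.true_intercept,
                           "clipped": clipped})
        return recs, truths

    std_rows, std_truth = rows_for(scn.standard_levels, "standard")
    smp_rows, smp_truth = rows_for(scn.sample_concentrations, "sample")
    return (pd.DataFrame(std_rows + smp_rows),
            pd.DataFrame(std_truth + smp_truth))


def default_calibration_scenario(seed: int = 0,
                                 relative_noise_sd: float = 4e-4,
                                 ) -> CalibrationScenario:
    """Study-condition run: the five serial-dilution levels plus paired
    total/DNA-bound samples with bound:total ratio around 6%.

    ``relative_noise_sd`` is in ratio units per ppb (the generator's noise
    law is sd = relative_noise_sd x concentration); the default equals 2%
    of the default slope, i.e. a 2% CV on the signal at every level.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9001]))
    totals = rng.uniform(20.0, 45.0, 4)
    bound = totals * rng.normal(0.06, 0.015, 4).clip(0.01, 0.12)
    samples = tuple(float(v) for pair in zip(totals, bound) for v in pair)
    return CalibrationScenario(relative_noise_sd=relative_noise_sd,
                               sample_concentrations=samples, seed=seed)


# ---------------------------------------------------------------------------
# writers and config


def write_isotopologue_tsv(spectra: pd.DataFrame, path) -> None:
    spectra.to_csv(path, sep="\t", index=False)


def write_image_tiff(image: np.ndarray, path) -> None:
    """Write a two-channel field as a multi-page TIFF (DAPI, gamma-H2AX)."""
    import tifffile
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def write_calibration_csv(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, index=False)


def write_ground_truth_json(truth, path) -> None:
    obj = truth.to_dict(orient="records") if isinstance(truth, pd.DataFrame) else truth
    Path(path).write_text(json.dumps(obj, indent=1, default=float))


def scenarios_from_yaml(path) -> dict:
    """Build scenario objects from one YAML config.

    Recognized top-level sections: ``tracing``, ``imaging``,
    ``calibration``; each maps field names onto the matching dataclass.
    Unknown keys raise a validation error naming the key.
    """
    import yaml
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    builders = {"tracing": TracingScenario, "imaging": ImageScenario,
                "calibration": CalibrationScenario}
    out = {}
    for section, payload in cfg.items():
        if section not in builders:
            raise ValueError(f"unknown config section {section!r}")
        cls = builders[section]
        valid = set(cls.__dataclass_fields__)
        for key in payload:
            if key not in valid:
                raise ValueError(f"unknown key {key!r} in section {section!r}")
        if section == "tracing":
            payload = dict(payload)
            payload["true_mids"] = {
                cond: {met: np.asarray(vec, dtype=float)
                       for met, vec in mids.items()}
                for cond, mids in payload["true_mids"].items()}
            payload["metabolites"] = [tuple(m) for m in payload["metabolites"]]
        out[section] = cls(**payload)
    return out
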