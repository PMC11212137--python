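"""End-to-end orchestration: simulate -> detect -> filter -> fit -> classify.

A :class:`RunConfig` (built directly or from YAML/JSON) names the simulated
conditions, the detection and filter settings, the histogram fits to run and
the classification layout (which condition is the PCA reference, which is
the second peptide, which are mixtures). ``run_pipeline`` executes the
stages in order with one derived seed per stochastic stage and returns a
JSON-serializable report whose numbers are exactly the stage outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import chiral_classify as cc
from . import eventio, fitting, trace_sim

logger = logging.getLogger(__name__)

__all__ = ["ConditionConfig", "FitSpec", "RunConfig", "run_pipeline", "condition_chain"]


@dataclass
class ConditionConfig:
    """One simulated recording condition."""

    duration_s: float
    populations: list[trace_sim.PopulationSpec] | str
    i0: float = 250.0
    baseline_noise_sd: float = 9.0
    sampling_rate: float = 250_000.0
    filter_cutoff: float = 5_000.0
    voltage_mv: float = 110.0

    def resolve_populations(self) -> list[trace_sim.PopulationSpec]:
        if isinstance(self.populations, str):
            presets = trace_sim.study_conditions()
            if self.populations not in presets:
                raise ValueError(
                    f"unknown population preset {self.populations!r}; "
                    f"choose from {sorted(presets)}"
                )
            return presets[self.populations]
        return self.populations


@dataclass
class FitSpec:
    condition: str
    kind: str  # blockade | dwell | frequency
    model: str = "gaussian"  # for blockade fits
    window: str | None = None  # key into fitting.WINDOWS


@dataclass
class RunConfig:
    conditions: dict[str, ConditionConfig]
    fits: list[FitSpec] = field(default_factory=list)
    detection: dict = field(
        default_factory=lambda: {
            "k": 7.0, "min_dwell_us": 200.0, "min_sigma_pa": 1.0, "min_norm_blockade": 0.2,
        }
    )
    classification: dict | None = None  # {reference, second, mixtures: [...]}
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        conditions = {}
        for name, c in d["conditions"].items():
            c = dict(c)
            pops = c.get("populations")
            if isinstance(pops, list):
                c["populations"] = [trace_sim.PopulationSpec(**p) for p in pops]
            conditions[name] = ConditionConfig(**c)
        fits = [FitSpec(**f) for f in d.get("fits", [])]
        detection = {
            "k": 7.0, "min_dwell_us": 200.0, "min_sigma_pa": 1.0, "min_norm_blockade": 0.2,
        }
        detection.update(d.get("detection", {}))
        cfg = cls(
            conditions=conditions,
            fits=fits,
            detection=detection,
            classification=d.get("classification"),
            seed=int(d.get("seed", 0)),
            outdir=d.get("outdir"),
        )
        # referenced conditions must exist
        if cfg.classification:
            referenced = [cfg.classification.get("reference"), cfg.classification.get("second")]
            referenced += cfg.classification.get("mixtures", [])
            for name in referenced:
                if name and name not in cfg.conditions:
                    raise ValueError(f"classification references undefined condition {name!r}")
        for f in cfg.fits:
            if f.condition not in cfg.conditions:
                raise ValueError(f"fit references undefined condition {f.condition!r}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def condition_chain(
    name: str,
    cond: ConditionConfig,
    detection: dict,
    seed: int,
    outdir: Path | None = None,
):
    """simulate -> baseline -> detect -> featurize -> filter for one condition.

    Returns (filtered_table, unfiltered_table, trace). The unfiltered table
    (threshold detections before the dwell/sigma/blockade filters) is what
    global event-frequency fits use.
    """
    config = trace_sim.SimConfig(
        duration_s=cond.duration_s,
        populations=cond.resolve_populations(),
        i0=cond.i0,
        baseline_noise_sd=cond.baseline_noise_sd,
        sampling_rate=cond.sampling_rate,
        filter_cutoff=cond.filter_cutoff,
        voltage_mv=cond.voltage_mv,
        condition=name,
        seed=seed,
    )
    trace = trace_sim.simulate_trace(config)
    baseline = eventio.estimate_baseline(trace, k=detection["k"])
    detected = eventio.detect_events(trace, baseline)
    featurized = eventio.extract_features(trace, detected)
    filtered = eventio.filter_events(
        featurized,
        min_dwell_us=detection["min_dwell_us"],
        min_sigma_pa=detection["min_sigma_pa"],
        min_norm_blockade=detection["min_norm_blockade"],
    )
    if outdir is not None:
        eventio.events_to_csv(filtered, outdir / f"{name}_events.csv")
        trace_sim.write_ledger(trace.ledger, outdir / f"{name}_ledger.csv")
    return filtered, featurized, trace


def _run_fit(spec: FitSpec, filtered, featurized, fit_seed: int) -> dict:
    window = fitting.WINDOWS[spec.window] if spec.window else None
    if spec.kind == "blockade":
        hist = fitting.blockade_histogram(filtered)
        fit = fitting.fit_blockade_peaks(hist, spec.model, window, seed=fit_seed)
    elif spec.kind == "dwell":
        fit = fitting.fit_dwell_time(filtered, window, seed=fit_seed)
    elif spec.kind == "frequency":
        fit = fitting.event_frequency(featurized, seed=fit_seed)
    else:
        raise ValueError(f"unknown fit kind {spec.kind!r}")
    return fitting.fit_to_dict(
        fit, condition=spec.condition, kind=spec.kind, window=spec.window
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; deterministic given ``config.seed``."""
    master = np.random.SeedSequence(config.seed)
    cond_names = sorted(config.conditions)
    seeds = {name: _child_seed(ss) for name, ss in zip(cond_names, master.spawn(len(cond_names)))}
    fit_ss, cls_ss = master.spawn(2)
    fit_seed, cls_seed = _child_seed(fit_ss), _child_seed(cls_ss)

    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {"seed": config.seed, "conditions": {}, "fits": [], "classification": None}
    tables: dict[str, tuple] = {}
    for name in cond_names:
        cond = config.conditions[name]
        try:
            filtered, featurized, trace = condition_chain(
                name, cond, config.detection, seeds[name], outdir
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'condition:{name}' failed: {exc}") from exc
        tables[name] = (filtered, featurized, trace)
        report["conditions"][name] = {
            "seed": seeds[name],
            "duration_s": cond.duration_s,
            "n_true_events": int(len(trace.ledger)),
            "n_detected": int(len(featurized)),
            "n_retained": int(len(filtered)),
            "filter_counts": filtered.metadata.get("filter_counts"),
            "baseline_i0_pA": filtered.baseline.i0,
            "baseline_sigma_pA": filtered.baseline.sigma,
        }

    for spec in config.fits:
        filtered, featurized, _ = tables[spec.condition]
        try:
            report["fits"].append(_run_fit(spec, filtered, featurized, fit_seed))
        except Exception as exc:
            raise RuntimeError(
                f"stage 'fit:{spec.kind}:{spec.condition}' failed: {exc}"
            ) from exc

    if config.classification:
        cls = config.classification
        try:
            report["classification"] = _run_classification(cls, tables, cls_seed, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage 'classification' failed: {exc}") from exc

    if outdir:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=str)
    return report


def _run_classification(cls: dict, tables: dict, seed: int, outdir: Path | None) -> dict:
    ref_name, second_name = cls["reference"], cls["second"]
    ref_table = tables[ref_name][0]
    second_table = tables[second_name][0]

    model = cc.fit_pca_model(ref_table)
    ref_proj = cc.project_events(ref_table, model)
    sec_proj = cc.project_events(second_table, model)
    band_d = cc.fit_pc2_band(ref_proj.pc2, cc.LABEL_D)
    band_l = cc.fit_pc2_band(sec_proj.pc2, cc.LABEL_L)

    # validation on the combined single-peptide data
    import pandas as pd

    combined = cc.LabeledEvents(
        pd.concat([ref_proj.data, sec_proj.data], ignore_index=True)
    )
    truth = np.array([cc.LABEL_D] * len(ref_proj) + [cc.LABEL_L] * len(sec_proj), dtype=object)
    pred = cc.monte_carlo_classify(combined, band_d, band_l, seed)
    cm = cc.evaluate_confusion(pred, truth)
    logit = cc.logistic_baseline(combined, truth, seed=seed)

    result = {
        "reference": ref_name,
        "second": second_name,
        "band_D": {"mean": band_d.mean, "sd": band_d.sd},
        "band_L": {"mean": band_l.mean, "sd": band_l.sd},
        "eigenvalues": model.eigenvalues.tolist(),
        "confusion_counts": {t: cm.counts.loc[t].to_dict() for t in cm.counts.index},
        "per_class_success": cm.per_class_success,
        "false_positive_rate": cm.false_positive_rate,
        "overall_success": cm.overall_success,
        "logistic_baseline": logit,
        "mixtures": {},
    }
    for mix_name in cls.get("mixtures", []):
        mix_proj = cc.project_events(tables[mix_name][0], model)
        mix_pred = cc.monte_carlo_classify(mix_proj, band_d, band_l, seed)
        ratio = cc.estimate_mixture_ratio(mix_pred)
        result["mixtures"][mix_name] = {
            "counts": mix_pred.counts(),
            "ratio_l_over_d": ratio.ratio,
            "ci": [ratio.ci_low, ratio.ci_high],
            "defined": ratio.defined,
        }
        if outdir is not None:
            mix_pred.data.to_csv(outdir / f"{mix_name}_labels.csv", index=False)
    if outdir is not None:
        model.to_json(outdir / "pca_model.json")
        with open(outdir / "bands.json", "w") as fh:
            json.dump(
                {
                    "D": {"mean": band_d.mean, "sd": band_d.sd},
                    "L": {"mean": band_l.mean, "sd": band_l.sd},
                    "half_width_multiplier": 3.0,
                    "seed": seed,
                },
                fh,
                indent=1,
            )
    return result
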