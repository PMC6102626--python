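"""End-to-end orchestration: simulate -> peaks -> calibrate -> quantify ->
align -> annotate -> GC -> MWCO -> safety -> report.

Every stage is a thin call into the corresponding module; the pipeline's own
job is bookkeeping (peak numbering, table assembly, auditing of filter
decisions) and deterministic report emission. Each report embeds the seed
and a hash of the configuration so reruns are attributable, and rerunning
with the same (config, seed) produces byte-identical output.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import align as align_mod
from . import gcri, masscalc, mwco, quant, safety, synth, traces
from .io import write_dataset


@dataclass(frozen=True)
class PipelineConfig:
    """One configuration object for the whole pipeline."""

    generation: synth.GenerationConfig = field(
        default_factory=synth.GenerationConfig
    )
    # must exceed the width of the broadest real feature (the ~30 min tannin
    # hump), otherwise the hump itself is treated as baseline
    baseline_window_min: float = 40.0
    min_height: float | None = None       # None -> 10 x estimated noise SD
    min_prominence: float | None = None   # None -> same as min_height
    hump_window_min: tuple[float, float] = (15.0, 45.0)
    hump_peak_window_min: float = 0.4
    loss_window_min: tuple[float, float] = (10.0, 50.0)
    rt_tol_min: float = 0.10
    rel_intensity_threshold: float = 0.20
    ppm_tol: float = 5.0
    marker_min_intensity: float = 0.0
    zones: tuple[tuple[str, float, float], ...] = (
        ("polar", 0.0, 8.0),
        ("polyphenol", 8.0, 60.0),
        ("nonpolar", 60.0, 75.0),
    )

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        kwargs = dict(data)
        gen = kwargs.pop("generation", None)
        cfg = cls(**_tuplify(kwargs))
        if gen is not None:
            cfg = replace(cfg, generation=synth.GenerationConfig.from_dict(gen))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def _tuplify(kwargs: dict) -> dict:
    out = {}
    for key, val in kwargs.items():
        if isinstance(val, list):
            out[key] = tuple(tuple(v) if isinstance(v, list) else v for v in val)
        else:
            out[key] = val
    return out


def _estimate_noise_sd(trace: traces.Trace, quiet_end_min: float = 0.8) -> float:
    """Robust noise estimate from the pre-elution segment of the run."""
    sel = trace.time_min <= quiet_end_min
    if sel.sum() < 10:
        sel = np.arange(trace.signal.size) < 10
    seg = trace.signal[sel]
    mad = float(np.median(np.abs(seg - np.median(seg))))
    return 1.4826 * mad


def _corrected(trace: traces.Trace, window_min: float) -> traces.Trace:
    base = traces.estimate_baseline(trace, window_min)
    tr = trace.resampled()
    return traces.Trace(tr.time_min, tr.signal - base.signal, tr.channel)


def run_pipeline(
    config: PipelineConfig | None = None,
    seed: int = 0,
    outdir: str | None = None,
) -> dict:
    """Run every stage on a freshly generated synthetic dataset.

    Returns the report bundle as a dict; when ``outdir`` is given, also
    writes the dataset CSVs, the constituent table, and ``report.json``.
    """
    config = config or PipelineConfig()
    gen = config.generation
    dataset = synth.generate_dataset(gen, seed)
    ctx = quant.DoseContext(dose_mg=gen.dose_mg, ttc_ug=gen.ttc_ug)

    # ---- calibration ------------------------------------------------------
    rf = quant.fit_response_factor(
        list(zip(dataset.standards["area"], dataset.standards["injected_mass_ug"])),
        names=tuple(sorted(set(dataset.standards["name"]))),
    )

    # ---- peak detection ---------------------------------------------------
    corrected = _corrected(dataset.cad_trace, config.baseline_window_min)
    noise_sd = _estimate_noise_sd(corrected)
    min_height = config.min_height if config.min_height is not None else max(
        10.0 * noise_sd, 1e-9
    )
    min_prom = config.min_prominence if config.min_prominence is not None else min_height
    lo_h, hi_h = config.hump_window_min
    all_peaks = traces.detect_peaks(corrected, min_height, min_prom)
    outside = [p for p in all_peaks if not (lo_h <= p.apex_rt_min <= hi_h)]
    narrow_in_hump, hump_area = traces.split_hump(
        corrected, config.hump_window_min, config.hump_peak_window_min,
        min_height=min_height, min_prominence=min_prom,
    )
    peaks = sorted(outside + narrow_in_hump, key=lambda p: p.apex_rt_min)

    # ---- quantitation -----------------------------------------------------
    quantified = [
        quant.quantify_peak(p, rf, gen.sample_conc_ug_per_ml, gen.injection_vol_ul, ctx)
        for p in peaks
    ]
    hump_peak = traces.Peak(
        apex_rt_min=0.5 * (lo_h + hi_h), start_rt_min=lo_h, end_rt_min=hi_h,
        area=hump_area, height=0.0 if hump_area == 0 else hump_area / (hi_h - lo_h),
        channel="CAD", label="tannin hump",
    )
    hump_q = quant.quantify_peak(
        hump_peak, rf, gen.sample_conc_ug_per_ml, gen.injection_vol_ul, ctx
    )

    # ---- MS alignment and formula annotation ------------------------------
    audit: list[dict] = []
    records: list[align_mod.ConstituentRecord] = []
    for i, qp in enumerate(quantified, start=1):
        accepted, rejected = align_mod.contributors(
            qp.peak, dataset.ms_features,
            rel_intensity_threshold=config.rel_intensity_threshold,
            rt_tol_min=config.rt_tol_min,
        )
        for f in accepted:
            audit.append(dict(stage="align", cad_peak=i, mz=round(f.mz, 4),
                              polarity=f.polarity, decision="accepted"))
        for f in rejected:
            audit.append(dict(stage="align", cad_peak=i, mz=round(f.mz, 4),
                              polarity=f.polarity, decision="rejected"))
        sub_labels = "abcdefghijklmnopqrstuvwxyz"
        if not accepted:
            records.append(align_mod.ConstituentRecord(
                cad_peak_id=i, sub_label="", rt_min=qp.peak.apex_rt_min,
                identification="unidentified", formula=None,
                amount_ug_per_dose=qp.amount_ug_per_dose, confidence="unknown",
            ))
            continue
        for j, f in enumerate(sorted(accepted, key=lambda f: -f.intensity)):
            adduct = "[M-H]-" if f.polarity == "neg" else "[M+H]+"
            candidates = masscalc.find_formulas(f.mz, adduct, tol_ppm=config.ppm_tol)
            formula = candidates[0].formula if candidates else None
            records.append(align_mod.ConstituentRecord(
                cad_peak_id=i,
                sub_label=sub_labels[min(j, len(sub_labels) - 1)] if len(accepted) > 1 else "",
                rt_min=qp.peak.apex_rt_min,
                identification=f"m/z {f.mz:.4f} ({f.polarity})",
                formula=formula,
                amount_ug_per_dose=qp.amount_ug_per_dose if j == 0 else None,
                confidence="partial" if formula else "unknown",
                contributing_mz=(round(f.mz, 4),),
            ))
    hump_id = len(quantified) + 1
    records.append(align_mod.ConstituentRecord(
        cad_peak_id=hump_id, sub_label="", rt_min=hump_peak.apex_rt_min,
        identification="tannins (polymeric proanthocyanidins)", formula=None,
        amount_ug_per_dose=hump_q.amount_ug_per_dose, confidence="matched",
    ))
    tally = align_mod.tally_confidence(records)

    # ---- TTC flags --------------------------------------------------------
    peak_amounts = [qp.amount_ug_per_dose for qp in quantified] + [
        hump_q.amount_ug_per_dose
    ]
    ttc_flags = quant.flag_above_ttc(peak_amounts, ctx)
    for i, flag in enumerate(ttc_flags, start=1):
        audit.append(dict(stage="ttc", cad_peak=i,
                          decision="above" if flag else "below"))

    # ---- class fractions: CAD peaks vs UV trace ---------------------------
    cad_fracs = quant.class_fractions(quantified + [hump_q], config.zones)
    uv_corr = _corrected(dataset.uv_trace, config.baseline_window_min)
    uv_fracs = quant.zone_area_fractions(uv_corr, config.zones)

    # ---- mass balance -----------------------------------------------------
    load = gen.load_ug
    cad_percent = 100.0 * (
        sum(qp.injected_mass_ug for qp in quantified) + hump_q.injected_mass_ug
    ) / load
    vol_masses, vol_percents, vol_balance = gcri.quantify_fid(
        dataset.gc_fid_peaks,
        list(zip(dataset.fid_standards["area"],
                 dataset.fid_standards["injected_mass_ug"])),
        load,
    )
    balance, over = quant.mass_balance(
        [min(cad_percent, 100.0), min(vol_balance, 100.0)]
    )

    # ---- adulteration screen ----------------------------------------------
    verdicts = masscalc.adulterant_screen(
        dataset.ms_features, tol_ppm=config.ppm_tol,
        min_intensity=config.marker_min_intensity,
    )
    adulterated = verdicts.get("A-type proanthocyanidin dimer") == "detected"

    # ---- GC retention indexes and volatile TTC ----------------------------
    gc_rows = []
    vol_amounts = []
    for p, m in zip(dataset.gc_fid_peaks, vol_masses):
        amount = m / load * gen.dose_mg * 1000.0
        vol_amounts.append(amount)
        gc_rows.append(dict(
            rt_min=round(p.apex_rt_min, 3),
            kovats_ri=round(gcri.kovats_ri(p.apex_rt_min, dataset.alkane_ladder), 1),
            amount_ug_per_dose=round(amount, 2),
        ))
    vol_flags = quant.flag_above_ttc(vol_amounts, ctx)
    for row, flag in zip(gc_rows, vol_flags):
        row["above_ttc"] = bool(flag)

    # ---- MWCO size distribution -------------------------------------------
    series = mwco.loss_series(
        dataset.cad_trace, dataset.mwco_traces, config.loss_window_min
    )
    bins, monotone_warning = mwco.size_distribution(series)

    # ---- safety assessment -------------------------------------------------
    assessable = [r for r in records if r.amount_ug_per_dose is not None]
    safety_verdicts = safety.assess_all(assessable, {}, ctx)
    safety_summary = safety.summarize(safety_verdicts)

    report = {
        "seed": seed,
        "config_hash": config.config_hash(),
        "response_factor": {
            "slope": round(rf.slope, 6), "r_squared": round(rf.r_squared, 6),
        },
        "n_cad_peaks": len(quantified) + 1,
        "n_constituents": len(records),
        "confidence_tally": tally,
        "peaks": [
            {
                "cad_peak": i + 1,
                "rt_min": round(qp.peak.apex_rt_min, 3),
                "area": round(qp.peak.area, 6),
                "amount_ug_per_dose": round(qp.amount_ug_per_dose, 2),
                "above_ttc": bool(flag),
            }
            for i, (qp, flag) in enumerate(zip(quantified, ttc_flags))
        ],
        "tannin_hump": {
            "cad_peak": hump_id,
            "window_min": list(config.hump_window_min),
            "area": round(hump_area, 6),
            "amount_ug_per_dose": round(hump_q.amount_ug_per_dose, 2),
            "above_ttc": bool(ttc_flags[-1]),
        },
        "ttc": {
            "ttc_ug": ctx.ttc_ug, "dose_mg": ctx.dose_mg,
            "threshold_percent": ctx.threshold_percent,
            "threshold_ppm": ctx.threshold_ppm,
            "n_above": int(sum(ttc_flags)),
        },
        "class_fractions": {
            "CAD": {k: round(v, 2) for k, v in cad_fracs.items()},
            "UV": {k: round(v, 2) for k, v in uv_fracs.items()},
        },
        "mass_balance": {
            "cad_percent": round(cad_percent, 1),
            "volatile_percent": vol_balance,
            "total_percent": balance,
            "over_accounted": over,
        },
        "adulteration": {
            "markers": verdicts,
            "adulterated": adulterated,
        },
        "volatiles": {
            "n_peaks": len(gc_rows),
            "n_above_ttc": int(sum(vol_flags)),
            "peaks": gc_rows,
        },
        "mwco": {
            "cutoffs_da": list(series.cutoffs_da),
            "loss_percent": [round(l, 2) for l in series.loss_percent],
            "size_bins_percent": [round(b, 2) for b in bins],
            "monotone_warning": monotone_warning,
        },
        "safety": safety_summary,
    }

    if outdir is not None:
        _write_report(report, records, audit, dataset, outdir)
    return report


def _records_frame(records: Sequence[align_mod.ConstituentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cad_peak": [r.cad_peak_id for r in records],
            "sub": [r.sub_label for r in records],
            "rt_min": [round(r.rt_min, 3) for r in records],
            "identification": [r.identification for r in records],
            "formula": [r.formula or "" for r in records],
            "amount_ug_per_dose": [
                "" if r.amount_ug_per_dose is None else round(r.amount_ug_per_dose, 2)
                for r in records
            ],
            "confidence": [r.confidence for r in records],
            "contributing_mz": [
                ";".join(f"{m:.4f}" for m in r.contributing_mz) for r in records
            ],
        }
    )


def _write_report(report, records, audit, dataset, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    meta = {"seed": report["seed"], "config_hash": report["config_hash"]}
    write_dataset(dataset, os.path.join(outdir, "dataset"))
    from .io import _write_with_comments  # shared CSV dialect

    _write_with_comments(
        _records_frame(records), os.path.join(outdir, "constituents.csv"), meta
    )
    _write_with_comments(
        pd.DataFrame(audit), os.path.join(outdir, "filter_audit.csv"), meta
    )
    with open(os.path.join(outdir, "report.json"), "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
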