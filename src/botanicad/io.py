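"""CSV dialects shared by the generator, the pipeline and the CLI.

All files are UTF-8 with '.' decimal separators and a header row; generated
files carry provenance (seed, config hash) in leading '#' comment lines.
Float formatting is fixed so that regenerating with the same seed produces
byte-identical files.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import pandas as pd

from .errors import InputError
from .gcri import AlkaneLadder
from .synth import MSFeature, SyntheticDataset
from .traces import Peak, Trace

FLOAT_FMT = "%.8g"


def _write_with_comments(df: pd.DataFrame, path, meta: Mapping | None) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def write_trace_csv(trace: Trace, path, meta: Mapping | None = None) -> None:
    df = pd.DataFrame({"time_min": trace.time_min, "signal": trace.signal})
    meta = dict(meta or {})
    meta.setdefault("channel", trace.channel)
    _write_with_comments(df, path, meta)


def read_trace_csv(path, channel: str | None = None) -> Trace:
    meta = read_meta(path)
    df = pd.read_csv(path, comment="#")
    if "time_min" not in df or "signal" not in df:
        raise InputError(f"{path}: expected columns time_min,signal")
    return Trace(
        df["time_min"].to_numpy(), df["signal"].to_numpy(),
        channel or meta.get("channel", "CAD"),
    )


def read_meta(path) -> dict[str, str]:
    """Parse leading '# key=value' comment lines."""
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
    return meta


def write_features_csv(
    features: Sequence[MSFeature], path, meta: Mapping | None = None
) -> None:
    df = pd.DataFrame(
        {
            "rt_min": [f.rt_min for f in features],
            "mz": [f.mz for f in features],
            "intensity": [f.intensity for f in features],
            "polarity": [f.polarity for f in features],
        }
    )
    _write_with_comments(df, path, meta)


def read_features_csv(path) -> list[MSFeature]:
    df = pd.read_csv(path, comment="#")
    return [
        MSFeature(
            rt_min=float(r.rt_min), mz=float(r.mz),
            intensity=float(r.intensity), polarity=str(r.polarity),
        )
        for r in df.itertuples()
    ]


def write_peaks_csv(peaks: Sequence[Peak], path, meta: Mapping | None = None) -> None:
    df = pd.DataFrame(
        {
            "apex_rt_min": [p.apex_rt_min for p in peaks],
            "start_rt_min": [p.start_rt_min for p in peaks],
            "end_rt_min": [p.end_rt_min for p in peaks],
            "area": [p.area for p in peaks],
            "height": [p.height for p in peaks],
            "channel": [p.channel for p in peaks],
        }
    )
    _write_with_comments(df, path, meta)


def read_peaks_csv(path) -> list[Peak]:
    df = pd.read_csv(path, comment="#")
    return [
        Peak(
            apex_rt_min=float(r.apex_rt_min), start_rt_min=float(r.start_rt_min),
            end_rt_min=float(r.end_rt_min), area=float(r.area),
            height=float(r.height), channel=str(r.channel),
        )
        for r in df.itertuples()
    ]


def write_ladder_csv(ladder: AlkaneLadder, path, meta: Mapping | None = None) -> None:
    df = pd.DataFrame(
        {"carbon_number": [n for n, _ in ladder.pairs],
         "rt_min": [rt for _, rt in ladder.pairs]}
    )
    _write_with_comments(df, path, meta)


def read_ladder_csv(path) -> AlkaneLadder:
    df = pd.read_csv(path, comment="#")
    return AlkaneLadder(list(zip(df["carbon_number"], df["rt_min"])))


def write_dataset(dataset: SyntheticDataset, outdir) -> list[str]:
    """Export a synthetic dataset as the CSV bundle the pipeline consumes.

    Returns the list of files written (relative names).
    """
    os.makedirs(outdir, exist_ok=True)
    meta = {"seed": dataset.seed, "config_hash": dataset.config.config_hash()}
    written = []

    def path(name):
        written.append(name)
        return os.path.join(outdir, name)

    write_trace_csv(dataset.cad_trace, path("cad_trace.csv"), meta)
    write_trace_csv(dataset.uv_trace, path("uv_trace.csv"), meta)
    write_features_csv(dataset.ms_features, path("ms_features.csv"), meta)
    write_peaks_csv(dataset.gc_fid_peaks, path("gc_fid_peaks.csv"), meta)
    write_ladder_csv(dataset.alkane_ladder, path("alkane_ladder.csv"), meta)
    for cutoff, trace in sorted(dataset.mwco_traces.items()):
        write_trace_csv(trace, path(f"mwco_{int(cutoff)}.csv"), meta)
    _write_with_comments(dataset.truth, path("truth_constituents.csv"), meta)
    _write_with_comments(dataset.ms_truth, path("truth_ms_features.csv"), meta)
    _write_with_comments(dataset.standards, path("standards.csv"), meta)
    _write_with_comments(dataset.tannin_standards, path("tannin_standards.csv"), meta)
    _write_with_comments(dataset.fid_standards, path("fid_standards.csv"), meta)
    return written
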