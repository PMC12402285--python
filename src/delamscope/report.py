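"""Pipeline orchestration and report assembly.

``run_all`` drives the full chain — simulate (or ingest) → track → detect
→ classify → stage → intensity → statistics — with fail-fast validation,
and ``assemble_report`` collects every stage's outputs into a single JSON
report plus a human-readable summary. Reports carry the config echo and an
exclusion log, contain no timestamps, and are byte-reproducible for a
fixed config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimConfig
from .detect import (classify_all, detect_delaminations, events_to_table,
                     isotropy_at_onset)
from .intensity import IntensityResult, measure_junctional_intensity
from .movie_io import assign_marker, extract_tracks, tracks_to_table
from .staging import (DEFAULT_WINDOWS, bin_events, cohort_table,
                      make_timeline, mosaic_ratio)
from .synth import simulate_movie

log = logging.getLogger(__name__)

REQUIRED_STAGES = ("config", "tracks", "events", "window_counts", "mosaic")


@dataclass
class ReportBundle:
    """Everything one pipeline run produced."""
    report: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    paths: dict[str, Path] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.report, indent=2, sort_keys=True,
                          default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _summary_text(report: dict) -> str:
    lines = ["delamscope run summary", "======================"]
    ev = report.get("events", {})
    lines.append(f"tracks: {report.get('n_tracks', 0)}; "
                 f"delamination events: {ev.get('n_events', 0)} "
                 f"({ev.get('n_border_excluded', 0)} border-excluded)")
    lines.append(f"geometry: {ev.get('geometry_counts', {})}")
    wc = report.get("window_counts", {})
    for win, n in wc.get("counts", {}).items():
        lines.append(f"  window {win} min: {n} events")
    mos = report.get("mosaic", {})
    if mos:
        lines.append(f"mosaic: {mos.get('n_pos')} marker+ vs "
                     f"{mos.get('n_neg')} marker- "
                     f"(ratio {mos.get('ratio')})")
    inten = report.get("intensity")
    if inten:
        lines.append(f"junctional intensity (frame {inten.get('frame')}): "
                     f"mean {inten.get('mean'):.2f} over "
                     f"{inten.get('mask_area_px')} px")
    iso = report.get("isotropy", {})
    if iso.get("test"):
        lines.append(f"isotropy rank-sum p = {iso['test']['p_two_sided']:.4g}")
    else:
        lines.append(f"isotropy: {iso.get('note', 'not computed')}")
    for item in report.get("exclusions", []):
        lines.append(f"excluded: {item}")
    return "\n".join(lines) + "\n"


def assemble_report(stages: dict, config: SimConfig,
                    outdir: str | Path | None = None) -> ReportBundle:
    """Assemble stage outputs into a report; missing stages are listed.

    *stages* maps stage names (``tracks``, ``events``, ``window_counts``,
    ``mosaic``, optionally ``intensity``, ``isotropy``, ``ground_truth``)
    to their outputs as produced by :func:`run_all`.
    """
    missing = [s for s in REQUIRED_STAGES if s != "config" and s not in stages]
    if missing:
        raise ValueError(f"missing stage outputs: {missing}")

    report: dict = {"config": config.to_dict(), "exclusions": []}
    tables: dict[str, pd.DataFrame] = {}

    tracks_df = stages["tracks"]
    tables["tracks"] = tracks_df
    report["n_tracks"] = int(tracks_df["cell_id"].nunique())

    events_df = stages["events"]
    tables["events"] = events_df
    usable = events_df[~events_df["border_excluded"].astype(bool)]
    report["events"] = {
        "n_events": int(len(usable)),
        "n_border_excluded": int(events_df["border_excluded"].sum()),
        "geometry_counts": {k: int(v) for k, v in
                            usable["geometry"].value_counts().items()},
        "n_onset_fallback": int(usable["fallback"].sum()),
    }
    for _, row in events_df[events_df["border_excluded"].astype(bool)].iterrows():
        report["exclusions"].append(
            f"cell {int(row['cell_id'])}: border contact")

    wc = stages["window_counts"]
    report["window_counts"] = {
        "counts": {f"[{lo:g},{hi:g})": int(n)
                   for (lo, hi), n in zip(wc.windows, wc.counts)},
        "total": wc.total, "outside_windows": wc.excluded,
    }
    mr = stages["mosaic"]
    report["mosaic"] = {"n_pos": mr.n_pos, "n_neg": mr.n_neg,
                        "ratio": (mr.ratio if mr.defined else None),
                        "defined": mr.defined}
    if not mr.defined:
        report["exclusions"].append(
            f"embryo {mr.embryo_id}: mosaic ratio undefined "
            "(no marker-negative delaminations)")

    iso = stages.get("isotropy")
    if iso is not None:
        test = iso.get("test")
        report["isotropy"] = {
            "n_rosette": int(iso["samples"]["rosette"].size),
            "n_new_junction": int(iso["samples"]["new_junction"].size),
            "note": iso["note"],
            "test": None if test is None else {
                "u_statistic": test.u_statistic,
                "p_two_sided": test.p_two_sided, "method": test.method},
        }
    inten: IntensityResult | None = stages.get("intensity")
    if inten is not None:
        report["intensity"] = {
            "frame": inten.frame, "mask_area_px": inten.mask_area_px,
            "mean": inten.mean, "median": inten.median,
            "integrated": inten.integrated,
            "threshold_method": inten.threshold_method,
            "threshold": inten.threshold,
            "dilation_radius": inten.dilation_radius,
            "selected_planes": list(inten.selected_planes)}
    if "ground_truth" in stages:
        gt = stages["ground_truth"]
        report["ground_truth"] = {"n_programmed_events": int(len(gt.events))}

    bundle = ReportBundle(report=report, tables=tables)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        bundle.paths["report"] = out / "report.json"
        bundle.paths["report"].write_text(bundle.to_json())
        bundle.paths["summary"] = out / "summary.txt"
        bundle.paths["summary"].write_text(_summary_text(report))
        for name, df in tables.items():
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            bundle.paths[name] = p
    return bundle


def run_all(config: SimConfig, outdir: str | Path | None = None,
            windows=None, marker_rule="ground_truth",
            intensity_frame: int | None = 0) -> ReportBundle:
    """Simulate and analyse one synthetic embryo end to end.

    Stages: simulate → track → marker assignment → detect → classify →
    stage/bin/mosaic → junctional intensity (one frame) → report. Marker
    assignment uses the rendered nuclear channel when
    ``marker_rule="otsu"``; the default bypass copies generator truth.
    Errors propagate with their stage name.
    """
    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    movie, seq = _stage("simulate", simulate_movie, config)
    gt = seq.ground_truth
    tracks = _stage("track", extract_tracks, movie)
    _stage("marker", assign_marker, movie, tracks,
           threshold_rule=marker_rule,
           ground_truth=gt.cells if marker_rule == "ground_truth" else None)
    events = _stage("detect", detect_delaminations, tracks, movie)
    _stage("classify", classify_all, events, movie)
    iso = _stage("isotropy", isotropy_at_onset, events)
    timeline = _stage("stage", make_timeline, movie, config.t0_frame)
    wc = _stage("bin", bin_events, events, timeline,
                windows or DEFAULT_WINDOWS, embryo_id=f"sim{config.seed}")
    mr = _stage("mosaic", mosaic_ratio, events, embryo_id=f"sim{config.seed}")
    inten = None
    if intensity_frame is not None and movie.channels.get("ecad", {}):
        frame = intensity_frame
        if frame not in movie.channels["ecad"]:
            frame = sorted(movie.channels["ecad"])[0]
        inten = _stage("intensity", measure_junctional_intensity, movie, frame)

    stages = {"config": config, "tracks": tracks_to_table(tracks, movie),
              "events": events_to_table(events), "window_counts": wc,
              "mosaic": mr, "isotropy": iso, "intensity": inten,
              "ground_truth": gt}
    if inten is None:
        stages.pop("intensity")
    bundle = _stage("report", assemble_report, stages, config, outdir)
    bundle.tables["ground_truth"] = gt.events
    if outdir is not None:
        p = Path(outdir) / "ground_truth.csv"
        gt.events.to_csv(p, index=False)
        bundle.paths["ground_truth"] = p
    return bundle
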