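"""Stage orchestration: reproducible runs tying the analysis stages together.

``run_pipeline`` executes the requested stages in dependency order with
structured logging (stage, parameters, counts, exclusions). A partial
failure reports the failing stage without corrupting artifacts written by
earlier stages. Any run is fully reproducible from (inputs, config, seed).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import contact as contact_mod
from . import linescan as linescan_mod
from . import morphology, simulate, tracking
from .config import RunConfig
from .exceptions import StageError
from .geometry import Polyline, polylines_from_csv
from .results import write_results
from .stack import read_stack, write_stack

log = logging.getLogger("mck")

_STAGE_ORDER = ["simulate", "shiftcurve", "coloc", "contact", "track",
                "msd", "events"]


def _provenance_dict(config: RunConfig) -> dict:
    """Scientific parameters only: output location does not affect results."""
    d = config.to_dict()
    d.pop("out_dir", None)
    d.pop("overwrite", None)
    return d


def _scene_spec(config: RunConfig) -> simulate.SceneSpec:
    s = config.scene
    return simulate.SceneSpec(field_size=tuple(s.field_size),
                              pixel_size=s.pixel_size,
                              frame_interval=s.frame_interval,
                              n_frames=s.n_frames, psf_sigma=s.psf_sigma,
                              photon_scale=s.photon_scale,
                              read_noise_sd=s.read_noise_sd,
                              seed=config.seed)


def _stage_simulate(config: RunConfig, ctx: dict) -> None:
    spec = _scene_spec(config)
    s = config.scene
    if s.kind == "spot_pair":
        stack, gt = simulate.generate_spot_pair_scene(spec, s.n_pairs,
                                                      s.offset_sd)
    elif s.kind == "tubular":
        hn, wn = spec.field_nm
        margin = s.tubule_diameter
        layout = Polyline(np.array([[margin, hn / 2], [wn - margin, hn / 2]]),
                          sampling_step=spec.pixel_size, line_id="tube0")
        stack, gt = simulate.generate_tubular_scene(spec, s.tubule_diameter,
                                                    layout)
    else:
        stack, gt = simulate.generate_mdt_event(spec, s.tip_speed, s.coupling)
    ctx["stack"], ctx["truth"], ctx["spec"] = stack, gt, spec
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_stack(stack, out / "scene.tiff")
    ctx["artifacts"]["scene"] = gt.write(out)
    ctx["artifacts"]["scene"]["tiff"] = out / "scene.tiff"
    log.info("simulate: kind=%s frames=%d channels=%s", s.kind,
             stack.n_frames, stack.channel_names)


def _require_stack(config: RunConfig, ctx: dict):
    if "stack" not in ctx:
        if config.stack_path is None:
            raise ValueError("stage needs a stack: run 'simulate' first or "
                             "set stack_path")
        ctx["stack"] = read_stack(config.stack_path,
                                  pixel_size=config.pixel_size,
                                  frame_interval=config.frame_interval)
    return ctx["stack"]


def _spot_pair_linescans(config: RunConfig, ctx: dict) -> list:
    """Linescans through the ground-truth A spots, along x, one per pair."""
    stack = ctx["stack"]
    sc = config.shiftcurve
    truth: simulate.GroundTruth = ctx["truth"]
    half = sc.max_shift + 4 * sc.step
    lines = []
    wn = stack.data.shape[3] * stack.pixel_size
    for tid, trk in truth.object_tracks.items():
        if not tid.startswith(config.shiftcurve.channel_a):
            continue
        x, y = trk.xy[0]
        # skip spots whose full shift window would leave the field
        if x - half < stack.pixel_size or x + half > wn - stack.pixel_size:
            continue
        lines.append(Polyline(np.array([[x - half, y], [x + half, y]]),
                              sampling_step=stack.pixel_size,
                              line_id=tid))
    if not lines:
        raise ValueError("no spot admits a full-length linescan; enlarge "
                         "the field or reduce max_shift")
    return lines


def _stage_shiftcurve(config: RunConfig, ctx: dict) -> None:
    stack = _require_stack(config, ctx)
    sc = config.shiftcurve
    if config.lines_path is not None:
        lines = polylines_from_csv(config.lines_path, stack.pixel_size,
                                   sampling_step=stack.pixel_size)
    elif "truth" in ctx:
        lines = _spot_pair_linescans(config, ctx)
    else:
        raise ValueError("shiftcurve needs lines_path or a simulated scene")
    scans = [linescan_mod.sample_linescan(stack, ln,
                                          channels=[sc.channel_a,
                                                    sc.channel_b])
             for ln in lines]
    curve = linescan_mod.shift_correlation_curve(scans, sc.channel_a,
                                                 sc.channel_b, sc.max_shift,
                                                 sc.step)
    try:
        linescan_mod.colocalization_threshold(curve, sc.confidence)
    except Exception as exc:                      # undefined threshold
        log.warning("shiftcurve: threshold undefined (%s)", exc)
    ctx["curve"] = curve
    ctx["artifacts"]["shiftcurve"] = write_results(
        curve, config.out_dir, "shiftcurve", _provenance_dict(config), config.seed,
        overwrite=config.overwrite)
    log.info("shiftcurve: %d linescans, threshold=%s nm",
             curve.n_linescans, curve.threshold_distance)


def _stage_coloc(config: RunConfig, ctx: dict) -> None:
    cc = config.coloc
    threshold = cc.threshold
    if threshold is None:
        curve = ctx.get("curve")
        if curve is None or not curve.threshold_distance:
            raise ValueError("coloc threshold not set and no recovered "
                             "shift-curve threshold available")
        threshold = curve.threshold_distance
    if "truth" in ctx:
        truth: simulate.GroundTruth = ctx["truth"]
        ca, cb = config.shiftcurve.channel_a, config.shiftcurve.channel_b
        pts_a = np.array([trk.xy[0] for tid, trk in
                          truth.object_tracks.items()
                          if tid.startswith(ca)])
        pts_b = np.array([trk.xy[0] for tid, trk in
                          truth.object_tracks.items()
                          if tid.startswith(cb)])
    else:
        import pandas as pd
        pts_a = pd.read_csv(config.points_a_path)[["x_nm", "y_nm"]].to_numpy()
        pts_b = pd.read_csv(config.points_b_path)[["x_nm", "y_nm"]].to_numpy()
    stack = ctx.get("stack")
    if stack is not None:
        h, w = stack.data.shape[2:]
        px = stack.pixel_size
    else:
        h, w, px = 512, 512, config.pixel_size or 32.0
    mask = np.ones((h, w), dtype=bool)
    result = linescan_mod.randomized_frequency(pts_a, pts_b, mask, threshold,
                                               cc.n_perm, seed=config.seed,
                                               pixel_size=px)
    ctx["coloc"] = result
    ctx["artifacts"]["coloc"] = write_results(
        result, config.out_dir, "coloc", _provenance_dict(config), config.seed,
        overwrite=config.overwrite)
    log.info("coloc: observed=%.3f null=%.3f p=%.2g",
             result.observed_fraction, result.null_mean, result.p_value)


def _stage_contact(config: RunConfig, ctx: dict) -> None:
    stack = _require_stack(config, ctx)
    cc = config.contact
    scenes = []
    for t in range(stack.n_frames):
        mito = contact_mod.binarize(stack.frame(t, cc.mito_channel),
                                    cc.background_radius, cc.method,
                                    cc.cutoff)
        er = contact_mod.binarize(stack.frame(t, cc.er_channel),
                                  cc.background_radius, cc.method, cc.cutoff)
        scenes.append(contact_mod.BinaryScene(
            mito, er, provenance=(cc.background_radius, cc.method)))
    series = contact_mod.contact_stability(scenes, stack.frame_interval,
                                           cc.dilation_radius)
    ctx["contact"] = series
    ctx["artifacts"]["contact"] = write_results(
        series, config.out_dir, "contact", _provenance_dict(config), config.seed,
        overwrite=config.overwrite)
    log.info("contact: mean R=%.3f instability=%.3f",
             series.r_values.mean(), series.mean_abs_delta_over_r0)


def _stage_track(config: RunConfig, ctx: dict) -> None:
    stack = _require_stack(config, ctx)
    tc = config.track
    detections = []
    for t in range(stack.n_frames):
        det = tracking.detect_spots(stack.frame(t, tc.channel),
                                    tc.expected_sigma, tc.min_quality,
                                    stack.pixel_size)
        detections.append(det[["x_nm", "y_nm"]].to_numpy())
    tracks = tracking.link_tracks(detections, tc.max_disp,
                                  stack.frame_interval)
    ctx["tracks"] = tracks
    ctx["artifacts"]["track"] = write_results(
        tracks, config.out_dir, "tracks", _provenance_dict(config), config.seed,
        overwrite=config.overwrite)
    log.info("track: %d detections/frame (mean), %d tracks",
             int(np.mean([len(d) for d in detections])), len(tracks))


def _stage_msd(config: RunConfig, ctx: dict) -> None:
    if "tracks" not in ctx:
        raise ValueError("msd needs the track stage (or track CSV input)")
    mc = config.msd
    usable = [t for t in ctx["tracks"] if len(t) > mc.max_lag]
    if not usable:
        raise ValueError("no track longer than max_lag")
    table = tracking.ensemble_msd(usable, mc.max_lag)
    fit = tracking.fit_anomalous_exponent(table, mc.fit_fraction)
    ctx["msd_fit"] = fit
    ctx["artifacts"]["msd"] = write_results(
        fit, config.out_dir, "msd", _provenance_dict(config), config.seed,
        overwrite=config.overwrite)
    log.info("msd: alpha=%.3f over %d tracks", fit.alpha, len(usable))


def _stage_events(config: RunConfig, ctx: dict) -> None:
    truth = ctx.get("truth")
    if truth is None or "tip" not in truth.object_tracks:
        raise ValueError("events stage needs a simulated MDT event")
    ec = config.events
    event_info = truth.event_log[0]
    spec = ctx["spec"]
    event = morphology.MdtEvent(
        onset_frame=event_info["onset_frame"],
        initiation_site=tuple(event_info["initiation_site_nm"]),
        tip_track=truth.object_tracks["tip"],
        nucleoid_tracks=[truth.object_tracks["nucleoid"]],
        window=(spec.n_frames - 1) * spec.frame_interval)
    morphology.classify_transport(event, ec.proximity_radius, ec.travel_min,
                                  ec.tip_tolerance)
    summary = {"scorable": event.scorable,
               "transport_labels": event.transport_labels,
               "tip_located": event.tip_located,
               "mode_scripted": event_info["mode"]}
    ctx["event"] = event
    ctx["artifacts"]["events"] = write_results(
        summary, config.out_dir, "events", _provenance_dict(config), config.seed,
        overwrite=config.overwrite)
    log.info("events: %s", summary)


_STAGE_FUNCS = {"simulate": _stage_simulate, "shiftcurve": _stage_shiftcurve,
                "coloc": _stage_coloc, "contact": _stage_contact,
                "track": _stage_track, "msd": _stage_msd,
                "events": _stage_events}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns a context dict holding in-memory results and an ``artifacts``
    map of written files. Raises :class:`StageError` naming the failing
    stage; artifacts of completed stages remain on disk.
    """
    ctx: dict = {"artifacts": {}}
    stages = [s for s in _STAGE_ORDER if s in config.stages]
    for stage in stages:
        try:
            _STAGE_FUNCS[stage](config, ctx)
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
    return ctx
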