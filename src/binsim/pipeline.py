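"""Configuration-driven pipeline orchestration.

Library equivalent of a batch driver: each stage reads the previous stage's
artifacts, writes its own (WAV/CSV/JSON) plus a ``manifest.json`` carrying
the seeds, parameters and content hashes that make a run auditable, and
refuses to run when its upstream manifest is missing.  Two runs with the
same :class:`RunConfig` produce identical outputs.

Stages
------
``scenes``    BRIRs for every azimuth the spatial configurations use.
``stimuli``   trial lists and spatialized binaural stimuli.
``process``   hearing-aid processing of every stimulus.
``predict``   BE/BU/all-cues SRM table across rooms and configurations.
``listeners`` synthetic-listener responses for the full grid.
``report``    condition-mean tables, the SRM table, calibration checks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import audio_io, behavior, fitting, ha, scenes, srm, stimuli

__all__ = ["RunConfig", "run_stage", "STAGES"]

STAGES = ("scenes", "stimuli", "process", "predict", "listeners", "report")

_UPSTREAM = {
    "scenes": None,
    "stimuli": "scenes",
    "process": "stimuli",
    "predict": "scenes",
    "listeners": "predict",
    "report": "listeners",
}


@dataclass
class RunConfig:
    """Everything a reproducible run needs.

    The default sizes are deliberately small (a smoke-scale run); the
    study-scale grid uses ``repetitions=10`` and ``n_listeners=15`` per
    group.
    """

    master_seed: int = 0
    fs: float = 16000.0
    rooms: tuple = ("anechoic", "hall")
    groups: tuple = ("NH", "HI")
    repetitions: int = 2
    n_listeners: int = 2
    n_maskers: int = 5
    n_targets: int = 8
    sentence_duration: float = 1.5
    n_stimuli: int = 6  # stimuli rendered per listener (subset of the grid)
    out_dir: str = "run"
    hall: scenes.RoomSpec = field(default_factory=scenes.hall_preset)
    head: scenes.HeadModel = field(default_factory=scenes.HeadModel)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, cls_ in (("hall", scenes.RoomSpec), ("head", scenes.HeadModel)):
            if key in raw:
                sub = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in raw[key].items()}
                raw[key] = cls_(**sub)
        for key in ("rooms", "groups"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["hall"] = dataclasses.asdict(self.hall)
        d["head"] = dataclasses.asdict(self.head)
        d["rooms"] = list(self.rooms)
        d["groups"] = list(self.groups)
        for sub in (d["hall"], d["head"]):
            for k, v in sub.items():
                if isinstance(v, tuple):
                    sub[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d))

    def room_spec(self, kind: str) -> scenes.RoomSpec:
        return scenes.anechoic_preset() if kind == "anechoic" else self.hall

    def stage_dir(self, stage: str) -> Path:
        return Path(self.out_dir) / stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(cfg: RunConfig, stage: str, params: dict, files: list[Path]) -> Path:
    d = cfg.stage_dir(stage)
    manifest = {
        "stage": stage,
        "master_seed": cfg.master_seed,
        "params": params,
        "files": {p.name: _sha256(p) for p in sorted(files)},
    }
    path = d / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _require_upstream(cfg: RunConfig, stage: str) -> None:
    up = _UPSTREAM[stage]
    if up is None:
        return
    manifest = cfg.stage_dir(up) / "manifest.json"
    if not manifest.exists():
        raise FileNotFoundError(
            f"stage {stage!r} needs the output of stage {up!r}; "
            f"run run_stage('{up}', config) first (missing {manifest})"
        )


def _used_azimuths() -> list[float]:
    azs = set()
    for cfg in stimuli.SPATIAL_CONFIGS.values():
        azs.add(scenes.quantize_azimuth(cfg.speech_azimuth))
        azs.update(scenes.quantize_azimuth(a) for a in cfg.noise_azimuths)
    return sorted(azs)


def _load_brirs(cfg: RunConfig, room: str) -> dict[float, scenes.BinauralImpulseResponse]:
    d = cfg.stage_dir("scenes")
    out = {}
    for az in _used_azimuths():
        stem = d / f"brir_{room}_{int(az):+04d}"
        fs, x = audio_io.read_wav(stem.with_suffix(".wav"))
        meta = audio_io.read_sidecar(stem)
        out[az] = scenes.BinauralImpulseResponse(
            left=x[0], right=x[1], fs=fs,
            source=scenes.SourcePosition(meta["azimuth"], meta["distance"]),
            room=cfg.room_spec(room), meta={"onset": meta["onset"]},
        )
    return out


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_scenes(cfg: RunConfig) -> list[Path]:
    d = cfg.stage_dir("scenes")
    files = []
    for room in cfg.rooms:
        spec = cfg.room_spec(room)
        for az in _used_azimuths():
            src = scenes.SourcePosition(azimuth=az, distance=1.9)
            brir = scenes.simulate_brir(spec, src, cfg.head, cfg.fs)
            stem = d / f"brir_{room}_{int(az):+04d}"
            files.append(audio_io.write_wav(stem.with_suffix(".wav"), cfg.fs,
                                            np.stack([brir.left, brir.right])))
            files.append(audio_io.write_sidecar(stem, {
                "azimuth": az, "distance": 1.9, "room": room, "fs": cfg.fs,
                "onset": brir.meta["onset"],
            }))
    return files


def _stage_stimuli(cfg: RunConfig) -> list[Path]:
    grid = stimuli.build_condition_grid(
        groups=cfg.groups, listeners_per_group=cfg.n_listeners,
        repetitions=cfg.repetitions, master_seed=cfg.master_seed,
    )
    d = cfg.stage_dir("stimuli")
    files = []
    rows = []
    brirs = {room: _load_brirs(cfg, room) for room in cfg.rooms}
    for (group, li), trials in grid.items():
        for ti, t in enumerate(trials):
            rows.append({
                "group": group, "listener": li, "index": ti, "room": t.room,
                "snr": t.snr, "config": t.config, "processing": t.processing,
                "repetition": t.repetition, "sentence_seed": t.seeds[0],
                "babble_seed1": t.seeds[1], "babble_seed2": t.seeds[2],
            })
            if ti >= cfg.n_stimuli or t.room not in brirs:
                continue
            stim = stimuli.spatialize_and_prune(
                t, brirs[t.room], cfg.fs, cfg.sentence_duration)
            stem = d / f"stim_{group}_{li}_{ti:04d}"
            files.append(audio_io.write_wav(
                stem.with_suffix(".wav"), cfg.fs,
                np.vstack([stim.ha_mic, stim.ear_canal])))
            files.append(audio_io.write_sidecar(stem, {
                **rows[-1],
                "target_start": stim.target_span.start,
                "target_stop": stim.target_span.stop,
            }))
    trials_csv = d / "trials.csv"
    pd.DataFrame(rows).to_csv(trials_csv, index=False)
    files.append(trials_csv)
    return files


def _hi_audiogram() -> fitting.Audiogram:
    # representative bilateral sloping mild-to-moderately-severe loss
    loss = (25.0, 30.0, 40.0, 50.0, 65.0, 70.0)
    return fitting.Audiogram(thresholds_left=loss, thresholds_right=loss)


def _stage_process(cfg: RunConfig) -> list[Path]:
    d = cfg.stage_dir("process")
    files = []
    audiogram = _hi_audiogram()
    rx = {
        ("HI", "linear"): tuple(fitting.nalr_prescription(audiogram, e) for e in ("left", "right")),
        ("HI", "mild"): tuple(fitting.wdrc_params(audiogram, e) for e in ("left", "right")),
        ("HI", "strong"): tuple(fitting.wdrc_params(audiogram, e) for e in ("left", "right")),
    }
    for wav in sorted(cfg.stage_dir("stimuli").glob("stim_*.wav")):
        meta = audio_io.read_sidecar(wav)
        fs, x = audio_io.read_wav(wav)
        stim = stimuli.EarStimulus(
            ha_mic=x[:2], ear_canal=x[2:], fs=fs,
            target_span=slice(meta["target_start"], meta["target_stop"]),
        )
        left, right = ha.process_ear(
            stim, meta["processing"], meta["group"],
            prescription=rx.get((meta["group"], meta["processing"])),
        )
        stem = d / wav.stem.replace("stim_", "proc_")
        files.append(audio_io.write_wav(stem.with_suffix(".wav"), fs,
                                        np.stack([left.combined, right.combined])))
        files.append(audio_io.write_sidecar(stem, meta))
    return files


def _model_inputs(cfg: RunConfig, room: str, config: str) -> srm.ModelInputs:
    n_targets = cfg.n_targets
    brirs = _load_brirs(cfg, room)
    sc = stimuli.SPATIAL_CONFIGS[config]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.master_seed, 11]))
    b_sp = brirs[scenes.quantize_azimuth(sc.speech_azimuth)]
    sents = []
    for _ in range(n_targets):
        s = scenes.gen_sentence(int(rng.integers(2**31 - 1)),
                                cfg.sentence_duration, cfg.fs)
        sents.append(np.stack([np.convolve(s.samples, b_sp.left),
                               np.convolve(s.samples, b_sp.right)]))
    target = srm.prepare_target(sents, cfg.fs)
    maskers = []
    for _ in range(cfg.n_maskers):
        total = None
        for az in sc.noise_azimuths:
            b = brirs[scenes.quantize_azimuth(az)]
            bab = scenes.gen_babble(int(rng.integers(2**31 - 1)),
                                    cfg.sentence_duration, cfg.fs)
            m = np.stack([np.convolve(bab.samples, b.left),
                          np.convolve(bab.samples, b.right)])
            if total is None:
                total = m
            else:
                n = min(total.shape[1], m.shape[1])
                total = total[:, :n] + m[:, :n]
        maskers.append(total[:, : target.shape[1]])
    return srm.ModelInputs(target_lr=target, maskers_lr=maskers, fs=cfg.fs)


def _stage_predict(cfg: RunConfig) -> list[Path]:
    d = cfg.stage_dir("predict")
    reference = _model_inputs(cfg, "anechoic", "colocated")
    rows = []
    for room in cfg.rooms:
        for config in stimuli.SPATIAL_CONFIGS:
            cond = (_model_inputs(cfg, room, config)
                    if not (room == "anechoic" and config == "colocated")
                    else reference)
            pred = srm.predict_srm(cond, reference)
            rows.append({
                "room": room, "config": config, "be_only": pred.be_only,
                "bu_only": pred.bu_only, "all_cues": pred.all_cues,
                "be_se": pred.be_se, "bu_se": pred.bu_se,
                "n_maskers": pred.n_realizations,
            })
    path = d / "srm.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return [path]


def _stage_listeners(cfg: RunConfig) -> list[Path]:
    srm_table = pd.read_csv(cfg.stage_dir("predict") / "srm.csv")
    srm_lookup = {
        (r.room, r.config): r.all_cues for r in srm_table.itertuples()
    }
    room_penalty = {"anechoic": 0.0, "hall": 3.0}  # reverberant smearing, dB
    frames = []
    d = cfg.stage_dir("listeners")
    for group in cfg.groups:
        listeners = behavior.make_listener_group(group, cfg.n_listeners,
                                                 seed=cfg.master_seed)
        grid = stimuli.build_condition_grid(
            groups=(group,), listeners_per_group=cfg.n_listeners,
            repetitions=cfg.repetitions, master_seed=cfg.master_seed,
        )
        for li, listener in enumerate(listeners):
            results = []
            for t in grid[(group, li)]:
                eff = (t.snr + srm_lookup.get((t.room, t.config), 0.0)
                       - room_penalty[t.room])
                results.append(behavior.respond(listener, t, eff))
            frames.append(behavior.results_frame(results, f"{group}{li:02d}"))
    path = d / "responses.csv"
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return [path]


def _stage_report(cfg: RunConfig) -> list[Path]:
    d = cfg.stage_dir("report")
    files = []
    df = pd.read_csv(cfg.stage_dir("listeners") / "responses.csv")
    summary = behavior.summarize(df, factor="config")
    means_csv = d / "condition_means.csv"
    summary["condition_means"].to_csv(means_csv, index=False)
    pw_csv = d / "pairwise_config.csv"
    summary["pairwise"].to_csv(pw_csv, index=False)
    files += [means_csv, pw_csv]

    srm_csv = d / "srm_table.csv"
    pd.read_csv(cfg.stage_dir("predict") / "srm.csv").to_csv(srm_csv, index=False)
    files.append(srm_csv)

    calib = {}
    for room in cfg.rooms:
        brirs = _load_brirs(cfg, room)
        brir0 = brirs[0.0]
        entry = {"drr_db": scenes.drr(brir0)}
        if room != "anechoic":
            entry["rt60_s"] = scenes.rt60(brir0)
        calib[room] = entry
    calib_json = d / "calibration.json"
    calib_json.write_text(json.dumps(calib, indent=2, sort_keys=True))
    files.append(calib_json)
    return files


_IMPL = {
    "scenes": _stage_scenes,
    "stimuli": _stage_stimuli,
    "process": _stage_process,
    "predict": _stage_predict,
    "listeners": _stage_listeners,
    "report": _stage_report,
}


def run_stage(stage: str, config: RunConfig) -> Path:
    """Run one pipeline stage; returns the path of its manifest.

    Raises ``FileNotFoundError`` naming the missing upstream stage when run
    out of order, and ``ValueError`` for an unknown stage name.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; stages are {STAGES}")
    _require_upstream(config, stage)
    config.stage_dir(stage).mkdir(parents=True, exist_ok=True)
    files = _IMPL[stage](config)
    params = {
        "fs": config.fs, "rooms": list(config.rooms),
        "groups": list(config.groups), "repetitions": config.repetitions,
        "n_listeners": config.n_listeners, "n_maskers": config.n_maskers,
    }
    return _write_manifest(config, stage, params, [Path(f) for f in files])
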