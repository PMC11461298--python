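"""End-to-end orchestration: detect -> override -> trim -> staircase -> evaluate.

A YAML run config drives the full characterization of a directory of clips:
motion onsets are detected and merged with any human overrides, clips are
trimmed so motion starts at frame 2, a simulated (or logged) staircase
locates each clip's category-recognition frame, and rating tables are
scored.  Every stage's parameters and the seed are embedded in the JSON
report so a rerun with the same config reproduces identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .motion_detection import MotionDetectionConfig, detect_motion_onset
from .psychometrics import (
    RatingMatrix,
    confusion_matrix,
    fleiss_kappa,
    one_sample_t,
    chance_level,
    score_ratings,
)
from .staircase import run_session
from .synthetic import make_observer_pool
from .video_core import load_video, read_onset_overrides, resolve_onsets, save_video, trim_to_onset

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_characterization"]

_VIDEO_SUFFIXES = {".mp4", ".m4v", ".avi", ".mov", ".gif"}


class ConfigError(ValueError):
    """Aggregated configuration problems; one message per offending key."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid run config:\n  - " + "\n  - ".join(problems))


@dataclass
class DetectorSettings:
    threshold_fraction: float = 0.10
    min_box_area: int = 400
    roi_y_min: int | None = None
    roi_y_max: int | None = None

    def to_config(self) -> MotionDetectionConfig:
        roi = None
        if self.roi_y_min is not None or self.roi_y_max is not None:
            roi = (self.roi_y_min or 1, self.roi_y_max or 10**9)
        return MotionDetectionConfig(
            threshold_fraction=self.threshold_fraction,
            min_box_area=self.min_box_area,
            roi_y=roi,
        )


@dataclass
class StaircaseSettings:
    guess_rate: float = 1.0 / 3.0
    lapse_rate: float = 0.0
    true_frames_csv: str | None = None  # columns video_id, r_frame
    n_iterations: int | None = None


@dataclass
class RunConfig:
    input_dir: str
    output_dir: str
    seed: int = 0
    fps: float = 60.0
    overrides_csv: str | None = None
    ratings_csv: str | None = None
    detector: DetectorSettings = field(default_factory=DetectorSettings)
    staircase: StaircaseSettings = field(default_factory=StaircaseSettings)
    log_level: str = "INFO"


_TOP_KEYS = {
    "input_dir",
    "output_dir",
    "seed",
    "fps",
    "overrides_csv",
    "ratings_csv",
    "detector",
    "staircase",
    "log_level",
}
_DETECTOR_KEYS = {"threshold_fraction", "min_box_area", "roi_y_min", "roi_y_max"}
_STAIRCASE_KEYS = {"guess_rate", "lapse_rate", "true_frames_csv", "n_iterations"}


def validate_config(source: str | Path | dict) -> RunConfig:
    """Parse and validate a YAML config (or an already-parsed mapping).

    Fills the standard defaults (10 % threshold, 400 px minimum box area,
    60 fps), checks ranges and cross-field consistency, and raises a single
    :class:`ConfigError` listing every problem found.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])
    problems: list[str] = []
    for key in set(raw) - _TOP_KEYS:
        problems.append(f"unknown key {key!r}")
    for key in ("input_dir", "output_dir"):
        if key not in raw:
            problems.append(f"missing required key {key!r}")
    det_raw = raw.get("detector") or {}
    for key in set(det_raw) - _DETECTOR_KEYS:
        problems.append(f"unknown detector key {key!r}")
    stair_raw = raw.get("staircase") or {}
    for key in set(stair_raw) - _STAIRCASE_KEYS:
        problems.append(f"unknown staircase key {key!r}")

    detector = DetectorSettings(**{k: det_raw[k] for k in det_raw if k in _DETECTOR_KEYS})
    staircase = StaircaseSettings(**{k: stair_raw[k] for k in stair_raw if k in _STAIRCASE_KEYS})

    if not 0 < detector.threshold_fraction < 1:
        problems.append(
            f"detector.threshold_fraction must be in (0, 1), got {detector.threshold_fraction}"
        )
    if detector.min_box_area < 1:
        problems.append(f"detector.min_box_area must be >= 1, got {detector.min_box_area}")
    if (
        detector.roi_y_min is not None
        and detector.roi_y_max is not None
        and detector.roi_y_max < detector.roi_y_min
    ):
        problems.append("detector.roi_y_max must be >= detector.roi_y_min")
    if not 0 <= staircase.guess_rate <= 1:
        problems.append(f"staircase.guess_rate must be in [0, 1], got {staircase.guess_rate}")
    if not 0 <= staircase.lapse_rate <= 1:
        problems.append(f"staircase.lapse_rate must be in [0, 1], got {staircase.lapse_rate}")
    fps = float(raw.get("fps", 60.0))
    if fps <= 0:
        problems.append(f"fps must be positive, got {fps}")
    if "input_dir" in raw and not Path(raw["input_dir"]).exists():
        problems.append(f"input_dir does not exist: {raw['input_dir']}")
    for key in ("overrides_csv", "ratings_csv"):
        if raw.get(key) and not Path(raw[key]).exists():
            problems.append(f"{key} does not exist: {raw[key]}")
    if staircase.true_frames_csv and not Path(staircase.true_frames_csv).exists():
        problems.append(f"staircase.true_frames_csv does not exist: {staircase.true_frames_csv}")
    if problems:
        raise ConfigError(problems)
    return RunConfig(
        input_dir=str(raw["input_dir"]),
        output_dir=str(raw["output_dir"]),
        seed=int(raw.get("seed", 0)),
        fps=fps,
        overrides_csv=raw.get("overrides_csv"),
        ratings_csv=raw.get("ratings_csv"),
        detector=detector,
        staircase=staircase,
        log_level=str(raw.get("log_level", "INFO")),
    )


def discover_videos(input_dir: str | Path) -> dict[str, Path]:
    """Map video_id -> path for every clip (frame directory or movie file)."""
    input_dir = Path(input_dir)
    found: dict[str, Path] = {}
    for entry in sorted(input_dir.iterdir()):
        if entry.is_dir() and any(
            f.suffix.lower() == ".png" for f in entry.iterdir() if f.is_file()
        ):
            found[entry.name] = entry
        elif entry.suffix.lower() in _VIDEO_SUFFIXES:
            found[entry.stem] = entry
    return found


def run_characterization(config: RunConfig) -> dict:
    """Run every configured stage and write onsets.csv, trimmed clips,
    convergence.csv and report.json under the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    det_config = config.detector.to_config()
    videos = discover_videos(config.input_dir)
    if not videos:
        raise ConfigError([f"no videos found under {config.input_dir}"])

    # Stage 1: motion onset detection.
    sequences = {}
    auto: dict[str, int] = {}
    rows = []
    for vid, path in videos.items():
        try:
            seq = load_video(path, default_fps=config.fps)
            result = detect_motion_onset(seq, det_config, video_id=vid)
        except Exception as exc:
            raise RuntimeError(f"stage detect-onset failed on video {vid!r}: {exc}") from exc
        sequences[vid] = seq
        if result.onset_frame is not None:
            auto[vid] = result.onset_frame
        rows.append(
            {
                "video_id": vid,
                "onset_frame": result.onset_frame,
                "n_frames": seq.n_frames,
                "fps": seq.fps,
            }
        )
    onsets_table = pd.DataFrame(rows).sort_values("video_id")

    # Stage 2: human overrides win on disagreement.
    if config.overrides_csv:
        manual = read_onset_overrides(config.overrides_csv)
        resolution = resolve_onsets(auto, manual)
        onsets = resolution.onsets
        n_overridden = len(resolution.disagreements)
    else:
        onsets = auto
        n_overridden = 0
    onsets_table["resolved_onset"] = onsets_table["video_id"].map(onsets)
    onsets_table.to_csv(out / "onsets.csv", index=False)

    # Stage 3: trim so motion starts at frame 2.
    trimmed_dir = out / "trimmed"
    trimmed = {}
    for vid, onset in onsets.items():
        try:
            trimmed[vid] = trim_to_onset(sequences[vid], onset)
            save_video(trimmed[vid], trimmed_dir / vid)
        except Exception as exc:
            raise RuntimeError(f"stage trim failed on video {vid!r}: {exc}") from exc

    report: dict = {
        "stimchar_version": __version__,
        "seed": config.seed,
        "parameters": {
            "detector": asdict(config.detector),
            "staircase": asdict(config.staircase),
            "fps": config.fps,
        },
        "n_videos": len(videos),
        "n_onsets_detected": len(auto),
        "n_onsets_overridden": n_overridden,
        "onsets": {vid: int(v) for vid, v in sorted(onsets.items())},
    }

    # Stage 4: simulated between-subject staircase (needs true frames).
    if config.staircase.true_frames_csv:
        tf_table = pd.read_csv(config.staircase.true_frames_csv, dtype={"video_id": str})
        true_frames = dict(zip(tf_table["video_id"], tf_table["r_frame"].astype(int)))
        n_frames = {vid: sequences[vid].n_frames for vid in true_frames if vid in sequences}
        true_frames = {vid: r for vid, r in true_frames.items() if vid in n_frames}
        pool = make_observer_pool(
            true_frames,
            n_frames=n_frames,
            guess_rate=config.staircase.guess_rate,
            lapse_rate=config.staircase.lapse_rate,
            seed=config.seed,
        )
        try:
            results, log = run_session(
                n_frames, pool, seed=config.seed, n_iterations=config.staircase.n_iterations
            )
        except Exception as exc:
            raise RuntimeError(f"stage staircase-sim failed: {exc}") from exc
        conv_table = pd.DataFrame(
            [
                {
                    "video_id": r.video_id,
                    "Nframe": n_frames[r.video_id],
                    "convergence_frame": r.convergence_frame,
                    "n_iterations": r.n_iterations,
                }
                for r in sorted(results, key=lambda r: r.video_id)
            ]
        )
        conv_table.to_csv(out / "convergence.csv", index=False)
        with open(out / "session_log.jsonl", "w") as fh:
            for record in log:
                fh.write(json.dumps(record) + "\n")
        report["n_convergence_rows"] = len(conv_table)

    # Stage 5: psychometric evaluation of a rating table.
    if config.ratings_csv:
        try:
            ratings = RatingMatrix.read_csv(config.ratings_csv)
            scores = score_ratings(ratings)
            kappa = fleiss_kappa(ratings)
            confusion = confusion_matrix(ratings)
            ttest = one_sample_t(
                scores["n_correct"].to_numpy(dtype=float),
                mu0=chance_level(ratings.n_items, len(ratings.labels)),
            )
        except Exception as exc:
            raise RuntimeError(f"stage evaluate failed: {exc}") from exc
        confusion.to_csv(out / "confusion.csv")
        scores.to_csv(out / "accuracy.csv")
        report["evaluation"] = {
            "n_items": ratings.n_items,
            "n_raters": ratings.n_raters,
            "mean_accuracy_pct": float(scores["pct_correct"].mean()),
            "fleiss_kappa": None if kappa.undefined else float(kappa.kappa),
            "chance_test": {
                "t": ttest.t,
                "df": ttest.df,
                "p": ttest.p,
                "ci": [ttest.ci_low, ttest.ci_high],
                "cohens_d": ttest.cohens_d,
            },
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
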