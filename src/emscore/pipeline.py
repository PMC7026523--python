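"""End-to-end orchestration: simulate → (reconstruct) → features → train →
score → report, behind a validated configuration and a fixed seed.

Two entry routes exist: the default consumes the generator's phase maps
directly; setting ``use_holography`` renders off-axis holograms and runs the
full numerical reconstruction before feature extraction. Feature and
classifier stages are independent of the optics stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, evaluate, features, holography, io, simulate
from .exceptions import ConfigurationError

logger = logging.getLogger(__name__)

STAGES = ["simulate", "reconstruct", "features", "train", "score", "report"]

DEFAULTS: dict = {
    "seed": 0,
    "wavelength_nm": 632.0,
    "pixel_pitch_um": 0.18,
    "delta_n": 0.044,
    "field_size": None,
    "use_holography": False,
    "carrier": [0.25, 0.25],
    "aberration": [0.0, 0.0, 0.0, 0.0],
    "noise_sd": 0.0,
    "min_area": 50,
    "test_n": 80,
    "C": 1.0,
    "kernel_scale": 1.0,
    "k_pcs": 6,
    "select_k": False,
    "folds": 5,
    "repeats": 5,
    "T": 200,
    "learning_rate": 0.1,
    "outlier_sd": 5.6,
    "epithelial_line": "GIE",
    "mesenchymal_line": "HGF",
    "lines": None,  # None: the four default populations
}

_TYPES = {
    "seed": int, "wavelength_nm": (int, float), "pixel_pitch_um": (int, float),
    "delta_n": (int, float), "field_size": (int, type(None)),
    "use_holography": bool, "carrier": list, "aberration": list,
    "noise_sd": (int, float), "min_area": int, "test_n": int,
    "C": (int, float), "kernel_scale": (int, float), "k_pcs": int,
    "select_k": bool, "folds": int, "repeats": int, "T": int,
    "learning_rate": (int, float), "outlier_sd": (int, float),
    "epithelial_line": str, "mesenchymal_line": str,
    "lines": (list, type(None)),
}


def validate_config(config=None) -> dict:
    """Normalize a configuration mapping (or JSON/YAML file path).

    Unknown keys are rejected; defaults are injected for missing keys;
    basic type and range checks are applied.
    """
    if config is None:
        config = {}
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        if str(config).endswith((".yaml", ".yml")):
            import yaml

            config = yaml.safe_load(text) or {}
        else:
            config = json.loads(text)
    unknown = sorted(set(config) - set(DEFAULTS))
    if unknown:
        raise ConfigurationError(f"unknown config keys: {unknown}")
    out = {**DEFAULTS, **config}
    bad_types = [
        k for k, t in _TYPES.items()
        if not isinstance(out[k], t) or (t is int and isinstance(out[k], bool) and k != "seed")
    ]
    if bad_types:
        raise ConfigurationError(f"config keys with wrong types: {sorted(bad_types)}")
    if out["delta_n"] <= 0:
        raise ConfigurationError("delta_n must be > 0")
    if out["pixel_pitch_um"] <= 0:
        raise ConfigurationError("pixel_pitch_um must be > 0")
    if not 1 <= out["k_pcs"] <= len(features.FEATURE_NAMES):
        raise ConfigurationError(
            f"k_pcs must be in 1..{len(features.FEATURE_NAMES)}"
        )
    if out["field_size"] is not None and out["field_size"] < 64:
        raise ConfigurationError("field_size must be >= 64")
    if out["folds"] < 2:
        raise ConfigurationError("folds must be >= 2")
    if out["noise_sd"] < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    return out


def simulation_config(cfg: dict) -> simulate.SimulationConfig:
    """Build the generator configuration from a validated pipeline config."""
    profiles = None
    if cfg["lines"] is not None:
        profiles = tuple(
            simulate.LineProfile(
                name=d["name"],
                n_cells=int(d["n_cells"]),
                blend_m=tuple(d["blend_m"]) if isinstance(d.get("blend_m", 0.0), list)
                else float(d.get("blend_m", 0.0)),
            )
            for d in cfg["lines"]
        )
    kwargs = dict(
        field_size=cfg["field_size"],
        pixel_pitch=cfg["pixel_pitch_um"],
        wavelength=cfg["wavelength_nm"],
        delta_n=cfg["delta_n"],
        seed=cfg["seed"],
    )
    if profiles is not None:
        kwargs["line_profiles"] = profiles
    return simulate.SimulationConfig(**kwargs)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: dict, outdir: Path) -> dict:
    sim = simulation_config(cfg)
    stage_dir = outdir / "simulate"
    stage_dir.mkdir(parents=True, exist_ok=True)
    outputs, counts = {}, {}
    for profile in sim.line_profiles:
        phase, gt = simulate.generate_field(sim, profile.name)
        base = stage_dir / profile.name
        io.save_phase_map(f"{base}_phase.tif", phase)
        io.save_ground_truth(f"{base}_truth.json", gt, f"{base}_labels.tif")
        outputs[profile.name] = {
            "phase": f"{base}_phase.tif",
            "truth": f"{base}_truth.json",
            "labels": f"{base}_labels.tif",
        }
        counts[profile.name] = len(gt.cells)
    return {"outputs": outputs, "counts": counts}


def stage_reconstruct(cfg: dict, outdir: Path) -> dict:
    """Render holograms from the simulated phase maps and reconstruct them.

    Pass-through when ``use_holography`` is off: downstream stages read the
    simulated phase maps directly.
    """
    if not cfg["use_holography"]:
        return {"skipped": True}
    stage_dir = outdir / "reconstruct"
    stage_dir.mkdir(parents=True, exist_ok=True)
    sim = simulation_config(cfg)
    outputs = {}
    rng = np.random.default_rng(cfg["seed"] + 101)
    for profile in sim.line_profiles:
        base_in = outdir / "simulate" / profile.name
        phase = io.load_phase_map(f"{base_in}_phase.tif", cfg["pixel_pitch_um"])
        holo, optics = simulate.render_hologram(
            phase,
            carrier=tuple(cfg["carrier"]),
            aberration=tuple(cfg["aberration"]),
            noise_sd=cfg["noise_sd"],
            rng=rng,
            wavelength=cfg["wavelength_nm"],
        )
        demod = holography.isolate_plus_one_order(holo, carrier=tuple(cfg["carrier"]))
        recon, model = holography.pca_aberration_compensate(demod)
        base = stage_dir / profile.name
        io.save_hologram(f"{base}_holo.tif", holo)
        io.save_phase_map(f"{base}_phase.tif", recon)
        model.to_json(f"{base}_aberration.json")
        outputs[profile.name] = {"phase": f"{base}_phase.tif",
                                 "hologram": f"{base}_holo.tif",
                                 "optics_truth": optics}
    return {"outputs": outputs}


def stage_features(cfg: dict, outdir: Path) -> dict:
    stage_dir = outdir / "features"
    stage_dir.mkdir(parents=True, exist_ok=True)
    sim = simulation_config(cfg)
    phase_src = "reconstruct" if cfg["use_holography"] else "simulate"
    fields = []
    for profile in sim.line_profiles:
        phase = io.load_phase_map(
            outdir / phase_src / f"{profile.name}_phase.tif", cfg["pixel_pitch_um"]
        )
        gt = io.load_ground_truth(
            outdir / "simulate" / f"{profile.name}_truth.json",
            outdir / "simulate" / f"{profile.name}_labels.tif",
        )
        hmap = holography.phase_to_height(phase, cfg["wavelength_nm"], cfg["delta_n"])
        fields.append((f"{profile.name}-f0", profile.name, hmap, gt))
    table = features.build_feature_table(fields, min_area=cfg["min_area"])
    path = stage_dir / "features.csv"
    table.to_csv(path, index=False)
    counts = table.groupby("line").size().to_dict()
    logger.info("feature table: %s rows (%s)", len(table), counts)
    return {"outputs": {"features": str(path)},
            "counts": {str(k): int(v) for k, v in counts.items()}}


def stage_train(cfg: dict, outdir: Path) -> dict:
    stage_dir = outdir / "train"
    stage_dir.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(outdir / "features" / "features.csv")
    lines = (cfg["epithelial_line"], cfg["mesenchymal_line"])
    arch = table[table["line"].isin(lines)]
    train, test = classify.partition_data(
        arch, test_n=cfg["test_n"], seed=cfg["seed"], lines=lines
    )
    k = cfg["k_pcs"]
    report_doc = {}
    if cfg["select_k"]:
        y_train = classify.labels_from_lines(train, *lines)
        k, sel = classify.select_pc_count(
            train, y_train, folds=cfg["folds"], repeats=cfg["repeats"],
            seed=cfg["seed"], C=cfg["C"],
        )
        report_doc["pc_selection"] = {
            "k_star": int(k),
            "F": sel.f_stat,
            "p": sel.p_value,
            "mean_accuracy_by_k": dict(
                zip(map(str, sel.candidates), sel.acc_table.mean(axis=0).tolist())
            ),
        }
    model = classify.train_em_model(
        train, k=k, C=cfg["C"], kernel_scale=cfg["kernel_scale"],
        T=cfg["T"], learning_rate=cfg["learning_rate"], seed=cfg["seed"],
        epithelial_line=lines[0], mesenchymal_line=lines[1],
    )
    y_train = classify.labels_from_lines(train, *lines)
    x_train = classify.pca_transform(model.pca, train)
    cv = classify.crossvalidate(
        classify.svm_trainer(C=cfg["C"], kernel_scale=cfg["kernel_scale"]),
        x_train, y_train, folds=cfg["folds"], repeats=cfg["repeats"],
        seed=cfg["seed"],
    )
    model_path = stage_dir / "em_model.json"
    model.to_json(model_path)
    train.to_csv(stage_dir / "train_cells.csv", index=False)
    test.to_csv(stage_dir / "test_cells.csv", index=False)
    report_doc.update({
        "k_pcs": int(k),
        "n_train": int(len(train)),
        "n_test": int(len(test)),
        "cv_accuracy_mean": cv.mean,
        "cv_accuracy_sd": cv.sd,
        "cv_accuracies": cv.accuracies.tolist(),
    })
    with open(stage_dir / "training_report.json", "w") as fh:
        json.dump(report_doc, fh, indent=2)
    return {"outputs": {"model": str(model_path)}, "counts": report_doc}


def stage_score(cfg: dict, outdir: Path) -> dict:
    stage_dir = outdir / "score"
    stage_dir.mkdir(parents=True, exist_ok=True)
    model = classify.EMModel.from_json(outdir / "train" / "em_model.json")
    table = pd.read_csv(outdir / "features" / "features.csv")
    test = pd.read_csv(outdir / "train" / "test_cells.csv")
    lines = (cfg["epithelial_line"], cfg["mesenchymal_line"])
    transfer_tbl = table[~table["line"].isin(lines)]
    test_scores = classify.transfer_score(model, test)
    transfer_scores = classify.transfer_score(model, transfer_tbl)
    test_scores.to_csv(stage_dir / "test_scores.csv", index=False)
    transfer_scores.to_csv(stage_dir / "transfer_scores.csv", index=False)
    return {"outputs": {"test_scores": str(stage_dir / "test_scores.csv"),
                        "transfer_scores": str(stage_dir / "transfer_scores.csv")},
            "counts": {"test": int(len(test_scores)),
                       "transfer": int(len(transfer_scores))}}


def stage_report(cfg: dict, outdir: Path) -> dict:
    stage_dir = outdir / "report"
    stage_dir.mkdir(parents=True, exist_ok=True)
    test_scores = pd.read_csv(outdir / "score" / "test_scores.csv")
    transfer_scores = pd.read_csv(outdir / "score" / "transfer_scores.csv")
    report = evaluate.evaluate_scores(
        test_scores, transfer_scores, outlier_sd=cfg["outlier_sd"]
    )
    doc = {
        "accuracy": report.accuracy,
        "auc": report.auc,
        "confusion": {k: v.to_dict() for k, v in report.confusion.items()},
        "excluded_outliers": [list(map(str, t)) for t in report.excluded_outliers],
        "correlations": report.correlations.to_dict(orient="records"),
        "representatives": {
            k: v.to_dict(orient="records") for k, v in report.representatives.items()
        },
    }
    with open(stage_dir / "report.json", "w") as fh:
        json.dump(doc, fh, indent=2, default=str)
    _render_figures(report, test_scores, transfer_scores, stage_dir)
    return {"outputs": {"report": str(stage_dir / "report.json")}}


def _render_figures(report, test_scores, transfer_scores, stage_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    all_scores = pd.concat([test_scores, transfer_scores], ignore_index=True)

    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    cols = ["svm_score", "platt_posterior", "boost_score", "bag_posterior"]
    for ax, col in zip(axes.ravel(), cols):
        hist = report.histograms[col]
        centers = 0.5 * (hist["edges"][1:] + hist["edges"][:-1])
        for line, counts in hist["counts"].items():
            ax.plot(centers, counts, label=line)
        ax.set_xlabel(col)
        ax.set_ylabel("cells")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(stage_dir / "score_histograms.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, pts in report.roc.items():
        ax.plot(pts[:, 0], pts[:, 1], label=f"{name} (AUC={report.auc[name]:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(stage_dir / "roc_curves.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, col in zip(axes, ["platt_posterior", "boost_score", "bag_posterior"]):
        ax.scatter(all_scores["svm_score"], all_scores[col], s=4, alpha=0.4)
        ax.set_xlabel("svm_score")
        ax.set_ylabel(col)
    fig.tight_layout()
    fig.savefig(stage_dir / "score_correlations.png", dpi=120)
    plt.close(fig)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "reconstruct": stage_reconstruct,
    "features": stage_features,
    "train": stage_train,
    "score": stage_score,
    "report": stage_report,
}


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_full(config=None, outdir="emscore_run", stages=None) -> dict:
    """Execute the pipeline stages in order and write a run manifest.

    A stage is skipped if the existing manifest shows the same config hash
    and all of the stage's declared output files still match their recorded
    checksums. The manifest (minus timestamps) is a pure function of the
    validated config.
    """
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest = {"config": cfg, "config_hash": _config_hash(cfg),
                "seed": cfg["seed"], "stages": {}}
    previous = None
    if manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            previous = None
        if previous and previous.get("config_hash") != manifest["config_hash"]:
            previous = None

    for name in stages or STAGES:
        if previous and name in previous.get("stages", {}):
            entry = previous["stages"][name]
            if _outputs_intact(entry):
                logger.info("stage %s: outputs intact, skipping", name)
                manifest["stages"][name] = entry
                continue
        t0 = time.time()
        try:
            result = _STAGE_FUNCS[name](cfg, outdir)
        except Exception:
            manifest["stages"][name] = {"status": "failed"}
            manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
            logger.exception("stage %s failed; partial manifest persisted", name)
            raise
        result["status"] = "ok"
        result["elapsed_s"] = round(time.time() - t0, 3)
        result["checksums"] = _collect_checksums(result.get("outputs", {}))
        manifest["stages"][name] = result
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _collect_checksums(outputs) -> dict:
    sums = {}
    for val in outputs.values():
        if isinstance(val, dict):
            sums.update(_collect_checksums(val))
        elif isinstance(val, (str, Path)) and Path(val).exists():
            sums[str(val)] = io.sha256_of(val)
    return sums


def _outputs_intact(entry: dict) -> bool:
    if entry.get("status") != "ok":
        return False
    sums = entry.get("checksums", {})
    if not sums and not entry.get("skipped"):
        return False
    for path, digest in sums.items():
        if not Path(path).exists() or io.sha256_of(path) != digest:
            return False
    return True
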