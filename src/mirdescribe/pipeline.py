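"""End-to-end orchestration: simulate -> encode -> train -> tree -> describe
-> evaluate, with a reproducibility manifest and a t-SNE latent plotting
helper.

The pipeline is configured by a single nested mapping (or YAML file) with
``data``, ``model`` and ``tree`` sections plus a global seed; every stage
derives its randomness from that seed, and the manifest records content
hashes of all written artifacts so a rerun can be verified byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .encoding import encode_image
from .features import binarize_features, build_feature_table, quantile_thresholds
from .metrics import classification_report
from .records import write_dataset
from .simulate import (
    GeneratorConfig,
    PlantedRuleConfig,
    generate_dataset,
    generate_planted_rule_dataset,
)
from .tree import LatentDescriptionTree, TreeConfig
from .vae.config import ModelConfig
from .vae.model import DivaVAE

__all__ = ["RunManifest", "run_pipeline", "plot_latent", "load_config"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "mirdescribe_run",
    "holdout_fraction": 0.25,
    "data": {"kind": "planted", "n_samples": 2000},
    "model": {"preset": "desk", "epochs": 25},
    "tree": {"max_depth": 5, "min_samples": 10, "min_acc": 0.8},
}


@dataclass
class RunManifest:
    config: dict
    seed: int
    package_version: str
    stages: dict[str, dict] = field(default_factory=dict)
    report: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _make_records(cfg: dict, seed: int):
    data_cfg = dict(cfg["data"])
    kind = data_cfg.pop("kind", "planted")
    if kind == "planted":
        return generate_planted_rule_dataset(
            PlantedRuleConfig(seed=seed, **data_cfg))
    if kind == "standard":
        return generate_dataset(GeneratorConfig(seed=seed, **data_cfg))
    raise ValueError(f"unknown data kind {kind!r}")


def _make_model_config(cfg: dict) -> tuple[ModelConfig, int | None]:
    model_cfg = dict(cfg["model"])
    preset = model_cfg.pop("preset", "desk")
    epochs = model_cfg.pop("epochs", None)
    factory = {"desk": ModelConfig.desk, "full": ModelConfig.full,
               "tiny": ModelConfig.tiny}[preset]
    return factory(**model_cfg), epochs


def run_pipeline(config=None, verbose: bool = False) -> RunManifest:
    """Execute every stage and write all artifacts under ``outdir``.

    Returns the manifest, whose ``report`` holds the reconstruction
    metrics, the held-out classification report and the extracted
    descriptions. Any stage failure raises with the stage name.
    """
    cfg = load_config(config)
    seed = int(cfg["seed"])
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=seed, package_version=__version__)

    stage = "simulate"
    try:
        t0 = time.time()
        records = _make_records(cfg, seed)
        write_dataset(records, outdir / "data")
        manifest.stages[stage] = {
            "n_records": len(records),
            "seconds": round(time.time() - t0, 2),
            "hashes": {p.name: _sha256(p) for p in sorted((outdir / "data").iterdir())},
        }

        stage = "encode"
        t0 = time.time()
        imgs, ms = zip(*(encode_image(r) for r in records))
        images = np.stack(imgs)
        bonds = np.stack(ms)
        labels = np.array([r.label for r in records])
        np.save(outdir / "images.npy", images)
        np.save(outdir / "bonds.npy", bonds)
        manifest.stages[stage] = {
            "seconds": round(time.time() - t0, 2),
            "hashes": {p.name: _sha256(p) for p in
                       [outdir / "images.npy", outdir / "bonds.npy"]},
        }

        stage = "split"
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(records))
        n_test = int(round(cfg["holdout_fraction"] * len(records)))
        test_idx, train_idx = order[:n_test], order[n_test:]
        manifest.stages[stage] = {"n_train": len(train_idx), "n_test": len(test_idx)}

        stage = "train"
        t0 = time.time()
        model = DivaVAE(images[train_idx], bonds[train_idx], labels[train_idx],
                        _make_model_config(cfg)[0])
        epochs = _make_model_config(cfg)[1]
        results = model.fit(seed=seed, epochs=epochs, verbose=verbose)
        model.save_state(outdir / "model.npz")
        results.history.to_csv(outdir / "history.csv", index=False)
        manifest.stages[stage] = {
            "epochs": len(results.history),
            "final_loss": float(results.history["loss"].iloc[-1]),
            "seconds": round(time.time() - t0, 2),
            "hashes": {"model.npz": _sha256(outdir / "model.npz")},
        }

        stage = "tree"
        t0 = time.time()
        table = build_feature_table(records)
        thresholds = quantile_thresholds(table.iloc[train_idx])
        binary = binarize_features(table, thresholds)
        z_train = results.encode_latents(images[train_idx])["z_m"]
        tree_model = LatentDescriptionTree(
            z_train, labels[train_idx], binary.iloc[train_idx],
            TreeConfig(seed=seed, **cfg["tree"]))
        tree = tree_model.fit()
        tree.to_json(outdir / "tree.json")
        z_test = results.encode_latents(images[test_idx])["z_m"]
        y_pred = tree.predict(z_test)
        clf_report = classification_report(labels[test_idx], y_pred)
        manifest.stages[stage] = {
            "seconds": round(time.time() - t0, 2),
            "training_accuracy": tree.training_accuracy,
            "hashes": {"tree.json": _sha256(outdir / "tree.json")},
        }

        stage = "describe"
        descriptions = [d.render() for d in tree.descriptions]
        (outdir / "descriptions.txt").write_text(
            "\n".join(descriptions) + "\n" if descriptions else "")
        (outdir / "tree.dot").write_text(tree.to_dot() + "\n")
        manifest.stages[stage] = {"n_descriptions": len(descriptions)}

        stage = "evaluate"
        t0 = time.time()
        recon = results.evaluate(images[test_idx])
        manifest.report = {
            "reconstruction": recon.as_dict(),
            "classification": clf_report,
            "descriptions": descriptions,
        }
        with open(outdir / "report.json", "w") as fh:
            json.dump(manifest.report, fh, indent=2)
        manifest.stages[stage] = {"seconds": round(time.time() - t0, 2)}
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest.save(outdir / "manifest.json")
    return manifest


def plot_latent(results, images: np.ndarray, color_values: np.ndarray,
                space: str = "z_m", seed: int = 0, path=None):
    """t-SNE scatter of one latent space, colored by class or a feature.

    Qualitative inspection only; the embedding is 2-D with a fixed seed so
    reruns reproduce identical coordinates.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.manifold import TSNE

    if space not in ("z_m", "z_y", "z_x"):
        raise ValueError("space must be one of z_m, z_y, z_x")
    z = results.encode_latents(images)[space]
    perplexity = min(30.0, max(2.0, (len(z) - 1) / 3.0))
    emb = TSNE(n_components=2, random_state=seed,
               perplexity=perplexity, init="pca").fit_transform(z)
    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(emb[:, 0], emb[:, 1], c=np.asarray(color_values),
                    s=8, cmap="viridis")
    fig.colorbar(sc, ax=ax)
    ax.set_title(f"t-SNE of {space}")
    ax.set_xticks([])
    ax.set_yticks([])
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return emb, fig
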