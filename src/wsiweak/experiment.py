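"""Config-driven experiment runner binding the whole pipeline together.

One experiment = generate (or load) a synthetic corpus, split it
stratified by label, train one named method, and evaluate per-class AUCs
with DeLong confidence intervals on the test split and on the small-lesion
subset (small-lesion cancerous slides plus all benign test slides).

Every source of randomness derives from the single config seed through a
``numpy SeedSequence``; the derived seeds are recorded in the report so a
rerun with the same config is reproducible bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import evalstats
from .mil import (MILClassifier, EMClassifier, MaxFeatRF, MILRNN, build_bags)
from .synthdata import (LabeledSlide, generate_corpus, is_small_lesion,
                        split_slides)
from .whole_slide import WholeSlideClassifier

__all__ = ["ExperimentConfig", "METHODS", "run_experiment", "run_benchmark",
           "build_corpus_and_split"]

METHODS = ("MIL_topk", "EM_LR", "EM_SVM", "MaxFeat_RF", "MIL_RNN",
           "WSI_GAP", "WSI_GMP")

_MIL_BASED = {"MIL_topk", "EM_LR", "EM_SVM", "MaxFeat_RF", "MIL_RNN"}


@dataclass
class ExperimentConfig:
    method: str = "WSI_GMP"
    k: Optional[int] = None
    # corpus
    n_per_class: int = 67
    size_px: int = 512
    small_lesion_quota: float = 0.3
    lesion_fraction_range: Tuple[float, float] = (0.02, 0.40)
    tissue_fraction_range: Tuple[float, float] = (0.2, 0.4)
    split_fractions: Tuple[float, float, float] = (0.5, 0.1, 0.4)
    # desk-scale model/pipeline
    channels: Tuple[int, ...] = (8, 16, 32)
    factor: float = 1.0
    target_side: int = 512
    instance_side: int = 56
    epochs: int = 15       # instance-model (MIL family) training epochs
    ws_epochs: int = 10    # whole-slide training epochs (512-px inputs)
    steps_per_epoch: int = 50
    lr: float = 1e-3
    batch_size: int = 8
    # bookkeeping
    seed: int = 0
    output_dir: Optional[str] = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; valid: {', '.join(METHODS)}"
            )
        if self.method == "MIL_topk" and self.k is None:
            raise ValueError("MIL_topk requires k (1, 3 or 5)")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        doc = yaml.safe_load(Path(path).read_text())
        for key in ("lesion_fraction_range", "tissue_fraction_range",
                    "split_fractions", "channels"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


def _derive_seeds(seed: int) -> Dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ("corpus", "split", "train", "aggregator")
    states = ss.generate_state(len(names))
    return {n: int(s % (2**31 - 1)) for n, s in zip(names, states)}


def build_corpus_and_split(cfg: ExperimentConfig):
    """Generate the corpus and return (train, val, test) slide lists."""
    seeds = _derive_seeds(cfg.seed)
    corpus = generate_corpus(
        n_per_class=cfg.n_per_class,
        lesion_fraction_range=cfg.lesion_fraction_range,
        small_lesion_quota=cfg.small_lesion_quota,
        size_px=cfg.size_px,
        seed=seeds["corpus"],
        tissue_fraction_range=cfg.tissue_fraction_range,
    )
    split = split_slides(corpus, cfg.split_fractions, seed=seeds["split"])
    by_id = {s.slide_id: s for s in corpus}
    parts = tuple(
        [by_id[i] for i in ids]
        for ids in (split.train_ids, split.val_ids, split.test_ids)
    )
    return parts, seeds


def _fit_mil_instance_model(train_bags, cfg, seed: int) -> MILClassifier:
    return MILClassifier(
        k=3, channels=cfg.channels, epochs=cfg.epochs, lr=cfg.lr,
        batch_size=cfg.batch_size, seed=seed,
    ).fit(train_bags)


def _evaluate(probs: np.ndarray, slides: Sequence[LabeledSlide]) -> Dict:
    labels = [s.label for s in slides]
    out = {}
    for target in ("ADC", "SqCC"):
        y, s = evalstats.one_vs_rest(probs, labels, target)
        if y.min() == y.max():
            out[target] = None
            continue
        res = evalstats.delong_ci(y, s)
        out[target] = {
            "auc": res.auc, "ci_low": res.ci_low, "ci_high": res.ci_high,
        }
    return out


def _small_lesion_subset(slides: Sequence[LabeledSlide]) -> List[int]:
    """Indices of small-lesion cancers plus all benign slides."""
    return [
        i for i, s in enumerate(slides)
        if s.label == "NC" or is_small_lesion(s)
    ]


def _round_floats(obj, ndigits=10):
    if isinstance(obj, (float, np.floating)):
        return float(round(float(obj), ndigits))
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_benchmark(methods: Sequence[str], cfg: ExperimentConfig,
                  return_models: bool = False):
    """Train several methods on one shared corpus and report per-class AUCs.

    MIL-based aggregators (MaxFeat_RF, MIL_RNN) share a single standard
    MIL (k=3) instance model, matching the published protocol where the
    patch-level model behind both aggregators is trained by standard MIL.
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(
                f"unknown method {m!r}; valid: {', '.join(METHODS)}"
            )
    (train_slides, val_slides, test_slides), seeds = \
        build_corpus_and_split(cfg)
    small_idx = _small_lesion_subset(test_slides)
    small_slides = [test_slides[i] for i in small_idx]

    need_bags = any(m in _MIL_BASED for m in methods)
    train_bags = val_bags = test_bags = None
    if need_bags:
        train_bags = build_bags(train_slides, instance_side=cfg.instance_side)
        val_bags = build_bags(val_slides, instance_side=cfg.instance_side)
        test_bags = build_bags(test_slides, instance_side=cfg.instance_side)

    mil3 = None

    def mil3_model():
        nonlocal mil3
        if mil3 is None:
            mil3 = _fit_mil_instance_model(train_bags, cfg, seeds["train"])
        return mil3

    cfg_echo = asdict(cfg)
    cfg_echo.pop("output_dir", None)   # filesystem location, not identity
    report = {
        "config": _round_floats(cfg_echo),
        "seeds": seeds,
        "n": {
            "train": len(train_slides), "val": len(val_slides),
            "test": len(test_slides), "small_lesion_test": len(small_slides),
        },
        "methods": {},
    }
    curves = {}
    fitted = {}
    for method in methods:
        if method in ("WSI_GMP", "WSI_GAP"):
            clf = WholeSlideClassifier(
                head="gmp" if method == "WSI_GMP" else "gap",
                channels=cfg.channels, factor=cfg.factor,
                target_side=cfg.target_side, lr=cfg.lr,
                steps_per_epoch=cfg.steps_per_epoch,
                max_epochs=cfg.ws_epochs,
                batch_size=cfg.batch_size, seed=seeds["train"],
            ).fit(train_slides, val_slides=val_slides)
            probs = clf.predict_proba(test_slides)
            curves[method] = clf.curves_
        elif method == "MIL_topk":
            k = cfg.k if cfg.k is not None else 3
            if k == 3:
                clf = mil3_model()
            else:
                clf = MILClassifier(
                    k=k, channels=cfg.channels, epochs=cfg.epochs,
                    lr=cfg.lr, batch_size=cfg.batch_size,
                    seed=seeds["train"],
                ).fit(train_bags)
            probs = clf.predict_proba(test_bags)
        elif method == "MaxFeat_RF":
            # aggregators see train+val bags: the CNN consumed val for
            # checkpoint selection, the slide-level aggregator has not
            clf = MaxFeatRF(instance_model=mil3_model().model_, k=3,
                            seed=seeds["aggregator"]).fit(
                                train_bags + val_bags)
            probs = clf.predict_proba(test_bags)
        elif method == "MIL_RNN":
            clf = MILRNN(instance_model=mil3_model().model_, k=3,
                         seed=seeds["aggregator"]).fit(
                             train_bags + val_bags)
            probs = clf.predict_proba(test_bags)
        else:  # EM_LR / EM_SVM
            clf = EMClassifier(
                kind="LR" if method == "EM_LR" else "SVM-RBF",
                channels=cfg.channels, epochs=max(4, cfg.epochs // 2),
                lr=cfg.lr, batch_size=cfg.batch_size, seed=seeds["train"],
            ).fit(train_bags)
            probs = clf.predict_proba(test_bags)

        entry = {"test": _evaluate(probs, test_slides)}
        entry["small_lesion"] = _evaluate(probs[small_idx], small_slides)
        report["methods"][method] = _round_floats(entry)
        fitted[method] = clf

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        for method, df in curves.items():
            df.to_csv(out / f"curves_{method}.csv", index=False)
    if return_models:
        data = {"train": train_slides, "val": val_slides,
                "test": test_slides, "small_idx": small_idx,
                "test_bags": test_bags, "train_bags": train_bags}
        return report, fitted, data
    return report


def run_experiment(cfg: ExperimentConfig) -> Dict:
    """Run the single method named in the config (see :func:`run_benchmark`)."""
    return run_benchmark([cfg.method], cfg)
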