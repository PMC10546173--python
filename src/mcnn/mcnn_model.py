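"""The full hybrid model: three channel networks fused by an ensemble head.

An RGB image is split into its channels; each channel is scored by its own
fixed-random-filter network (ELM-solved output unit, logistic probability),
and the three per-channel probabilities are the input features of a small
classifier head — a Random Forest by default, with Gaussian Naive Bayes,
an SVM, and AdaBoost available as comparison heads.  Swapping the head
never touches the channel networks: all heads consume identical
per-channel probabilities.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .channel_network import ChannelNetwork, ChannelNetworkConfig
from .elm import DEFAULT_LAM, score_to_probability, solve_ridge

__all__ = ["MCNNModel", "HEAD_KINDS", "make_head", "CHANNELS"]

CHANNELS = ("red", "green", "blue")

#: forest size of the default head
N_TREES = 500

HEAD_KINDS = ("random_forest", "naive_bayes", "svm", "adaboost")


def make_head(kind: str, seed: int):
    """Construct an unfitted head classifier of the given kind.

    All heads are used with library-default hyperparameters (they are
    comparison baselines, not tuned models) and a fixed seed so fits are
    reproducible.
    """
    if kind == "random_forest":
        return RandomForestClassifier(n_estimators=N_TREES, random_state=seed)
    if kind == "naive_bayes":
        return GaussianNB()
    if kind == "svm":
        return SVC(probability=True, random_state=seed)
    if kind == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    raise ValueError(f"unknown head kind {kind!r}; choose from {HEAD_KINDS}")


class MCNNModel:
    """Three per-channel networks plus a probability-fusion head.

    Parameters
    ----------
    input_size
        Height/width the (already preprocessed) images must have.
    head_kind
        One of :data:`HEAD_KINDS`.
    seed
        Master seed; per-channel network seeds and the head seed are
        derived from it, so a model is fully determined by its
        configuration.
    """

    def __init__(
        self,
        input_size: tuple[int, int] = (256, 256),
        head_kind: str = "random_forest",
        seed: int = 0,
    ) -> None:
        if head_kind not in HEAD_KINDS:
            raise ValueError(f"unknown head kind {head_kind!r}; choose from {HEAD_KINDS}")
        self.input_size = tuple(input_size)
        self.head_kind = head_kind
        self.seed = int(seed)
        child_seeds = self._child_seeds(self.seed)
        self.channels = {
            name: ChannelNetwork(ChannelNetworkConfig(input_size=self.input_size, seed=s))
            for name, s in zip(CHANNELS, child_seeds[:3])
        }
        self._head_seed = child_seeds[3]
        self.head = None

    @staticmethod
    def _child_seeds(seed: int) -> list[int]:
        ss = np.random.SeedSequence(seed)
        return [int(s) % (2**31) for s in ss.generate_state(4)]

    # ------------------------------------------------------------------
    def _check_images(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=float)
        if images.ndim != 4 or images.shape[3] != 3:
            raise ValueError(f"expected RGB stack (N, H, W, 3), got shape {images.shape}")
        if images.shape[1:3] != self.input_size:
            raise ValueError(
                f"expected images of size {self.input_size}, got {images.shape[1:3]}"
            )
        return images

    def fit(self, images: np.ndarray, labels: np.ndarray, lam: float = DEFAULT_LAM) -> "MCNNModel":
        """Fit the three channel networks by ELM, then the head on their
        training-set probabilities.

        ``images`` is an (N, H, W, 3) RGB stack with intensities in [0, 1];
        ``labels`` is binary with both classes present.
        """
        images = self._check_images(images)
        labels = np.asarray(labels).astype(int)
        if np.unique(labels).size < 2:
            raise ValueError("training set must contain both classes")
        t = 2.0 * (labels > 0) - 1.0
        probs = np.empty((images.shape[0], 3))
        for i, name in enumerate(CHANNELS):
            net = self.channels[name]
            # extract once: the same features serve the ELM solve and the
            # head's training-set probabilities
            features = net.extract_features_batch(images[..., i])
            H = np.hstack([features, np.ones((features.shape[0], 1))])
            net.output_weights = solve_ridge(H, t, lam).beta
            scores = features @ net.output_weights[:-1] + net.output_weights[-1]
            probs[:, i] = score_to_probability(scores)
        self.head = make_head(self.head_kind, self._head_seed)
        self.head.fit(probs, labels)
        return self

    def channel_probabilities(self, images: np.ndarray) -> np.ndarray:
        """Per-channel positive-class probabilities, shape (N, 3) in
        (red, green, blue) order — the head's input features."""
        images = self._check_images(images)
        cols = [
            score_to_probability(self.channels[name].decision_scores(images[..., i]))
            for i, name in enumerate(CHANNELS)
        ]
        return np.column_stack(cols)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Head probability of the positive class per image."""
        if self.head is None:
            raise RuntimeError("model is not fitted; call fit() first")
        probs = self.channel_probabilities(images)
        positive = list(self.head.classes_).index(1)
        return self.head.predict_proba(probs)[:, positive]

    def predict(self, images: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(images) >= threshold).astype(int)

    def predict_per_channel(self, images: np.ndarray, channel: str) -> np.ndarray:
        """Positive-class probability from one channel's network alone
        (for the channel-ablation analysis; threshold at 0.5 to score)."""
        if channel not in CHANNELS:
            raise ValueError(f"unknown channel {channel!r}; choose from {CHANNELS}")
        images = self._check_images(images)
        idx = CHANNELS.index(channel)
        return score_to_probability(self.channels[channel].decision_scores(images[..., idx]))

    # ------------------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Write a model bundle: per-channel weight containers, the fitted
        head, and a JSON manifest of the configuration."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, net in self.channels.items():
            net.save(directory / f"channel_{name}.npz")
        if self.head is not None:
            joblib.dump(self.head, directory / "head.joblib")
        manifest = {
            "input_size": list(self.input_size),
            "head_kind": self.head_kind,
            "seed": self.seed,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "MCNNModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        model = cls(
            input_size=tuple(manifest["input_size"]),
            head_kind=manifest["head_kind"],
            seed=manifest["seed"],
        )
        for name in CHANNELS:
            model.channels[name] = ChannelNetwork.load(directory / f"channel_{name}.npz")
        head_path = directory / "head.joblib"
        if head_path.exists():
            model.head = joblib.load(head_path)
        return model
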