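"""Monte-Carlo prediction uncertainty.

A trained DU-former maps an epoch to a Gaussian embedding; repeating the
forward pass with fresh noise draws K class-probability vectors per epoch.
The per-sample "uncertainty level" is the normalized predictive entropy of
the MC-mean probability vector, H(p_bar)/ln(n_classes) in [0, 1] (0 for a
degenerate prediction, 1 for a uniform one). The MC standard deviation of
the top-class probability is reported alongside as an alternative spread
measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nn import Module


@dataclass
class UncertaintyReport:
    """Per-sample MC uncertainty and the run's global parameters."""

    predicted_class: np.ndarray
    mean_probs: np.ndarray  # (n, n_classes)
    uncertainty: np.ndarray  # normalized predictive entropy in [0, 1]
    prob_spread: np.ndarray  # MC std of the top-class probability
    n_draws: int
    seed: int
    band: str = ""

    def __len__(self) -> int:
        return len(self.uncertainty)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "predicted_class": self.predicted_class,
            "uncertainty": self.uncertainty,
            "prob_spread": self.prob_spread,
            **{
                f"mean_prob_{c}": self.mean_probs[:, c]
                for c in range(self.mean_probs.shape[1])
            },
        })


def normalized_entropy(probs: np.ndarray) -> np.ndarray:
    """Shannon entropy of each probability row, normalized by ln(n_classes)."""
    p = np.clip(np.asarray(probs, dtype=float), 1e-12, 1.0)
    h = -(p * np.log(p)).sum(axis=-1)
    return h / np.log(probs.shape[-1])


def mc_predict(
    model: Module,
    segments: np.ndarray,
    k: int = 30,
    seed: int = 0,
    band: str = "",
    batch_size: int = 256,
) -> UncertaintyReport:
    """K stochastic forward passes -> per-sample predictive uncertainty."""
    if k < 1:
        raise ValueError("k must be >= 1")
    segments = np.asarray(segments, dtype=np.float32)
    model.set_training(False)
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(k):
        chunks = [
            model.forward(segments[i:i + batch_size], rng=rng, mode="mc").probs.data
            for i in range(0, len(segments), batch_size)
        ]
        draws.append(np.concatenate(chunks))
    stack = np.stack(draws)  # (K, n, n_classes)
    mean_probs = stack.mean(axis=0)
    mean_probs /= mean_probs.sum(axis=-1, keepdims=True)
    top = mean_probs.argmax(axis=-1)
    spread = stack[:, np.arange(stack.shape[1]), top].std(axis=0)
    return UncertaintyReport(
        predicted_class=top,
        mean_probs=mean_probs,
        uncertainty=normalized_entropy(mean_probs),
        prob_spread=spread,
        n_draws=k,
        seed=seed,
        band=band,
    )


def uncertainty_histogram(
    report: UncertaintyReport, bin_edges: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Occurrence rate per uncertainty bin; rates sum to 1."""
    if len(report) == 0:
        raise ValueError("empty report")
    if bin_edges is None:
        bin_edges = np.linspace(0.0, 1.0, 11)
    bin_edges = np.asarray(bin_edges, dtype=float)
    counts, _ = np.histogram(np.clip(report.uncertainty, 0.0, 1.0), bins=bin_edges)
    return bin_edges, counts / counts.sum()


def acceptance_rate(report: UncertaintyReport, threshold: float = 0.3) -> float:
    """Fraction of samples whose uncertainty is at most ``threshold``."""
    if len(report) == 0:
        raise ValueError("empty report")
    return float((report.uncertainty <= threshold).mean())


def plot_uncertainty_histogram(report: UncertaintyReport, path: str) -> None:
    """Bar chart of occurrence rate vs uncertainty level, saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges, rates = uncertainty_histogram(report)
    centers = (edges[:-1] + edges[1:]) / 2
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(centers, rates, width=np.diff(edges) * 0.9)
    ax.set_xlabel("Uncertainty Level")
    ax.set_ylabel("Occurrence Rate")
    if report.band:
        ax.set_title(f"{report.band} band (K={report.n_draws})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
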