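"""Two-view synthetic benchmark with a known latent correspondence.

The generator produces two feature x sample matrices whose first ``n_signal``
rows are noisy copies of two deterministic base curves over the sample axis:

    g1(j) = j/M + sin(pi*j/M)          (rising ramp + half-period sine)
    g2(j) = (M-j)/M + sin(pi*j/M)      (falling ramp + half-period sine)

for j = 1..M.  Signal rows of view k are ``(c/2)*gk(j) + (1-c)*eps`` with
entry-wise uniform noise eps ~ U[0,1]; the remaining rows are pure U[0,1]
noise.  The two base curves are built from the same orthogonal parts with
opposite ramps, so the raw Pearson correlation between a view-1 and a view-2
signal row is near zero — the cross-view correspondence is latent, visible
only through the shared sine/ramp decomposition, which is exactly what the
tensor pipeline is meant to recover.

Defaults (c=0.8, N=1000, N0=M=50) are the benchmark's study conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tensors import CASE_SHARED_SAMPLES, MultiViewSet, ViewMatrix

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_two_view"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the two-view benchmark.

    c         signal weight in [0, 1] (c=1: pure signal, c=0: pure noise)
    n_features  N, rows per view
    n_signal    N0, number of signal rows (the first N0)
    n_samples   M, shared sample count
    seed        RNG seed
    """

    c: float = 0.8
    n_features: int = 1000
    n_signal: int = 50
    n_samples: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"signal weight c={self.c} must lie in [0, 1]")
        if self.n_signal < 1 or self.n_signal > self.n_features:
            raise ValueError(
                f"need 1 <= n_signal <= n_features, got "
                f"{self.n_signal} / {self.n_features}"
            )
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")


@dataclass
class SyntheticDataset:
    """Generated benchmark plus the ground truth used by test oracles."""

    views: tuple[ViewMatrix, ViewMatrix]
    signal_indices: np.ndarray  # 0-based row indices of signal features
    base_curves: tuple[np.ndarray, np.ndarray]  # g1, g2 over j=1..M
    config: SyntheticConfig = field(repr=False, default=None)

    def as_multiview(self) -> MultiViewSet:
        return MultiViewSet(list(self.views), case=CASE_SHARED_SAMPLES)

    @property
    def signal_mask(self) -> np.ndarray:
        mask = np.zeros(self.views[0].n_features, dtype=bool)
        mask[self.signal_indices] = True
        return mask


def base_curves(n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """The deterministic generating profiles g1, g2 at j = 1..M."""
    j = np.arange(1, n_samples + 1, dtype=float)
    s = np.sin(np.pi * j / n_samples)
    g1 = j / n_samples + s
    g2 = (n_samples - j) / n_samples + s
    return g1, g2


def generate_two_view(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one realization of the two-view benchmark.

    Noise is drawn entry-wise from a single RNG stream, view 1 fully before
    view 2, rows in row-major order, so a seed pins the dataset down exactly
    across platforms.  Non-signal rows are raw U[0,1] draws (full weight, not
    scaled by 1-c).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    g1, g2 = base_curves(cfg.n_samples)
    views = []
    for k, g in enumerate((g1, g2)):
        eps = rng.random((cfg.n_features, cfg.n_samples))
        vals = eps.copy()
        vals[: cfg.n_signal] = cfg.c / 2.0 * g + (1.0 - cfg.c) * eps[: cfg.n_signal]
        views.append(
            ViewMatrix(
                vals,
                feature_ids=[f"f{i + 1}" for i in range(cfg.n_features)],
                sample_ids=[f"s{j + 1}" for j in range(cfg.n_samples)],
                name=f"view{k + 1}",
            )
        )
    return SyntheticDataset(
        views=(views[0], views[1]),
        signal_indices=np.arange(cfg.n_signal),
        base_curves=(g1, g2),
        config=cfg,
    )
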