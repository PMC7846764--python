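"""Training-set class balancing: SMOTE plus random over-/under-sampling.

SMOTE synthesizes minority-class samples on segments between an original
sample and one of its k nearest same-class neighbours, so every class is
brought up to the size of the largest (or an explicit target).  Originals
are always retained unchanged; only the training split should ever be
passed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["SmoteConfig", "smote_balance", "random_oversample", "random_undersample"]


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    target_size: int | str = "largest-class"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if isinstance(self.target_size, str) and self.target_size != "largest-class":
            raise ValueError("target_size must be an int or 'largest-class'")


def _class_indices(y: np.ndarray) -> dict[object, np.ndarray]:
    return {cls: np.flatnonzero(y == cls) for cls in sorted(set(y.tolist()))}


def _resolve_target(cfg: SmoteConfig, sizes: dict[object, int]) -> int:
    if cfg.target_size == "largest-class":
        return max(sizes.values())
    return int(cfg.target_size)


def smote_balance(
    X: np.ndarray, y: np.ndarray, cfg: SmoteConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample every class to the target size with SMOTE interpolation.

    Each synthetic sample is ``x + u * (z - x)`` with ``u ~ U(0, 1)`` and
    ``z`` one of the ``k_neighbors`` nearest same-class neighbours of ``x``
    (Euclidean).  The per-class deficit is distributed round-robin over the
    class's original samples so class sizes come out exactly flat.
    """
    cfg = cfg or SmoteConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    rng = np.random.default_rng(cfg.seed)
    groups = _class_indices(y)
    target = _resolve_target(cfg, {c: len(i) for c, i in groups.items()})

    out_X = [X]
    out_y = [y]
    for cls in groups:
        idx = groups[cls]
        deficit = target - len(idx)
        if deficit < 0:
            raise ValueError(
                f"class {cls!r} exceeds target size {target}; SMOTE only oversamples"
            )
        if deficit == 0:
            continue
        if len(idx) <= cfg.k_neighbors:
            raise ValueError(
                f"class {cls!r} has {len(idx)} samples; needs > k_neighbors="
                f"{cfg.k_neighbors}"
            )
        Xc = X[idx]
        nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(Xc)
        neigh = nn.kneighbors(Xc, return_distance=False)[:, 1:]  # drop self
        # Round-robin over sources: sample i contributes ceil-or-floor share.
        sources = np.arange(len(idx))[np.arange(deficit) % len(idx)]
        picked = neigh[sources, rng.integers(0, cfg.k_neighbors, size=deficit)]
        u = rng.random(deficit)[:, None]
        synth = Xc[sources] + u * (Xc[picked] - Xc[sources])
        out_X.append(synth)
        out_y.append(np.full(deficit, cls, dtype=object))
    return np.vstack(out_X), np.concatenate(out_y)


def random_oversample(
    X: np.ndarray, y: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Duplicate minority samples (with replacement) up to the largest class size."""
    X = np.asarray(X)
    y = np.asarray(y, dtype=object)
    rng = np.random.default_rng(seed)
    groups = _class_indices(y)
    target = max(len(i) for i in groups.values())
    out_X, out_y = [X], [y]
    for cls, idx in groups.items():
        deficit = target - len(idx)
        if deficit == 0:
            continue
        extra = rng.choice(idx, size=deficit, replace=True)
        out_X.append(X[extra])
        out_y.append(y[extra])
    return np.vstack(out_X), np.concatenate(out_y)


def random_undersample(
    X: np.ndarray, y: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Subsample every class (without replacement) down to the smallest class size."""
    X = np.asarray(X)
    y = np.asarray(y, dtype=object)
    rng = np.random.default_rng(seed)
    groups = _class_indices(y)
    target = min(len(i) for i in groups.values())
    keep = np.concatenate(
        [rng.choice(idx, size=target, replace=False) for idx in groups.values()]
    )
    keep.sort()
    return X[keep], y[keep]
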