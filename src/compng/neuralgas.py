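"""Neural gas: rank-based online vector quantization of CLR sample vectors.

The algorithm maintains K codebook units w_i in feature space.  Each
presented sample x ranks all units by Euclidean distance (rank r_i = 0 for
the winner) and every unit moves toward x by

    w_i <- w_i + eps(t) * exp(-r_i / lambda(t)) * (x - w_i)

with exponentially annealed step size eps(t) = eps_i * (eps_f/eps_i)^(t/t_max)
and neighbourhood range lambda(t) = lambda_i * (lambda_f/lambda_i)^(t/t_max),
where t counts individual sample presentations and t_max = epochs * n.
Distance ties are broken toward the lower unit index.  Units are
initialised at K distinct data rows chosen by the seeded generator, so the
codebook starts — and, updates being convex combinations, remains — inside
the axis-aligned bounding box of the data.

A codebook unit together with the samples mapped to it is a
"best-matching unit" (BMU) in the sense used for self-organising maps;
`bmu`-named aliases are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .compositional import CLRMatrix


@dataclass(frozen=True)
class NGConfig:
    """Hyperparameters of a neural gas run.

    Defaults: 5 units, 1000 training epochs, initial step size 0.5 and
    initial decay (neighbourhood) constant 4.5; annealing targets
    eps_final=0.005 and lambda_final=0.01 make late training nearly
    winner-only.
    """

    k_units: int = 5
    epochs: int = 1000
    eps_initial: float = 0.5
    eps_final: float = 0.005
    lambda_initial: float = 4.5
    lambda_final: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_units < 1 or self.epochs < 1:
            raise ValueError("k_units and epochs must be >= 1")
        if not (0 < self.eps_final <= self.eps_initial <= 1):
            raise ValueError("need 0 < eps_final <= eps_initial <= 1")
        if not (0 < self.lambda_final <= self.lambda_initial):
            raise ValueError("need 0 < lambda_final <= lambda_initial")


@dataclass
class NGModel:
    """Trained codebook plus configuration and diagnostics."""

    codebook: pd.DataFrame          # k_units x n_features, CLR units
    config: NGConfig
    quantization_error: float       # final mean sample-to-nearest-unit distance
    initial_quantization_error: float
    n_presentations: int

    @property
    def k_units(self) -> int:
        return self.codebook.shape[0]


@dataclass
class BMUAssignment:
    """Sample -> unit mapping; unit indices are 1-based for reporting."""

    labels: pd.Series               # sample_id -> unit index in 1..K
    k_units: int

    @property
    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {u: [] for u in range(1, self.k_units + 1)}
        for sid, u in self.labels.items():
            out[int(u)].append(sid)
        return out

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().reindex(
            range(1, self.k_units + 1), fill_value=0)


def _as_array(X) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(X, CLRMatrix):
        return X.data.to_numpy(dtype=float), X.sample_ids, X.feature_ids
    df = pd.DataFrame(X)
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [
        str(c) for c in df.columns]


def train_neural_gas(X, config: NGConfig = NGConfig()) -> NGModel:
    """Train a neural gas codebook on samples-by-features data.

    Fully reproducible from ``config.seed``: the seeded generator draws the
    K distinct initialisation rows, then one fresh presentation order per
    epoch.
    """
    arr, sample_ids, feature_ids = _as_array(X)
    n, p = arr.shape
    k = config.k_units
    if k > n:
        raise ValueError(f"k_units={k} exceeds n_samples={n}")
    if not np.isfinite(arr).all():
        raise ValueError("training data contains non-finite values")

    rng = np.random.default_rng(config.seed)
    init_idx = rng.choice(n, size=k, replace=False)
    W = arr[init_idx].copy()
    initial_qe = float(cdist(arr, W).min(axis=1).mean())

    t_max = config.epochs * n
    t_grid = np.arange(t_max) / t_max
    eps_sched = config.eps_initial * (
        config.eps_final / config.eps_initial) ** t_grid
    lam_sched = config.lambda_initial * (
        config.lambda_final / config.lambda_initial) ** t_grid

    ranks = np.empty(k, dtype=np.intp)
    t = 0
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for i in order:
            x = arr[i]
            diff = x - W
            d = np.einsum("ij,ij->i", diff, diff)
            # stable argsort: ties resolved toward the lower unit index
            ranks[np.argsort(d, kind="stable")] = np.arange(k)
            h = eps_sched[t] * np.exp(-ranks / lam_sched[t])
            W += h[:, None] * diff
            t += 1

    lo, hi = arr.min(axis=0), arr.max(axis=0)
    assert (W >= lo - 1e-9).all() and (W <= hi + 1e-9).all(), \
        "codebook escaped the data bounding box"

    codebook = pd.DataFrame(W, index=range(1, k + 1), columns=feature_ids)
    qe = float(cdist(arr, W).min(axis=1).mean())
    return NGModel(codebook=codebook, config=config, quantization_error=qe,
                   initial_quantization_error=initial_qe,
                   n_presentations=t_max)


def assign_bmu(model: NGModel, X) -> BMUAssignment:
    """Map each sample to its nearest codebook unit (ties -> lowest index)."""
    arr, sample_ids, feature_ids = _as_array(X)
    if arr.shape[1] != model.codebook.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: data has {arr.shape[1]}, "
            f"codebook has {model.codebook.shape[1]}")
    d = cdist(arr, model.codebook.to_numpy())
    win = d.argmin(axis=1) + 1  # argmin takes the first (lowest) on ties
    labels = pd.Series(win, index=sample_ids, name="unit")
    return BMUAssignment(labels=labels, k_units=model.k_units)


def quantization_error(model: NGModel, X) -> float:
    """Mean distance from each sample to its nearest codebook unit."""
    arr, _, _ = _as_array(X)
    return float(cdist(arr, model.codebook.to_numpy()).min(axis=1).mean())


def relabel_units(model: NGModel,
                  assignment: BMUAssignment) -> tuple[NGModel, BMUAssignment]:
    """Renumber units by decreasing membership (ties keep original order)."""
    sizes = assignment.sizes
    # sort by (-size, original index); stable by construction
    new_order = sorted(sizes.index, key=lambda u: (-sizes[u], u))
    old_to_new = {old: new + 1 for new, old in enumerate(new_order)}
    codebook = model.codebook.loc[new_order].copy()
    codebook.index = range(1, model.k_units + 1)
    new_model = replace(model, codebook=codebook)
    new_labels = assignment.labels.map(old_to_new)
    return new_model, BMUAssignment(labels=new_labels, k_units=model.k_units)


# field-style aliases: a unit plus its mapped samples is one "BMU"
assign_best_matching_units = assign_bmu
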