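"""Complexity, power and attention-entropy accounting for edge deployment.

FLOP counts use the multiply-accumulate convention
``FLOPs_conv = 2 n k C_in C_out`` (n = output spatial length) and
``FLOPs_dense = 2 N_in N_out``; attention bottleneck MLPs are counted as
dense layers, once per pooling path.  Auxiliary operations (batch norm,
activations, attention pooling, ~5% extra) are excluded.  Model size
assumes 32-bit parameters and decimal megabytes.

Power uses a linear idle-to-max interpolation against CPU utilization;
battery life is capacity over power.  Attention entropy is the Shannon
entropy of the normalized attention weight vector divided by log C, so
1 means uniform attention and 0 a one-hot concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ArchitectureSpec, CANONICAL_SPEC, Network, build_network

BYTES_PER_PARAM_FP32 = 4


@dataclass(frozen=True)
class PowerModel:
    """Linear power model of a small single-board computer.

    Defaults are the published idle (2.7 W) and full-load (6.4 W) draw
    of a Raspberry Pi 4B.
    """

    p_idle_w: float = 2.7
    p_max_w: float = 6.4
    utilization: float = 0.0

    def __post_init__(self) -> None:
        if self.p_idle_w > self.p_max_w:
            raise ValueError("idle power must not exceed max power")
        if not 0.0 <= self.utilization <= 1.0:
            raise ValueError("utilization must lie in [0, 1]")


@dataclass
class ComplexityReport:
    """Per-layer parameter/FLOP table plus totals."""

    rows: list  # (name, params, flops)
    total_params: int
    total_flops: int
    flops_by_kind: dict[str, int]
    param_bytes: int

    @property
    def param_megabytes(self) -> float:
        return self.param_bytes / 1e6


@dataclass(frozen=True)
class EntropyReport:
    """Normalized Shannon entropy of an attention map and its mean raw weight."""

    normalized_entropy: float
    mean_weight: float


def _row_flops(meta: dict) -> int:
    kind = meta.get("kind")
    if kind == "conv":
        return 2 * meta["n"] * meta["k"] * meta["c_in"] * meta["c_out"]
    if kind == "dense":
        return 2 * meta["n_in"] * meta["n_out"]
    if kind == "attention":
        c, r = meta["c"], meta["r"]
        per_path = 2 * c * (c // r) + 2 * (c // r) * c
        return 2 * per_path  # average- and max-pool paths
    return 0


def estimate_flops(spec: ArchitectureSpec = CANONICAL_SPEC,
                   network: "Network | None" = None) -> ComplexityReport:
    """Layer-by-layer FLOP and parameter accounting.

    The parameter column is taken from the model's own layer table (a
    single source of truth shared with the architecture audit).
    """
    net = network if network is not None else build_network(spec)
    rows = []
    by_kind: dict[str, int] = {}
    total_flops = 0
    for row in net.layer_table():
        fl = _row_flops(row.meta)
        kind = row.meta.get("kind", "other")
        by_kind[kind] = by_kind.get(kind, 0) + fl
        total_flops += fl
        rows.append((row.name, row.params, fl))
    total_params = net.num_params()
    return ComplexityReport(
        rows=rows,
        total_params=total_params,
        total_flops=total_flops,
        flops_by_kind=by_kind,
        param_bytes=model_bytes(total_params),
    )


def model_bytes(param_count: int, bytes_per_param: int = BYTES_PER_PARAM_FP32) -> int:
    """Parameter storage in bytes (FP32 by default)."""
    if param_count < 0:
        raise ValueError("parameter count must be non-negative")
    return int(param_count) * bytes_per_param


def estimate_power(power_model: PowerModel) -> float:
    """Inference power draw in W: idle + (max-idle) x utilization, 1-decimal."""
    p = power_model.p_idle_w + (power_model.p_max_w - power_model.p_idle_w) * power_model.utilization
    return round(p, 1)


def battery_hours(capacity_wh: float, power_w: float) -> float:
    """Continuous runtime in hours from a battery of ``capacity_wh``."""
    if power_w <= 0:
        raise ValueError("power must be positive")
    if capacity_wh < 0:
        raise ValueError("capacity must be non-negative")
    return capacity_wh / power_w


def attention_entropy(attention_map: np.ndarray) -> EntropyReport:
    """Normalized entropy of one attention weight vector.

    Weights are normalized to a distribution; Shannon entropy (natural
    log) is divided by log(C).  The mean of the raw, pre-normalization
    weights is reported alongside.
    """
    w = np.asarray(attention_map, dtype=float).ravel()
    if w.size < 2:
        raise ValueError("need at least two attention weights")
    if (w < 0).any():
        raise ValueError("attention weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("attention map is all zeros")
    p = w / total
    nz = p > 0
    h = float(-(p[nz] * np.log(p[nz])).sum())
    return EntropyReport(
        normalized_entropy=h / np.log(w.size),
        mean_weight=float(w.mean()),
    )
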