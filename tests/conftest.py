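"""Shared fixtures: toy expression sets and small simulated benchmarks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from qpcrbench import (
    ExpressionSet,
    NoiseConfig,
    default_design,
    estimate_expression,
    expression_set_from_truth,
    generate_truth,
    simulate_benchmark,
)
from qpcrbench.simulate import TruthConfig


def make_expression_set(
    expression: dict[str, list[float]],
    quality: dict[str, list[float]] | None = None,
    features: list[str] | None = None,
    method_name: str = "toy",
    quality_threshold_default: float = 0.99,
) -> ExpressionSet:
    """Build an ExpressionSet from per-sample columns; quality defaults to 1."""
    expr = pd.DataFrame(expression, dtype=float)
    if features is None:
        features = [f"feat{i + 1}" for i in range(len(expr))]
    expr.index = features
    if quality is None:
        qual = pd.DataFrame(1.0, index=expr.index, columns=expr.columns)
    else:
        qual = pd.DataFrame(quality, dtype=float)
        qual.index = features
    return ExpressionSet(
        method_name=method_name,
        expression=expr,
        quality=qual,
        quality_threshold_default=quality_threshold_default,
    )


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def noisefree_sim():
    """Small noise-free benchmark simulation (60 features, full design)."""
    truth = generate_truth(60, seed=11)
    dataset, sample_table = simulate_benchmark(truth, noise=NoiseConfig.noiseless(seed=12))
    return truth, dataset, sample_table


@pytest.fixture(scope="session")
def noisefree_b4(noisefree_sim):
    """b4 estimates fitted to the noise-free simulation (matching family)."""
    _, dataset, _ = noisefree_sim
    return estimate_expression(dataset, "b4")


@pytest.fixture(scope="session")
def noisy_truth_es():
    """Truth-derived estimates with replicate jitter only (no curve fitting)."""
    truth = generate_truth(500, seed=21)
    _, sample_table = simulate_benchmark(
        truth,
        noise=NoiseConfig(
            ct_noise_sd=0.25,
            fluor_noise_sd=0.0,
            failure_rate=0.0,
            dropout_expression_midpoint=None,
            seed=22,
        ),
    )
    return expression_set_from_truth(sample_table)
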