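"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-implementations (per-pair loops,
exhaustive enumeration) used to check the vectorized library code; they
must stay independent of the code paths they verify.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from taphospace.matrix import CharacterMatrix, UnitRecord
from taphospace.staging import FrameworkConfig, simulate_framework


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def gower_oracle(states: np.ndarray, weights=None) -> np.ndarray:
    """Naive per-pair, per-character Gower loop (NaN = unknown)."""
    n, p = states.shape
    w = np.ones(p) if weights is None else np.asarray(weights, dtype=float)
    D = np.full((n, n), np.nan)
    for i in range(n):
        D[i, i] = 0.0
        for j in range(i + 1, n):
            num = den = 0.0
            for c in range(p):
                a, b = states[i, c], states[j, c]
                if math.isnan(a) or math.isnan(b):
                    continue
                num += w[c] * abs(a - b)
                den += w[c]
            if den > 0:
                D[i, j] = D[j, i] = num / den
    return D


def comparable_counts_oracle(states: np.ndarray) -> np.ndarray:
    n, p = states.shape
    C = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(n):
            C[i, j] = sum(
                1
                for c in range(p)
                if not math.isnan(states[i, c]) and not math.isnan(states[j, c])
            )
    return C


def isotonic_oracle(y: np.ndarray) -> np.ndarray:
    """Exact monotone least squares by enumerating contiguous level-set
    partitions (the optimum is piecewise-constant on blocks with
    non-decreasing means)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    best, best_sse = None, np.inf
    for cuts in itertools.product([0, 1], repeat=n - 1):
        blocks, start = [], 0
        for i, c in enumerate(cuts, start=1):
            if c:
                blocks.append((start, i))
                start = i
        blocks.append((start, n))
        means = [y[a:b].mean() for a, b in blocks]
        if any(m2 < m1 for m1, m2 in zip(means, means[1:])):
            continue
        fit = np.concatenate([np.full(b - a, m) for (a, b), m in zip(blocks, means)])
        sse = float(np.sum((y - fit) ** 2))
        if sse < best_sse - 1e-15:
            best, best_sse = fit, sse
    return best


def random_unknown_matrix(
    rng: np.random.Generator, n_units: int, n_chars: int, p_unknown: float = 0.2
) -> CharacterMatrix:
    states = rng.integers(0, 2, size=(n_units, n_chars)).astype(float)
    states[rng.random(states.shape) < p_unknown] = np.nan
    units = [UnitRecord(unit_id=f"u{i}", taxon=f"t{i}") for i in range(n_units)]
    return CharacterMatrix(
        characters=[f"c{j}" for j in range(n_chars)], units=units, states=states
    )


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def default_framework():
    """The default simulated framework: 4 taxa, 71 characters, 6 decay
    stages, resistant-last retention, seed 1."""
    return simulate_framework(FrameworkConfig(seed=1))


@pytest.fixture(scope="session")
def table1_framework():
    from taphospace.staging import table1_config

    return simulate_framework(table1_config(seed=1))


@pytest.fixture
def tiny_matrix():
    """Three units, four characters, one unknown."""
    states = np.array(
        [
            [1.0, 0.0, 1.0, 0.0],
            [0.0, 0.0, 1.0, 0.0],
            [1.0, np.nan, 0.0, 1.0],
        ]
    )
    units = [
        UnitRecord("a", taxon="A", unit_class="semaphoront", ontogenetic_rank=0, decay_stage=0),
        UnitRecord("b", taxon="B", unit_class="semataphont", decay_stage=1),
        UnitRecord("c", taxon="C", unit_class="fossil_specimen"),
    ]
    return CharacterMatrix(characters=["c1", "c2", "c3", "c4"], units=units, states=states)
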