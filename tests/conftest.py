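import numpy as np
import pytest

from gaitspace import (
    AssembledMatrix,
    EffectComponent,
    SyntheticConfig,
    assemble_matrix,
    generate,
    whiten,
)

# Simulation scale used for cross-validated checks throughout the suite:
# the study's 11 subjects are kept (so subject-level binomial thresholds
# match), with fewer trials/markers/timepoints for speed.
REDUCED = dict(subjects=11, trials_per_condition=8, markers=4, timepoints=31)


def reduced_config(seed: int = 1, **overrides) -> SyntheticConfig:
    kw = dict(REDUCED)
    kw.update(overrides)
    return SyntheticConfig(seed=seed, **kw)


def planted_whitened(seed: int = 1, **overrides):
    """Whitened reduced-scale matrix with the default planted effect + truth."""
    trials, truth = generate(reduced_config(seed, **overrides))
    return whiten(assemble_matrix(trials)), truth


def null_whitened(seed: int = 0, **overrides):
    """Whitened reduced-scale matrix with no condition effect."""
    trials, _ = generate(reduced_config(seed, effects=(), **overrides))
    return whiten(assemble_matrix(trials))


@pytest.fixture(scope="session")
def planted():
    """One planted-effect whitened matrix shared across read-only tests."""
    return planted_whitened(seed=1)


@pytest.fixture(scope="session")
def tiny_planted():
    """Very small planted set for reconstruction arithmetic."""
    trials, truth = generate(
        SyntheticConfig(
            subjects=3,
            trials_per_condition=3,
            markers=3,
            timepoints=21,
            effect_snr=6.0,
            seed=7,
        )
    )
    return whiten(assemble_matrix(trials)), truth


def _point_segment_nearest(p, s1, s2):
    d = s2 - s1
    denom = float(d @ d)
    t = 0.0 if denom == 0.0 else float(np.clip((p - s1) @ d / denom, 0.0, 1.0))
    q = s1 + t * d
    return q, float(np.linalg.norm(p - q))


def hard_margin_oracle(A: np.ndarray, B: np.ndarray):
    """Exact maximum-margin oracle for 2-D separable sets, by enumeration.

    The nearest pair of points between two convex hulls in the plane is
    attained at a (vertex, edge-or-vertex) pair, so exhaustively checking
    every point of one set against every segment of the other (and vice
    versa) yields the exact hull-to-hull distance; the optimal separating
    direction is the connecting vector and the margin width its length.
    """
    best = (np.inf, None, None)
    for P, Q in ((A, B), (B, A)):
        for p in P:
            for i in range(len(Q)):
                for j in range(i, len(Q)):
                    q, dist = _point_segment_nearest(p, Q[i], Q[j])
                    if dist < best[0]:
                        best = (dist, p, q)
    dist, p, q = best
    gap = p - q
    return gap / np.linalg.norm(gap), dist
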