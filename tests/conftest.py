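"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive model quantities by brute force
(outcome-tree enumeration, dense grid search) so the analytical code paths
are checked against something that cannot share their mistakes.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest


def enumerate_female_distribution(d: float, e: float) -> tuple[float, float, float]:
    """Brute-force (P2, P1, P0) by enumerating the escape/detection tree.

    Outcomes: Xi escapes or not (e / 1-e); each transcribing allele (the Xa
    always, the Xi if escaped) detected or not (d / 1-d).
    """
    probs = [0.0, 0.0, 0.0]
    for esc in (0, 1):
        p_esc = e if esc else 1.0 - e
        alleles = 1 + esc  # Xa always transcribes; Xi only if escaped
        for detected in itertools.product((0, 1), repeat=alleles):
            p_det = 1.0
            for hit in detected:
                p_det *= d if hit else 1.0 - d
            probs[2 - sum(detected)] += p_esc * p_det
    p0, p1, p2 = probs[2], probs[1], probs[0]
    return p2, p1, p0


def grid_search_escape(
    n2: int, n1: int, n0: int, d: float, step: float = 1e-4
) -> float:
    """Dense grid-search MLE of the escape probability (independent oracle)."""
    grid = np.arange(0.0, 1.0 + step / 2, step)
    p2 = e_grid = grid
    p2 = grid * d * d
    p1 = grid * 2 * d * (1 - d) + (1 - grid) * d
    p0 = 1.0 - p2 - p1
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            n2 * np.log(np.maximum(p2, 1e-300))
            + n1 * np.log(np.maximum(p1, 1e-300))
            + n0 * np.log(np.maximum(p0, 1e-300))
        )
    return float(grid[int(np.argmax(ll))])


def enumerate_pair_conditional(e_a: float, e_b: float) -> float:
    """P(both escape | >= 1 escapes) by enumerating the four escape outcomes."""
    outcomes = {}
    for ea, eb in itertools.product((0, 1), repeat=2):
        p = (e_a if ea else 1 - e_a) * (e_b if eb else 1 - e_b)
        outcomes[(ea, eb)] = p
    conditioned = {k: v for k, v in outcomes.items() if any(k)}
    total = sum(conditioned.values())
    return conditioned[(1, 1)] / total


@pytest.fixture(scope="session")
def fixture_report():
    """The full fixture-replay report, computed once per session."""
    from xescape.pipeline import RunConfig, reproduce_fixtures

    return reproduce_fixtures(RunConfig(seed=1))
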