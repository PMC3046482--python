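"""Generative model of the stochastic-escape RNA-FISH experiment.

Female nuclei carry one X that always transcribes an expressed locus (the
active X) and one inactive X whose allele transcribes with a locus-specific
escape probability ``e``. Each transcribing allele yields a visible signal
independently with detection probability ``d``; each of the two autosomal
control alleles is detected with ``control_detection``. Male nuclei carry a
single X whose allele always transcribes. Zero-signal "shielded" nuclei
emerge from control/test dropout; there is no separate shielding parameter.

Two-locus runs couple the escape events of the pair with a single mixture
parameter rho: with probability rho one shared uniform draw thresholds both
escape probabilities (comonotone, i.e. maximally coordinated), otherwise the
draws are independent. Marginal escape rates are invariant to rho.

All generators are deterministic given their seed; given the same seed the
emitted tables are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .detection import expected_female_distribution
from .locus_model import NucleusScore, PairNucleusScore, Sex

__all__ = [
    "LocusSim",
    "SimConfig",
    "simulate_single_locus",
    "simulate_pair",
    "simulate_counts",
    "simulate_pair_conditioned",
    "pair_category_probs",
    "simulate_qpcr",
]


@dataclass(frozen=True)
class LocusSim:
    """Ground-truth parameters for one simulated locus."""

    locus_id: str
    escape_prob: float
    detection_prob: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.escape_prob <= 1.0):
            raise ValueError(f"{self.locus_id}: escape_prob outside [0, 1]")
        if not (0.0 < self.detection_prob <= 1.0):
            raise ValueError(f"{self.locus_id}: detection_prob outside (0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Scenario for a scored-nucleus simulation run."""

    loci: tuple[LocusSim, ...]
    n_nuclei: int
    sex: Sex = Sex.FEMALE
    control_detection: float = 0.97
    coordination: float = 0.0
    seed: int = 0
    individual_id: str = "sim1"

    def __post_init__(self) -> None:
        if self.n_nuclei <= 0:
            raise ValueError("n_nuclei must be positive")
        if not (0.0 < self.control_detection <= 1.0):
            raise ValueError("control_detection outside (0, 1]")
        if not (0.0 <= self.coordination <= 1.0):
            raise ValueError("coordination rho outside [0, 1]")
        if len(self.loci) == 0:
            raise ValueError("at least one locus required")


def _detect(rng: np.random.Generator, transcribing, d: float) -> np.ndarray:
    """Per-allele detection: Bernoulli(d) where the allele transcribes."""
    transcribing = np.asarray(transcribing, dtype=bool)
    return np.where(transcribing, rng.random(transcribing.shape) < d, False)


def simulate_single_locus(cfg: SimConfig) -> list[NucleusScore]:
    """Simulate scored nuclei for each configured locus, one probe at a time.

    Females: active-X allele transcribes always, inactive-X allele with
    probability ``e``; males: the single X allele transcribes always. Each
    transcribing allele is detected with probability ``d``; two control
    alleles each with ``control_detection``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_nuclei
    out: list[NucleusScore] = []
    for locus in cfg.loci:
        if cfg.sex is Sex.FEMALE:
            xa = np.ones(n, dtype=bool)
            xi = rng.random(n) < locus.escape_prob
            test = (
                _detect(rng, xa, locus.detection_prob).astype(int)
                + _detect(rng, xi, locus.detection_prob).astype(int)
            )
        else:
            test = _detect(rng, np.ones(n, dtype=bool), locus.detection_prob).astype(int)
        control = rng.binomial(2, cfg.control_detection, size=n)
        for i in range(n):
            out.append(
                NucleusScore(
                    nucleus_id=i,
                    individual_id=cfg.individual_id,
                    sex=cfg.sex,
                    locus_id=locus.locus_id,
                    test_signals=int(test[i]),
                    control_signals=int(control[i]),
                )
            )
    return out


def simulate_pair(cfg: SimConfig) -> list[PairNucleusScore]:
    """Simulate a two-color two-locus experiment with escape coupling ``rho``.

    Escape events (E_A, E_B) are Bernoulli(e_A), Bernoulli(e_B): with
    probability ``rho`` a shared uniform draw thresholds both (comonotone
    coupling), otherwise independent draws. Detection is per locus per
    transcribing allele as in :func:`simulate_single_locus`. Only female
    nuclei have a second (inactive) X; male pairs always co-locate trivially.
    """
    if len(cfg.loci) != 2:
        raise ValueError("simulate_pair requires exactly two configured loci")
    if cfg.sex is not Sex.FEMALE:
        raise ValueError("two-locus escape simulation is defined for females")
    a, b = cfg.loci
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_nuclei
    shared = rng.random(n) < cfg.coordination
    u_common = rng.random(n)
    u_a = rng.random(n)
    u_b = rng.random(n)
    esc_a = np.where(shared, u_common < a.escape_prob, u_a < a.escape_prob)
    esc_b = np.where(shared, u_common < b.escape_prob, u_b < b.escape_prob)
    ones = np.ones(n, dtype=bool)
    sig_a = (
        _detect(rng, ones, a.detection_prob).astype(int)
        + _detect(rng, esc_a, a.detection_prob).astype(int)
    )
    sig_b = (
        _detect(rng, ones, b.detection_prob).astype(int)
        + _detect(rng, esc_b, b.detection_prob).astype(int)
    )
    return [
        PairNucleusScore(
            nucleus_id=i,
            individual_id=cfg.individual_id,
            sex=cfg.sex,
            locus_a_signals=int(sig_a[i]),
            locus_b_signals=int(sig_b[i]),
        )
        for i in range(n)
    ]


def simulate_counts(
    e: float, d: float, n: int, rng: np.random.Generator | int
) -> tuple[int, int, int]:
    """Draw female (n2, n1, n0) counts directly from the signal distribution.

    Distributionally identical to tallying :func:`simulate_single_locus`
    output for diploid nuclei; used for replicated calibration studies where
    per-nucleus records are not needed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    probs = expected_female_distribution(d, e)
    n2, n1, n0 = rng.multinomial(n, probs)
    return int(n2), int(n1), int(n0)


def pair_category_probs(
    e_a: float, e_b: float, rho: float
) -> tuple[float, float, float]:
    """(a_only, b_only, both) probabilities among conditioned nuclei, d = 1.

    Under the mixture coupling P(both) = rho * min(e_a, e_b) +
    (1 - rho) * e_a * e_b; conditioning is on at least one locus escaping.
    """
    p_both = rho * min(e_a, e_b) + (1.0 - rho) * e_a * e_b
    p_a_only = e_a - p_both
    p_b_only = e_b - p_both
    union = p_a_only + p_b_only + p_both
    if union <= 0:
        raise ValueError("degenerate pair: no nucleus can escape at either locus")
    return p_a_only / union, p_b_only / union, p_both / union


def simulate_pair_conditioned(
    e_a: float,
    e_b: float,
    rho: float,
    n_conditioned: int,
    rng: np.random.Generator | int,
) -> tuple[int, int, int]:
    """Draw (a_only, b_only, both) counts for ``n_conditioned`` scored nuclei.

    Emulates the published scoring design, which fixes the number of nuclei
    with at least one escaping locus (perfect detection assumed).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    probs = pair_category_probs(e_a, e_b, rho)
    a_only, b_only, both = rng.multinomial(n_conditioned, probs)
    return int(a_only), int(b_only), int(both)


def simulate_qpcr(
    genes: Sequence[tuple[str, float]],
    n_f: int = 6,
    n_m: int = 5,
    noise_sd: float = 0.1,
    seed: int = 0,
    n_replicates: int = 3,
    ct_reference: float = 20.0,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Synthetic qPCR Ct table for X-borne genes with known escape probability.

    Relative expression (vs an autosomal reference) is 1 for males and
    ``1 + e`` for females — one always-active allele plus an inactive-X
    allele transcribing in a fraction ``e`` of cells. Test-gene Ct values are
    ``ct_reference - log_eff(expression) + Normal(0, noise_sd)`` per
    replicate; the reference-gene Ct is fixed.

    Returns a DataFrame with columns
    ``gene individual_id sex replicate ct_test ct_reference``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("amplification efficiency outside (1, 2]")
    rng = np.random.default_rng(seed)
    rows = []
    samples = [("F", i, Sex.FEMALE) for i in range(n_f)] + [
        ("M", i, Sex.MALE) for i in range(n_m)
    ]
    for gene, e in genes:
        if not (0.0 <= e <= 1.0):
            raise ValueError(f"{gene}: escape probability outside [0, 1]")
        for prefix, i, sex in samples:
            expr = 1.0 + e if sex is Sex.FEMALE else 1.0
            for rep in range(1, n_replicates + 1):
                delta = -np.log(expr) / np.log(efficiency) + rng.normal(0.0, noise_sd)
                rows.append(
                    (gene, f"{prefix}{i + 1}", sex.value, rep,
                     round(ct_reference + delta, 6), ct_reference)
                )
    return pd.DataFrame(
        rows,
        columns=["gene", "individual_id", "sex", "replicate", "ct_test", "ct_reference"],
    )
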