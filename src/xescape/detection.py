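"""Probe detection efficiency from male cells and expected signal distributions.

A male fibroblast carries a single X, so its one transcribing allele either
yields a signal (probability ``d``, the hybridization detection efficiency)
or not. The fraction of diploid male nuclei with one test signal therefore
estimates ``d`` directly. In females the two alleles are detected
independently, so for a fully escaping locus the 2/1/0-signal probabilities
follow the binomial expansion p^2 + 2pq + q^2 with p = d, q = 1 - d; the
escape model generalizes this with the Xi allele transcribing only with
probability ``e``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .locus_model import CountSummary

__all__ = [
    "DetectionEstimate",
    "FitResult",
    "estimate_detection",
    "expected_female_distribution",
    "chi2_fit",
    "NOT_EXPRESSED_THRESHOLD",
]

# loci with essentially no male signal are treated as not expressed in
# fibroblasts and excluded downstream; the margin above exactly 0 guards
# simulated edge cases
NOT_EXPRESSED_THRESHOLD = 0.05


@dataclass(frozen=True)
class DetectionEstimate:
    """Per-locus detection efficiency with a Wilson 95% interval."""

    locus_id: str
    d_hat: float
    n: int
    ci_low: float
    ci_high: float
    expressed: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.d_hat <= self.ci_high <= 1.0):
            raise ValueError(
                f"{self.locus_id}: interval ({self.ci_low}, {self.ci_high}) "
                f"does not bracket d_hat={self.d_hat}"
            )


@dataclass(frozen=True)
class FitResult:
    """Pearson goodness-of-fit of observed 2/1/0 counts to an expected triple."""

    chi2_stat: float
    df: int
    p_value: float
    expected: tuple[float, float, float]


def estimate_detection(male_summary: CountSummary) -> DetectionEstimate:
    """Estimate detection efficiency ``d`` from diploid-filtered male counts.

    ``d_hat`` is the one-signal fraction. Two-signal male nuclei are
    biologically unexpected for an X-borne probe (single X) and raise a
    warning, not an error. Loci with ``d_hat`` below
    :data:`NOT_EXPRESSED_THRESHOLD` are flagged ``expressed=False``.
    """
    if male_summary.n_scored < 1:
        raise ValueError(f"{male_summary.locus_id}: no scored male nuclei")
    if male_summary.n2 > 0:
        warnings.warn(
            f"{male_summary.locus_id}: {male_summary.n2} male nucleus(ei) with "
            "two test signals (possible polyploidy or cross-hybridization)",
            stacklevel=2,
        )
    d_hat = male_summary.n1 / male_summary.n_scored
    lo, hi = proportion_confint(
        male_summary.n1, male_summary.n_scored, alpha=0.05, method="wilson"
    )
    # Wilson bounds always bracket the point estimate; clip float fuzz
    lo = min(float(lo), d_hat)
    hi = max(float(hi), d_hat)
    return DetectionEstimate(
        locus_id=male_summary.locus_id,
        d_hat=d_hat,
        n=male_summary.n_scored,
        ci_low=lo,
        ci_high=hi,
        expressed=d_hat >= NOT_EXPRESSED_THRESHOLD,
    )


def expected_female_distribution(d: float, e: float) -> tuple[float, float, float]:
    """Probabilities of (2, 1, 0) signals in a female nucleus.

    The active-X allele transcribes always; the inactive-X allele transcribes
    with escape probability ``e``; each transcribing allele is detected
    independently with probability ``d``:

        P2 = e d^2
        P1 = e 2d(1-d) + (1-e) d
        P0 = e (1-d)^2 + (1-e)(1-d)

    At ``e = 1`` this reduces to the binomial expansion (p^2, 2pq, q^2) with
    p = d. The triple sums to 1 exactly.
    """
    if not (0.0 < d <= 1.0):
        raise ValueError(f"detection probability d={d} outside (0, 1]")
    if not (0.0 <= e <= 1.0):
        raise ValueError(f"escape probability e={e} outside [0, 1]")
    p2 = e * d * d
    p1 = e * 2.0 * d * (1.0 - d) + (1.0 - e) * d
    p0 = 1.0 - p2 - p1
    return p2, p1, p0


def chi2_fit(
    observed: CountSummary, expected: tuple[float, float, float]
) -> FitResult:
    """Pearson chi-square of observed (n2, n1, n0) against expected probabilities.

    The degrees of freedom are fixed at 2 (three cells, fully specified
    expectation; when ``d`` is plugged in from an independent male sample no
    parameter is fitted to these counts).
    """
    probs = np.asarray(expected, dtype=float)
    if not np.isclose(probs.sum(), 1.0, atol=1e-8):
        raise ValueError(f"expected probabilities sum to {probs.sum()}, not 1")
    if observed.n_scored < 1:
        raise ValueError(f"{observed.locus_id}: empty summary")
    obs = np.array([observed.n2, observed.n1, observed.n0], dtype=float)
    exp = probs * observed.n_scored
    if (exp < 1.0).any():
        warnings.warn(
            f"{observed.locus_id}: expected count below 1 "
            f"({exp.round(3).tolist()}); consider an exact/simulated p-value",
            stacklevel=2,
        )
    if ((exp == 0) & (obs > 0)).any():
        stat = float("inf")
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0)
        stat = float(terms.sum())
    df = 2
    return FitResult(
        chi2_stat=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        expected=tuple(exp),
    )
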