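"""Two-locus coordination analysis of escape from X inactivation.

If escape were coordinated across a chromatin domain, two neighboring loci
would escape together: nuclei with signal on the inactive X at one locus
would usually show it at the other too. Under independent escape, concordant
nuclei are rare (probability ~ e_a * e_b). Scoring conditions on nuclei where
at least one locus shows two signals, so both the unconditional product scale
(the scale printed alongside the published tables) and the coherent
conditional scale are reported, together with an exact binomial test of the
observed concordant count.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from scipy import stats

from .locus_model import PairNucleusScore

__all__ = [
    "PairTable",
    "PairResult",
    "Verdict",
    "classify_pair",
    "expected_concordance",
    "test_independence",
]


class Verdict(str, Enum):
    INDEPENDENT = "independent-compatible"
    COORDINATE = "coordinate-compatible"
    NEITHER = "neither"


@dataclass(frozen=True)
class PairTable:
    """Xi-escape categories among nuclei with >= 1 escaping locus.

    ``e_a``/``e_b`` are the per-locus escape frequencies used for model
    expectations (from single-locus runs, or the pair margins).
    """

    locus_a: str
    locus_b: str
    n_conditioned: int
    a_only: int
    b_only: int
    both: int
    e_a: float | None = None
    e_b: float | None = None

    def __post_init__(self) -> None:
        if self.a_only + self.b_only + self.both != self.n_conditioned:
            raise ValueError(
                f"{self.locus_a}/{self.locus_b}: categories "
                f"{self.a_only}+{self.b_only}+{self.both} != {self.n_conditioned}"
            )

    @property
    def discordant(self) -> int:
        return self.a_only + self.b_only


@dataclass(frozen=True)
class PairResult:
    """Independence test and model expectations for one locus pair."""

    locus_a: str
    locus_b: str
    expected_independent_unconditional: float
    expected_independent_conditional: float | None
    expected_coordinate: float
    observed_both_fraction: float
    p_value: float | None
    verdict: Verdict
    note: str = ""


def classify_pair(
    scores: Sequence[PairNucleusScore],
    locus_a: str = "A",
    locus_b: str = "B",
) -> PairTable:
    """Categorize nuclei by which loci show two signals (escape on the Xi).

    A nucleus enters the table iff at least one locus shows two signals:
    ``both`` (2, 2), ``a_only`` (2, <2), ``b_only`` (<2, 2). Margins over the
    full input provide default escape-frequency estimates ``e_a``, ``e_b``.
    """
    a_only = b_only = both = 0
    a2_total = b2_total = 0
    for s in scores:
        a2 = s.locus_a_signals == 2
        b2 = s.locus_b_signals == 2
        a2_total += a2
        b2_total += b2
        if a2 and b2:
            both += 1
        elif a2:
            a_only += 1
        elif b2:
            b_only += 1
    n_total = len(scores)
    return PairTable(
        locus_a=locus_a,
        locus_b=locus_b,
        n_conditioned=a_only + b_only + both,
        a_only=a_only,
        b_only=b_only,
        both=both,
        e_a=a2_total / n_total if n_total else None,
        e_b=b2_total / n_total if n_total else None,
    )


def expected_concordance(
    e_a: float, e_b: float
) -> tuple[float, float | None, float]:
    """Expected concordant-escape fractions under the two hypotheses.

    Returns ``(independent_unconditional, independent_conditional,
    coordinate)``:

    - unconditional: ``e_a * e_b`` — probability a random nucleus escapes at
      both loci under independence (the scale quoted in print);
    - conditional: ``e_a e_b / (e_a + e_b - e_a e_b)`` — probability of
      concordance among nuclei with at least one escaping locus, i.e. on the
      scale the scoring design actually samples (``None`` when both e are 0);
    - coordinate: ``(e_a + e_b) / 2`` — concordant fraction if a single
      domain-level event drove both loci, evaluated at the average frequency.
    """
    for name, e in (("e_a", e_a), ("e_b", e_b)):
        if not (0.0 <= e <= 1.0):
            raise ValueError(f"{name}={e} outside [0, 1]")
    uncond = e_a * e_b
    union = e_a + e_b - uncond
    cond = uncond / union if union > 0 else None
    coord = (e_a + e_b) / 2.0
    return uncond, cond, coord


def test_independence(
    table: PairTable,
    e_a: float | None = None,
    e_b: float | None = None,
    alpha: float = 0.05,
) -> PairResult:
    """Exact binomial test of the concordant count against independent escape.

    The observed ``both`` count is tested two-sided against a binomial with
    the *conditional* independence probability (the design conditions on
    >= 1 escaping locus, so margins are not fixed and a 2x2 chi-square does
    not apply). Verdict ``independent-compatible`` when the test does not
    reject and the observed fraction falls below the coordinate-model
    expectation; ``coordinate-compatible`` when it rejects and the observed
    fraction is closer to the coordinate expectation than to the conditional
    independence one.
    """
    if table.n_conditioned < 1:
        raise ValueError(f"{table.locus_a}/{table.locus_b}: empty pair table")
    e_a = table.e_a if e_a is None else e_a
    e_b = table.e_b if e_b is None else e_b
    if e_a is None or e_b is None:
        raise ValueError("escape frequencies e_a, e_b must be supplied")
    uncond, cond, coord = expected_concordance(e_a, e_b)
    obs = table.both / table.n_conditioned
    if cond is None:
        return PairResult(
            locus_a=table.locus_a,
            locus_b=table.locus_b,
            expected_independent_unconditional=uncond,
            expected_independent_conditional=None,
            expected_coordinate=coord,
            observed_both_fraction=obs,
            p_value=None,
            verdict=Verdict.NEITHER,
            note="conditional independence expectation undefined (e_a = e_b = 0)",
        )
    p = float(
        stats.binomtest(
            table.both, table.n_conditioned, cond, alternative="two-sided"
        ).pvalue
    )
    if p >= alpha and obs < coord:
        verdict = Verdict.INDEPENDENT
    elif p < alpha and abs(obs - coord) < abs(obs - cond):
        verdict = Verdict.COORDINATE
    else:
        verdict = Verdict.NEITHER
    return PairResult(
        locus_a=table.locus_a,
        locus_b=table.locus_b,
        expected_independent_unconditional=uncond,
        expected_independent_conditional=cond,
        expected_coordinate=coord,
        observed_both_fraction=obs,
        p_value=p,
        verdict=verdict,
    )
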