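"""Relative expression and female:male dosage ratios from qPCR Ct tables.

Expression of each test gene is quantified relative to an autosomal
reference (GAPDH by default) by comparative quantification:
``expression = efficiency ** (ct_reference - ct_test)``. The female:male
ratio of mean relative expression measures dosage compensation: 1.0 is
complete compensation, 2.0 is none (both female alleles fully active).
Uncertainty via a seeded bootstrap; significance via a label-permutation
test on the mean log-expression difference, which is distribution-free at
the 5-6 samples per sex typical of these designs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .locus_model import Sex, TableFormatError

__all__ = [
    "QpcrRecord",
    "RatioResult",
    "read_qpcr_table",
    "records_from_frame",
    "relative_expression",
    "collapse_replicates",
    "sex_ratio",
]

QPCR_COLUMNS = ["gene", "individual_id", "sex", "replicate", "ct_test", "ct_reference"]

REPLICATE_OUTLIER_CT = 1.0  # flag replicates > 1 Ct from the replicate median


@dataclass(frozen=True)
class QpcrRecord:
    gene: str
    individual_id: str
    sex: Sex
    replicate: int
    ct_test: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name in ("ct_test", "ct_reference"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{self.gene}/{self.individual_id}: {name}={v}")
        if self.replicate < 1:
            raise ValueError("replicate numbering starts at 1")


@dataclass(frozen=True)
class RatioResult:
    """Female:male relative-expression ratio for one gene."""

    gene: str
    ratio: float
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    n_f: int
    n_m: int


def read_qpcr_table(path: str | Path) -> list[QpcrRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")
    return records_from_frame(df)


def records_from_frame(df: pd.DataFrame) -> list[QpcrRecord]:
    """Typed records from a Ct DataFrame (e.g. the simulator's output)."""
    return [
        QpcrRecord(
            gene=str(r.gene),
            individual_id=str(r.individual_id),
            sex=Sex(str(r.sex)),
            replicate=int(r.replicate),
            ct_test=float(r.ct_test),
            ct_reference=float(r.ct_reference),
        )
        for r in df.itertuples(index=False)
    ]


def relative_expression(record: QpcrRecord, efficiency: float = 2.0) -> float:
    """Expression of the test gene relative to the reference for one well."""
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("amplification efficiency outside (1, 2]")
    return float(efficiency ** (record.ct_reference - record.ct_test))


def collapse_replicates(
    records: Sequence[QpcrRecord], efficiency: float = 2.0
) -> pd.DataFrame:
    """Average replicate wells per (gene, individual) on the linear scale.

    Replicates whose delta-Ct lies more than 1 Ct from the replicate median
    are flagged in the ``n_outliers`` column (kept in the average, reported
    for inspection). Returns columns
    ``gene individual_id sex expression n_replicates n_outliers``.
    """
    rows: dict[tuple[str, str], list[QpcrRecord]] = {}
    for r in records:
        rows.setdefault((r.gene, r.individual_id), []).append(r)
    out = []
    for (gene, ind), group in rows.items():
        dct = np.array([r.ct_test - r.ct_reference for r in group])
        outliers = int(np.sum(np.abs(dct - np.median(dct)) > REPLICATE_OUTLIER_CT))
        expr = float(np.mean([relative_expression(r, efficiency) for r in group]))
        out.append((gene, ind, group[0].sex.value, expr, len(group), outliers))
    return pd.DataFrame(
        out,
        columns=["gene", "individual_id", "sex", "expression",
                 "n_replicates", "n_outliers"],
    )


def sex_ratio(
    expressions: pd.DataFrame,
    gene: str | None = None,
    n_bootstrap: int = 2000,
    n_permutations: int = 9999,
    seed: int = 0,
) -> RatioResult:
    """Female:male ratio of mean relative expression with CI and permutation p.

    ``expressions`` is the output of :func:`collapse_replicates` (one row per
    sample). The ratio is mean(female)/mean(male); the 95% CI is a seeded
    percentile bootstrap over samples within each sex; the p-value is a
    two-sided permutation test on the difference of mean log-expression
    under shuffled sex labels. With fewer than 2 samples in either sex the
    point ratio is reported without CI or p-value.
    """
    df = expressions if gene is None else expressions[expressions["gene"] == gene]
    if gene is None:
        genes = df["gene"].unique()
        if len(genes) != 1:
            raise ValueError(f"expressions table holds {len(genes)} genes; pass gene=")
        gene = str(genes[0])
    fem = df.loc[df["sex"] == Sex.FEMALE.value, "expression"].to_numpy(float)
    mal = df.loc[df["sex"] == Sex.MALE.value, "expression"].to_numpy(float)
    if len(fem) == 0 or len(mal) == 0:
        raise ValueError(f"{gene}: need samples of both sexes")
    ratio = float(fem.mean() / mal.mean())
    if len(fem) < 2 or len(mal) < 2:
        return RatioResult(gene, ratio, None, None, None, len(fem), len(mal))

    rng = np.random.default_rng(seed)
    f_idx = rng.integers(0, len(fem), size=(n_bootstrap, len(fem)))
    m_idx = rng.integers(0, len(mal), size=(n_bootstrap, len(mal)))
    boots = fem[f_idx].mean(axis=1) / mal[m_idx].mean(axis=1)
    ci_low, ci_high = np.quantile(boots, [0.025, 0.975])

    logged = np.log(np.concatenate([fem, mal]))
    n_f = len(fem)
    obs = abs(logged[:n_f].mean() - logged[n_f:].mean())
    perm = np.tile(logged, (n_permutations, 1))
    perm = rng.permuted(perm, axis=1)
    diffs = np.abs(perm[:, :n_f].mean(axis=1) - perm[:, n_f:].mean(axis=1))
    p = (1 + int(np.sum(diffs >= obs - 1e-12))) / (1 + n_permutations)
    return RatioResult(
        gene=gene,
        ratio=ratio,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=float(p),
        n_f=n_f,
        n_m=len(mal),
    )
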