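"""Signed two-sample Kolmogorov-Smirnov ranking of proteins.

Spectral-count data are undersampled and far from normal, so disease-vs-
control differentiality is scored with the non-parametric two-sample KS test:
D is the maximum vertical distance between the two empirical CDFs, and the
direction of the mean shift gives the sign. Each protein is ranked by
``sign * (-log10 p)``, a signed, significance-monotone score, and the whole
list (every quantified protein, not just the significant ones) is the input
to gene-set enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import CountMatrix, InputError

#: Score magnitude cap used when the KS p-value underflows.
SCORE_CAP = 16.0


@dataclass(frozen=True)
class DifferentialScore:
    protein_id: str
    ks_D: float
    p_value: float
    sign: int
    score: float


@dataclass
class RankedList:
    """Strictly ordered protein list, descending by signed score.

    ``table`` is indexed by protein id with columns ks_D, p_value, sign,
    score; rows are already in rank order.
    """

    table: pd.DataFrame

    @property
    def ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.table)

    def reversed(self) -> "RankedList":
        return RankedList(self.table.iloc[::-1])


def signed_ks(
    disease_values, control_values, method: str = "asymp"
) -> tuple[float, float, int]:
    """Two-sample KS D, p-value, and sign of the disease-vs-control shift.

    Returns ``(ks_D, p_value, sign)`` with sign +1 when the disease mean
    exceeds the control mean, -1 when below, 0 when equal. ``method`` is
    passed to :func:`scipy.stats.ks_2samp` ('asymp' default; 'exact'
    available for small samples).
    """
    d = np.asarray(disease_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if d.size < 2 or c.size < 2:
        raise InputError(
            f"signed_ks needs >=2 values per group, got {d.size} and {c.size}"
        )
    res = stats.ks_2samp(d, c, method=method)
    ks_d = float(res.statistic)
    p = float(min(res.pvalue, 1.0))
    diff = d.mean() - c.mean()
    sign = 0 if diff == 0 else (1 if diff > 0 else -1)
    if ks_d == 0.0:
        sign = 0
        p = 1.0
    return ks_d, p, sign


def score_proteins(
    counts: CountMatrix, stage: str, method: str = "asymp"
) -> list[DifferentialScore]:
    """Per-protein signed KS scores for one disease stage."""
    if stage not in counts.stages:
        raise InputError(
            f"unknown stage {stage!r}; available stages: {counts.stages}"
        )
    dis = counts.samples_for(stage, "disease")
    ctl = counts.samples_for(stage, "control")
    if len(dis) < 2 or len(ctl) < 2:
        raise InputError(
            f"stage {stage!r} needs >=2 disease and >=2 control samples "
            f"(found {len(dis)} and {len(ctl)})"
        )
    dvals = counts.values[dis].to_numpy(dtype=float)
    cvals = counts.values[ctl].to_numpy(dtype=float)
    out = []
    for i, pid in enumerate(counts.protein_ids):
        ks_d, p, sign = signed_ks(dvals[i], cvals[i], method=method)
        out.append(DifferentialScore(pid, ks_d, p, sign, _rank_score(p, sign)))
    return out


def _rank_score(p: float, sign: int) -> float:
    if sign == 0:
        return 0.0
    if p <= 0.0:
        return sign * SCORE_CAP
    return float(sign * min(-np.log10(p), SCORE_CAP))


def rank_proteins(
    counts: CountMatrix, stage: str, method: str = "asymp"
) -> RankedList:
    """Rank all proteins of a stage by ``sign * (-log10 p)``, descending.

    Ties are broken by descending |D| then lexicographic protein id, so the
    ordering is strict and reproducible.
    """
    scores = score_proteins(counts, stage, method=method)
    table = pd.DataFrame(
        {
            "ks_D": [s.ks_D for s in scores],
            "p_value": [s.p_value for s in scores],
            "sign": [s.sign for s in scores],
            "score": [s.score for s in scores],
        },
        index=pd.Index([s.protein_id for s in scores], name="protein_id"),
    )
    order = sorted(
        range(len(scores)),
        key=lambda i: (-scores[i].score, -scores[i].ks_D, scores[i].protein_id),
    )
    return RankedList(table.iloc[order])


def summarize_significant(
    scores: list[DifferentialScore], alpha: float = 0.05
) -> tuple[int, int, int]:
    """Count significant proteins and their up/down split.

    Returns ``(n_total, n_up, n_down)`` where n_total counts p < alpha and
    the split is by sign (sign-0 proteins count in the total only).
    """
    if not 0 < alpha < 1:
        raise InputError(f"alpha must be in (0, 1), got {alpha}")
    sig = [s for s in scores if s.p_value < alpha]
    n_up = sum(1 for s in sig if s.sign > 0)
    n_down = sum(1 for s in sig if s.sign < 0)
    return len(sig), n_up, n_down
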