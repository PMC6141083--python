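"""Replicate-level statistics: mean +/- SEM, one-tailed Student t-tests
and the significance tiers used for force-peak and free-energy
comparisons (p < 0.05 significant, 0.05 <= p < 0.10 marginal).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import stats as sps

from .errors import ConfigError, DomainError

__all__ = [
    "ReplicateSet", "ComparisonResult", "mean_sem", "one_tailed_t",
    "classify_p", "summarize_experiment",
]


@dataclass
class ReplicateSet:
    """Labelled replicate measurements (one value per independent run)."""

    label: str
    values: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DomainError("values must be one-dimensional")

    @property
    def n(self) -> int:
        return len(self.values)


def mean_sem(values) -> tuple[float, float]:
    """Arithmetic mean and standard error of the mean (ddof=1)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise DomainError("mean_sem needs at least two values")
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(len(v)))


def one_tailed_t(a: ReplicateSet, b: ReplicateSet,
                 alternative: Literal["a_less", "a_greater"] = "a_less",
                 pooled: bool = True) -> float:
    """One-sided two-sample Student t-test p-value.

    Pooled-variance by default (n = 3 replicates per condition leaves
    little room for variance estimation; ``pooled=False`` switches to
    Welch).  Degenerate zero-variance input follows the documented
    convention: equal means give p = 0.5, unequal means give 0 or 1
    depending on the direction.
    """
    if a.n < 2 or b.n < 2:
        raise DomainError("both groups need at least two replicates")
    if alternative not in ("a_less", "a_greater"):
        raise DomainError(f"unknown alternative {alternative!r}")
    va, vb = a.values, b.values
    if va.std(ddof=1) == 0.0 and vb.std(ddof=1) == 0.0:
        if va.mean() == vb.mean():
            return 0.5
        less = va.mean() < vb.mean()
        return 0.0 if (less == (alternative == "a_less")) else 1.0
    scipy_alt = "less" if alternative == "a_less" else "greater"
    res = sps.ttest_ind(va, vb, equal_var=pooled, alternative=scipy_alt)
    return float(res.pvalue)


def classify_p(p: float) -> str:
    """Significance tier: 'significant' below 0.05, 'marginal' in
    [0.05, 0.10), else 'not_significant'."""
    if not (0.0 <= p <= 1.0):
        raise DomainError(f"p-value {p} outside [0, 1]")
    if p < 0.05:
        return "significant"
    if p < 0.10:
        return "marginal"
    return "not_significant"


@dataclass
class ComparisonResult:
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    p_value: float
    tier: str


@dataclass
class ExperimentReport:
    conditions: dict[str, dict]
    comparisons: list[ComparisonResult]
    reference: str
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "reference": self.reference,
            "conditions": self.conditions,
            "comparisons": [vars(c) for c in self.comparisons],
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return Path(path)

    def to_text(self) -> str:
        lines = [f"reference condition: {self.reference}"]
        for label, st in self.conditions.items():
            lines.append(f"  {label}: {st['mean']:.3f} +/- {st['sem']:.3f}"
                         f" (n={st['n']})")
        for c in self.comparisons:
            lines.append(f"  {c.group_a} vs {c.group_b}: p={c.p_value:.4f}"
                         f" [{c.tier}]")
        return "\n".join(lines)


def summarize_experiment(results: dict[str, "ReplicateSet | list | np.ndarray"],
                         reference: str,
                         alternative: Literal["a_less", "a_greater"] = "a_less",
                         pooled: bool = True,
                         provenance: dict | None = None) -> ExperimentReport:
    """Per-condition mean +/- SEM plus one-tailed comparisons of every
    condition against the reference.

    ``alternative='a_less'`` tests whether each non-reference condition's
    mean is below the reference (the oxidized-weaker-than-wild-type
    reading).
    """
    if reference not in results:
        raise ConfigError(f"reference condition {reference!r} missing")
    sets = {
        label: (v if isinstance(v, ReplicateSet) else ReplicateSet(label, v))
        for label, v in results.items()
    }
    conditions = {}
    for label, rs in sets.items():
        m, s = mean_sem(rs.values)
        conditions[label] = {"mean": m, "sem": s, "n": rs.n, "unit": rs.unit}
    ref = sets[reference]
    comparisons = []
    for label, rs in sets.items():
        if label == reference:
            continue
        p = one_tailed_t(rs, ref, alternative=alternative, pooled=pooled)
        comparisons.append(ComparisonResult(
            group_a=label, group_b=reference,
            mean_a=conditions[label]["mean"], mean_b=conditions[reference]["mean"],
            sem_a=conditions[label]["sem"], sem_b=conditions[reference]["sem"],
            p_value=p, tier=classify_p(p),
        ))
    return ExperimentReport(conditions, comparisons, reference,
                            provenance or {})
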