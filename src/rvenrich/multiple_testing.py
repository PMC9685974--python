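"""Benjamini-Hochberg false-discovery-rate control over association results.

The step-up adjustment is applied over one *family* of testable results.
Two family definitions are supported:

* ``"pooled"`` (default): every testable table across all case-control
  comparisons forms a single family. This is the definition under which
  the packaged study fixture reproduces its published selection counts.
* ``"per_comparison"``: each comparison's testable variants are adjusted
  separately.

Untestable results (variant absent from the case or control cohort of a
comparison) never enter a family and keep their untestable status.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .model import AssociationResult, Status

__all__ = ["bh_adjust", "PValueFamily", "build_families", "annotate_significance"]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, q_(i) monotone).

    ``q_(i) = min_{j >= i} min(1, m * p_(j) / j)`` on the sorted p-values,
    mapped back to input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0.0) | (p > 1.0)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class PValueFamily:
    """One multiple-testing family: a label and its member results."""

    label: str
    members: list[AssociationResult]

    @property
    def pvalues(self) -> list[float]:
        return [r.p_raw for r in self.members]  # type: ignore[misc]


def build_families(
    results: Iterable[AssociationResult], mode: str = "pooled"
) -> list[PValueFamily]:
    """Group testable results into BH families under the chosen definition."""
    testable = [r for r in results if r.testable]
    if any(r.p_raw is None for r in testable):
        raise ValueError("testable result without a raw p-value")
    if mode == "pooled":
        return [PValueFamily("all_comparisons", testable)] if testable else []
    if mode == "per_comparison":
        by_label: dict[str, list[AssociationResult]] = {}
        for r in testable:
            by_label.setdefault(r.comparison.label, []).append(r)
        return [PValueFamily(label, mem) for label, mem in by_label.items()]
    raise ValueError(f"unknown family mode {mode!r}")


def annotate_significance(
    results: Iterable[AssociationResult],
    families: list[PValueFamily] | None = None,
    alpha: float = 0.05,
    family_mode: str = "pooled",
) -> list[AssociationResult]:
    """BH-adjust every family and set each result's significance status.

    Significance uses strict ``p_adjusted < alpha``. Untestable results are
    untouched. Results are modified in place and returned as a list.
    """
    results = list(results)
    if families is None:
        families = build_families(results, mode=family_mode)
    in_family = {id(r) for fam in families for r in fam.members}
    for r in results:
        if r.testable and id(r) not in in_family:
            raise ValueError(
                f"testable result {r.key.label} ({r.comparison}) missing "
                "from every family"
            )
    for fam in families:
        q = bh_adjust(fam.pvalues)
        for r, qi in zip(fam.members, q):
            r.p_adjusted = float(qi)
            r.status = Status.SIGNIFICANT if qi < alpha else Status.NOT_SIGNIFICANT
    return results
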