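"""Cross-cohort p-value integration: harmonic mean, then BH-FDR.

One subgroup's per-cohort panel Wald p-values (x, y, z, ...) are combined
with the plain harmonic mean n / sum(1/p_i) — for two values 2xy/(x+y), for
three 3xyz/(xy+yz+xz) — and the integrated values are then Benjamini-
Hochberg adjusted across the family of subgroups (the four strata of one
cancer analysis by default, m = 4).

An "as-printed" audit variant of the three-value formula with a leading
constant of 2 instead of 3 is selectable; it is not the default because only
the standard form is a mean (idempotent and bounded by its inputs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

STANDARD = "standard"
AS_PRINTED = "as-printed"


class IntegrationError(ValueError):
    pass


@dataclass
class IntegrationResult:
    subgroup: str
    cohort_ps: list[float]
    raw_integrated_p: float
    fdr_adjusted_p: float
    family_size: int

    def to_dict(self) -> dict:
        return {
            "subgroup": self.subgroup,
            "cohort_ps": self.cohort_ps,
            "raw_integrated_p": self.raw_integrated_p,
            "fdr_adjusted_p": self.fdr_adjusted_p,
            "family_size": self.family_size,
        }


def harmonic_mean_p(ps: Sequence[float], variant: str = STANDARD) -> float:
    """Harmonic mean of p-values: n / sum(1/p_i).

    All inputs must lie in (0, 1]. ``variant="as-printed"`` reproduces the
    three-value audit formula 2xyz/(xy+yz+xz) (two-value case is identical).
    """
    ps = [float(p) for p in ps]
    if len(ps) == 0:
        raise IntegrationError("harmonic_mean_p: need at least one p-value")
    for p in ps:
        if not 0.0 < p <= 1.0:
            raise IntegrationError(f"p-value out of (0, 1]: {p!r}")
    hm = len(ps) / sum(1.0 / p for p in ps)
    if variant == STANDARD:
        return hm
    if variant == AS_PRINTED:
        return (2.0 / len(ps)) * hm
    raise IntegrationError(f"unknown harmonic-mean variant {variant!r}")


def bh_fdr(ps: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sorted p(i) become p(i) * m / i with monotonicity enforced from the
    largest rank down and values capped at 1.
    """
    arr = np.asarray(list(ps), dtype=float)
    if arr.size == 0:
        raise IntegrationError("bh_fdr: empty input")
    if np.any((arr < 0) | (arr > 1)) or not np.all(np.isfinite(arr)):
        raise IntegrationError("bh_fdr: p-values must lie in [0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, arr[i] * m / rank)
        adjusted[i] = running
    return [float(q) for q in adjusted]


def integrate_subgroups(
    subgroup_ps: Mapping[str, Sequence[float]],
    variant: str = STANDARD,
) -> list[IntegrationResult]:
    """Harmonic-mean combine each subgroup's per-cohort p-values, then BH
    across the subgroup family (m = number of subgroups).

    Subgroups may carry different cohort counts (e.g., a validation cohort
    lacking one stratum); each is combined over what exists.
    """
    if not subgroup_ps:
        raise IntegrationError("integrate_subgroups: no subgroups")
    names = list(subgroup_ps.keys())
    raw = [harmonic_mean_p(subgroup_ps[name], variant=variant) for name in names]
    adjusted = bh_fdr(raw)
    return [
        IntegrationResult(
            subgroup=name,
            cohort_ps=[float(p) for p in subgroup_ps[name]],
            raw_integrated_p=float(r),
            fdr_adjusted_p=float(a),
            family_size=len(names),
        )
        for name, r, a in zip(names, raw, adjusted)
    ]
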