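"""qRT-PCR relative expression (2^-ΔCt) and two-group comparison.

Relative expression of a target against an internal control (a spiked-in
cel-miR-39 or endogenous U6) is 2^-ΔCt with ΔCt = Ct(target) − Ct(control).
Group comparisons use an unpaired Student's t test for equal variances and
Welch's t test otherwise; the variance-equality choice is caller-supplied or
auto-selected by a two-sided F-ratio test at the 0.05 level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class QpcrMeasurement:
    sample_id: str
    target_ct: float
    control_ct: float
    control_name: str = "cel-miR-39"

    def __post_init__(self) -> None:
        for v in (self.target_ct, self.control_ct):
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"Ct values must be finite and positive, got {v}")


def relative_expression(measurement: QpcrMeasurement) -> float:
    """2^-(Ct_target − Ct_control)."""
    return 2.0 ** -(measurement.target_ct - measurement.control_ct)


def variances_equal(group_a: Sequence[float], group_b: Sequence[float],
                    alpha: float = 0.05) -> bool:
    """Two-sided F-ratio test for equal variances at level alpha."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return True
    hi, lo = max(va, vb), min(va, vb)
    if lo == 0:
        return False
    dfn = (a.size if va >= vb else b.size) - 1
    dfd = (b.size if va >= vb else a.size) - 1
    p = 2 * stats.f.sf(hi / lo, dfn, dfd)
    return min(p, 1.0) >= alpha


def group_compare(
    expressions_a: Sequence[float],
    expressions_b: Sequence[float],
    equal_variance: bool | None = None,
) -> tuple[float, float, float, float]:
    """(mean_a, mean_b, t, two-sided p) for two groups of relative expressions.

    ``equal_variance=None`` auto-selects via :func:`variances_equal`.
    """
    a = np.asarray(expressions_a, float)
    b = np.asarray(expressions_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if equal_variance is None:
        equal_variance = variances_equal(a, b)
    res = stats.ttest_ind(a, b, equal_var=equal_variance)
    t = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(t):  # identical constant groups: no evidence of difference
        t, p = 0.0, 1.0
    return float(a.mean()), float(b.mean()), t, p


def read_qpcr_tsv(path: str | Path) -> dict[str, list[QpcrMeasurement]]:
    """Read ``sample  group  target_ct  control_ct [control_name]`` rows."""
    groups: dict[str, list[QpcrMeasurement]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            m = QpcrMeasurement(
                sample_id=f[idx["sample"]],
                target_ct=float(f[idx["target_ct"]]),
                control_ct=float(f[idx["control_ct"]]),
                control_name=f[idx["control_name"]] if "control_name" in idx else "cel-miR-39",
            )
            groups.setdefault(f[idx["group"]], []).append(m)
    return groups
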