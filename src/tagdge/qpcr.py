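"""Relative qPCR quantification by the Livak 2^-ddCt method.

A target gene's Ct is first normalised to an internal control gene within
the same sample (dCt = Ct_target - Ct_reference), then to a calibrator
sample (ddCt = dCt_sample - dCt_calibrator); relative expression is
2^-ddCt.  Replicate Ct values are averaged arithmetically before
differencing, and the replicate SD is propagated into the dCt SD column
(sqrt of the summed variances), which readers can convert to a fold range.
Perfect doubling per cycle is assumed; no amplification-efficiency
correction is applied.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Sequence

__all__ = ["CtMeasurement", "RelativeExpression", "relative_expression", "quantify_table"]


@dataclass(frozen=True)
class CtMeasurement:
    """Cycle-threshold replicates for one gene in one sample."""

    sample_id: str
    gene: str
    ct_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.ct_values:
            raise ValueError(f"{self.sample_id}/{self.gene}: no Ct replicates")
        for ct in self.ct_values:
            if not (0.0 < ct < 60.0):
                raise ValueError(f"{self.sample_id}/{self.gene}: Ct {ct} outside (0, 60)")

    @property
    def mean(self) -> float:
        return sum(self.ct_values) / len(self.ct_values)

    @property
    def sd(self) -> float:
        if len(self.ct_values) < 2:
            return 0.0
        return statistics.stdev(self.ct_values)


@dataclass(frozen=True)
class RelativeExpression:
    """2^-ddCt output for one (sample, gene) pair."""

    sample_id: str
    gene: str
    delta_ct: float
    delta_delta_ct: float
    fold: float
    delta_ct_sd: float = 0.0


def relative_expression(
    target: CtMeasurement,
    reference: CtMeasurement,
    target_calibrator: CtMeasurement,
    reference_calibrator: CtMeasurement,
) -> RelativeExpression:
    """Fold change of a target gene relative to a calibrator sample.

    dCt = mean Ct(target) - mean Ct(reference) within each sample,
    ddCt = dCt(sample) - dCt(calibrator), fold = 2^-ddCt.  The calibrator
    measured against itself always yields fold exactly 1.
    """
    delta_ct = target.mean - reference.mean
    delta_ct_cal = target_calibrator.mean - reference_calibrator.mean
    ddct = delta_ct - delta_ct_cal
    sd = math.sqrt(target.sd**2 + reference.sd**2)
    return RelativeExpression(
        sample_id=target.sample_id,
        gene=target.gene,
        delta_ct=delta_ct,
        delta_delta_ct=ddct,
        fold=2.0**-ddct,
        delta_ct_sd=sd,
    )


def quantify_table(
    rows: Sequence[tuple[str, str, float]],
    reference_gene: str,
    calibrator: str,
) -> list[RelativeExpression]:
    """Run 2^-ddCt over a tidy Ct table (sample_id, gene, ct per replicate).

    Every target gene must be measured, alongside the reference gene, in
    both the calibrator sample and each quantified sample.  Output covers
    every (sample, target-gene) pair, calibrator included (fold 1), in
    first-appearance order.
    """
    grouped: dict[tuple[str, str], list[float]] = {}
    order: list[tuple[str, str]] = []
    for sample_id, gene, ct in rows:
        key = (sample_id, gene)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(ct)

    def measurement(sample_id: str, gene: str) -> CtMeasurement:
        key = (sample_id, gene)
        if key not in grouped:
            raise KeyError(f"no Ct rows for gene {gene!r} in sample {sample_id!r}")
        return CtMeasurement(sample_id, gene, tuple(grouped[key]))

    if not any(s == calibrator for s, _ in order):
        raise KeyError(f"calibrator sample {calibrator!r} absent from the table")
    ref_cal = measurement(calibrator, reference_gene)

    results = []
    for sample_id, gene in order:
        if gene == reference_gene:
            continue
        results.append(
            relative_expression(
                measurement(sample_id, gene),
                measurement(sample_id, reference_gene),
                measurement(calibrator, gene),
                ref_cal,
            )
        )
    return results
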