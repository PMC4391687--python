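"""Analytical-validation statistics: concordance accounting and exact bounds.

Sensitivity = TP / (TP + FN); specificity = TN / (TN + FP).  Lower one-sided
confidence limits use the Clopper-Pearson exact method: the lower bound is
the ``p`` at which observing ``successes`` or more out of ``trials`` has
probability exactly ``1 - confidence``; when every trial succeeded this
reduces to the closed form ``(1 - confidence)**(1/trials)``.

Reported percentages are truncated (not rounded) to the requested number of
decimals, so a bound of 0.999237 prints as ">= 99.92%"; full precision is
kept on the objects themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.stats import beta as beta_dist

from .calling import VariantCall, Zygosity
from .model import PanelDefinition


@dataclass
class ConcordanceTable:
    """TP/FN/FP/TN accounting over a base-complete comparison."""

    true_positives: int
    false_negatives: int
    false_positives: int
    true_negatives: int
    bases_analyzed_per_sample: int
    n_samples: int
    discordant_sites: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("true_positives", "false_negatives", "false_positives",
                     "true_negatives"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} negative")

    @property
    def total_bases(self) -> int:
        return self.n_samples * self.bases_analyzed_per_sample

    def conserves_bases(self) -> bool:
        return (self.true_positives + self.false_negatives + self.false_positives
                + self.true_negatives) == self.total_bases


@dataclass(frozen=True)
class ConfidenceBound:
    point_estimate: float
    lower_bound: float
    confidence: float = 0.95
    method: str = "exact one-sided"

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower_bound <= self.point_estimate <= 1.0):
            raise ValueError(
                f"invalid bound: lower {self.lower_bound}, point {self.point_estimate}"
            )


def truncate_percent(proportion: float, decimals: int = 2) -> float:
    """Truncate a proportion to a percentage with ``decimals`` places."""
    scale = 10 ** decimals
    return math.floor(proportion * 100 * scale) / scale


def compare_callsets(
    test: list[VariantCall],
    truth: list[VariantCall],
    panel: PanelDefinition | None = None,
    bases_analyzed_per_sample: int | None = None,
    n_samples: int | None = None,
) -> ConcordanceTable:
    """Site-level concordance between a test call set and a truth set.

    Per (sample, contig, position, ref, alt): present in both with matching
    zygosity -> TP; truth-only -> FN; test-only -> FP; a zygosity mismatch is
    the most conservative case and counts as one FN plus one FP, itemized in
    ``discordant_sites``.  TN is every remaining tested base.
    """
    if bases_analyzed_per_sample is None:
        if panel is None:
            raise ValueError("need panel or bases_analyzed_per_sample")
        bases_analyzed_per_sample = panel.total_bases()
    if panel is not None:
        for c in list(test) + list(truth):
            if panel.region_for_position(c.contig, c.position) is None:
                raise ValueError(
                    f"call at {c.contig}:{c.position} outside every panel region"
                )
    if n_samples is None:
        n_samples = len({c.sample_id for c in list(test) + list(truth)})
    test_map = {c.key: c for c in test}
    truth_map = {c.key: c for c in truth}
    tp = fn = fp = 0
    discordant: list[tuple] = []
    for key, t in truth_map.items():
        m = test_map.get(key)
        if m is None:
            fn += 1
            discordant.append((key, "missing_in_test"))
        elif m.zygosity == t.zygosity:
            tp += 1
        else:
            fn += 1
            fp += 1
            discordant.append((key, f"zygosity {t.zygosity.value} vs {m.zygosity.value}"))
    for key in test_map:
        if key not in truth_map:
            fp += 1
            discordant.append((key, "absent_from_truth"))
    tn = n_samples * bases_analyzed_per_sample - tp - fn - fp
    return ConcordanceTable(
        true_positives=tp, false_negatives=fn, false_positives=fp,
        true_negatives=tn, bases_analyzed_per_sample=bases_analyzed_per_sample,
        n_samples=n_samples, discordant_sites=discordant,
    )


def sensitivity(table: ConcordanceTable) -> float:
    denom = table.true_positives + table.false_negatives
    if denom == 0:
        raise ValueError("sensitivity undefined: no positive sites (TP + FN == 0)")
    return table.true_positives / denom


def specificity(table: ConcordanceTable) -> float:
    denom = table.true_negatives + table.false_positives
    if denom == 0:
        raise ValueError("specificity undefined: no negative sites (TN + FP == 0)")
    return table.true_negatives / denom


def exact_lower_bound(
    successes: int, trials: int, confidence: float = 0.95
) -> ConfidenceBound:
    """Clopper-Pearson one-sided lower confidence limit for a proportion.

    The bound is the beta quantile ``Beta(1 - confidence; x, n - x + 1)``;
    for ``x == n`` this equals ``(1 - confidence)**(1/n)``, and for
    ``x == 0`` the lower bound is 0.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not (0 <= successes <= trials):
        raise ValueError("successes must lie in [0, trials]")
    alpha = 1.0 - confidence
    point = successes / trials
    if successes == 0:
        lower = 0.0
    elif successes == trials:
        lower = alpha ** (1.0 / trials)
    else:
        lower = float(beta_dist.ppf(alpha, successes, trials - successes + 1))
    return ConfidenceBound(point_estimate=point, lower_bound=lower,
                           confidence=confidence)


def summary_report(table: ConcordanceTable, confidence: float = 0.95) -> str:
    """Human-readable counts table plus sensitivity/specificity with bounds."""
    sens = sensitivity(table)
    spec = specificity(table)
    sens_b = exact_lower_bound(
        table.true_positives, table.true_positives + table.false_negatives, confidence
    )
    spec_b = exact_lower_bound(
        table.true_negatives, table.true_negatives + table.false_positives, confidence
    )
    lines = [
        "Concordance summary",
        f"  Samples                    {table.n_samples}",
        f"  Bases analyzed (per sample) {table.bases_analyzed_per_sample:,}",
        f"  Total positive bases       {table.true_positives + table.false_negatives:,}",
        f"  Total negative bases       {table.true_negatives + table.false_positives:,}",
        f"  TP {table.true_positives:,}  FN {table.false_negatives:,}  "
        f"FP {table.false_positives:,}  TN {table.true_negatives:,}",
        f"  Sensitivity {sens:.6f}  (lower {confidence:.0%} bound "
        f">{truncate_percent(sens_b.lower_bound):.2f}%)",
        f"  Specificity {spec:.6f}  (lower {confidence:.0%} bound "
        f">{truncate_percent(spec_b.lower_bound):.2f}%)",
    ]
    if table.discordant_sites:
        lines.append("  Discordant sites:")
        for key, why in table.discordant_sites:
            lines.append(f"    {key}: {why}")
    return "\n".join(lines)
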