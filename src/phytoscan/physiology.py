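"""Radiotracer transfer percentages and anion group statistics.

Transfer percentages partition whole-plant label between shoot and root;
group comparisons use one-way ANOVA plus Tukey HSD, with mutants flagged
against a reference (wild-type) group at the stated alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

REFERENCE_LABEL_DEFAULT = "WT"


class PhysiologyError(ValueError):
    """Invalid measurement or group structure."""


@dataclass(frozen=True)
class TracerMeasurement:
    """Scintillation counts for one plant after a labeling assay."""

    plant_id: str
    genotype: str
    treatment: str  # +Pi | -Pi
    direction: str  # root_to_shoot | shoot_to_root
    cpm_shoot: float
    cpm_root: float

    def __post_init__(self) -> None:
        if self.cpm_shoot < 0 or self.cpm_root < 0:
            raise PhysiologyError(f"{self.plant_id}: negative counts")
        if self.direction not in ("root_to_shoot", "shoot_to_root"):
            raise PhysiologyError(
                f"{self.plant_id}: unknown direction {self.direction!r}"
            )


@dataclass(frozen=True)
class AnionMeasurement:
    """Anion concentration (umol per g FW) for one pooled tissue sample."""

    pool_id: str
    genotype: str
    tissue: str  # shoot | root
    treatment: str
    anion: str  # Pi | sulfate
    concentration: float
    n_plants: int = 10

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise PhysiologyError(f"{self.pool_id}: negative concentration")


@dataclass(frozen=True)
class GroupStats:
    label: str
    n: int
    mean: float
    sd: float
    tukey_vs_reference: bool | None  # None for the reference group itself
    p_vs_reference: float | None = None


@dataclass
class ComparisonResult:
    """One-way ANOVA omnibus plus Tukey HSD comparisons vs a reference."""

    groups: list[GroupStats]
    anova_p: float
    alpha: float
    pairwise: pd.DataFrame = field(repr=False, default=None)

    def flagged(self) -> list[str]:
        return [g.label for g in self.groups if g.tukey_vs_reference]


def transfer_percent(m: TracerMeasurement) -> float:
    """Percent of whole-plant label recovered in the destination organ.

    root_to_shoot -> 100 * shoot / (shoot + root);
    shoot_to_root -> 100 * root / (shoot + root).
    """
    total = m.cpm_shoot + m.cpm_root
    if total <= 0:
        raise PhysiologyError(f"{m.plant_id}: zero total counts")
    if m.direction == "root_to_shoot":
        return 100.0 * m.cpm_shoot / total
    return 100.0 * m.cpm_root / total


@lru_cache(maxsize=None)
def _q_crit(alpha: float, k: int, df: int) -> float:
    return float(stats.studentized_range.ppf(1.0 - alpha, k, df))


def _tukey_pairwise(
    labels: Sequence[str],
    samples: Sequence[np.ndarray],
    alpha: float,
    pvalues: bool = True,
) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons via the studentized-range law.

    Flags compare the pair statistic to a cached critical value, which is
    much cheaper than evaluating the studentized-range survival function
    per pair; set ``pvalues=False`` to skip the (slow) adjusted p-values.
    """
    k = len(labels)
    df = sum(s.size - 1 for s in samples)
    mse = sum(float(np.var(s, ddof=1)) * (s.size - 1) for s in samples) / df
    qc = _q_crit(alpha, k, df)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(np.mean(samples[i]) - np.mean(samples[j]))
            se = math.sqrt(mse / 2.0 * (1.0 / samples[i].size
                                        + 1.0 / samples[j].size))
            q = abs(diff) / se
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": diff,
                    "q_stat": q,
                    "p_adj": float(stats.studentized_range.sf(q, k, df))
                    if pvalues
                    else float("nan"),
                    "significant": bool(q > qc),
                }
            )
    return pd.DataFrame(rows)


def compare_groups(
    values: Mapping[str, Sequence[float]],
    reference: str = REFERENCE_LABEL_DEFAULT,
    alpha: float = 0.05,
    pvalues: bool = True,
) -> ComparisonResult:
    """One-way ANOVA + Tukey HSD of every group against ``reference``.

    All groups need >= 2 replicates.  When every group has zero
    within-group variance the F statistic is 0/0; that degenerate case is
    decided by exact equality of means (significant iff any mean differs).
    """
    if len(values) < 2:
        raise PhysiologyError("need >= 2 groups")
    if reference not in values:
        raise PhysiologyError(f"reference group {reference!r} not present")
    if not 0 < alpha < 1:
        raise PhysiologyError(f"alpha must be in (0,1), got {alpha}")
    labels = list(values.keys())
    samples = []
    for label in labels:
        arr = np.asarray(values[label], dtype=float)
        if arr.size < 2:
            raise PhysiologyError(f"group {label!r} has < 2 replicates")
        samples.append(arr)

    means = {lab: float(np.mean(s)) for lab, s in zip(labels, samples)}
    within_var = sum(float(np.var(s, ddof=1)) for s in samples)

    if within_var == 0.0:
        # degenerate: decide by exact equality of means
        any_diff = len({means[lab] for lab in labels}) > 1
        anova_p = 0.0 if any_diff else 1.0
        groups = [
            GroupStats(
                label=lab,
                n=len(values[lab]),
                mean=means[lab],
                sd=0.0,
                tukey_vs_reference=None
                if lab == reference
                else means[lab] != means[reference],
                p_vs_reference=None
                if lab == reference
                else (0.0 if means[lab] != means[reference] else 1.0),
            )
            for lab in labels
        ]
        return ComparisonResult(groups=groups, anova_p=anova_p, alpha=alpha,
                                pairwise=None)

    anova_p = float(stats.f_oneway(*samples).pvalue)
    pairwise = _tukey_pairwise(labels, samples, alpha, pvalues=pvalues)

    def _ref_row(lab: str):
        mask = (
            (pairwise["group_a"] == reference) & (pairwise["group_b"] == lab)
        ) | ((pairwise["group_a"] == lab) & (pairwise["group_b"] == reference))
        return pairwise[mask].iloc[0]

    groups = []
    for lab, s in zip(labels, samples):
        if lab == reference:
            flag, p = None, None
        else:
            row = _ref_row(lab)
            flag = bool(row["significant"])
            p = float(row["p_adj"]) if pvalues else None
        groups.append(
            GroupStats(
                label=lab,
                n=s.size,
                mean=means[lab],
                sd=float(np.std(s, ddof=1)),
                tukey_vs_reference=flag,
                p_vs_reference=p,
            )
        )
    return ComparisonResult(groups=groups, anova_p=anova_p, alpha=alpha,
                            pairwise=pairwise)


@dataclass(frozen=True)
class FoldChange:
    ratio: float
    direction: str  # increase | decrease | unchanged


def fold_change(summary_a: GroupStats, summary_b: GroupStats) -> FoldChange:
    """Ratio of group means (a over b), with a direction label."""
    if summary_a.mean <= 0 or summary_b.mean <= 0:
        raise PhysiologyError("fold change requires positive means")
    ratio = summary_a.mean / summary_b.mean
    if ratio > 1:
        direction = "increase"
    elif ratio < 1:
        direction = "decrease"
    else:
        direction = "unchanged"
    return FoldChange(ratio=ratio, direction=direction)


# ---------------------------------------------------------------------------
# tabular I/O


def read_tracer_csv(path: str | Path) -> list[TracerMeasurement]:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    return [
        TracerMeasurement(
            plant_id=str(r.plant_id),
            genotype=str(r.genotype),
            treatment=str(r.treatment),
            direction=str(r.direction),
            cpm_shoot=float(r.cpm_shoot),
            cpm_root=float(r.cpm_root),
        )
        for r in df.itertuples()
    ]


def read_anion_csv(path: str | Path) -> list[AnionMeasurement]:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    return [
        AnionMeasurement(
            pool_id=str(r.pool_id),
            genotype=str(r.genotype),
            tissue=str(r.tissue),
            treatment=str(r.treatment),
            anion=str(r.anion),
            concentration=float(r.concentration),
            n_plants=int(getattr(r, "n_plants", 10)),
        )
        for r in df.itertuples()
    ]


def format_mean_sd(g: GroupStats) -> str:
    star = "*" if g.tukey_vs_reference else ""
    return f"{g.mean:.2f} ± {g.sd:.2f}{star}"


def tracer_table(
    measurements: Iterable[TracerMeasurement],
    reference_genotype: str = REFERENCE_LABEL_DEFAULT,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genotype x (direction, treatment) matrix of "mean +/- SD" transfer
    percentages, mutants starred when Tukey-flagged vs the reference."""
    rows: dict[tuple[str, str], dict[str, list[float]]] = {}
    for m in measurements:
        cell = rows.setdefault((m.direction, m.treatment), {})
        cell.setdefault(m.genotype, []).append(transfer_percent(m))
    genotypes: list[str] = []
    for cell in rows.values():
        for g in cell:
            if g not in genotypes:
                genotypes.append(g)
    table = pd.DataFrame(index=genotypes,
                         columns=pd.MultiIndex.from_tuples(sorted(rows)))
    for key, cell in rows.items():
        comp = compare_groups(cell, reference=reference_genotype, alpha=alpha)
        for g in comp.groups:
            table.loc[g.label, key] = format_mean_sd(g)
    return table


def write_groupstats_tsv(result: ComparisonResult, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("group\tn\tmean\tsd\ttukey_vs_reference\tp_vs_reference\n")
        for g in result.groups:
            flag = "" if g.tukey_vs_reference is None else int(g.tukey_vs_reference)
            p = "" if g.p_vs_reference is None else f"{g.p_vs_reference:.4g}"
            fh.write(f"{g.label}\t{g.n}\t{g.mean:.6g}\t{g.sd:.6g}\t{flag}\t{p}\n")


def anion_fold_change(
    measurements: Iterable[AnionMeasurement],
    anion: str,
    tissue: str,
    treatment_a: str,
    treatment_b: str,
    genotype: str = REFERENCE_LABEL_DEFAULT,
) -> FoldChange:
    """Fold change of mean concentration between two treatments."""
    vals: dict[str, list[float]] = {treatment_a: [], treatment_b: []}
    for m in measurements:
        if (m.anion, m.tissue, m.genotype) == (anion, tissue, genotype) \
                and m.treatment in vals:
            vals[m.treatment].append(m.concentration)
    stats_ = {}
    for tr, v in vals.items():
        if not v:
            raise PhysiologyError(f"no measurements for treatment {tr!r}")
        arr = np.asarray(v, dtype=float)
        stats_[tr] = GroupStats(
            label=tr, n=arr.size, mean=float(arr.mean()),
            sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            tukey_vs_reference=None,
        )
    if math.isnan(stats_[treatment_a].mean):
        raise PhysiologyError("NaN mean")
    return fold_change(stats_[treatment_a], stats_[treatment_b])
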