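"""Comparative-CT relative quantification of qPCR data.

Technical replicates are averaged on the CT scale; per biological replicate
the target CT is differenced against the reference gene (default UBQ10) and
then against the pooled calibrator condition of the same tissue.  Results
are log2 relative quantities (log2_rq = -ddCT), summarized as mean +/- SD
across biological replicates.  Amplification efficiency is assumed to be 2
in quantification; the dilution-series efficiency check (pass threshold
1.85) is a separate QC step, not a correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_REF_GENE = "UBQ10"

#: technical-replicate CT spread (cycles) above which a record is flagged
TECH_RANGE_FLAG = 0.5


class QpcrError(ValueError):
    """Invalid CT table or missing reference/calibrator data."""


@dataclass(frozen=True)
class CtRecord:
    """Raw CT measurements for one (sample, gene) pair.

    ``ct_values`` holds the technical replicates (typically a triplicate).
    ``(genotype, tissue, treatment, gene, bio_rep)`` uniquely identifies a
    record within a table.
    """

    sample_id: str
    genotype: str
    tissue: str
    treatment: str
    gene: str
    bio_rep: int
    ct_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.ct_values:
            raise QpcrError(f"{self.sample_id}/{self.gene}: no CT values")
        if any(not math.isfinite(c) or c <= 0 for c in self.ct_values):
            raise QpcrError(
                f"{self.sample_id}/{self.gene}: CT values must be positive "
                f"and finite, got {self.ct_values}"
            )

    @property
    def ct_mean(self) -> float:
        return float(np.mean(self.ct_values))

    @property
    def ct_range(self) -> float:
        return float(max(self.ct_values) - min(self.ct_values))


@dataclass(frozen=True)
class RelExpression:
    """log2 relative quantity of a gene in one condition vs the calibrator."""

    gene: str
    genotype: str
    tissue: str
    treatment: str
    log2_rq: float
    sd: float | None
    n_bio: int

    @property
    def relative_quantity(self) -> float:
        return 2.0 ** self.log2_rq


@dataclass(frozen=True)
class EfficiencyQC:
    """Dilution-series amplification-efficiency check for one primer pair."""

    primer_pair: str
    slope: float
    efficiency: float
    passed: bool
    diagnostic: str = ""


def read_ct_table(path: str | Path) -> list[CtRecord]:
    """Read a long-format CT table (TSV or CSV by extension).

    Required columns: sample_id, genotype, tissue, treatment, gene, bio_rep,
    plus one or more ct_1..ct_k columns.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    meta = ["sample_id", "genotype", "tissue", "treatment", "gene", "bio_rep"]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise QpcrError(f"{path}: missing columns {missing}")
    ct_cols = [c for c in df.columns if c.startswith("ct_")]
    if not ct_cols:
        raise QpcrError(f"{path}: no ct_* columns found")
    records = []
    for _, row in df.iterrows():
        cts = tuple(
            float(row[c]) for c in ct_cols if pd.notna(row[c])
        )
        records.append(
            CtRecord(
                sample_id=str(row["sample_id"]),
                genotype=str(row["genotype"]),
                tissue=str(row["tissue"]),
                treatment=str(row["treatment"]),
                gene=str(row["gene"]),
                bio_rep=int(row["bio_rep"]),
                ct_values=cts,
            )
        )
    return records


def _condition_key(rec: CtRecord) -> tuple[str, str, str]:
    return (rec.genotype, rec.tissue, rec.treatment)


def _delta_ct_by_replicate(
    records: Sequence[CtRecord], target_gene: str, ref_gene: str
) -> dict[tuple[str, str, str, int], float]:
    """Per biological replicate: mean CT(target) - mean CT(reference)."""
    targets: dict[tuple, CtRecord] = {}
    refs: dict[tuple, CtRecord] = {}
    for rec in records:
        if rec.ct_range > TECH_RANGE_FLAG:
            logger.warning(
                "technical CT range %.2f > %.2f cycles for %s/%s",
                rec.ct_range, TECH_RANGE_FLAG, rec.sample_id, rec.gene,
            )
        key = (*_condition_key(rec), rec.bio_rep)
        if rec.gene == target_gene:
            if key in targets:
                raise QpcrError(f"duplicate target record for {key}")
            targets[key] = rec
        elif rec.gene == ref_gene:
            if key in refs:
                raise QpcrError(f"duplicate reference record for {key}")
            refs[key] = rec
    out = {}
    for key, trec in targets.items():
        if key not in refs:
            raise QpcrError(
                f"sample {trec.sample_id} (condition {key}) has no "
                f"reference-gene ({ref_gene}) record"
            )
        out[key] = trec.ct_mean - refs[key].ct_mean
    return out


def ddct(
    table: Iterable[CtRecord],
    target_gene: str,
    ref_gene: str = DEFAULT_REF_GENE,
    calibrator: tuple[str, str | None, str] = ("WT", None, "complete"),
) -> list[RelExpression]:
    """Comparative-CT quantification of ``target_gene`` vs ``ref_gene``.

    ``calibrator`` is ``(genotype, tissue, treatment)``; a ``None`` tissue
    means each sample is calibrated against the calibrator condition of its
    own tissue (the usual case when roots and shoots are plotted as separate
    series).  Per biological replicate, log2_rq = -(dCT_sample - mean
    calibrator dCT); summaries are mean +/- SD over biological replicates.
    """
    records = list(table)
    cal_genotype, cal_tissue, cal_treatment = calibrator
    dcts = _delta_ct_by_replicate(records, target_gene, ref_gene)

    tissues = {key[1] for key in dcts}
    cal_mean: dict[str, float] = {}
    for tissue in tissues:
        ct = cal_tissue if cal_tissue is not None else tissue
        vals = [
            v
            for (g, t, tr, _b), v in dcts.items()
            if g == cal_genotype and t == ct and tr == cal_treatment
        ]
        if not vals:
            raise QpcrError(
                f"no calibrator ({cal_genotype}, {ct}, {cal_treatment}) "
                f"replicates found for tissue {tissue!r}"
            )
        cal_mean[tissue] = float(np.mean(vals))

    by_condition: dict[tuple[str, str, str], list[float]] = {}
    for (g, t, tr, _b), dct in sorted(dcts.items()):
        ddct_val = dct - cal_mean[t]
        by_condition.setdefault((g, t, tr), []).append(-ddct_val)

    out = []
    for (g, t, tr), vals in by_condition.items():
        n = len(vals)
        out.append(
            RelExpression(
                gene=target_gene,
                genotype=g,
                tissue=t,
                treatment=tr,
                log2_rq=float(np.mean(vals)),
                sd=float(np.std(vals, ddof=1)) if n >= 2 else None,
                n_bio=n,
            )
        )
    return out


def efficiency_qc(
    dilution_series: Iterable[tuple[float, float]],
    threshold: float = 1.85,
    primer_pair: str = "",
) -> EfficiencyQC:
    """Estimate amplification efficiency from a (log10_dilution, CT) series.

    Slope comes from ordinary least squares of CT on log10(dilution);
    efficiency = 10**(-1/slope).  Passes when efficiency >= ``threshold``.
    A non-negative slope is reported as a failure with a diagnostic rather
    than an error.
    """
    pts = list(dilution_series)
    if len({x for x, _ in pts}) < 3:
        raise QpcrError("efficiency QC needs >= 3 distinct dilutions")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    slope = float(np.polyfit(x, y, 1)[0])
    if slope >= 0:
        return EfficiencyQC(
            primer_pair=primer_pair,
            slope=slope,
            efficiency=float("nan"),
            passed=False,
            diagnostic=f"non-negative slope {slope:.4g}: CT must decrease "
            "with template amount",
        )
    eff = 10.0 ** (-1.0 / slope)
    return EfficiencyQC(
        primer_pair=primer_pair,
        slope=slope,
        efficiency=eff,
        passed=eff >= threshold,
    )


def write_relexpression_tsv(
    results: Iterable[RelExpression], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene\tgenotype\ttissue\ttreatment\tlog2_rq\tsd\tn_bio\n")
        for r in results:
            sd = "" if r.sd is None else f"{r.sd:.6g}"
            fh.write(
                f"{r.gene}\t{r.genotype}\t{r.tissue}\t{r.treatment}\t"
                f"{r.log2_rq:.6g}\t{sd}\t{r.n_bio}\n"
            )
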