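"""Seeded generators for promoter sets, CT tables and group data.

Every generator is deterministic under a fixed seed and returns its ground
truth alongside the data, so downstream stages can be validated end to end:
planted motif sites are recoverable at exactly the planted distance and
strand, CT tables carry known log2 condition effects, and group tables are
drawn from stated means/SDs (normal noise, truncated at zero for physical
quantities — a modelling choice, not a measured property).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .motif import P1BS, DegeneratePattern, compile_pattern, _revcomp
from .promoters import PromoterRecord
from .qpcr import CtRecord
from .physiology import TracerMeasurement

UNIFORM_COMPOSITION = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
#: Arabidopsis-like intergenic composition (~36% GC)
ARABIDOPSIS_COMPOSITION = {"A": 0.32, "C": 0.18, "G": 0.18, "T": 0.32}

#: -Pi shoot-to-root transfer percentages, mean/SD per genotype (assay data
#: used as generator parameters; n per group is a required choice, not given)
TRANSFER_MINUS_PI_SHOOT_TO_ROOT: dict[str, tuple[float, float]] = {
    "WT": (1.51, 0.27),
    "phr1": (0.83, 0.12),
    "sultr1;3": (0.63, 0.28),
    "sultr2;1": (1.42, 0.42),
}


class SyntheticError(ValueError):
    """Invalid generator specification."""


# ---------------------------------------------------------------------------
# promoters with planted sites


@dataclass(frozen=True)
class PlantedSiteSpec:
    """A motif planted in one synthetic promoter.

    ``word`` is the concrete instantiation; ``None`` draws each degenerate
    position uniformly from its base set.  ``strand`` "-" plants the
    reverse complement on the coding strand so the motif reads 5'->3' on
    the minus strand.
    """

    promoter_index: int
    upstream_distance: int
    strand: str = "+"
    word: str | None = None


def _instantiate(pattern: DegeneratePattern, word: str | None, rng) -> str:
    if word is not None:
        word = word.upper()
        if not pattern.matches(word):
            raise SyntheticError(
                f"planted word {word!r} does not match pattern {pattern.text}"
            )
        return word
    return "".join(rng.choice(sorted(s)) for s in pattern.position_sets)


def synth_promoters(
    n: int,
    length: int = 500,
    base_composition: Mapping[str, float] = UNIFORM_COMPOSITION,
    planted: Sequence[PlantedSiteSpec] = (),
    seed: int | None = None,
    pattern: DegeneratePattern | str = P1BS,
) -> tuple[list[PromoterRecord], list[dict]]:
    """Generate i.i.d.-background promoters with planted motif sites.

    Returns ``(records, truth)`` where ``truth`` rows record every planted
    site (gene_model_id, upstream_distance, strand, word).  Planted windows
    within one promoter must not overlap.
    """
    if isinstance(pattern, str):
        pattern = compile_pattern(pattern)
    if n < 0 or length <= 0:
        raise SyntheticError("n must be >= 0 and length positive")
    bases = sorted(base_composition)
    probs = np.array([base_composition[b] for b in bases], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise SyntheticError(f"base probabilities sum to {probs.sum()}, not 1")
    k = pattern.k
    by_promoter: dict[int, list[PlantedSiteSpec]] = {}
    for spec in planted:
        if not 0 <= spec.promoter_index < n:
            raise SyntheticError(f"promoter index {spec.promoter_index} out of range")
        if not k <= spec.upstream_distance <= length:
            raise SyntheticError(
                f"upstream_distance {spec.upstream_distance} outside [{k},{length}]"
            )
        if spec.strand not in ("+", "-"):
            raise SyntheticError(f"strand must be + or -, got {spec.strand!r}")
        by_promoter.setdefault(spec.promoter_index, []).append(spec)
    for idx, specs in by_promoter.items():
        ivals = sorted(
            (length - s.upstream_distance, length - s.upstream_distance + k)
            for s in specs
        )
        for (a0, a1), (b0, _b1) in zip(ivals, ivals[1:]):
            if b0 < a1:
                raise SyntheticError(f"overlapping planted sites in promoter {idx}")

    rng = np.random.default_rng(seed)
    width = max(4, len(str(max(n, 1))))
    records: list[PromoterRecord] = []
    truth: list[dict] = []
    for i in range(n):
        seq = rng.choice(bases, size=length, p=probs)
        gid = f"SYN{i:0{width}d}.1"
        for spec in by_promoter.get(i, ()):
            word = _instantiate(pattern, spec.word, rng)
            placed = word if spec.strand == "+" else _revcomp(word)
            start = length - spec.upstream_distance  # 0-based
            seq[start : start + k] = list(placed)
            truth.append(
                {
                    "gene_model_id": gid,
                    "upstream_distance": spec.upstream_distance,
                    "strand": spec.strand,
                    "word": word,
                }
            )
        records.append(
            PromoterRecord(
                gene_model_id=gid,
                sequence="".join(seq),
                window=length,
            )
        )
    return records, truth


def write_truth_tsv(truth: Iterable[dict], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_model_id\tupstream_distance\tstrand\tword\n")
        for row in truth:
            fh.write(
                f"{row['gene_model_id']}\t{row['upstream_distance']}\t"
                f"{row['strand']}\t{row['word']}\n"
            )


# ---------------------------------------------------------------------------
# qPCR design


@dataclass(frozen=True)
class QpcrDesignSpec:
    """Shape and noise model of a synthetic comparative-CT experiment.

    ``conditions`` is the (genotype, tissue, treatment) grid;
    ``true_effects`` maps (gene, genotype, tissue, treatment) to the log2
    effect vs the calibrator (absent keys mean 0; the calibrator condition
    must be 0).  SDs are on the CT/cycle scale.
    """

    conditions: tuple[tuple[str, str, str], ...]
    genes: tuple[str, ...]
    true_effects: Mapping[tuple[str, str, str, str], float]
    calibrator: tuple[str, str | None, str] = ("WT", None, "complete")
    ref_gene: str = "UBQ10"
    ref_drift_sd: float = 0.0
    technical_sd: float = 0.0
    biological_sd: float = 0.0
    n_bio: int = 3
    n_tech: int = 3
    ref_baseline: float = 20.0
    gene_offset: float = 5.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_bio < 1 or self.n_tech < 1:
            raise SyntheticError("n_bio and n_tech must be >= 1")
        if min(self.ref_drift_sd, self.technical_sd, self.biological_sd) < 0:
            raise SyntheticError("SDs must be >= 0")
        cal_g, cal_t, cal_tr = self.calibrator
        for (gene, g, t, tr), eff in self.true_effects.items():
            cal_match = g == cal_g and tr == cal_tr and (
                cal_t is None or t == cal_t
            )
            if cal_match and eff != 0.0:
                raise SyntheticError("calibrator condition must have effect 0")


def synth_qpcr(spec: QpcrDesignSpec) -> tuple[list[CtRecord], dict]:
    """Simulate a CT table with known log2 effects.

    Per sample a loading shift (ref drift) moves target and reference CTs
    together, so it cancels in the differencing; the biological effect and
    biological noise act on the target only.  Truth maps
    (gene, genotype, tissue, treatment) -> true log2 effect.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[CtRecord] = []
    truth: dict[tuple[str, str, str, str], float] = {}
    for genotype, tissue, treatment in spec.conditions:
        for b in range(1, spec.n_bio + 1):
            sample_id = f"{genotype}_{tissue}_{treatment}_b{b}"
            shift = rng.normal(0.0, spec.ref_drift_sd) if spec.ref_drift_sd else 0.0
            ref_ct = spec.ref_baseline + shift
            records.append(
                CtRecord(
                    sample_id=sample_id,
                    genotype=genotype,
                    tissue=tissue,
                    treatment=treatment,
                    gene=spec.ref_gene,
                    bio_rep=b,
                    ct_values=tuple(
                        ref_ct + (rng.normal(0.0, spec.technical_sd)
                                  if spec.technical_sd else 0.0)
                        for _ in range(spec.n_tech)
                    ),
                )
            )
            for gene in spec.genes:
                key = (gene, genotype, tissue, treatment)
                effect = float(spec.true_effects.get(key, 0.0))
                truth[key] = effect
                bio = rng.normal(0.0, spec.biological_sd) if spec.biological_sd else 0.0
                target_ct = (
                    spec.ref_baseline + shift + spec.gene_offset - effect - bio
                )
                records.append(
                    CtRecord(
                        sample_id=sample_id,
                        genotype=genotype,
                        tissue=tissue,
                        treatment=treatment,
                        gene=gene,
                        bio_rep=b,
                        ct_values=tuple(
                            target_ct + (rng.normal(0.0, spec.technical_sd)
                                         if spec.technical_sd else 0.0)
                            for _ in range(spec.n_tech)
                        ),
                    )
                )
    return records, truth


def write_ct_tsv(records: Iterable[CtRecord], path: str | Path) -> None:
    records = list(records)
    n_tech = max(len(r.ct_values) for r in records)
    cols = "\t".join(f"ct_{i + 1}" for i in range(n_tech))
    with Path(path).open("w") as fh:
        fh.write(
            "sample_id\tgenotype\ttissue\ttreatment\tgene\tbio_rep\t" + cols + "\n"
        )
        for r in records:
            cts = list(r.ct_values) + [""] * (n_tech - len(r.ct_values))
            ct_str = "\t".join(
                f"{c:.6f}" if c != "" else "" for c in cts
            )
            fh.write(
                f"{r.sample_id}\t{r.genotype}\t{r.tissue}\t{r.treatment}\t"
                f"{r.gene}\t{r.bio_rep}\t{ct_str}\n"
            )


# ---------------------------------------------------------------------------
# group data (tracer percentages, anion concentrations)


@dataclass(frozen=True)
class GroupSpec:
    label: str
    mean: float
    sd: float
    n: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise SyntheticError(f"{self.label}: sd must be >= 0")
        if self.n < 2:
            raise SyntheticError(f"{self.label}: n must be >= 2")


def synth_groups(
    specs: Sequence[GroupSpec],
    seed: int | None = None,
    truncate_at_zero: bool = True,
) -> dict[str, np.ndarray]:
    """Draw replicate values per group (normal, optionally clipped at 0).

    A per-group ``seed`` overrides the stream spawned from the global one.
    """
    root = np.random.default_rng(seed)
    children = root.spawn(len(specs))
    out: dict[str, np.ndarray] = {}
    for spec, child in zip(specs, children):
        rng = np.random.default_rng(spec.seed) if spec.seed is not None else child
        vals = rng.normal(spec.mean, spec.sd, size=spec.n)
        if truncate_at_zero:
            vals = np.maximum(vals, 0.0)
        out[spec.label] = vals
    return out


def synth_tracer(
    specs: Sequence[GroupSpec],
    direction: str = "shoot_to_root",
    treatment: str = "-Pi",
    total_cpm: float = 10_000.0,
    seed: int | None = None,
) -> list[TracerMeasurement]:
    """Per-plant tracer counts whose transfer percentages follow ``specs``.

    Percent draws are clipped to [0, 100] and converted to destination /
    source counts over a fixed whole-plant total.
    """
    groups = synth_groups(specs, seed=seed)
    out: list[TracerMeasurement] = []
    for label, percents in groups.items():
        for i, p in enumerate(np.minimum(percents, 100.0), start=1):
            dest = total_cpm * p / 100.0
            rest = total_cpm - dest
            shoot, root = (dest, rest) if direction == "root_to_shoot" else (rest, dest)
            out.append(
                TracerMeasurement(
                    plant_id=f"{label}_{i}",
                    genotype=label,
                    treatment=treatment,
                    direction=direction,
                    cpm_shoot=shoot,
                    cpm_root=root,
                )
            )
    return out
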