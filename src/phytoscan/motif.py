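"""IUPAC degenerate-motif compilation and promoter scanning.

A degenerate pattern is expanded to per-position base sets and matched
window-by-window.  Matching is implemented with overlap-aware regular
expressions built from the position sets; an 'N' in the *sequence* never
matches any position set (including a pattern 'N'), because an unknown base
is evidence of nothing.

The "upstream distance" coordinate of a hit is the number of bases from the
start-codon anchor to the 5'-most matched base on the coding strand: for a
window starting at 1-based offset i in a promoter of length L, the distance
is L - i + 1.  A site fully inside a 500-bp window therefore has distance
between k and 500.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

from .promoters import PromoterRecord

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
# canonical code for each base subset (inverse of IUPAC_SETS)
_SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

P1BS = "GNATATNC"

Strands = Literal["forward", "both"]


class PatternError(ValueError):
    """Invalid IUPAC pattern text."""


class SequenceError(ValueError):
    """Sequence contains characters outside {A,C,G,T,N}."""


@dataclass(frozen=True)
class DegeneratePattern:
    """An IUPAC pattern expanded to per-position base subsets."""

    text: str
    position_sets: tuple[frozenset[str], ...]

    @property
    def k(self) -> int:
        return len(self.position_sets)

    def matches(self, window: str) -> bool:
        """Set-membership check of one k-mer against the pattern."""
        if len(window) != self.k:
            return False
        return all(b in s for b, s in zip(window, self.position_sets))

    def is_self_reverse_complement(self) -> bool:
        return reverse_complement_pattern(self).position_sets == self.position_sets


def compile_pattern(iupac_text: str) -> DegeneratePattern:
    """Compile an IUPAC string (case-insensitive) into a DegeneratePattern."""
    if not iupac_text:
        raise PatternError("pattern must be non-empty")
    text = iupac_text.upper()
    sets = []
    for i, ch in enumerate(text, start=1):
        try:
            sets.append(IUPAC_SETS[ch])
        except KeyError:
            raise PatternError(
                f"invalid IUPAC code {ch!r} at position {i} of {iupac_text!r}"
            ) from None
    return DegeneratePattern(text=text, position_sets=tuple(sets))


def reverse_complement_pattern(p: DegeneratePattern) -> DegeneratePattern:
    """Reverse the position sets and complement each, re-encoding the text."""
    sets = tuple(
        frozenset(b.translate(_COMPLEMENT) for b in s)
        for s in reversed(p.position_sets)
    )
    text = "".join(_SET_TO_CODE[s] for s in sets)
    return DegeneratePattern(text=text, position_sets=sets)


def _regex(p: DegeneratePattern) -> re.Pattern[str]:
    # lookahead + capture reports overlapping windows; N is excluded because
    # classes are built only from {A,C,G,T}
    body = "".join("[" + "".join(sorted(s)) + "]" for s in p.position_sets)
    return re.compile(f"(?=({body}))")


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def scan_sequence(
    seq: str, p: DegeneratePattern, strands: Strands = "both"
) -> list[tuple[int, str, str]]:
    """Scan a sequence for a degenerate pattern.

    Returns ``(offset, strand, matched_sequence)`` tuples, ``offset`` being
    the 1-based window start within ``seq``.  Overlapping windows are all
    reported.  With ``strands="both"``, a window matching on both strands
    (always the case for a self-reverse-complementary pattern) is reported
    exactly once with strand ``"±"`` and the forward-strand read.
    """
    bad = set(seq) - set("ACGTN")
    if bad:
        raise SequenceError(f"invalid sequence characters: {sorted(bad)}")
    fwd = {m.start(1): m.group(1) for m in _regex(p).finditer(seq)}
    if strands == "forward":
        return [(i + 1, "+", w) for i, w in sorted(fwd.items())]
    rc_hits = {
        m.start(1): m.group(1)
        for m in _regex(reverse_complement_pattern(p)).finditer(seq)
    }
    out: list[tuple[int, str, str]] = []
    for i in sorted(fwd.keys() | rc_hits.keys()):
        if i in fwd and i in rc_hits:
            out.append((i + 1, "±", fwd[i]))
        elif i in fwd:
            out.append((i + 1, "+", fwd[i]))
        else:
            out.append((i + 1, "-", _revcomp(rc_hits[i])))
    return out


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence in "bp upstream of the anchor" coordinates.

    The match occupies distances ``upstream_distance`` down to
    ``upstream_distance - k + 1``; ``matched_sequence`` is the k-mer read
    5'->3' on the matching strand (forward read for strand ``"±"``).
    """

    gene_model_id: str
    upstream_distance: int
    strand: str
    matched_sequence: str


def scan_promoter(
    rec: PromoterRecord, p: DegeneratePattern, strands: Strands = "both"
) -> list[MotifHit]:
    """Scan one promoter; offsets are converted to upstream distances."""
    L = len(rec.sequence)
    if L < p.k:
        return []
    return [
        MotifHit(
            gene_model_id=rec.gene_model_id,
            upstream_distance=L - offset + 1,
            strand=strand,
            matched_sequence=word,
        )
        for offset, strand, word in scan_sequence(rec.sequence, p, strands)
    ]


@dataclass
class ScreenResult:
    """Genome-wide screen summary: per-model hits and presence counts."""

    n_models_scanned: int
    hits: dict[str, list[MotifHit]] = field(default_factory=dict)

    @property
    def n_models_with_hit(self) -> int:
        return sum(1 for h in self.hits.values() if h)

    @property
    def n_loci_with_hit(self) -> int:
        """Model count collapsed to loci (AGI '.n' suffix stripped)."""
        loci = {gid.split(".")[0] for gid, h in self.hits.items() if h}
        return len(loci)

    def to_summary_dict(self) -> dict:
        return {
            "n_models_scanned": self.n_models_scanned,
            "n_models_with_hit": self.n_models_with_hit,
            "n_loci_with_hit": self.n_loci_with_hit,
            "n_hits_total": sum(len(h) for h in self.hits.values()),
        }


def screen(
    records: Iterable[PromoterRecord],
    p: DegeneratePattern,
    strands: Strands = "both",
) -> ScreenResult:
    """Scan a promoter set; counts each model once regardless of multiplicity."""
    records = list(records)
    ids = [r.gene_model_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("gene_model_ids must be unique within a screen")
    result = ScreenResult(n_models_scanned=len(records))
    for rec in records:
        hits = scan_promoter(rec, p, strands)
        if hits:
            result.hits[rec.gene_model_id] = hits
    return result


# ---------------------------------------------------------------------------
# exports


def write_hits_tsv(result: ScreenResult, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("gene_model_id\tupstream_distance\tstrand\tmatched_sequence\n")
        for gid, hits in result.hits.items():
            for h in hits:
                fh.write(
                    f"{gid}\t{h.upstream_distance}\t{h.strand}\t"
                    f"{h.matched_sequence}\n"
                )


def write_summary_json(result: ScreenResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_summary_dict(), indent=2) + "\n")


def write_hits_bed(
    result: ScreenResult,
    promoter_lengths: Mapping[str, int],
    k: int,
    path: str | Path,
) -> None:
    """BED-like six-column export in promoter-local 0-based half-open coords."""
    with Path(path).open("w") as fh:
        for gid, hits in result.hits.items():
            L = promoter_lengths[gid]
            for h in hits:
                start = L - h.upstream_distance  # 0-based
                strand = "+" if h.strand == "±" else h.strand
                fh.write(
                    f"{gid}\t{start}\t{start + k}\t{h.matched_sequence}\t0\t"
                    f"{strand}\n"
                )
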