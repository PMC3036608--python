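"""Upstream regulatory-region handling.

Reads pre-extracted upstream-sequence FASTA files (TAIR-style dialect) and
extracts fixed-length upstream windows from a genome FASTA + GFF3 annotation,
anchored either at the start codon or at the transcription start.

Coordinates follow the usual GFF3 convention: 1-based, inclusive.  A
promoter sequence is always reported 5'->3' on the gene's coding strand,
with its last base immediately adjacent to the anchor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

Anchor = Literal["start_codon", "transcription_start"]


class PromoterError(ValueError):
    """Raised on malformed promoter input (bad FASTA, duplicate ids, ...)."""


@dataclass(frozen=True)
class PromoterRecord:
    """One gene model's upstream regulatory sequence.

    ``sequence`` runs 5'->3' on the coding strand; its last base abuts the
    anchor (start codon by default).  ``window`` is the requested length;
    ``truncated`` is set when a chromosome end shortened the region.
    """

    gene_model_id: str
    sequence: str
    window: int
    truncated: bool = False

    def __post_init__(self) -> None:
        if not self.gene_model_id:
            raise PromoterError("gene_model_id must be non-empty")
        if self.window <= 0:
            raise PromoterError(f"window must be positive, got {self.window}")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise PromoterError(
                f"{self.gene_model_id}: invalid sequence characters {sorted(bad)}"
            )
        if len(self.sequence) > self.window:
            raise PromoterError(
                f"{self.gene_model_id}: sequence length {len(self.sequence)} "
                f"exceeds window {self.window}"
            )
        if len(self.sequence) < self.window and not self.truncated:
            raise PromoterError(
                f"{self.gene_model_id}: sequence shorter than window but not "
                "flagged truncated"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _check_unique(records: Iterable[PromoterRecord]) -> list[PromoterRecord]:
    records = list(records)
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.gene_model_id] = seen.get(rec.gene_model_id, 0) + 1
    dups = sorted(gid for gid, n in seen.items() if n > 1)
    if dups:
        raise PromoterError(f"duplicate gene_model_id(s): {', '.join(dups)}")
    return records


def parse_upstream_fasta(path: str | Path, window: int = 500) -> list[PromoterRecord]:
    """Parse a pre-extracted upstream-sequence FASTA into promoter records.

    The gene model id is the first whitespace-delimited token of the header;
    TAIR pipe-annotated headers (``>AT1G00010.1 | chr1:...``) are supported
    since everything after the first token is ignored.  Sequences are
    uppercased.  Records longer than ``window`` are rejected; shorter ones
    are flagged truncated.
    """
    path = Path(path)
    if window <= 0:
        raise PromoterError(f"window must be positive, got {window}")
    records: list[PromoterRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        gid = entry.id.strip()
        if not gid:
            raise PromoterError(f"empty FASTA header in {path}")
        seq = str(entry.seq).upper().replace("\r", "")
        bad = set(seq) - VALID_BASES
        if bad:
            raise PromoterError(
                f"record '{entry.description}': invalid characters {sorted(bad)}"
            )
        if len(seq) > window:
            raise PromoterError(
                f"record '{entry.description}': length {len(seq)} exceeds "
                f"window {window}"
            )
        records.append(
            PromoterRecord(
                gene_model_id=gid,
                sequence=seq,
                window=window,
                truncated=len(seq) < window,
            )
        )
    return _check_unique(records)


def write_fasta(records: Iterable[PromoterRecord], path: str | Path) -> None:
    """Write promoter records as a plain FASTA file (60-column wrap)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_model_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def write_index_tsv(records: Iterable[PromoterRecord], path: str | Path) -> None:
    """Write a TSV index (gene_model_id, length, truncated)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_model_id\tlength\ttruncated\n")
        for rec in records:
            fh.write(f"{rec.gene_model_id}\t{len(rec)}\t{int(rec.truncated)}\n")


# ---------------------------------------------------------------------------
# de-novo extraction from genome FASTA + GFF3


@dataclass
class ExtractionReport:
    """Bookkeeping for extract_upstream: skipped models and counts."""

    n_extracted: int = 0
    n_skipped_no_anchor: int = 0
    skipped_ids: list[str] = field(default_factory=list)


def _anchor_positions(
    db, anchor: Anchor
) -> Iterator[tuple[str, str, int, str]]:
    """Yield (gene_model_id, seqid, anchor_first_base_1based, strand).

    The anchor's first base is the 5'-most base of the anchored feature on
    the model's own strand: feature start for '+', feature end for '-'.
    For ``start_codon`` the anchor feature is the first CDS segment of the
    model; for ``transcription_start`` it is the mRNA extent.
    """
    featuretype = "mRNA"
    for mrna in db.features_of_type(featuretype):
        gid = mrna.id
        if anchor == "transcription_start":
            pos = mrna.start if mrna.strand == "+" else mrna.end
            yield gid, mrna.seqid, pos, mrna.strand
            continue
        cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
        if not cds:
            yield gid, mrna.seqid, -1, mrna.strand  # sentinel: no anchor
            continue
        if mrna.strand == "+":
            pos = min(c.start for c in cds)
        else:
            pos = max(c.end for c in cds)
        yield gid, mrna.seqid, pos, mrna.strand


def extract_upstream(
    genome: str | Path,
    annotation: str | Path,
    window: int = 500,
    anchor: Anchor = "start_codon",
    report: ExtractionReport | None = None,
) -> list[PromoterRecord]:
    """Extract fixed-length upstream regions for every mRNA in a GFF3 file.

    For a plus-strand model with anchor first base at 1-based position p the
    window is ``genome[p-window .. p-1]`` in genome orientation; for a
    minus-strand model it is the reverse complement of
    ``genome[p+1 .. p+window]``.  Windows clipped at chromosome boundaries
    are flagged truncated.  Models lacking the required anchor feature are
    skipped with a warning and counted in ``report``.
    """
    import gffutils

    if window <= 0:
        raise PromoterError(f"window must be positive, got {window}")
    chroms = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome), "fasta")
    }
    db = gffutils.create_db(
        str(annotation),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    if report is None:
        report = ExtractionReport()
    records: list[PromoterRecord] = []
    for gid, seqid, pos, strand in _anchor_positions(db, anchor):
        if pos < 0:
            logger.warning("model %s has no CDS anchor feature; skipped", gid)
            report.n_skipped_no_anchor += 1
            report.skipped_ids.append(gid)
            continue
        if seqid not in chroms:
            raise PromoterError(
                f"chromosome '{seqid}' in GFF3 is absent from the genome FASTA"
            )
        chrom = chroms[seqid]
        if strand == "+":
            lo = max(1, pos - window)  # 1-based inclusive
            hi = pos - 1
            seq = chrom[lo - 1 : hi]
        else:
            lo = pos + 1
            hi = min(len(chrom), pos + window)
            seq = str(Seq(chrom[lo - 1 : hi]).reverse_complement())
        truncated = len(seq) < window
        records.append(
            PromoterRecord(
                gene_model_id=gid,
                sequence=seq,
                window=window,
                truncated=truncated,
            )
        )
        report.n_extracted += 1
    return _check_unique(records)
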