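"""Gene models: representative-transcript selection and exon/intron length sums.

Every FPKM in the pipeline is normalized by a per-gene region length, so each
gene is reduced to a single representative transcript before quantification.
Selection prefers the best-supported transcript model (smallest Transcript
Support Level, TSL) and, among equally supported models, the longest one.

Coordinates are 0-based half-open throughout (BED convention), which makes
abutting exons and length arithmetic unambiguous.  Strand is irrelevant for
length sums and is ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "TranscriptModel",
    "GeneModel",
    "select_representative_transcript",
    "compute_gene_lengths",
    "build_gene_table",
    "read_transcripts_gtf",
    "read_gene_lengths_tsv",
    "write_gene_lengths_tsv",
]


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript model with its exon structure.

    ``tsl`` is the Transcript Support Level rank (smaller = better supported);
    ``None`` means the annotation carries no TSL, which ranks after every
    numeric level.  ``exon_intervals`` are 0-based half-open genomic intervals,
    stored sorted; overlapping exons are rejected.
    """

    transcript_id: str
    gene_id: str
    exon_intervals: tuple[tuple[int, int], ...]
    tsl: int | None = None

    def __post_init__(self) -> None:
        if not self.exon_intervals:
            raise ValueError(f"transcript {self.transcript_id!r} has no exons")
        intervals = tuple(sorted((int(s), int(e)) for s, e in self.exon_intervals))
        prev_end = None
        for start, end in intervals:
            if end <= start:
                raise ValueError(
                    f"transcript {self.transcript_id!r}: empty or inverted exon [{start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id!r}: overlapping exons at [{start}, {end})"
                )
            prev_end = end
        object.__setattr__(self, "exon_intervals", intervals)
        if self.tsl is not None and int(self.tsl) < 1:
            raise ValueError(f"transcript {self.transcript_id!r}: TSL must be >= 1")

    @property
    def transcript_length_bp(self) -> int:
        """Sum of exon lengths (mature transcript length)."""
        return sum(end - start for start, end in self.exon_intervals)

    @property
    def span_bp(self) -> int:
        """Genomic span: last exon end minus first exon start."""
        return self.exon_intervals[-1][1] - self.exon_intervals[0][0]


@dataclass(frozen=True)
class GeneModel:
    """Per-gene length summary derived from the representative transcript."""

    gene_id: str
    representative_transcript_id: str
    exon_length_bp: int
    intron_length_bp: int

    def __post_init__(self) -> None:
        if self.exon_length_bp <= 0:
            raise ValueError(f"gene {self.gene_id!r}: exon length must be positive")
        if self.intron_length_bp < 0:
            raise ValueError(f"gene {self.gene_id!r}: negative intron length")


def select_representative_transcript(
    transcripts: Sequence[TranscriptModel],
) -> TranscriptModel:
    """Pick the representative transcript of one gene.

    Order of preference: smallest TSL (missing TSL ranks last), then longest
    transcript, then lexicographically smallest transcript id so the choice is
    deterministic and independent of input order.
    """
    transcripts = list(transcripts)
    if not transcripts:
        raise ValueError("no transcripts supplied: malformed annotation")
    gene_ids = {t.gene_id for t in transcripts}
    if len(gene_ids) != 1:
        raise ValueError(f"transcripts belong to multiple genes: {sorted(gene_ids)}")
    return min(
        transcripts,
        key=lambda t: (
            t.tsl if t.tsl is not None else math.inf,
            -t.transcript_length_bp,
            t.transcript_id,
        ),
    )


def compute_gene_lengths(transcript: TranscriptModel) -> GeneModel:
    """Exonic and intronic length sums of a transcript.

    Intron length is the genomic span minus the exon sum, which for half-open
    intervals is exactly the summed gap between consecutive exons.
    """
    exon_bp = transcript.transcript_length_bp
    intron_bp = transcript.span_bp - exon_bp
    return GeneModel(
        gene_id=transcript.gene_id,
        representative_transcript_id=transcript.transcript_id,
        exon_length_bp=exon_bp,
        intron_length_bp=intron_bp,
    )


def build_gene_table(transcripts: Iterable[TranscriptModel]) -> pd.DataFrame:
    """Group transcripts by gene, select representatives and tabulate lengths.

    Returns a DataFrame indexed by gene_id with columns
    ``representative_transcript_id``, ``exon_length_bp``, ``intron_length_bp``.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    rows = []
    for gene_id in sorted(by_gene):
        model = compute_gene_lengths(select_representative_transcript(by_gene[gene_id]))
        rows.append(
            {
                "gene_id": model.gene_id,
                "representative_transcript_id": model.representative_transcript_id,
                "exon_length_bp": model.exon_length_bp,
                "intron_length_bp": model.intron_length_bp,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def _parse_tsl(raw: str | None) -> int | None:
    # GTF values look like "1", "NA", or "1 (assigned to previous version)".
    if raw is None:
        return None
    token = str(raw).strip().split()[0] if str(raw).strip() else ""
    try:
        return int(token)
    except ValueError:
        return None


def read_transcripts_gtf(path: str) -> list[TranscriptModel]:
    """Read transcript models from a GTF/GFF file via gffutils.

    Requires ``gene_id`` and ``transcript_id`` attributes on exon features;
    ``transcript_support_level`` is taken from the transcript feature when
    present, otherwise from the exons.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    tsl_by_tx: dict[str, int | None] = {}
    for feat in db.features_of_type(("transcript", "mRNA")):
        tx = feat.attributes.get("transcript_id", [feat.id])[0]
        tsl_by_tx[tx] = _parse_tsl(
            (feat.attributes.get("transcript_support_level") or [None])[0]
        )
    exons: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        tx = feat.attributes["transcript_id"][0]
        gene = feat.attributes["gene_id"][0]
        entry = exons.setdefault(tx, {"gene_id": gene, "intervals": []})
        # GTF is 1-based closed; convert to 0-based half-open.
        entry["intervals"].append((feat.start - 1, feat.end))
        if tx not in tsl_by_tx:
            tsl_by_tx[tx] = _parse_tsl(
                (feat.attributes.get("transcript_support_level") or [None])[0]
            )
    return [
        TranscriptModel(
            transcript_id=tx,
            gene_id=entry["gene_id"],
            exon_intervals=tuple(entry["intervals"]),
            tsl=tsl_by_tx.get(tx),
        )
        for tx, entry in sorted(exons.items())
    ]


def read_gene_lengths_tsv(path: str) -> pd.DataFrame:
    """Read a gene-length table (gene_id, exon_length_bp, intron_length_bp)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing gene_id column")
    return df.set_index("gene_id")


def write_gene_lengths_tsv(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t")
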