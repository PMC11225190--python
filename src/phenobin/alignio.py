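"""Multiple-sequence-alignment plumbing.

The pipeline never infers molecular trees, but it checks alignment
dimensions and concatenates per-marker alignments (e.g. ITS + nuLSU +
mtSSU) for bookkeeping. Reading goes through Biopython's AlignIO.
"""

from __future__ import annotations

from pathlib import Path

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import EmptyAlignmentError, RaggedAlignmentError

_SCHEMAS = {"fasta": "fasta", "relaxed_phylip": "phylip-relaxed"}


def read_alignment(path: str | Path, format: str = "fasta") -> MultipleSeqAlignment:
    """Read an alignment; raises on ragged or empty input."""
    if format not in _SCHEMAS:
        raise ValueError(f"unknown alignment format {format!r}")
    path = Path(path)
    if format == "fasta":
        # read records first so ragged fasta gives a named error
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise EmptyAlignmentError(f"no sequences in {path}")
        lengths = {len(r.seq) for r in records}
        if len(lengths) > 1:
            raise RaggedAlignmentError(
                f"{path}: sequence lengths differ ({sorted(lengths)})"
            )
        return MultipleSeqAlignment(records)
    try:
        aln = AlignIO.read(str(path), _SCHEMAS[format])
    except ValueError as exc:
        msg = str(exc).lower()
        if "no records" in msg or "empty" in msg:
            raise EmptyAlignmentError(f"no sequences in {path}") from exc
        raise RaggedAlignmentError(f"{path}: {exc}") from exc
    return aln


def dimensions(aln: MultipleSeqAlignment) -> tuple[int, int]:
    """(n_terminals, n_columns)."""
    return len(aln), aln.get_alignment_length()


def concatenate_alignments(
    alignments: list[MultipleSeqAlignment], pad_missing: bool = False
) -> MultipleSeqAlignment:
    """Concatenate partitions; column count is the sum of the parts.

    With ``pad_missing`` a terminal absent from one partition receives a
    gap-only stretch for it; otherwise all partitions must share the same
    label set.
    """
    if not alignments:
        raise EmptyAlignmentError("nothing to concatenate")
    labels: list[str] = []
    for aln in alignments:
        for rec in aln:
            if rec.id not in labels:
                labels.append(rec.id)
    if not pad_missing:
        for k, aln in enumerate(alignments):
            ids = {rec.id for rec in aln}
            if ids != set(labels):
                raise RaggedAlignmentError(
                    f"partition {k}: label set differs (pad_missing=False)"
                )
    pieces = {lab: [] for lab in labels}
    for aln in alignments:
        ncol = aln.get_alignment_length()
        by_id = {rec.id: str(rec.seq) for rec in aln}
        for lab in labels:
            pieces[lab].append(by_id.get(lab, "-" * ncol))
    return MultipleSeqAlignment(
        [SeqRecord(Seq("".join(pieces[lab])), id=lab, description="") for lab in labels]
    )


def verify_supplementary_dimensions(directory: str | Path) -> dict[str, tuple[int, int]]:
    """Dimension report for user-supplied supplementary alignments.

    Expects FASTA files ``S1.fasta`` (ITS), ``S2.fasta`` (nuLSU),
    ``S3.fasta`` (mtSSU) and ``S4.fasta`` (extended ITS) in ``directory``;
    returns per-file and concatenated (terminals, columns) so published
    dimensions can be checked. Raises FileNotFoundError when absent.
    """
    directory = Path(directory)
    out: dict[str, tuple[int, int]] = {}
    parts = []
    for name in ("S1", "S2", "S3"):
        aln = read_alignment(directory / f"{name}.fasta", "fasta")
        out[name] = dimensions(aln)
        parts.append(aln)
    out["S1-S3_concatenated"] = dimensions(
        concatenate_alignments(parts, pad_missing=True)
    )
    out["S4"] = dimensions(read_alignment(directory / "S4.fasta", "fasta"))
    return out
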