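"""Scanning transcripts for ACUAA 5-mers and bipartite QREs.

The QKI response element (QRE) is a bipartite RNA motif: an upstream
half-site matching UACUAAY followed, after an unconstrained spacer of
1-20 nt, by a UAAY half-site.  T and U are equivalent everywhere;
Y = {C, T/U}.  Lowercase (masked) bases match; IUPAC-ambiguous subject
bases never match.

Target classification counts QREs on the mature (spliced) sequence of
the longest annotated transcript of each gene; the same matcher is used
on intron sequence by the RNA-map analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from qremap.io import AnnotationRecord

log = logging.getLogger("qremap")

_U2T = str.maketrans("Uu", "Tt")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: the 5-mer core half-site used for positional enrichment analysis
ACUAA = "ACTAA"

HALF1_LEN = 7
HALF2_LEN = 4
MIN_SPACER = 1
MAX_SPACER = 20


def _norm(seq: str) -> str:
    """Uppercase and map U to T so RNA and DNA spellings compare equal."""
    return seq.translate(_U2T).upper()


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def find_kmer_positions(seq: str, kmer: str) -> list[int]:
    """All 0-based offsets of ``kmer`` in ``seq``, overlapping occurrences included."""
    if len(kmer) < 1:
        raise ValueError("kmer must be non-empty")
    s, k = _norm(seq), _norm(kmer)
    out: list[int] = []
    i = s.find(k)
    while i != -1:
        out.append(i)
        i = s.find(k, i + 1)
    return out


@dataclass(frozen=True)
class QreMatch:
    """One bipartite QRE hit, in 0-based offsets on the scanned sequence."""

    half1_start: int
    half1_seq: str
    spacer_len: int
    half2_start: int
    half2_seq: str
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.half2_start != self.half1_start + HALF1_LEN + self.spacer_len:
            raise ValueError("inconsistent QRE coordinates")
        if not MIN_SPACER <= self.spacer_len <= MAX_SPACER:
            raise ValueError(f"spacer length {self.spacer_len} outside [{MIN_SPACER},{MAX_SPACER}]")


def _half1_at(s: str, i: int, first_pos: str) -> bool:
    if i + HALF1_LEN > len(s):
        return False
    first_ok = s[i] == "T" if first_pos == "U" else s[i] in "ACGT"
    return first_ok and s[i + 1 : i + 6] == "ACTAA" and s[i + 6] in "CT"


def _half2_at(s: str, j: int) -> bool:
    return j + HALF2_LEN <= len(s) and s[j : j + 3] == "TAA" and s[j + 3] in "CT"


def find_qre(
    seq: str,
    first_pos: str = "U",
    pairing: str = "greedy",
    transcript_id: str = "",
) -> list[QreMatch]:
    """Enumerate bipartite QRE matches in ``seq``, left to right.

    With ``pairing="greedy"`` (default) each upstream half-site is
    paired with the nearest downstream UAAY whose spacer lies in
    [1, 20]; scanning then resumes past that match's second half-site,
    so matches never overlap.  ``pairing="all"`` reports every
    (half-site, UAAY) combination with an admissible spacer.

    ``first_pos="U"`` uses the strict UACUAAY upstream half-site;
    ``first_pos="N"`` allows any base in the first position.
    """
    if pairing not in ("greedy", "all"):
        raise ValueError(f"unknown pairing {pairing!r}")
    s = _norm(seq)
    n = len(s)
    matches: list[QreMatch] = []

    def _match(i: int, j: int) -> QreMatch:
        return QreMatch(
            half1_start=i,
            half1_seq=seq[i : i + HALF1_LEN],
            spacer_len=j - i - HALF1_LEN,
            half2_start=j,
            half2_seq=seq[j : j + HALF2_LEN],
            transcript_id=transcript_id,
        )

    if pairing == "all":
        for i in range(n - HALF1_LEN - HALF2_LEN):
            if not _half1_at(s, i, first_pos):
                continue
            for spacer in range(MIN_SPACER, MAX_SPACER + 1):
                j = i + HALF1_LEN + spacer
                if _half2_at(s, j):
                    matches.append(_match(i, j))
        return matches

    i = 0
    while i <= n - (HALF1_LEN + MIN_SPACER + HALF2_LEN):
        if _half1_at(s, i, first_pos):
            for spacer in range(MIN_SPACER, MAX_SPACER + 1):
                j = i + HALF1_LEN + spacer
                if _half2_at(s, j):
                    matches.append(_match(i, j))
                    i = j + HALF2_LEN
                    break
            else:
                i += 1
        else:
            i += 1
    return matches


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered set of exon intervals on one chromosome."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # sorted by genomic start, half-open

    @property
    def mature_length(self) -> int:
        return sum(e - s for s, e in self.exons)


def transcript_models(annotation: list[AnnotationRecord]) -> list[TranscriptModel]:
    """Group exon records into :class:`TranscriptModel` objects."""
    by_tx: dict[str, list[AnnotationRecord]] = {}
    for rec in annotation:
        by_tx.setdefault(rec.transcript_id, []).append(rec)
    models = []
    for tx, recs in sorted(by_tx.items()):
        recs = sorted(recs, key=lambda r: r.start)
        models.append(
            TranscriptModel(
                gene_id=recs[0].gene_id,
                transcript_id=tx,
                chrom=recs[0].chrom,
                strand=recs[0].strand,
                exons=tuple((r.start, r.end) for r in recs),
            )
        )
    return models


def select_longest_transcript(models: list[TranscriptModel]) -> dict[str, TranscriptModel]:
    """Per gene, the transcript with maximal mature length.

    Ties are broken by the lexicographically smallest transcript_id so
    the selection is deterministic.
    """
    if not models:
        raise ValueError("no transcripts supplied")
    best: dict[str, TranscriptModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if (
            cur is None
            or m.mature_length > cur.mature_length
            or (m.mature_length == cur.mature_length and m.transcript_id < cur.transcript_id)
        ):
            best[m.gene_id] = m
    return best


def mature_sequence(model: TranscriptModel, sequences: dict[str, str]) -> str | None:
    """Spliced sense-strand sequence of a transcript, or None if unavailable.

    ``sequences`` may be keyed by transcript id (mature sequences) or by
    chromosome (genomic sequence, from which exons are spliced out and
    minus-strand transcripts reverse-complemented).
    """
    if model.transcript_id in sequences:
        return sequences[model.transcript_id]
    if model.chrom in sequences:
        chrom_seq = sequences[model.chrom]
        if model.exons[-1][1] > len(chrom_seq):
            return None
        spliced = "".join(chrom_seq[s:e] for s, e in model.exons)
        return reverse_complement(spliced) if model.strand == "-" else spliced
    return None


def count_qre_table(
    annotation: list[AnnotationRecord],
    sequences: dict[str, str],
    first_pos: str = "U",
    pairing: str = "greedy",
) -> pd.DataFrame:
    """Per-gene QRE and ACUAA counts on the longest annotated transcript.

    Genes whose sequence cannot be obtained get NA counts (and a logged
    warning); downstream analyses exclude NA rows rather than treating
    them as zero.
    """
    chosen = select_longest_transcript(transcript_models(annotation))
    rows = []
    for gene_id in sorted(chosen):
        model = chosen[gene_id]
        seq = mature_sequence(model, sequences)
        if seq is None:
            log.warning("no sequence for %s (%s); QRE count set to NA", gene_id, model.transcript_id)
            qre_n: object = pd.NA
            acuaa_n: object = pd.NA
        else:
            qre_n = len(find_qre(seq, first_pos=first_pos, pairing=pairing))
            acuaa_n = len(find_kmer_positions(seq, ACUAA))
        rows.append(
            {
                "gene_id": gene_id,
                "transcript_id": model.transcript_id,
                "qre_count": qre_n,
                "acuaa_count": acuaa_n,
            }
        )
    df = pd.DataFrame(rows, columns=["gene_id", "transcript_id", "qre_count", "acuaa_count"])
    df["qre_count"] = df["qre_count"].astype("Int64")
    df["acuaa_count"] = df["acuaa_count"].astype("Int64")
    return df
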