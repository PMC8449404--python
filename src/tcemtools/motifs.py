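"""T cell exposed motif (TCEM) extraction and proteome indexing.

A TCEM is the five-residue stretch of an HLA-I-bound peptide that contacts
the TCR CDR3 region: positions 4-8 of a 9-mer or 5-9 of a 10-mer (1-based).
The human proteome is decomposed into overlapping 9-mer windows; the TCEM of
each window is counted, so a motif's "frequency" is the number of 9-mer
windows exposing it, not the number of raw 5-mer substring hits.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Size of the pentamer motif space: every 5-letter word over the 20-letter
#: standard alphabet.
MOTIF_LENGTH = 5
WINDOW_LENGTH = 9
#: Offset of the motif within a 9-mer window (0-based start of position 4).
_MOTIF_OFFSET_9 = 3


def motif_space() -> Iterator[str]:
    """Lazily enumerate all pentamers over the standard alphabet (20^5)."""
    import itertools

    for letters in itertools.product(AMINO_ACIDS, repeat=MOTIF_LENGTH):
        yield "".join(letters)


def motif_space_size() -> int:
    """Cardinality of the pentamer motif space, by alphabet arithmetic."""
    return len(AMINO_ACIDS) ** MOTIF_LENGTH


def is_standard(sequence: str) -> bool:
    """True iff every residue is one of the 20 standard amino acids."""
    return all(ch in _AA_SET for ch in sequence)


def validate_motif(motif: str) -> str:
    if len(motif) != MOTIF_LENGTH:
        raise ValueError(f"motif must have length {MOTIF_LENGTH}, got {motif!r}")
    if not is_standard(motif):
        raise ValueError(f"motif contains non-standard letters: {motif!r}")
    return motif


def extract_tcem(peptide: str) -> str:
    """TCEM of an epitope peptide.

    Positions 4-8 (1-based) for 9-mers, 5-9 for 10-mers -- the residues left
    exposed between the HLA anchor positions.

    Raises
    ------
    ValueError
        If the peptide length is not 9 or 10, or it contains a non-standard
        amino-acid letter.
    """
    if len(peptide) not in (9, 10):
        raise ValueError(f"epitope peptide must be 9 or 10 residues, got {len(peptide)}")
    if not is_standard(peptide):
        raise ValueError(f"peptide contains non-standard letters: {peptide!r}")
    if len(peptide) == 9:
        return peptide[3:8]
    return peptide[4:9]


@dataclass
class ProteomeIndex:
    """TCEM occurrence index over a set of proteins.

    Attributes
    ----------
    proteins : list of (id, sequence)
        Input records, in input order.
    counts : Counter
        motif -> number of 9-mer windows exposing it.
    occurrences : dict
        motif -> list of (protein_id, window_start) with 1-based,
        fully-closed window starts.
    n_skipped_windows : int
        Windows dropped because they contained a non-standard letter.
    """

    proteins: list[tuple[str, str]] = field(default_factory=list)
    counts: Counter = field(default_factory=Counter)
    occurrences: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    n_skipped_windows: int = 0

    @classmethod
    def build(cls, proteins: Iterable[tuple[str, str]]) -> "ProteomeIndex":
        """Index an iterable of (protein-id, sequence) records.

        Each protein of length L >= 9 contributes L - 8 overlapping 9-mer
        windows; windows containing any non-standard letter are skipped and
        counted in ``n_skipped_windows``. Duplicate protein ids are an error
        (identical sequences under different ids are all counted).
        """
        index = cls()
        seen_ids: set[str] = set()
        for pid, seq in proteins:
            if pid in seen_ids:
                raise ValueError(f"duplicate protein id: {pid!r}")
            seen_ids.add(pid)
            seq = seq.upper()
            index.proteins.append((pid, seq))
            for start0 in range(len(seq) - WINDOW_LENGTH + 1):
                window = seq[start0 : start0 + WINDOW_LENGTH]
                if not is_standard(window):
                    index.n_skipped_windows += 1
                    continue
                motif = window[_MOTIF_OFFSET_9 : _MOTIF_OFFSET_9 + MOTIF_LENGTH]
                index.counts[motif] += 1
                index.occurrences.setdefault(motif, []).append((pid, start0 + 1))
        if index.n_skipped_windows:
            logger.info("skipped %d windows with non-standard letters", index.n_skipped_windows)
        if not index.proteins:
            raise ValueError("empty proteome: no protein records")
        return index

    @classmethod
    def from_fasta(cls, path) -> "ProteomeIndex":
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        return cls.build(records)

    def frequency(self, motif: str) -> int:
        """Number of 9-mer windows in the proteome exposing ``motif``."""
        validate_motif(motif)
        return self.counts.get(motif, 0)

    def total_windows(self) -> int:
        return sum(self.counts.values())

    def pentamer_space_coverage(self) -> float:
        """Fraction of the 20^5 motif space observed at least once."""
        return len(self.counts) / motif_space_size()

    def windows(self) -> Iterator[tuple[str, int, str]]:
        """Yield (protein_id, window_start_1based, window_sequence) for every
        standard-letter 9-mer window, in protein then position order."""
        for pid, seq in self.proteins:
            for start0 in range(len(seq) - WINDOW_LENGTH + 1):
                window = seq[start0 : start0 + WINDOW_LENGTH]
                if is_standard(window):
                    yield pid, start0 + 1, window


def build_proteome_index(proteins: Iterable[tuple[str, str]]) -> ProteomeIndex:
    """Functional wrapper over :meth:`ProteomeIndex.build`."""
    return ProteomeIndex.build(proteins)


def tcem_frequency(index: ProteomeIndex, motif: str) -> int:
    return index.frequency(motif)


def classify_frequency(count: int, threshold: int = 4) -> str:
    """Classify a motif as ``"rare"`` (count < threshold) or ``"nonrare"``.

    Motifs seen fewer than four times in the human proteome are unlikely to
    be presented on cTECs during positive selection.
    """
    if count < 0:
        raise ValueError(f"count must be nonnegative, got {count}")
    return "rare" if count < threshold else "nonrare"


def pentamer_space_coverage(index: ProteomeIndex) -> float:
    return index.pentamer_space_coverage()
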