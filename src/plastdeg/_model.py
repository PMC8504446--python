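"""Core data model: annotated circular plastomes and degradation-state matrices.

Coordinates are 0-based half-open throughout. A feature on a circular
molecule that crosses the sequence origin is stored as an explicit
multi-interval location (e.g. ``[(150000, 154000), (0, 500)]``), never by
doubling the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """A gene annotation: symbol, kind, strand, and exon intervals.

    ``location`` is an ordered list of half-open intervals in transcription
    order; a feature wrapping the origin of a circular record carries two
    (or more) intervals.
    """

    gene: str
    kind: str  # CDS | tRNA | rRNA
    strand: str  # '+' | '-'
    location: tuple[tuple[int, int], ...]
    pseudo: bool = False

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if self.kind not in ("CDS", "tRNA", "rRNA"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.location or any(b <= a for a, b in self.location):
            raise ValueError(f"{self.gene}: intervals must be non-empty")
        object.__setattr__(self, "location", tuple((int(a), int(b)) for a, b in self.location))

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.location)

    @property
    def start(self) -> int:
        return self.location[0][0]

    @property
    def end(self) -> int:
        return self.location[-1][1]

    def extract(self, sequence: str) -> str:
        """Spliced feature sequence on the coding strand."""
        parts = [sequence[a:b] for a, b in self.location]
        if self.strand == "-":
            # intervals are stored in transcription order: for a minus-strand
            # feature the first interval is the 3'-most on the forward strand
            return "".join(revcomp(p) for p in parts)
        return "".join(parts)


@dataclass
class PlastomeRecord:
    """One circular annotated plastid genome."""

    id: str
    taxon: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.id}: non-ACGTN symbols {sorted(bad)}")
        n = len(self.sequence)
        for f in self.features:
            for a, b in f.location:
                if not (0 <= a < b <= n):
                    raise ValueError(
                        f"{self.id}: feature {f.gene} interval ({a}, {b}) "
                        f"outside [0, {n})"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def genes(self, symbol: str) -> list[GeneFeature]:
        return [f for f in self.features if f.gene == symbol]

    def rotated(self, offset: int) -> "PlastomeRecord":
        """Record with the sequence origin moved to ``offset`` (circular only)."""
        if not self.circular:
            raise ValueError("cannot rotate a linear record")
        n = len(self.sequence)
        offset %= n
        seq = self.sequence[offset:] + self.sequence[:offset]
        feats = []
        for f in self.features:
            loc = []
            for a, b in f.location:
                a2, b2 = (a - offset) % n, (b - offset) % n
                if b2 == 0:
                    b2 = n
                if a2 < b2:
                    loc.append((a2, b2))
                else:  # interval now wraps the new origin
                    loc.append((a2, n))
                    loc.append((0, b2))
            feats.append(replace(f, location=tuple(loc)))
        return PlastomeRecord(self.id, self.taxon, seq, feats, circular=True)


# -- degradation-state matrix -------------------------------------------------

STATE_FUNCTIONAL = 0
STATE_PREMATURE_STOP = 1
STATE_TRUNCATED = 2
STATE_LOST = 3


@dataclass
class CharacterMatrix:
    """Taxa x gene matrix of degradation states.

    Values live in ``alphabet`` (``(0, 1, 2, 3)`` for the four-state code,
    ``(0, 1)`` after binarization). Backed by a pandas DataFrame with taxa
    as the index and gene symbols as columns.
    """

    data: pd.DataFrame
    alphabet: tuple[int, ...] = (0, 1, 2, 3)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate taxa in character matrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate gene columns in character matrix")
        vals = set(self.data.to_numpy().ravel().tolist())
        if not vals <= set(self.alphabet):
            raise ValueError(f"states {sorted(vals - set(self.alphabet))} outside alphabet")

    @classmethod
    def from_dict(
        cls,
        states: dict[str, dict[str, int]],
        taxa: Sequence[str] | None = None,
        genes: Sequence[str] | None = None,
        alphabet: tuple[int, ...] = (0, 1, 2, 3),
    ) -> "CharacterMatrix":
        df = pd.DataFrame.from_dict(states, orient="index").fillna(0).astype(int)
        if taxa is not None:
            df = df.reindex(list(taxa)).fillna(0).astype(int)
        if genes is not None:
            for g in genes:
                if g not in df.columns:
                    df[g] = 0
            df = df[list(genes)]
        return cls(df, alphabet)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    def column(self, gene: str) -> dict[str, int]:
        return self.data[gene].to_dict()

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="taxon")

    @classmethod
    def read_tsv(cls, path, alphabet: tuple[int, ...] = (0, 1, 2, 3)) -> "CharacterMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0).astype(int)
        df.index.name = "taxon"
        return cls(df, alphabet)
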