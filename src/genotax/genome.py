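"""Core sequence containers: replicons and multi-replicon genome assemblies.

A bacterial assembly is modelled as an ordered set of replicons (the
chromosome plus zero or more plasmids), each a single DNA sequence with a
known-or-claimed topology. Rhizobial genomes in particular carry a high-GC
chromosome and several megaplasmids of visibly lower GC, which is why GC
content is a first-class attribute here.

Coordinates are 0-based, half-open throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DNA_ALPHABET = "ACGT"
_BASE_TO_INT = {b: i for i, b in enumerate(DNA_ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def seq_to_ints(seq: str) -> np.ndarray:
    """Encode an ACGT string as uint8 codes 0..3."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _BASE_TO_INT.items():
        out[arr == ord(base)] = code
    if (out == 255).any():
        bad = chr(arr[out == 255][0])
        raise ValueError(f"sequence contains non-ACGT character {bad!r}")
    return out


def ints_to_seq(codes: np.ndarray) -> str:
    lut = np.frombuffer(DNA_ALPHABET.encode("ascii"), dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass
class Replicon:
    """One assembled sequence: chromosome or plasmid, circular or linear."""

    id: str
    seq: str
    circular: bool = False
    role_truth: str = "chromosome"  # {"chromosome", "plasmid"}

    def __post_init__(self) -> None:
        if len(self.seq) == 0:
            raise ValueError(f"replicon {self.id!r} has empty sequence")
        if self.role_truth not in ("chromosome", "plasmid"):
            raise ValueError(f"unknown replicon role {self.role_truth!r}")
        # Cheap alphabet check without a full scan per base.
        stripped = (
            self.seq.count("A") + self.seq.count("C")
            + self.seq.count("G") + self.seq.count("T")
        )
        if stripped != len(self.seq):
            raise ValueError(
                f"replicon {self.id!r} contains characters outside {{A,C,G,T}}"
            )

    @property
    def gc(self) -> float:
        """G+C fraction of the sequence, computed, never stored stale."""
        return gc_fraction(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Genome:
    """An assembled strain: ordered replicons plus a strain identifier."""

    strain_id: str
    replicons: list[Replicon] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.replicons:
            raise ValueError(f"genome {self.strain_id!r} has no replicons")
        if not any(r.role_truth == "chromosome" for r in self.replicons):
            raise ValueError(
                f"genome {self.strain_id!r} has no chromosome-candidate replicon"
            )
        ids = [r.id for r in self.replicons]
        if len(set(ids)) != len(ids):
            raise ValueError(f"genome {self.strain_id!r} has duplicate replicon ids")

    @property
    def size(self) -> int:
        return sum(len(r) for r in self.replicons)

    @property
    def chromosome(self) -> Replicon:
        return next(r for r in self.replicons if r.role_truth == "chromosome")

    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.id == replicon_id:
                return r
        raise KeyError(replicon_id)
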