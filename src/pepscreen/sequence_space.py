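"""Peptide sequence spaces, residue classification and screening-set rules.

The screening unit is a peptide written as a one-letter string over the 20
gene-encoded amino acids.  Two restricted alphabets recur throughout the
screen: the 17-letter alphabet that drops the aromatic residues F, W and Y
(their strong self-assembly makes them undesirable in food-grade
emulsifiers), and the 13-letter alphabet that additionally drops the charged
residues R, K, E and D, whose solvation suppresses interfacial adsorption.

A tetrapeptide screening set is assembled from three rules:

1. every single-residue extension (N- or C-terminal) of a list of
   high-adsorption "hit" tripeptides, over the 17-letter alphabet;
2. every tetrapeptide over the 13-letter alphabet carrying L or I at a
   terminal position;
3. a negative-control set: every 17-letter tetrapeptide containing the
   di-arginine motif RR.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "CANONICAL_RESIDUES",
    "Alphabet",
    "FULL_ALPHABET",
    "NO_AROMATIC_ALPHABET",
    "REDUCED_ALPHABET",
    "ResidueClass",
    "ScreeningRules",
    "enumerate_sequences",
    "contains_motif",
    "extend_tripeptide",
    "build_screening_set",
    "classify_residue",
    "amphiphilicity_pattern",
    "net_charge",
    "validate_sequence",
    "read_sequences",
    "write_sequences",
]

#: The 20 gene-encoded amino acids, alphabetical by one-letter code.
CANONICAL_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

#: Side-chain charge at neutral pH.  Histidine is treated as neutral.
SIDE_CHAIN_CHARGE: Mapping[str, int] = {
    **{aa: 0 for aa in CANONICAL_RESIDUES},
    "K": +1,
    "R": +1,
    "D": -1,
    "E": -1,
}

#: Standard hydropathy split.  Only H (polar) and G/I (nonpolar) are fixed by
#: the screen's design rationale; the rest follow the conventional table and
#: may be overridden where a different split is wanted.
NONPOLAR_RESIDUES: frozenset[str] = frozenset("AVLIMPGCFWY")
POLAR_RESIDUES: frozenset[str] = frozenset("STNQHRKDE")


class Alphabet:
    """An ordered, duplicate-free subset of the 20 canonical residues.

    Residues are kept in alphabetical (canonical) order regardless of the
    order given, so enumeration output is reproducible.
    """

    __slots__ = ("residues",)

    def __init__(self, residues: Iterable[str]):
        letters = list(residues)
        if not letters:
            raise ValueError("alphabet must be non-empty")
        bad = [aa for aa in letters if aa not in CANONICAL_RESIDUES]
        if bad:
            raise ValueError(f"non-canonical residue codes: {bad!r}")
        if len(set(letters)) != len(letters):
            raise ValueError("duplicate residues in alphabet")
        self.residues: tuple[str, ...] = tuple(sorted(letters))

    @classmethod
    def excluding(cls, excluded: Iterable[str]) -> "Alphabet":
        """The canonical alphabet minus ``excluded``."""
        dropped = set(excluded)
        return cls(aa for aa in CANONICAL_RESIDUES if aa not in dropped)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def __contains__(self, item: str) -> bool:
        return item in self.residues

    def __eq__(self, other) -> bool:
        return isinstance(other, Alphabet) and self.residues == other.residues

    def __hash__(self) -> int:
        return hash(self.residues)

    def __repr__(self) -> str:
        return f"Alphabet({''.join(self.residues)!r})"


#: All 20 gene-encoded residues.
FULL_ALPHABET = Alphabet(CANONICAL_RESIDUES)
#: 17 letters: aromatics F, W, Y excluded.
NO_AROMATIC_ALPHABET = Alphabet.excluding("FWY")
#: 13 letters: aromatics and charged residues R, K, E, D excluded.
REDUCED_ALPHABET = Alphabet.excluding("FWYRKED")


def validate_sequence(seq: str) -> str:
    """Check that ``seq`` is a non-empty canonical one-letter string."""
    if not isinstance(seq, str) or not seq:
        raise ValueError("peptide sequence must be a non-empty string")
    bad = [aa for aa in seq if aa not in CANONICAL_RESIDUES]
    if bad:
        raise ValueError(f"non-canonical residues {bad!r} in sequence {seq!r}")
    return seq


@dataclass(frozen=True)
class ResidueClass:
    """Charge and polarity class of one amino acid."""

    code: str
    charge: int
    polarity: str  # "polar" | "nonpolar"


@dataclass
class ScreeningRules:
    """Parameters of the three tetrapeptide screening-set rules."""

    hit_tripeptides: list[str] = field(default_factory=list)
    extension_alphabet: Alphabet = NO_AROMATIC_ALPHABET
    terminal_residues: frozenset[str] = frozenset("LI")
    reduced_alphabet: Alphabet = REDUCED_ALPHABET
    control_motif: str = "RR"
    control_alphabet: Alphabet = NO_AROMATIC_ALPHABET
    length: int = 4

    def __post_init__(self) -> None:
        for tri in self.hit_tripeptides:
            validate_sequence(tri)
            if len(tri) != 3:
                raise ValueError(f"hit tripeptide {tri!r} does not have length 3")
        self.terminal_residues = frozenset(self.terminal_residues)
        if not self.terminal_residues <= set(self.reduced_alphabet):
            raise ValueError("terminal residues must lie in the reduced alphabet")

    @classmethod
    def from_file(cls, path: str | Path) -> "ScreeningRules":
        """Load rules from a YAML/JSON config mirroring the field names."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs: dict = {}
        if "hit_tripeptides" in raw:
            kwargs["hit_tripeptides"] = list(raw["hit_tripeptides"])
        for key in ("extension_alphabet", "reduced_alphabet", "control_alphabet"):
            if key in raw:
                kwargs[key] = Alphabet(raw[key])
        if "terminal_residues" in raw:
            kwargs["terminal_residues"] = frozenset(raw["terminal_residues"])
        if "control_motif" in raw:
            kwargs["control_motif"] = str(raw["control_motif"])
        if "length" in raw:
            kwargs["length"] = int(raw["length"])
        return cls(**kwargs)


def enumerate_sequences(length: int, alphabet: Alphabet) -> list[str]:
    """All ``|alphabet| ** length`` sequences in lexicographic order.

    Examples
    --------
    >>> len(enumerate_sequences(3, NO_AROMATIC_ALPHABET))
    4913
    """
    if length < 1:
        raise ValueError("sequence length must be >= 1")
    return ["".join(p) for p in itertools.product(alphabet.residues, repeat=length)]


def contains_motif(seq: str, motif: str) -> bool:
    """True iff ``motif`` occurs as a contiguous substring of ``seq``."""
    if not motif:
        raise ValueError("motif must be non-empty")
    return motif in validate_sequence(seq)


def extend_tripeptide(tri: str, alphabet: Alphabet) -> set[str]:
    """All single-residue N- or C-terminal extensions of a tripeptide.

    Returns the set ``{a + tri, tri + a : a in alphabet}``; its size is
    ``2 * |alphabet|`` unless prepending and appending coincide (which
    requires ``a + tri == tri + a``, i.e. a homo-tripeptide extended by its
    own residue).
    """
    validate_sequence(tri)
    if len(tri) != 3:
        raise ValueError(f"expected a tripeptide, got {tri!r}")
    return {a + tri for a in alphabet} | {tri + a for a in alphabet}


def rule_predicates(rules: ScreeningRules):
    """The three membership predicates, as functions of a sequence.

    Exposed so the assembled screening set can be cross-checked against a
    plain filter over a full enumeration.
    """
    hits = set(rules.hit_tripeptides)
    ext = set(rules.extension_alphabet)
    red = set(rules.reduced_alphabet)
    ctrl = set(rules.control_alphabet)
    n = rules.length

    def rule1(seq: str) -> bool:
        return (
            len(seq) == 4
            and bool(hits)
            and set(seq) <= ext
            and (seq[:3] in hits or seq[1:] in hits)
        )

    def rule2(seq: str) -> bool:
        return (
            len(seq) == n
            and set(seq) <= red
            and (seq[0] in rules.terminal_residues or seq[-1] in rules.terminal_residues)
        )

    def rule3(seq: str) -> bool:
        return (
            len(seq) == n
            and len(rules.control_motif) <= n
            and set(seq) <= ctrl
            and rules.control_motif in seq
        )

    return rule1, rule2, rule3


def build_screening_set(rules: ScreeningRules):
    """Assemble the screening set; one row per unique sequence.

    Returns a :class:`pandas.DataFrame` sorted by sequence with boolean
    columns ``rule1``/``rule2``/``rule3`` recording which rules admitted each
    sequence, so the control subset remains recoverable after deduplication.
    """
    import pandas as pd

    members: dict[str, list[bool]] = {}

    def admit(seq: str, which: int) -> None:
        flags = members.setdefault(seq, [False, False, False])
        flags[which] = True

    for tri in rules.hit_tripeptides:
        for seq in extend_tripeptide(tri, rules.extension_alphabet):
            admit(seq, 0)

    if rules.terminal_residues:
        inner = enumerate_sequences(rules.length - 1, rules.reduced_alphabet) if rules.length > 1 else [""]
        for t in sorted(rules.terminal_residues):
            for body in inner:
                admit(t + body, 1)
                admit(body + t, 1)

    if len(rules.control_motif) <= rules.length:
        for seq in enumerate_sequences(rules.length, rules.control_alphabet):
            if rules.control_motif in seq:
                admit(seq, 2)

    ordered = sorted(members)
    return pd.DataFrame(
        {
            "sequence": ordered,
            "rule1": [members[s][0] for s in ordered],
            "rule2": [members[s][1] for s in ordered],
            "rule3": [members[s][2] for s in ordered],
        }
    )


def classify_residue(code: str, polar: frozenset[str] = POLAR_RESIDUES) -> ResidueClass:
    """Fixed charge/polarity record for one canonical residue."""
    if code not in CANONICAL_RESIDUES:
        raise ValueError(f"unknown residue code {code!r}")
    return ResidueClass(
        code=code,
        charge=SIDE_CHAIN_CHARGE[code],
        polarity="polar" if code in polar else "nonpolar",
    )


def amphiphilicity_pattern(seq: str, polar: frozenset[str] = POLAR_RESIDUES) -> str:
    """Hyphen-joined p/n pattern, e.g. ``"HGII" -> "p-n-n-n"``.

    The p-n reduction reads a sequence as a surfactant: a polar head and a
    nonpolar tail make the classic amphiphile.
    """
    validate_sequence(seq)
    return "-".join(classify_residue(aa, polar).polarity[0] for aa in seq)


def net_charge(seq: str) -> int:
    """Sum of side-chain charges; zwitterionic termini contribute net zero."""
    validate_sequence(seq)
    return sum(SIDE_CHAIN_CHARGE[aa] for aa in seq)


def write_sequences(seqs: Sequence[str], path: str | Path, fmt: str = "txt") -> None:
    """Write sequences one-per-line (``txt``) or as FASTA (``fasta``).

    In FASTA output the record id is the peptide string itself.
    """
    path = Path(path)
    if fmt == "txt":
        path.write_text("".join(f"{s}\n" for s in seqs))
    elif fmt == "fasta":
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [SeqRecord(Seq(s), id=s, description="") for s in seqs]
        seqio_write(records, str(path), "fasta")
    else:
        raise ValueError(f"unknown sequence format {fmt!r}")


def read_sequences(path: str | Path, fmt: str = "txt") -> list[str]:
    """Read sequences written by :func:`write_sequences`."""
    path = Path(path)
    if fmt == "txt":
        seqs = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    elif fmt == "fasta":
        from Bio.SeqIO import parse as seqio_parse

        seqs = [str(rec.seq) for rec in seqio_parse(str(path), "fasta")]
    else:
        raise ValueError(f"unknown sequence format {fmt!r}")
    return [validate_sequence(s) for s in seqs]
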