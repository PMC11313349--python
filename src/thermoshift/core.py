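"""Domain types for missense-mutation thermostability data.

A dataset row pairs a protein sequence with a single amino-acid
substitution (written ``K79I``: wild residue, 1-based position, mutant
residue), optional environmental conditions (pH, wild-type melting
temperature Tm in degC) and an optional measured melting-temperature
change dTm = Tm(mutant) - Tm(wild) in degC.

Only the 20 canonical residues are accepted.  Records carrying
nonstandard letters (X, B, Z, U, O, ...) are rejected rather than
imputed: every downstream property lookup (AAindex, PSSM, scales)
assumes the canonical alphabet and silent imputation would corrupt
those features.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

#: The 20 canonical one-letter residue codes, alphabetical.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Canonical column order for per-residue score vectors: the order used
#: by PSI-BLAST's ASCII PSSM output, adopted for bit-compatibility.
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"

_CANONICAL_SET = frozenset(CANONICAL_AA)

_MUTATION_RE = re.compile(r"^([A-Za-z])([0-9]+)([A-Za-z])$")


class ThermoshiftError(Exception):
    """Base class for package errors."""


class MutationParseError(ThermoshiftError):
    """Raised for malformed or invalid mutation strings."""


class MutationBindingError(ThermoshiftError):
    """Raised when a mutation does not fit the protein it is bound to."""


class SequenceAlphabetError(ThermoshiftError):
    """Raised for sequences containing non-canonical residue letters."""


@dataclass(frozen=True)
class ProteinRecord:
    """A named protein sequence over the canonical 20-letter alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise SequenceAlphabetError(f"{self.id}: empty sequence")
        bad = sorted(set(self.sequence) - _CANONICAL_SET)
        if bad:
            raise SequenceAlphabetError(
                f"{self.id}: non-canonical residue letter(s) {''.join(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Mutation:
    """Single amino-acid substitution with a 1-based position."""

    wild: str
    position: int
    mutant: str

    def __post_init__(self) -> None:
        for res, what in ((self.wild, "wild"), (self.mutant, "mutant")):
            if res not in _CANONICAL_SET:
                raise MutationParseError(f"non-canonical {what} residue {res!r}")
        if self.position < 1:
            raise MutationParseError(f"position must be >= 1, got {self.position}")
        if self.wild == self.mutant:
            raise MutationParseError(
                f"silent substitution {self.wild}{self.position}{self.mutant} rejected"
            )

    def __str__(self) -> str:
        return f"{self.wild}{self.position}{self.mutant}"

    def reverse(self) -> "Mutation":
        """The inverse substitution (mutant back to wild) at the same site."""
        return Mutation(self.mutant, self.position, self.wild)


@dataclass(frozen=True)
class Condition:
    """Environmental conditions of a melting measurement.

    Either field may be absent (None).  pH is unitless in [0, 14];
    ``tm_wild`` is the wild-type melting temperature in degC.
    """

    ph: float | None = None
    tm_wild: float | None = None

    def __post_init__(self) -> None:
        if self.ph is not None and not (0.0 <= self.ph <= 14.0):
            raise ValueError(f"pH {self.ph} outside [0, 14]")
        if self.tm_wild is not None and not _finite(self.tm_wild):
            raise ValueError(f"tm_wild must be finite, got {self.tm_wild}")


@dataclass(frozen=True)
class MutationRecord:
    """One observation: protein, substitution, conditions, optional label."""

    protein_id: str
    mutation: Mutation
    condition: Condition = field(default_factory=Condition)
    delta_tm: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.delta_tm is not None and not _finite(self.delta_tm):
            raise ValueError(f"delta_tm must be finite, got {self.delta_tm}")

    @property
    def key(self) -> tuple[str, str]:
        """(protein id, mutation string) — identifies the variant."""
        return (self.protein_id, str(self.mutation))

    @property
    def record_id(self) -> str:
        parts = [self.protein_id, str(self.mutation)]
        if self.condition.ph is not None:
            parts.append(f"pH{self.condition.ph:g}")
        if self.condition.tm_wild is not None:
            parts.append(f"Tm{self.condition.tm_wild:g}")
        return "|".join(parts)


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


# ---------------------------------------------------------------------------
# Residue grouping

#: Group labels in fixed order; indexes into the 6x6 transition matrix.
GROUP_LABELS = (
    "hydrophobic",
    "negative",
    "positive",
    "conformational",
    "polar",
    "other",
)

#: Partition of the 20 residues into six physicochemical groups:
#: hydrophobic (V I L F M W Y C), negatively charged (D E), positively
#: charged (R K H), conformational (G P), polar (N Q S), others (A T).
SIX_GROUPS: dict[str, str] = {}
for _res in "VILFMWYC":
    SIX_GROUPS[_res] = "hydrophobic"
for _res in "DE":
    SIX_GROUPS[_res] = "negative"
for _res in "RKH":
    SIX_GROUPS[_res] = "positive"
for _res in "GP":
    SIX_GROUPS[_res] = "conformational"
for _res in "NQS":
    SIX_GROUPS[_res] = "polar"
for _res in "AT":
    SIX_GROUPS[_res] = "other"
del _res


# ---------------------------------------------------------------------------
# Parsing / validation / application


def parse_mutation(text: str) -> Mutation:
    """Parse a mutation string like ``K79I`` (case-insensitive).

    Raises :class:`MutationParseError` for malformed strings, silent
    substitutions (wild == mutant) and non-canonical residue letters.
    """
    m = _MUTATION_RE.match(text.strip())
    if m is None:
        raise MutationParseError(f"malformed mutation string {text!r}")
    wild, pos, mutant = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    if pos < 1:
        raise MutationParseError(f"position must be >= 1 in {text!r}")
    return Mutation(wild, pos, mutant)


def format_mutation(mutation: Mutation) -> str:
    """Canonical upper-case string form, inverse of :func:`parse_mutation`."""
    return str(mutation)


def bind_and_validate(
    protein: ProteinRecord, mutation: Mutation
) -> tuple[ProteinRecord, Mutation]:
    """Check that *mutation* fits *protein*; return the pair unchanged.

    The position must lie within the sequence (1-based) and the sequence
    residue there must equal the stated wild residue.
    """
    if not (1 <= mutation.position <= len(protein)):
        raise MutationBindingError(
            f"{protein.id}: position {mutation.position} out of range "
            f"(length {len(protein)})"
        )
    found = protein.sequence[mutation.position - 1]
    if found != mutation.wild:
        raise MutationBindingError(
            f"{protein.id}: expected {mutation.wild} at position "
            f"{mutation.position}, sequence has {found}"
        )
    return protein, mutation


def apply_mutation(protein: ProteinRecord, mutation: Mutation) -> str:
    """Return the mutant sequence (validates the binding first)."""
    bind_and_validate(protein, mutation)
    i = mutation.position - 1
    return protein.sequence[:i] + mutation.mutant + protein.sequence[i + 1 :]
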