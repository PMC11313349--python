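"""Hand-crafted sequence feature families.

Seven extractor families, each emitting named columns:

- AAindex differences / pair-matrix lookups (one column per entry)
- neighborhood residue frequencies in a 25-residue window (20 columns)
- 6x6 physicochemical group-transition one-hot (36 columns)
- PSSM sectioning: 20 sections x 20 score columns (400 columns)
- whole-protein physicochemical quantities (7 columns)
- SIFT deleteriousness annotations (3 columns)
- amino-acid scale differences (one column per configured scale)

plus the environmental covariates (pH, wild-type Tm) of the chosen
dataset variant.  Extractors are pure functions of their inputs; the
orchestrator :func:`extract_traditional` assembles a FeatureTable and
drops records whose required resources are missing (or imputes, by
explicit policy).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.SeqUtils.ProtParam import ProteinAnalysis

from ..core import (
    GROUP_LABELS,
    PSIBLAST_ORDER,
    SIX_GROUPS,
    Mutation,
    MutationRecord,
    ProteinRecord,
    ThermoshiftError,
    bind_and_validate,
)
from ..dataio import PSSM, AAindexEntry, ScaleSet, SiftRecord, fallback_pssm
from .table import FeatureTable

logger = logging.getLogger(__name__)

#: Window width (residues) for neighborhood frequencies: site +/- 12.
NEIGHBORHOOD_WINDOW = 25

#: Number of contiguous PSSM sections averaged per score column.
PSSM_SECTIONS = 20


class FeatureExtractionError(ThermoshiftError):
    """Raised when a record cannot be featurized; carries a reason tag."""

    def __init__(self, reason: str, message: str = "") -> None:
        super().__init__(message or reason)
        self.reason = reason


# ---------------------------------------------------------------------------
# AAindex


def aaindex_features(
    mutation: Mutation, entries: Sequence[AAindexEntry]
) -> dict[str, float]:
    """One column per AAindex entry.

    Kind-1 entries contribute ``value(mutant) - value(wild)``; kind-2/3
    entries contribute the matrix cell ``[wild, mutant]``.  A queried
    NaN cell raises (policy applied by the orchestrator).
    """
    out: dict[str, float] = {}
    for e in entries:
        name = f"aaindex{e.kind}_{e.accession}"
        if e.kind == 1:
            assert e.index is not None
            val = e.index[mutation.mutant] - e.index[mutation.wild]
        else:
            val = e.pair_value(mutation.wild, mutation.mutant)
        if math.isnan(val):
            raise FeatureExtractionError(
                "aaindex_na",
                f"{e.accession}[{mutation.wild},{mutation.mutant}] is NA",
            )
        out[name] = float(val)
    return out


# ---------------------------------------------------------------------------
# Neighborhood frequencies


def neighborhood_features(
    protein: ProteinRecord, mutation: Mutation
) -> dict[str, float]:
    """Residue frequencies in the window centered on the mutation site.

    The window spans site +/- 12 on the wild-type sequence, clipped at
    the termini; frequencies are normalized by the clipped window size
    and therefore always sum to 1.
    """
    bind_and_validate(protein, mutation)
    half = (NEIGHBORHOOD_WINDOW - 1) // 2
    lo = max(1, mutation.position - half)
    hi = min(len(protein), mutation.position + half)
    window = protein.sequence[lo - 1 : hi]
    counts = Counter(window)
    n = len(window)
    return {f"neigh_freq_{res}": counts.get(res, 0) / n for res in PSIBLAST_ORDER}


# ---------------------------------------------------------------------------
# Group transitions


def grouping_features(
    mutation: Mutation, scheme: Mapping[str, str] = SIX_GROUPS
) -> dict[str, float]:
    """One-hot over the 6x6 (wild group, mutant group) transition cells."""
    wg = scheme[mutation.wild]
    mg = scheme[mutation.mutant]
    return {
        f"group_{a}_to_{b}": 1.0 if (a == wg and b == mg) else 0.0
        for a in GROUP_LABELS
        for b in GROUP_LABELS
    }


# ---------------------------------------------------------------------------
# PSSM sectioning


def pssm_section_bounds(length: int, sections: int = PSSM_SECTIONS) -> list[tuple[int, int]]:
    """Balanced partition of ``range(length)`` into contiguous sections.

    The first ``length % sections`` sections get ``ceil(length/sections)``
    positions, the rest ``floor``; 0-based half-open bounds.
    """
    if length < sections:
        raise FeatureExtractionError(
            "sequence_too_short", f"length {length} < {sections} sections"
        )
    base, extra = divmod(length, sections)
    bounds = []
    start = 0
    for i in range(sections):
        size = base + (1 if i < extra else 0)
        bounds.append((start, start + size))
        start += size
    return bounds


def pssm_features(protein: ProteinRecord, pssm: PSSM) -> dict[str, float]:
    """Sectioned PSSM means: 20 sections x 20 score columns = 400.

    Ordered section-major: all 20 residue columns of section 1, then
    section 2, ...  Sequences shorter than 20 residues cannot be
    sectioned and raise ``sequence_too_short``.
    """
    if pssm.residues != protein.sequence:
        raise FeatureExtractionError(
            "pssm_mismatch", f"PSSM rows do not match {protein.id}"
        )
    out: dict[str, float] = {}
    for s, (lo, hi) in enumerate(pssm_section_bounds(len(protein)), start=1):
        means = pssm.scores[lo:hi].mean(axis=0)
        for j, res in enumerate(PSIBLAST_ORDER):
            out[f"pssm_s{s:02d}_{res}"] = float(means[j])
    return out


# ---------------------------------------------------------------------------
# Whole-protein physicochemical quantities

# Atom counts (C, H, N, O, S) of the free amino acids; residues in a
# chain lose one water (2 H + 1 O) per peptide bond.
_FORMULAS: dict[str, tuple[int, int, int, int, int]] = {
    "A": (3, 7, 1, 2, 0),
    "R": (6, 14, 4, 2, 0),
    "N": (4, 8, 2, 3, 0),
    "D": (4, 7, 1, 4, 0),
    "C": (3, 7, 1, 2, 1),
    "Q": (5, 10, 2, 3, 0),
    "E": (5, 9, 1, 4, 0),
    "G": (2, 5, 1, 2, 0),
    "H": (6, 9, 3, 2, 0),
    "I": (6, 13, 1, 2, 0),
    "L": (6, 13, 1, 2, 0),
    "K": (6, 14, 2, 2, 0),
    "M": (5, 11, 1, 2, 1),
    "F": (9, 11, 1, 2, 0),
    "P": (5, 9, 1, 2, 0),
    "S": (3, 7, 1, 3, 0),
    "T": (4, 9, 1, 3, 0),
    "W": (11, 12, 2, 2, 0),
    "Y": (9, 11, 1, 3, 0),
    "V": (5, 11, 1, 2, 0),
}


def total_atoms(sequence: str) -> int:
    """Total atom count of the polypeptide (free residues minus one
    three-atom water per peptide bond)."""
    atoms = sum(sum(_FORMULAS[res]) for res in sequence)
    return atoms - 3 * (len(sequence) - 1)


def aliphatic_index(sequence: str) -> float:
    """Relative volume occupied by aliphatic side chains:
    X(Ala) + 2.9 X(Val) + 3.9 (X(Ile) + X(Leu)), X in mole percent."""
    n = len(sequence)
    x = {res: 100.0 * sequence.count(res) / n for res in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def physicochemical_features(protein: ProteinRecord) -> dict[str, float]:
    """Seven whole-protein quantities computed from the wild sequence:
    residue count, average molecular weight, theoretical pI, total atom
    count, molar extinction coefficient at 280 nm (Trp/Tyr/cystine),
    instability index and aliphatic index."""
    pa = ProteinAnalysis(protein.sequence)
    _, ext_cystines = pa.molar_extinction_coefficient()
    return {
        "param_length": float(len(protein)),
        "param_mol_weight": float(pa.molecular_weight()),
        "param_pi": float(pa.isoelectric_point()),
        "param_atoms": float(total_atoms(protein.sequence)),
        "param_extinction": float(ext_cystines),
        "param_instability": float(pa.instability_index()),
        "param_aliphatic": aliphatic_index(protein.sequence),
    }


# ---------------------------------------------------------------------------
# SIFT annotations

#: Neutral imputation values used when a variant is unscored and the
#: policy is ``impute``: benign score, typical diversity median, no
#: aligned sequences.
SIFT_NEUTRAL = SiftRecord(sift_score=1.0, sift_median=3.0, num_seq=0)


def sift_features(
    record: MutationRecord,
    sift_map: Mapping[tuple[str, str], SiftRecord],
    policy: str = "drop",
    neutral: SiftRecord = SIFT_NEUTRAL,
) -> dict[str, float]:
    """SIFT score, conservation median and aligned-sequence count."""
    rec = sift_map.get(record.key)
    if rec is None:
        if policy == "impute":
            rec = neutral
        else:
            raise FeatureExtractionError(
                "no_sift", f"no SIFT record for {record.key}"
            )
    return {
        "sift_score": rec.sift_score,
        "sift_median": rec.sift_median,
        "sift_num_seq": float(rec.num_seq),
    }


# ---------------------------------------------------------------------------
# Scales


def scale_features(mutation: Mutation, scales: ScaleSet) -> dict[str, float]:
    """Per scale: value(mutant) - value(wild); antisymmetric under
    wild/mutant swap."""
    return {
        f"scale_{name}": table[mutation.mutant] - table[mutation.wild]
        for name, table in scales.scales.items()
    }


# ---------------------------------------------------------------------------
# Environmental covariates


def condition_features(record: MutationRecord, variant_tag: str) -> dict[str, float]:
    """pH and/or wild-type Tm columns, per dataset variant."""
    if variant_tag == "common":
        return {}
    if variant_tag == "tm":
        if record.condition.tm_wild is None:
            raise FeatureExtractionError("missing_condition", f"{record.key}: no Tm")
        return {"tm": record.condition.tm_wild}
    if variant_tag == "ph_tm":
        if record.condition.ph is None or record.condition.tm_wild is None:
            raise FeatureExtractionError(
                "missing_condition", f"{record.key}: needs both pH and Tm"
            )
        return {"ph": record.condition.ph, "tm": record.condition.tm_wild}
    raise ValueError(f"unknown variant tag {variant_tag!r}")


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class ExtractionConfig:
    """Which extractors run and how missing resources are handled.

    ``pssm_policy``: ``drop`` (exclude the record) or ``fallback``
    (synthesize a substitution-matrix PSSM).  ``sift_policy``: ``drop``
    or ``impute`` (neutral values).
    """

    aaindex: bool = True
    neighborhood: bool = True
    grouping: bool = True
    pssm: bool = True
    physicochemical: bool = True
    sift: bool = True
    scales: bool = True
    conditions: bool = True
    variant_tag: str = "common"
    pssm_policy: str = "drop"
    pssm_fallback_matrix: str = "BLOSUM62"
    sift_policy: str = "drop"


def extract_traditional(
    proteins: Mapping[str, ProteinRecord],
    records: Sequence[MutationRecord],
    config: ExtractionConfig | None = None,
    *,
    aaindex_entries: Sequence[AAindexEntry] = (),
    scales: ScaleSet | None = None,
    pssms: Mapping[str, PSSM] | None = None,
    sift_map: Mapping[tuple[str, str], SiftRecord] | None = None,
) -> tuple[FeatureTable, Counter]:
    """Run the enabled extractors over *records*.

    Returns the assembled FeatureTable plus a counter of dropped
    records by reason.  Records sharing a record id (exact duplicates)
    keep the first occurrence.
    """
    config = config or ExtractionConfig()
    rows: dict[str, dict[str, float]] = {}
    drops: Counter = Counter()
    prov: dict[str, dict] = {}
    pssm_cache: dict[str, PSSM] = dict(pssms or {})
    for record in records:
        protein = proteins.get(record.protein_id)
        if protein is None:
            drops["no_sequence"] += 1
            continue
        try:
            bind_and_validate(protein, record.mutation)
            row: dict[str, float] = {}

            def _add(cols: dict[str, float], extractor: str, **params) -> None:
                row.update(cols)
                for c in cols:
                    if c not in prov:
                        prov[c] = {"extractor": extractor, **params}

            if config.conditions:
                _add(
                    condition_features(record, config.variant_tag),
                    "condition",
                    variant=config.variant_tag,
                )
            if config.aaindex and aaindex_entries:
                _add(aaindex_features(record.mutation, aaindex_entries), "aaindex")
            if config.neighborhood:
                _add(
                    neighborhood_features(protein, record.mutation),
                    "neighborhood",
                    window=NEIGHBORHOOD_WINDOW,
                )
            if config.grouping:
                _add(grouping_features(record.mutation), "grouping")
            if config.pssm:
                pssm = pssm_cache.get(record.protein_id)
                if pssm is None:
                    if config.pssm_policy == "fallback":
                        pssm = fallback_pssm(protein, config.pssm_fallback_matrix)
                        pssm_cache[record.protein_id] = pssm
                    else:
                        raise FeatureExtractionError(
                            "no_pssm", f"no PSSM for {record.protein_id}"
                        )
                _add(
                    pssm_features(protein, pssm),
                    "pssm",
                    provenance=pssm.provenance,
                    sections=PSSM_SECTIONS,
                )
            if config.physicochemical:
                _add(physicochemical_features(protein), "physicochemical")
            if config.sift:
                _add(
                    sift_features(record, sift_map or {}, policy=config.sift_policy),
                    "sift",
                    policy=config.sift_policy,
                )
            if config.scales and scales is not None:
                _add(scale_features(record.mutation, scales), "scales")
        except FeatureExtractionError as exc:
            drops[exc.reason] += 1
            continue
        except ThermoshiftError:
            drops["sequence_mismatch"] += 1
            continue
        if record.record_id in rows:
            drops["duplicate_record_id"] += 1
            continue
        rows[record.record_id] = row
    if not rows:
        return FeatureTable.from_rows({}), drops
    return FeatureTable.from_rows(rows, prov), drops
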