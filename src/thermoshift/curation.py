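"""Dataset curation: cleaning, merging and environment variants.

Raw per-source mutation tables are cleaned (unparseable mutations,
missing labels, sequence mismatches and duplicates dropped with
per-reason counts), merged across sources (cross-source duplicates
averaged), and materialized into three dataset variants:

``common``
    Environmental conditions discarded; replicate measurements of the
    same (protein, mutation) under different conditions are averaged
    into a single labelled record.
``tm``
    Only records with a wild-type melting temperature; pH stripped.
``ph_tm``
    Only records carrying both pH and wild-type Tm.

Train/test splitting is keyed on (protein, mutation) so condition-level
replicates of one variant never straddle the split.
"""

from __future__ import annotations

import statistics
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    Condition,
    MutationRecord,
    ProteinRecord,
    ThermoshiftError,
    bind_and_validate,
)
from .dataio import row_to_record

VARIANT_TAGS = ("common", "tm", "ph_tm")

#: pH and Tm are compared at 1 decimal place when collapsing duplicates
#: (the printed precision of typical source tables).
_COND_DECIMALS = 1


@dataclass
class DatasetVariant:
    """One environment variant of the curated dataset."""

    tag: str
    records: list[MutationRecord]
    provenance: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        if self.tag not in VARIANT_TAGS:
            raise ValueError(f"unknown variant tag {self.tag!r}")
        _check_variant_invariants(self.tag, self.records)


def _check_variant_invariants(tag: str, records: Sequence[MutationRecord]) -> None:
    if tag == "common":
        keys = [r.key for r in records]
        if len(keys) != len(set(keys)):
            raise ValueError("common variant has duplicate (protein, mutation) keys")
        for r in records:
            if r.condition.ph is not None or r.condition.tm_wild is not None:
                raise ValueError("common variant records must carry no conditions")
    elif tag == "tm":
        if any(r.condition.tm_wild is None for r in records):
            raise ValueError("tm variant records must carry tm_wild")
    elif tag == "ph_tm":
        if any(
            r.condition.tm_wild is None or r.condition.ph is None for r in records
        ):
            raise ValueError("ph_tm variant records must carry both ph and tm_wild")


def _cond_key(r: MutationRecord) -> tuple:
    ph = r.condition.ph
    tm = r.condition.tm_wild
    return (
        r.protein_id,
        str(r.mutation),
        None if ph is None else round(ph, _COND_DECIMALS),
        None if tm is None else round(tm, _COND_DECIMALS),
    )


def clean_source(
    rows: Iterable[Mapping[str, str] | MutationRecord],
    proteins: Mapping[str, ProteinRecord],
    require_conditions: Sequence[str] = (),
) -> tuple[list[MutationRecord], Counter]:
    """Clean one raw source table.

    Drops rows that fail any of: parseable single missense mutation;
    finite dTm label present; sequence available with matching wild
    residue; required condition fields (``"ph"``/``"tm"``) present.
    Exact duplicates (same protein, mutation, pH, Tm, dTm) collapse to
    one.  Returns the surviving records and a per-reason drop counter.
    """
    kept: list[MutationRecord] = []
    reasons: Counter = Counter()
    seen: set[tuple] = set()
    for row in rows:
        if isinstance(row, MutationRecord):
            rec = row
        else:
            try:
                rec = row_to_record(row)
            except (ThermoshiftError, ValueError, KeyError):
                reasons["unparseable"] += 1
                continue
        if rec.delta_tm is None:
            reasons["no_label"] += 1
            continue
        protein = proteins.get(rec.protein_id)
        if protein is None:
            reasons["no_sequence"] += 1
            continue
        try:
            bind_and_validate(protein, rec.mutation)
        except ThermoshiftError:
            reasons["sequence_mismatch"] += 1
            continue
        if "ph" in require_conditions and rec.condition.ph is None:
            reasons["missing_condition"] += 1
            continue
        if "tm" in require_conditions and rec.condition.tm_wild is None:
            reasons["missing_condition"] += 1
            continue
        dup_key = _cond_key(rec) + (round(rec.delta_tm, _COND_DECIMALS),)
        if dup_key in seen:
            reasons["duplicate"] += 1
            continue
        seen.add(dup_key)
        kept.append(rec)
    return kept, reasons


def merge_sources(tables: Sequence[Sequence[MutationRecord]]) -> list[MutationRecord]:
    """Union cleaned source tables, collapsing cross-source duplicates.

    Records sharing (protein, mutation, pH, Tm) are merged into one
    with the mean dTm and concatenated source tags; otherwise the union
    preserves input order.
    """
    groups: dict[tuple, list[MutationRecord]] = defaultdict(list)
    order: list[tuple] = []
    for table in tables:
        for rec in table:
            key = _cond_key(rec)
            if key not in groups:
                order.append(key)
            groups[key].append(rec)
    merged: list[MutationRecord] = []
    for key in order:
        recs = groups[key]
        first = recs[0]
        if len(recs) == 1:
            merged.append(first)
            continue
        sources = []
        for r in recs:
            for tag in r.source.split("+"):
                if tag and tag not in sources:
                    sources.append(tag)
        merged.append(
            MutationRecord(
                protein_id=first.protein_id,
                mutation=first.mutation,
                condition=first.condition,
                delta_tm=float(np.mean([r.delta_tm for r in recs])),
                source="+".join(sources),
            )
        )
    return merged


def make_variant(
    records: Sequence[MutationRecord], tag: str, stat: str = "mean"
) -> DatasetVariant:
    """Materialize one environment variant from a merged table.

    ``common`` groups by (protein, mutation), aggregates dTm across
    conditions (arithmetic mean by default, median via ``stat``) and
    strips conditions.  ``tm`` keeps rows with Tm and strips pH;
    ``ph_tm`` keeps rows with both conditions.
    """
    if tag not in VARIANT_TAGS:
        raise ValueError(f"unknown variant tag {tag!r}")
    if stat not in ("mean", "median"):
        raise ValueError(f"unknown aggregation stat {stat!r}")
    agg = statistics.mean if stat == "mean" else statistics.median
    out: list[MutationRecord] = []
    if tag == "common":
        groups: dict[tuple, list[MutationRecord]] = defaultdict(list)
        order: list[tuple] = []
        for rec in records:
            if rec.key not in groups:
                order.append(rec.key)
            groups[rec.key].append(rec)
        for key in order:
            recs = groups[key]
            sources = []
            for r in recs:
                for t in r.source.split("+"):
                    if t and t not in sources:
                        sources.append(t)
            out.append(
                MutationRecord(
                    protein_id=recs[0].protein_id,
                    mutation=recs[0].mutation,
                    condition=Condition(),
                    delta_tm=float(agg([r.delta_tm for r in recs])),
                    source="+".join(sources),
                )
            )
    elif tag == "tm":
        for rec in records:
            if rec.condition.tm_wild is None:
                continue
            out.append(
                MutationRecord(
                    protein_id=rec.protein_id,
                    mutation=rec.mutation,
                    condition=Condition(tm_wild=rec.condition.tm_wild),
                    delta_tm=rec.delta_tm,
                    source=rec.source,
                )
            )
    else:  # ph_tm
        for rec in records:
            if rec.condition.tm_wild is None or rec.condition.ph is None:
                continue
            out.append(rec)
    provenance: Counter = Counter()
    for rec in out:
        for t in rec.source.split("+"):
            provenance[t or "unknown"] += 1
    return DatasetVariant(tag, out, provenance)


def split_train_test(
    variant: DatasetVariant, fraction: float, seed: int
) -> tuple[list[MutationRecord], list[MutationRecord]]:
    """Split a variant at the (protein, mutation) key level.

    All condition rows of one key land in the same partition, so a
    variant measured under several conditions can never leak across
    the split.  Reproducible under *seed*.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    keys = []
    seen: set[tuple] = set()
    for rec in variant.records:
        if rec.key not in seen:
            seen.add(rec.key)
            keys.append(rec.key)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(keys))
    n_test = int(round(fraction * len(keys)))
    test_keys = {keys[i] for i in perm[:n_test]}
    train = [r for r in variant.records if r.key not in test_keys]
    test = [r for r in variant.records if r.key in test_keys]
    return train, test


def curation_report(
    per_source_reasons: Mapping[str, Counter],
    variants: Mapping[str, DatasetVariant],
) -> dict:
    """JSON-serializable summary: drop counts per reason per source and
    record counts per variant."""
    return {
        "drops": {src: dict(cnt) for src, cnt in per_source_reasons.items()},
        "variants": {
            tag: {"n_records": len(v.records), "provenance": dict(v.provenance)}
            for tag, v in variants.items()
        },
    }
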