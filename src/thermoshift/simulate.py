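"""Synthetic datasets with the statistical structure the pipeline assumes.

Sequences are i.i.d. uniform over the 20 canonical residues; single
missense mutations are sampled uniformly over positions; each
(protein, mutation) variant receives one to several environmental
conditions on a Table-like grid (pH in steps of 0.5, wild-type Tm
increasing with pH); labels are a known sparse linear function of
deterministically computable record features plus Gaussian noise:

    dTm = sum_j w_j f_j(record) + eps,   eps ~ N(0, sd^2)

The effect features are restricted to quantities the extractors also
compute (hydropathy difference, charge-group change, hydrophobic
neighborhood fraction, pH, Tm and a pH x Tm interaction), so a model
trained on extracted features can in principle recover the signal.
The truth manifest records the weights, per-record noiseless labels
and the seed.

Noise is drawn from per-record streams keyed by (seed, protein,
mutation, condition), making label generation invariant to record
order.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .core import (
    CANONICAL_AA,
    Condition,
    Mutation,
    MutationRecord,
    ProteinRecord,
)
from .dataio import (
    SiftRecord,
    default_scales,
    fallback_pssm,
    write_ascii_pssm,
    write_fasta,
    write_mutation_table,
    write_sift_output,
)

_HYDROPHOBIC = set("VILFMWYC")
_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.5}


def _kd() -> dict[str, float]:
    return default_scales().scales["hydropathy_kyte_doolittle"]


def _hydropathy_delta(protein, mutation, condition) -> float:
    kd = _kd()
    return kd[mutation.mutant] - kd[mutation.wild]


def _charge_delta(protein, mutation, condition) -> float:
    return _CHARGE.get(mutation.mutant, 0.0) - _CHARGE.get(mutation.wild, 0.0)


def _neigh_hydrophobic_frac(protein, mutation, condition) -> float:
    lo = max(1, mutation.position - 12)
    hi = min(len(protein), mutation.position + 12)
    window = protein.sequence[lo - 1 : hi]
    return sum(res in _HYDROPHOBIC for res in window) / len(window)


def _ph_centered(protein, mutation, condition) -> float:
    return 0.0 if condition.ph is None else condition.ph - 7.0


def _tm_centered(protein, mutation, condition) -> float:
    return 0.0 if condition.tm_wild is None else condition.tm_wild - 65.0


def _ph_tm_interaction(protein, mutation, condition) -> float:
    return _ph_centered(protein, mutation, condition) * _tm_centered(
        protein, mutation, condition
    )


#: Deterministically computable effect features the labels may load on.
EFFECT_FEATURES: dict[str, Callable] = {
    "hydropathy_delta": _hydropathy_delta,
    "charge_delta": _charge_delta,
    "neigh_hydrophobic_frac": _neigh_hydrophobic_frac,
    "ph_centered": _ph_centered,
    "tm_centered": _tm_centered,
    "ph_tm_interaction": _ph_tm_interaction,
}

#: Environment-dependent effect model: labels load on sequence features
#: and on pH/Tm, so the same variant shifts across conditions.
ENV_WEIGHTS: dict[str, float] = {
    "hydropathy_delta": -0.6,
    "charge_delta": 1.2,
    "neigh_hydrophobic_frac": 3.0,
    "ph_centered": 1.0,
    "tm_centered": -0.25,
    "ph_tm_interaction": 0.02,
}

#: Sequence-only effect model: conditions carry no signal.
SEQ_WEIGHTS: dict[str, float] = {
    "hydropathy_delta": -1.2,
    "charge_delta": 1.8,
    "neigh_hydrophobic_frac": 5.0,
}

#: Pure-noise model.
NULL_WEIGHTS: dict[str, float] = {}


@dataclass
class SyntheticSpec:
    """Study conditions of the generator.

    Defaults mimic a curated thermostability table at desk scale: 200
    random proteins of 60-250 residues, 10 variants each, 1-5
    measurement conditions per variant on a pH 2-9 grid in 0.5 steps
    with wild-type Tm rising with pH, and 2 degC Gaussian label noise.
    """

    n_proteins: int = 200
    length_min: int = 60
    length_max: int = 250
    mutations_per_protein: int = 10
    conditions_min: int = 1
    conditions_max: int = 5
    ph_min: float = 2.0
    ph_max: float = 9.0
    ph_step: float = 0.5
    tm_min: float = 35.0
    tm_max: float = 95.0
    weights: dict[str, float] = field(default_factory=lambda: dict(ENV_WEIGHTS))
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_min < 1 or self.length_max < self.length_min:
            raise ValueError("empty sequence-length range")
        if self.conditions_min < 1 or self.conditions_max < self.conditions_min:
            raise ValueError("empty conditions range")
        if self.ph_max < self.ph_min or self.tm_max < self.tm_min:
            raise ValueError("empty condition grid")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")
        unknown = set(self.weights) - set(EFFECT_FEATURES)
        if unknown:
            raise ValueError(f"unknown effect features {sorted(unknown)}")


@dataclass
class SyntheticDataset:
    """Generated proteins, labelled records and the truth manifest."""

    proteins: list[ProteinRecord]
    records: list[MutationRecord]
    truth: dict

    @property
    def protein_map(self) -> dict[str, ProteinRecord]:
        return {p.id: p for p in self.proteins}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "proteins.fasta", self.proteins)
        write_mutation_table(outdir / "mutations.tsv", self.records)
        (outdir / "truth.json").write_text(
            json.dumps(self.truth, indent=1, sort_keys=True)
        )


def _record_rng(seed: int, pid: str, mut: str, ph: float, tm: float) -> np.random.Generator:
    key = f"{seed}|{pid}|{mut}|{ph:.1f}|{tm:.1f}"
    return np.random.default_rng(zlib.crc32(key.encode()) & 0x7FFFFFFF)


def effect_value(
    protein: ProteinRecord,
    mutation: Mutation,
    condition: Condition,
    weights: dict[str, float],
) -> float:
    """Noiseless label under the given effect model."""
    return sum(
        w * EFFECT_FEATURES[name](protein, mutation, condition)
        for name, w in weights.items()
    )


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a dataset under *spec*; byte-identical under one seed."""
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(CANONICAL_AA))
    ph_grid = np.round(
        np.arange(spec.ph_min, spec.ph_max + 1e-9, spec.ph_step), 1
    )
    proteins: list[ProteinRecord] = []
    records: list[MutationRecord] = []
    noiseless: dict[str, float] = {}
    for p in range(spec.n_proteins):
        length = int(rng.integers(spec.length_min, spec.length_max + 1))
        seq = "".join(rng.choice(aa, size=length))
        protein = ProteinRecord(f"SYN{p:04d}", seq)
        proteins.append(protein)
        # wild-type melting behavior: Tm rises with pH (Table-2-like)
        tm_mid = float(rng.uniform(spec.tm_min + 10, spec.tm_max - 10))
        tm_slope = float(rng.uniform(2.0, 4.0))
        n_mut = min(spec.mutations_per_protein, length)
        positions = rng.choice(length, size=n_mut, replace=False) + 1
        for pos in sorted(int(x) for x in positions):
            wild = seq[pos - 1]
            mutant = str(rng.choice([a for a in CANONICAL_AA if a != wild]))
            mutation = Mutation(wild, pos, mutant)
            k = int(rng.integers(spec.conditions_min, spec.conditions_max + 1))
            k = min(k, len(ph_grid))
            start = int(rng.integers(0, len(ph_grid) - k + 1))
            for ph in ph_grid[start : start + k]:
                ph = float(ph)
                tm = float(
                    np.clip(tm_mid + tm_slope * (ph - 5.5), 5.0, 120.0)
                )
                condition = Condition(ph=ph, tm_wild=round(tm, 1))
                clean = effect_value(protein, mutation, condition, spec.weights)
                eps = 0.0
                if spec.noise_sd > 0:
                    eps = float(
                        _record_rng(spec.seed, protein.id, str(mutation), ph, tm)
                        .normal(0.0, spec.noise_sd)
                    )
                record = MutationRecord(
                    protein_id=protein.id,
                    mutation=mutation,
                    condition=condition,
                    delta_tm=round(clean + eps, 4),
                    source="synthetic",
                )
                records.append(record)
                noiseless[record.record_id] = round(clean, 6)
    truth = {
        "seed": spec.seed,
        "weights": dict(spec.weights),
        "noise_sd": spec.noise_sd,
        "spec": {k: v for k, v in asdict(spec).items() if k != "weights"},
        "noiseless": noiseless,
    }
    return SyntheticDataset(proteins, records, truth)


# ---------------------------------------------------------------------------
# Abstract selection fixture (informative + noise columns)


def make_selection_fixture(
    seed: int,
    n_rows: int = 500,
    n_informative: int = 5,
    n_noise: int = 45,
    noise_sd: float = 0.5,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Feature-selection benchmark: standard-normal columns of which
    only the first *n_informative* carry signal.

    Returns (X, y, informative column names); coefficients alternate
    in sign with magnitudes 1..n_informative.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_rows, n_informative + n_noise))
    coefs = np.array(
        [(i + 1) * (1 if i % 2 == 0 else -1) for i in range(n_informative)],
        dtype=float,
    )
    y = X[:, :n_informative] @ coefs + rng.normal(0.0, noise_sd, size=n_rows)
    names = [f"inf_{i:02d}" for i in range(n_informative)] + [
        f"noise_{i:02d}" for i in range(n_noise)
    ]
    return pd.DataFrame(X, columns=names), y, names[:n_informative]


# ---------------------------------------------------------------------------
# Fixture suite


def make_fixture_suite(outdir: str | Path) -> None:
    """Write the small deterministic fixture tree used across tests:
    bundled AAindex copies, toy PSSMs, a synthetic SIFT table and three
    canned datasets (null, environment-dependent, sequence-dependent).
    Running twice produces identical trees.
    """
    from importlib import resources

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pkg = resources.files("thermoshift.data")
    for fname in (
        "aaindex1_fixture.txt",
        "aaindex2_synthetic.txt",
        "aaindex3_synthetic.txt",
    ):
        (outdir / fname).write_text((pkg / fname).read_text())
    small = dict(
        n_proteins=20, mutations_per_protein=5, length_min=40, length_max=120
    )
    datasets = {
        "null": SyntheticSpec(weights=dict(NULL_WEIGHTS), seed=101, **small),
        "env": SyntheticSpec(weights=dict(ENV_WEIGHTS), seed=102, **small),
        "seq": SyntheticSpec(weights=dict(SEQ_WEIGHTS), seed=103, **small),
    }
    generated = {name: generate(spec) for name, spec in datasets.items()}
    for name, ds in generated.items():
        ds.write(outdir / name)
    pssm_dir = outdir / "pssms"
    pssm_dir.mkdir(exist_ok=True)
    for protein in generated["seq"].proteins[:2]:
        write_ascii_pssm(pssm_dir / f"{protein.id}.pssm", fallback_pssm(protein))
    sift = {}
    for record in generated["seq"].records[:40]:
        r = _record_rng(7, record.protein_id, str(record.mutation), 0.0, 0.0)
        sift[record.key] = SiftRecord(
            sift_score=round(float(r.uniform(0, 1)), 3),
            sift_median=round(float(r.uniform(2.5, 4.5)), 2),
            num_seq=int(r.integers(10, 400)),
        )
    write_sift_output(outdir / "sift.tsv", sift)
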